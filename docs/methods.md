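# Methods

This note documents the models implemented in `ppiboost`, the conventions
and numerical choices behind them, what the synthetic benchmark does and
does not emulate, and the package's known limitations.

## Encoders

All four encoders are deterministic functions of the sequence (and, for
PsePSSM, the profile). Property values are standardized to population mean
0 / SD 1 over the 20 amino acids (divisor 20); the wildcard residue X takes
the post-normalization mean (0) for every property and is excluded from
composition counts and denominators, so every encoder remains well defined
on sequences containing unknown residues without inventing chemistry for
them.

**PseAAC** is Chou's type-1 construction with the classical property triple
(hydrophobicity, hydrophilicity, side-chain mass). The correlation function
Θ(a,b) is the mean of squared standardized-property differences; the k-th
order factor averages Θ over all position pairs at distance k. Composition
counts and weighted factors share one normalizer, so the 20+λ components
are non-negative and sum to 1 (a property test asserts this to 1e-9). The
weight factor w defaults to 0.05, the value conventional for this encoding;
λ defaults to 11. A sequence must be longer than λ.

**PsePSSM** standardizes each PSSM row across its 20 scores (population
SD). A zero-variance row — possible in synthetic or degenerate profiles —
maps to an all-zero row rather than dividing by zero. The first 20 features
are column means of the standardized profile; the 20·ξ lag features are
mean squared differences between scores g positions apart (g = 1..ξ,
ξ default 9). When a protein has no PSSM, a pseudo-profile is built from
the BLOSUM62 row of each residue so the pipeline runs end to end; the
fallback is logged once per run and carries no evolutionary information
beyond residue identity.

**RSIV** realizes the 120 + 77 split as: six standardized physicochemical
indices (the seven-property set minus net charge index) times residue
frequency (6×20 = 120); then, over the seven conjoint-triad classes
{A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}: 7 class
frequencies, 49 ordered adjacent class-dipeptide frequencies and 21
unordered distinct-class transition frequencies, the latter two divided by
L−1. Dipeptide positions involving X are skipped while the L−1 denominator
is kept, a deliberate convention so feature scales do not jump when a
single unknown residue appears.

**Autocorrelation descriptors** use the seven-property set of the
autocovariance literature (hydrophobicity, hydrophilicity, side-chain
volume, polarity, polarizability, solvent-accessible surface area, net
charge index). For the standardized signal P′ with mean P̄ at lag d:
Moreau–Broto is the raw lagged product mean; Moran is the lagged
autocovariance over the 1/L-normalized variance; Geary is half the mean
lagged squared difference over the 1/(L−1)-normalized variance. A signal
with zero variance (homopolymers) yields Moran = Geary = 0 by convention;
"zero variance" is detected relative to the signal's scale (sum of squared
deviations ≤ 1e-20 × max(1, ‖P′‖²)) because an exactly constant signal can
acquire ~1e-31 of rounding noise and would otherwise produce a spurious
ratio of two negligible quantities.

Every encoder is pinned against an independent literal-summation
implementation (plain Python loops and dictionaries, no shared code) on 100
random sequences of length 12–60, with max absolute difference below
1e-10.

## Feature selection

The L1-penalized logistic objective is solved by LIBLINEAR coordinate
descent (scikit-learn's `liblinear` solver), whose parameterization —
penalty term unscaled, data term scaled by C — matches the objective stated
above, so larger C keeps more features. Support extraction uses
`|ω_j| > 1e-8`: solvers return float dust rather than exact zeros, and this
tolerance separates true sparsity from noise without discarding genuinely
small coefficients. Features enter selection exactly as encoded (no
per-column rescaling) by default; a `standardize` flag exists for users who
want scale-free selection. Correctness is checked against the subgradient
optimality conditions of the objective (|C·∂loss/∂ω_j| ≤ 1 on the inactive
set, vanishing total subgradient on the active set, tolerance 1e-3).

Projection onto an empty support is refused with an error rather than
emitting a zero-column matrix; cross-validation fits the selector on the
training fold only, and a test asserts the selected supports differ across
folds (a leakage sentinel).

## Classification

Gradient tree boosting minimizes the binomial deviance stagewise: the
initial score is the prior log-odds, each depth-limited regression tree is
fitted to the deviance residuals y − p, and the line-search step is
realized by the standard per-leaf one-step Newton value
Σ(residual)/Σ p(1−p), scaled by the learning rate. The implementation is
scikit-learn's `GradientBoostingClassifier`; a single-iteration test pins
it against a literal implementation of exactly this recursion (exhaustive
stump search on an 8-point dataset, agreement to 1e-10), and the staged
training deviance is asserted non-increasing. Defaults: M = 1000
iterations, learning rate 0.1, depth 3, no subsampling, no early stopping.
M and the loss are the pipeline's specified configuration; learning rate
and depth are the conventional companions of this family and are exposed in
the config.

## Evaluation

Recall, precision, ACC and MCC come from the confusion counts at the 0.5
threshold (configurable). Zero-denominator ratios are reported as 0 with a
warning flag instead of NaN so reports serialize cleanly. ROC uses the
tie-grouped descending-score sweep and trapezoidal area; the PR area uses
the step-wise (right-continuous) rule, which avoids the optimistic bias of
trapezoidal interpolation on PR axes. AUROC is verified against
brute-force Mann–Whitney pair counting.

Cross-validation stratifies over pairs (default k = 5). Splitting is over
pairs, not proteins: a protein may appear on both sides of a split. This
matches the common benchmark protocol for this task and is a known
benchmark-design caveat, documented rather than silently "fixed". Fold
seeds derive deterministically from the master seed via a seed sequence;
identical inputs and seed reproduce every metric exactly. The aggregate
report carries per-fold metrics with mean ± SD, plus pooled held-out curves
across folds.

## Synthetic benchmark

The generator emulates the *shape* of a PPI benchmark, not its biology:
each protein draws a 20-letter composition bias from a symmetric
Dirichlet(0.5) and its residues i.i.d. from that bias; pseudo-PSSMs are
BLOSUM62 rows plus integer noise in [−2, 2]; pairs are sampled without
replacement. The latent interaction score is

    score = signal · σ_ε · z(cos(b_a, b_b)) + ε,   ε ~ Logistic(0, 1),

with z the pool-standardized cosine similarity of the two bias vectors and
σ_ε = π/√3 the logistic SD, so `signal` is a dimensionless effect size
(planted-signal SD in noise-SD units). Labels are score > pool median,
the positive fraction is enforced exactly by stratified subsampling, and
`noise_flip` (default 0.05) labels are flipped. Defaults: 120 proteins of
length 50–200, 400 pairs, balanced classes, signal 2.0.

What this does and does not show: the signal is planted in *composition
similarity*, reachable in principle through the composition-bearing feature
blocks (PseAAC, RSIV), so encoder ablations order predictably and a
signal-free generator yields chance-level downstream AUROC. But a pure
similarity signal has, by partner symmetry, no per-feature main effects:
linear L1 selection cannot rank the informative columns, and small boosted
trees must discover a 20-way symmetric interaction between the two halves
of the concatenated pair vector. At the default effect size and sample
size, even an oracle using the true bias cosine tops out near 0.90 AUROC
(the unit logistic noise plus 5% flips bound it), the empirical-composition
cosine reaches ≈0.85, and the full pipeline recovers substantially less.
Passing tests on this benchmark therefore demonstrate correctness,
determinism and null-calibration of the pipeline — not the predictive
performance attainable on real interaction data, where discriminative
signal is carried by main effects of evolutionary-profile features that
this generator deliberately does not emulate.

Problem sizes used in the test suite (chosen to keep the full run short
while leaving every contract observable): unit tests use 8–80 proteins and
10–80 pairs; the learnability checks use the full default benchmark (400
pairs) with M = 200 boosting iterations; the end-to-end determinism check
uses 20 proteins, 50 pairs, M = 30.

## Design choices

* Pairs are encoded in table order (A then B) without canonicalization; a
  `mirror` flag can append (B, A) duplicates at training time, off by
  default.
* FASTA parsing is lenient by default (B, Z, U, O, J, `*` → X, logged);
  strict mode errors with the offending position. Characters outside both
  sets always error.
* Pair labels accept `1`/`0` and `+1`/`−1` (`−1` → 0), since both
  conventions occur in published benchmark files.
* PSSMs are treated as given inputs (the package never runs the profile
  search itself); association with sequences is by exact id, and a missing
  PSSM falls back to the logged pseudo-profile, never a silent default.
* Model files embed a schema-version string and are refused on mismatch.
* The pipeline manifest records the config hash and SHA-256 of every
  artifact; `verify_artifacts` detects post-hoc tampering.

## Limitations

* Encoder internals follow the canonical constructions of each family and
  are pinned by their dimensional contracts (31/200/197/231/659/1318); other
  realizations of the same families (different property sets, different
  reduced alphabets) would produce different feature values at the same
  dimensions.
* The synthetic benchmark's similarity-planted signal is adversarial to
  this pipeline's linear selection stage by construction (see above); it is
  a correctness harness, not a performance benchmark.
* No hyperparameter search is provided beyond the exposed configuration;
  comparator selectors and classifiers are out of scope.
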
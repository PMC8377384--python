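"""Per-protein sequence feature encoders and their fusion.

Four encoders map a protein sequence (plus, for PsePSSM, its evolutionary
profile) to fixed-length numeric vectors:

* **PseAAC** — type-1 pseudo amino acid composition: 20 composition terms
  plus ``lambda`` sequence-order correlation factors, jointly normalized to
  sum to 1 (default ``lambda=11`` → 31 features).
* **PsePSSM** — column means of the per-row standardized PSSM plus lagged
  squared-difference profile terms (default ``xi=9`` → 20 + 20×9 = 200).
* **RSIV** — reduced sequence and index vectors: six physicochemical indices
  weighted by residue frequency (6×20 = 120) plus reduced-alphabet sequence
  statistics over the seven conjoint-triad classes (7 + 49 + 21 = 77),
  197 features in total.
* **AD** — Moreau-Broto, Moran and Geary autocorrelation of seven
  physicochemical property signals at lags 1..``lag`` (default ``lag=11`` →
  3×7×11 = 231).

Fusing all four yields the 659-dimensional per-protein vector; concatenating
the two proteins of a pair yields the 1318-dimensional classifier input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .properties import (
    AD_PROPERTIES,
    RSIV_PROPERTIES,
    physicochemical_properties,
    pseaac_properties,
    rsiv_properties,
)
from .seqio import (
    AMINO_ACIDS,
    PSSM_ALPHABET,
    WILDCARD,
    PSSMatrix,
    PairRecord,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

#: Conjoint-triad seven-class reduced amino-acid alphabet.
REDUCED_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

_CLASS_OF = {aa: idx for idx, group in enumerate(REDUCED_CLASSES) for aa in group}


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the four encoders.

    lam : PseAAC sequence-order rank (λ), default 11.
    xi : PsePSSM profile lag (ξ), default 9.
    lag : maximum autocorrelation lag, default 11.
    w : PseAAC weight factor in (0, 1], default 0.05.

    Every encoded sequence must be longer than each of lam, xi and lag.
    """

    lam: int = 11
    xi: int = 9
    lag: int = 11
    w: float = 0.05

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.xi < 0:
            raise ValueError("xi must be >= 0")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if not 0 < self.w <= 1:
            raise ValueError("w must be in (0, 1]")

    @property
    def n_features(self) -> int:
        """Fused per-protein dimensionality implied by this configuration."""
        return (20 + self.lam) + (20 + 20 * self.xi) + 197 + 3 * 7 * self.lag


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length real vector with stable, unique feature names."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))
        if values.ndim != 1 or len(values) != len(self.names):
            raise ValueError("values and names must be equal-length 1-D")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature vector contains non-finite entries")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names are not unique")

    def __len__(self) -> int:
        return len(self.values)

    @staticmethod
    def concat(parts: Iterable["FeatureVector"]) -> "FeatureVector":
        parts = list(parts)
        return FeatureVector(
            np.concatenate([p.values for p in parts]),
            tuple(n for p in parts for n in p.names),
        )


def _residue_counts(sequence: str) -> np.ndarray:
    """Counts of the 20 standard residues; the wildcard X is excluded."""
    counts = np.zeros(20)
    for r in sequence:
        if r != WILDCARD:
            counts[AMINO_ACIDS.index(r)] += 1
    return counts


# ---------------------------------------------------------------------------
# PseAAC
# ---------------------------------------------------------------------------

def encode_pseaac(protein: ProteinRecord, config: EncoderConfig = EncoderConfig()) -> FeatureVector:
    """Type-1 pseudo amino acid composition (20 + λ features, sum 1).

    The k-th sequence-order factor is the average over positions of the
    squared-difference correlation Θ(R_i, R_{i+k}), where Θ is the mean of
    squared differences of the three standardized PseAAC properties between
    two residues. Composition counts f_u and the weighted factors w·θ_k share
    the normalizer Σf + w·Σθ, so all 20+λ components sum to 1.
    """
    seq = protein.sequence
    L = len(seq)
    lam, w = config.lam, config.w
    if L <= lam:
        raise ValueError(
            f"protein {protein.id!r}: sequence too short for lambda ({L} <= {lam})"
        )
    profiles = np.stack([t.profile(seq) for t in pseaac_properties()])  # 3 x L
    thetas = np.empty(lam)
    for k in range(1, lam + 1):
        diff = profiles[:, :-k] - profiles[:, k:]  # 3 x (L-k)
        thetas[k - 1] = np.mean(diff**2, axis=0).mean()
    counts = _residue_counts(seq)
    denom = counts.sum() + w * thetas.sum()
    if denom == 0:
        raise ValueError(f"protein {protein.id!r}: no standard residues")
    values = np.concatenate([counts, w * thetas]) / denom
    names = tuple(f"pseaac_comp_{a}" for a in AMINO_ACIDS) + tuple(
        f"pseaac_theta_{k}" for k in range(1, lam + 1)
    )
    return FeatureVector(values, names)


# ---------------------------------------------------------------------------
# PsePSSM
# ---------------------------------------------------------------------------

def encode_psepssm(
    protein: ProteinRecord,
    pssm: PSSMatrix,
    config: EncoderConfig = EncoderConfig(),
) -> FeatureVector:
    """Pseudo-PSSM features (20 + 20·ξ).

    Each PSSM row is standardized across its 20 scores (population SD;
    zero-variance rows become all-zero). The first 20 features are the column
    means of the standardized profile; the remaining 20·ξ are, for each lag
    g = 1..ξ and column j, the mean squared difference between standardized
    scores g positions apart.
    """
    L = len(protein.sequence)
    xi = config.xi
    if pssm.scores.shape[0] != L:
        raise ValueError(
            f"protein {protein.id!r}: PSSM has {pssm.scores.shape[0]} rows "
            f"but the sequence has {L} residues"
        )
    if L <= xi:
        raise ValueError(f"protein {protein.id!r}: sequence too short for xi ({L} <= {xi})")
    p = standardize_pssm_rows(pssm.scores)
    blocks = [p.mean(axis=0)]
    for g in range(1, xi + 1):
        d = p[:-g] - p[g:]
        blocks.append((d**2).mean(axis=0))
    values = np.concatenate(blocks)
    names = tuple(f"psepssm_mean_{a}" for a in PSSM_ALPHABET) + tuple(
        f"psepssm_lag{g}_{a}" for g in range(1, xi + 1) for a in PSSM_ALPHABET
    )
    return FeatureVector(values, names)


def standardize_pssm_rows(scores: np.ndarray) -> np.ndarray:
    """Standardize each PSSM row over its 20 entries; zero-variance rows → 0."""
    mu = scores.mean(axis=1, keepdims=True)
    sd = scores.std(axis=1, keepdims=True)
    out = np.zeros_like(scores, dtype=float)
    np.divide(scores - mu, sd, out=out, where=sd > 0)
    return out


# ---------------------------------------------------------------------------
# RSIV
# ---------------------------------------------------------------------------

def encode_rsiv(protein: ProteinRecord) -> FeatureVector:
    """Reduced sequence and index-vector features (120 + 77 = 197).

    Index-vector block: for each of six physicochemical properties and each
    amino acid, the standardized property value times the residue's relative
    frequency. Reduced-sequence block over the seven conjoint-triad classes:
    7 class frequencies, 49 ordered adjacent class-dipeptide frequencies and
    21 unordered distinct-class adjacent transition frequencies (dipeptide
    and transition counts divided by L−1). Wildcard residues are excluded
    from counts.
    """
    seq = protein.sequence
    L = len(seq)
    if L < 2:
        raise ValueError(f"protein {protein.id!r}: sequence too short for RSIV (L < 2)")
    counts = _residue_counts(seq)
    n_std = counts.sum()
    if n_std == 0:
        raise ValueError(f"protein {protein.id!r}: no standard residues")
    freqs = counts / n_std

    iv_values = []
    iv_names = []
    for table in rsiv_properties():
        for i, a in enumerate(AMINO_ACIDS):
            iv_values.append(table.normalized[a] * freqs[i])
            iv_names.append(f"rsiv_iv_{table.name}_{a}")

    classes = [_CLASS_OF.get(r) for r in seq]  # None for wildcard
    class_counts = np.zeros(7)
    for c in classes:
        if c is not None:
            class_counts[c] += 1
    class_freqs = class_counts / n_std

    dipep = np.zeros((7, 7))
    for c1, c2 in zip(classes, classes[1:]):
        if c1 is not None and c2 is not None:
            dipep[c1, c2] += 1
    dipep /= L - 1

    values = list(iv_values) + list(class_freqs) + list(dipep.ravel())
    names = iv_names + [f"rsiv_class_{c}" for c in range(7)] + [
        f"rsiv_dipep_{c1}_{c2}" for c1 in range(7) for c2 in range(7)
    ]
    for c1 in range(7):
        for c2 in range(c1 + 1, 7):
            values.append(dipep[c1, c2] + dipep[c2, c1])
            names.append(f"rsiv_trans_{c1}_{c2}")
    return FeatureVector(np.array(values), tuple(names))


# ---------------------------------------------------------------------------
# Autocorrelation descriptors
# ---------------------------------------------------------------------------

def encode_ad(protein: ProteinRecord, config: EncoderConfig = EncoderConfig()) -> FeatureVector:
    """Moreau-Broto, Moran and Geary autocorrelation descriptors (3·7·lag).

    For the standardized property signal P' with sequence mean P̄ and lag d:

    * Moreau-Broto: mean of P'_i · P'_{i+d} over the L−d positions.
    * Moran: lagged autocovariance of the centered signal divided by its
      (1/L-normalized) variance.
    * Geary: half the mean lagged squared difference divided by the
      (1/(L−1)-normalized) variance.

    Zero-variance signals give Moran = Geary = 0 by convention. Order of the
    output is (descriptor family, property, lag).
    """
    seq = protein.sequence
    L = len(seq)
    lag = config.lag
    if L <= lag:
        raise ValueError(f"protein {protein.id!r}: sequence too short for lag ({L} <= {lag})")
    profiles = {t.name: t.profile(seq) for t in physicochemical_properties()}

    values: list[float] = []
    names: list[str] = []
    for family in ("mba", "ma", "ga"):
        for prop in AD_PROPERTIES:
            p = profiles[prop]
            centered = p - p.mean()
            ss = float(centered @ centered)
            if ss <= 1e-20 * max(1.0, float(p @ p)):
                ss = 0.0  # constant signal up to float rounding
            for d in range(1, lag + 1):
                if family == "mba":
                    v = float(p[:-d] @ p[d:]) / (L - d)
                elif family == "ma":
                    v = (
                        (float(centered[:-d] @ centered[d:]) / (L - d)) / (ss / L)
                        if ss > 0
                        else 0.0
                    )
                else:  # ga
                    diff = p[:-d] - p[d:]
                    v = (
                        (float(diff @ diff) / (2 * (L - d))) / (ss / (L - 1))
                        if ss > 0
                        else 0.0
                    )
                values.append(v)
                names.append(f"ad_{family}_{prop}_d{d}")
    return FeatureVector(np.array(values), tuple(names))


# ---------------------------------------------------------------------------
# Fusion and pairing
# ---------------------------------------------------------------------------

def encode_protein(
    protein: ProteinRecord,
    pssm: PSSMatrix,
    config: EncoderConfig = EncoderConfig(),
) -> FeatureVector:
    """Fused per-protein vector: PseAAC ∥ PsePSSM ∥ RSIV ∥ AD.

    With the default configuration (λ=11, ξ=9, lag=11) the result has
    31 + 200 + 197 + 231 = 659 features.
    """
    return FeatureVector.concat(
        [
            encode_pseaac(protein, config),
            encode_psepssm(protein, pssm, config),
            encode_rsiv(protein),
            encode_ad(protein, config),
        ]
    )


def encode_pair(vec_a: FeatureVector, vec_b: FeatureVector) -> FeatureVector:
    """Pair vector: protein-A features followed by protein-B features.

    Both proteins must have been encoded with the same configuration; with
    defaults the result has 2 × 659 = 1318 features.
    """
    if len(vec_a) != len(vec_b) or vec_a.names != vec_b.names:
        raise ValueError("per-protein vectors do not share a feature layout")
    return FeatureVector(
        np.concatenate([vec_a.values, vec_b.values]),
        tuple(f"a_{n}" for n in vec_a.names) + tuple(f"b_{n}" for n in vec_b.names),
    )


@lru_cache(maxsize=1)
def _blosum62_rows() -> dict[str, np.ndarray]:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    rows = {}
    for aa in AMINO_ACIDS + WILDCARD:
        rows[aa] = np.array([blosum[aa, b] for b in PSSM_ALPHABET], dtype=float)
    return rows


def pseudo_pssm(protein: ProteinRecord) -> PSSMatrix:
    """Substitution-matrix stand-in profile for a protein without a PSSM.

    Row i is the BLOSUM62 score row of residue R_i in PSI-BLAST column
    order, so the pipeline runs end-to-end when no profile search output is
    available. Callers log the fallback; it carries no evolutionary
    information beyond residue identity.
    """
    rows = _blosum62_rows()
    scores = np.stack([rows[r] for r in protein.sequence])
    return PSSMatrix(protein.id, scores, residues=protein.sequence)


def build_pair_features(
    proteins: Sequence[ProteinRecord],
    pssms: Mapping[str, PSSMatrix] | None,
    pairs: Sequence[PairRecord],
    config: EncoderConfig = EncoderConfig(),
    *,
    mirror: bool = False,
):
    """Encode every pair into a samples × features DataFrame plus labels.

    Per-protein vectors are computed once and reused across pairs. Proteins
    with no PSSM fall back to :func:`pseudo_pssm` (logged once, listing how
    many proteins were affected). With ``mirror=True`` the (B, A) mirror of
    each pair is appended (training-time augmentation; off by default).

    Returns ``(X, y)``: a pandas DataFrame indexed by ``id_a::id_b`` and an
    integer label array aligned with its rows.
    """
    import pandas as pd

    pssms = pssms or {}
    by_id = {p.id: p for p in proteins}
    missing = sorted({pid for pr in pairs for pid in (pr.id_a, pr.id_b)} - set(pssms))
    missing = [m for m in missing if m in by_id]
    if missing:
        logger.warning(
            "no PSSM for %d protein(s) (e.g. %s); using the BLOSUM62 pseudo-PSSM fallback",
            len(missing),
            missing[0],
        )

    per_protein: dict[str, FeatureVector] = {}

    def vector_for(pid: str) -> FeatureVector:
        if pid not in per_protein:
            if pid not in by_id:
                raise KeyError(f"unknown protein id {pid!r}")
            prot = by_id[pid]
            pssm = pssms.get(pid) or pseudo_pssm(prot)
            per_protein[pid] = encode_protein(prot, pssm, config)
        return per_protein[pid]

    work = list(pairs)
    if mirror:
        work += [PairRecord(p.id_b, p.id_a, p.label) for p in pairs]
    rows, index, labels = [], [], []
    names: tuple[str, ...] | None = None
    for pr in work:
        vec = encode_pair(vector_for(pr.id_a), vector_for(pr.id_b))
        if names is None:
            names = vec.names
        rows.append(vec.values)
        index.append(f"{pr.id_a}::{pr.id_b}")
        labels.append(pr.label)
    X = pd.DataFrame(np.array(rows), index=index, columns=list(names or ()))
    return X, np.array(labels, dtype=int)
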
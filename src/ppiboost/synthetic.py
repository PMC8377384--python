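"""Synthetic proteins, profiles and labelled pair datasets.

Every pipeline stage is testable without downloads: the generator emits
random protein sequences over the 20-letter alphabet, pseudo-PSSM files in
the PSI-BLAST ASCII layout, and interaction labels carrying a plantable
composition-similarity signal.

Generative model
----------------
Each protein draws a composition-bias vector from a symmetric Dirichlet and
its residues i.i.d. from that bias; its pseudo-PSSM is the BLOSUM62 row of
each residue plus small integer noise. Candidate pairs are sampled without
replacement; the latent interaction score is

    score = signal · σ_ε · z(cos(b_a, b_b)) + ε,     ε ~ Logistic(0, 1),

where z(·) standardizes the cosine similarity of the two bias vectors over
the candidate pool and σ_ε = π/√3 is the SD of the logistic noise, so that
``signal`` reads as a dimensionless effect size (planted-signal SD in noise
SD units). Labels are 1 where the score exceeds the pool median, the
requested positive fraction is enforced by stratified subsampling, and
``noise_flip`` labels are flipped at random. Everything is reproducible from
the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .encoders import pseudo_pssm
from .seqio import (
    AMINO_ACIDS,
    PSSMatrix,
    PairRecord,
    ProteinRecord,
    write_fasta,
    write_pair_table,
    write_pssm_ascii,
)

#: Standard deviation of the unit-scale logistic noise term.
LOGISTIC_SD = float(np.pi / np.sqrt(3.0))


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    Defaults: 120 proteins of length 50-200 (long enough for every default
    encoder parameter), 400 pairs at a balanced positive fraction, effect
    size 2.0 and a 5% label-flip rate.
    """

    n_proteins: int = 120
    length_range: tuple[int, int] = (50, 200)
    n_pairs: int = 400
    positive_fraction: float = 0.5
    signal: float = 2.0
    noise_flip: float = 0.05
    seed: int = 0
    dirichlet_alpha: float = 0.5
    pssm_noise: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length_range")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.signal < 0:
            raise ValueError("signal must be >= 0")
        if not 0 <= self.noise_flip < 0.5:
            raise ValueError("noise_flip must be in [0, 0.5)")
        if self.n_proteins < 2 or self.n_pairs < 1:
            raise ValueError("need at least 2 proteins and 1 pair")


@dataclass
class SyntheticDataset:
    proteins: list[ProteinRecord]
    pssms: dict[str, PSSMatrix]
    pairs: list[PairRecord]
    bias: dict[str, np.ndarray]
    config: SynthConfig


def generate_dataset(config: SynthConfig = SynthConfig()) -> SyntheticDataset:
    """Draw a complete labelled PPI dataset from the generative model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = [f"prot{i:04d}" for i in range(n)]
    bias = rng.dirichlet(config.dirichlet_alpha * np.ones(20), size=n)
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    letters = np.array(list(AMINO_ACIDS))
    proteins = [
        ProteinRecord(pid, "".join(rng.choice(letters, size=lengths[i], p=bias[i])))
        for i, pid in enumerate(ids)
    ]
    pssms = {}
    for prot in proteins:
        base = pseudo_pssm(prot).scores
        noise = rng.integers(-config.pssm_noise, config.pssm_noise + 1, size=base.shape)
        pssms[prot.id] = PSSMatrix(prot.id, base + noise, residues=prot.sequence)

    n_distinct = n * (n - 1) // 2
    if config.n_pairs > n_distinct:
        raise ValueError(
            f"n_pairs={config.n_pairs} exceeds the {n_distinct} distinct pairs "
            f"of {n} proteins"
        )
    # candidate pool (without replacement), larger than needed so stratified
    # subsampling can enforce the positive fraction exactly
    pool_size = min(n_distinct, max(3 * config.n_pairs, config.n_pairs + 50))
    all_idx = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    pool = all_idx[rng.choice(n_distinct, size=pool_size, replace=False)]

    a, b = bias[pool[:, 0]], bias[pool[:, 1]]
    cos = np.einsum("ij,ij->i", a, b) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    )
    z = (cos - cos.mean()) / cos.std() if cos.std() > 0 else np.zeros_like(cos)
    score = config.signal * LOGISTIC_SD * z + rng.logistic(size=pool_size)
    labels = (score > np.median(score)).astype(int)

    n_pos = int(round(config.positive_fraction * config.n_pairs))
    n_neg = config.n_pairs - n_pos
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if len(pos_idx) < n_pos or len(neg_idx) < n_neg:
        raise ValueError("candidate pool too small to enforce positive_fraction")
    chosen = np.concatenate(
        [
            rng.choice(pos_idx, size=n_pos, replace=False),
            rng.choice(neg_idx, size=n_neg, replace=False),
        ]
    )
    rng.shuffle(chosen)
    flips = rng.random(config.n_pairs) < config.noise_flip
    pairs = [
        PairRecord(
            ids[pool[idx, 0]],
            ids[pool[idx, 1]],
            int(labels[idx] ^ flips[pos]),
        )
        for pos, idx in enumerate(chosen)
    ]
    return SyntheticDataset(
        proteins=proteins,
        pssms=pssms,
        pairs=pairs,
        bias={pid: bias[i] for i, pid in enumerate(ids)},
        config=config,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict:
    """Write proteins.fasta, pssm/<id>.pssm, pairs.tsv and a manifest JSON.

    Returns the manifest (config plus SHA-256 of every file written).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "pssm").mkdir(exist_ok=True)
    write_fasta(dataset.proteins, outdir / "proteins.fasta")
    for pid, pssm in sorted(dataset.pssms.items()):
        write_pssm_ascii(pssm, outdir / "pssm" / f"{pid}.pssm")
    write_pair_table(dataset.pairs, outdir / "pairs.tsv")

    files = ["proteins.fasta", "pairs.tsv"] + [
        f"pssm/{pid}.pssm" for pid in sorted(dataset.pssms)
    ]
    manifest = {
        "config": _config_dict(dataset.config),
        "files": {
            name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            for name in files
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _config_dict(config: SynthConfig) -> dict:
    d = asdict(config)
    d["length_range"] = list(d["length_range"])
    return d
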
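"""Physicochemical amino-acid property tables.

Two packaged sets: the classical three-property pseudo amino acid composition
set (hydrophobicity, hydrophilicity, side-chain mass) and the seven-property
set used by autocovariance-style sequence descriptors (hydrophobicity,
hydrophilicity, side-chain volume, polarity, polarizability, solvent
accessible surface area, net charge index). Raw values ship as CSV under
``ppiboost/data`` with provenance comments; normalization is to population
mean 0 / SD 1 over the 20 residues (divisor 20). The wildcard residue X
takes the post-normalization mean, i.e. 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

from .seqio import AMINO_ACIDS, WILDCARD

PSEAAC_PROPERTIES = ("hydrophobicity", "hydrophilicity", "side_chain_mass")
AD_PROPERTIES = (
    "hydrophobicity",
    "hydrophilicity",
    "side_chain_volume",
    "polarity",
    "polarizability",
    "sasa",
    "net_charge_index",
)
#: RSIV uses the first six of the seven (everything but net charge index).
RSIV_PROPERTIES = AD_PROPERTIES[:6]


@dataclass(frozen=True)
class PropertyTable:
    """A named physicochemical index: one raw value per amino acid.

    ``normalized`` standardizes the raw values to mean 0 and population
    standard deviation 1 across the 20 amino acids.
    """

    name: str
    raw: dict[str, float]
    normalized: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.raw) != set(AMINO_ACIDS):
            raise ValueError(f"property {self.name!r}: must key exactly the 20 amino acids")
        values = np.array([self.raw[a] for a in AMINO_ACIDS])
        mu, sd = values.mean(), values.std()  # population convention, divisor 20
        if sd == 0:
            raise ValueError(f"property {self.name!r}: constant across amino acids")
        norm = {a: (self.raw[a] - mu) / sd for a in AMINO_ACIDS}
        object.__setattr__(self, "normalized", norm)

    def value(self, residue: str) -> float:
        """Normalized value of a residue; the wildcard X contributes 0 (the mean)."""
        if residue == WILDCARD:
            return 0.0
        return self.normalized[residue]

    def profile(self, sequence: str) -> np.ndarray:
        """Normalized property signal along a sequence."""
        return np.array([self.value(r) for r in sequence])


def _load_csv(name: str) -> dict[str, PropertyTable]:
    text = resources.files("ppiboost.data").joinpath(name).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split(",")
    assert header[0] == "amino_acid"
    columns: dict[str, dict[str, float]] = {c: {} for c in header[1:]}
    for line in lines[1:]:
        fields = line.split(",")
        aa = fields[0]
        for col, val in zip(header[1:], fields[1:]):
            columns[col][aa] = float(val)
    return {c: PropertyTable(c, vals) for c, vals in columns.items()}


@lru_cache(maxsize=None)
def pseaac_properties() -> tuple[PropertyTable, ...]:
    """The three classical PseAAC property tables, fixed order."""
    tables = _load_csv("pseaac_properties.csv")
    return tuple(tables[name] for name in PSEAAC_PROPERTIES)


@lru_cache(maxsize=None)
def physicochemical_properties() -> tuple[PropertyTable, ...]:
    """The seven autocorrelation property tables, fixed order."""
    tables = _load_csv("physicochemical_properties.csv")
    return tuple(tables[name] for name in AD_PROPERTIES)


@lru_cache(maxsize=None)
def rsiv_properties() -> tuple[PropertyTable, ...]:
    tables = _load_csv("physicochemical_properties.csv")
    return tuple(tables[name] for name in RSIV_PROPERTIES)
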
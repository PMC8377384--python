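"""Readers and writers for every external format the pipeline touches.

Formats: FASTA protein sequences, labelled pair tables (TSV/CSV with columns
``id_a, id_b, label``), PSI-BLAST ASCII position-specific scoring matrices
(the ``-out_ascii_pssm`` layout), feature-matrix CSV, a single-file model
store with an embedded schema version, and JSON evaluation reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Column order of PSI-BLAST PSSM output (and BLOSUM-style matrices).
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Wildcard residue for unknown/non-standard amino acids.
WILDCARD = "X"

#: Non-standard codes mapped to the wildcard in lenient parsing mode.
NONSTANDARD = set("BZUOJ*")

MODEL_SCHEMA_VERSION = "ppiboost-model-1"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its residue string.

    The sequence is upper-case over the 20-letter alphabet plus the optional
    wildcard ``X``; the identifier contains no whitespace.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid protein id {self.id!r}: empty or contains whitespace")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS) - {WILDCARD}
        if bad:
            raise ValueError(f"protein {self.id!r}: residues outside alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairRecord:
    """An ordered protein pair with a binary interaction label (1 = interacting)."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"pair ({self.id_a}, {self.id_b}): label must be 0 or 1")


@dataclass(frozen=True)
class PSSMatrix:
    """L x 20 position-specific scores for one protein.

    Columns follow the PSI-BLAST amino-acid order ``A R N D C Q E G H I L K M
    F P S T W Y V``. ``residues`` is the query sequence as reconstructed from
    the per-position residue letters, exposed for cross-checking against the
    FASTA record.
    """

    protein_id: str
    scores: np.ndarray
    residues: str = ""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.protein_id!r}: expected L x 20 scores, got {scores.shape}"
            )
        if self.residues and len(self.residues) != scores.shape[0]:
            raise ValueError(f"PSSM for {self.protein_id!r}: residue string length mismatch")

    def __len__(self) -> int:
        return self.scores.shape[0]


def sanitize_sequence(seq: str, *, strict: bool = False, context: str = "") -> str:
    """Upper-case a raw residue string and resolve non-standard codes.

    In lenient mode (default) the non-standard codes B, Z, U, O, J and ``*``
    are mapped to the wildcard ``X``; in strict mode any character outside the
    20-letter alphabet raises, naming the offending position (1-based).
    """
    seq = seq.upper()
    out = []
    for i, c in enumerate(seq):
        if c in AMINO_ACIDS or c == WILDCARD:
            out.append(c)
        elif c in NONSTANDARD and not strict:
            out.append(WILDCARD)
        else:
            raise ValueError(
                f"{context}invalid residue {c!r} at position {i + 1}"
            )
    return "".join(out)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, *, strict: bool = False) -> list[ProteinRecord]:
    """Parse a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Ids are the first whitespace-delimited token of each header. Raises on an
    empty file, on duplicate ids, and on invalid residues (see
    :func:`sanitize_sequence` for the strict/lenient distinction).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        seq = sanitize_sequence(raw, strict=strict, context=f"{path}: record {rec.id!r}: ")
        mapped += sum(1 for a, b in zip(raw.upper(), seq) if a != b)
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no records")
    if mapped:
        logger.warning("%s: %d non-standard residues mapped to %s", path, mapped, WILDCARD)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write protein records as wrapped FASTA."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Pair tables
# ---------------------------------------------------------------------------

_LABEL_MAP = {"1": 1, "0": 0, "+1": 1, "-1": 0}


def _is_numeric(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_pair_table(path: str | Path, delimiter: str | None = None) -> list[PairRecord]:
    """Read a three-column ``id_a, id_b, label`` table, row order preserved.

    The delimiter is sniffed (tab, then comma) when not given. A single
    header row is auto-detected when the third field is not a recognised
    label. Labels accept ``1``/``0`` and ``+1``/``-1`` (``-1`` maps to 0).
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: no records")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","
    pairs: list[PairRecord] = []
    for row_no, line in enumerate(lines, start=1):
        fields = [f.strip() for f in line.split(delimiter)]
        if len(fields) != 3:
            raise ValueError(f"{path}: row {row_no}: expected 3 columns, got {len(fields)}")
        if row_no == 1 and fields[2] not in _LABEL_MAP and not _is_numeric(fields[2]):
            continue  # header row
        if fields[2] not in _LABEL_MAP:
            raise ValueError(f"{path}: row {row_no}: invalid label {fields[2]!r}")
        pairs.append(PairRecord(fields[0], fields[1], _LABEL_MAP[fields[2]]))
    if not pairs:
        raise ValueError(f"{path}: no records")
    return pairs


def write_pair_table(pairs: Iterable[PairRecord], path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(("id_a", "id_b", "label")) + "\n")
        for p in pairs:
            fh.write(delimiter.join((p.id_a, p.id_b, str(p.label))) + "\n")


def resolve_pairs(pairs: Sequence[PairRecord], proteins: Iterable[ProteinRecord]) -> None:
    """Check that every pair id resolves against the protein collection."""
    known = {p.id for p in proteins}
    for pr in pairs:
        for pid in (pr.id_a, pr.id_b):
            if pid not in known:
                raise KeyError(f"pair ({pr.id_a}, {pr.id_b}): unknown protein id {pid!r}")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm_ascii(path: str | Path, protein_id: str | None = None) -> PSSMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first 20-column block (log-odds scores) is kept; the percentage
    columns and trailing statistics lines are ignored. The parse is
    insensitive to run-length whitespace. The per-position residue letters
    are joined into :attr:`PSSMatrix.residues`.
    """
    path = Path(path)
    rows: list[list[int]] = []
    residues: list[str] = []
    for line in path.read_text().splitlines():
        tokens = line.split()
        if len(tokens) < 2 or not tokens[0].isdigit() or len(tokens[1]) != 1 or not tokens[1].isalpha():
            continue  # banner, header, blank or statistics line
        row_no = len(rows) + 1
        score_tokens = tokens[2:22]
        try:
            scores = [int(t) for t in score_tokens]
        except ValueError as exc:
            raise ValueError(f"{path}: data row {row_no}: non-integer score") from exc
        if len(scores) < 20:
            raise ValueError(
                f"{path}: data row {row_no}: expected 20 score columns, got {len(scores)}"
            )
        rows.append(scores)
        residues.append(tokens[1].upper())
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return PSSMatrix(
        protein_id=protein_id or path.stem,
        scores=np.array(rows, dtype=float),
        residues="".join(residues),
    )


def write_pssm_ascii(pssm: PSSMatrix, path: str | Path) -> None:
    """Write a PSSM in the PSI-BLAST ``-out_ascii_pssm`` ASCII layout.

    Emits the banner, the 40-letter header, one data row per position (scores
    followed by placeholder percentage columns), and trailing statistics
    lines, so files round-trip through :func:`read_pssm_ascii` and resemble
    real PSI-BLAST output closely enough for third-party parsers.
    """
    scores = pssm.scores
    residues = pssm.residues or "X" * len(pssm)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        letters = " ".join(PSSM_ALPHABET)
        fh.write(" " * 11 + letters + "   " + letters + "\n")
        for i, (row, res) in enumerate(zip(scores, residues), start=1):
            cells = "".join(f"{int(v):4d}" for v in row)
            pct = "".join(f"{0:4d}" for _ in row)
            fh.write(f"{i:5d} {res} {cells} {pct}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1375     0.3160\n")


def read_pssm_dir(directory: str | Path, suffix: str = ".pssm") -> dict[str, PSSMatrix]:
    """Read every ``<id>.pssm`` file in a directory into an id-keyed dict."""
    directory = Path(directory)
    out: dict[str, PSSMatrix] = {}
    for path in sorted(directory.glob(f"*{suffix}")):
        out[path.stem] = read_pssm_ascii(path)
    return out


# ---------------------------------------------------------------------------
# Feature matrices, model store, reports
# ---------------------------------------------------------------------------

def write_feature_csv(frame, path: str | Path) -> None:
    """Write a sample-by-feature DataFrame as CSV with a leading sample-id column."""
    frame.to_csv(path, index_label="sample_id")


def read_feature_csv(path: str | Path):
    import pandas as pd

    frame = pd.read_csv(path, index_col="sample_id")
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no feature columns")
    return frame


def save_model(obj, path: str | Path) -> None:
    """Serialize a model object with an embedded schema-version string."""
    joblib.dump({"schema_version": MODEL_SCHEMA_VERSION, "payload": obj}, path)


def load_model(path: str | Path):
    blob = joblib.load(path)
    if not isinstance(blob, dict) or "schema_version" not in blob:
        raise ValueError(f"{path}: not a ppiboost model file")
    if blob["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema version {blob['schema_version']!r} "
            f"(expected {MODEL_SCHEMA_VERSION!r})"
        )
    return blob["payload"]


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
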
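"""Top-level modelling interface and config-driven orchestration.

:class:`PPIBoostModel` is built from data (FASTA + pair table + optional
PSSM directory, or a synthetic dataset); its :meth:`~PPIBoostModel.fit` runs
stratified cross-validation of the select-then-boost pipeline and a final
fit on all pairs, returning a :class:`PPIBoostResults` that carries the
fold-level metrics, the selected feature support, the fitted models and a
``summary()`` table. :func:`run_pipeline` is the file-in/file-out driver
behind the CLI: it writes every intermediate artifact plus a manifest with
content hashes so a rerun with the same config and seed reproduces the
report exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import seqio
from .encoders import EncoderConfig, build_pair_features
from .evaluation import EvalReport, METRIC_KEYS, cross_validate_features
from .gtb import GTBModel, predict_proba, train_gtb
from .selection import SelectionModel, apply_selection, fit_l1rlr
from .seqio import PairRecord, ProteinRecord, PSSMatrix
from .synthetic import SynthConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration of the file-driven pipeline (CLI ``run``)."""

    fasta: str = "proteins.fasta"
    pssm_dir: str | None = "pssm"
    pairs: str = "pairs.tsv"
    workdir: str = "ppiboost_run"
    lam: int = 11
    xi: int = 9
    lag: int = 11
    w: float = 0.05
    C: float = 1.0
    M: int = 1000
    learning_rate: float = 0.1
    max_depth: int = 3
    k: int = 5
    threshold: float = 0.5
    seed: int = 42
    log_level: str = "INFO"

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(lam=self.lam, xi=self.xi, lag=self.lag, w=self.w)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class PPIBoostModel:
    """Sequence-based PPI prediction model built from proteins and pairs.

    Parameters
    ----------
    proteins : protein records covering every id referenced by the pairs.
    pairs : labelled protein pairs (1 = interacting).
    pssms : optional id-keyed PSSM mapping; proteins without one fall back
        to the BLOSUM62 pseudo-profile (logged).
    encoder_config : the four encoders' hyperparameters (λ, ξ, lag, w).
    """

    def __init__(
        self,
        proteins: Sequence[ProteinRecord],
        pairs: Sequence[PairRecord],
        pssms: Mapping[str, PSSMatrix] | None = None,
        encoder_config: EncoderConfig = EncoderConfig(),
    ) -> None:
        seqio.resolve_pairs(pairs, proteins)
        self.proteins = list(proteins)
        self.pairs = list(pairs)
        self.pssms = dict(pssms or {})
        self.encoder_config = encoder_config
        self._features: pd.DataFrame | None = None
        self._labels: np.ndarray | None = None

    @classmethod
    def from_files(
        cls,
        fasta: str | Path,
        pairs: str | Path,
        pssm_dir: str | Path | None = None,
        encoder_config: EncoderConfig = EncoderConfig(),
    ) -> "PPIBoostModel":
        proteins = seqio.read_fasta(fasta)
        pair_records = seqio.read_pair_table(pairs)
        pssms = seqio.read_pssm_dir(pssm_dir) if pssm_dir else None
        return cls(proteins, pair_records, pssms, encoder_config)

    @classmethod
    def from_synthetic(
        cls,
        config: SynthConfig = SynthConfig(),
        encoder_config: EncoderConfig = EncoderConfig(),
    ) -> "PPIBoostModel":
        ds = generate_dataset(config)
        return cls(ds.proteins, ds.pairs, ds.pssms, encoder_config)

    @property
    def exog(self) -> pd.DataFrame:
        """The pair feature matrix (encoded lazily, cached)."""
        if self._features is None:
            self._features, self._labels = build_pair_features(
                self.proteins, self.pssms, self.pairs, self.encoder_config
            )
        return self._features

    @property
    def endog(self) -> np.ndarray:
        """The binary interaction labels aligned with :attr:`exog`."""
        self.exog
        return self._labels

    def fit(
        self,
        C: float = 1.0,
        M: int = 1000,
        learning_rate: float = 0.1,
        max_depth: int = 3,
        k: int = 5,
        seed: int = 0,
        threshold: float = 0.5,
    ) -> "PPIBoostResults":
        """Cross-validate the pipeline, then fit selector + booster on all pairs."""
        X, y = self.exog, self.endog
        report = cross_validate_features(
            X, y, C=C, M=M, learning_rate=learning_rate, max_depth=max_depth,
            k=k, seed=seed, threshold=threshold,
        )
        selection = fit_l1rlr(X, y, C=C, seed=seed)
        classifier = train_gtb(
            apply_selection(X, selection), y,
            M=M, learning_rate=learning_rate, max_depth=max_depth, seed=seed,
        )
        return PPIBoostResults(self, report, selection, classifier, threshold, seed)


@dataclass
class PPIBoostResults:
    """Fitted pipeline: CV report, feature support, final models."""

    model: PPIBoostModel
    report: EvalReport
    selection: SelectionModel
    classifier: GTBModel
    threshold: float = 0.5
    seed: int = 0

    @property
    def selected_features(self) -> tuple[str, ...]:
        return self.selection.support_names

    def predict(self, pairs: Sequence[PairRecord] | None = None) -> pd.DataFrame:
        """Interaction probabilities and labels for pairs (default: training pairs)."""
        if pairs is None:
            X = self.model.exog
            pair_list = self.model.pairs
        else:
            X, _ = build_pair_features(
                self.model.proteins, self.model.pssms, pairs, self.model.encoder_config
            )
            pair_list = list(pairs)
        proba = predict_proba(self.classifier, apply_selection(X, self.selection))
        return pd.DataFrame(
            {
                "id_a": [p.id_a for p in pair_list],
                "id_b": [p.id_b for p in pair_list],
                "probability": proba,
                "label": (proba >= self.threshold).astype(int),
            }
        )

    def summary(self) -> str:
        """Human-readable fit summary with per-fold metrics and mean ± SD."""
        rep = self.report
        lines = [
            "PPIBoost cross-validation results",
            "=" * 64,
            f"pairs: {len(self.model.endog)}   features: {self.model.exog.shape[1]}"
            f"   selected: {self.selection.n_selected}",
            f"folds: {len(rep.per_fold or [])}   boosting iterations: {self.classifier.M}"
            f"   C: {self.selection.C}   seed: {self.seed}",
            "-" * 64,
            "fold   recall  precision    acc      mcc    auroc    auprc",
        ]
        for i, fold in enumerate(rep.per_fold or [], start=1):
            lines.append(
                f"{i:4d}  {fold.recall:7.4f}  {fold.precision:8.4f}  {fold.acc:7.4f}"
                f"  {fold.mcc:7.4f}  {fold.auroc:7.4f}  {fold.auprc:7.4f}"
            )
        lines.append("-" * 64)
        if rep.mean:
            mean, std = rep.mean, rep.std
            lines.append(
                "mean  "
                + "  ".join(f"{mean[key]:7.4f}" for key in METRIC_KEYS)
            )
            lines.append(
                "sd    "
                + "  ".join(f"{std[key]:7.4f}" for key in METRIC_KEYS)
            )
        if rep.warnings:
            lines.append("warnings: " + "; ".join(rep.warnings))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# File-driven orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> EvalReport:
    """Execute encode → select → train → evaluate and write all artifacts.

    Writes into ``config.workdir``: ``features.csv``, ``selected.csv``,
    ``support.txt``, ``selection.model``, ``gtb.model``,
    ``predictions.csv``, ``report.json`` and ``manifest.json`` (config hash
    plus SHA-256 of every artifact). A rerun with the same inputs, config
    and seed reproduces the report exactly.
    """
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        model = PPIBoostModel.from_files(
            config.fasta, config.pairs, config.pssm_dir, config.encoder_config()
        )
        stage = "encode"
        X = model.exog
        seqio.write_feature_csv(X, workdir / "features.csv")
        stage = "select+train+evaluate"
        results = model.fit(
            C=config.C, M=config.M, learning_rate=config.learning_rate,
            max_depth=config.max_depth, k=config.k, seed=config.seed,
            threshold=config.threshold,
        )
        stage = "write"
        seqio.write_feature_csv(
            apply_selection(X, results.selection), workdir / "selected.csv"
        )
        (workdir / "support.txt").write_text(
            "\n".join(results.selected_features) + "\n"
        )
        seqio.save_model(results.selection, workdir / "selection.model")
        seqio.save_model(results.classifier, workdir / "gtb.model")
        results.predict().to_csv(workdir / "predictions.csv", index=False)
        seqio.write_json(results.report.to_dict(), workdir / "report.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    artifacts = [
        "features.csv", "selected.csv", "support.txt", "selection.model",
        "gtb.model", "predictions.csv", "report.json",
    ]
    config_blob = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "artifacts": {name: _sha256(workdir / name) for name in artifacts},
    }
    seqio.write_json(manifest, workdir / "manifest.json")
    return results.report


def verify_artifacts(workdir: str | Path) -> None:
    """Check every artifact against the manifest hashes; raise on tampering."""
    workdir = Path(workdir)
    manifest = seqio.read_json(workdir / "manifest.json")
    for name, digest in manifest["artifacts"].items():
        actual = _sha256(workdir / name)
        if actual != digest:
            raise ValueError(f"artifact {name!r} does not match its manifest hash")
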
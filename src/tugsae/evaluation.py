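"""Full-experiment orchestration: generate, transform, classify, report.

`FallRiskExperiment` is the model object: it is built from an
`ExperimentConfig` (cohort generator, time-frequency settings, classifier
hyperparameters, repeat count), and `fit()` runs the whole protocol —
synthetic cohort -> per-axis Morlet images -> per-axis stacked-autoencoder
LOOCV, plus feature extraction -> t-test screening -> per-axis LDA LOOCV —
repeated `n_repeats` times with seeds derived from the master seed. The
returned `ExperimentResults` carries per-run confusion matrices and exposes
mean +- sd accuracy/sensitivity/specificity per axis and method, a
`summary()` table and CSV export. The report is a pure function of the
config: rerunning with the same config reproduces it bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as fb
from . import sae as sae_mod
from . import tfa
from .features import ConfusionSummary
from .sae import SAEClassifier, SAEHyperparams, TrainConfig
from .synthetic import AXES, GeneratorConfig, SubjectRecord, generate_cohort

__all__ = [
    "ExperimentConfig",
    "EvaluationReport",
    "ExperimentResults",
    "FallRiskExperiment",
    "cohort_images",
    "labels_binary",
    "loocv_sae",
    "run_experiment",
    "report_to_tables",
]

logger = logging.getLogger("tugsae")

_METHODS = ("sae", "lda")
_METRICS = ("accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class ExperimentConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    grid_fmin: float = 0.05
    grid_fmax: float = 5.0
    grid_bins: int = 100
    image_size: int = 28
    sae: SAEHyperparams = field(default_factory=SAEHyperparams)
    train: TrainConfig = field(default_factory=TrainConfig)
    alpha: float = 0.05
    n_repeats: int = 1
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def labels_binary(cohort: list[SubjectRecord]) -> np.ndarray:
    """0/1 label vector for a cohort; 1 = at risk (the positive class)."""
    return np.array([1 if r.label == "at_risk" else 0 for r in cohort])


def cohort_images(
    cohort: list[SubjectRecord],
    axis: str,
    config: ExperimentConfig | None = None,
) -> np.ndarray:
    """Flattened (n, H*W*3) Morlet images of one axis for every subject."""
    config = config or ExperimentConfig()
    grid = tfa.make_frequency_grid(config.grid_fmin, config.grid_fmax, config.grid_bins)
    out = []
    for rec in cohort:
        fs = rec.n_samples / rec.tug_time
        tfr = tfa.transform(rec.axis(axis), fs, grid)
        img = tfa.render_image(tfr, config.image_size, config.image_size)
        out.append(img.flatten())
    return np.vstack(out)


def loocv_sae(
    images: np.ndarray,
    labels: np.ndarray,
    hyper: SAEHyperparams | None = None,
    config: TrainConfig | None = None,
) -> ConfusionSummary:
    """Leave-one-out SAE evaluation: one prediction per subject, one confusion matrix.

    Each fold retrains the full stack (pretraining + head + fine-tuning) on
    all other subjects with a fold-specific seed derived from the config
    seed, then predicts the held-out subject.
    """
    X = np.asarray(images, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes must be present")
    hyper = hyper or SAEHyperparams()
    config = config or TrainConfig()
    n = X.shape[0]
    fold_seeds = [
        int(c.generate_state(1)[0] % 2**31)
        for c in np.random.SeedSequence(config.seed).spawn(n)
    ]
    preds = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            clf = SAEClassifier(
                hyper=hyper, config=dataclasses.replace(config, seed=fold_seeds[i])
            ).fit(X[mask], y[mask])
        except Exception as exc:  # annotate with the fold for diagnosis
            raise RuntimeError(f"SAE training failed in LOOCV fold {i}") from exc
        preds[i] = int(clf.predict(X[i : i + 1])[0])
        mask[i] = True
        logger.info("fold %d/%d: true=%d pred=%d", i + 1, n, y[i], preds[i])
    return ConfusionSummary.from_predictions(y, preds)


@dataclass
class EvaluationReport:
    """Per-axis, per-method metrics over repeated runs, with provenance."""

    per_run: dict  # (axis, method) -> list[ConfusionSummary], one per repeat
    config_digest: str
    master_seed: int
    timestamp: str

    def metrics(self, axis: str, method: str) -> dict:
        runs = self.per_run[(axis, method)]
        out = {}
        for metric in _METRICS:
            vals = np.array([getattr(r, metric) for r in runs])
            out[f"{metric}_mean"] = float(vals.mean())
            out[f"{metric}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return out


@dataclass
class ExperimentResults:
    """Results object of a fitted `FallRiskExperiment`."""

    report: EvaluationReport
    selection: fb.SelectionResult
    feature_frame: pd.DataFrame

    def to_tables(self) -> pd.DataFrame:
        """Table-shaped export: axis, method, metric means and sds (6 rows)."""
        rows = []
        for axis in AXES:
            for method in _METHODS:
                if (axis, method) not in self.report.per_run:
                    continue
                rows.append(
                    {"axis": axis, "method": method, **self.report.metrics(axis, method)}
                )
        cols = ["axis", "method"] + [f"{m}_{s}" for m in _METRICS for s in ("mean", "sd")]
        return pd.DataFrame(rows, columns=cols)

    def summary(self) -> str:
        """Human-readable report in the accuracy/sensitivity/specificity layout."""
        lines = [
            "Fall-risk classification under leave-one-out cross-validation",
            f"(config {self.report.config_digest}, master seed {self.report.master_seed})",
            "",
            f"{'axis':<6}{'method':<8}{'accuracy':>16}{'sensitivity':>16}{'specificity':>16}",
        ]
        for row in self.to_tables().itertuples(index=False):
            lines.append(
                f"{row.axis:<6}{row.method:<8}"
                f"{100 * row.accuracy_mean:>10.1f} ± {100 * row.accuracy_sd:<4.1f}"
                f"{100 * row.sensitivity_mean:>10.1f} ± {100 * row.sensitivity_sd:<4.1f}"
                f"{100 * row.specificity_mean:>10.1f} ± {100 * row.specificity_sd:<4.1f}"
            )
        lines.append("")
        lines.append("selected features: " + ", ".join(self.selection.selected_names()))
        return "\n".join(lines)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_tables().to_csv(directory / "metrics.csv", index=False)
        self.feature_frame.to_csv(directory / "features.csv", index=False)
        pd.DataFrame(
            {
                "feature": fb.FEATURE_NAMES,
                "p_value": self.selection.p_values,
                "normality_p": self.selection.normality_p,
                "selected": self.selection.selected,
            }
        ).to_csv(directory / "selection.csv", index=False)
        (directory / "summary.txt").write_text(self.summary() + "\n")
        return directory


class FallRiskExperiment:
    """The full evaluation protocol as a model object.

    Parameters live in the `ExperimentConfig`; `fit()` executes the
    protocol and returns an `ExperimentResults`.
    """

    def __init__(self, config: ExperimentConfig | None = None):
        self.config = config or ExperimentConfig()

    def fit(self) -> ExperimentResults:
        cfg = self.config
        cohort = generate_cohort(cfg.generator)
        y = labels_binary(cohort)
        logger.info("generated cohort of %d subjects", len(cohort))

        frame = fb.feature_table(cohort)
        selection = fb.select_features(frame, y, alpha=cfg.alpha)

        per_run: dict = {(a, m): [] for a in AXES for m in _METHODS}
        images = {axis: cohort_images(cohort, axis, cfg) for axis in AXES}

        repeat_seeds = [
            int(c.generate_state(1)[0] % 2**31)
            for c in np.random.SeedSequence(cfg.train.seed).spawn(cfg.n_repeats)
        ]
        for axis in AXES:
            axis_features = [f"{s}_{axis}" for s in ("mean", "std", "max", "min", "mcr")]
            chosen = [f for f in axis_features if selection.selected[fb.FEATURE_NAMES.index(f)]]
            if not chosen:  # nothing survived screening on this axis
                chosen = axis_features
            X_lda = frame[chosen].to_numpy()
            for r, seed in enumerate(repeat_seeds):
                logger.info("axis %s repeat %d/%d", axis, r + 1, cfg.n_repeats)
                per_run[(axis, "sae")].append(
                    loocv_sae(
                        images[axis], y, cfg.sae, dataclasses.replace(cfg.train, seed=seed)
                    )
                )
                per_run[(axis, "lda")].append(fb.loocv_lda(X_lda, y))

        report = EvaluationReport(
            per_run=per_run,
            config_digest=cfg.digest(),
            master_seed=cfg.train.seed,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )
        results = ExperimentResults(report=report, selection=selection, feature_frame=frame)
        if cfg.output_dir:
            results.save(cfg.output_dir)
        return results


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentResults:
    """Convenience wrapper: `FallRiskExperiment(config).fit()`."""
    return FallRiskExperiment(config).fit()


def report_to_tables(results: ExperimentResults) -> pd.DataFrame:
    """Alias for `ExperimentResults.to_tables`."""
    return results.to_tables()
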
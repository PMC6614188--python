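"""Evaluation: confusion metrics, AUC, log-ratio summaries, subsampling curves.

The positive class is cancer/anomaly throughout: a true positive is a sample
labeled cancer that the detector calls an anomaly. Specificity — the fraction
of truly normal samples called normal — is the focal metric, because residual
batch effects between training and test cohorts inflate false positives.
Metrics with a zero denominator propagate as NaN, never as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data_io import ExpressionMatrix
from .detector import DetectorError, fit_detector, score_samples

logger = logging.getLogger(__name__)


class EvalError(ValueError):
    pass


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


@dataclass
class EvalReport:
    """Confusion counts plus the four ratio metrics and (optionally) AUC."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    specificity: float
    accuracy: float
    auc: float = math.nan

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int, auc: float = math.nan):
        return cls(
            tp=tp, fp=fp, tn=tn, fn=fn,
            precision=_ratio(tp, tp + fp),
            recall=_ratio(tp, tp + fn),
            specificity=_ratio(tn, tn + fp),
            accuracy=_ratio(tp + tn, tp + fp + tn + fn),
            auc=auc,
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "specificity": self.specificity, "accuracy": self.accuracy,
            "auc": self.auc,
        }


def confusion_metrics(table: pd.DataFrame) -> EvalReport:
    """Confusion counts and ratio metrics from a fully labeled score table."""
    if table["true_label"].isna().any():
        raise EvalError("confusion metrics require a true label for every sample")
    is_pos = table["true_label"].to_numpy() == "cancer"
    called = table["call"].to_numpy() == "anomaly"
    if not is_pos.any() or is_pos.all():
        raise EvalError("both a positive and a negative sample are required")
    tp = int((called & is_pos).sum())
    fp = int((called & ~is_pos).sum())
    fn = int((~called & is_pos).sum())
    tn = int((~called & ~is_pos).sum())
    return EvalReport.from_counts(tp, fp, tn, fn)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random cancer sample outscores a random normal one.

    Mann–Whitney form with ties counted one half; threshold-free (raw scores,
    not calls).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind == "b":
        y = labels
    else:
        y = labels == "cancer"
    if not y.any() or y.all():
        raise EvalError("AUC requires both classes to be present")
    return float(roc_auc_score(y, scores))


def evaluate_scores(table: pd.DataFrame) -> EvalReport:
    """Confusion metrics plus AUC from a labeled score table."""
    report = confusion_metrics(table)
    report.auc = auc(table["score"].to_numpy(), table["true_label"].to_numpy())
    return report


def log_ratio_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-label summaries of log_ratio, suitable for a score-vs-threshold plot.

    One row per group (normal, cancer) with n, median, quartiles and the
    fraction of samples above 0 — i.e. above the anomaly threshold. An empty
    group is reported with n=0 and NaN summaries.
    """
    if "true_label" not in table.columns or table["true_label"].isna().all():
        raise EvalError("log-ratio summary requires true labels")
    rows = []
    for group in ("normal", "cancer"):
        lr = table.loc[table["true_label"] == group, "log_ratio"].to_numpy()
        if lr.size:
            q1, med, q3 = np.percentile(lr, [25, 50, 75])
            frac = float((lr > 0).mean())
        else:
            q1 = med = q3 = frac = math.nan
        rows.append(
            {"group": group, "n": int(lr.size), "median": med,
             "q1": q1, "q3": q3, "frac_above_threshold": frac}
        )
    return pd.DataFrame(rows).set_index("group")


@dataclass
class SubsampleCurve:
    """Mean specificity per training-set size across repeated random subsets."""

    sizes: list[int]
    per_bootstrap: np.ndarray       # len(sizes) x n_bootstraps
    n_bootstraps: int
    seed: int
    skipped_sizes: list[int] = field(default_factory=list)

    @property
    def mean_specificity(self) -> np.ndarray:
        return self.per_bootstrap.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for i, size in enumerate(self.sizes):
            for b in range(self.n_bootstraps):
                records.append(
                    {"size": size, "bootstrap": b,
                     "specificity": self.per_bootstrap[i, b]}
                )
        return pd.DataFrame(records)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size": self.sizes, "mean_specificity": self.mean_specificity}
        )


def subsample_experiment(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    sizes: list[int],
    n_bootstraps: int = 10,
    seed: int = 0,
    replace: bool = False,
    **fit_kwargs,
) -> SubsampleCurve:
    """Refit the full pipeline on random training subsets of growing size.

    For each size, ``n_bootstraps`` subsets are drawn (without replacement
    within a subset by default; ``replace=True`` switches to resampling) and
    the standardizer + detector are refit from scratch; specificity is then
    measured on the fixed, labeled test set. Sub-seeds per curve cell are
    derived deterministically from the master seed, so any cell is
    reproducible in isolation. Sizes too small to fit the requested number of
    components are skipped with a warning.
    """
    if test.labels is None or not any(
        lab == "normal" for lab in test.labels.values()
    ):
        raise EvalError("the test set must contain labeled normal samples")
    sizes = sorted(set(int(s) for s in sizes))
    if max(sizes) > train.n_samples:
        raise EvalError(
            f"largest size {max(sizes)} exceeds training n={train.n_samples}"
        )
    normal_ids = [s for s in test.sample_ids if test.labels.get(s) == "normal"]
    size_seqs = np.random.SeedSequence(seed).spawn(len(sizes))
    kept: list[int] = []
    skipped: list[int] = []
    grid: list[list[float]] = []
    for size, seq in zip(sizes, size_seqs):
        boot_seqs = seq.spawn(n_bootstraps)
        specs: list[float] = []
        try:
            for bseq in boot_seqs:
                rng = np.random.default_rng(bseq)
                # sorted so that a full-set subset reproduces the full pipeline
                # bit for bit, independent of draw order
                idx = np.sort(rng.choice(train.n_samples, size=size, replace=replace))
                model = fit_detector(train.subset_samples(idx), **fit_kwargs)
                scored = score_samples(model, test)
                on_normals = scored[scored["sample_id"].isin(normal_ids)]
                specs.append(float((on_normals["call"] == "normal").mean()))
        except DetectorError as exc:
            logger.warning("skipping size %d: %s", size, exc)
            skipped.append(size)
            continue
        kept.append(size)
        grid.append(specs)
    return SubsampleCurve(
        sizes=kept,
        per_bootstrap=np.asarray(grid, dtype=float),
        n_bootstraps=n_bootstraps,
        seed=seed,
        skipped_sizes=skipped,
    )


def pca_coordinates(z: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample coordinates on the first principal components of a standardized
    matrix — a plot-ready table for visual inspection of cohort structure."""
    vals = z.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(vals - vals.mean(axis=1, keepdims=True), full_matrices=False)
    coords = (s[:n_components, None] * vt[:n_components, :]).T
    return pd.DataFrame(
        coords, index=z.columns, columns=[f"PC{i+1}" for i in range(n_components)]
    )
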
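"""PCA residual analysis: subspace fit, Q (SPE) scores, and false-alarm thresholds.

A detector is trained on standardized healthy samples only. The training
covariance is eigen-decomposed through an economy SVD of the standardized data
matrix (never forming the p x p covariance, since p is typically much larger
than n). A sample's anomaly score is the squared norm of its residue — the
component orthogonal to the retained principal subspace. Scores are compared
against a control limit targeting a stipulated false-alarm rate alpha, either
the closed-form Jackson–Mudholkar chi-square approximation built from the
moments of the discarded eigenvalue spectrum, or an empirical quantile of the
training scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix
from .preprocess import Standardizer, apply_standardizer, fit_standardizer

logger = logging.getLogger(__name__)

#: eigenvalues below RANK_TOL * largest are treated as numerically zero
RANK_TOL = 1e-12

JACKSON_MUDHOLKAR = "jackson_mudholkar"
EMPIRICAL = "empirical"


class DetectorError(ValueError):
    pass


class JMThreshold(NamedTuple):
    """Jackson–Mudholkar control limit with all intermediates, for audit.

    theta_i is the sum of the i-th powers of the discarded eigenvalues,
    h0 = 1 - 2*theta1*theta3 / (3*theta2**2), c_alpha the upper-alpha
    standard-normal quantile, and q_threshold the resulting limit Q_alpha.
    """

    theta1: float
    theta2: float
    theta3: float
    h0: float
    c_alpha: float
    q_threshold: float


@dataclass
class DetectorModel:
    """A fitted tissue detector: retained loadings, spectrum, and threshold."""

    standardizer: Standardizer
    loadings: np.ndarray          # p x k orthonormal
    eigenvalues: np.ndarray       # full non-increasing spectrum
    k: int
    alpha: float
    theta1: float
    theta2: float
    theta3: float
    h0: float
    c_alpha: float
    q_threshold: float
    threshold_method: str = JACKSON_MUDHOLKAR
    log_ratio_base: float = math.e

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        gram = self.loadings.T @ self.loadings
        if np.abs(gram - np.eye(self.k)).max() > 1e-8:
            raise DetectorError("loadings columns are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10 * max(self.eigenvalues[0], 1.0)):
            raise DetectorError("eigenvalues must be non-increasing")
        if not 1 <= self.k < self.rank:
            raise DetectorError(
                f"k={self.k} must satisfy 1 <= k < rank={self.rank} "
                "(at least one component must be discarded)"
            )
        if self.theta1 <= 0 or self.q_threshold <= 0:
            raise DetectorError("theta1 and q_threshold must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return self.standardizer.gene_ids

    @property
    def rank(self) -> int:
        ev = self.eigenvalues
        return int((ev > RANK_TOL * ev[0]).sum()) if ev.size else 0


def fit_subspace(
    z_train: pd.DataFrame | np.ndarray,
    k: int | None = None,
    variance_fraction: float = 0.90,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Eigen-decompose the training covariance and choose the retained rank.

    ``z_train`` is a standardized genes x samples matrix (per-gene mean zero,
    so the sample covariance is Z Z^T / (n-1)). Returns ``(P, eigenvalues, k)``
    where P holds the first k loadings and ``eigenvalues`` is the full economy
    spectrum. When ``k`` is None, the smallest k whose cumulative eigenvalue
    share reaches ``variance_fraction`` is used. A rule that leaves no
    discarded component is an error: the residue would be identically zero.
    """
    z = np.asarray(z_train, dtype=float)
    if z.ndim != 2 or z.shape[1] < 3:
        raise DetectorError("subspace fitting requires a 2-D matrix with >= 3 samples")
    n = z.shape[1]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    if eigenvalues[0] <= 0:
        raise DetectorError("training matrix is identically zero")
    if k is None:
        if not 0 < variance_fraction < 1:
            raise DetectorError("variance_fraction must lie in (0, 1)")
        shares = np.cumsum(eigenvalues) / eigenvalues.sum()
        k = int(np.searchsorted(shares, variance_fraction - 1e-12) + 1)
    k = int(k)
    if k < 1:
        raise DetectorError("k must be at least 1")
    if k >= eigenvalues.size:
        raise DetectorError(
            f"k={k} exhausts the spectrum of size {eigenvalues.size}: "
            "no discarded components; residue degenerate"
        )
    return u[:, :k].copy(), eigenvalues, k


def residue_score(
    loadings: np.ndarray, z: np.ndarray | pd.DataFrame
) -> float | np.ndarray:
    """Squared norm of the component of ``z`` orthogonal to the retained subspace.

    ``z`` may be a single length-p vector (returns a scalar) or a p x m matrix
    (returns one score per column). Gene order must match the loadings.
    """
    p = loadings.shape[0]
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    if single:
        z = z[:, None]
    if z.shape[0] != p:
        raise DetectorError(
            f"sample vector has length {z.shape[0]}, model expects {p} genes"
        )
    resid = z - loadings @ (loadings.T @ z)
    scores = np.einsum("ij,ij->j", resid, resid)
    return float(scores[0]) if single else scores


def _spectrum_moments(
    eigenvalues: np.ndarray, k: int
) -> tuple[float, float, float, float]:
    """theta1..theta3 and h0 of the discarded part of the spectrum."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    lam = eigenvalues[k:]
    if eigenvalues.size:
        lam = lam[lam > RANK_TOL * eigenvalues[0]]
    if lam.size == 0 or lam.sum() <= 0:
        raise DetectorError("all discarded eigenvalues are zero; residue degenerate")
    theta1 = float(lam.sum())
    theta2 = float((lam**2).sum())
    theta3 = float((lam**3).sum())
    h0 = 1.0 - 2.0 * theta1 * theta3 / (3.0 * theta2**2)
    return theta1, theta2, theta3, h0


def jm_threshold(eigenvalues: np.ndarray, k: int, alpha: float) -> JMThreshold:
    """Closed-form control limit Q_alpha for the residue score.

    Built from the first three moments (theta1..theta3) of the discarded
    eigenvalue spectrum:

        Q_alpha = theta1 * [ c_alpha*sqrt(2*theta2*h0^2)/theta1 + 1
                             + theta2*h0*(h0-1)/theta1^2 ]^(1/h0)

    For extreme alpha or ill-conditioned spectra the bracket can be
    non-positive (or h0 can vanish), in which case the approximation is
    inapplicable and an error advises the empirical threshold instead.
    """
    if not 0 < alpha < 1:
        raise DetectorError("alpha must lie in (0, 1)")
    theta1, theta2, theta3, h0 = _spectrum_moments(eigenvalues, k)
    c_alpha = float(stats.norm.isf(alpha))
    if h0 == 0.0:
        raise DetectorError(
            "h0 = 0: chi-square approximation inapplicable; use empirical_threshold"
        )
    bracket = (
        c_alpha * math.sqrt(2.0 * theta2 * h0**2) / theta1
        + 1.0
        + theta2 * h0 * (h0 - 1.0) / theta1**2
    )
    if bracket <= 0:
        raise DetectorError(
            "non-positive bracket in the control-limit formula; "
            "use empirical_threshold instead"
        )
    q = theta1 * bracket ** (1.0 / h0)
    return JMThreshold(theta1, theta2, theta3, h0, c_alpha, q)


def empirical_threshold(train_scores: np.ndarray, alpha: float) -> float:
    """(1 - alpha) empirical quantile of training residue scores.

    Linear interpolation between order statistics; requires at least 20
    scores so the upper tail is minimally resolved.
    """
    if not 0 < alpha < 1:
        raise DetectorError("alpha must lie in (0, 1)")
    scores = np.asarray(train_scores, dtype=float)
    if scores.size < 20:
        raise DetectorError("empirical threshold requires at least 20 training scores")
    return float(np.quantile(scores, 1.0 - alpha))


def classify(
    model: DetectorModel,
    z_test: pd.DataFrame | np.ndarray,
    true_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Score standardized samples and call anomalies against the threshold.

    A sample is called an anomaly iff score > q_threshold — strictly, so a tie
    is called normal. ``log_ratio`` is log(score / q_threshold) in the model's
    base, with a score of zero mapped to -inf.
    """
    if isinstance(z_test, pd.DataFrame):
        sample_ids = list(z_test.columns)
        z = z_test.to_numpy(dtype=float)
    else:
        z = np.asarray(z_test, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        sample_ids = [f"sample_{i}" for i in range(z.shape[1])]
    scores = np.atleast_1d(residue_score(model.loadings, z))
    with np.errstate(divide="ignore"):
        log_ratio = np.log(scores / model.q_threshold) / math.log(model.log_ratio_base)
    call = np.where(scores > model.q_threshold, "anomaly", "normal")
    labels = [
        (true_labels or {}).get(s) if true_labels is not None else None
        for s in sample_ids
    ]
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "score": scores,
            "log_ratio": log_ratio,
            "call": call,
            "true_label": labels,
        }
    )


def fit_detector(
    train: ExpressionMatrix,
    *,
    log: bool = False,
    pseudocount: float = 1.0,
    min_sd: float = 1e-8,
    k: int | None = None,
    variance_fraction: float = 0.90,
    alpha: float = 0.05,
    threshold_method: str = JACKSON_MUDHOLKAR,
    log_ratio_base: float = math.e,
) -> DetectorModel:
    """Full training pipeline: standardize, fit the subspace, set the threshold.

    The default pipeline z-scores FPKM values directly; ``log=True`` inserts a
    log2(v + pseudocount) step first. The threshold targets false-alarm rate
    ``alpha`` via the Jackson–Mudholkar limit by default, or the empirical
    training-score quantile with ``threshold_method="empirical"``.
    """
    if threshold_method not in (JACKSON_MUDHOLKAR, EMPIRICAL):
        raise DetectorError(f"unknown threshold_method {threshold_method!r}")
    standardizer = fit_standardizer(train, min_sd=min_sd, log=log, pseudocount=pseudocount)
    z = apply_standardizer(standardizer, train)
    loadings, eigenvalues, k_used = fit_subspace(
        z, k=k, variance_fraction=variance_fraction
    )
    theta1, theta2, theta3, h0 = _spectrum_moments(eigenvalues, k_used)
    c_alpha = float(stats.norm.isf(alpha))
    if threshold_method == EMPIRICAL:
        train_scores = residue_score(loadings, z.to_numpy())
        q = empirical_threshold(train_scores, alpha)
    else:
        q = jm_threshold(eigenvalues, k_used, alpha).q_threshold
    logger.info(
        "fitted detector: n=%d p=%d k=%d alpha=%g threshold=%g (%s), %d genes dropped",
        train.n_samples, standardizer.n_genes, k_used, alpha, q,
        threshold_method, standardizer.n_dropped,
    )
    return DetectorModel(
        standardizer=standardizer,
        loadings=loadings,
        eigenvalues=eigenvalues,
        k=k_used,
        alpha=alpha,
        theta1=theta1,
        theta2=theta2,
        theta3=theta3,
        h0=h0,
        c_alpha=c_alpha,
        q_threshold=q,
        threshold_method=threshold_method,
        log_ratio_base=log_ratio_base,
    )


def score_samples(
    model: DetectorModel,
    x: ExpressionMatrix,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Standardize ``x`` with the model's frozen standardizer, score and call.

    With ``on_missing="intersect"`` the model is restricted to the shared
    genes: the corresponding loading rows are re-orthonormalized so scores are
    computed in the reduced gene space (logged; geometry is no longer exactly
    the training geometry).
    """
    z = apply_standardizer(model.standardizer, x, on_missing=on_missing)
    loadings = model.loadings
    if list(z.index) != model.gene_ids:
        rows = [i for i, g in enumerate(model.gene_ids) if g in set(z.index)]
        loadings, _ = np.linalg.qr(loadings[rows, :])
        logger.warning(
            "scoring in a reduced space of %d/%d genes", len(rows), len(model.gene_ids)
        )
    restricted = DetectorModel.__new__(DetectorModel)
    restricted.__dict__.update(model.__dict__)
    restricted.loadings = loadings
    return classify(restricted, z, true_labels=x.labels)
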
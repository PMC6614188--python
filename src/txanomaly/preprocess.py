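"""Per-gene z-score standardization with parameters frozen on the training set.

The detector is trained on healthy samples only, so each gene's mean and
standard deviation are estimated once from the training matrix and then
re-applied, unchanged, to any test data. An optional log2(v + pseudocount)
transform can precede standardization; whether it was applied is recorded in
the standardizer so that test data always pass through the identical pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass
class Standardizer:
    """Frozen per-gene standardization parameters.

    ``gene_ids`` lists the retained genes in training order; genes whose
    training standard deviation fell at or below ``min_sd`` were dropped
    (``n_dropped`` of them). ``sds`` uses the n-1 (sampling) denominator.
    """

    gene_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    log_applied: bool = False
    pseudocount: float = 1.0
    min_sd: float = 1e-8
    n_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.gene_ids) == self.means.size == self.sds.size):
            raise PreprocessError("gene_ids, means and sds must have equal length")
        if self.min_sd < 0:
            raise PreprocessError("min_sd must be non-negative")
        if self.sds.size and self.sds.min() <= self.min_sd:
            raise PreprocessError("every retained sd must exceed min_sd")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def log_transform(x: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return a copy of ``x`` with every value v replaced by log2(v + pseudocount)."""
    if pseudocount < 0:
        raise PreprocessError("pseudocount must be non-negative")
    if pseudocount == 0 and x.values.size and x.values.min() <= 0:
        raise PreprocessError("pseudocount 0 requires strictly positive values")
    return ExpressionMatrix(
        gene_ids=list(x.gene_ids),
        sample_ids=list(x.sample_ids),
        values=np.log2(x.values + pseudocount),
        labels=dict(x.labels) if x.labels is not None else None,
        non_negative=False,
    )


def fit_standardizer(
    train: ExpressionMatrix,
    min_sd: float = 1e-8,
    log: bool = False,
    pseudocount: float = 1.0,
) -> Standardizer:
    """Estimate per-gene means and SDs on the training matrix.

    Genes with sd <= ``min_sd`` (near-constant in training) carry no usable
    signal and would blow up the z-score, so they are dropped; the count is
    logged. Applying ``log=True`` computes the statistics on the
    log2(v + pseudocount) scale.
    """
    if train.n_samples < 2:
        raise PreprocessError("fitting a standardizer requires at least 2 samples")
    values = log_transform(train, pseudocount).values if log else train.values
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    keep = sds > min_sd
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d/%d genes with sd <= %g", n_dropped, train.n_genes, min_sd
        )
    if not keep.any():
        raise PreprocessError("all genes dropped by the variance filter")
    return Standardizer(
        gene_ids=[g for g, k in zip(train.gene_ids, keep) if k],
        means=means[keep],
        sds=sds[keep],
        log_applied=log,
        pseudocount=pseudocount,
        min_sd=min_sd,
        n_dropped=n_dropped,
    )


def apply_standardizer(
    s: Standardizer,
    x: ExpressionMatrix,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Standardize ``x`` with the frozen training parameters of ``s``.

    Returns a genes x samples DataFrame whose rows follow ``s.gene_ids``. With
    ``on_missing="intersect"``, genes of ``s`` absent from ``x`` are dropped
    (logged); the default ``"error"`` refuses, naming the first missing gene,
    because silently shrinking the gene panel changes the model's geometry.
    """
    if on_missing not in ("error", "intersect"):
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    pos = {g: i for i, g in enumerate(x.gene_ids)}
    missing = [g for g in s.gene_ids if g not in pos]
    if missing:
        if on_missing == "error":
            raise PreprocessError(
                f"gene {missing[0]!r} required by the standardizer is absent "
                f"from the input ({len(missing)} missing in total)"
            )
        logger.warning(
            "restricting standardizer to %d/%d shared genes",
            s.n_genes - len(missing), s.n_genes,
        )
    keep = [i for i, g in enumerate(s.gene_ids) if g in pos]
    gene_ids = [s.gene_ids[i] for i in keep]
    values = x.values
    if s.log_applied:
        if s.pseudocount == 0 and values.size and values.min() <= 0:
            raise PreprocessError("pseudocount 0 requires strictly positive values")
        values = np.log2(values + s.pseudocount)
    rows = [pos[g] for g in gene_ids]
    z = (values[rows, :] - s.means[keep, None]) / s.sds[keep, None]
    return pd.DataFrame(z, index=gene_ids, columns=x.sample_ids)
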
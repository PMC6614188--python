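"""Synthetic transcriptome generator with known low-rank latent structure.

Healthy bulk expression is emulated by a linear factor model on the log2
scale: L = mu + W z + eps, with per-gene intercepts mu, a p x d loading matrix
W whose orthogonalized columns are scaled so each factor contributes variance
``loading_scale**2`` per gene on average, latent factors z ~ N(0, I) per
sample, and isotropic noise eps with sd ``noise_sd``. Expression values are
then 2**L - pseudocount, clipped at zero, so they are FPKM-like and
non-negative, and the pipeline's log2(v + pseudocount) transform approximately
linearizes the structure.

Anomalies depart from the healthy law in one of two ways:

* ``off_subspace`` — a displacement of magnitude ``delta`` along a fresh
  random unit vector orthogonal to all columns of W (anomalies need not
  resemble each other); this is what the residue statistic is built to catch.
* ``factor_inflation`` — the latent z is scaled by ``delta``, moving the
  sample far *within* the modeled subspace; a documented negative control
  that the residue statistic is largely blind to.

A batch-shift stressor adds one shared per-gene log-scale offset to every
sample, emulating an inter-cohort bias that inflates false alarms.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .data_io import ExpressionMatrix

_STREAMS = ("model", "normal", "anomaly", "test")

OFF_SUBSPACE = "off_subspace"
FACTOR_INFLATION = "factor_inflation"


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults describe a mid-sized bulk cohort: 2000 genes, 300 healthy
    training samples, a rank-10 latent structure whose factors dominate the
    per-gene variance (joint loading scale 3 vs. noise sd 1 on the log2
    scale), and 200 anomalous samples displaced by delta = 10 noise-sd units.
    The baseline intercepts put the median around 2**6 = 64 FPKM so that
    clipping at zero touches only a small low-expression tail.
    """

    p: int = 2000
    n_normal: int = 300
    n_anomaly: int = 200
    d: int = 10
    loading_scales: float | Sequence[float] = 3.0
    noise_sd: float = 1.0
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    delta: float = 10.0
    anomaly_mode: str = OFF_SUBSPACE
    batch_shift_sd: float = 0.0
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.isscalar(self.loading_scales):
            self.loading_scales = (float(self.loading_scales),) * self.d
        else:
            self.loading_scales = tuple(float(v) for v in self.loading_scales)
        if len(self.loading_scales) != self.d:
            raise SyntheticError("loading_scales must have length d")
        if self.d >= min(self.p, self.n_normal):
            raise SyntheticError("d must be smaller than both p and n_normal")
        if any(v <= 0 for v in self.loading_scales):
            raise SyntheticError("loading_scales must be positive")
        if self.noise_sd <= 0:
            raise SyntheticError("noise_sd must be positive")
        if self.delta < 0 or self.batch_shift_sd < 0 or self.pseudocount < 0:
            raise SyntheticError("delta, batch_shift_sd, pseudocount must be >= 0")
        if self.anomaly_mode not in (OFF_SUBSPACE, FACTOR_INFLATION):
            raise SyntheticError(f"unknown anomaly_mode {self.anomaly_mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["loading_scales"] = list(self.loading_scales)
        return d


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(spec.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


def _orthogonalize(a: np.ndarray) -> np.ndarray:
    """Sequential projection-removal (Gram–Schmidt) of the columns of ``a``."""
    q = np.empty_like(a, dtype=float)
    for j in range(a.shape[1]):
        v = a[:, j].copy()
        for i in range(j):
            v -= (q[:, i] @ v) * q[:, i]
        norm = np.linalg.norm(v)
        if norm == 0:
            raise SyntheticError("degenerate loading draw; change the seed")
        q[:, j] = v / norm
    return q


def draw_latent_model(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """The (W, mu) pair shared by normal and anomalous samples of one spec.

    W's columns are orthogonal with norm sqrt(p/d) * scale_j: with equal
    scales s, the d factors jointly contribute variance s**2 to a typical
    gene (s**2/d each), so s directly sets the strength of the latent block
    against the noise floor — s = 3 vs noise_sd = 1 puts ~90% of the per-gene
    variance in the d dominant covariance directions.
    """
    rng = _rng(spec, "model")
    basis = _orthogonalize(rng.standard_normal((spec.p, spec.d)))
    w = basis * (np.sqrt(spec.p / spec.d) * np.asarray(spec.loading_scales))
    mu = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.p)
    return w, mu


def _expression(spec: SyntheticSpec, log_values: np.ndarray) -> np.ndarray:
    return np.clip(2.0 ** log_values - spec.pseudocount, 0.0, None)


def _wrap(
    spec: SyntheticSpec, values: np.ndarray, prefix: str, label: str
) -> ExpressionMatrix:
    gene_ids = [f"G{i:05d}" for i in range(spec.p)]
    sample_ids = [f"{prefix}_{j:04d}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        labels={s: label for s in sample_ids},
    )


def generate_normal(
    spec: SyntheticSpec,
    n_samples: int | None = None,
    stream: str = "normal",
    sample_prefix: str | None = None,
) -> ExpressionMatrix:
    """Healthy samples from the latent factor model; labels all normal.

    ``stream="test"`` draws an independent cohort (same W and mu) for held-out
    evaluation without touching the training stream.
    """
    n = spec.n_normal if n_samples is None else int(n_samples)
    w, mu = draw_latent_model(spec)
    rng = _rng(spec, stream)
    z = rng.standard_normal((spec.d, n))
    eps = spec.noise_sd * rng.standard_normal((spec.p, n))
    log_values = mu[:, None] + w @ z + eps
    prefix = sample_prefix or ("normal" if stream == "normal" else stream)
    return _wrap(spec, _expression(spec, log_values), prefix, "normal")


def generate_anomalies(
    spec: SyntheticSpec,
    w: np.ndarray | None = None,
    mu: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Anomalous samples sharing the healthy model's (W, mu); labels all cancer.

    With ``delta=0`` the off-subspace mode reduces exactly to the healthy
    generative law (an independent draw from it).
    """
    if spec.n_anomaly < 1:
        raise SyntheticError("n_anomaly must be at least 1")
    if w is None or mu is None:
        w, mu = draw_latent_model(spec)
    rng = _rng(spec, "anomaly")
    n = spec.n_anomaly
    if spec.anomaly_mode == OFF_SUBSPACE:
        if spec.d >= spec.p:
            raise SyntheticError("no direction orthogonal to W exists when d = p")
        z = rng.standard_normal((spec.d, n))
        basis = w / np.linalg.norm(w, axis=0)
        raw = rng.standard_normal((spec.p, n))
        u = raw - basis @ (basis.T @ raw)
        u /= np.linalg.norm(u, axis=0)
        displacement = spec.delta * u
        log_values = mu[:, None] + w @ z + displacement
    else:  # factor_inflation: anomalous within the modeled subspace
        z = spec.delta * rng.standard_normal((spec.d, n))
        log_values = mu[:, None] + w @ z
    log_values = log_values + spec.noise_sd * rng.standard_normal((spec.p, n))
    return _wrap(spec, _expression(spec, log_values), "cancer", "cancer")


def apply_batch_shift(
    x: ExpressionMatrix,
    batch_shift_sd: float,
    seed: int,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Add one shared per-gene log2-scale offset (sd ``batch_shift_sd``) to
    every sample — a stress input emulating an inter-batch bias."""
    if batch_shift_sd < 0:
        raise SyntheticError("batch_shift_sd must be >= 0")
    if batch_shift_sd == 0:
        return x
    offsets = np.random.default_rng(seed).normal(0.0, batch_shift_sd, x.n_genes)
    shifted = np.clip(
        (x.values + pseudocount) * 2.0 ** offsets[:, None] - pseudocount, 0.0, None
    )
    return ExpressionMatrix(
        gene_ids=list(x.gene_ids),
        sample_ids=list(x.sample_ids),
        values=shifted,
        labels=dict(x.labels) if x.labels is not None else None,
    )


def simulate(
    spec: SyntheticSpec, n_test_normal: int | None = None
) -> dict[str, ExpressionMatrix]:
    """One full study: a healthy training cohort, and a labeled test cohort of
    held-out healthy samples plus anomalies (batch-shifted if requested)."""
    from .data_io import concat_samples

    w, mu = draw_latent_model(spec)
    train = generate_normal(spec)
    held_out = generate_normal(
        spec,
        n_samples=spec.n_normal if n_test_normal is None else n_test_normal,
        stream="test",
    )
    test = concat_samples(held_out, generate_anomalies(spec, w, mu))
    if spec.batch_shift_sd > 0:
        shift_seed = int(np.random.SeedSequence(spec.seed).spawn(5)[4].generate_state(1)[0] % (2**31))
        test = apply_batch_shift(
            test, spec.batch_shift_sd, shift_seed, pseudocount=spec.pseudocount
        )
    return {"train": train, "test": test}
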
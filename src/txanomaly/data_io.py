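"""Reading and writing expression matrices, label files, score tables, and models.

The canonical in-memory layout is genes-as-rows: an expression matrix holds one
row per gene and one column per sample, with non-negative FPKM-like values.
Files are plain delimited text (TSV by default) with IDs in the first
row/column. Missing values are not supported: any non-numeric cell is a hard
error rather than silent imputation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: permitted sample labels (the positive class is "cancer" throughout)
LABEL_TOKENS = ("normal", "cancer")

#: token used for absent true labels in score tables
NA_TOKEN = "NA"

MODEL_FORMAT = "txanomaly-model"
MODEL_FORMAT_VERSION = 1

SCORE_COLUMNS = ["sample_id", "score", "log_ratio", "call", "true_label"]


class DataError(ValueError):
    """Malformed input data (duplicate IDs, non-numeric or negative cells...)."""


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with optional sample labels.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row and column identifiers.
    values
        ``(n_genes, n_samples)`` array of finite values. Raw expression must be
        non-negative; transformed copies (e.g. log scale) may relax this via
        ``non_negative=False``.
    labels
        Optional map from sample_id to ``"normal"`` or ``"cancer"``; used for
        evaluation only, never for fitting.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: dict[str, str] | None = None
    non_negative: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise DataError(f"duplicate {name} ID: {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values must be finite")
        if self.non_negative and self.values.size and self.values.min() < 0:
            raise DataError("expression values must be non-negative")
        if self.labels is not None:
            known = set(self.sample_ids)
            for sid, lab in self.labels.items():
                if sid not in known:
                    raise DataError(f"label for unknown sample {sid!r}")
                if lab not in LABEL_TOKENS:
                    raise DataError(
                        f"label {lab!r} for sample {sid!r}; permitted: {LABEL_TOKENS}"
                    )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        labels: Mapping[str, str] | None = None,
        non_negative: bool = True,
    ) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index),
            sample_ids=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            labels=dict(labels) if labels is not None else None,
            non_negative=non_negative,
        )

    def subset_samples(self, which: Sequence[int] | Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to the given sample indices or IDs."""
        if len(which) and isinstance(which[0], str):
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = [pos[s] for s in which]
        else:
            idx = [int(i) for i in which]
        sample_ids = [self.sample_ids[i] for i in idx]
        labels = None
        if self.labels is not None:
            labels = {s: self.labels[s] for s in sample_ids if s in self.labels}
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=sample_ids,
            values=self.values[:, idx].copy(),
            labels=labels,
            non_negative=self.non_negative,
        )


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def concat_samples(*matrices: ExpressionMatrix) -> ExpressionMatrix:
    """Column-bind matrices that share an identical gene panel."""
    first = matrices[0]
    for m in matrices[1:]:
        if m.gene_ids != first.gene_ids:
            raise DataError("cannot concatenate: gene panels differ")
    labels: dict[str, str] = {}
    for m in matrices:
        labels.update(m.labels or {})
    return ExpressionMatrix(
        gene_ids=list(first.gene_ids),
        sample_ids=[s for m in matrices for s in m.sample_ids],
        values=np.hstack([m.values for m in matrices]),
        labels=labels or None,
        non_negative=all(m.non_negative for m in matrices),
    )


def read_expression(
    path: str | Path,
    orientation: str = "genes_as_rows",
    delimiter: str = "\t",
) -> ExpressionMatrix:
    """Read a delimited expression matrix into canonical genes-as-rows form.

    The first row and first column hold sample and gene IDs (or vice versa for
    ``orientation="samples_as_rows"``). Duplicate IDs, non-numeric cells and
    negative values are hard errors.
    """
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    col_ids = [c.strip() for c in header[1:]]
    dup = _first_duplicate(col_ids)
    if dup is not None:
        raise DataError(f"duplicate ID in header of {path.name}: {dup!r}")
    raw = pd.read_csv(
        path, sep=delimiter, index_col=0, header=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    raw.columns = col_ids
    row_ids = [str(i).strip() for i in raw.index]
    dup = _first_duplicate(row_ids)
    if dup is not None:
        raise DataError(f"duplicate ID in first column of {path.name}: {dup!r}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            i = int(bad[0])
            raise DataError(
                f"non-numeric cell {raw.iat[i, j]!r} at row {row_ids[i]!r}, "
                f"column {col!r} of {path.name}"
            )
        values[:, j] = converted.to_numpy()
    if orientation == "samples_as_rows":
        values = values.T
        gene_ids, sample_ids = col_ids, row_ids
    else:
        gene_ids, sample_ids = row_ids, col_ids
    if values.size and values.min() < 0:
        i, j = np.unravel_index(int(np.argmin(values)), values.shape)
        raise DataError(
            f"negative value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)


def write_expression(
    x: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    x.to_frame().to_csv(path, sep=delimiter, index_label="gene_id")


def read_labels(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column sample_id / label file.

    Labels are matched case-insensitively against ``normal`` and ``cancer``.
    A first row whose second field is not a permitted token is treated as a
    header. An empty file yields an empty map.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise DataError(f"line {lineno + 1}: expected two fields, got {line!r}")
            sid, token = parts[0].strip(), parts[1].strip().lower()
            if token not in LABEL_TOKENS:
                if lineno == 0:
                    continue  # header row
                raise DataError(
                    f"line {lineno + 1}: unknown label {parts[1]!r}; "
                    f"permitted tokens: {LABEL_TOKENS}"
                )
            if sid in labels:
                raise DataError(f"duplicate sample ID in label file: {sid!r}")
            labels[sid] = token
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["sample_id", "label"]) + "\n")
        for sid, lab in labels.items():
            fh.write(delimiter.join([sid, lab]) + "\n")


def write_scores(
    table: pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a score table as TSV (columns sample_id, score, log_ratio, call,
    true_label), with optional ``# key: value`` metadata header lines so that
    the detector settings behind every call remain auditable."""
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"score table is missing columns: {missing}")
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        table[SCORE_COLUMNS].to_csv(fh, sep="\t", index=False, na_rep=NA_TOKEN)


def read_scores(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", comment="#", na_values=[NA_TOKEN], keep_default_na=False,
    )
    for col in ("score", "log_ratio"):
        table[col] = pd.to_numeric(table[col])
    return table


def _model_to_dict(model) -> dict:
    from . import __version__

    s = model.standardizer
    return {
        "format": MODEL_FORMAT,
        "format_version": MODEL_FORMAT_VERSION,
        "software_version": __version__,
        "standardizer": {
            "gene_ids": list(s.gene_ids),
            "means": [float(v) for v in s.means],
            "sds": [float(v) for v in s.sds],
            "log_applied": bool(s.log_applied),
            "pseudocount": float(s.pseudocount),
            "min_sd": float(s.min_sd),
            "n_dropped": int(s.n_dropped),
        },
        "detector": {
            "loadings": [[float(v) for v in row] for row in model.loadings],
            "eigenvalues": [float(v) for v in model.eigenvalues],
            "k": int(model.k),
            "alpha": float(model.alpha),
            "theta1": float(model.theta1),
            "theta2": float(model.theta2),
            "theta3": float(model.theta3),
            "h0": float(model.h0),
            "c_alpha": float(model.c_alpha),
            "q_threshold": float(model.q_threshold),
            "threshold_method": model.threshold_method,
            "log_ratio_base": float(model.log_ratio_base),
        },
    }


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted detector (standardizer included) to a JSON container.

    The standardizer travels inside the same file so that scoring with a
    mismatched standardizer is impossible.
    """
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path):
    from .detector import DetectorModel
    from .preprocess import Standardizer

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != MODEL_FORMAT:
        raise DataError(f"{path}: not a {MODEL_FORMAT} file")
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise DataError(
            f"{path}: unsupported format version {doc.get('format_version')!r}"
        )
    sd = doc["standardizer"]
    standardizer = Standardizer(
        gene_ids=list(sd["gene_ids"]),
        means=np.asarray(sd["means"], dtype=float),
        sds=np.asarray(sd["sds"], dtype=float),
        log_applied=bool(sd["log_applied"]),
        pseudocount=float(sd["pseudocount"]),
        min_sd=float(sd["min_sd"]),
        n_dropped=int(sd.get("n_dropped", 0)),
    )
    dd = doc["detector"]
    return DetectorModel(
        standardizer=standardizer,
        loadings=np.asarray(dd["loadings"], dtype=float),
        eigenvalues=np.asarray(dd["eigenvalues"], dtype=float),
        k=int(dd["k"]),
        alpha=float(dd["alpha"]),
        theta1=float(dd["theta1"]),
        theta2=float(dd["theta2"]),
        theta3=float(dd["theta3"]),
        h0=float(dd["h0"]),
        c_alpha=float(dd["c_alpha"]),
        q_threshold=float(dd["q_threshold"]),
        threshold_method=dd["threshold_method"],
        log_ratio_base=float(dd["log_ratio_base"]),
    )
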
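"""Expression preprocessing: probe collapsing, missingness filtering,
log transform, per-tissue SVD variance diagnostics, and z-score scaling.

The fixed pipeline order is collapse -> filter/impute -> log -> SVD report ->
z-score.  The SVD step is diagnostic only (no components are removed); the
log transform is skipped for matrices that already contain negative values,
which are taken to be on a log-like scale already.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix

__all__ = [
    "SvdReport",
    "collapse_probes",
    "filter_missing",
    "log_transform",
    "svd_variance_report",
    "zscore_normalize",
]


@dataclass
class SvdReport:
    """Per-tissue singular-value variance fractions (diagnostic only)."""

    tissue: str
    component_variance_fractions: list[float]
    degenerate: bool = False  # all-zero matrix after centering

    def __post_init__(self) -> None:
        f = np.asarray(self.component_variance_fractions)
        if len(f) and not self.degenerate:
            if abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("variance fractions must sum to 1")
            if np.any(np.diff(f) > 1e-12):
                raise ValueError("variance fractions must be non-increasing")


def collapse_probes(matrix: ExpressionMatrix,
                    probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to gene symbols by per-sample mean.

    Probes absent from the mapping are dropped.  The mean for each
    (gene, sample) cell is taken over the probes with a non-missing value in
    that sample; a cell is missing only if every mapped probe is missing.
    """
    if not probe_to_gene:
        raise ValueError("probe-to-gene mapping is empty")
    mapped = [p for p in matrix.values.index if p in probe_to_gene]
    if not mapped:
        raise ValueError("no probe in the matrix is covered by the mapping")
    sub = matrix.values.loc[mapped]
    symbols = pd.Index([probe_to_gene[p] for p in mapped], name="gene")
    collapsed = sub.groupby(symbols, sort=True).mean()  # skips NaN per cell
    return ExpressionMatrix(collapsed, matrix.samples)


def filter_missing(matrix: ExpressionMatrix,
                   max_fraction: float = 0.30) -> ExpressionMatrix:
    """Drop genes with missing fraction >= ``max_fraction`` (inclusive) and
    mean-impute the rest within tissue.

    Imputation uses the gene's mean over non-missing samples of the same
    tissue; if a gene is entirely missing within one tissue, the gene's
    global mean fills in.  The result contains no missing values.
    """
    frac = matrix.values.isna().mean(axis=1)
    keep = frac[frac < max_fraction].index
    if len(keep) == 0:
        raise ValueError("missingness filter removed every gene")
    values = matrix.values.loc[keep].copy()
    tissues = matrix.samples["tissue"]
    for tissue in tissues.unique():
        cols = tissues.index[tissues == tissue]
        block = values[cols]
        means = block.mean(axis=1)
        values[cols] = block.T.fillna(means).T
    # tissue-wide gaps fall back to the global gene mean
    if values.isna().any().any():
        values = values.T.fillna(values.mean(axis=1)).T
    return ExpressionMatrix(values, matrix.samples)


def log_transform(matrix: ExpressionMatrix, force: bool = False) -> ExpressionMatrix:
    """Apply ``log2(x + 1)`` elementwise.

    Matrices containing negative values are assumed to be pre-logged and are
    returned unchanged unless ``force`` is set.  Values at or below -1 under
    ``force`` would produce non-finite results and raise, naming the genes.
    """
    vals = matrix.values
    if (vals.values < 0).any() and not force:
        return matrix
    out = np.log2(vals + 1.0)
    bad = out.index[~np.isfinite(out).all(axis=1)].tolist()
    if bad:
        raise ValueError(f"log transform produced non-finite values for genes: {bad[:5]}")
    return ExpressionMatrix(out, matrix.samples)


def svd_variance_report(matrix: ExpressionMatrix) -> list[SvdReport]:
    """Per-tissue variance fractions of the row-centered expression submatrix.

    For each tissue with >=2 samples, rows (genes) are centered across that
    tissue's samples and the squared singular values are normalized to
    fractions.  Tissues with a single sample are skipped with a warning.
    This is a diagnostic of inter-sample variation; nothing is corrected.
    """
    reports: list[SvdReport] = []
    tissues = matrix.samples["tissue"]
    for tissue in sorted(tissues.unique()):
        cols = tissues.index[tissues == tissue]
        if len(cols) < 2:
            warnings.warn(f"tissue '{tissue}' has a single sample; SVD skipped")
            continue
        sub = matrix.values[cols].to_numpy(float)
        centered = sub - sub.mean(axis=1, keepdims=True)
        s = np.linalg.svd(centered, compute_uv=False)
        total = float((s ** 2).sum())
        if total == 0.0:
            reports.append(SvdReport(tissue=str(tissue),
                                     component_variance_fractions=[],
                                     degenerate=True))
            continue
        fractions = (s ** 2 / total).tolist()
        reports.append(SvdReport(tissue=str(tissue),
                                 component_variance_fractions=fractions))
    return reports


def zscore_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene row to mean 0, population SD 1.

    Zero-variance rows cannot be scaled; they are set to all-zeros and
    reported through a warning.  Requires a complete (no missing) matrix.
    """
    vals = matrix.values.to_numpy(float)
    if np.isnan(vals).any():
        raise ValueError("z-score requires a complete matrix; run filter_missing first")
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population SD
    flat = sd[:, 0] == 0.0
    sd[flat] = 1.0
    out = (vals - mu) / sd
    out[flat] = 0.0
    if flat.any():
        names = matrix.values.index[flat].tolist()
        warnings.warn(f"zero-variance genes set to zeros: {names[:5]}"
                      + ("..." if len(names) > 5 else ""))
    return ExpressionMatrix(pd.DataFrame(out, index=matrix.values.index,
                                         columns=matrix.values.columns),
                            matrix.samples)
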
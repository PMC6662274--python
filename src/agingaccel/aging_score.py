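"""Reference-based transcriptomic aging score and group comparisons.

A sample's raw aging score is the Euclidean distance (over a marker-gene
panel) to its nearest *young* normal reference (age <= 50 y) minus the
distance to its nearest *old* normal reference (age > 50 y); the score is
then arctan-transformed into (-pi/2, pi/2).  A positive score means the
profile sits closer to the old references — an "older" transcriptome.
Samples that belong to a reference pool are scored leave-one-out so they
never match themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import kruskal

from .data_model import ExpressionMatrix

__all__ = [
    "ReferencePools",
    "build_reference_pools",
    "compute_aging_scores",
    "kruskal_wallis_by_group",
    "age_group_summary",
    "DEFAULT_AGE_FLOORS",
]

DEFAULT_AGE_FLOORS = (58, 60, 65, 70, 75, 80, 85)


@dataclass
class ReferencePools:
    """Young (age <= threshold) and old (age > threshold) normal references,
    restricted to the marker panel; rows are samples."""

    young_ids: list[str]
    old_ids: list[str]
    young: np.ndarray
    old: np.ndarray
    marker_genes: list[str]

    def __post_init__(self) -> None:
        if len(self.young_ids) == 0 or len(self.old_ids) == 0:
            raise ValueError("both reference pools must be non-empty")
        if set(self.young_ids) & set(self.old_ids):
            raise ValueError("reference pools must be disjoint")


def build_reference_pools(matrix: ExpressionMatrix, marker_genes: list[str],
                          age_threshold: float = 50.0) -> ReferencePools:
    """Split the cohort's normal samples into young/old pools over the panel."""
    normal = matrix.samples["diagnosis"] == "normal"
    ages = matrix.samples["age"]
    young_ids = [s for s in matrix.sample_ids if normal[s] and ages[s] <= age_threshold]
    old_ids = [s for s in matrix.sample_ids if normal[s] and ages[s] > age_threshold]
    sub = matrix.values.loc[marker_genes]
    return ReferencePools(
        young_ids=young_ids, old_ids=old_ids,
        young=sub[young_ids].to_numpy(float).T,
        old=sub[old_ids].to_numpy(float).T,
        marker_genes=list(marker_genes),
    )


def compute_aging_scores(matrix: ExpressionMatrix, pools: ReferencePools,
                         marker_genes: list[str] | None = None) -> pd.DataFrame:
    """Score every sample of ``matrix``.

    Returns a DataFrame indexed by sample id with columns ``raw`` (nearest
    young distance minus nearest old distance), ``atan`` (arctan of raw),
    ``age`` and ``diagnosis``.  A sample that is itself a pool member is
    excluded from that pool when its minimum is taken; if that exclusion
    empties a pool, the sample cannot be scored and an error is raised.
    """
    genes = list(marker_genes) if marker_genes is not None else pools.marker_genes
    if genes != pools.marker_genes:
        raise ValueError("marker panel must match the pools' panel")
    Q = matrix.values.loc[genes].to_numpy(float).T
    d_young = cdist(Q, pools.young, metric="euclidean")
    d_old = cdist(Q, pools.old, metric="euclidean")

    young_pos = {s: j for j, s in enumerate(pools.young_ids)}
    old_pos = {s: j for j, s in enumerate(pools.old_ids)}
    for i, sid in enumerate(matrix.sample_ids):
        if sid in young_pos:
            d_young[i, young_pos[sid]] = np.inf
        if sid in old_pos:
            d_old[i, old_pos[sid]] = np.inf

    min_young = d_young.min(axis=1)
    min_old = d_old.min(axis=1)
    if not np.isfinite(min_young).all() or not np.isfinite(min_old).all():
        bad = [matrix.sample_ids[i] for i in
               np.flatnonzero(~np.isfinite(min_young) | ~np.isfinite(min_old))]
        raise ValueError(f"self-exclusion emptied a reference pool for: {bad[:5]}")

    raw = min_young - min_old
    return pd.DataFrame({
        "raw": raw,
        "atan": np.arctan(raw),
        "age": matrix.samples["age"].to_numpy(float),
        "diagnosis": matrix.samples["diagnosis"].to_numpy(),
    }, index=pd.Index(matrix.sample_ids, name="sample_id"))


def kruskal_wallis_by_group(scores: np.ndarray | pd.Series,
                            group_labels: np.ndarray | pd.Series) -> dict:
    """Kruskal-Wallis rank test across groups.

    Returns ``{"H": statistic, "p": p-value}`` with the usual tie correction
    and a chi-squared reference with (groups - 1) degrees of freedom.  If
    every observation is identical the statistic is 0 and p is reported as 1
    with a warning (the test is uninformative).
    """
    scores = np.asarray(scores, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = [scores[group_labels == g] for g in np.unique(group_labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if np.all(scores == scores[0]):
        warnings.warn("all scores identical; Kruskal-Wallis is uninformative")
        return {"H": 0.0, "p": 1.0}
    stat, p = kruskal(*groups)
    return {"H": float(stat), "p": float(p)}


def age_group_summary(scores: pd.DataFrame,
                      floors: tuple[int, ...] = DEFAULT_AGE_FLOORS) -> pd.DataFrame:
    """Median/mean aging score and age per diagnosis in nested age strata.

    Each row corresponds to a floor f and summarizes samples with age >= f,
    split by diagnosis; empty strata are reported as NaN with a zero count.
    """
    rows = []
    for floor in floors:
        sub = scores[scores["age"] >= floor]
        row: dict = {"age_floor": floor}
        for dx in ("AD", "normal"):
            grp = sub[sub["diagnosis"] == dx]
            row[f"median_score_{dx}"] = float(grp["atan"].median()) if len(grp) else np.nan
            row[f"mean_score_{dx}"] = float(grp["atan"].mean()) if len(grp) else np.nan
            row[f"median_age_{dx}"] = float(grp["age"].median()) if len(grp) else np.nan
            row[f"mean_age_{dx}"] = float(grp["age"].mean()) if len(grp) else np.nan
            row[f"n_{dx}"] = int(len(grp))
        rows.append(row)
    return pd.DataFrame(rows).set_index("age_floor")
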
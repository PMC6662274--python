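"""The aging-acceleration network: a differential product-correlation graph.

For every unordered gene pair, the per-sample product of the two expression
values is correlated (Pearson) with the samples' arctan aging scores,
separately within AD and within normal samples.  An edge between the two
genes is retained iff

1. p < ``p_threshold`` in both conditions,
2. Benjamini-Hochberg FDR < ``fdr_threshold`` in both conditions (the BH
   family is all tested pairs within each condition), and
3. the correlation signs differ between conditions.

Such a pair tracks the aging process in opposite directions in disease and
health — "aging acceleration".  Validation utilities: Fisher overlap of two
networks over the all-pairs universe, a log-log degree-distribution
linearity check for scale-freeness, and a degree-ranked hub predictor that
reuses the nearest-neighbour classifier machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

from .data_model import ExpressionMatrix
from .enrichment import bh_fdr
from .predictor import CvCurve, RankedGeneList, cross_validate_topk, evaluate, fit_nna

__all__ = [
    "AccelNetwork",
    "pair_product_correlations",
    "build_network",
    "fisher_overlap_test",
    "degree_distribution_fit",
    "degree_ranking",
    "hub_predictor",
]


@dataclass
class AccelNetwork:
    """Undirected acceleration network plus the roster of profiled genes.

    ``graph`` holds only genes incident to at least one retained edge; the
    isolated genes stay in ``genes`` so pair universes and degree rankings
    cover the whole profile.
    """

    graph: nx.Graph
    genes: list[str]

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0


def _pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r with n observations (t reference, n-2 df)."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def pair_product_correlations(matrix: ExpressionMatrix, aging_scores: pd.Series,
                              chunk_rows: int = 32) -> pd.DataFrame:
    """Pearson correlation of every pairwise expression product with the
    aging score, within one condition's samples.

    ``aging_scores`` must be indexed by the matrix's sample ids (arctan
    scale).  Pairs are enumerated in canonical (lexicographic gene-symbol)
    order.  Products are formed in row blocks of ``chunk_rows`` genes, so
    peak memory scales with ``chunk_rows * n_genes * n_samples`` — not with
    the total pair count.  Pairs whose product vector has zero variance are
    excluded and reported via a warning.

    Returns a DataFrame with columns ``gene_i``, ``gene_j``, ``r``, ``p``.
    """
    s = aging_scores.loc[matrix.sample_ids].to_numpy(float)
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    order = np.argsort(np.asarray(matrix.genes))
    genes = [matrix.genes[i] for i in order]
    X = matrix.values.to_numpy(float)[order]
    G = len(genes)

    sc = s - s.mean()
    s_norm = np.linalg.norm(sc)
    if s_norm == 0:
        raise ValueError("aging scores are constant; correlations undefined")

    gi_all: list[np.ndarray] = []
    gj_all: list[np.ndarray] = []
    r_all: list[np.ndarray] = []
    dropped = 0
    for start in range(0, G - 1, chunk_rows):
        stop = min(start + chunk_rows, G - 1)
        for i in range(start, stop):
            prod = X[i] * X[i + 1:]                      # (G-i-1) x n
            pc = prod - prod.mean(axis=1, keepdims=True)
            norms = np.linalg.norm(pc, axis=1)
            ok = norms > 0
            dropped += int((~ok).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (pc @ sc) / (norms * s_norm)
            gi_all.append(np.full(int(ok.sum()), i, dtype=np.int32))
            gj_all.append((np.flatnonzero(ok) + i + 1).astype(np.int32))
            r_all.append(r[ok])
    if dropped:
        warnings.warn(f"{dropped} pair(s) with zero-variance product excluded")

    gi = np.concatenate(gi_all) if gi_all else np.array([], dtype=np.int32)
    gj = np.concatenate(gj_all) if gj_all else np.array([], dtype=np.int32)
    r = np.concatenate(r_all) if r_all else np.array([])
    gene_arr = np.array(genes)
    return pd.DataFrame({
        "gene_i": gene_arr[gi],
        "gene_j": gene_arr[gj],
        "r": r,
        "p": _pearson_pvalues(r, n),
    })


def build_network(records_ad: pd.DataFrame, records_normal: pd.DataFrame,
                  genes: list[str], p_threshold: float = 0.05,
                  fdr_threshold: float = 0.2) -> AccelNetwork:
    """Apply the three retention criteria to matched AD/normal pair records.

    Both record frames must cover the identical canonical pair universe
    (pairs dropped as zero-variance in either condition are excluded from
    both).  BH FDR is computed over all tested pairs within each condition
    separately.
    """
    key = ["gene_i", "gene_j"]
    merged = records_ad.merge(records_normal, on=key, how="inner",
                              suffixes=("_ad", "_normal"))
    n_union = len(records_ad) + len(records_normal) - len(merged)
    if len(merged) != len(records_ad) or len(merged) != len(records_normal):
        if n_union - len(merged) > max(len(records_ad), len(records_normal)) * 0.01:
            raise ValueError("pair universes differ between conditions")
        warnings.warn(f"{n_union - len(merged)} pair(s) present in only one "
                      "condition excluded")
    merged = merged.assign(
        fdr_ad=bh_fdr(merged["p_ad"].to_numpy()),
        fdr_normal=bh_fdr(merged["p_normal"].to_numpy()),
    )
    keep = (
        (merged["p_ad"] < p_threshold)
        & (merged["p_normal"] < p_threshold)
        & (merged["fdr_ad"] < fdr_threshold)
        & (merged["fdr_normal"] < fdr_threshold)
        & (merged["r_ad"] * merged["r_normal"] < 0)
    )
    edges = merged[keep]
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.gene_i, row.gene_j, r_ad=row.r_ad, p_ad=row.p_ad,
                   fdr_ad=row.fdr_ad, r_normal=row.r_normal,
                   p_normal=row.p_normal, fdr_normal=row.fdr_normal)
    return AccelNetwork(graph=g, genes=list(genes))


def edge_table(network: AccelNetwork) -> pd.DataFrame:
    """Edge list with per-condition statistics, in canonical order."""
    rows = []
    for u, v, d in network.graph.edges(data=True):
        gi, gj = sorted((u, v))
        rows.append({"gene_i": gi, "gene_j": gj, **d})
    df = pd.DataFrame(rows, columns=["gene_i", "gene_j", "r_ad", "p_ad", "fdr_ad",
                                     "r_normal", "p_normal", "fdr_normal"])
    return df.sort_values(["gene_i", "gene_j"]).reset_index(drop=True)


def fisher_overlap_test(network_a: AccelNetwork, network_b: AccelNetwork) -> dict:
    """One-sided Fisher exact test for edge overlap of two networks.

    The pair universe is all unordered pairs over the shared profiled-gene
    roster (isolated genes included).  Returns the 2x2 table and the
    enrichment (greater) p-value from the hypergeometric tail.
    """
    shared = sorted(set(network_a.genes) & set(network_b.genes))
    if len(shared) < 2:
        raise ValueError("networks share fewer than two genes")
    shared_set = set(shared)
    ea = {e for e in network_a.edge_set if e[0] in shared_set and e[1] in shared_set}
    eb = {e for e in network_b.edge_set if e[0] in shared_set and e[1] in shared_set}
    if not ea or not eb:
        raise ValueError("both networks must have at least one edge over shared genes")
    universe = len(shared) * (len(shared) - 1) // 2
    a = len(ea & eb)
    b = len(ea - eb)
    c = len(eb - ea)
    d = universe - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="greater")
    return {"odds_table": table, "p": float(p)}


def degree_distribution_fit(network: AccelNetwork) -> dict:
    """Log-log linearity of the degree distribution (scale-free diagnostic).

    P(d) is the fraction of degree>=1 nodes with degree exactly d.  The
    Pearson correlation between log10(d) and log10(P(d)) over distinct
    degrees is returned with its two-sided p; strongly negative r indicates
    power-law-like decay.  Fewer than 3 distinct degrees is an error.
    """
    degs = np.array([d for _, d in network.graph.degree() if d >= 1])
    if degs.size == 0:
        raise ValueError("network has no connected nodes")
    uniq, counts = np.unique(degs, return_counts=True)
    if len(uniq) < 3:
        raise ValueError(f"only {len(uniq)} distinct degree(s); log-log fit undefined")
    prob = counts / degs.size
    r, p = stats.pearsonr(np.log10(uniq), np.log10(prob))
    return {"degrees": uniq, "probabilities": prob,
            "loglog_pearson_r": float(r), "p": float(p)}


def degree_ranking(network: AccelNetwork) -> RankedGeneList:
    """All profiled genes ranked by network degree (desc), then symbol (asc)."""
    degs = np.array([network.degree(g) for g in network.genes], dtype=float)
    genes = np.array(network.genes)
    order = np.lexsort((genes, -degs))
    return RankedGeneList(genes=list(genes[order]), weights=degs[order])


def hub_predictor(network: AccelNetwork, train: ExpressionMatrix,
                  test: ExpressionMatrix, train_labels: np.ndarray,
                  test_labels: np.ndarray, top_models: int = 100,
                  folds: int = 5, seed: int = 0) -> dict:
    """Train/evaluate a nearest-neighbour predictor on degree-ranked genes.

    The ranking replaces the ReliefF ordering; model selection and held-out
    evaluation reuse the predictor machinery unchanged.  If fewer than
    ``top_models`` genes have degree >= 1 the scan is clipped with a warning.
    """
    ranking = degree_ranking(network)
    n_connected = int((ranking.weights >= 1).sum())
    if n_connected == 0:
        raise ValueError("network has no connected genes to rank")
    if n_connected < top_models:
        warnings.warn(f"only {n_connected} genes with degree >= 1; "
                      f"top_models clipped from {top_models}")
        top_models = n_connected
    curve = cross_validate_topk(train, train_labels, ranking,
                                top_models=top_models, folds=folds, seed=seed)
    panel = ranking.top(curve.best_k)
    model = fit_nna(train, train_labels, panel)
    result = evaluate(model, test, np.asarray(test_labels, dtype=int))
    return {"curve": curve, "panel": panel, "model": model, **result}
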
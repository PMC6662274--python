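"""Aging-AD bipartite graph: shortest paths between the two biomarker panels
inside the acceleration network, plus the cross-panel correlation matrix.

Every (aging marker, AD marker) pair is queried for a shortest path in the
unweighted acceleration network (breadth-first search, which coincides with
Dijkstra under unit edge weights).  Reachable pairs form the bipartite
graph; each reported path is the lexicographically smallest node sequence
among the shortest ones, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix
from .network import AccelNetwork

__all__ = [
    "BipartitePair",
    "shortest_paths_between_sets",
    "build_bipartite_graph",
    "biomarker_correlations",
]


@dataclass
class BipartitePair:
    aging_marker: str
    ad_marker: str
    path: list[str]
    path_length: int

    def __post_init__(self) -> None:
        if self.path[0] != self.aging_marker or self.path[-1] != self.ad_marker:
            raise ValueError("path endpoints must be the two markers")
        if self.path_length != len(self.path) - 1 or self.path_length < 1:
            raise ValueError("path_length must equal hops and be >= 1")


def _lex_smallest_shortest_path(g: nx.Graph, source: str,
                                dist_to_target: dict, target: str) -> list[str]:
    """Greedy walk along BFS distance levels, always taking the smallest
    neighbour that still lies on some shortest path."""
    path = [source]
    cur = source
    while cur != target:
        remaining = dist_to_target[cur]
        nxt = min(n for n in g.neighbors(cur)
                  if dist_to_target.get(n, np.inf) == remaining - 1)
        path.append(nxt)
        cur = nxt
    return path


def shortest_paths_between_sets(network: AccelNetwork, aging_markers: list[str],
                                ad_markers: list[str]) -> list[BipartitePair]:
    """One shortest path per reachable (aging, AD) marker pair.

    Markers absent from the network (degree 0) are unreachable by
    definition; unreachable pairs and same-gene pairs are omitted.  Ties are
    broken toward the lexicographically smallest node sequence.
    """
    g = network.graph
    if g.number_of_edges() == 0:
        raise ValueError("acceleration network has no edges")
    pairs: list[BipartitePair] = []
    for ad in ad_markers:
        if ad not in g:
            continue
        dist = nx.single_source_shortest_path_length(g, ad)
        for aging in aging_markers:
            if aging == ad or aging not in dist:
                continue
            path = _lex_smallest_shortest_path(g, aging, dist, ad)
            pairs.append(BipartitePair(aging_marker=aging, ad_marker=ad,
                                       path=path, path_length=len(path) - 1))
    pairs.sort(key=lambda p: (p.aging_marker, p.ad_marker))
    return pairs


def build_bipartite_graph(pairs: list[BipartitePair]) -> dict:
    """Summarize the bipartite connection structure.

    Returns counts of connected aging and AD markers, number of pairs, and
    per-marker connection degrees (how many markers of the other panel each
    marker reaches) — the basis of the "links the most" hub ranking.
    """
    aging_degree: dict[str, int] = {}
    ad_degree: dict[str, int] = {}
    for p in pairs:
        aging_degree[p.aging_marker] = aging_degree.get(p.aging_marker, 0) + 1
        ad_degree[p.ad_marker] = ad_degree.get(p.ad_marker, 0) + 1
    return {
        "n_pairs": len(pairs),
        "n_aging_connected": len(aging_degree),
        "n_ad_connected": len(ad_degree),
        "aging_degree": dict(sorted(aging_degree.items(), key=lambda kv: (-kv[1], kv[0]))),
        "ad_degree": dict(sorted(ad_degree.items(), key=lambda kv: (-kv[1], kv[0]))),
    }


def biomarker_correlations(ad_matrix: ExpressionMatrix, aging_markers: list[str],
                           ad_markers: list[str]) -> dict:
    """Pearson correlations between the two marker panels in AD samples.

    Rows are aging markers, columns AD markers.  Zero-variance markers give
    undefined (NaN) entries and are listed in ``undefined``.  The pair with
    the largest |r| (excluding any self-pair and NaN) is reported.
    """
    A = ad_matrix.values.loc[aging_markers].to_numpy(float)
    B = ad_matrix.values.loc[ad_markers].to_numpy(float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    undefined = ([g for g, v in zip(aging_markers, na) if v == 0]
                 + [g for g, v in zip(ad_markers, nb) if v == 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Ac @ Bc.T) / np.outer(na, nb)
    mat = pd.DataFrame(R, index=aging_markers, columns=ad_markers)

    best = None
    absR = np.abs(np.nan_to_num(R, nan=-1.0))
    for i, gi in enumerate(aging_markers):
        for j, gj in enumerate(ad_markers):
            if gi == gj:
                absR[i, j] = -1.0
    if absR.max() >= 0:
        i, j = np.unravel_index(np.argmax(absR), absR.shape)
        best = (aging_markers[i], ad_markers[j], float(R[i, j]))
    return {"matrix": mat, "max_abs_pair": best, "undefined": undefined}
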
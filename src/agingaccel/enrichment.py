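"""Hypergeometric over-representation tests with Benjamini-Hochberg FDR.

The urn model: a background of N profiled genes contains M members of a
known set; drawing the n query genes without replacement, the upper-tail
probability of seeing at least the observed overlap x is

    p = P(X >= x) = 1 - sum_{k=0}^{x-1} C(M,k) C(N-M, n-k) / C(N,n).

Gene sets are intersected with the background before M is counted, so the
urn stays coherent; the BH family is the collection of sets tested in one
call.  Significance uses strict thresholds p < 0.05 and FDR < 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_model import GeneSetCollection

__all__ = ["EnrichmentResult", "hypergeom_pvalue", "bh_fdr", "enrich"]


@dataclass
class EnrichmentResult:
    set_name: str
    N: int   # background size
    M: int   # set size within background
    n: int   # query size
    x: int   # overlap
    p: float
    fdr: float
    significant: bool


def hypergeom_pvalue(N: int, M: int, n: int, x: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    ``N``: background size; ``M``: marked genes in the background; ``n``:
    query size; ``x``: observed overlap.  Evaluated via the survival
    function of the hypergeometric distribution, which works in log space
    internally and stays stable at N ~ 1e4.
    """
    if not (N >= M >= 0 and N >= n >= 0):
        raise ValueError(f"invalid urn: N={N}, M={M}, n={n}")
    if not 0 <= x <= min(M, n):
        raise ValueError(f"overlap x={x} outside [0, min(M={M}, n={n})]")
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, N, M, n))


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(query_genes: Iterable[str], gene_sets: GeneSetCollection,
           background: Iterable[str], p_threshold: float = 0.05,
           fdr_threshold: float = 0.2) -> list[EnrichmentResult]:
    """Test each gene set for over-representation of the query.

    The background is the full profiled gene universe (its size is N of the
    urn); query genes outside the background are ignored.  One result per
    set, sorted by ascending p; ``significant`` requires both p <
    ``p_threshold`` and BH FDR < ``fdr_threshold`` (strict), with the BH
    family being all sets tested in this call.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    query = set(query_genes) & bg
    if not query:
        raise ValueError("query is empty after intersection with the background")
    if len(gene_sets) == 0:
        raise ValueError("gene-set collection is empty")
    N, n = len(bg), len(query)
    names, ps, Ms, xs = [], [], [], []
    for name, members in gene_sets.sets.items():
        mem = set(members) & bg
        M = len(mem)
        x = len(mem & query)
        names.append(name)
        Ms.append(M)
        xs.append(x)
        ps.append(hypergeom_pvalue(N, M, n, x))
    fdrs = bh_fdr(np.array(ps))
    results = [
        EnrichmentResult(set_name=name, N=N, M=M, n=n, x=x, p=p, fdr=float(f),
                         significant=bool(p < p_threshold and f < fdr_threshold))
        for name, M, x, p, f in zip(names, Ms, xs, ps, fdrs)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results
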
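"""Synthetic cohort generator with planted statistical structure.

The generator emulates the shape of a merged brain-expression compendium:
hundreds of samples spanning young (<=50 y) to old ages, normal and AD
diagnoses, a few tissues, optional missing values, and three kinds of planted
signal that the downstream analyses are designed to detect:

* **aging markers** — genes whose expression drifts linearly with
  standardized chronological age in every sample;
* **AD markers** — genes mean-shifted in AD samples only;
* **planted acceleration edges** — gene pairs ``(g_i, g_j)`` coupled as
  ``x_j = b * a * x_i + eps`` in normal samples and ``x_j = -b * a * x_i + eps``
  in AD samples, where ``a`` is the sample's standardized age.  The product
  ``x_i * x_j`` then correlates with any age-increasing score with opposite
  signs in the two diagnosis groups, which is precisely the edge-retention
  criterion of the acceleration network.

An optional ``ad_acceleration`` shift moves AD samples along the aging-marker
axis so their transcriptomic age exceeds their chronological age, the
"accelerated aging" pattern the aging score is meant to expose.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix

__all__ = ["SimulationSpec", "GroundTruth", "generate_cohort", "generate_worked_graph"]

TISSUES = ("frontal_cortex", "temporal_cortex", "hippocampus")


@dataclass
class SimulationSpec:
    """Parameters of one synthetic cohort.

    Defaults are the cohort conditions used throughout the test suite:
    500 genes, 300 samples per diagnosis arm, unit effect sizes and unit
    noise, and edge-planting coefficient ``edge_strength = 1``.
    """

    n_genes: int = 500
    n_samples_normal: int = 300
    n_samples_ad: int = 300
    n_aging_markers: int = 30
    n_ad_markers: int = 30
    n_planted_edges: int = 20
    aging_effect: float = 1.0      # slope of expression on standardized age
    ad_effect: float = 1.0         # mean shift of AD markers in AD samples
    ad_acceleration: float = 0.0   # extra shift of AD samples along aging markers
    edge_strength: float = 1.0     # planting coefficient b > 0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_samples_normal < 0 or self.n_samples_ad < 0:
            raise ValueError("sample counts must be non-negative")
        if self.n_samples_normal + self.n_samples_ad == 0:
            raise ValueError("cohort must contain at least one sample")
        needed = self.n_aging_markers + self.n_ad_markers + 2 * self.n_planted_edges
        if needed > self.n_genes:
            raise ValueError(
                f"spec infeasible: markers + edge endpoints need {needed} genes "
                f"but n_genes={self.n_genes}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0,1)")
        if self.edge_strength < 0:
            raise ValueError("edge_strength must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GroundTruth:
    """What was planted: marker gene lists and acceleration edges."""

    aging_markers: list[str]
    ad_markers: list[str]
    planted_edges: list[tuple[str, str]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "aging_markers": self.aging_markers,
                "ad_markers": self.ad_markers,
                "planted_edges": [list(e) for e in self.planted_edges],
            }, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(aging_markers=d["aging_markers"], ad_markers=d["ad_markers"],
                   planted_edges=[tuple(e) for e in d["planted_edges"]])


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_cohort(spec: SimulationSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one cohort with the planted structure described in the module docs.

    Ages are uniform on [20, 100]; the expression baseline is i.i.d.
    ``Normal(0, noise_sd)``.  Marker genes, AD shifts and planted edges are
    layered on top of the baseline.  Sample order and all draws are fully
    determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_samples_normal + spec.n_samples_ad
    sample_ids = [f"S{i:05d}" for i in range(1, n_total + 1)]
    diagnosis = np.array(["normal"] * spec.n_samples_normal + ["AD"] * spec.n_samples_ad)
    ages = rng.uniform(20.0, 100.0, size=n_total)
    a = (ages - ages.mean()) / ages.std()  # standardized age surrogate

    genes = _gene_names(spec.n_genes)
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_total))

    # disjoint gene blocks: aging markers, AD markers, planted-edge endpoints
    idx = 0
    aging_idx = np.arange(idx, idx + spec.n_aging_markers); idx += spec.n_aging_markers
    ad_idx = np.arange(idx, idx + spec.n_ad_markers); idx += spec.n_ad_markers
    edge_idx = np.arange(idx, idx + 2 * spec.n_planted_edges)

    X[aging_idx] += spec.aging_effect * a

    is_ad = diagnosis == "AD"
    if spec.n_ad_markers and is_ad.any():
        X[np.ix_(ad_idx, np.flatnonzero(is_ad))] += spec.ad_effect
    if spec.ad_acceleration and is_ad.any():
        X[np.ix_(aging_idx, np.flatnonzero(is_ad))] += spec.ad_acceleration

    edges: list[tuple[str, str]] = []
    sign = np.where(is_ad, -1.0, 1.0)
    for k in range(spec.n_planted_edges):
        i, j = edge_idx[2 * k], edge_idx[2 * k + 1]
        eps = rng.normal(0.0, spec.noise_sd, size=n_total)
        X[j] = sign * spec.edge_strength * a * X[i] + eps
        gi, gj = genes[i], genes[j]
        edges.append((gi, gj) if gi < gj else (gj, gi))

    if spec.missing_rate > 0:
        mask = rng.random(X.shape) < spec.missing_rate
        X = np.where(mask, np.nan, X)

    tissue = np.array(TISSUES)[rng.integers(0, len(TISSUES), size=n_total)]
    split = _stratified_split_labels(diagnosis, rng)

    values = pd.DataFrame(X, index=genes, columns=sample_ids)
    samples = pd.DataFrame({
        "age": ages, "diagnosis": diagnosis, "tissue": tissue, "split": split,
    }, index=pd.Index(sample_ids, name="sample_id"))
    truth = GroundTruth(
        aging_markers=[genes[i] for i in aging_idx],
        ad_markers=[genes[i] for i in ad_idx],
        planted_edges=edges,
    )
    return ExpressionMatrix(values, samples), truth


def _stratified_split_labels(diagnosis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """2:1 train/test assignment, stratified by diagnosis."""
    split = np.empty(len(diagnosis), dtype=object)
    for group in np.unique(diagnosis):
        pos = np.flatnonzero(diagnosis == group)
        perm = rng.permutation(pos)
        n_train = int(round(len(pos) * 2 / 3))
        split[perm[:n_train]] = "train"
        split[perm[n_train:]] = "test"
    return split.astype(str)


def generate_worked_graph() -> tuple[nx.Graph, ExpressionMatrix]:
    """A hard-coded <=20-node graph plus a tiny deterministic expression fixture.

    The graph is seed-independent so tests can rely on its exact shortest
    paths and degree distribution.  It contains a hub (``N01``), a chain, a
    cycle that creates tied shortest paths, and one isolated pair.
    """
    g = nx.Graph()
    edges = [
        ("N01", "N02"), ("N01", "N03"), ("N01", "N04"), ("N01", "N05"),  # hub
        ("N02", "N06"), ("N06", "N07"), ("N07", "N08"),                    # chain
        ("N03", "N09"), ("N04", "N09"),                                    # tied paths N01->N09
        ("N05", "N10"), ("N10", "N11"),
        ("N12", "N13"),                                                    # separate component
    ]
    g.add_edges_from(edges)

    nodes = sorted(g.nodes)
    n_samples = 8
    t = np.arange(n_samples)
    # deterministic, non-degenerate values: distinct phase/frequency per gene
    rows = [np.cos(0.37 * (k + 1) * t + 0.11 * k) + 0.05 * k for k in range(len(nodes))]
    values = pd.DataFrame(np.array(rows), index=nodes,
                          columns=[f"W{i:02d}" for i in range(1, n_samples + 1)])
    ages = np.linspace(30, 90, n_samples)
    samples = pd.DataFrame({
        "age": ages,
        "diagnosis": ["normal", "AD"] * (n_samples // 2),
        "tissue": ["frontal_cortex"] * n_samples,
    }, index=pd.Index(values.columns, name="sample_id"))
    return g, ExpressionMatrix(values, samples)
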
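"""Core data containers and plain-text readers/writers shared by every stage.

The package works on a genes-by-samples expression matrix with per-sample
metadata (age in years, diagnosis, tissue, optional train/test split).
Expression is carried as a :class:`pandas.DataFrame` indexed by gene symbol
with sample identifiers as columns; ``NaN`` marks a missing measurement and is
serialized as the literal string ``NA``.  Gene sets for enrichment are read
from GMT files (one set per line: name, description, members).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "AnalysisConfig",
    "read_expression",
    "write_expression",
    "read_gmt",
]

#: metadata columns that must be present for every sample
REQUIRED_METADATA = ("age", "diagnosis", "tissue")

#: recognised diagnosis labels
DIAGNOSES = ("AD", "normal")


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued matrix with aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame with unique gene symbols as the index and unique sample
        identifiers as columns.  ``NaN`` entries are missing measurements.
    samples
        DataFrame indexed by sample identifier, in the same order as
        ``values.columns``, with at least ``age`` (years), ``diagnosis``
        (``AD`` or ``normal``) and ``tissue`` columns.  A ``split`` column
        (``train``/``test``) may be present.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0:
            raise ValueError("expression matrix has no genes")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes)[:5]}")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing[:5]}")
        # keep metadata aligned to the column order
        self.samples = self.samples.loc[list(self.values.columns)]
        for col in REQUIRED_METADATA:
            if col not in self.samples.columns:
                raise ValueError(f"metadata lacks required column '{col}'")
        ages = pd.to_numeric(self.samples["age"], errors="coerce")
        bad = self.samples.index[ages.isna()].tolist()
        if bad:
            raise ValueError(f"unparseable or missing age for samples: {bad[:5]}")
        if (ages < 0).any():
            bad = self.samples.index[ages < 0].tolist()
            raise ValueError(f"negative age for samples: {bad[:5]}")
        self.samples = self.samples.assign(age=ages.astype(float))
        bad_dx = sorted(set(self.samples["diagnosis"]) - set(DIAGNOSES))
        if bad_dx:
            raise ValueError(f"unknown diagnosis labels: {bad_dx}")
        self.values = self.values.astype(float)
        self.values.index.name = "gene"
        self.values.columns.name = None

    # -- convenience accessors ------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids])

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        absent = [g for g in genes if g not in self.values.index]
        if absent:
            raise KeyError(f"genes not in matrix: {absent[:5]}")
        return ExpressionMatrix(self.values.loc[genes], self.samples)

    def where(self, mask: pd.Series) -> "ExpressionMatrix":
        """Subset samples by a boolean mask over sample ids."""
        ids = [s for s in self.sample_ids if bool(mask.loc[s])]
        return self.subset_samples(ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style); duplicates within a set are collapsed."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set '{name}' is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class AnalysisConfig:
    """Thresholds and sizes shared across the pipeline stages."""

    age_threshold: float = 50.0
    p_threshold: float = 0.05
    fdr_threshold: float = 0.2
    top_models: int = 100
    cv_folds: int = 5
    missing_fraction_max: float = 0.30
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "fdr_threshold", "missing_fraction_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if self.top_models < 1:
            raise ValueError("top_models must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (genes x samples, ``NA`` = missing) plus metadata.

    The expression file has gene symbols in the first column and a header row
    of sample ids.  The metadata TSV must contain ``sample_id`` plus the
    required :data:`REQUIRED_METADATA` columns; samples present in the
    expression file but absent from the metadata are rejected.
    """
    # round_trip parsing keeps write->read bit-exact for shortest-repr floats
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                         keep_default_na=False, float_precision="round_trip")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str}, na_values=["NA"],
                       keep_default_na=False, float_precision="round_trip")
    if "sample_id" not in meta.columns:
        raise ValueError("metadata lacks a 'sample_id' column")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dupes[:5]}")
    meta = meta.set_index("sample_id")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, meta)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     metadata_path: str | Path | None = None) -> None:
    """Write a matrix (and optionally its metadata) back to TSV.

    Missing entries are written as ``NA`` so that a write/read round trip
    reproduces values and missingness exactly.
    """
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="gene")
    if metadata_path is not None:
        matrix.samples.to_csv(metadata_path, sep="\t", na_rep="NA", index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then member genes.

    Duplicate genes within one line are collapsed (first occurrence kept);
    a line with fewer than three tab-separated fields is an error reported
    with its line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >=3 tab-separated fields, "
                                 f"got {len(fields)}")
            name = fields[0]
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise ValueError(f"GMT line {lineno}: set '{name}' has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets, source=str(path))
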
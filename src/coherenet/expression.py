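"""Per-dataset expression matrices and DEG labels.

Expression samples may come from many independent studies (different
organisms, tissues, platforms), so each dataset is kept separate and every
pairwise statistic is computed within a dataset, never across datasets.
A gene pair is *eligible* in a dataset when both genes are measured on at
least ``min_n`` shared samples after complete-case filtering ("more than
two samples": the default minimum is 3).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DEG_DIRECTIONS = ("up", "down")


class DuplicateGeneError(ValueError):
    """A dataset contains the same gene identifier twice."""


@dataclass
class PairedVectors:
    """Aligned complete-case expression vectors for one gene pair in one
    dataset."""

    dataset_id: str
    x: np.ndarray
    y: np.ndarray

    @property
    def n(self) -> int:
        return len(self.x)

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("paired vectors must have equal length")


class ExpressionDataset:
    """One genes x samples matrix belonging to a named dataset.

    Values are platform-dependent abundances treated as unitless reals;
    missing values are NaN.
    """

    def __init__(self, dataset_id: str, matrix: pd.DataFrame,
                 tags: dict | None = None) -> None:
        if matrix.index.has_duplicates:
            dups = matrix.index[matrix.index.duplicated()].unique().tolist()
            raise DuplicateGeneError(
                f"dataset {dataset_id!r}: duplicate gene id(s) {dups}")
        if matrix.shape[0] == 0 or matrix.shape[1] == 0:
            raise ValueError(f"dataset {dataset_id!r}: empty matrix")
        self.dataset_id = dataset_id
        self.matrix = matrix.astype(float)
        self.tags = dict(tags or {})

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def __repr__(self) -> str:
        return (f"ExpressionDataset({self.dataset_id!r}, "
                f"{self.matrix.shape[0]} genes x {self.matrix.shape[1]} samples)")

    # numpy views cached for fast per-pair access (the UGP null needs
    # tens of thousands of pair lookups)
    @cached_property
    def _values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    @cached_property
    def _gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.matrix.index)}


@dataclass
class ExpressionCollection:
    """Named expression datasets analyzed separately and independently."""

    datasets: list[ExpressionDataset]
    manifest: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [ds.dataset_id for ds in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate dataset ids in collection: {ids}")
        self._by_id = {ds.dataset_id: ds for ds in self.datasets}

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)

    def __getitem__(self, dataset_id: str) -> ExpressionDataset:
        return self._by_id[dataset_id]


def read_expression(path: str | Path, dataset_id: str | None = None,
                    log2: bool = False, tags: dict | None = None) -> ExpressionDataset:
    """Load one dataset from TSV (first column ``gene``, then sample ids).

    Non-numeric cells (e.g. ``NA``) become missing values.  With ``log2``
    the matrix is transformed as log2(x + 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.apply(pd.to_numeric, errors="coerce")
    if log2:
        df = np.log2(df + 1.0)
    return ExpressionDataset(dataset_id or path.stem, df, tags=tags)


def read_manifest(path: str | Path, log2: bool = False) -> ExpressionCollection:
    """Load a collection from a YAML/JSON manifest: list of
    ``{id, path, tags}`` with paths resolved relative to the manifest."""
    path = Path(path)
    with path.open() as fh:
        entries = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    if not isinstance(entries, list) or not entries:
        raise ValueError(f"manifest {path} must be a non-empty list")
    datasets = []
    for entry in entries:
        ds_path = Path(entry["path"])
        if not ds_path.is_absolute():
            ds_path = path.parent / ds_path
        datasets.append(read_expression(ds_path, entry["id"], log2=log2,
                                        tags=entry.get("tags")))
    return ExpressionCollection(datasets, manifest=entries)


def read_deg_labels(path: str | Path) -> dict[str, str]:
    """Load DEG labels from 2-column TSV ``gene\\tdirection``.

    Each gene must carry exactly one direction in {up, down}.
    """
    labels: dict[str, str] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            gene, direction = fields[0].strip(), fields[1].strip().lower()
            if lineno == 1 and (gene.lower(), direction) == ("gene", "direction"):
                continue
            if direction not in DEG_DIRECTIONS:
                raise ValueError(f"{path}:{lineno}: direction must be up/down, "
                                 f"got {direction!r}")
            if gene in labels and labels[gene] != direction:
                raise ValueError(f"{path}:{lineno}: conflicting direction for {gene!r}")
            labels[gene] = direction
    return labels


def pair_observations(gene_i: str, gene_j: str,
                      ds: ExpressionDataset) -> PairedVectors | None:
    """Aligned complete-case vectors for a pair in one dataset, or None if
    either gene is absent.  Samples missing either gene are dropped."""
    idx = ds._gene_index
    if gene_i not in idx or gene_j not in idx:
        return None
    x = ds._values[idx[gene_i]]
    y = ds._values[idx[gene_j]]
    mask = np.isfinite(x) & np.isfinite(y)
    return PairedVectors(ds.dataset_id, x[mask], y[mask])


def eligible_datasets(gene_i: str, gene_j: str, coll: ExpressionCollection,
                      min_n: int = 3) -> list[PairedVectors]:
    """All datasets where the pair has at least ``min_n`` shared samples.

    The pair is *eligible* iff the returned list is nonempty.  ``min_n``
    below 3 is rejected: a correlation needs more than two observations.
    """
    if min_n < 3:
        raise ValueError(f"min_n must be >= 3, got {min_n}")
    out = []
    for ds in coll:
        pv = pair_observations(gene_i, gene_j, ds)
        if pv is not None and pv.n >= min_n:
            out.append(pv)
    return out


def eligible_pair_mask(coll: ExpressionCollection, genes: list[str],
                       min_n: int = 3) -> np.ndarray:
    """Boolean genes x genes matrix of pair eligibility, vectorized.

    Entry (i, j) is True when some dataset holds >= ``min_n`` shared
    complete samples for (genes[i], genes[j]).  Used by the UGP sampler to
    screen thousands of candidate pairs at once.
    """
    if min_n < 3:
        raise ValueError(f"min_n must be >= 3, got {min_n}")
    n = len(genes)
    out = np.zeros((n, n), dtype=bool)
    for ds in coll:
        rows = [ds._gene_index.get(g, -1) for g in genes]
        present = np.array([r >= 0 for r in rows])
        if not present.any():
            continue
        obs = np.isfinite(ds._values[[r for r in rows if r >= 0]]).astype(np.int32)
        counts = obs @ obs.T            # shared-sample counts
        sub = counts >= min_n
        pidx = np.where(present)[0]
        out[np.ix_(pidx, pidx)] |= sub
    return out
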
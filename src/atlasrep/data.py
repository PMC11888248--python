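"""Core data model and I/O for cell-by-gene expression atlases.

An atlas is a sparse genes x cells count matrix plus per-cell metadata
(cluster, dissection region, slice index, x/y coordinates in mm). Counts are
normalised to log(CPM + 1); cluster centroids and per-gene z-scores are the
two derived representations every downstream stage consumes. Disk layout is
Matrix Market for counts with TSV sidecars for genes and cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

CELL_COLUMNS = ["cell_id", "cluster", "region", "slice", "x", "y"]


class DataError(ValueError):
    """Malformed dataset input (dimension mismatch, duplicates, bad counts)."""


@dataclass
class ExpressionDataset:
    """Sparse count matrix (genes x cells) with per-cell annotations.

    ``cells`` is indexed by cell id and carries ``cluster`` plus the optional
    ``region``, ``slice``, ``x``, ``y`` columns.
    """

    dataset_id: str
    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cells)):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cells)} cells"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cells.index)):
            dup = pd.Index(ids).duplicated()
            if dup.any():
                raise DataError(f"duplicate {name} ids: {pd.Index(ids)[dup].tolist()[:5]}")
        data = self.counts.data
        if data.size:
            if not np.all(np.isfinite(data)):
                raise DataError("counts contain non-finite entries")
            if np.any(data < 0):
                i = int(np.argmax(data < 0))
                raise DataError(f"negative count at stored entry {i}")
            if np.any(data != np.round(data)):
                i = int(np.argmax(data != np.round(data)))
                raise DataError(f"non-integer count at stored entry {i}")
        if "cluster" not in self.cells.columns or self.cells["cluster"].isna().any():
            raise DataError("every cell needs a cluster label")

    # -- convenience accessors -------------------------------------------------
    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells.index.to_numpy()

    @property
    def cluster_of(self) -> pd.Series:
        return self.cells["cluster"]

    @property
    def region_of(self) -> pd.Series | None:
        return self.cells["region"] if "region" in self.cells.columns else None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def clusters(self) -> np.ndarray:
        return np.array(sorted(self.cells["cluster"].unique()))

    def cluster_sizes(self) -> pd.Series:
        return self.cells["cluster"].value_counts().sort_index()

    def subset_genes(self, genes) -> "ExpressionDataset":
        idx = pd.Index(self.gene_ids).get_indexer(genes)
        if np.any(idx < 0):
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise DataError(f"genes absent from dataset: {missing[:5]}")
        return ExpressionDataset(
            self.dataset_id, self.counts[idx], np.asarray(genes, dtype=object), self.cells.copy()
        )


@dataclass
class NormalizedView:
    """log(CPM + 1) transform of a dataset; ``values`` is dense genes x cells."""

    values: np.ndarray
    parent: ExpressionDataset
    log_base: float

    @property
    def gene_ids(self) -> np.ndarray:
        return self.parent.gene_ids

    @property
    def cluster_of(self) -> pd.Series:
        return self.parent.cluster_of


@dataclass
class HvgSet:
    """Ordered highly-variable-gene list plus the parameters that produced it."""

    gene_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# hvg provenance: {self.provenance}\n")
            fh.write("gene_id\n")
            for g in self.gene_ids:
                fh.write(f"{g}\n")

    @classmethod
    def from_tsv(cls, path) -> "HvgSet":
        prov = {}
        genes = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    continue
                if line and line != "gene_id":
                    genes.append(line)
        return cls(genes, prov)


@dataclass
class RegionMap:
    """Many-to-one mapping from atlas dissection regions to a common vocabulary."""

    entries: dict[str, str]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"source": list(self.entries), "aligned": list(self.entries.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RegionMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


# -- file I/O -----------------------------------------------------------------

def read_dataset(matrix_path, genes_path, cells_path, dataset_id: str = "") -> ExpressionDataset:
    """Read a Matrix Market counts file with genes.tsv / cells.tsv sidecars."""
    counts = sp.csr_matrix(mmread(str(matrix_path)))
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    gene_ids = genes.iloc[:, 0].to_numpy(dtype=object)
    cells = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str, "cluster": str, "region": str})
    if counts.shape[0] != len(gene_ids):
        raise DataError(f"matrix has {counts.shape[0]} rows but genes file lists {len(gene_ids)}")
    if counts.shape[1] != len(cells):
        raise DataError(f"matrix has {counts.shape[1]} columns but cells file lists {len(cells)}")
    cells = cells.set_index("cell_id")
    did = dataset_id or Path(matrix_path).stem
    return ExpressionDataset(did, counts, gene_ids, cells)


def write_dataset(ds: ExpressionDataset, out_dir) -> dict[str, Path]:
    """Write the .mtx/genes.tsv/cells.tsv layout ``read_dataset`` accepts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
    }
    mmwrite(str(paths["matrix"]), sp.coo_matrix(self_int(ds.counts)))
    pd.DataFrame({"gene_id": ds.gene_ids}).to_csv(paths["genes"], sep="\t", index=False)
    cells = ds.cells.copy()
    cells.insert(0, "cell_id", cells.index)
    cells.to_csv(paths["cells"], sep="\t", index=False)
    return paths


def self_int(m: sp.spmatrix) -> sp.spmatrix:
    m = m.copy()
    m.data = m.data.astype(np.int64)
    return m


# -- transforms ---------------------------------------------------------------

def normalize_log_cpm(ds: ExpressionDataset, log_base: float = np.e) -> NormalizedView:
    """log(CPM + 1) per cell; all-zero cells stay all-zero (with a warning)."""
    counts = np.asarray(ds.counts.todense(), dtype=np.float64)
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cells left as zeros", stacklevel=2)
    safe = np.where(zero, 1.0, totals)
    cpm = counts / safe[None, :] * 1e6
    values = np.log1p(cpm) / np.log(log_base)
    return NormalizedView(values, ds, float(log_base))


def compute_centroids(nv: NormalizedView) -> pd.DataFrame:
    """Per-cluster mean log-CPM profile; clusters x genes DataFrame."""
    labels = nv.cluster_of.to_numpy()
    clusters = np.array(sorted(pd.unique(labels)))
    rows = np.empty((len(clusters), nv.values.shape[0]))
    for i, k in enumerate(clusters):
        mask = labels == k
        if not mask.any():
            raise DataError(f"empty cluster {k!r}")
        rows[i] = nv.values[:, mask].mean(axis=1)
    return pd.DataFrame(rows, index=clusters, columns=nv.gene_ids)


def zscore_genes(nv: NormalizedView) -> np.ndarray:
    """Per-gene z-score across cells (sample SD, ddof=1); constant genes -> 0."""
    v = nv.values
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True) if v.shape[1] > 1 else np.zeros_like(mean)
    out = np.zeros_like(v)
    ok = (sd > 0).ravel()
    out[ok] = (v[ok] - mean[ok]) / sd[ok]
    return out


def select_hvgs(views: list[NormalizedView], n_bins: int = 10, quantile: float = 0.75) -> HvgSet:
    """Highly variable genes shared across datasets.

    Genes are intersected across datasets first. Per dataset, genes are split
    into ``n_bins`` equal-size bins by mean log-CPM; within each bin a gene is
    flagged when its variance exceeds the bin's ``quantile`` variance quantile.
    The returned set contains genes flagged in every dataset, sorted by id.
    """
    if not views:
        raise DataError("need at least one dataset")
    shared = pd.Index(views[0].gene_ids)
    for v in views[1:]:
        shared = shared.intersection(pd.Index(v.gene_ids))
    if len(shared) == 0:
        raise DataError("no genes shared across datasets")
    shared = shared.sort_values()
    flagged_all = np.ones(len(shared), dtype=bool)
    for v in views:
        idx = pd.Index(v.gene_ids).get_indexer(shared)
        sub = v.values[idx]
        means = sub.mean(axis=1)
        variances = sub.var(axis=1, ddof=1) if sub.shape[1] > 1 else np.zeros(len(shared))
        order = np.argsort(means, kind="stable")
        flagged = np.zeros(len(shared), dtype=bool)
        for bin_idx in np.array_split(order, n_bins):
            if bin_idx.size == 0:
                continue
            thr = np.quantile(variances[bin_idx], quantile)
            flagged[bin_idx] = variances[bin_idx] > thr
        flagged_all &= flagged
    genes = [g for g, f in zip(shared, flagged_all) if f]
    prov = {
        "n_bins": n_bins,
        "quantile": quantile,
        "datasets": [v.parent.dataset_id for v in views],
        "n_shared_genes": int(len(shared)),
    }
    return HvgSet(genes, prov)


def align_regions(ds: ExpressionDataset, rm: RegionMap, passthrough=()) -> ExpressionDataset:
    """Relabel per-cell dissection regions through a RegionMap.

    Labels in ``passthrough`` are kept as-is; any other label missing from the
    map is an error. Cells with missing regions stay missing and are excluded
    from region-level statistics downstream.
    """
    if ds.region_of is None:
        raise DataError("dataset has no region annotations")
    cells = ds.cells.copy()
    observed = set(cells["region"].dropna().unique())
    unmapped = observed - set(rm.entries) - set(passthrough)
    if unmapped:
        raise DataError(f"regions not covered by the map: {sorted(unmapped)}")
    cells["region"] = cells["region"].map(lambda r: rm.entries.get(r, r) if pd.notna(r) else r)
    return ExpressionDataset(ds.dataset_id, ds.counts, ds.gene_ids, cells)
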
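"""Marker-set specificity evaluation and marker-based cluster pairing.

A cluster's marker set scores each cell by the mean z-scored log-CPM of its
markers; AUROCs of these scores against every cluster form a marker-set by
cluster matrix whose diagonal is the on-target (global) specificity. The
local variant restricts the comparison to the target cluster and its best
off-target cluster, which is where small marker panels fail for similar
clusters. Cross-atlas marker overlaps are tested hypergeometrically, and the
matrix also yields a marker-based cluster pairing used as a baseline for
transcriptome-wide neighbor voting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import grouped_auroc
from .data import ExpressionDataset, NormalizedView, normalize_log_cpm, zscore_genes
from .stats import adjust_p, auroc, hypergeom_overlap_test


@dataclass
class MarkerCatalog:
    """Ordered marker gene lists per cluster."""

    markers: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for k, genes in self.markers.items():
            if not genes:
                raise ValueError(f"empty marker list for cluster {k!r}")

    def to_tsv(self, path) -> None:
        rows = [(k, g, r + 1) for k, genes in self.markers.items() for r, g in enumerate(genes)]
        pd.DataFrame(rows, columns=["cluster", "gene", "rank"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, source: str = "") -> "MarkerCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"cluster": str, "gene": str})
        df = df.sort_values(["cluster", "rank"])
        markers = {k: list(sub["gene"]) for k, sub in df.groupby("cluster", sort=True)}
        return cls(markers, source or str(path))


@dataclass
class MarkerAurocMatrix:
    """Marker-set x cluster AUROC scores; the diagonal is on-target."""

    values: pd.DataFrame
    dataset_id: str

    def on_target(self) -> pd.Series:
        shared = [k for k in self.values.index if k in self.values.columns]
        return pd.Series({k: self.values.loc[k, k] for k in shared})


def _as_view(ds) -> NormalizedView:
    return ds if isinstance(ds, NormalizedView) else normalize_log_cpm(ds)


def marker_score_cells(z: np.ndarray, gene_ids, markers) -> np.ndarray:
    """Mean z-scored expression of a marker set, per cell.

    Markers absent from ``gene_ids`` are dropped with a warning; an entirely
    absent set is an error.
    """
    idx = pd.Index(gene_ids).get_indexer(list(markers))
    present = idx[idx >= 0]
    if present.size == 0:
        raise ValueError(f"no marker of {list(markers)[:5]}... present in the dataset")
    if present.size < len(markers):
        warnings.warn(f"{len(markers) - present.size} marker(s) absent, dropped", stacklevel=2)
    return z[present].mean(axis=0)


def marker_auroc_matrix(ds, catalog: MarkerCatalog) -> MarkerAurocMatrix:
    """AUROC of every catalog marker set against every dataset cluster."""
    nv = _as_view(ds)
    z = zscore_genes(nv)
    labels = nv.cluster_of.to_numpy()
    clusters = np.array(sorted(pd.unique(labels)))
    cluster_set = set(clusters)
    sets = sorted(catalog.markers)
    extras = [k for k in sets if k not in cluster_set]
    if extras:
        warnings.warn(f"{len(extras)} catalog cluster(s) absent from dataset", stacklevel=2)
    rows = np.empty((len(sets), len(clusters)))
    for i, k in enumerate(sets):
        scores = marker_score_cells(z, nv.gene_ids, catalog.markers[k])
        rows[i] = grouped_auroc(scores, labels, clusters)
    return MarkerAurocMatrix(pd.DataFrame(rows, index=sets, columns=clusters), nv.parent.dataset_id)


def marker_local_auroc(ds, catalog: MarkerCatalog, target: str,
                       matrix: MarkerAurocMatrix | None = None) -> float:
    """On-target AUROC restricted to the target cluster and its best off-target.

    The best off-target is the cluster where the same marker set scores
    highest among non-target clusters (ties to the smallest label).
    """
    nv = _as_view(ds)
    if matrix is None:
        matrix = marker_auroc_matrix(nv, catalog)
    row = matrix.values.loc[target].drop(labels=[target], errors="ignore")
    best_off = row.index[np.argmax(row.to_numpy())]  # index sorted -> smallest-label ties
    z = zscore_genes(nv)
    scores = marker_score_cells(z, nv.gene_ids, catalog.markers[target])
    labels = nv.cluster_of.to_numpy()
    keep = (labels == target) | (labels == best_off)
    return auroc(scores[keep], labels[keep] == target)


def marker_overlap_pairs(
    cat_a: MarkerCatalog,
    cat_b: MarkerCatalog,
    universe_size: int,
    alpha: float = 0.05,
    correction: str = "all-pairs",
) -> pd.DataFrame:
    """Cross-atlas cluster pairs with significant marker-list overlap.

    ``correction='all-pairs'`` Bonferroni-divides alpha by |A| x |B|;
    ``'per-atlas'`` by max(|A|, |B|) — the relaxed threshold that corrects
    for the cluster count of the larger atlas.
    """
    n_tests = {
        "all-pairs": len(cat_a.markers) * len(cat_b.markers),
        "per-atlas": max(len(cat_a.markers), len(cat_b.markers)),
    }[correction]
    rows = []
    for ka, ga in cat_a.markers.items():
        set_a = set(ga)
        for kb, gb in cat_b.markers.items():
            set_b = set(gb)
            k = len(set_a & set_b)
            res = hypergeom_overlap_test(k, len(set_a), len(set_b), universe_size)
            p_adj = min(1.0, res.p_value * n_tests)
            if p_adj < alpha:
                rows.append((ka, kb, k, res.p_value, p_adj))
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "overlap", "p", "p_adj"])


def marker_based_pairing(cat_a: MarkerCatalog, ds_b) -> pd.DataFrame:
    """Pair each A marker set with its best-scoring B cluster.

    When one B cluster is the best hit for several marker sets, only the
    pairing with the highest AUROC is kept, so B clusters are unique.
    """
    matrix = marker_auroc_matrix(ds_b, cat_a)
    best_idx = matrix.values.to_numpy().argmax(axis=1)
    rows = pd.DataFrame({
        "cluster_a": matrix.values.index,
        "cluster_b": matrix.values.columns[best_idx],
        "auroc": matrix.values.to_numpy()[np.arange(len(best_idx)), best_idx],
    })
    rows = rows.sort_values(["cluster_b", "auroc", "cluster_a"], ascending=[True, False, True])
    rows = rows.drop_duplicates("cluster_b", keep="first").sort_values("cluster_a")
    return rows.reset_index(drop=True)
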
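"""Centroid-correlation cell calling for spatial data and concordance stats.

Every spatial cell is assigned to the most Pearson-correlated cluster
centroid in log(CPM+1) space, repeated over random gene subsamples; the
modal winner and the mean winning correlation decide the call, and cells
whose mean correlation falls below a threshold (default 0.5) are left
uncalled. Calls made independently from two atlas references are then
scored for landing on the two sides of a reciprocal best-hit pair, and a
battery of summaries (per-slice proportions, diversity mismatch under
downsampling, region enrichment, paired centroid distances, dissection-
region agreement) quantifies the spatial coherence of the matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import center_unit_rows, substream
from .data import NormalizedView, RegionMap
from .matching import ReciprocalPairTable
from .stats import spearman


@dataclass
class SpatialCallTable:
    """Per-cell best cluster, mean winning correlation and pass flag."""

    calls: pd.DataFrame  # index cell_id; best_cluster, mean_correlation, passed, slice, region, x, y
    reference_id: str
    threshold: float

    def passed(self) -> pd.DataFrame:
        return self.calls[self.calls["passed"]]

    def to_tsv(self, path) -> None:
        out = self.calls.copy()
        out.insert(0, "cell_id", out.index)
        out.to_csv(path, sep="\t", index=False)


def call_cells(
    spatial: NormalizedView,
    centroids: pd.DataFrame,
    n_rounds: int = 100,
    subsample_frac: float = 0.8,
    threshold: float = 0.5,
    seed: int = 0,
) -> SpatialCallTable:
    """Repeated-subsampling centroid-correlation assignment.

    Per round, ceil(subsample_frac x shared genes) genes are drawn without
    replacement and each cell goes to its most correlated centroid over those
    genes. The final cluster is the modal round winner (ties -> higher mean
    winning correlation, then smallest label); a cell passes when its mean
    winning correlation reaches ``threshold``.
    """
    shared = pd.Index(centroids.columns).intersection(pd.Index(spatial.gene_ids))
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} genes shared with the centroids; need >= 10")
    shared = shared.sort_values()
    rng = substream(seed, "call_cells")
    cent = centroids[shared].to_numpy()
    idx = pd.Index(spatial.gene_ids).get_indexer(shared)
    cells = spatial.values[idx].T  # cells x genes
    n_cells = cells.shape[0]
    n_sub = int(np.ceil(subsample_frac * len(shared)))
    clusters = centroids.index.to_numpy()
    win_counts = np.zeros((n_cells, len(clusters)), dtype=np.int64)
    win_corr_sum = np.zeros(n_cells)
    win_corr_by_cluster = np.zeros((n_cells, len(clusters)))
    for _ in range(n_rounds):
        cols = rng.choice(len(shared), size=n_sub, replace=False)
        x, _ = center_unit_rows(cells[:, cols])
        c, _ = center_unit_rows(cent[:, cols])
        corr = x @ c.T
        winner = corr.argmax(axis=1)
        wc = corr[np.arange(n_cells), winner]
        win_counts[np.arange(n_cells), winner] += 1
        win_corr_sum += wc
        win_corr_by_cluster[np.arange(n_cells), winner] += wc
    # modal winner; ties by higher mean winning correlation, then smallest label
    mean_by_cluster = np.where(win_counts > 0, win_corr_by_cluster / np.maximum(win_counts, 1), -np.inf)
    order = np.lexsort((np.arange(len(clusters))[None, :] * np.ones((n_cells, 1)),
                        -mean_by_cluster, -win_counts), axis=1)
    best = order[:, 0]
    mean_corr = win_corr_sum / n_rounds
    calls = pd.DataFrame(
        {
            "best_cluster": clusters[best],
            "mean_correlation": mean_corr,
            "passed": mean_corr >= threshold,
        },
        index=pd.Index(spatial.parent.cell_ids, name="cell_id"),
    )
    for col in ("slice", "region", "x", "y", "cluster"):
        if col in spatial.parent.cells.columns:
            name = "true_cluster" if col == "cluster" else col
            calls[name] = spatial.parent.cells[col].to_numpy()
    return SpatialCallTable(calls, str(centroids.index.name or "reference"), threshold)


def pair_concordance(
    calls_a: SpatialCallTable, calls_b: SpatialCallTable, pairs: ReciprocalPairTable
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag cells whose two calls land on the two sides of one reciprocal pair.

    Returns the per-cell flag and per-slice summaries: the flagged proportion
    among cells passing under both references, and the count of distinct
    clusters detected (union of passed calls).
    """
    if not calls_a.calls.index.equals(calls_b.calls.index):
        raise ValueError("call tables cover different cells")
    recip = set(zip(pairs.reciprocal()["cluster_a"], pairs.reciprocal()["cluster_b"]))
    both = calls_a.calls["passed"] & calls_b.calls["passed"]
    landed = pd.Series(
        list(zip(calls_a.calls["best_cluster"], calls_b.calls["best_cluster"])),
        index=calls_a.calls.index,
    ).isin(recip)
    flag = both & landed
    per_slice = []
    if "slice" in calls_a.calls.columns:
        for sl, sub in calls_a.calls.groupby("slice"):
            cells = sub.index
            n_both = int(both[cells].sum())
            prop = float(flag[cells].sum() / n_both) if n_both else float("nan")
            detected = set(calls_a.calls.loc[cells][calls_a.calls.loc[cells, "passed"]]["best_cluster"])
            detected |= set(calls_b.calls.loc[cells][calls_b.calls.loc[cells, "passed"]]["best_cluster"])
            per_slice.append({"slice": sl, "prop_concordant": prop,
                              "n_both_passed": n_both, "n_clusters_detected": len(detected)})
    return flag, pd.DataFrame(per_slice)


def diversity_mismatch(
    calls_a: SpatialCallTable, calls_b: SpatialCallTable, n_rep: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Per-slice surplus of distinct clusters in A-calls after matching B's cell count.

    The side with more passed calls is subsampled (without replacement,
    ``n_rep`` times) to the other side's count before counting distinct
    clusters; a swap is recorded with a sign flip.
    """
    rng = substream(seed, "diversity")
    rows = []
    for sl in sorted(calls_a.calls["slice"].dropna().unique()):
        a = calls_a.passed().query("slice == @sl")["best_cluster"].to_numpy()
        b = calls_b.passed().query("slice == @sl")["best_cluster"].to_numpy()
        sign = 1.0
        if len(a) < len(b):
            a, b = b, a
            sign = -1.0
        if len(b) == 0:
            continue
        if len(a) == len(b) and sign == 1.0:
            sub_counts = [len(np.unique(a))] * 1
        else:
            sub_counts = [len(np.unique(rng.choice(a, size=len(b), replace=False)))
                          for _ in range(n_rep)]
        rows.append({
            "slice": sl,
            "mismatch": sign * (float(np.mean(sub_counts)) - len(np.unique(b))),
            "swapped": sign < 0,
        })
    return pd.DataFrame(rows)


def region_enrichment(
    calls: pd.DataFrame, flag: pd.Series, rm: RegionMap | None = None, min_cells: int = 50
) -> pd.Series:
    """log2 enrichment of concordant calls per region vs the global rate."""
    regions = calls["region"]
    if rm is not None:
        regions = regions.map(lambda r: rm.entries.get(r, r))
    overall = flag.mean()
    out = {}
    for r, cells in calls.groupby(regions).groups.items():
        if len(cells) < min_cells:
            continue
        frac = flag[cells].mean()
        out[r] = float(np.log2(frac / overall)) if frac > 0 and overall > 0 else float("-inf")
    return pd.Series(out).sort_index()


def paired_centroid_distance(
    calls_a: SpatialCallTable,
    calls_b: SpatialCallTable,
    pairs: list[tuple[str, str]],
    slice_spacing: float = 0.2,
) -> pd.DataFrame:
    """Euclidean distance (mm) between the spatial centroids of each pair's calls.

    A cluster's centroid is the mean (x, y, slice x spacing) of the cells
    confidently called to it; pairs with an unlocated side are skipped.
    """

    def centroid(table: SpatialCallTable, cluster: str):
        sub = table.passed()
        sub = sub[sub["best_cluster"] == cluster]
        if len(sub) == 0:
            return None
        return np.array([sub["x"].mean(), sub["y"].mean(), sub["slice"].mean() * slice_spacing])

    rows = []
    for ca, cb in pairs:
        pa, pb = centroid(calls_a, ca), centroid(calls_b, cb)
        if pa is None or pb is None:
            rows.append({"cluster_a": ca, "cluster_b": cb, "distance_mm": float("nan"),
                         "located": False})
        else:
            rows.append({"cluster_a": ca, "cluster_b": cb,
                         "distance_mm": float(np.linalg.norm(pa - pb)), "located": True})
    return pd.DataFrame(rows)


def slice_diversity_correlation(per_slice: pd.DataFrame) -> float:
    """Spearman between per-slice concordance and per-slice cluster diversity."""
    sub = per_slice.dropna(subset=["prop_concordant"])
    return spearman(sub["prop_concordant"], sub["n_clusters_detected"])


def top_region_match(
    ds_a, ds_b, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Dissection-region agreement of matched cluster pairs.

    top1: the modal regions coincide. top2 (defined only when both clusters
    span >= 2 regions): the unordered top-two region sets coincide.
    """

    def region_dist(ds, cluster):
        sub = ds.cells[ds.cells["cluster"] == cluster]["region"].dropna()
        return sub.value_counts()

    rows = []
    for ca, cb in pairs:
        da, db = region_dist(ds_a, ca), region_dist(ds_b, cb)
        if len(da) == 0 or len(db) == 0:
            continue
        top1 = da.index[0] == db.index[0]
        if len(da) >= 2 and len(db) >= 2:
            top2 = set(da.index[:2]) == set(db.index[:2])
        else:
            top2 = None
        rows.append({"cluster_a": ca, "cluster_b": cb, "top1": bool(top1), "top2": top2})
    return pd.DataFrame(rows)
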
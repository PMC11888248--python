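"""Cross-dataset neighbor voting over a Spearman similarity network.

Each cell is represented by the mid-ranks of its highly-variable-gene
expression, mean-centered and scaled to unit norm, so the inner product of
two cell vectors *is* their Spearman correlation. A reference cluster votes
for a target cell with the mean correlation between that cell and the
cluster's cells; by linearity this equals the inner product with the
cluster's mean normalized vector, which is what makes voting fast at scale.
One-vs-all AUROCs of these votes quantify cluster replicability in each
direction, and the symmetric table (mean of the two directions) feeds
reciprocal best-hit detection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import center_unit_rows, grouped_auroc
from .data import HvgSet, NormalizedView


@dataclass
class RankNormalizedCells:
    """cells x HVG matrix of centered, unit-norm within-cell expression mid-ranks."""

    vectors: np.ndarray
    cell_ids: np.ndarray
    clusters: pd.Series
    hvg: HvgSet
    gene_ids: list[str]  # HVGs actually present in the dataset, in use order
    dataset_id: str
    degenerate: np.ndarray  # constant-expression cells; zero vectors


@dataclass
class AurocTable:
    """Reference-cluster x target-cluster replicability scores."""

    values: pd.DataFrame
    direction: tuple[str, str] | str

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")
        with open(str(path) + ".json", "w") as fh:
            json.dump({"direction": list(self.direction) if isinstance(self.direction, tuple)
                       else self.direction}, fh)


def rank_normalize(nv: NormalizedView, hvg: HvgSet) -> RankNormalizedCells:
    """Project cells onto the HVG space of within-cell mid-ranks.

    Absent genes are ignored; zeros tie at the shared minimum mid-rank. The
    resulting vectors satisfy <v_i, v_j> == spearman(cell_i, cell_j) exactly.
    """
    idx = pd.Index(nv.gene_ids).get_indexer(hvg.gene_ids)
    present = [g for g, i in zip(hvg.gene_ids, idx) if i >= 0]
    idx = idx[idx >= 0]
    if idx.size < 3:
        raise ValueError(f"only {idx.size} HVGs present in {nv.parent.dataset_id}; need >= 3")
    sub = nv.values[idx]  # genes x cells
    ranks = rankdata(sub, axis=0).T  # cells x genes, within-cell mid-ranks
    vectors, degenerate = center_unit_rows(ranks)
    return RankNormalizedCells(
        vectors, nv.parent.cell_ids, nv.cluster_of, hvg, present,
        nv.parent.dataset_id, degenerate
    )


def cluster_centroids(rnc: RankNormalizedCells) -> pd.DataFrame:
    """Per-cluster mean of the normalized cell vectors (clusters x HVG)."""
    labels = rnc.clusters.to_numpy()
    clusters = np.array(sorted(pd.unique(labels)))
    rows = np.stack([rnc.vectors[labels == k].mean(axis=0) for k in clusters])
    return pd.DataFrame(rows, index=clusters, columns=rnc.gene_ids)


def votes(reference: RankNormalizedCells, target: RankNormalizedCells) -> pd.DataFrame:
    """Mean Spearman similarity of every target cell to every reference cluster.

    Computed as inner products with reference cluster centroids — an exact
    identity with averaging the full cell-cell correlation matrix.
    """
    if list(reference.gene_ids) != list(target.gene_ids):
        raise ValueError("reference and target must share the same ordered HVG list")
    cent = cluster_centroids(reference)
    v = target.vectors @ cent.to_numpy().T
    return pd.DataFrame(v, index=target.cell_ids, columns=cent.index)


def one_vs_all_auroc(
    reference: RankNormalizedCells, target: RankNormalizedCells
) -> AurocTable:
    """Directional replicability: reference-cluster votes rank each target
    cluster's cells against all other (non-degenerate) target cells."""
    v = votes(reference, target).to_numpy()
    keep = ~target.degenerate
    labels = target.clusters.to_numpy()[keep]
    v = v[keep]
    target_clusters = np.array(sorted(pd.unique(labels)))
    cent_index = votes_columns = sorted(pd.unique(reference.clusters.to_numpy()))
    out = np.full((len(votes_columns), len(target_clusters)), np.nan)
    for i in range(len(votes_columns)):
        out[i] = grouped_auroc(v[:, i], labels, target_clusters)
    df = pd.DataFrame(out, index=cent_index, columns=target_clusters)
    return AurocTable(df, (reference.dataset_id, target.dataset_id))


def symmetric_auroc(ab: AurocTable, ba: AurocTable) -> AurocTable:
    """Elementwise mean of the two directional tables (target axis transposed)."""
    ba_t = ba.values.T
    if not (ab.values.index.equals(ba_t.index) and ab.values.columns.equals(ba_t.columns)):
        ba_t = ba_t.reindex(index=ab.values.index, columns=ab.values.columns)
        if ba_t.isna().any().any():
            raise ValueError("directional tables do not share cluster labels")
    return AurocTable((ab.values + ba_t) / 2.0, "symmetric")


def brute_force_votes(reference: RankNormalizedCells, target: RankNormalizedCells) -> pd.DataFrame:
    """Oracle: average the explicit cell-cell Spearman matrix per reference cluster.

    Quadratic in cells; used only to validate the centroid formulation.
    """
    sim = target.vectors @ reference.vectors.T  # target cells x reference cells
    labels = reference.clusters.to_numpy()
    clusters = sorted(pd.unique(labels))
    cols = {k: sim[:, labels == k].mean(axis=1) for k in clusters}
    return pd.DataFrame(cols, index=target.cell_ids)
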
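"""Reciprocal best-hit detection, best-vs-next discrimination, and pretrained
cluster models.

Two clusters are a reciprocal top hit when each is the other's best match in
the symmetric neighbor-voting AUROC table. A reciprocal pair is *confident*
when, on both sides, the reference cluster's votes can discriminate the two
most similar clusters of the other atlas (best-vs-next AUROC with a
Bonferroni-corrected rank-sum test) — the filter that screens out fine
splits whose siblings are interchangeable. Pretrained models store only the
per-cluster mean rank-normalized vectors, so independent datasets (including
reduced-gene-panel spatial data) can be matched without the original cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import center_unit_rows, grouped_auroc
from .data import HvgSet, NormalizedView
from .stats import TestResult, auroc, fisher_exact_2x2, rank_sum_test
from .voting import (
    AurocTable,
    RankNormalizedCells,
    cluster_centroids,
    one_vs_all_auroc,
    rank_normalize,
    symmetric_auroc,
    votes,
)


@dataclass
class ReciprocalPairTable:
    """Per-A-cluster best hits with reciprocity and best-vs-next annotations."""

    table: pd.DataFrame
    alpha: float = 0.05

    def reciprocal(self) -> pd.DataFrame:
        return self.table[self.table["is_reciprocal"]]

    def confident(self) -> pd.DataFrame:
        return self.table[self.table["confident"]]

    def reciprocal_pairs(self) -> list[tuple[str, str]]:
        r = self.reciprocal()
        return list(zip(r["cluster_a"], r["cluster_b"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class PretrainedModel:
    """Portable matching reference: per-cluster mean rank-normalized vectors."""

    gene_ids: list[str]
    centroids: pd.DataFrame  # clusters x genes
    cluster_sizes: pd.Series
    dataset_id: str
    hvg_provenance: dict = field(default_factory=dict)

    def to_files(self, tsv_path, json_path) -> None:
        self.centroids.to_csv(tsv_path, sep="\t")
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "dataset_id": self.dataset_id,
                    "cluster_sizes": {str(k): int(v) for k, v in self.cluster_sizes.items()},
                    "hvg_provenance": {k: str(v) for k, v in self.hvg_provenance.items()},
                },
                fh, indent=1,
            )

    @classmethod
    def from_files(cls, tsv_path, json_path) -> "PretrainedModel":
        centroids = pd.read_csv(tsv_path, sep="\t", index_col=0)
        with open(json_path) as fh:
            meta = json.load(fh)
        sizes = pd.Series(meta["cluster_sizes"]).astype(int)
        return cls(list(centroids.columns), centroids, sizes, meta["dataset_id"],
                   meta.get("hvg_provenance", {}))


def top_hits(sym: AurocTable) -> list[tuple[str, str]]:
    """Mutual best hits of the symmetric AUROC table (ties -> smallest label)."""
    vals = sym.values.sort_index(axis=0).sort_index(axis=1)
    arr = vals.to_numpy()
    row_best = arr.argmax(axis=1)  # argmax takes the first = smallest label
    col_best = arr.argmax(axis=0)
    pairs = []
    for i, j in enumerate(row_best):
        if col_best[j] == i:
            pairs.append((vals.index[i], vals.columns[j]))
    return pairs


def best_vs_next(
    vote_col: np.ndarray, target_labels: np.ndarray, ova_row: pd.Series
) -> tuple[float, TestResult, str, str]:
    """Discriminability of the reference cluster's two best target clusters.

    Returns (AUROC of votes restricted to the top-two clusters' cells with
    the best cluster positive, rank-sum TestResult, best, next).
    """
    row = ova_row.dropna().sort_values(ascending=False)
    if len(row) < 2:
        raise ValueError("need at least two eligible target clusters")
    d1, d2 = row.index[0], row.index[1]
    m1 = target_labels == d1
    m2 = target_labels == d2
    a = auroc(np.concatenate([vote_col[m1], vote_col[m2]]),
              np.concatenate([np.ones(m1.sum(), bool), np.zeros(m2.sum(), bool)]))
    res = rank_sum_test(vote_col[m1], vote_col[m2], tail="two-sided")
    return a, res, str(d1), str(d2)


@dataclass
class MatchResult:
    """Bundle of everything the matching stage derives from one atlas pair."""

    rnc_a: RankNormalizedCells
    rnc_b: RankNormalizedCells
    ab: AurocTable
    ba: AurocTable
    sym: AurocTable
    pairs: ReciprocalPairTable


def match_datasets(
    nv_a: NormalizedView, nv_b: NormalizedView, hvg: HvgSet, alpha: float = 0.05
) -> MatchResult:
    """Full cross-atlas matching: voting both ways, reciprocity, best-vs-next.

    Best-vs-next rank-sum p-values are Bonferroni-corrected within each
    atlas's family of reference clusters; a reciprocal pair is ``confident``
    when both adjusted p-values fall below ``alpha``.
    """
    rnc_a = rank_normalize(nv_a, hvg)
    rnc_b = rank_normalize(nv_b, hvg)
    ab = one_vs_all_auroc(rnc_a, rnc_b)
    ba = one_vs_all_auroc(rnc_b, rnc_a)
    sym = symmetric_auroc(ab, ba)
    votes_into_b = votes(rnc_a, rnc_b).to_numpy()
    votes_into_a = votes(rnc_b, rnc_a).to_numpy()
    labels_a = rnc_a.clusters.to_numpy()
    labels_b = rnc_b.clusters.to_numpy()
    clusters_a = list(sym.values.index)
    clusters_b = list(sym.values.columns)
    sizes_a = pd.Series(labels_a).value_counts()
    sizes_b = pd.Series(labels_b).value_counts()
    recip = set(top_hits(sym))

    rows = []
    arr = sym.values.to_numpy()
    for i, ca in enumerate(clusters_a):
        j = int(arr[i].argmax())
        cb = clusters_b[j]
        bvn_a, res_a, _, _ = best_vs_next(votes_into_b[:, i], labels_b, ab.values.loc[ca])
        # B-side reference: how well does cb discriminate its two best A clusters
        jb = clusters_b.index(cb)
        bvn_b, res_b, _, _ = best_vs_next(votes_into_a[:, jb], labels_a, ba.values.loc[cb])
        rows.append({
            "cluster_a": ca, "cluster_b": cb,
            "symmetric_auroc": arr[i, j],
            "best_vs_next_a": bvn_a, "best_vs_next_b": bvn_b,
            "bvn_p_a": res_a.p_value, "bvn_p_b": res_b.p_value,
            "size_a": int(sizes_a[ca]), "size_b": int(sizes_b[cb]),
            "is_reciprocal": (ca, cb) in recip,
        })
    table = pd.DataFrame(rows)
    table["bvn_p_adj_a"] = np.minimum(1.0, table["bvn_p_a"] * len(clusters_a))
    table["bvn_p_adj_b"] = np.minimum(1.0, table["bvn_p_b"] * len(clusters_b))
    table["confident"] = (
        table["is_reciprocal"]
        & (table["bvn_p_adj_a"] < alpha)
        & (table["bvn_p_adj_b"] < alpha)
    )
    return MatchResult(rnc_a, rnc_b, ab, ba, sym, ReciprocalPairTable(table, alpha))


# -- pretrained models --------------------------------------------------------

def build_pretrained(rnc: RankNormalizedCells) -> PretrainedModel:
    """Average the rank-normalized vectors per cluster into a portable model."""
    cent = cluster_centroids(rnc)
    sizes = rnc.clusters.value_counts().sort_index()
    return PretrainedModel(list(cent.columns), cent, sizes, rnc.dataset_id,
                           dict(rnc.hvg.provenance))


def apply_pretrained(
    model: PretrainedModel, nv_target: NormalizedView
) -> tuple[AurocTable, pd.DataFrame]:
    """Match an independent dataset against a pretrained model.

    Both sides are restricted to the shared genes and re-centered /
    re-normalized there (target cells re-ranked); per-cluster rescaling is
    monotone, so at full gene overlap the AUROC table equals training-time
    one-vs-all exactly. Returns the table and per-target-cluster best matches.
    """
    shared = [g for g in model.gene_ids if g in set(map(str, nv_target.gene_ids))]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} genes shared between model ({len(model.gene_ids)}) "
            f"and target ({len(nv_target.gene_ids)}); need >= 3"
        )
    cent = model.centroids[shared].to_numpy()
    cent, _ = center_unit_rows(cent)
    idx = pd.Index(nv_target.gene_ids).get_indexer(shared)
    sub = nv_target.values[idx]
    ranks = rankdata(sub, axis=0).T
    tv, degenerate = center_unit_rows(ranks)
    vote_mat = tv @ cent.T  # target cells x model clusters
    labels = nv_target.cluster_of.to_numpy()
    keep = ~degenerate
    labels_k = labels[keep]
    target_clusters = np.array(sorted(pd.unique(labels_k)))
    out = np.stack([
        grouped_auroc(vote_mat[keep, i], labels_k, target_clusters)
        for i in range(cent.shape[0])
    ])
    table = AurocTable(
        pd.DataFrame(out, index=model.centroids.index, columns=target_clusters),
        (model.dataset_id, nv_target.parent.dataset_id),
    )
    best_idx = np.nanargmax(out, axis=0)
    best = pd.DataFrame({
        "target_cluster": target_clusters,
        "best_model_cluster": model.centroids.index.to_numpy()[best_idx],
        "auroc": out[best_idx, np.arange(len(target_clusters))],
    })
    return table, best


def reciprocal_enrichment(best: pd.DataFrame, reciprocal_set: set,
                          model_clusters) -> TestResult:
    """Fisher enrichment of reciprocal-hit clusters among assigned best matches.

    2x2 table: target clusters best-matching reciprocal vs non-reciprocal
    model clusters, against the availability of reciprocal vs non-reciprocal
    clusters in the model itself.
    """
    in_recip = best["best_model_cluster"].isin(reciprocal_set)
    model_clusters = list(model_clusters)
    n_recip_model = sum(1 for c in model_clusters if c in reciprocal_set)
    table = [
        [int(in_recip.sum()), int((~in_recip).sum())],
        [n_recip_model, len(model_clusters) - n_recip_model],
    ]
    return fisher_exact_2x2(table, tail="two-sided")


def two_model_summary(
    best_a: pd.DataFrame, best_b: pd.DataFrame, pairs: ReciprocalPairTable
) -> pd.DataFrame:
    """Per-target-cluster count of reciprocal best matches under the two models.

    ``hit_count`` in {0, 1, 2}; ``best_auroc`` is the better of the two
    best-match scores, the quantity whose median rises with the count.
    """
    recip = pairs.reciprocal()
    recip_a = set(recip["cluster_a"])
    recip_b = set(recip["cluster_b"])
    a = best_a.set_index("target_cluster")
    b = best_b.set_index("target_cluster")
    if set(a.index) != set(b.index):
        raise ValueError("the two match maps cover different target clusters")
    rows = []
    for t in sorted(a.index):
        count = int(a.loc[t, "best_model_cluster"] in recip_a) + int(
            b.loc[t, "best_model_cluster"] in recip_b
        )
        rows.append({
            "target_cluster": t,
            "hit_count": count,
            "best_auroc": max(float(a.loc[t, "auroc"]), float(b.loc[t, "auroc"])),
        })
    return pd.DataFrame(rows)


def select_pair_markers(
    pair: tuple[str, str],
    nv_a: NormalizedView,
    nv_b: NormalizedView,
    sym: AurocTable,
    m: int = 4,
) -> tuple[list[str], dict[str, float]]:
    """Markers that distinguish both sides of a reciprocal pair locally.

    The contrast cluster in each atlas is the runner-up in the symmetric
    AUROC profile (second-best A cluster for the B side and vice versa). Each
    gene is scored by the smaller of its two single-gene AUROCs (pair cluster
    vs contrast cluster); the top-m genes are returned together with the
    local AUROC their mean z-score achieves in each atlas.
    """
    ca, cb = pair
    col = sym.values[cb].drop(labels=[ca], errors="ignore")
    row = sym.values.loc[ca].drop(labels=[cb], errors="ignore")
    ca2 = col.index[np.argmax(col.to_numpy())]
    cb2 = row.index[np.argmax(row.to_numpy())]
    shared = pd.Index(nv_a.gene_ids).intersection(pd.Index(nv_b.gene_ids)).sort_values()

    def gene_aurocs(nv, pos_cluster, neg_cluster):
        labels = nv.cluster_of.to_numpy()
        keep = (labels == pos_cluster) | (labels == neg_cluster)
        idx = pd.Index(nv.gene_ids).get_indexer(shared)
        sub = nv.values[idx][:, keep]
        pos = labels[keep] == pos_cluster
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        ranks = rankdata(sub, axis=1)
        r_pos = ranks[:, pos].sum(axis=1)
        return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    score = np.minimum(gene_aurocs(nv_a, ca, ca2), gene_aurocs(nv_b, cb, cb2))
    if m > len(shared):
        import warnings

        warnings.warn("m exceeds available genes; returning all", stacklevel=2)
        m = len(shared)
    top = np.argsort(-score, kind="stable")[:m]
    selected = [str(shared[i]) for i in top]

    from .data import zscore_genes
    from .markers import marker_score_cells

    local = {}
    for nv, pos_cluster, neg_cluster, key in (
        (nv_a, ca, ca2, "a"), (nv_b, cb, cb2, "b")
    ):
        z = zscore_genes(nv)
        s = marker_score_cells(z, nv.gene_ids, selected)
        labels = nv.cluster_of.to_numpy()
        keep = (labels == pos_cluster) | (labels == neg_cluster)
        local[key] = auroc(s[keep], labels[keep] == pos_cluster)
    return selected, local
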
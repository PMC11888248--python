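"""Coordinated gene expression across reciprocally matched cluster centroids.

For every gene outside the HVG set used for matching, the per-gene Spearman
correlation between its two centroid profiles (one per atlas, one column per
matched pair) measures how well the matched clusters reproduce its
expression pattern. Specificity asks whether the same-gene correlation beats
correlations between that gene and every other gene, summarized as a
percentile and a strict is-top flag; both are computed with rank-matrix
products so all genes are handled at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import center_unit_rows, rank_rows, substream
from .data import HvgSet, NormalizedView, compute_centroids
from .stats import adjust_p, rank_sum_test


@dataclass
class CoordExprTable:
    """Per-gene coordinated-expression statistics."""

    table: pd.DataFrame  # index gene; same_gene_rho, percentile, is_top, n_pairs_used
    n_pairs: int

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False)


def paired_centroid_matrices(
    nv_a: NormalizedView,
    nv_b: NormalizedView,
    pairs: list[tuple[str, str]],
    exclude: HvgSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x pair centroid matrices, one per atlas, on shared non-HVG genes."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched pairs")
    shared = pd.Index(nv_a.gene_ids).intersection(pd.Index(nv_b.gene_ids)).sort_values()
    if exclude is not None:
        shared = shared.difference(pd.Index(exclude.gene_ids))
    cent_a = compute_centroids(nv_a)
    cent_b = compute_centroids(nv_b)
    cols_a = [a for a, _ in pairs]
    cols_b = [b for _, b in pairs]
    mat_a = cent_a.loc[cols_a, shared].T
    mat_b = cent_b.loc[cols_b, shared].T
    mat_a.columns = mat_b.columns = [f"pair{i}" for i in range(len(pairs))]
    return mat_a, mat_b


def _rank_unit(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranked = rank_rows(mat)
    return center_unit_rows(ranked)


def coordinated_rho(mat_a: pd.DataFrame, mat_b: pd.DataFrame) -> pd.Series:
    """Per-gene Spearman between the two centroid profiles; constant rows -> NaN."""
    if mat_a.shape != mat_b.shape:
        raise ValueError("matrices must be conformable")
    ra, dega = _rank_unit(mat_a.to_numpy())
    rb, degb = _rank_unit(mat_b.to_numpy())
    rho = np.einsum("ij,ij->i", ra, rb)
    rho[dega | degb] = np.nan
    return pd.Series(rho, index=mat_a.index)


def specificity(
    mat_a: pd.DataFrame, mat_b: pd.DataFrame, tie_tol: float = 1e-12
) -> pd.DataFrame:
    """Same-gene correlation percentile against all cross-gene correlations.

    For gene g the comparison set is {rho(g_A, h_B)} union {rho(h_A, g_B)}
    over h != g; the percentile counts strictly-smaller members plus half the
    ties; is_top requires the same-gene rho to strictly exceed every member.
    Constant (rank-degenerate) genes are excluded throughout.
    """
    ra, dega = _rank_unit(mat_a.to_numpy())
    rb, degb = _rank_unit(mat_b.to_numpy())
    ok = ~(dega | degb)
    idx_ok = np.where(ok)[0]
    c = ra[ok] @ rb[ok].T  # cross-correlation among non-degenerate genes
    diag = np.diag(c)
    n = c.shape[0]
    pct = np.full(mat_a.shape[0], np.nan)
    top = np.zeros(mat_a.shape[0], dtype=bool)
    for pos in range(n):
        others = np.concatenate([
            np.delete(c[pos], pos),      # g_A vs h_B
            np.delete(c[:, pos], pos),   # h_A vs g_B
        ])
        d = diag[pos]
        below = np.sum(others < d - tie_tol)
        ties = np.sum(np.abs(others - d) <= tie_tol)
        g = idx_ok[pos]
        pct[g] = 100.0 * (below + 0.5 * ties) / others.size
        top[g] = bool(np.all(others < d - tie_tol))
    out = pd.DataFrame(
        {"same_gene_rho": coordinated_rho(mat_a, mat_b),
         "percentile": pct, "is_top": top},
        index=mat_a.index,
    )
    return out


def coordinated_table(
    mat_a: pd.DataFrame, mat_b: pd.DataFrame, excluded_hvg: HvgSet | None = None
) -> CoordExprTable:
    df = specificity(mat_a, mat_b)
    df["n_pairs_used"] = mat_a.shape[1]
    return CoordExprTable(df, mat_a.shape[1])


def subsample_curves(
    mat_a: pd.DataFrame,
    mat_b: pd.DataFrame,
    fractions=(0.1, 0.25, 0.5, 1.0),
    n_rep: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Stability of the three statistics under pair-column subsampling.

    Per fraction, ``n_rep`` random column subsets are scored; fraction 1.0 is
    computed once on the full data (zero spread). Fractions leaving < 3 pairs
    are skipped with a flag row.
    """
    rng = substream(seed, "subsample_curves")
    n_pairs = mat_a.shape[1]
    rows = []
    for f in fractions:
        k = int(np.ceil(f * n_pairs))
        if k < 3:
            rows.append({"fraction": f, "n_pairs": k, "skipped": True,
                         "mean_rho": np.nan, "mean_percentile": np.nan,
                         "prop_top": np.nan, "sd_rho": np.nan})
            continue
        reps = 1 if k == n_pairs else n_rep
        stats = []
        for _ in range(reps):
            cols = np.sort(rng.choice(n_pairs, size=k, replace=False)) if k < n_pairs \
                else np.arange(n_pairs)
            sa, sb = mat_a.iloc[:, cols], mat_b.iloc[:, cols]
            spec = specificity(sa, sb)
            stats.append((
                np.nanmean(spec["same_gene_rho"]),
                np.nanmean(spec["percentile"]),
                float(np.mean(spec["is_top"][spec["percentile"].notna()])),
            ))
        arr = np.array(stats)
        rows.append({
            "fraction": f, "n_pairs": k, "skipped": False,
            "mean_rho": arr[:, 0].mean(), "mean_percentile": arr[:, 1].mean(),
            "prop_top": arr[:, 2].mean(), "sd_rho": arr[:, 0].std(ddof=0),
        })
    return pd.DataFrame(rows)


def read_gmt(path) -> dict[str, set[str]]:
    """Flat GMT gene-set reader: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def gene_set_summary(
    coord: CoordExprTable,
    sets: dict[str, set[str]],
    min_size: int = 15,
    max_size: int = 150,
) -> pd.DataFrame:
    """Per-set coordinated-expression summaries with a rank-sum enrichment test.

    Sets are intersected with scored genes and dropped outside
    [min_size, max_size]; in-set percentiles are compared with the complement
    by a rank-sum test, BH-adjusted across sets.
    """
    if not sets:
        raise ValueError("empty gene-set collection")
    scored = coord.table.dropna(subset=["percentile"])
    genes = pd.Index(scored.index)
    rows = []
    for name in sorted(sets):
        members = genes.intersection(pd.Index(sorted(sets[name])))
        if not (min_size <= len(members) <= max_size):
            continue
        inside = scored.loc[members, "percentile"].to_numpy()
        outside = scored.loc[genes.difference(members), "percentile"].to_numpy()
        res = rank_sum_test(inside, outside, tail="greater")
        rows.append({
            "set": name, "n_genes": len(members),
            "mean_rho": float(scored.loc[members, "same_gene_rho"].mean()),
            "mean_percentile": float(inside.mean()),
            "p": res.p_value,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = adjust_p(df["p"].to_numpy(), "bh")
    return df
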
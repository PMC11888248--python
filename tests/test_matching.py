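import numpy as np
import pandas as pd
import pytest

import atlasrep as ar
from atlasrep.data import HvgSet
from atlasrep.matching import (
    apply_pretrained,
    best_vs_next,
    build_pretrained,
    reciprocal_enrichment,
    select_pair_markers,
    top_hits,
    two_model_summary,
)
from atlasrep.simulate import simulate_pair, split_config
from atlasrep.voting import one_vs_all_auroc, rank_normalize


def _table(arr, rows, cols):
    return ar.AurocTable(pd.DataFrame(arr, index=rows, columns=cols), ("A", "B"))


class TestTopHits:
    def test_clean_diagonal(self):
        sym = _table([[0.9, 0.2], [0.3, 0.8]], ["a1", "a2"], ["b1", "b2"])
        assert top_hits(sym) == [("a1", "b1"), ("a2", "b2")]

    def test_non_mutual_best_excluded(self):
        # a2's best is b1, but b1 prefers a1 -> only (a1, b1) is reciprocal
        sym = _table([[0.9, 0.8], [0.85, 0.2]], ["a1", "a2"], ["b1", "b2"])
        assert top_hits(sym) == [("a1", "b1")]

    def test_reciprocity_symmetric_under_transpose(self, default_pair):
        sym = default_pair.match.sym
        fwd = set(top_hits(sym))
        flipped = ar.AurocTable(sym.values.T, "symmetric")
        rev = {(a, b) for b, a in top_hits(flipped)}
        assert fwd == rev

    def test_reciprocal_rows_are_one_to_one(self, split_pair):
        rec = split_pair.match.pairs.reciprocal()
        assert rec["cluster_a"].is_unique and rec["cluster_b"].is_unique


class TestBestVsNext:
    def test_separated_clusters_score_one(self):
        votes = np.array([0.9, 0.9, 0.2, 0.2, 0.0, 0.0])
        labels = np.array(["d1", "d1", "d2", "d2", "d3", "d3"])
        row = pd.Series({"d1": 0.99, "d2": 0.7, "d3": 0.5})
        a, res, d1, d2 = best_vs_next(votes, labels, row)
        assert (a, d1, d2) == (1.0, "d1", "d2")
        assert res.p_value < 0.4  # n=2 vs 2 caps attainable significance

    def test_identical_vote_distributions_null(self):
        rng = np.random.default_rng(0)
        aurocs, ps = [], []
        for _ in range(60):
            votes = rng.normal(0, 1, 80)
            labels = np.array(["d1"] * 40 + ["d2"] * 40)
            row = pd.Series({"d1": 0.9, "d2": 0.89})
            a, res, *_ = best_vs_next(votes, labels, row)
            aurocs.append(a)
            ps.append(res.p_value)
        assert abs(np.mean(aurocs) - 0.5) < 0.03
        assert 0.3 < np.mean(ps) < 0.7  # roughly uniform p under the null

    def test_split_children_indistinguishable(self, split_pair):
        t = split_pair.match.pairs.table
        parents = t[t["cluster_a"].isin(split_pair.truth.split_map)]
        assert abs(parents["best_vs_next_a"].mean() - 0.5) < 0.2
        assert parents["confident"].mean() < 0.2

    def test_split_parents_rarely_confident_across_seeds(self):
        """Planted fine splits should not survive the best-vs-next filter."""
        rates = []
        for seed in (1, 2):
            a, b, truth, *_ = simulate_pair(split_config(seed=seed))
            nva, nvb = ar.normalize_log_cpm(a), ar.normalize_log_cpm(b)
            hvg = ar.select_hvgs([nva, nvb])
            res = ar.match_datasets(nva, nvb, hvg)
            t = res.pairs.table
            parents = t[t["cluster_a"].isin(truth.split_map)]
            rates.append(1.0 - parents["confident"].mean())
        assert np.mean(rates) >= 0.5


class TestPretrained:
    def test_round_trip_serialization(self, small_pair, tmp_path):
        model = build_pretrained(small_pair.match.rnc_a)
        model.to_files(tmp_path / "m.tsv", tmp_path / "m.json")
        back = ar.PretrainedModel.from_files(tmp_path / "m.tsv", tmp_path / "m.json")
        np.testing.assert_allclose(back.centroids.to_numpy(),
                                   model.centroids.to_numpy(), atol=1e-9)
        assert list(back.cluster_sizes) == list(model.cluster_sizes)

    def test_singleton_cluster_centroid_is_the_cell(self):
        from conftest import tiny_dataset

        ds = tiny_dataset(n_genes=20, n_cells=3, n_clusters=3)
        rnc = rank_normalize(ar.normalize_log_cpm(ds), HvgSet([f"g{i}" for i in range(20)]))
        model = build_pretrained(rnc)
        for i, k in enumerate(ds.cells["cluster"]):
            np.testing.assert_allclose(model.centroids.loc[k], rnc.vectors[i], atol=1e-12)

    def test_self_application_reproduces_one_vs_all(self, small_pair):
        rnc = small_pair.match.rnc_a
        model = build_pretrained(rnc)
        table, best = apply_pretrained(model, small_pair.nv_a)
        ref = one_vs_all_auroc(rnc, rnc)
        np.testing.assert_allclose(
            table.values.to_numpy(), ref.values.to_numpy(), atol=1e-8
        )
        assert (best["best_model_cluster"] == best["target_cluster"]).all()

    def test_insufficient_gene_overlap_rejected(self, small_pair):
        model = build_pretrained(small_pair.match.rnc_a)
        tiny = small_pair.ds_a.subset_genes(small_pair.ds_a.gene_ids[:1])
        with pytest.raises(ValueError, match="shared"):
            apply_pretrained(model, ar.normalize_log_cpm(tiny))


class TestEnrichmentAndSummary:
    def test_all_reciprocal_matches_extreme(self):
        best = pd.DataFrame({"target_cluster": list("xyz"),
                             "best_model_cluster": ["r1", "r2", "r1"],
                             "auroc": [0.9, 0.9, 0.9]})
        res = reciprocal_enrichment(best, {"r1", "r2"}, ["r1", "r2", "n1", "n2"])
        assert res.statistic == float("inf")

    def test_proportional_matches_near_unit_odds(self):
        rng = np.random.default_rng(0)
        model_clusters = [f"m{i}" for i in range(40)]
        recip = set(model_clusters[:20])
        best = pd.DataFrame({
            "target_cluster": [f"t{i}" for i in range(200)],
            "best_model_cluster": rng.choice(model_clusters, 200),
            "auroc": rng.random(200),
        })
        res = reciprocal_enrichment(best, recip, model_clusters)
        assert 0.5 < res.statistic < 2.0
        assert res.p_value > 0.05

    def test_two_model_hit_counts(self):
        pairs = ar.ReciprocalPairTable(pd.DataFrame({
            "cluster_a": ["a1", "a2"], "cluster_b": ["b1", "b2"],
            "is_reciprocal": [True, False], "confident": [True, False],
        }))
        best_a = pd.DataFrame({"target_cluster": ["t1", "t2"],
                               "best_model_cluster": ["a1", "a2"],
                               "auroc": [0.95, 0.8]})
        best_b = pd.DataFrame({"target_cluster": ["t1", "t2"],
                               "best_model_cluster": ["b1", "b2"],
                               "auroc": [0.9, 0.7]})
        out = two_model_summary(best_a, best_b, pairs).set_index("target_cluster")
        assert out.loc["t1", "hit_count"] == 2
        assert out.loc["t2", "hit_count"] == 0
        assert out.loc["t1", "best_auroc"] == pytest.approx(0.95)

    def test_median_auroc_nondecreasing_in_hit_count(self, default_pair):
        m = default_pair.match
        model_a = build_pretrained(m.rnc_a)
        model_b = build_pretrained(m.rnc_b)
        _, best_a = apply_pretrained(model_a, default_pair.nv_b)
        _, best_b = apply_pretrained(model_b, default_pair.nv_b)
        best_b = best_b.copy()
        out = two_model_summary(best_a, best_b, m.pairs)
        med = out.groupby("hit_count")["best_auroc"].median()
        assert med.is_monotonic_increasing


class TestPairMarkers:
    def test_planted_pair_yields_high_local_auroc(self, default_pair):
        m = default_pair.match
        pair = default_pair.truth.shared_pairs[0]
        genes, local = select_pair_markers(pair, default_pair.nv_a, default_pair.nv_b,
                                           m.sym, m=4)
        assert len(genes) == 4
        assert local["a"] > 0.9 and local["b"] > 0.9

    def test_oversized_m_warns_and_returns_all(self, small_pair):
        m = small_pair.match
        pair = small_pair.truth.shared_pairs[0]
        with pytest.warns(UserWarning, match="exceeds"):
            genes, _ = select_pair_markers(pair, small_pair.nv_a, small_pair.nv_b,
                                           m.sym, m=10**6)
        assert len(genes) == small_pair.ds_a.n_genes

    def test_split_pairs_hard_to_discriminate(self, split_pair):
        """Few sibling-split pairs reach local AUROC >= 0.95 with 4 markers."""
        m = split_pair.match
        rec = m.pairs.reciprocal().head(15)
        hits = 0
        for row in rec.itertuples():
            _, local = select_pair_markers((row.cluster_a, row.cluster_b),
                                           split_pair.nv_a, split_pair.nv_b, m.sym, m=4)
            if min(local.values()) >= 0.95:
                hits += 1
        assert hits / len(rec) < 0.5
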
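import numpy as np
import pandas as pd
import pytest

import atlasrep as ar
from atlasrep.data import RegionMap, compute_centroids
from atlasrep.matching import ReciprocalPairTable
from atlasrep.simulate import simulate_spatial_panel
from atlasrep.spatial import (
    call_cells,
    diversity_mismatch,
    pair_concordance,
    paired_centroid_distance,
    region_enrichment,
    top_region_match,
)


@pytest.fixture(scope="module")
def spatial_setup(default_pair):
    sp = simulate_spatial_panel(default_pair.ds_a, default_pair.truth,
                                panel_size=500, noise_sd=0.1, seed=5)
    nv_sp = ar.normalize_log_cpm(sp)
    cent_a = compute_centroids(default_pair.nv_a)
    cent_b = compute_centroids(default_pair.nv_b)
    calls_a = call_cells(nv_sp, cent_a, n_rounds=50, seed=5)
    calls_b = call_cells(nv_sp, cent_b, n_rounds=50, seed=5)
    return sp, nv_sp, cent_a, cent_b, calls_a, calls_b


def _call_table(rows, threshold=0.5, ref="ref"):
    df = pd.DataFrame(rows)
    df = df.set_index("cell_id")
    from atlasrep.spatial import SpatialCallTable

    return SpatialCallTable(df, ref, threshold)


class TestCallCells:
    def test_cell_equal_to_centroid_called_perfectly(self, default_pair):
        cent = compute_centroids(default_pair.nv_a)
        k = cent.index[3]
        vals = cent.loc[[k, k]].to_numpy().T  # two cells, exact centroid profile
        ds = ar.ExpressionDataset(
            "probe",
            np.zeros((default_pair.ds_a.n_genes, 2), dtype=int),
            default_pair.ds_a.gene_ids,
            pd.DataFrame({"cluster": ["?", "?"]},
                         index=pd.Index(["p0", "p1"], name="cell_id")),
        )
        nv = ar.NormalizedView(vals, ds, np.e)
        calls = call_cells(nv, cent, n_rounds=10, seed=0)
        assert (calls.calls["best_cluster"] == k).all()
        np.testing.assert_allclose(calls.calls["mean_correlation"], 1.0, atol=1e-9)
        assert calls.calls["passed"].all()

    def test_threshold_extremes(self, spatial_setup, default_pair):
        _, nv_sp, cent_a, *_ = spatial_setup
        none = call_cells(nv_sp, cent_a, n_rounds=5, threshold=1.0 + 1e-9, seed=1)
        assert not none.calls["passed"].any()
        every = call_cells(nv_sp, cent_a, n_rounds=5, threshold=-1.0, seed=1)
        assert every.calls["passed"].all()

    def test_single_round_full_genes_is_plain_argmax(self, spatial_setup):
        sp, nv_sp, cent_a, *_ = spatial_setup
        calls = call_cells(nv_sp, cent_a, n_rounds=1, subsample_frac=1.0, seed=2)
        shared = pd.Index(cent_a.columns).intersection(pd.Index(nv_sp.gene_ids)).sort_values()
        x = nv_sp.values[pd.Index(nv_sp.gene_ids).get_indexer(shared)].T
        c = cent_a[shared].to_numpy()
        xc = (x - x.mean(1, keepdims=True)) / np.linalg.norm(x - x.mean(1, keepdims=True), axis=1, keepdims=True)
        cc = (c - c.mean(1, keepdims=True)) / np.linalg.norm(c - c.mean(1, keepdims=True), axis=1, keepdims=True)
        expected = cent_a.index[(xc @ cc.T).argmax(axis=1)]
        assert (calls.calls["best_cluster"].to_numpy() == expected.to_numpy()).all()

    def test_more_rounds_reduce_correlation_variance(self, spatial_setup):
        _, nv_sp, cent_a, *_ = spatial_setup
        reps = {n: [] for n in (10, 100)}
        for n_rounds in reps:
            for seed in range(8):
                calls = call_cells(nv_sp, cent_a, n_rounds=n_rounds, seed=100 + seed)
                reps[n_rounds].append(calls.calls["mean_correlation"].iloc[0])
        assert np.var(reps[100]) < np.var(reps[10])

    def test_deterministic_given_seed(self, spatial_setup):
        _, nv_sp, cent_a, *_ = spatial_setup
        c1 = call_cells(nv_sp, cent_a, n_rounds=5, seed=3)
        c2 = call_cells(nv_sp, cent_a, n_rounds=5, seed=3)
        pd.testing.assert_frame_equal(c1.calls, c2.calls)


class TestConcordance:
    def test_flags_require_both_passes_and_reciprocal_pair(self):
        pairs = ReciprocalPairTable(pd.DataFrame({
            "cluster_a": ["a1", "a2"], "cluster_b": ["b1", "b2"],
            "is_reciprocal": [True, False], "confident": [True, False],
        }))
        rows_a = [
            {"cell_id": "c1", "best_cluster": "a1", "mean_correlation": 0.9,
             "passed": True, "slice": 0},
            {"cell_id": "c2", "best_cluster": "a1", "mean_correlation": 0.4,
             "passed": False, "slice": 0},
            {"cell_id": "c3", "best_cluster": "a2", "mean_correlation": 0.8,
             "passed": True, "slice": 0},
        ]
        rows_b = [
            {"cell_id": "c1", "best_cluster": "b1", "mean_correlation": 0.9,
             "passed": True, "slice": 0},
            {"cell_id": "c2", "best_cluster": "b1", "mean_correlation": 0.9,
             "passed": True, "slice": 0},
            {"cell_id": "c3", "best_cluster": "b2", "mean_correlation": 0.9,
             "passed": True, "slice": 0},
        ]
        flag, per_slice = pair_concordance(_call_table(rows_a), _call_table(rows_b), pairs)
        assert flag.tolist() == [True, False, False]  # c2 failed; (a2,b2) not reciprocal
        assert per_slice.iloc[0]["prop_concordant"] == pytest.approx(0.5)

    def test_synthetic_concordance_high_for_planted_pairs(self, spatial_setup, default_pair):
        *_, calls_a, calls_b = spatial_setup
        flag, per_slice = pair_concordance(calls_a, calls_b, default_pair.match.pairs)
        assert flag.mean() > 0.9
        assert per_slice["prop_concordant"].between(0, 1).all()


class TestDiversityMismatch:
    def test_identical_calls_give_zero(self, spatial_setup):
        *_, calls_a, _ = spatial_setup
        out = diversity_mismatch(calls_a, calls_a, n_rep=10, seed=0)
        assert (out["mismatch"] == 0).all()

    def test_broader_reference_gives_positive_mismatch(self):
        rng = np.random.default_rng(0)
        rows_a = [{"cell_id": f"c{i}", "best_cluster": f"k{i % 10}", "passed": True,
                   "mean_correlation": 0.9, "slice": 0} for i in range(100)]
        rows_b = [{"cell_id": f"c{i}", "best_cluster": f"k{i % 5}", "passed": True,
                   "mean_correlation": 0.9, "slice": 0} for i in range(100)]
        out = diversity_mismatch(_call_table(rows_a), _call_table(rows_b), n_rep=50, seed=1)
        assert out.iloc[0]["mismatch"] > 0

    def test_seed_determinism(self, spatial_setup):
        *_, calls_a, calls_b = spatial_setup
        o1 = diversity_mismatch(calls_a, calls_b, n_rep=10, seed=4)
        o2 = diversity_mismatch(calls_a, calls_b, n_rep=10, seed=4)
        pd.testing.assert_frame_equal(o1, o2)


class TestRegionEnrichment:
    def _calls(self):
        regions = ["r1"] * 60 + ["r2"] * 60
        flagged = [True] * 30 + [False] * 30 + [True] * 45 + [False] * 15
        calls = pd.DataFrame({"region": regions},
                             index=[f"c{i}" for i in range(120)])
        return calls, pd.Series(flagged, index=calls.index)

    def test_global_rate_region_maps_to_zero(self):
        calls, flag = self._calls()
        enr = region_enrichment(calls, pd.Series(True, index=calls.index) & flag,
                                min_cells=10)
        # r1 at 50% vs global 62.5%: log2(0.8); r2 at 75%: log2(1.2)
        assert enr["r1"] == pytest.approx(np.log2(0.5 / 0.625))
        assert enr["r2"] == pytest.approx(np.log2(0.75 / 0.625))

    def test_weighted_mean_of_linear_enrichment_is_one(self):
        calls, flag = self._calls()
        enr = region_enrichment(calls, flag, min_cells=0)
        weights = calls["region"].value_counts()
        linear = (2.0 ** enr) * weights[enr.index]
        assert linear.sum() / weights.sum() == pytest.approx(1.0)

    def test_small_regions_suppressed(self):
        calls, flag = self._calls()
        calls.iloc[:3, calls.columns.get_loc("region")] = "tiny"
        enr = region_enrichment(calls, flag, min_cells=50)
        assert "tiny" not in enr.index


class TestDistancesAndRegions:
    def test_three_four_five(self):
        rows_a = [{"cell_id": "c1", "best_cluster": "a", "passed": True,
                   "mean_correlation": 1.0, "slice": 0, "x": 0.0, "y": 0.0}]
        rows_b = [{"cell_id": "c1", "best_cluster": "b", "passed": True,
                   "mean_correlation": 1.0, "slice": 0, "x": 3.0, "y": 4.0}]
        out = paired_centroid_distance(_call_table(rows_a), _call_table(rows_b),
                                       [("a", "b")])
        assert out.iloc[0]["distance_mm"] == pytest.approx(5.0)

    def test_unlocated_pair_flagged(self, spatial_setup):
        *_, calls_a, calls_b = spatial_setup
        out = paired_centroid_distance(calls_a, calls_b, [("ghost", "ghost")])
        assert not out.iloc[0]["located"]

    def test_planted_pairs_closer_than_random(self, spatial_setup, default_pair):
        *_, calls_a, calls_b = spatial_setup
        truth = default_pair.truth
        planted = paired_centroid_distance(calls_a, calls_b, truth.shared_pairs)
        rng = np.random.default_rng(2)
        b_sides = [b for _, b in truth.shared_pairs]
        rand = [(a, b_sides[rng.integers(len(b_sides))]) for a, _ in truth.shared_pairs]
        random_d = paired_centroid_distance(calls_a, calls_b, rand)
        assert planted["distance_mm"].mean() < random_d["distance_mm"].mean()

    def test_top_region_match_rules(self, tiny_ds):
        import scipy.sparse as sp_

        def mk(regions, clusters, did):
            cells = pd.DataFrame({"cluster": clusters, "region": regions},
                                 index=pd.Index([f"{did}{i}" for i in range(len(clusters))],
                                                name="cell_id"))
            counts = sp_.csr_matrix(np.ones((2, len(clusters)), dtype=int))
            return ar.ExpressionDataset(did, counts, np.array(["g0", "g1"], dtype=object), cells)

        ds_a = mk(["X"] * 4 + ["X", "Y", "Y", "Y"], ["k1"] * 4 + ["k2"] * 4, "a")
        ds_b = mk(["X"] * 4 + ["Y", "Y", "Y", "X"], ["k1"] * 4 + ["k2"] * 4, "b")
        out = top_region_match(ds_a, ds_b, [("k1", "k1"), ("k2", "k2")])
        row1 = out[out["cluster_a"] == "k1"].iloc[0]
        assert row1["top1"] and row1["top2"] is None  # single-region pair: top2 undefined
        row2 = out[out["cluster_a"] == "k2"].iloc[0]
        assert row2["top1"] and row2["top2"] is True  # unordered {X, Y} matches
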
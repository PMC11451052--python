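import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from paintprox import (
    AcquisitionConfig,
    ProximityConfig,
    estimate_precision,
    export_pair_distances,
    median_distance_matrix,
    nn_distances,
    rank_partners,
    simulate_experiment,
    simulate_target_round,
)
from paintprox.proximity import InsufficientDataError

from conftest import make_table


def brute_force_nn(src, tgt, cutoff):
    if len(src) == 0 or len(tgt) == 0:
        return np.empty(0)
    d = cdist(src, tgt).min(axis=1)
    return d[d < cutoff]


class TestNNDistances:
    def test_three_four_five_triangle(self):
        s = nn_distances(make_table([(0.0, 0.0)]), make_table([(30.0, 40.0)]), 500.0)
        assert s.distances == pytest.approx([50.0])
        assert s.n_source == 1 and s.n_kept == 1

    def test_cutoff_is_strict(self):
        far = nn_distances(make_table([(0.0, 0.0)]), make_table([(600.0, 0.0)]), 500.0)
        assert far.n_kept == 0
        at_cut = nn_distances(make_table([(0.0, 0.0)]), make_table([(500.0, 0.0)]), 500.0)
        assert at_cut.n_kept == 0  # boundary equality excluded
        inside = nn_distances(make_table([(0.0, 0.0)]), make_table([(499.9, 0.0)]), 500.0)
        assert inside.n_kept == 1

    def test_identical_tables_give_zero(self):
        t = make_table([(1.0, 2.0), (3.0, 4.0)])
        assert np.allclose(nn_distances(t, t, 500.0).distances, 0.0)

    def test_empty_target_is_not_an_error(self):
        s = nn_distances(make_table([(0.0, 0.0)]), make_table(np.empty((0, 2))), 500.0)
        assert s.n_kept == 0 and s.n_source == 1

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            nn_distances(make_table([(0.0, 0.0)]), make_table([(1.0, 1.0)]), -5.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_matches_exhaustive_search(self, seed):
        """k-d tree NN distances equal brute-force O(n²) search exactly."""
        rng = np.random.default_rng(seed)
        n_s, n_t = rng.integers(1, 300, size=2)
        src = rng.uniform(0, 2000, size=(n_s, 2))
        tgt = rng.uniform(0, 2000, size=(n_t, 2))
        sample = nn_distances(make_table(src), make_table(tgt), 500.0)
        assert np.array_equal(sample.distances, brute_force_nn(src, tgt, 500.0))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_cutoff_monotonicity(self, seed):
        """Distances kept at a small cutoff are a subset of those kept at a
        larger one, and the median cannot decrease with the cutoff."""
        rng = np.random.default_rng(seed)
        src = make_table(rng.uniform(0, 3000, size=(150, 2)))
        tgt = make_table(rng.uniform(0, 3000, size=(40, 2)))
        small = nn_distances(src, tgt, 200.0).distances
        large = nn_distances(src, tgt, 600.0).distances
        assert set(np.round(small, 9)) <= set(np.round(large, 9))
        if len(small) and len(large):
            assert np.median(small) <= np.median(large) + 1e-12

    def test_adding_target_points_never_increases_distances(self):
        rng = np.random.default_rng(4)
        src = make_table(rng.uniform(0, 1000, size=(100, 2)))
        tgt_small = rng.uniform(0, 1000, size=(20, 2))
        tgt_big = np.vstack([tgt_small, rng.uniform(0, 1000, size=(50, 2))])
        d_small = cdist(src.xy, tgt_small).min(axis=1)
        d_big = nn_distances(src, make_table(tgt_big), 1e9).distances
        assert (d_big <= d_small + 1e-12).all()


class TestMedianMatrix:
    def test_parallel_lines_30nm(self):
        """Dense parallel lines 30 nm apart → both directed medians ≈ 30."""
        x = np.arange(0, 20_000.0, 4.0)
        a = make_table(np.column_stack([x, np.zeros_like(x)]), channel="A")
        b = make_table(np.column_stack([x, np.full_like(x, 30.0)]), channel="B")
        res = median_distance_matrix({"A": a, "B": b})
        assert res.median_matrix.loc["A", "B"] == pytest.approx(30.0, rel=0.01)
        assert res.median_matrix.loc["B", "A"] == pytest.approx(30.0, rel=0.01)

    def test_self_pair_is_zero_and_copy_median_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 500, size=(60, 2))
        res = median_distance_matrix(
            {"A": make_table(pts, channel="A"), "B": make_table(pts, channel="B")}
        )
        assert res.median_matrix.loc["A", "A"] == 0.0
        assert res.median_matrix.loc["A", "B"] == 0.0

    def test_distant_channels_are_missing(self):
        rng = np.random.default_rng(1)
        a = make_table(rng.uniform(0, 100, size=(80, 2)), channel="A")
        b = make_table(rng.uniform(0, 100, size=(80, 2)) + 5000.0, channel="B")
        res = median_distance_matrix({"A": a, "B": b})
        assert np.isnan(res.median_matrix.loc["A", "B"])

    def test_min_pair_count_guard(self):
        a = make_table([(0.0, 0.0)] * 10, channel="A")
        b = make_table([(5.0, 0.0)] * 10, channel="B")
        res = median_distance_matrix({"A": a, "B": b}, ProximityConfig(min_pair_count=50))
        assert np.isnan(res.median_matrix.loc["A", "B"])
        res2 = median_distance_matrix({"A": a, "B": b}, ProximityConfig(min_pair_count=5))
        assert res2.median_matrix.loc["A", "B"] == pytest.approx(5.0)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="two channels"):
            median_distance_matrix({"A": make_table([(0.0, 0.0)])})

    def test_directed_medians_differ_on_asymmetric_densities(self):
        """A tight cluster versus a sparse spread: i→j and j→i medians are
        legitimately different."""
        rng = np.random.default_rng(2)
        tight = make_table(rng.normal(0, 5, size=(200, 2)), channel="tight")
        sparse = make_table(rng.uniform(-400, 400, size=(200, 2)), channel="sparse")
        res = median_distance_matrix(
            {"tight": tight, "sparse": sparse}, ProximityConfig(min_pair_count=10)
        )
        m = res.median_matrix
        assert abs(m.loc["tight", "sparse"] - m.loc["sparse", "tight"]) > 20.0

    def test_symmetrize_pools_both_directions(self):
        rng = np.random.default_rng(3)
        a = make_table(rng.uniform(0, 800, size=(120, 2)), channel="A")
        b = make_table(rng.uniform(0, 800, size=(60, 2)), channel="B")
        res = median_distance_matrix(
            {"A": a, "B": b}, ProximityConfig(symmetrize=True, min_pair_count=10)
        )
        m = res.median_matrix
        assert m.loc["A", "B"] == m.loc["B", "A"]
        pooled = np.concatenate(
            [res.samples[("A", "B")].distances, res.samples[("B", "A")].distances]
        )
        assert m.loc["A", "B"] == pytest.approx(np.median(pooled))


class TestExports:
    def make_result(self):
        rng = np.random.default_rng(5)
        dataset = {
            name: make_table(rng.uniform(0, 600, size=(80, 2)), channel=name)
            for name in ("A", "B", "C")
        }
        return median_distance_matrix(dataset, ProximityConfig(min_pair_count=10))

    def test_row_count_is_total_kept(self):
        res = self.make_result()
        table = export_pair_distances(res)
        assert len(table) == sum(s.n_kept for s in res.samples.values())

    def test_groupby_median_reproduces_matrix(self):
        res = self.make_result()
        table = export_pair_distances(res)
        meds = table.groupby(["source_channel", "target_channel"])["distance_nm"].median()
        for (a, b), sample in res.samples.items():
            if sample.n_kept >= res.config.min_pair_count:
                assert meds[(a, b)] == res.median_matrix.loc[a, b]

    def test_empty_result_gives_header_only(self):
        a = make_table([(0.0, 0.0)] * 5, channel="A")
        b = make_table([(9000.0, 9000.0)] * 5, channel="B")
        res = median_distance_matrix({"A": a, "B": b}, ProximityConfig(min_pair_count=1))
        table = export_pair_distances(res)
        assert len(table) == 0
        assert list(table.columns) == ["source_channel", "target_channel", "distance_nm"]


class TestRankPartners:
    def test_orders_by_median_with_alphabetical_ties(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(0, 500, size=(100, 2))
        dataset = {
            "Q": make_table(base, channel="Q"),
            "B": make_table(base + [30.0, 0.0], channel="B"),
            "A": make_table(base + [0.0, 30.0], channel="A"),
            "far": make_table(base + [120.0, 0.0], channel="far"),
        }
        res = median_distance_matrix(dataset, ProximityConfig(min_pair_count=10))
        ranks = rank_partners(res, "Q")
        assert ranks[0][0] in ("A", "B") and ranks[-1][0] == "far"
        # exact tie breaks alphabetically
        if ranks[0][1] == ranks[1][1]:
            assert ranks[0][0] == "A"

    def test_unknown_query_rejected(self):
        res = TestRankPartners().make_simple()
        with pytest.raises(KeyError):
            rank_partners(res, "nope")

    def make_simple(self):
        a = make_table([(0.0, 0.0)] * 60, channel="A")
        b = make_table([(10.0, 0.0)] * 60, channel="B")
        return median_distance_matrix({"A": a, "B": b}, ProximityConfig(min_pair_count=10))

    def test_all_missing_gives_empty_list(self):
        a = make_table([(0.0, 0.0)] * 60, channel="A")
        b = make_table([(9000.0, 0.0)] * 60, channel="B")
        res = median_distance_matrix({"A": a, "B": b})
        assert rank_partners(res, "A") == []


class TestPrecision:
    def simulate_channel(self, sigma, seed=0, n_sites=500):
        rng = np.random.default_rng(seed)
        sites = rng.uniform(0, 20_000, size=(n_sites, 2))
        cfg = AcquisitionConfig(
            round_order=("A",),
            mean_blinks_per_site=10.0,
            sigma_loc=sigma,
            linkage_radius=0.0,
            false_rate=0.0,
        )
        return simulate_target_round(sites, cfg, 0, seed=seed + 1)

    @pytest.mark.parametrize("sigma", [5.0, 10.0, 20.0])
    def test_recovers_simulated_sigma(self, sigma):
        table = self.simulate_channel(sigma)
        est = estimate_precision(table, fit_range=max(100.0, 8 * sigma))
        assert est.sigma == pytest.approx(sigma, rel=0.10)
        assert est.method == "nena_adjacent_frame"

    def test_degenerate_noiseless_channel(self):
        table = self.simulate_channel(0.0)
        est = estimate_precision(table)
        assert est.sigma < 0.5

    def test_too_few_localizations_rejected(self):
        table = make_table(np.random.default_rng(0).uniform(0, 100, size=(10, 2)))
        with pytest.raises(InsufficientDataError):
            estimate_precision(table)


def test_layer_separation_recovered_via_pipeline(flat_two_layer_model, noise_free_acq):
    """With noise off and dense labeling, the measured median approaches the
    true layer separation."""
    tables, _ = simulate_experiment(flat_two_layer_model, noise_free_acq, seed=4)
    res = median_distance_matrix(tables)
    assert res.median_matrix.loc["A", "B"] == pytest.approx(30.0, rel=0.05)
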
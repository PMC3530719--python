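import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bedmr.coloc import (
    ColocError,
    NullModel,
    call_bedmrs,
    coloc_test,
    cumulative_curve,
    fit_null_models,
    inter_dmr_spacings,
    nearest_distance,
    randomize_dmr_locations,
)
from bedmr.core import GenomeSpec


def ber_frame(centers, chrom="chr1"):
    return pd.DataFrame({"chrom": [chrom] * len(centers), "center": list(centers)})


def point_frame(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": [chrom] * len(positions), "pos": list(positions)})


class TestNearestDistance:
    def test_picks_nearer_of_two_targets(self):
        d = nearest_distance(point_frame([4_000_000]), ber_frame([1_000_000, 5_000_000]))
        assert d[0] == 1_000_000

    def test_coincident_point_has_zero_distance(self):
        assert nearest_distance(point_frame([5_000_000]), ber_frame([5_000_000]))[0] == 0

    def test_ber_free_chromosome_gives_infinity(self):
        d = nearest_distance(point_frame([100], chrom="chr2"), ber_frame([500]))
        assert np.isinf(d[0])

    def test_no_targets_anywhere_is_an_error(self):
        with pytest.raises(ValueError):
            nearest_distance(point_frame([1]), ber_frame([]))

    def test_matches_brute_force_all_pairs(self, rng):
        points = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 60),
            "pos": rng.uniform(0, 1e7, 60),
        })
        bers = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 15),
            "center": rng.uniform(0, 1e7, 15),
        })
        got = nearest_distance(points, bers)
        for i, row in points.iterrows():
            same = bers[bers["chrom"] == row["chrom"]]
            expected = (
                np.min(np.abs(same["center"] - row["pos"])) if len(same) else np.inf
            )
            assert got[i] == pytest.approx(expected)


class TestFitNullModels:
    def test_gamma_ml_recovers_generating_parameters(self):
        gen = np.random.default_rng(5)
        s = gen.gamma(2.0, 1e6, 500)
        models = fit_null_models(s)
        g = models["gamma"].params
        assert g["shape"] == pytest.approx(2.0, rel=0.10)
        assert g["scale"] == pytest.approx(1e6, rel=0.10)

    def test_exponential_spacings_fit_shape_near_one(self):
        gen = np.random.default_rng(6)
        s = gen.exponential(2e6, 500)
        models = fit_null_models(s)
        assert models["gamma"].params["shape"] == pytest.approx(1.0, rel=0.15)

    def test_normal_by_moments_and_uniform_upper(self):
        s = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10]) * 1e5
        models = fit_null_models(s)
        assert models["normal"].params["mean"] == pytest.approx(s.mean())
        assert models["normal"].params["sd"] == pytest.approx(s.std(ddof=1))
        assert models["uniform"].params == {"lower": 0.0, "upper": 1e6}

    def test_constant_spacings_get_sd_floor_and_flag(self):
        models = fit_null_models(np.full(20, 1e6))
        assert models["normal"].degenerate
        assert models["normal"].params["sd"] > 0
        assert models["gamma"].params["shape"] >= 1e5  # near-deterministic spacing

    def test_nonpositive_spacings_dropped_with_warning(self):
        s = np.concatenate([np.full(15, 1e5), [-1.0, 0.0]])
        with pytest.warns(UserWarning, match="non-positive"):
            fit_null_models(s)


class TestRandomize:
    def test_uniform_model_positions_pass_ks_uniformity(self):
        genome = GenomeSpec(("chr1",), (50_000_000,))
        model = NullModel("uniform", {"lower": 0.0, "upper": 1e6})
        rng = np.random.default_rng(3)
        pts = randomize_dmr_locations(model, {"chr1": 1000}, genome, rng)
        u = pts["pos"].to_numpy() / 50_000_000
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_zero_count_chromosome_gets_no_positions(self):
        genome = GenomeSpec(("chr1", "chr2"), (1_000_000, 1_000_000))
        model = NullModel("uniform", {"lower": 0.0, "upper": 1e5})
        pts = randomize_dmr_locations(model, {"chr1": 5, "chr2": 0},
                                      genome, np.random.default_rng(0))
        assert set(pts["chrom"]) == {"chr1"}

    def test_gamma_walk_spacings_match_model_mean(self):
        # chromosome much longer than the walk, so a single renewal walk
        # almost surely fits and the spacing distribution is untruncated
        genome = GenomeSpec(("chr1",), (100_000_000_000,))
        model = NullModel("gamma", {"shape": 2.0, "scale": 5e5})  # mean 1 Mb
        rng = np.random.default_rng(4)
        pts = randomize_dmr_locations(model, {"chr1": 1000}, genome, rng)
        spacings = np.diff(np.sort(pts["pos"].to_numpy()))
        assert spacings.mean() == pytest.approx(model.mean_spacing, rel=0.10)

    def test_counts_always_match_request(self):
        genome = GenomeSpec(("chr1",), (10_000_000,))
        model = NullModel("gamma", {"shape": 2.0, "scale": 2e6})
        pts = randomize_dmr_locations(model, {"chr1": 8}, genome,
                                      np.random.default_rng(9))
        assert len(pts) == 8
        assert ((pts["pos"] >= 0) & (pts["pos"] < 1e7)).all()

    def test_impossible_spacings_raise_after_restarts(self):
        genome = GenomeSpec(("chr1",), (1_000,))
        model = NullModel("gamma", {"shape": 100.0, "scale": 1e6})  # >> chrom
        with pytest.raises(ColocError, match="chr1"):
            randomize_dmr_locations(model, {"chr1": 10}, genome,
                                    np.random.default_rng(0), max_restarts=5)


@pytest.fixture
def genome():
    return GenomeSpec(("chr1", "chr2"), (60_000_000, 60_000_000))


@pytest.fixture
def bers():
    return pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2", "chr2"],
        "center": [10_000_000, 40_000_000, 20_000_000, 50_000_000],
    })


class TestColocTest:
    def test_planted_proximity_detected_with_small_dstar(self, genome, bers):
        gen = np.random.default_rng(21)
        rows = []
        for _, b in bers.iterrows():  # 10 DMRs within 0.5 Mb of each BER
            for _ in range(10):
                rows.append((b["chrom"], b["center"] + gen.uniform(-5e5, 5e5)))
        points = pd.DataFrame(rows, columns=["chrom", "pos"])
        models = fit_null_models(inter_dmr_spacings(points))
        res = coloc_test(points, bers, genome, models["gamma"], n_rand=500, seed=2)
        assert res.min_q < 0.05
        assert res.d_star <= 2_000_000

    def test_null_draw_shows_no_significant_colocalization(self, genome, bers):
        model = NullModel("uniform", {"lower": 0, "upper": 1e6})
        rng = np.random.default_rng(8)
        points = randomize_dmr_locations(model, {"chr1": 20, "chr2": 20}, genome, rng)
        res = coloc_test(points, bers, genome, model, n_rand=300, seed=3)
        assert res.min_q > 0.05

    def test_curves_are_monotone_and_saturate_to_one(self, genome, bers):
        gen = np.random.default_rng(13)
        points = pd.DataFrame({
            "chrom": ["chr1"] * 20, "pos": gen.uniform(0, 6e7, 20)
        })
        models = fit_null_models(inter_dmr_spacings(points))
        grid = np.arange(0, 61e6, 1e6)  # beyond max possible distance
        res = coloc_test(points, bers, genome, models["gamma"], n_rand=200,
                         grid=grid, seed=4)
        assert (np.diff(res.observed_curve) >= 0).all()
        assert res.observed_curve[-1] == 1.0
        assert res.null_mean[-1] == pytest.approx(1.0)
        assert res.p_grid[-1] > 0.5  # saturated grid point is uninformative

    def test_uniform_null_is_less_stringent_than_gamma(self, genome, bers):
        """Stringency ordering on planted signal: p_uniform <= p_gamma at d*."""
        gen = np.random.default_rng(31)
        rows = []
        for _, b in bers.iterrows():
            for _ in range(8):
                rows.append((b["chrom"], b["center"] + gen.uniform(-5e5, 5e5)))
        points = pd.DataFrame(rows, columns=["chrom", "pos"])
        models = fit_null_models(inter_dmr_spacings(points))
        res_u = coloc_test(points, bers, genome, models["uniform"], n_rand=400, seed=5)
        res_g = coloc_test(points, bers, genome, models["gamma"], n_rand=400, seed=5)
        assert res_u.p_at_dstar <= res_g.p_at_dstar + 1e-12

    def test_doubling_randomizations_keeps_dstar(self, genome, bers):
        gen = np.random.default_rng(41)
        rows = []
        for _, b in bers.iterrows():
            for _ in range(8):
                rows.append((b["chrom"], b["center"] + gen.uniform(-4e5, 4e5)))
        points = pd.DataFrame(rows, columns=["chrom", "pos"])
        models = fit_null_models(inter_dmr_spacings(points))
        res1 = coloc_test(points, bers, genome, models["gamma"], n_rand=250, seed=6)
        res2 = coloc_test(points, bers, genome, models["gamma"], n_rand=500, seed=6)
        assert res1.d_star == res2.d_star

    def test_ranksum_mode_also_flags_planted_signal(self, genome, bers):
        gen = np.random.default_rng(51)
        rows = []
        for _, b in bers.iterrows():
            for _ in range(8):
                rows.append((b["chrom"], b["center"] + gen.uniform(-4e5, 4e5)))
        points = pd.DataFrame(rows, columns=["chrom", "pos"])
        models = fit_null_models(inter_dmr_spacings(points))
        res = coloc_test(points, bers, genome, models["gamma"], n_rand=150,
                         seed=7, mode="ranksum")
        assert res.min_q < 0.05


class TestCallBedmrs:
    def test_threshold_filtering(self):
        dmrs = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [4_100_000, 6_100_000],
            "end": [4_300_000, 6_300_000],
        })
        bers = ber_frame([5_000_000])
        out = call_bedmrs(dmrs, bers, threshold=1_000_000)
        # midpoints at 4.2 / 6.2 Mb -> distances 0.8 / 1.2 Mb
        assert len(out) == 1
        assert out.at[0, "start"] == 4_100_000
        assert out.at[0, "ber_center"] == 5_000_000
        assert out.at[0, "ber_distance"] == pytest.approx(800_000)

    def test_matches_brute_force_distance_filter(self, rng):
        dmrs = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 50),
            "start": rng.integers(0, int(1e7), 50),
        })
        dmrs["end"] = dmrs["start"] + 100_000
        bers = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 10),
            "center": rng.integers(0, int(1e7), 10),
        })
        out = call_bedmrs(dmrs, bers, threshold=1e6)
        expected = []
        for _, row in dmrs.iterrows():
            mid = (row["start"] + row["end"]) // 2
            same = bers[bers["chrom"] == row["chrom"]]
            if len(same) and np.min(np.abs(same["center"] - mid)) <= 1e6:
                expected.append((row["chrom"], row["start"]))
        assert sorted(expected) == sorted(zip(out["chrom"], out["start"]))

    def test_cumulative_curve_counts_fractions(self):
        d = np.array([0.0, 5e5, 2e6, np.inf])
        grid = np.array([0.0, 1e6, 3e6])
        np.testing.assert_allclose(cumulative_curve(d, grid), [1 / 3, 2 / 3, 1.0])
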
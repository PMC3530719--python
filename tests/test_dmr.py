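import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from bedmr import cnv
from bedmr.core import GenomeSpec, MethylCallSet
from bedmr.dmr import (
    Baseline,
    bh_fdr,
    call_dmrs,
    estimate_baseline,
    hotelling_test,
    scan_windows,
)


# ---------------------------------------------------------------- oracles

def gaussian_elimination_solve(A, b):
    """Plain partial-pivot Gaussian elimination, independent of numpy.linalg."""
    A = [list(map(float, row)) for row in A]
    b = list(map(float, b))
    n = len(b)
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(A[r][col]))
        A[col], A[piv] = A[piv], A[col]
        b[col], b[piv] = b[piv], b[col]
        for r in range(col + 1, n):
            f = A[r][col] / A[col][col]
            for c in range(col, n):
                A[r][c] -= f * A[col][c]
            b[r] -= f * b[col]
    x = [0.0] * n
    for r in range(n - 1, -1, -1):
        x[r] = (b[r] - sum(A[r][c] * x[c] for c in range(r + 1, n))) / A[r][r]
    return x


def brute_force_hotelling(X, mu0):
    """Explicit covariance loops + Gaussian elimination + F tail by quadrature."""
    n, p = len(X), 3
    mean = [sum(row[j] for row in X) / n for j in range(p)]
    S = [[0.0] * p for _ in range(p)]
    for row in X:
        for i in range(p):
            for j in range(p):
                S[i][j] += (row[i] - mean[i]) * (row[j] - mean[j])
    S = [[v / (n - 1) for v in row] for row in S]
    d = [mean[j] - mu0[j] for j in range(p)]
    x = gaussian_elimination_solve(S, d)
    T2 = n * sum(di * xi for di, xi in zip(d, x))
    F = (n - p) / (p * (n - 1)) * T2

    def f_pdf(t, d1, d2):
        c = (
            (d1 / d2) ** (d1 / 2)
            * t ** (d1 / 2 - 1)
            * (1 + d1 * t / d2) ** (-(d1 + d2) / 2)
            / special.beta(d1 / 2, d2 / 2)
        )
        return c

    p_val, _ = integrate.quad(f_pdf, F, np.inf, args=(p, n - p), limit=400,
                              epsabs=1e-13, epsrel=1e-11)
    return T2, F, p_val


def random_triplet_windows(rng, n_windows, n_range=(5, 20), lam=(9.0, 6.0, 4.0)):
    """Independent-Poisson triplets: components not collinear, S full rank."""
    windows = []
    for _ in range(n_windows):
        n = int(rng.integers(*n_range))
        windows.append(rng.poisson(lam, size=(n, 3)).astype(float))
    return windows


# ------------------------------------------------------------------ tests

class TestEstimateBaseline:
    def test_constant_fragments_give_zero_covariance(self):
        X = np.tile([30, 3, 7], (10, 1))
        base = estimate_baseline(X)
        np.testing.assert_array_equal(base.mu0, [30, 3, 7])
        np.testing.assert_array_equal(base.B, np.zeros((3, 3)))

    def test_hand_computed_two_group_covariance(self):
        # 5 copies each of (10,0,0) and (0,0,10): mean (5,0,5);
        # sum of squared deviations 10*25 = 250, divisor n-1 = 9
        X = np.array([[10, 0, 0]] * 5 + [[0, 0, 10]] * 5, dtype=float)
        base = estimate_baseline(X)
        np.testing.assert_allclose(base.mu0, [5, 0, 5])
        v = 250 / 9
        np.testing.assert_allclose(
            base.B, [[v, 0, -v], [0, 0, 0], [-v, 0, v]]
        )

    def test_multinomial_mean_within_three_standard_errors(self, rng):
        n_samples, probs = 40, np.array([0.25, 0.5, 0.25])
        X = rng.multinomial(n_samples, probs, size=4000).astype(float)
        base = estimate_baseline(X)
        se = np.sqrt(n_samples * probs * (1 - probs) / 4000)
        assert (np.abs(base.mu0 - n_samples * probs) < 3 * se).all()

    def test_too_few_fragments_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline(np.ones((3, 3)))


class TestHotellingTest:
    def test_window_at_baseline_mean_has_t2_zero_p_one(self):
        X = np.array([[9, 6, 5], [11, 6, 3], [10, 6, 4], [10, 6, 4]], dtype=float)
        base = Baseline(X.mean(axis=0), np.eye(3))
        res = hotelling_test(X, base)
        assert res.T2 == 0.0 and res.p == 1.0

    def test_matches_brute_force_linear_algebra_oracle(self, rng):
        """T2, F, p equal an explicit-elimination + quadrature computation."""
        mu0 = [9.0, 6.0, 4.0]
        base = Baseline(mu0, np.eye(3))
        for X in random_triplet_windows(rng, 100):
            if np.linalg.matrix_rank(np.cov(X.T, ddof=1)) < 3:
                continue  # oracle needs a nonsingular system
            res = hotelling_test(X, base)
            T2o, Fo, po = brute_force_hotelling(X.tolist(), mu0)
            assert res.rank == 3
            assert res.T2 == pytest.approx(T2o, rel=1e-8)
            assert res.F == pytest.approx(Fo, rel=1e-8)
            assert res.p == pytest.approx(po, rel=1e-8, abs=1e-12)

    def test_rank_deficient_complete_data_uses_effective_rank(self, rng):
        X = rng.multinomial(40, [0.25, 0.5, 0.25], size=10).astype(float)
        base = Baseline([10, 20, 10], np.eye(3))
        res = hotelling_test(X, base)
        assert res.rank == 2
        assert np.isfinite(res.p)

    def test_invariant_under_state_axis_permutation(self, rng):
        X = random_triplet_windows(rng, 1)[0]
        mu0 = np.array([9.0, 6.0, 4.0])
        base = Baseline(mu0, np.eye(3))
        perm = [2, 0, 1]
        res1 = hotelling_test(X, base)
        res2 = hotelling_test(X[:, perm], Baseline(mu0[perm], np.eye(3)))
        assert res1.T2 == pytest.approx(res2.T2, rel=1e-10)

    def test_t2_scales_linearly_in_n_for_fixed_moments(self):
        # duplicating the window doubles n while keeping mean and S nearly
        # fixed (covariance divisor changes); check the explicit formula
        X = np.array([[12, 5, 3], [8, 7, 5], [10, 6, 4], [11, 5, 4], [9, 7, 4]],
                     dtype=float)
        base = Baseline([9, 6, 5], np.eye(3))
        d = X.mean(axis=0) - base.mu0
        S = np.cov(X.T, ddof=1)
        for n_mult in (1, 2, 5):
            T2 = len(X) * n_mult * d @ np.linalg.pinv(S) @ d
            assert T2 == pytest.approx(n_mult * (len(X) * d @ np.linalg.pinv(S) @ d))

    def test_small_windows_rejected(self):
        base = Baseline([1, 1, 1], np.eye(3))
        with pytest.raises(ValueError):
            hotelling_test(np.ones((3, 3)), base)


class TestBhFdr:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_fdr([0.04]), [0.04])

    def test_hand_step_up_example(self):
        # q_i = min over j>=i of p_j * m / j -> all 0.04 here
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(0.001, 1, 50)
        perm = rng.permutation(50)
        q = bh_fdr(p)
        q_perm = bh_fdr(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


def build_callset_and_partition(rng, n_windows, frags_per_window, n_samples,
                                probs, planted=None, shift=None):
    """One chromosome; windows of 100 kb; fragments every 100kb/frags."""
    win_size = 100_000
    genome = GenomeSpec(("chr1",), (n_windows * win_size,))
    bps = pd.DataFrame(
        {"sample_id": "x", "chrom": "chr1",
         "pos": np.arange(1, n_windows) * win_size}
    )
    partition = cnv.partition_genome(bps, genome)
    spacing = win_size // frags_per_window
    mids = np.arange(spacing // 2, n_windows * win_size, spacing)
    frags = pd.DataFrame(
        {"fragment_id": [f"f{i}" for i in range(len(mids))],
         "chrom": "chr1", "start": mids - 10, "end": mids + 10}
    )
    calls_idx = rng.choice(3, p=probs, size=(len(mids), n_samples))
    if planted is not None:
        windows = mids // win_size
        mask = np.isin(windows, planted)
        calls_idx[mask] = rng.choice(3, p=shift, size=(int(mask.sum()), n_samples))
    calls = np.array([1.0, 0.0, -1.0])[calls_idx]
    cs = MethylCallSet(frags, [f"s{i}" for i in range(n_samples)], calls)
    return cs, partition


class TestWindowTesting:
    def test_null_pvalues_roughly_uniform_and_few_calls(self, rng):
        cs, part = build_callset_and_partition(
            rng, n_windows=400, frags_per_window=10, n_samples=40,
            probs=[0.25, 0.5, 0.25],
        )
        res = scan_windows(cs, part)
        assert len(res) == 400
        ks = stats.kstest(res["p"], "uniform").statistic
        assert ks < 0.08
        assert (res["q"] < 0.01).mean() <= 0.02

    def test_planted_windows_recovered_with_few_false_calls(self, rng):
        planted = np.arange(0, 200, 20)  # 10 of 200 windows
        cs, part = build_callset_and_partition(
            rng, n_windows=200, frags_per_window=10, n_samples=40,
            probs=[0.25, 0.5, 0.25], planted=planted, shift=[0.75, 0.075, 0.175],
        )
        res = scan_windows(cs, part)
        dmrs = call_dmrs(res, alpha=0.01)
        called = set(dmrs["window"])
        sens = len(called & set(planted)) / len(planted)
        false = len(called - set(planted)) / (200 - len(planted))
        assert sens >= 0.9
        assert false <= 0.01

    def test_direction_and_score_sign_convention(self, rng):
        """Hyper windows get +(-log10 p); hypo windows the negative."""
        planted = [2]
        cs, part = build_callset_and_partition(
            rng, n_windows=40, frags_per_window=10, n_samples=40,
            probs=[0.25, 0.5, 0.25], planted=planted, shift=[0.75, 0.075, 0.175],
        )
        res = scan_windows(cs, part)
        row = res[res["window"] == 2].iloc[0]
        assert row["direction"] == "hyper"
        assert row["score"] == pytest.approx(-np.log10(row["p"]))
        # hypo planting flips the sign
        cs2, part2 = build_callset_and_partition(
            rng, n_windows=40, frags_per_window=10, n_samples=40,
            probs=[0.25, 0.5, 0.25], planted=planted, shift=[0.175, 0.075, 0.75],
        )
        row2 = scan_windows(cs2, part2).query("window == 2").iloc[0]
        assert row2["direction"] == "hypo"
        assert row2["score"] == pytest.approx(np.log10(row2["p"]))
        assert row2["score"] < 0

    def test_sparse_windows_are_skipped(self, rng):
        cs, part = build_callset_and_partition(
            rng, n_windows=10, frags_per_window=2, n_samples=20,
            probs=[0.25, 0.5, 0.25],
        )
        res = scan_windows(cs, part)  # 2 fragments < min 4 everywhere
        assert len(res) == 0
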
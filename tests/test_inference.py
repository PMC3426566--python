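import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gtenet.errors import ConvergenceError
from gtenet.fluorescence import FluorescenceRecording
from gtenet.inference import (
    EstimatorSpec,
    conditioning_mask,
    differentiate,
    discretize,
    gc_score,
    gte_score,
    mi_score,
    population_average,
    rank_and_threshold,
    score_matrix,
    select_conditioning_level,
    xc_score,
)


from _oracles import standard_te_oracle


class TestPreprocessing:
    def test_differentiate_constant_and_ramp(self):
        f = np.tile(np.arange(10.0)[:, None] * 0.3, (1, 2))
        x = differentiate(FluorescenceRecording(f, 0.02))
        assert x.shape == (9, 2)
        assert np.allclose(x, 0.3)
        assert np.allclose(differentiate(np.ones((5, 3))), 0.0)

    def test_differentiate_matches_manual(self, rng):
        f = rng.random((50, 4))
        assert np.allclose(differentiate(f), f[1:] - f[:-1])

    def test_population_average(self, rng):
        f = rng.random((20, 5))
        g = population_average(FluorescenceRecording(f, 0.02))
        assert g.shape == (20,)
        assert np.allclose(g, f.mean(1))
        same = np.tile(f[:, :1], (1, 5))
        assert np.allclose(population_average(same), f[:, 0])


class TestConditioning:
    def test_all_true_when_unbounded(self, rng):
        g = rng.random(100)
        assert conditioning_mask(g).all()

    def test_hand_checked_threshold(self):
        g = np.array([0.1, 0.5, 0.3, 0.9])
        assert np.array_equal(conditioning_mask(g, 0.2, 0.6),
                              [False, True, True, False])

    def test_seven_ranges_partition_exactly(self, rng):
        from gtenet.evaluation import state_ranges

        g = rng.random(5000)
        ranges = state_ranges(g, 7)
        counts = sum(int(conditioning_mask(g, lo, hi).sum()) for lo, hi in ranges)
        assert counts == g.size

    def test_gaussian_level_is_mu_plus_2sd(self, rng):
        g = rng.normal(0.2, 0.05, 200_000)
        level = select_conditioning_level(g)
        assert level == pytest.approx(0.2 + 2 * 0.05, abs=0.01)

    def test_mixture_fits_left_component(self, rng):
        body = rng.normal(0.1, 0.02, 80_000)
        tail = rng.uniform(0.2, 1.0, 8_000)
        level = select_conditioning_level(np.concatenate([body, tail]))
        assert level == pytest.approx(0.14, abs=0.02)

    def test_monotone_distribution_raises(self):
        g = np.linspace(1.0, 0.0, 1000) ** 3  # histogram peaks at the last bin
        with pytest.raises(ConvergenceError):
            select_conditioning_level(np.sort(g)[::-1] * -1 + 1.0)


class TestDiscretize:
    def test_constant_signal(self):
        assert np.all(discretize(np.ones(10), 3) == 0)

    def test_hand_enumerated_binning(self):
        x = np.array([0.0, 0.5, 1.0])
        assert np.array_equal(discretize(x, 2), [0, 1, 1])
        assert np.array_equal(discretize(x, 3), [0, 1, 2])

    def test_outliers_clip_into_boundary_bins(self):
        x = np.array([-5.0, 0.0, 0.5, 1.0, 7.0])
        sym = discretize(x, 3, edges_from=np.array([0.0, 1.0]))
        assert np.array_equal(sym, [0, 0, 1, 2, 2])

    def test_bin_width_near_twice_signal_sd(self, bursting_recording):
        # with b=3 levels over the conditioned range, the bin width is
        # comparable to twice the standard deviation of the signal
        _, _, rec = bursting_recording
        x = differentiate(rec)[:, 0]
        width = (x.max() - x.min()) / 3
        assert 0.5 * 2 * x.std() < width < 3.0 * 2 * x.std()


class TestTransferEntropy:
    def test_binary_chain_one_bit(self, rng):
        n = 100_000
        x = rng.integers(0, 2, n).astype(float)
        y = np.roll(x, 1)
        spec = EstimatorSpec(order=1, same_bin=False, bins=2)
        assert gte_score(y, x, spec) == pytest.approx(1.0, abs=0.02)
        assert gte_score(x, y, spec) < 0.01

    def test_same_bin_detects_zero_lag_coupling(self, rng):
        x = rng.integers(0, 2, 50_000).astype(float)
        off = EstimatorSpec(order=1, same_bin=False, bins=2)
        on = EstimatorSpec(order=1, same_bin=True, bins=2)
        assert gte_score(x, x, off) < 0.01
        assert gte_score(x, x, on) > 0.5

    def test_independence_below_shuffle_band(self, rng):
        n = 100_000
        x = rng.integers(0, 3, n).astype(float)
        z = rng.integers(0, 3, n).astype(float)
        spec = EstimatorSpec(order=1, same_bin=False, bins=3)
        obs = gte_score(z, x, spec)
        null = [gte_score(z, np.roll(x, rng.integers(100, n - 100)), spec)
                for _ in range(30)]
        assert obs < np.quantile(null, 0.95) + 1e-4

    def test_reduces_to_standard_te(self, rng):
        # same-bin off + unbounded conditioning == conventional TE
        for k in (1, 2):
            y = rng.random(4000)
            x = np.roll(y, 1) + 0.5 * rng.random(4000)
            spec = EstimatorSpec(order=k, same_bin=False, bins=3)
            assert gte_score(y, x, spec) == pytest.approx(
                standard_te_oracle(y, x, k, 3), abs=1e-12)

    def test_plugin_converges_at_sqrt_n(self, rng):
        # plug-in estimate of the 1-bit chain approaches the enumerated
        # truth roughly as 1/sqrt(n)
        errs = []
        for n in (10**3, 10**4, 10**5):
            x = rng.integers(0, 2, n).astype(float)
            y = np.roll(x, 1)
            spec = EstimatorSpec(order=1, same_bin=False, bins=2)
            errs.append(abs(gte_score(y, x, spec) - 1.0))
        assert errs[2] < errs[0]
        assert errs[2] < 0.02

    def test_conditioning_above_max_is_noop(self, rng):
        y = rng.random(3000)
        x = rng.random(3000)
        m = conditioning_mask(np.full(3000, 0.5), g_high=10.0)
        spec = EstimatorSpec(order=2, same_bin=True, bins=3)
        assert gte_score(y, x, spec, m) == gte_score(y, x, spec)

    def test_affine_invariance(self, rng):
        y = rng.random(5000)
        x = np.roll(y, 1)
        spec = EstimatorSpec(order=1, same_bin=False, bins=3)
        assert gte_score(3.0 * y + 1.0, -2.0 * x + 0.5, spec) == pytest.approx(
            gte_score(y, x, spec), abs=1e-12)


class TestCompetitors:
    def test_mi_identical_streams_equals_entropy(self, rng):
        x = rng.integers(0, 2, 100_000).astype(float)
        spec = EstimatorSpec(method="mi", bins=2)
        assert mi_score(x, x, spec) == pytest.approx(1.0, abs=0.01)

    def test_mi_known_joint_table(self):
        # hand-computed MI of the exact empirical 2x2 joint table over the
        # retained samples (the first `order` frames are excluded)
        a = np.array([0, 0, 0, 0, 1, 1, 1, 1, 0, 1], float)
        b = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 0], float)
        spec = EstimatorSpec(method="mi", bins=2)
        joint = np.zeros((2, 2))
        for ai, bi in zip(a[spec.order:], b[spec.order:]):
            joint[int(ai), int(bi)] += 1
        p = joint / joint.sum()
        expect = sum(
            p[i, j] * np.log2(p[i, j] / (p[i].sum() * p[:, j].sum()))
            for i in range(2) for j in range(2) if p[i, j] > 0
        )
        assert mi_score(a, b, spec) == pytest.approx(expect, abs=1e-12)

    def test_mi_symmetric_and_nonnegative(self, rng):
        x, y = rng.random(5000), rng.random(5000)
        spec = EstimatorSpec(method="mi", bins=3)
        assert mi_score(x, y, spec) == pytest.approx(mi_score(y, x, spec), abs=1e-12)
        assert mi_score(x, y, spec) >= -1e-12

    def test_xc_identical_and_shifted(self, rng):
        s = rng.normal(size=20_000)
        assert xc_score(s, s) == pytest.approx(1.0, abs=1e-9)
        assert xc_score(np.roll(s, 1), s, EstimatorSpec(xc_lags=2)) == pytest.approx(1.0, abs=1e-6)

    def test_xc_brute_force_correlogram(self, rng):
        # AR(1) pair with known coupling vs a direct correlogram oracle
        n = 20_000
        e = rng.normal(size=n)
        x = np.zeros(n)
        for t in range(1, n):
            x[t] = 0.5 * x[t - 1] + e[t]
        y = 0.7 * np.roll(x, 1) + 0.3 * rng.normal(size=n)
        L = 3
        best = -np.inf
        for lag in range(-L, L + 1):
            t0, t1 = max(0, lag), n + min(0, lag)
            best = max(best, np.corrcoef(y[t0:t1], x[t0 - lag:t1 - lag])[0, 1])
        assert xc_score(y, x, EstimatorSpec(xc_lags=L)) == pytest.approx(best, abs=1e-9)

    def test_gc_white_noise_near_zero(self, rng):
        x, y = rng.normal(size=50_000), rng.normal(size=50_000)
        assert gc_score(y, x, EstimatorSpec(method="gc", order=1, same_bin=False)) < 1e-3

    def test_gc_matches_regression_oracle(self, rng):
        import statsmodels.api as sm_api

        n = 30_000
        x = rng.normal(size=n)
        y = 0.8 * np.roll(x, 1) + 0.5 * rng.normal(size=n)
        spec = EstimatorSpec(method="gc", order=1, same_bin=False)
        got = gc_score(y, x, spec)
        Y = y[1:]
        X_uni = sm_api.add_constant(y[:-1])
        X_biv = sm_api.add_constant(np.column_stack([y[:-1], x[:-1]]))
        r_uni = sm_api.OLS(Y, X_uni).fit().resid
        r_biv = sm_api.OLS(Y, X_biv).fit().resid
        expect = np.log((r_uni**2).mean() / (r_biv**2).mean())
        assert got == pytest.approx(expect, abs=1e-10)

    def test_gc_order_nesting_on_ar1(self, rng):
        n = 50_000
        x = rng.normal(size=n)
        y = 0.8 * np.roll(x, 1) + 0.5 * rng.normal(size=n)
        g1 = gc_score(y, x, EstimatorSpec(method="gc", order=1, same_bin=False))
        g2 = gc_score(y, x, EstimatorSpec(method="gc", order=2, same_bin=False))
        assert g2 == pytest.approx(g1, abs=0.01)


class TestScoreMatrix:
    @pytest.fixture(scope="class")
    def toy_rec(self):
        rng = np.random.default_rng(5)
        f = np.cumsum(rng.normal(0, 0.05, (3000, 3)), axis=0)
        f[2:, 1] += 0.8 * np.diff(f[:, 0])[:-1]  # 0 drives 1 with lag
        return FluorescenceRecording(f, 0.02)

    @pytest.mark.parametrize("method", ["te", "mi", "xc", "gc"])
    def test_matches_per_pair_calls(self, toy_rec, method):
        spec = EstimatorSpec(method=method, order=2, bins=3, cond_high=np.inf)
        sm = score_matrix(toy_rec, spec)
        from gtenet.inference import _prepare

        x, m = _prepare(toy_rec, spec)
        pair_fn = {"te": gte_score, "mi": mi_score, "xc": xc_score, "gc": gc_score}[method]
        for i in range(3):
            for j in range(3):
                if i == j:
                    assert np.isnan(sm.values[i, j])
                    continue
                # values[source, target]
                expect = pair_fn(x[:, j], x[:, i], spec, m)
                assert sm.values[i, j] == pytest.approx(expect, abs=1e-10)

    def test_deterministic(self, toy_rec):
        a = score_matrix(toy_rec, EstimatorSpec())
        b = score_matrix(toy_rec, EstimatorSpec())
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_neuron_permutation_equivariance(self, toy_rec):
        spec = EstimatorSpec(cond_high=np.inf)
        sm = score_matrix(toy_rec, spec)
        perm = [2, 0, 1]
        rec_p = FluorescenceRecording(toy_rec.data[:, perm], toy_rec.frame_interval)
        sm_p = score_matrix(rec_p, spec)
        expect = sm.values[np.ix_(perm, perm)]
        assert np.allclose(sm_p.values, expect, equal_nan=True)


class TestRankAndThreshold:
    def test_fraction_one_is_complete_offdiagonal(self, rng):
        from gtenet.inference import ScoreMatrix

        vals = rng.random((5, 5))
        np.fill_diagonal(vals, np.nan)
        sm = ScoreMatrix(vals, EstimatorSpec(), 100)
        net = rank_and_threshold(sm, 1.0)
        assert net.n_links == 20

    def test_top_fraction_link_budget(self, rng):
        from gtenet.inference import ScoreMatrix

        vals = rng.random((100, 100))
        np.fill_diagonal(vals, np.nan)
        sm = ScoreMatrix(vals, EstimatorSpec(), 100)
        assert rank_and_threshold(sm, 0.10).n_links == 990

    def test_tie_break_lexical(self):
        from gtenet.inference import ScoreMatrix

        vals = np.ones((3, 3))
        np.fill_diagonal(vals, np.nan)
        sm = ScoreMatrix(vals, EstimatorSpec(), 10)
        net = rank_and_threshold(sm, 2 / 6)
        # all scores tie: the first two links in (source, target) order win
        assert net.adjacency[0, 1] and net.adjacency[0, 2]
        assert net.n_links == 2

    def test_invalid_fraction(self, rng):
        from gtenet.inference import ScoreMatrix

        vals = rng.random((4, 4))
        sm = ScoreMatrix(vals, EstimatorSpec(), 5)
        with pytest.raises(ValueError):
            rank_and_threshold(sm, 0.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=4), st.integers(min_value=0, max_value=10**6))
def test_te_nonnegative_and_affine_invariant(bins, seed):
    """Plug-in TE is non-negative and blind to affine signal rescaling."""
    rng = np.random.default_rng(seed)
    y = rng.random(800)
    x = rng.random(800)
    spec = EstimatorSpec(order=1, same_bin=True, bins=bins)
    te = gte_score(y, x, spec)
    assert te >= -1e-12
    assert gte_score(2.5 * y - 1.0, -0.5 * x + 3.0, spec) == pytest.approx(te, abs=1e-12)
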
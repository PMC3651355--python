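import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ironnorm import (
    ChipLayout,
    FitCurve,
    NormalizationError,
    PipelineConfig,
    SimSpec,
    apply_fit_curve,
    build_fit_curve,
    build_training_set,
    density_weights,
    fit_correction,
    iterative_rank_prune,
    median_scale_pair,
    normalize_pair,
    simulate_chip_set,
)

from conftest import random_chip


class TestBuildTrainingSet:
    CFG = PipelineConfig(min_training_size=3)

    def test_all_minimum_ties_excluded(self):
        sample = np.array([5.0, 5.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0])
        reference = np.linspace(100, 800, 8)
        idx = build_training_set(sample, reference, config=self.CFG)
        # the three probes tied at the sample minimum go, as do each chip's max
        assert 0 not in idx and 1 not in idx and 2 not in idx
        assert 7 not in idx  # max on both chips

    def test_saturated_probe_excluded(self):
        sample = np.array([10.0, 65_000.0, 30.0, 40.0, 50.0, 60.0])
        reference = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        idx = build_training_set(sample, reference, config=self.CFG)
        assert 1 not in idx  # above the 64 000 saturation threshold

    def test_layout_rules(self):
        ids = [f"p{i}" for i in range(8)]
        layout = ChipLayout(
            probe_to_probeset={p: "A" for p in ids[:7]},  # p7 unassigned
            masked={"p1"},
        )
        sample = np.arange(10.0, 90.0, 10.0)
        reference = np.arange(11.0, 91.0, 10.0)
        idx = build_training_set(
            sample, reference, layout=layout, config=self.CFG, feature_ids=ids
        )
        assert 1 not in idx  # masked
        assert 7 not in idx  # not part of any probeset
        assert {2, 3, 4, 5} <= set(idx)

    def test_no_layout_only_intensity_rules(self):
        sample = np.linspace(10, 100, 10)
        reference = np.linspace(10, 100, 10)
        idx = build_training_set(sample, reference, config=self.CFG)
        np.testing.assert_array_equal(idx, np.arange(1, 9))

    def test_too_few_survivors_error(self):
        with pytest.raises(NormalizationError, match="candidate"):
            build_training_set(
                np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]),
                config=PipelineConfig(min_training_size=5),
            )


class TestIterativeRankPrune:
    CFG = PipelineConfig(min_training_size=10)

    def test_rank_preserving_map_converges_immediately(self, rng):
        x = np.sort(rng.normal(10, 2, 500))
        y = x**3 + 5.0  # strictly increasing transform: identical ranks
        ts = iterative_rank_prune(x, y, self.CFG)
        assert ts.converged
        assert ts.iteration_sizes == [500]
        assert ts.size == 500

    def test_adjacent_swap_within_tolerance(self, rng):
        """Two adjacent-ranked points swapped in a 200-point set give a max
        rank difference of exactly 0.5% — inside the 1% convergence band."""
        x = np.sort(rng.uniform(1, 100, 200))
        y = x.copy()
        y[[10, 11]] = y[[11, 10]]
        ts = iterative_rank_prune(x, y, self.CFG)
        assert ts.converged and ts.size == 200 and ts.n_iterations == 0

    def test_upshifted_arm_pruned(self, rng):
        """A strongly up-shifted minority arm is almost entirely removed."""
        n, n_arm = 10_000, 3_000
        x = rng.normal(10, 2.5, n + n_arm)
        y = x + rng.normal(0, 0.05, n + n_arm)
        arm = np.zeros(n + n_arm, bool)
        arm[rng.permutation(n + n_arm)[:n_arm]] = True
        y[arm] += rng.uniform(1.0, 3.0, n_arm)
        ts = iterative_rank_prune(x, y, self.CFG)
        assert ts.converged
        surviving_arm = arm[ts.indices].sum()
        assert surviving_arm / n_arm < 0.05

    def test_sizes_strictly_decrease_and_terminates(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(0, 1, 800)
            y = 0.6 * x + r.normal(0, 0.8, 800)
            ts = iterative_rank_prune(x, y, self.CFG)
            sizes = ts.iteration_sizes
            assert all(a > b for a, b in zip(sizes, sizes[1:]))
            assert ts.converged
            # final max rank difference really is within tolerance
            from scipy.stats import rankdata
            pct = np.abs(rankdata(ts.x) - rankdata(ts.y)) / ts.size * 100
            assert pct.max() <= 1.0

    def test_shrink_below_minimum_error_with_trajectory(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 1, 40)  # unrelated: heavy pruning expected
        with pytest.raises(NormalizationError) as err:
            iterative_rank_prune(x, y, PipelineConfig(min_training_size=35))
        assert err.value.trajectory  # trajectory attached


def brute_density_weights(a, frac, exponent):
    """Nested-loop oracle: sample std of every window, mean over windows
    containing each point, raised to the exponent."""
    n = len(a)
    w = max(2, round(frac * n))
    stds = [np.std(a[i:i + w], ddof=1) for i in range(n - w + 1)]
    out = np.empty(n)
    for j in range(n):
        mine = [stds[i] for i in range(n - w + 1) if i <= j <= i + w - 1]
        out[j] = np.mean(mine) ** exponent
    return out


class TestDensityWeights:
    def test_equally_spaced_uniform(self):
        a = np.linspace(0, 10, 300)
        w = density_weights(a, PipelineConfig())
        np.testing.assert_allclose(w, w[0], rtol=1e-9)

    def test_isolated_point_up_weighted(self):
        a = np.sort(np.concatenate([np.linspace(0, 1, 199), [8.0]]))
        w = density_weights(a, PipelineConfig())
        assert w[-1] > np.median(w[:-1])

    def test_matches_brute_force(self, rng):
        a = np.sort(rng.normal(0, 3, 500))
        cfg = PipelineConfig()
        got = density_weights(a, cfg)
        want = brute_density_weights(a, cfg.window_frac_sigma, cfg.weight_exponent)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_constant_input_uniform_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            w = density_weights(np.full(50, 3.0), PipelineConfig())
        np.testing.assert_array_equal(w, np.ones(50))
        assert "uniform" in caplog.text

    def test_unsorted_rejected(self):
        with pytest.raises(NormalizationError, match="ascending"):
            density_weights(np.array([3.0, 1.0, 2.0]), PipelineConfig())


def brute_fit_correction(x, y, weights, frac):
    """All-windows oracle using numpy's weighted polyfit per window."""
    n = len(x)
    w2 = max(3, round(frac * n))
    a, m = x + y, x - y
    lines = []
    for i in range(n - w2 + 1):
        sl = slice(i, i + w2)
        if np.ptp(a[sl]) == 0 or weights[sl].sum() == 0:
            slope, offset = 0.0, np.average(m[sl], weights=weights[sl])
        else:
            # polyfit weights are sqrt of WLS weights
            slope, offset = np.polyfit(a[sl], m[sl], 1, w=np.sqrt(weights[sl]))
        lines.append((slope, offset))
    out = np.empty(n)
    for j in range(n):
        mine = [lines[i] for i in range(n - w2 + 1) if i <= j <= i + w2 - 1]
        sbar = np.mean([s for s, _ in mine])
        obar = np.mean([o for _, o in mine])
        out[j] = sbar * a[j] + obar
    return out


class TestFitCorrection:
    CFG = PipelineConfig()

    def _sorted_pair(self, rng, n):
        a = np.sort(rng.normal(20, 4, n))
        m = 0.1 * a - 1.5 + rng.normal(0, 0.2, n)
        x = (a + m) / 2
        y = (a - m) / 2
        return x, y

    def test_zero_ratio_fits_zero(self, rng):
        y = np.sort(rng.uniform(4, 12, 300))
        fitted = fit_correction(y, y, np.ones(300), self.CFG)
        np.testing.assert_allclose(fitted, 0.0, atol=1e-12)

    def test_constant_ratio_fits_constant(self, rng):
        x = np.sort(rng.uniform(4, 12, 300))
        y = x - 2.5  # M = 2.5 everywhere
        w = density_weights(x + y, self.CFG)
        fitted = fit_correction(x, y, w, self.CFG)
        np.testing.assert_allclose(fitted, 2.5, rtol=1e-9)

    def test_linear_trend_recovered_and_matches_oracle(self, rng):
        x, y = self._sorted_pair(rng, 1000)
        w = density_weights(x + y, self.CFG)
        fitted = fit_correction(x, y, w, self.CFG)
        want = brute_fit_correction(x, y, w, self.CFG.window_frac_fit)
        np.testing.assert_allclose(fitted, want, atol=1e-10)
        # recovers the generating line within the noise scale
        resid = fitted - (0.1 * (x + y) - 1.5)
        assert np.abs(np.median(resid)) < 0.05


class TestBuildFitCurve:
    CFG = PipelineConfig()

    def test_perfect_fit_keeps_training_points(self, rng):
        x = np.sort(rng.uniform(4, 12, 100))
        y = x - 1.0
        fitted = x - y  # fitted == observed M → d == 0
        curve = build_fit_curve(x, y, fitted, self.CFG)
        np.testing.assert_allclose(curve.y_proj, y, atol=1e-12)
        np.testing.assert_allclose(curve.x_proj, x, atol=1e-12)

    def test_algebraic_identities(self, rng):
        x = np.sort(rng.uniform(4, 12, 200))
        y = x + rng.normal(0, 0.5, 200)
        fitted = rng.normal(0, 0.3, 200)
        curve = build_fit_curve(x, y, fitted, self.CFG)
        np.testing.assert_allclose(
            curve.x_proj - curve.y_proj, curve.correction, atol=1e-12
        )
        # A coordinate preserved by projection (no merged duplicates here)
        np.testing.assert_allclose(
            np.sort(curve.x_proj + curve.y_proj), np.sort(x + y), atol=1e-10
        )
        assert np.all(np.diff(curve.y_proj) > 0)

    def test_duplicate_y_proj_merged_by_mean(self):
        # engineered so both points project onto y_proj = 4.95:
        # y_proj = y − (fitted − (x − y))/2 gives 4.95 for both rows
        x = np.array([5.0, 5.0])
        y = np.array([5.1, 5.3])
        fitted = np.array([0.2, 0.4])
        d = fitted - (x - y)
        assert (y - d / 2)[0] == (y - d / 2)[1] == 4.95
        curve = build_fit_curve(x, y, fitted, self.CFG)
        assert curve.n_points == 1
        assert curve.correction[0] == pytest.approx(0.3)  # mean of 0.2 and 0.4

    def test_head_tail_corrections(self, rng):
        x = np.sort(rng.uniform(4, 12, 50))
        y = x.copy()
        fitted = np.linspace(0, 1, 50)
        curve = build_fit_curve(x, y, fitted, PipelineConfig(extrapolation_points=10))
        order = np.argsort(y - (fitted - (x - y)) / 2)
        assert curve.head_correction == pytest.approx(fitted[order][:10].mean())
        assert curve.tail_correction == pytest.approx(fitted[order][-10:].mean())


class TestApplyFitCurve:
    CFG = PipelineConfig()

    def _curve(self, y_proj, corr, k=10):
        y_proj = np.asarray(y_proj, float)
        corr = np.asarray(corr, float)
        kk = min(k, len(corr))
        return FitCurve(
            y_proj=y_proj, x_proj=y_proj + corr, correction=corr,
            head_correction=float(corr[:kk].mean()),
            tail_correction=float(corr[-kk:].mean()),
        )

    def test_zero_corrections_identity(self, rng):
        v = random_chip(rng, 500)
        curve = self._curve(np.linspace(0, 20, 30), np.zeros(30))
        np.testing.assert_allclose(apply_fit_curve(v, curve, self.CFG), v, rtol=1e-12)

    def test_unit_log2_correction_doubles(self, rng):
        v = random_chip(rng, 500)
        curve = self._curve(np.linspace(0, 20, 30), np.ones(30))
        np.testing.assert_allclose(apply_fit_curve(v, curve, self.CFG), 2 * v, rtol=1e-12)

    def test_out_of_range_uses_terminal_means(self):
        corr = np.linspace(0.0, 2.9, 30)
        curve = self._curve(np.linspace(10, 15, 30), corr)
        low = apply_fit_curve(np.array([2.0**5]), curve, self.CFG)  # log2=5 < 10
        high = apply_fit_curve(np.array([2.0**18]), curve, self.CFG)  # log2=18 > 15
        assert low[0] == pytest.approx(2.0 ** (5 + corr[:10].mean()))
        assert high[0] == pytest.approx(2.0 ** (18 + corr[-10:].mean()))

    def test_interior_mapping_continuous(self):
        """y → y + c(y) is continuous across fit points (linear interpolation)."""
        rng = np.random.default_rng(0)
        yp = np.sort(rng.uniform(5, 15, 40))
        curve = self._curve(yp, rng.normal(0, 0.5, 40))
        eps = 1e-9
        for knot in yp[1:-1]:
            lo = apply_fit_curve(np.array([2.0 ** (knot - eps)]), curve, self.CFG)
            hi = apply_fit_curve(np.array([2.0 ** (knot + eps)]), curve, self.CFG)
            assert np.log2(hi / lo) == pytest.approx(0.0, abs=1e-6)

    def test_single_point_curve_rejected(self):
        curve = self._curve([5.0], [0.1])
        with pytest.raises(NormalizationError, match="2 points"):
            apply_fit_curve(np.array([10.0]), curve, self.CFG)


class TestNormalizePair:
    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_self_normalization_identity(self, seed):
        """normalize_pair(v, v) returns v within 1e−9 relative for any chip."""
        v = random_chip(np.random.default_rng(seed), 2000)
        norm, _, _, _ = normalize_pair(v, v)
        np.testing.assert_allclose(norm, v, rtol=1e-9)

    def test_reference_never_modified(self, rng):
        ref = random_chip(rng, 2000)
        sam = ref * 1.7
        ref_copy = ref.copy()
        normalize_pair(sam, ref)
        np.testing.assert_array_equal(ref, ref_copy)

    def test_constant_gain_recovered(self, rng):
        ref = random_chip(rng, 10_000)
        norm, curve, _, _ = normalize_pair(2.0 * ref, ref)
        assert np.median(np.abs(np.log2(norm / ref))) < 0.01
        np.testing.assert_allclose(curve.correction, -1.0, atol=1e-6)

    def test_pair_independence(self, rng):
        """The result depends only on the two vectors and the config."""
        ref = random_chip(rng, 3000)
        sam = ref * np.power(2.0, rng.normal(0, 0.1, 3000))
        a, _, _, _ = normalize_pair(sam, ref)
        b, _, _, _ = normalize_pair(sam, ref)
        np.testing.assert_array_equal(a, b)

    def test_warp_plus_arm_recovery(self):
        """Smooth monotone warp + 30% up-arm: non-arm residuals shrink ≥ 10×."""
        spec = SimSpec(
            n_probes=10_000, n_probesets=2_000, n_chips=2, seed=5,
            arm_fraction=0.30,
            distortion=[
                ("identity", {}),
                ("smooth_spline_warp", {"anchors": [
                    (2.0, 3.0), (64.0, 110.0), (1024.0, 1400.0),
                    (16_384.0, 11_000.0), (262_144.0, 350_000.0)]}),
            ],
        )
        matrix, layout, truth = simulate_chip_set(spec)
        ref, sam = matrix.values[:, 0], matrix.values[:, 1]
        arm = truth["probes"]["arm"].to_numpy()
        norm, _, _, _ = normalize_pair(
            sam, ref, layout=layout, feature_ids=matrix.feature_ids
        )
        pre = np.median(np.abs(np.log2(sam / ref))[~arm])
        post = np.median(np.abs(np.log2(norm / ref))[~arm])
        assert post < 0.10 * pre

    def test_stage_errors_are_labeled(self, rng):
        ref = random_chip(rng, 50)
        with pytest.raises(NormalizationError, match="training-set stage"):
            normalize_pair(ref, ref)  # below default min_training_size


class TestMedianScaleBaseline:
    def test_matches_global_median_ratio(self, rng):
        ref = random_chip(rng, 1000)
        sam = ref / 4.0
        np.testing.assert_allclose(median_scale_pair(sam, ref), ref, rtol=1e-9)
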
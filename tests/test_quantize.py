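"""PMF estimation and Lloyd-Max / fixed-binning quantizer correctness.

Closed-form oracles: for a uniform source on [a,b] the optimal N-level
quantizer has equal cells and MSE (b-a)^2/(12 N^2); for a standard normal
source at N=2 the representation points are +/- sqrt(2/pi) with
MSE 1 - 2/pi.  The exhaustive-partition oracle in oracles.py provides exact
global optima on small discrete PMFs.
"""

import numpy as np
import pytest
from scipy import stats

from forcequant import (
    Histogram,
    Quantizer,
    apply_quantizer,
    estimate_pmf,
    fixed_binning_fit,
    lloyd_fit,
    lloyd_fit_samples,
    normal_reference_width,
    quantizer_distortion,
)
from forcequant.scenarios import fit_quantizers
from forcequant.synthetic import daylight_mask

from .oracles import optimal_partition_distortion


class TestNormalReferenceWidth:
    @pytest.mark.parametrize("sigma, n, expected_rounded", [
        (1.7032, 9600, 0.3),   # wind speed
        (0.6029, 9600, 0.1),   # vapour pressure deficit
    ])
    def test_reference_rule_widths(self, sigma, n, expected_rounded):
        w = normal_reference_width(sigma, n)
        assert w == pytest.approx(3.5 * sigma * n ** (-1 / 3), rel=1e-12)
        assert round(w, 1) == expected_rounded

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            normal_reference_width(0.0, 100)
        with pytest.raises(ValueError):
            normal_reference_width(1.0, 1)


class TestEstimatePmf:
    def test_hand_count_with_outlier(self):
        # origin 0.5, width 1: bins [0.5,1.5) ... [4.5,5.5) covering 1..5
        h = estimate_pmf(np.array([1.0, 1.0, 1.0, 5.0]), 1.0, origin=0.5)
        np.testing.assert_allclose(h.masses, [0.75, 0, 0, 0, 0.25])
        assert h.n == 4

    def test_hand_count_eight_values(self):
        data = np.array([0.1, 0.4, 1.2, 1.4, 1.6, 2.2, 2.6, 2.9])
        h = estimate_pmf(data, 1.0, origin=0.0)
        np.testing.assert_array_equal(h.counts, [2, 3, 3])

    def test_density_normalizes(self, rng):
        data = rng.normal(size=500)
        h = estimate_pmf(data, 0.25)
        assert h.masses.sum() == pytest.approx(1.0, abs=1e-12)
        assert (h.density * h.bin_width).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_masked_is_error(self):
        with pytest.raises(ValueError):
            estimate_pmf(np.arange(5.0), 1.0, mask=np.zeros(5, bool))


def _uniform_pmf(n_bins=2000):
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return Histogram(edges, np.ones(n_bins))


def _normal_pmf(n_bins=4000, span=5.0):
    edges = np.linspace(-span, span, n_bins + 1)
    counts = np.diff(stats.norm.cdf(edges))
    return Histogram(edges, counts / counts.sum() * 1e9)


class TestLloydClosedForms:
    def test_uniform_two_levels(self):
        q = lloyd_fit(_uniform_pmf(), 2)
        assert q.converged
        np.testing.assert_allclose(q.points, [0.25, 0.75], atol=1e-3)
        assert q.thresholds[1] == pytest.approx(0.5, abs=1e-3)
        assert q.distortion == pytest.approx(1 / 48, abs=1e-4)

    @pytest.mark.parametrize("n_levels", [2, 3, 4])
    def test_uniform_mse_scales_inverse_square(self, n_levels):
        q = lloyd_fit(_uniform_pmf(), n_levels)
        assert q.distortion == pytest.approx(1 / (12 * n_levels**2), rel=2e-3)

    def test_standard_normal_two_levels(self):
        q = lloyd_fit(_normal_pmf(), 2)
        root = np.sqrt(2 / np.pi)
        np.testing.assert_allclose(q.points, [-root, root], atol=2e-3)
        assert q.distortion == pytest.approx(1 - 2 / np.pi, abs=1e-3)

    def test_single_level_is_mean_and_variance(self):
        pmf = estimate_pmf(np.array([1.0, 2.0, 4.0, 4.0]), 0.5)
        q = lloyd_fit(pmf, 1)
        assert q.points[0] == pytest.approx(pmf.mean)
        assert q.distortion == pytest.approx(pmf.variance)


class TestWorkedTemperatureExample:
    """The two-level air-temperature example: converged representation points
    20.5 and 26.7 degC imply the final decision threshold 23.6 degC."""

    def test_midpoint_threshold_from_converged_points(self):
        # equal mass at the two representation points: Lloyd returns them as
        # conditional means and places the threshold at their midpoint
        edges = np.array([20.45, 20.55, 26.65, 26.75])
        pmf = Histogram(edges, np.array([50.0, 0.0, 50.0]))
        q = lloyd_fit(pmf, 2)
        np.testing.assert_allclose(q.points, [20.5, 26.7], atol=1e-9)
        assert q.thresholds[1] == pytest.approx((20.5 + 26.7) / 2, abs=1e-9)
        assert q.thresholds[1] == pytest.approx(23.6, abs=1e-9)

    def test_application_of_printed_quantizer(self):
        q = Quantizer(np.array([11.8, 23.6, 33.0]), np.array([20.5, 26.7]))
        assert q.quantize(np.array([22.0]))[0] == 20.5     # 22.0 <= 23.6
        assert q.quantize(np.array([23.6]))[0] == 20.5     # boundary joins lower cell
        assert q.quantize(np.array([23.7]))[0] == 26.7
        assert q.quantize(np.array([5.0]))[0] == 20.5      # clamps below T0
        assert q.quantize(np.array([40.0]))[0] == 26.7     # clamps above TN


class TestFixedBinning:
    def test_simple_range(self):
        q = fixed_binning_fit(0.0, 10.0, 2)
        np.testing.assert_allclose(q.thresholds, [0, 5, 10])
        np.testing.assert_allclose(q.points, [2.5, 7.5])

    def test_temperature_range_two_levels(self):
        q = fixed_binning_fit(11.8, 33.0, 2)
        assert q.thresholds[1] == pytest.approx(22.4)
        np.testing.assert_allclose(q.points, [17.1, 27.7])

    def test_single_level_midrange(self):
        q = fixed_binning_fit(2.0, 4.0, 1)
        assert q.points[0] == pytest.approx(3.0)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            fixed_binning_fit(1.0, 1.0, 2)


class TestGlobalOptimality:
    def test_matches_exhaustive_partition_oracle(self, rng):
        """On small discrete PMFs the multi-restart Lloyd fit attains the
        globally optimal contiguous-partition distortion."""
        for _ in range(20):
            k = int(rng.integers(4, 13))
            support = np.sort(rng.uniform(-5, 5, size=k))
            sample = rng.choice(support, size=200,
                                p=rng.dirichlet(np.ones(k)))
            x, counts = np.unique(sample, return_counts=True)
            n_levels = int(rng.integers(2, min(4, len(x) - 1) + 1))
            q = lloyd_fit_samples(sample, n_levels, tol=1e-12, seed=0, restarts=32)
            oracle = optimal_partition_distortion(x, counts / counts.sum(), n_levels)
            assert q.distortion == pytest.approx(oracle, rel=1e-7, abs=1e-12)

    def test_six_point_pmf_two_levels(self, rng):
        sample = np.repeat([0.0, 1.0, 2.0, 6.0, 7.0, 9.0], [3, 2, 1, 2, 1, 1])
        q = lloyd_fit_samples(sample, 2, tol=1e-12, seed=0, restarts=16)
        x, counts = np.unique(sample, return_counts=True)
        oracle = optimal_partition_distortion(x, counts / counts.sum(), 2)
        assert q.distortion == pytest.approx(oracle, rel=1e-9)


class TestIterationContracts:
    @pytest.mark.parametrize("seed", range(100))
    def test_distortion_trace_non_increasing_random_inits(self, seed):
        pmf = _normal_pmf(n_bins=60, span=4.0)
        q = lloyd_fit(pmf, 4, init="random", seed=seed, restarts=1)
        trace = np.asarray(q.trace)
        assert np.all(np.diff(trace) <= 1e-9 * max(trace[0], 1.0))

    def test_converged_optimality_conditions(self, season100):
        """At convergence, thresholds are midpoints of adjacent points and
        points are conditional means of their cells."""
        ta = season100["Ta"].values
        pmf = estimate_pmf(ta, normal_reference_width(ta.std(), ta.size))
        q = lloyd_fit(pmf, 3, tol=1e-10)
        assert q.converged
        mids = 0.5 * (q.points[:-1] + q.points[1:])
        np.testing.assert_allclose(q.thresholds[1:-1], mids, atol=1e-6 * np.ptp(ta))
        x, p = pmf.centers, pmf.masses
        cells = q.assign(x)
        for j in range(3):
            sel = cells == j
            cond_mean = (p[sel] @ x[sel]) / p[sel].sum()
            assert q.points[j] == pytest.approx(cond_mean, abs=1e-6 * np.ptp(ta))

    def test_insufficient_support_is_error(self):
        pmf = estimate_pmf(np.array([1.0, 1.0, 2.0, 2.0]), 1.0)
        with pytest.raises(ValueError, match="insufficient support"):
            lloyd_fit(pmf, 5)

    def test_zero_mass_interior_bins_never_crash(self):
        # two widely separated clusters leave interior bins empty
        data = np.concatenate([np.full(50, 0.0), np.full(50, 10.0),
                               np.array([0.1, 9.9])])
        pmf = estimate_pmf(data, 0.5)
        q = lloyd_fit(pmf, 2)
        assert q.converged
        assert q.n_levels == 2

    def test_unconverged_flag_when_iteration_capped(self):
        pmf = _normal_pmf(n_bins=200)
        q = lloyd_fit(pmf, 4, tol=1e-14, max_iter=2)
        assert not q.converged
        assert q.n_iter == 2


class TestLloydDominatesFixedBinning:
    @pytest.mark.parametrize("var", ["Ta", "U", "VPD", "Rg"])
    @pytest.mark.parametrize("n_levels", [2, 3, 4, 5])
    def test_distortion_never_worse_on_suite(self, season100, var, n_levels):
        s = season100[var]
        mask = daylight_mask(s, 5.0) if var == "Rg" else None
        vals = s.values if mask is None else s.values[mask]
        pmf = estimate_pmf(vals, normal_reference_width(vals.std(), vals.size))
        ql = lloyd_fit(pmf, n_levels, seed=0, restarts=64)
        qf = fixed_binning_fit(vals.min(), vals.max(), n_levels)
        assert ql.distortion <= quantizer_distortion(qf, pmf) + 1e-12


class TestApplyQuantizer:
    def test_all_below_first_threshold_constant_output(self):
        q = Quantizer(np.array([0.0, 5.0, 10.0]), np.array([2.0, 7.0]))
        ts_vals = np.array([1.0, 2.0, 3.0])
        import pandas as pd

        from forcequant import ForcingSeries
        s = ForcingSeries("x", ts_vals,
                          pd.date_range("2018-05-30", periods=3, freq="15min"))
        out = apply_quantizer(s, q)
        np.testing.assert_array_equal(out.values, [2.0, 2.0, 2.0])
        assert out.levels.tolist() == [0, 0, 0]

    def test_masked_out_steps_pass_through_exactly(self, season100):
        rg = season100["Rg"]
        mask = daylight_mask(rg, 5.0)
        pmf = estimate_pmf(rg.values[mask], 50.0)
        q = lloyd_fit(pmf, 2)
        out = apply_quantizer(rg, q, mask=mask)
        np.testing.assert_array_equal(out.values[~mask], rg.values[~mask])
        assert set(np.unique(out.values[mask])) <= set(q.points)
        assert np.all(out.levels[~mask] == -1)

    def test_quantizer_summary_mentions_method(self):
        q = fixed_binning_fit(0, 1, 3)
        assert "fixed" in q.summary()


def test_sample_and_pmf_modes_agree_on_fine_histogram(rng):
    data = rng.normal(20, 3, size=4000)
    q_samples = lloyd_fit_samples(data, 3, seed=0, restarts=8)
    pmf = estimate_pmf(data, 0.05)  # fine bins
    q_pmf = lloyd_fit(pmf, 3, seed=0, restarts=8)
    np.testing.assert_allclose(q_samples.points, q_pmf.points, atol=0.05)
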
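"""CV analysis: epoch statistics, normalized coordinates, angle phi, locus calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvlocus import (
    CVPoint,
    QuantalParams,
    expected_mean,
    expected_variance,
    presynaptic_endpoint,
    theoretical_inv_cv2,
)
from cvlocus.analysis import (
    LTD,
    LTP,
    MIXED,
    POSTSYNAPTIC,
    PRESYNAPTIC,
    DegenerateEpochError,
    EpochStats,
    InvalidEpochError,
    NoiseDominatesError,
    analyze_series,
    binned_inv_cv2,
    classify_locus,
    cv_point,
    epoch_stats,
    group_phi_test,
    phi_angle,
)
from cvlocus.simulate import (
    ExperimentDesign,
    default_ltd_scenario,
    run_monte_carlo,
    simulate_experiment,
)


def stats_from_moments(params: QuantalParams, include_bg: bool = False) -> EpochStats:
    """Exact-moment epoch statistics (infinite-data limit)."""
    mu = expected_mean(params)
    sd = math.sqrt(expected_variance(params, include_background=include_bg))
    return EpochStats(mean=mu, sd=sd, cv=sd / mu, n_sweeps=0)


class TestEpochStats:
    def test_constant_epoch(self):
        s = epoch_stats([1.0, 1.0, 1.0])
        assert (s.mean, s.sd, s.cv) == (1.0, 0.0, 0.0)

    def test_sample_sd_uses_n_minus_one(self):
        s = epoch_stats([0.8, 1.0, 1.2])
        assert s.cv == pytest.approx(0.2, rel=1e-12)

    def test_noise_correction_subtracts_background_variance(self):
        amps = [1.0 - 0.2, 1.0 + 0.2, 1.0 - 0.2, 1.0 + 0.2]  # sample sd ~0.2309
        s = epoch_stats(amps, sd_background=0.1, correct_noise=True)
        sd_meas = np.std(amps, ddof=1)
        assert s.sd == pytest.approx(math.sqrt(sd_meas**2 - 0.01), rel=1e-12)

    def test_noise_dominated_epoch_rejected(self):
        with pytest.raises(NoiseDominatesError):
            epoch_stats([1.0, 1.001, 0.999], sd_background=0.5, correct_noise=True)

    @pytest.mark.parametrize("amps", [[1.0], [-1.0, -2.0, -3.0]])
    def test_invalid_epochs_rejected(self, amps):
        with pytest.raises(InvalidEpochError):
            epoch_stats(amps)


class TestCVPointCoordinates:
    def test_identical_epochs_map_to_identity(self):
        s = epoch_stats([0.8, 1.0, 1.2])
        pt = cv_point(s, s)
        assert (pt.mu_norm, pt.inv_cv2_norm) == (1.0, 1.0)

    def test_presynaptic_ltd_from_exact_moments_hits_box_endpoint(self):
        """Noiseless p: 0.55 -> 0.4 analyzed from exact moments lands on the
        closed-form presynaptic endpoint (cross-module oracle)."""
        base = stats_from_moments(QuantalParams(5, 0.55, 0.35))
        post = stats_from_moments(QuantalParams(5, 0.4, 0.35))
        pt = cv_point(base, post)
        oracle = presynaptic_endpoint(0.55, 0.4 / 0.55)
        assert pt.mu_norm == pytest.approx(oracle.mu_norm, rel=1e-12)
        assert pt.inv_cv2_norm == pytest.approx(oracle.inv_cv2_norm, rel=1e-12)

    def test_pure_postsynaptic_change_stays_on_horizontal_line(self):
        base = stats_from_moments(QuantalParams(5, 0.55, 0.35))
        post = stats_from_moments(QuantalParams(5, 0.55, 0.175))
        pt = cv_point(base, post)
        assert pt.mu_norm == pytest.approx(0.5, rel=1e-12)
        assert pt.inv_cv2_norm == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_post_epoch_rejected(self):
        base = epoch_stats([0.8, 1.0, 1.2])
        post = epoch_stats([1.0, 1.0, 1.0])
        with pytest.raises(DegenerateEpochError):
            cv_point(base, post)

    @given(scale=st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=50)
    def test_pure_gain_invariance(self, scale):
        """Scaling all amplitudes of both epochs leaves the point unchanged."""
        rng = np.random.default_rng(77)
        b = rng.normal(1.0, 0.2, 50)
        p = rng.normal(0.7, 0.25, 50)
        pt1 = cv_point(epoch_stats(b), epoch_stats(p))
        pt2 = cv_point(epoch_stats(scale * b), epoch_stats(scale * p))
        assert pt2.mu_norm == pytest.approx(pt1.mu_norm, rel=1e-9)
        assert pt2.inv_cv2_norm == pytest.approx(pt1.inv_cv2_norm, rel=1e-9)


class TestPhiAngle:
    @pytest.mark.parametrize(
        "point, direction",
        [(CVPoint(0.7, 0.7), LTD), (CVPoint(1.3, 1.3), LTP)],
    )
    def test_zero_on_the_diagonal(self, point, direction):
        assert phi_angle(point, direction) == 0.0

    @pytest.mark.parametrize(
        "point, direction",
        [(CVPoint(0.7, 1.0), LTD), (CVPoint(1.5, 1.0), LTP)],
    )
    def test_minus_45_on_the_horizontal_line(self, point, direction):
        assert phi_angle(point, direction) == pytest.approx(-45.0, abs=1e-9)

    def test_reference_ltd_point_is_positive_14_degrees(self):
        # arccos(v.d/|v||d|) with v = (-0.27273, -0.45455), d = (-1,-1)/sqrt(2)
        phi = phi_angle(CVPoint(0.72727, 0.54545), LTD)
        assert phi == pytest.approx(14.04, abs=0.05)

    def test_sign_mirrors_for_ltp(self):
        """Above-diagonal is presynaptic (positive) for LTP, below for LTD."""
        assert phi_angle(CVPoint(1.3, 1.6), LTP) > 0
        assert phi_angle(CVPoint(1.6, 1.3), LTP) < 0
        assert phi_angle(CVPoint(0.7, 0.5), LTD) > 0
        assert phi_angle(CVPoint(0.5, 0.7), LTD) < 0

    def test_undefined_at_identity_point(self):
        from cvlocus import InvalidParameterError

        with pytest.raises(InvalidParameterError):
            phi_angle(CVPoint(1.0, 1.0), LTD)

    def test_continuity_between_diagonal_and_horizontal(self):
        """phi decreases continuously from 0 to -45 as the point rotates from
        the diagonal to the horizontal line."""
        phis = [
            phi_angle(CVPoint(0.7, 0.7 + f * 0.3), LTD) for f in np.linspace(0, 1, 21)
        ]
        assert phis[0] == 0.0
        assert phis[-1] == pytest.approx(-45.0, abs=1e-9)
        assert np.all(np.diff(phis) < 0)


class TestClassifyLocus:
    @pytest.mark.parametrize(
        "point, direction, expected",
        [
            (CVPoint(0.72727, 0.54545), LTD, PRESYNAPTIC),
            (CVPoint(0.7, 1.0), LTD, POSTSYNAPTIC),
            (CVPoint(0.7, 0.88), LTD, MIXED),  # phi ~ -23.2 deg, between bands
            (CVPoint(1.4, 1.8), LTP, PRESYNAPTIC),
            (CVPoint(1.4, 1.02), LTP, POSTSYNAPTIC),
        ],
    )
    def test_band_classification(self, point, direction, expected):
        assert classify_locus(point, direction) == expected

    def test_band_width_is_configurable(self):
        pt = CVPoint(0.7, 0.88)  # phi ~ -23.2 deg
        assert classify_locus(pt, LTD, delta_post_deg=15.0) == MIXED
        assert classify_locus(pt, LTD, delta_post_deg=25.0) == POSTSYNAPTIC


class TestEnsembleConvergence:
    def test_pure_presynaptic_converges_to_endpoint(self):
        """Long noiseless experiments converge on the closed-form endpoint."""
        big = ExperimentDesign(n_baseline_sweeps=5000, n_post_sweeps=5000)
        scenario = default_ltd_scenario(sd_background=0.0)
        ensemble = run_monte_carlo(big, scenario, n_reps=10, base_seed=21)
        pts = [analyze_series(s).point for s in ensemble]
        oracle = presynaptic_endpoint(0.55, 0.4 / 0.55)
        assert np.mean([p.mu_norm for p in pts]) == pytest.approx(
            oracle.mu_norm, abs=0.02
        )
        assert np.mean([p.inv_cv2_norm for p in pts]) == pytest.approx(
            oracle.inv_cv2_norm, abs=0.03
        )

    def test_pure_postsynaptic_inv_cv2_converges_to_one(self):
        """Only q changes: ensemble mean 1/CV^2_norm approaches 1."""
        big = ExperimentDesign(n_baseline_sweeps=2000, n_post_sweeps=2000)
        scenario = default_ltd_scenario(
            p_baseline=0.55, p_post=0.55, sd_background=0.0
        )
        ensemble = run_monte_carlo(big, scenario, n_reps=20, base_seed=22)
        # halve q in the post epoch by scaling post amplitudes
        icvs = []
        for s in ensemble:
            base = epoch_stats(s.baseline)
            post = epoch_stats(0.5 * s.post)
            icvs.append(cv_point(base, post).inv_cv2_norm)
        assert np.mean(icvs) == pytest.approx(1.0, abs=0.05)


class TestBinnedInvCV2:
    def test_constant_bins_flagged_infinite(self, design):
        series = simulate_experiment(
            design,
            default_ltd_scenario(p_baseline=1.0, p_post=1.0, sd_background=0.0),
            seed=0,
        )
        vals = binned_inv_cv2(series, 20)
        assert np.all(np.isinf(vals))

    def test_partial_trailing_bin_dropped(self, design, ltd_scenario):
        series = simulate_experiment(design, ltd_scenario, seed=0)
        assert binned_inv_cv2(series, 25).size == 300 // 25

    def test_stationary_bins_scatter_around_theoretical_value(self):
        """Bins of a stationary baseline scatter around the analytic 1/CV^2
        (background noise included)."""
        big = ExperimentDesign(n_baseline_sweeps=4000, n_post_sweeps=1)
        scenario = default_ltd_scenario()
        series = simulate_experiment(big, scenario, seed=13)
        vals = binned_inv_cv2(series, 400)[:-1]  # last bin spans the epoch switch
        theory = theoretical_inv_cv2(
            scenario.baseline_params, include_background=True
        )
        assert np.mean(vals) == pytest.approx(theory, rel=0.10)

    def test_bin_size_must_be_at_least_two(self, design, ltd_scenario):
        series = simulate_experiment(design, ltd_scenario, seed=0)
        with pytest.raises(InvalidEpochError):
            binned_inv_cv2(series, 1)


class TestGroupPhiTest:
    def test_all_zero_angles(self):
        out = group_phi_test([0.0, 0.0, 0.0])
        assert (out["t"], out["p"]) == (0.0, 1.0)

    def test_hand_computed_mean_and_sem(self):
        out = group_phi_test([10, 12, 14, 16, 18])
        assert out["mean"] == pytest.approx(14.0)
        assert out["sem"] == pytest.approx(math.sqrt(10) / math.sqrt(5), rel=1e-9)
        assert out["p"] < 0.001
        assert out["wilcoxon_p"] < 0.1

    def test_symmetric_angles_are_not_significant(self):
        out = group_phi_test([-8.0, 8.0, -3.0, 3.0])
        assert out["mean"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_requires_two_angles(self):
        with pytest.raises(InvalidEpochError):
            group_phi_test([5.0])
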
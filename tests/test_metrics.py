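"""Discrimination, Brier, calibration and Wilson intervals."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import riskvalid as rv
from riskvalid.metrics import MetricError

from conftest import brute_force_auc


class TestAuc:
    def test_perfect_separation(self):
        a, _ = rv.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert a == 1.0

    def test_pure_ties(self):
        a, _ = rv.auc([0.3] * 6, [0, 1, 0, 1, 0, 1])
        assert a == 0.5

    def test_hand_counted_pairs(self):
        # 4 case-control pairs, 3 concordant
        a, _ = rv.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert a == pytest.approx(0.75)

    def test_antiperfect_is_one_minus_perfect(self):
        p = [0.1, 0.2, 0.8, 0.9]
        y = [0, 0, 1, 1]
        a_fwd, _ = rv.auc(p, y)
        a_rev, _ = rv.auc(p, [1 - v for v in y])
        assert a_rev == pytest.approx(1.0 - a_fwd)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            rv.auc([0.1, 0.9], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        # discrete scores force ties through the midrank path
        p = rng.integers(0, 8, n) / 8.0
        a, _ = rv.auc(p, y)
        assert a == pytest.approx(brute_force_auc(p, y), abs=1e-12)

    def test_delong_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(5)
        n = 600
        eta = rng.normal(-2.0, 1.2, n)
        y = (rng.random(n) < expit(eta)).astype(int)
        _, v = rv.auc(expit(eta), y)
        boots = []
        for _ in range(300):
            idx = rng.integers(0, n, n)
            if y[idx].min() == y[idx].max():
                continue
            boots.append(rv.auc(expit(eta[idx]), y[idx])[0])
        assert np.sqrt(v) == pytest.approx(np.std(boots), rel=0.25)


class TestBrier:
    def test_perfect_predictions(self):
        assert rv.brier([0.0, 1.0, 1.0], [0, 1, 1]) == 0.0

    def test_half_everywhere(self):
        assert rv.brier([0.5] * 4, [0, 1, 0, 1]) == pytest.approx(0.25)

    def test_hand_example(self):
        assert rv.brier([0.8, 0.2], [1, 0]) == pytest.approx(0.04)

    def test_constant_prevalence_prediction_closed_form(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 500)
        prev = y.mean()
        assert rv.brier(np.full(500, prev), y) == pytest.approx(prev * (1 - prev))

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(MetricError):
            rv.brier([1.2], [1])


@pytest.fixture(scope="module")
def self_simulated():
    rng = np.random.default_rng(17)
    n = 50_000
    eta = rng.normal(-2.2, 1.0, n)
    y = (rng.random(n) < expit(eta)).astype(int)
    return eta, y


class TestCalibration:
    def test_self_calibration_recovery(self, self_simulated):
        eta, y = self_simulated
        rep = rv.calibration(eta, y)
        assert rep.citl == pytest.approx(0.0, abs=0.03)
        assert rep.slope == pytest.approx(1.0, abs=0.05)
        assert rep.eo_ratio == pytest.approx(1.0, abs=0.03)

    def test_offset_shift_recovered_as_citl(self):
        rng = np.random.default_rng(29)
        n = 50_000
        eta_model = rng.normal(-3.5, 1.0, n)
        y = (rng.random(n) < expit(eta_model + 2.0)).astype(int)
        rep = rv.calibration(eta_model, y)
        assert rep.citl == pytest.approx(2.0, abs=0.06)
        assert rep.eo_ratio < 1.0  # underprediction

    def test_halved_eta_gives_slope_two(self):
        # truth log-odds are 2 * model eta => refit slope ~ 2
        rng = np.random.default_rng(31)
        n = 50_000
        eta_model = rng.normal(-1.2, 0.6, n)
        y = (rng.random(n) < expit(2.0 * eta_model)).astype(int)
        rep = rv.calibration(eta_model, y)
        assert rep.slope == pytest.approx(2.0, abs=0.1)

    def test_expected_and_observed_fields(self, self_simulated):
        eta, y = self_simulated
        rep = rv.calibration(eta, y)
        assert rep.expected == pytest.approx(float(expit(eta).sum()))
        assert rep.observed == int(y.sum())
        assert rep.eo_ratio == pytest.approx(rep.expected / rep.observed)


class TestCalibrationPlot:
    def test_singleton_groups(self):
        data = rv.calibration_plot_data(np.linspace(0.05, 0.5, 10), np.zeros(10), 10)
        assert (data.group_size == 1).all()

    def test_group_sizes_differ_by_at_most_one(self):
        data = rv.calibration_plot_data(np.random.default_rng(0).random(103), np.zeros(103), 10)
        assert data.group_size.max() - data.group_size.min() <= 1
        assert data.group_size.sum() == 103

    def test_groups_ordered_by_predicted_risk(self):
        p = np.random.default_rng(1).random(200)
        data = rv.calibration_plot_data(p, np.zeros(200), 10)
        assert (np.diff(data.mean_predicted) >= 0).all()

    def test_coverage_on_calibrated_simulation(self):
        rng = np.random.default_rng(41)
        n = 50_000
        eta = rng.normal(-2.2, 1.0, n)
        p = expit(eta)
        y = (rng.random(n) < p).astype(int)
        data = rv.calibration_plot_data(p, y, 10)
        inside = (
            (data.mean_predicted >= data.ci_lower)
            & (data.mean_predicted <= data.ci_upper)
        ).sum()
        assert inside >= 9

    def test_all_ties_warns_and_splits_stably(self):
        with pytest.warns(UserWarning, match="distinct"):
            data = rv.calibration_plot_data(np.full(20, 0.3), np.zeros(20), 5)
        assert data.group_size.sum() == 20

    def test_too_few_groups_rejected(self):
        with pytest.raises(MetricError):
            rv.calibration_plot_data([0.1, 0.2], [0, 1], 1)


class TestWilson:
    def test_reference_cohort_follow_up_interval(self):
        # 85 events among 845 followed up: 10%, printed as 8% to 12%
        ci = rv.wilson_ci(85, 845)
        assert ci.lower == pytest.approx(0.0821, abs=1e-3)
        assert ci.upper == pytest.approx(0.1227, abs=1e-3)
        assert round(100 * ci.lower) == 8
        assert round(100 * ci.upper) == 12

    def test_zero_successes(self):
        ci = rv.wilson_ci(0, 10)
        assert ci.lower == 0.0
        assert ci.upper == pytest.approx(0.2775, abs=1e-3)

    def test_symmetry_at_half(self):
        ci = rv.wilson_ci(5, 10)
        assert ci.upper - 0.5 == pytest.approx(0.5 - ci.lower)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=500), st.data())
    def test_interval_contains_estimate_within_unit_range(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        ci = rv.wilson_ci(k, n)
        assert 0.0 <= ci.lower <= ci.estimate <= ci.upper <= 1.0
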
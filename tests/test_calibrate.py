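"""Baseline-hazard calibration: interpolation, the marching solver against a
bisection oracle, incidence/survival/onset predictions, and the Table-style
incidence grid."""

import numpy as np
import pandas as pd
import pytest

from polyhazard.calibrate import (BaselineIncidence, IncidenceCalibrator,
                                  calibrate_baseline, interpolate_baseline)
from polyhazard.datasets import load_ad_weights, load_us_incidence
from polyhazard.score import PHSDistribution, reference_distribution


def point_mass(s=0.0):
    return PHSDistribution([s], [1.0], [False], "exact_enumeration")


def two_point():
    return PHSDistribution([0.0, np.log(2.0)], [0.5, 0.5], [False, False],
                           "exact_enumeration")


class TestInterpolateBaseline:
    def test_knots_recovered_exactly(self):
        base = load_us_incidence()
        h = interpolate_baseline(base, base.ages)
        rates = 100.0 * (1.0 - np.exp(-h))
        assert rates[0] == pytest.approx(0.08, abs=1e-12)
        assert rates[-1] == pytest.approx(12.10, abs=1e-12)

    def test_midpoint_is_geometric_mean(self):
        base = BaselineIncidence([60.0, 65.0], [0.08, 0.17])
        h = interpolate_baseline(base, [62.5])
        rate = 100.0 * (1.0 - np.exp(-h[0]))
        assert rate == pytest.approx(np.sqrt(0.08 * 0.17), rel=1e-3)
        assert rate == pytest.approx(0.1166, abs=2e-4)

    def test_constant_table_gives_constant_hazard(self):
        base = BaselineIncidence([60.0, 70.0, 80.0], [1.0, 1.0, 1.0])
        h = interpolate_baseline(base, np.linspace(60, 80, 7))
        assert np.allclose(h, h[0])

    def test_out_of_range_requires_extrapolation_flag(self):
        base = load_us_incidence()
        with pytest.raises(ValueError, match="extrapolate"):
            interpolate_baseline(base, [99.0])
        h99 = interpolate_baseline(base, [99.0], extrapolate=True)
        assert h99[0] > base.hazards[-1]  # log-linear continuation keeps rising

    @pytest.mark.parametrize(
        "ages,rates", [([60.0, 60.0], [1.0, 1.0]), ([60.0, 65.0], [0.0, 1.0])]
    )
    def test_invalid_tables_rejected(self, ages, rates):
        with pytest.raises(ValueError):
            BaselineIncidence(ages, rates)


class TestCalibration:
    def test_degenerate_distribution_recovers_population_hazard(self):
        cal = IncidenceCalibrator().fit(load_us_incidence(), point_mass(0.0))
        assert np.max(np.abs(cal.h0_ - cal.h_pop_)) < 1e-12
        assert np.max(np.abs(cal.diagnostics_)) < 1e-12

    def test_matches_stepwise_bisection_oracle(self):
        """Two-point score distribution, constant population hazard: the
        marching solve must agree with an independent per-step bisection of
        the same fixed-point condition."""
        base = BaselineIncidence([60.0, 100.0], [1.0, 1.0])  # ~0.01/yr
        dist = two_point()
        cal = IncidenceCalibrator(dt=0.25, max_age=100.0, lead_in=0.0).fit(base, dist)

        h_pop = cal.h_pop_
        rr = np.exp(dist.support)
        w = dist.weights.copy()
        surv = np.ones_like(w)
        oracle = np.empty_like(cal.h0_)
        for j in range(oracle.size):
            ws = w * surv

            def excess(h):
                # population hazard among survivors at the cell midpoint
                wm = ws * np.exp(-h * rr * cal.dt / 2.0)
                return h * (wm @ rr) / wm.sum() - h_pop[j]

            lo, hi = 0.0, 10.0
            for _ in range(80):  # bisection: excess is increasing in h
                mid = 0.5 * (lo + hi)
                if excess(mid) < 0.0:
                    lo = mid
                else:
                    hi = mid
            oracle[j] = 0.5 * (lo + hi)
            surv = surv * np.exp(-oracle[j] * rr * cal.dt)
        assert np.max(np.abs(cal.h0_ - oracle)) < 1e-10

    def test_calibration_exactness_with_published_weights(self):
        w = load_ad_weights()
        freqs = {v: 0.3 for v in w.variant if v.startswith("rs")}
        dist = reference_distribution(
            w, freqs, apoe_freqs=(0.08, 0.78, 0.14), n_mc=20_000, seed=2
        )
        cal = IncidenceCalibrator().fit(load_us_incidence(), dist)
        assert np.max(np.abs(cal.diagnostics_)) < 1e-12
        assert np.all(cal.h0_ > 0)

    def test_grid_refinement_stability(self):
        dist = two_point()
        base = load_us_incidence()
        c1 = IncidenceCalibrator(dt=0.25).fit(base, dist)
        c2 = IncidenceCalibrator(dt=0.125).fit(base, dist)
        ages = np.array([65.0, 75.0, 85.0, 94.0])
        for s in (0.0, 1.0):
            a1 = c1.annualized_incidence(s, ages)
            a2 = c2.annualized_incidence(s, ages)
            assert np.max(np.abs(a1 - a2) / a1) < 0.005


class TestPredictions:
    def test_annualized_incidence_closed_form_constant_hazard(self):
        base = BaselineIncidence([60.0, 100.0], [0.1, 0.1])  # 0.001/yr
        cal = IncidenceCalibrator(lead_in=0.0).fit(base, point_mass())
        val = float(cal.annualized_incidence(0.0, 70.0))
        assert val == pytest.approx(100.0 * (1.0 - np.exp(-0.0010005)), rel=1e-3)

    def test_incidence_strictly_increasing_in_score(self):
        cal = IncidenceCalibrator().fit(load_us_incidence(), two_point())
        ss = np.linspace(-2, 2, 9)
        vals = [float(cal.annualized_incidence(s, 75.0)) for s in ss]
        assert np.all(np.diff(vals) > 0)

    def test_survival_curve_ph_identity_and_closed_form(self):
        base = BaselineIncidence([60.0, 100.0], [1.0, 1.0])
        cal = IncidenceCalibrator(lead_in=0.0).fit(base, point_mass())
        ages, s0 = cal.survival_curve(0.0, 60.0)
        _, s1 = cal.survival_curve(np.log(2.0), 60.0)
        ok = s0 > 0
        assert np.allclose(np.log(s1[ok]), 2.0 * np.log(s0[ok]), atol=1e-10)
        # constant h ~ -ln(1-0.01): S(70|60) = exp(-10h)
        h = -np.log(1 - 0.01)
        i70 = np.searchsorted(ages, 70.0)
        assert s0[i70] == pytest.approx(np.exp(-10 * h), rel=1e-6)

    def test_fine_grid_integration_agreement(self):
        dist = two_point()
        base = load_us_incidence()
        cal = IncidenceCalibrator(dt=0.25).fit(base, dist)
        fine = IncidenceCalibrator(dt=0.025).fit(base, dist)
        _, s_coarse = cal.survival_curve(0.5, 60.0, ages=[80.0])
        _, s_fine = fine.survival_curve(0.5, 60.0, ages=[80.0])
        assert abs(s_coarse[0] - s_fine[0]) < 1e-3

    def test_expected_onset_exponential_median(self):
        base = BaselineIncidence([60.0, 200.0], [100 * (1 - np.exp(-0.1)), ] * 2)
        cal = IncidenceCalibrator(dt=0.01, max_age=200.0, lead_in=0.0).fit(
            base, point_mass()
        )
        med = cal.expected_onset_age(0.0, q=0.5, from_age=60.0)
        assert med == pytest.approx(60.0 + np.log(2) / 0.1, abs=0.02)

    def test_onset_age_limits_and_monotonicity(self):
        cal = IncidenceCalibrator().fit(load_us_incidence(), two_point())
        assert cal.expected_onset_age(0.0, q=1e-9, from_age=60.0) == pytest.approx(
            60.0, abs=0.3
        )
        ages = [cal.expected_onset_age(s, q=0.5, from_age=60.0) for s in (0.0, 0.5, 1.0)]
        finite = [a for a in ages if np.isfinite(a)]
        assert all(a > b for a, b in zip(finite, finite[1:]))
        with pytest.raises(ValueError):
            cal.expected_onset_age(0.0, q=1.5)

    def test_low_risk_profile_never_reaches_half(self):
        cal = IncidenceCalibrator().fit(load_us_incidence(), point_mass())
        assert cal.expected_onset_age(-3.0, q=0.9, from_age=60.0) == np.inf


class TestIncidenceTable:
    def _dist(self, n_mc=50_000):
        w = load_ad_weights()
        freqs = {v: 0.3 for v in w.variant if v.startswith("rs")}
        return reference_distribution(
            w, freqs, apoe_freqs=(0.08, 0.78, 0.14), n_mc=n_mc, seed=11
        )

    def test_point_mass_table_equals_baseline_column(self):
        cal = IncidenceCalibrator().fit(load_us_incidence(), point_mass())
        table = cal.incidence_table(percentiles=(20, 80))
        for col in ("phs_p20", "phs_p80"):
            assert np.allclose(table[col], table["baseline"], rtol=1e-12)

    def test_columns_ordered_across_percentiles(self):
        cal = IncidenceCalibrator().fit(load_us_incidence(), self._dist())
        table = cal.incidence_table(percentiles=(1, 20, 80, 99))
        assert (table["phs_p99"] > table["phs_p80"]).all()
        assert (table["phs_p80"] > table["phs_p20"]).all()
        assert (table["phs_p20"] > table["phs_p1"]).all()

    def test_columns_nondecreasing_in_age(self):
        cal = IncidenceCalibrator().fit(load_us_incidence(), self._dist())
        table = cal.incidence_table(percentiles=(1, 20, 80, 99), apoe_strata=True)
        for col in table.columns:
            assert (np.diff(table[col]) > 0).all()

    def test_e4_carriers_exceed_noncarriers(self):
        cal = IncidenceCalibrator().fit(load_us_incidence(), self._dist())
        table = cal.incidence_table(apoe_strata=True)
        assert (table["apoe_e4_carrier"] > table["apoe_e4_noncarrier"]).all()

    def test_fixed_quantile_ratio_is_exact_hazard_ratio(self):
        """On the hazard scale the 99th/1st-percentile ratio equals
        e^{s99 - s1} at every age (no survivor depletion for a fixed s)."""
        dist = self._dist()
        cal = IncidenceCalibrator().fit(load_us_incidence(), dist)
        table = cal.incidence_table(percentiles=(1, 99))
        s1, s99 = dist.quantile(0.01), dist.quantile(0.99)
        haz = -np.log(1.0 - table[["phs_p1", "phs_p99"]] / 100.0)
        ratio = haz["phs_p99"] / haz["phs_p1"]
        assert np.allclose(ratio, np.exp(s99 - s1), rtol=1e-9)

    def test_survivor_conditioned_ratio_shrinks_with_age(self):
        dist = self._dist()
        cal = IncidenceCalibrator().fit(load_us_incidence(), dist)
        table = cal.incidence_table(percentiles=(1, 99), mode="survivor_quantile")
        haz = -np.log(1.0 - table[["phs_p1", "phs_p99"]] / 100.0)
        ratio = (haz["phs_p99"] / haz["phs_p1"]).to_numpy()
        assert (np.diff(ratio) <= 1e-9).all()

    def test_invalid_percentile_rejected(self):
        cal = IncidenceCalibrator().fit(load_us_incidence(), point_mass())
        with pytest.raises(ValueError):
            cal.incidence_table(percentiles=(0, 50))

    def test_cells_capped_at_100(self):
        cal = IncidenceCalibrator().fit(load_us_incidence(), point_mass())
        assert float(cal.annualized_incidence(5.0, 95.0)) <= 100.0


def test_functional_wrapper_matches_estimator():
    cal1 = calibrate_baseline(load_us_incidence(), two_point())
    cal2 = IncidenceCalibrator().fit(load_us_incidence(), two_point())
    assert np.allclose(cal1.h0_, cal2.h0_)
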
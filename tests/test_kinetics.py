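"""Michaelis-Menten inversion: rate law, corrections, fitting, derived rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streammox.kinetics import (
    blank_correct,
    carbon_fixation,
    dilution_correct,
    fit_mm,
    in_situ_rate,
    mm_rate,
    normalize_per_area,
    rate_points,
)
from streammox.synth import default_schedule, simulate_incubation
from streammox.types import ChamberConfig, KineticFit, RatePoint


class TestMMRate:
    def test_half_saturation(self):
        assert mm_rate(3.0, 10.0, 3.0) == pytest.approx(5.0)
        assert mm_rate(10.6, 53.9, 10.6) == pytest.approx(53.9 / 2)

    def test_saturation_limit(self):
        assert mm_rate(1e9, 53.9, 10.6) == pytest.approx(53.9, rel=1e-6)

    @given(s=st.floats(0.0, 1e3), s2=st.floats(0.0, 1e3))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_and_bounded(self, s, s2):
        lo, hi = sorted([s, s2])
        assert mm_rate(lo, 10.0, 3.0) <= mm_rate(hi, 10.0, 3.0) <= 10.0

    def test_invalid_zero_over_zero(self):
        with pytest.raises(ValueError):
            mm_rate(0.0, 10.0, 0.0)
        assert mm_rate(0.0, 0.0, 0.0) == 0.0


class TestDilutionCorrect:
    def test_matches_simulator_ledger(self, noisefree_series):
        intervals = dilution_correct(noisefree_series)
        ledger = noisefree_series.truth["interval_consumed"]
        for iv, truth in zip(intervals, ledger):
            assert iv["consumed_nmol"] == pytest.approx(truth, rel=1e-6)

    def test_no_withdrawal_equals_naive_differencing(self):
        ch = ChamberConfig(withdrawal_ml=0.0)
        s = simulate_incubation(10.0, 3.0, chamber=ch, noise_cv=0.0)
        c = s.conc["CH4"]
        for i, iv in enumerate(dilution_correct(s)):
            naive = s.water_volume * (c[i] - c[i + 1])
            assert iv["consumed_nmol"] == pytest.approx(naive, rel=1e-12)

    def test_replacement_equal_to_chamber_gives_zero(self):
        ch = ChamberConfig(repl_ch4=15.607470193804733)  # = initial conc
        s = simulate_incubation(0.0, 0.0, chamber=ch, noise_cv=0.0,
                                init_ch4=ch.repl_ch4)
        for iv in dilution_correct(s):
            assert iv["consumed_nmol"] == pytest.approx(0.0, abs=1e-9)

    def test_interval_s_is_geometric_mean(self, noisefree_series):
        iv = dilution_correct(noisefree_series)[0]
        assert iv["s_um"] == pytest.approx(
            np.sqrt(iv["c_start_adj"] * iv["c_end"]))


class TestBlankCorrect:
    def test_zero_blank_is_identity(self):
        pts = [RatePoint(S=5.0, V=2.0), RatePoint(S=3.0, V=1.0)]
        blanks = [[RatePoint(S=5.0, V=0.0), RatePoint(S=3.0, V=0.0)]]
        out = blank_correct(pts, blanks)
        assert [p.V for p in out] == [2.0, 1.0]

    def test_blank_equal_to_sediment_gives_zero(self):
        pts = [RatePoint(S=5.0, V=2.0)]
        out = blank_correct(pts, [[RatePoint(S=5.0, V=2.0)]])
        assert out[0].V == 0.0

    def test_missing_blanks_pass_through_with_warning(self, caplog):
        pts = [RatePoint(S=5.0, V=2.0)]
        with caplog.at_level("WARNING"):
            out = blank_correct(pts, [])
        assert out[0].V == 2.0
        assert "no blank" in caplog.text

    def test_recovers_sediment_only_rates(self):
        """10% streamwater MOX in blanks: early-interval corrected rates
        match the sediment-only truth within 2% (noise-free)."""
        ch = ChamberConfig()
        sched = default_schedule(days=2.0, per_day=4)
        w_vmax = 0.1 * ch.sediment_area_m2 / ch.water_volume_ml * 10.0
        sed = simulate_incubation(10.0, 3.0, chamber=ch, schedule=sched,
                                  noise_cv=0.0, seed=1, water_v_max=w_vmax,
                                  water_k_s=3.0)
        blank = simulate_incubation(0.0, 0.0, chamber=ch, schedule=sched,
                                    noise_cv=0.0, seed=2, is_blank=True,
                                    water_v_max=w_vmax, water_k_s=3.0)
        corrected = blank_correct(rate_points(sed, per_area=False),
                                  [rate_points(blank, per_area=False)])
        truth = sed.truth["interval_consumed_sed"]
        dt = np.diff(sed.times)
        rel = [(p.V - t / d) / (t / d)
               for p, t, d in zip(corrected[:4], truth[:4], dt[:4])]
        assert max(abs(r) for r in rel) < 0.02


class TestFitMM:
    def test_noise_free_round_trip_within_one_percent(self):
        series = [simulate_incubation(10.0, 3.0, noise_cv=0.0, seed=r)
                  for r in range(3)]
        fit = fit_mm(series=series)
        assert fit.converged
        assert fit.v_max == pytest.approx(10.0, rel=0.01)
        assert fit.k_s == pytest.approx(3.0, rel=0.01)

    def test_zero_consumption_returns_zero_convention(self):
        s = simulate_incubation(0.0, 0.0, noise_cv=0.0, seed=0)
        fit = fit_mm(series=[s])
        assert (fit.v_max, fit.k_s) == (0.0, 0.0)
        assert fit.converged

    def test_pointwise_agrees_on_dense_series(self):
        sched = default_schedule(days=4.0, per_day=6)
        s = simulate_incubation(10.0, 3.0, schedule=sched, noise_cv=0.0)
        pts = [RatePoint(S=p.S, V=p.V / s.sediment_area)
               for p in rate_points(s, per_area=False)]
        fit = fit_mm(points=pts, mode="pointwise")
        assert fit.v_max == pytest.approx(10.0, rel=0.05)
        assert fit.k_s == pytest.approx(3.0, rel=0.15)

    def test_ks_invariant_to_sediment_area_rescaling(self):
        fits = []
        for area_factor in (1.0, 2.0):
            ch = ChamberConfig(specific_area_m2_per_g=area_factor)
            # same µM h⁻¹ consumption: halve V_max when doubling area
            s = simulate_incubation(10.0 / area_factor, 3.0, chamber=ch,
                                    noise_cv=0.0)
            fits.append(fit_mm(series=[s]))
        assert fits[0].k_s == pytest.approx(fits[1].k_s, rel=1e-4)
        assert fits[0].v_max == pytest.approx(2 * fits[1].v_max, rel=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_mm(points=[RatePoint(S=1.0, V=1.0)] * 3, mode="pointwise")

    def test_fitted_rate_at_ks_is_half_vmax(self):
        s = simulate_incubation(20.0, 5.0, noise_cv=0.0)
        fit = fit_mm(series=[s])
        assert mm_rate(fit.k_s, fit.v_max, fit.k_s) == pytest.approx(
            fit.v_max / 2)


class TestDerivedRates:
    def _fit(self, v_max, k_s):
        return KineticFit(site_id="x", v_max=v_max, k_s=k_s, rss=0.0,
                          se_vmax=0.0, se_ks=0.0, converged=True,
                          mode="trajectory")

    def test_in_situ_rate_at_half_saturation(self):
        # the largest fitted kinetics evaluated at ambient S = K_S give the
        # maximum putative in-situ rate, ~27 when rounded
        rate = in_situ_rate(self._fit(53.9, 10.6), 10.6)
        assert rate == pytest.approx(26.95)
        assert round(rate) == 27

    def test_in_situ_rate_edge_cases(self):
        assert in_situ_rate(self._fit(0.0, 0.0), 5.0) == 0.0
        assert in_situ_rate(self._fit(10.0, 3.0), 0.0) == 0.0

    def test_carbon_fixation(self):
        assert carbon_fixation(27.0, 0.5) == pytest.approx(13.5)
        assert carbon_fixation(0.0) == 0.0
        assert carbon_fixation(7.0, 1.0) == 7.0
        with pytest.raises(ValueError):
            carbon_fixation(1.0, cue=1.5)

    def test_normalize_per_area(self):
        assert normalize_per_area(100.0, 2.0) == 50.0
        assert normalize_per_area(0.0, 2.0) == 0.0
        assert normalize_per_area(100.0, 4.0) == normalize_per_area(100.0, 2.0) / 2
        with pytest.raises(ValueError):
            normalize_per_area(1.0, 0.0)
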
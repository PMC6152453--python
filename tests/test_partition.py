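"""Respiration/light-response models, campaign fitting and daily sums."""

import numpy as np
import pandas as pd
import pytest

from cropflux import solar
from cropflux.partition import (
    CampaignParams,
    UnfittableCampaignError,
    daily_gep,
    daily_par,
    estimate_reco_at_nep_times,
    fit_light_campaign,
    fit_reco_campaign,
    interpolate_params,
    light_response,
    reco_model,
    reconstruct_30min,
)


class TestRecoModel:
    def test_reference_temperature_identity(self):
        assert reco_model(10.0, 3.7, 250.0) == pytest.approx(3.7)

    def test_hand_evaluation(self):
        # rref=2, e0=308.56, t=20 C: 2*exp(308.56*(1/56.02 - 1/66.02))
        assert reco_model(20.0, 2.0, 308.56) == pytest.approx(4.60, abs=0.01)

    def test_monotone_in_temperature(self):
        t = np.linspace(-5, 35, 50)
        r = reco_model(t, 2.0, 300.0)
        assert np.all(np.diff(r) > 0)

    def test_below_t0_rejected(self):
        with pytest.raises(ValueError):
            reco_model(-50.0, 2.0, 300.0)


class TestLightResponse:
    def test_dark_and_asymptote(self):
        assert light_response(0.0, 0.05, 30.0) == 0.0
        assert light_response(1e9, 0.05, 30.0) == pytest.approx(30.0, rel=1e-5)

    def test_half_saturation_identity(self):
        # PAR = gpmax/alpha gives exactly gpmax/2
        assert light_response(30.0 / 0.05, 0.05, 30.0) == pytest.approx(15.0)


class TestCampaignFits:
    def test_noiseless_reco_recovery(self):
        t = np.linspace(5, 25, 12)
        f = reco_model(t, 3.0, 200.0)
        rref, e0, diag = fit_reco_campaign(t, f)
        assert rref == pytest.approx(3.0, rel=1e-6)
        assert e0 == pytest.approx(200.0, rel=1e-6)
        assert not diag["fixed_e0"]

    def test_fixed_e0_fallback_when_no_span(self):
        t = np.full(6, 15.0)
        f = np.full(6, 4.2)
        rref, e0, diag = fit_reco_campaign(t, f)
        assert diag["fixed_e0"] and e0 == 308.56
        # closed form: measured flux mapped back to Tref
        assert reco_model(15.0, rref, e0) == pytest.approx(4.2, rel=1e-12)

    def test_too_few_fluxes(self):
        with pytest.raises(UnfittableCampaignError):
            fit_reco_campaign([10, 12, 14], [2, 3, 4])

    def test_noiseless_light_recovery(self):
        par = np.linspace(20, 1600, 10)
        gep = light_response(par, 0.05, 30.0)
        alpha, gpmax, diag = fit_light_campaign(par, gep)
        assert alpha == pytest.approx(0.05, rel=1e-6)
        assert gpmax == pytest.approx(30.0, rel=1e-6)

    def test_all_zero_gep_flagged_degenerate(self):
        par = np.linspace(20, 1600, 8)
        alpha, gpmax, diag = fit_light_campaign(par, np.zeros(8))
        assert diag["degenerate"]
        assert gpmax < 1.0

    def test_insufficient_par_span(self):
        with pytest.raises(UnfittableCampaignError):
            fit_light_campaign([500, 550, 600, 650], [10, 11, 12, 13])

    def test_gep_from_nep_plus_reco(self):
        reco = estimate_reco_at_nep_times(2.0, 308.56, [10.0, 20.0])
        assert reco[0] == pytest.approx(2.0)
        nep = np.array([5.0, -2.0])
        gep = nep + reco
        assert gep[0] == pytest.approx(7.0)
        # brute-force per-record evaluation
        assert reco[1] == pytest.approx(reco_model(20.0, 2.0, 308.56))


class TestInterpolation:
    def grid(self):
        return pd.date_range("2012-05-01", "2012-05-11", freq="30min")

    def camp(self, day, **p):
        defaults = dict(rref=2.0, e0=300.0, alpha=0.04, gpmax=20.0)
        defaults.update(p)
        return CampaignParams(pd.Timestamp(day), "p", **defaults)

    def test_anchor_and_midpoint(self):
        c1 = self.camp("2012-05-02", gpmax=20.0)
        c2 = self.camp("2012-05-08", gpmax=40.0)
        out = interpolate_params([c1, c2], self.grid())
        assert out.loc["2012-05-02 12:00", "gpmax"] == pytest.approx(20.0)
        assert out.loc["2012-05-05 12:00", "gpmax"] == pytest.approx(30.0)

    def test_hold_outside_span_and_single_campaign(self):
        out = interpolate_params([self.camp("2012-05-05")], self.grid())
        assert (out["gpmax"] == 20.0).all()

    def test_no_campaigns(self):
        with pytest.raises(UnfittableCampaignError):
            interpolate_params([], self.grid())


class TestReconstruction:
    def test_night_step_and_conservation(self):
        idx = pd.date_range("2012-05-01", periods=48, freq="30min")
        params = pd.DataFrame(
            {"rref": 2.0, "e0": 300.0, "alpha": 0.05, "gpmax": 30.0}, index=idx
        )
        par = np.zeros(48)
        par[20:30] = 900.0
        drv = pd.DataFrame({"par": par, "t_reco": 14.0}, index=idx)
        out = reconstruct_30min(params, drv)
        assert (out.loc[par == 0, "gep"] == 0).all()
        assert np.allclose(out["nep"], out["gep"] - out["reco"])

    def test_grid_mismatch(self):
        idx = pd.date_range("2012-05-01", periods=8, freq="30min")
        params = pd.DataFrame(
            {"rref": 2.0, "e0": 300.0, "alpha": 0.05, "gpmax": 30.0}, index=idx
        )
        drv = pd.DataFrame({"par": 0.0, "t_reco": 10.0}, index=idx[:-1])
        with pytest.raises(ValueError):
            reconstruct_30min(params, drv)


class TestSolarWindow:
    def test_equinox_daylength(self):
        sunrise, sunset = solar.day_window(80, 52.43)
        assert sunset - sunrise == pytest.approx(12.0, abs=0.25)

    def test_midsummer_high_latitude(self):
        assert solar.daylength_hours(172, 52.43) > 16.0

    def test_polar_rejected(self):
        with pytest.raises(ValueError):
            solar.day_window(172, 70.0)


class TestDailyAggregation:
    def series(self, gep):
        idx = pd.date_range("2012-06-01", periods=48, freq="30min")
        return pd.DataFrame({"gep": gep, "par": 700.0}, index=idx)

    def test_constant_gep_hand_sum(self):
        # 24 daylight half-hours of 10 umol m-2 s-1: 10*1800*24*12.011e-6
        s = self.series(10.0)
        out = daily_gep(s, "2012-06-01", (6.0, 17.5))  # 24 steps inclusive
        assert out == pytest.approx(5.189, abs=0.001)

    def test_zero_gep(self):
        assert daily_gep(self.series(0.0), "2012-06-01", (6.0, 17.5)) == 0.0

    def test_additive_over_subwindows(self):
        rng = np.random.default_rng(0)
        s = self.series(rng.uniform(0, 20, 48))
        total = daily_gep(s, "2012-06-01", (4.0, 20.0))
        left = daily_gep(s, "2012-06-01", (4.0, 11.5))
        right = daily_gep(s, "2012-06-01", (12.0, 20.0))
        assert total == pytest.approx(left + right, rel=1e-12)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        gep = rng.uniform(0, 25, 48)
        s = self.series(gep)
        window = (5.0, 19.0)
        out = daily_gep(s, "2012-06-01", window)
        hours = s.index.hour + s.index.minute / 60.0
        mask = (hours >= window[0]) & (hours <= window[1])
        oracle = float(np.sum(gep[mask]) * 1800 * 12.011e-6)
        assert out == pytest.approx(oracle, rel=1e-14)

    def test_missing_steps_error(self):
        s = self.series(10.0).drop(pd.Timestamp("2012-06-01 12:00"))
        with pytest.raises(ValueError, match="missing"):
            daily_gep(s, "2012-06-01", (6.0, 18.0))

    def test_daily_par_mean_and_night_exclusion(self):
        idx = pd.date_range("2012-06-01", periods=48, freq="30min")
        par = np.zeros(48)
        hours = idx.hour + idx.minute / 60.0
        window = (4.0, 20.0)
        day = (hours >= window[0]) & (hours <= window[1])
        par[day] = 800.0
        drv = pd.DataFrame({"par": par}, index=idx)
        assert daily_par(drv, "2012-06-01", window) == pytest.approx(800.0)

    def test_half_sine_mean_matches_analytic(self):
        # mean of a half-sinusoid with peak P is 2P/pi
        idx = pd.date_range("2012-06-01", periods=48, freq="30min")
        hours = np.asarray(idx.hour + idx.minute / 60.0)
        sunrise, sunset = 5.0, 19.0
        par = np.where(
            (hours >= sunrise) & (hours <= sunset),
            1000.0 * np.sin(np.pi * (hours - sunrise) / (sunset - sunrise)),
            0.0,
        )
        drv = pd.DataFrame({"par": par}, index=idx)
        out = daily_par(drv, "2012-06-01", (sunrise, sunset))
        # the 30-min grid slightly underweights the peak of the sinusoid
        assert out == pytest.approx(2000.0 / np.pi, rel=0.05)
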
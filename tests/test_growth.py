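import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ruecanopy.growth import (
    GrainFillPAR,
    HarvestRecord,
    LightReading,
    aboveground_biomass,
    accumulate_ipar,
    grain_fill_par,
    light_interception_pct,
    par_from_irradiance,
    rue_grain_filling,
    rue_interval,
    rue_slope,
    rue_total,
)

STAGE_DAYS = {"E40": 40, "InB": 61, "A7": 83, "PM": 116}


class TestLightInterception:
    def test_hand_value(self):
        assert light_interception_pct(2000, 100, 400) == pytest.approx(100 * 1500 / 1900)

    def test_full_interception_and_transmission(self):
        assert light_interception_pct(1500, 0, 0) == 100.0
        assert light_interception_pct(1500, 0, 1500) == 0.0

    def test_reflected_exceeding_incident_errors(self):
        with pytest.raises(ValueError, match="PAR_i must exceed"):
            light_interception_pct(100, 100, 0)

    def test_inconsistent_sensor_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert light_interception_pct(1000, 100, 950) == 0.0

    def test_reading_invariants(self):
        with pytest.raises(ValueError):
            LightReading(PAR_i=0, PAR_r=0, PAR_g=0)
        with pytest.warns(UserWarning):
            LightReading(PAR_i=100, PAR_r=60, PAR_g=60)
        assert LightReading(2000, 100, 400).li_pct == pytest.approx(78.947, abs=1e-3)


class TestParConversion:
    def test_values_and_linearity(self):
        assert par_from_irradiance(20.0) == pytest.approx(9.0)
        assert par_from_irradiance(0.0) == 0.0
        s = pd.Series([10.0, 20.0, 30.0])
        assert par_from_irradiance(s).sum() == pytest.approx(0.45 * s.sum())

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            par_from_irradiance([-1.0])


class TestAccumulateIpar:
    def test_full_interception_constant_par(self):
        out = accumulate_ipar({"E40": 100.0}, 10.0 * np.ones(40), {"E40": 40})
        assert out["E40"] == pytest.approx(400.0)

    def test_li_scaling(self):
        out = accumulate_ipar({"E40": 50.0}, 10.0 * np.ones(40), {"E40": 40})
        assert out["E40"] == pytest.approx(200.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_daily_loop(self, seed):
        rng = np.random.default_rng(seed)
        par = rng.uniform(4, 12, size=116)
        li = {s: v for s, v in zip(("E40", "InB", "A7"), np.sort(rng.uniform(30, 99, 3)))}
        out = accumulate_ipar(li, par, STAGE_DAYS)
        days = np.arange(1, 117)
        li_t = np.interp(days, [40, 61, 83], [li["E40"], li["InB"], li["A7"]])
        cum = np.cumsum(par * li_t / 100.0)
        for s, d in STAGE_DAYS.items():
            assert out[s] == pytest.approx(cum[d - 1], abs=1e-9)

    def test_monotone_across_stages(self):
        rng = np.random.default_rng(1)
        out = accumulate_ipar(
            {"E40": 60.0, "A7": 95.0}, rng.uniform(2, 12, 116), STAGE_DAYS
        )
        vals = [out[s] for s in ("E40", "InB", "A7", "PM")]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_stage_outside_series_errors(self):
        with pytest.raises(ValueError, match="outside met series"):
            accumulate_ipar({"E40": 50.0}, np.ones(30), {"E40": 40})

    def test_grain_fill_split_sums_to_gf_total(self):
        rng = np.random.default_rng(2)
        par = rng.uniform(4, 12, size=116)
        li = {"E40": 60.0, "InB": 90.0, "A7": 95.0}
        acc = accumulate_ipar(li, par, STAGE_DAYS)
        gf = grain_fill_par(li, par, STAGE_DAYS)
        assert gf.mj_acc_75 + gf.mj_acc_25 == pytest.approx(acc["PM"] - acc["A7"], abs=1e-9)


class TestBiomass:
    def test_hand_value(self):
        h = HarvestRecord(total_FW=2000, subsample_FW=100, subsample_DW=20, harvested_area=0.8)
        assert aboveground_biomass(h) == pytest.approx(500.0)

    def test_fully_dry_subsample(self):
        h = HarvestRecord(total_FW=300, subsample_FW=50, subsample_DW=50, harvested_area=0.4)
        assert aboveground_biomass(h) == pytest.approx(300 / 0.4)

    def test_doubling_area_halves_result(self):
        a = HarvestRecord(total_FW=2000, subsample_FW=100, subsample_DW=20, harvested_area=0.4)
        b = HarvestRecord(total_FW=2000, subsample_FW=100, subsample_DW=20, harvested_area=0.8)
        assert aboveground_biomass(a) == pytest.approx(2 * aboveground_biomass(b))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            HarvestRecord(total_FW=100, subsample_FW=200, subsample_DW=20, harvested_area=0.8)
        with pytest.raises(ValueError):
            HarvestRecord(total_FW=100, subsample_FW=50, subsample_DW=20, harvested_area=0)


class TestRueWindows:
    def test_interval_hand_value(self):
        assert rue_interval(200, 500, 230, 380).rue == pytest.approx(2.0)

    def test_zero_growth(self):
        assert rue_interval(400, 400, 230, 380).rue == 0.0

    def test_equal_ipar_endpoints_error(self):
        with pytest.raises(ValueError):
            rue_interval(200, 500, 380, 380)

    def test_negative_rue_flagged(self):
        res = rue_interval(500, 400, 230, 380)
        assert res.flagged_negative

    def test_pre_grain_fill_is_ipar_weighted_combination(self):
        bm = dict(E40=200.0, InB=500.0, A7=900.0)
        ip = dict(E40=230.0, InB=380.0, A7=560.0)
        r1 = rue_interval(bm["E40"], bm["InB"], ip["E40"], ip["InB"]).rue
        r2 = rue_interval(bm["InB"], bm["A7"], ip["InB"], ip["A7"]).rue
        rp = rue_interval(bm["E40"], bm["A7"], ip["E40"], ip["A7"]).rue
        w = (ip["InB"] - ip["E40"]) / (ip["A7"] - ip["E40"])
        assert rp == pytest.approx(w * r1 + (1 - w) * r2, abs=1e-12)

    def test_grain_filling_hand_value(self):
        gf = GrainFillPAR(mj_acc_75=200, mj_acc_25=100)
        assert rue_grain_filling(1000, 1300, gf).rue == pytest.approx(300 / 250)

    def test_correction_vanishes_without_final_quarter(self):
        gf = GrainFillPAR(mj_acc_75=200, mj_acc_25=0)
        direct = rue_interval(1000, 1300, 0, 200).rue
        assert rue_grain_filling(1000, 1300, gf).rue == pytest.approx(direct)

    def test_half_weighting_increases_rue_vs_full_weight(self):
        gf = GrainFillPAR(mj_acc_75=200, mj_acc_25=100)
        full_weight = (1300 - 1000) / (gf.mj_acc_75 + gf.mj_acc_25)
        assert rue_grain_filling(1000, 1300, gf).rue > full_weight

    def test_total_hand_value(self):
        gf = GrainFillPAR(mj_acc_75=0, mj_acc_25=100)
        res = rue_total(200, 1400, acc_ipar_E40=230, acc_ipar_PM_75=750, gf=gf)
        assert res.rue == pytest.approx(1200 / (750 + 50 - 230), abs=1e-9)

    def test_total_denominator_is_sum_of_pregf_and_gf_denominators(self):
        ip_e40, ip_a7 = 230.0, 560.0
        gf = GrainFillPAR(mj_acc_75=180.0, mj_acc_25=60.0)
        den_pregf = ip_a7 - ip_e40
        den_gf = gf.effective
        acc_pm75 = ip_a7 + gf.mj_acc_75
        den_total = acc_pm75 + 0.5 * gf.mj_acc_25 - ip_e40
        assert den_total == pytest.approx(den_pregf + den_gf, abs=1e-12)

    def test_nonpositive_denominator_errors(self):
        with pytest.raises(ValueError):
            rue_grain_filling(1000, 1300, GrainFillPAR(0, 0))
        with pytest.raises(ValueError):
            rue_total(200, 1400, acc_ipar_E40=800, acc_ipar_PM_75=750, gf=GrainFillPAR(0, 0))

    def test_slope_method_recovers_linear_trajectory(self):
        ipar = np.array([230.0, 380.0, 560.0, 800.0])
        bm = 150.0 + 1.8 * ipar
        assert rue_slope(bm, ipar).rue == pytest.approx(1.8, abs=1e-12)
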
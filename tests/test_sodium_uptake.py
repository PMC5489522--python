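"""Shoot Na+ uptake chain: bypass water, suberin dynamics, mass delivery."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ricesalt.parameters import TraitParameters, AuxiliaryConstants, ConfigurationError
from ricesalt import sodium_uptake as su


@pytest.mark.parametrize(
    "rh,expected",
    [(0.0, 3.92), (92.0, -0.0275 * 92 + 3.92), (58.0, -0.0275 * 58 + 3.92)],
)
def test_relative_bypass_water_linear_form(rh, expected):
    assert su.relative_bypass_water(rh) == pytest.approx(expected, abs=1e-12)


def test_relative_bypass_water_rejects_out_of_range():
    with pytest.raises(ValueError):
        su.relative_bypass_water(-1.0)
    with pytest.raises(ValueError):
        su.relative_bypass_water(101.0)


@pytest.mark.parametrize(
    "tr,rjv,expected",
    [(0.0, 2.0, 0.0), (5.0, 2.0, 0.1), (4.0, -0.0275 * 92 + 3.92, 4 * 1.39 / 100)],
)
def test_bypass_water_flux(tr, rjv, expected):
    assert su.bypass_water_flux(tr, rjv) == pytest.approx(expected, abs=1e-12)


def test_bypass_water_flux_rejects_negative_transpiration():
    with pytest.raises(ValueError):
        su.bypass_water_flux(-0.1, 2.0)


class TestSuberinDeposition:
    def test_zero_salinity_no_induction(self):
        assert su.suberin_deposition_response(0.0, 400.0, 0.62) == 0.0

    def test_saturating_salinity_clamped_to_one(self):
        # literal value 1/(1-0.62) = 2.63 is clamped
        assert su.suberin_deposition_response(400.0, 400.0, 0.62) == 1.0

    def test_zero_efficiency_reduces_to_concentration_ratio(self):
        assert su.suberin_deposition_response(200.0, 400.0, 0.0) == pytest.approx(0.5)

    def test_full_efficiency_is_singular(self):
        with pytest.raises(ZeroDivisionError):
            su.suberin_deposition_response(10.0, 400.0, 1.0)


class TestSuberinContent:
    def test_full_signal_collapses_to_max(self):
        assert su.suberin_content(1.0, 1.0, 30.0) == pytest.approx(30.0)

    def test_maturity_without_signal_reaches_max(self):
        # 2 * 1.5 / 3 = 1 times sc_max
        assert su.suberin_content(2.0, 0.0, 30.0) == pytest.approx(30.0)

    def test_zero_at_emergence(self):
        assert su.suberin_content(0.0, 0.0, 30.0) == 0.0

    def test_degenerate_limit_returns_zero(self):
        assert su.suberin_content(0.0, 1.0, 30.0) == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        dvs=st.floats(0.0, 2.0),
        f1=st.floats(0.0, 1.0),
        f2=st.floats(0.0, 1.0),
        d2=st.floats(0.0, 2.0),
    )
    def test_monotone_in_age_and_signal(self, dvs, f1, f2, d2):
        sc_max = 30.0
        lo_f, hi_f = sorted((f1, f2))
        lo_d, hi_d = sorted((dvs, d2))
        # non-decreasing in DVS at fixed signal
        assert su.suberin_content(hi_d, lo_f, sc_max) >= su.suberin_content(lo_d, lo_f, sc_max) - 1e-12
        # non-decreasing in signal at fixed DVS > 0
        if lo_d > 0:
            assert su.suberin_content(lo_d, hi_f, sc_max) >= su.suberin_content(lo_d, lo_f, sc_max) - 1e-12
        assert su.suberin_content(dvs, f1, sc_max) <= sc_max + 1e-12


class TestRelativeBypassFlow:
    def test_endpoints(self, traits, aux):
        assert su.relative_bypass_flow(traits.sc_max, traits, aux) == pytest.approx(0.05)
        assert su.relative_bypass_flow(aux.sc_min, traits, aux) == pytest.approx(1.0)

    def test_midpoint_is_geometric_mean(self, traits, aux):
        mid = 0.5 * (aux.sc_min + traits.sc_max)
        assert su.relative_bypass_flow(mid, traits, aux) == pytest.approx(0.05**0.5, rel=1e-9)

    def test_literal_mode_matches_printed_formula(self, traits, aux):
        mid = 0.5 * (aux.sc_min + traits.sc_max)
        assert su.relative_bypass_flow(mid, traits, aux, literal_mode=True) == pytest.approx(
            0.01 * 5.0**0.5
        )

    def test_bad_configuration_rejected(self, traits):
        bad = AuxiliaryConstants(sc_min=traits.sc_max + 1.0)
        with pytest.raises(ConfigurationError):
            su.relative_bypass_flow(10.0, traits, bad)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(s1=st.floats(0.0, 40.0), s2=st.floats(0.0, 40.0))
    def test_monotone_non_increasing_in_suberin(self, traits, aux, s1, s2):
        lo, hi = sorted((s1, s2))
        rl = su.relative_bypass_flow(lo, traits, aux)
        rh = su.relative_bypass_flow(hi, traits, aux)
        assert rh <= rl + 1e-12
        assert 0.0 < rh <= 1.0


@pytest.mark.parametrize(
    "jv,rrbf,na,expected",
    [(0.1, 1.0, 0.0, 0.0), (0.1, 0.0, 10.0, 0.0), (0.1, 1.0, 10.0, 0.1 * 1e4 * 10 * 22.99)],
)
def test_apoplastic_na_uptake(jv, rrbf, na, expected):
    assert su.apoplastic_na_uptake(jv, rrbf, na) == pytest.approx(expected)


class TestTotalUptake:
    def test_zero_apoplastic_gives_zero(self, aux):
        assert su.total_na_uptake(0.0, 75.0, aux) == 0.0

    def test_share_arithmetic(self):
        aux = AuxiliaryConstants(bypass_share_at_lo=25.0, bypass_share_at_hi=25.0)
        assert su.total_na_uptake(100.0, 75.0, aux) == pytest.approx(400.0)

    def test_share_stays_in_reported_band(self, aux):
        # the apoplastic share of total uptake stays within the 22-35 % range
        for rh in (0.0, 58.0, 70.0, 92.0, 100.0):
            assert 22.0 <= aux.bypass_share(rh) <= 35.0
        assert aux.bypass_share(58.0) == pytest.approx(35.0)
        assert aux.bypass_share(92.0) == pytest.approx(22.0)


class TestDailyUptake:
    def test_zero_when_no_salt_or_no_transpiration(self, traits, aux):
        assert su.daily_shoot_uptake(5.0, 70.0, 0.0, 1.0, traits, aux) == 0.0
        assert su.daily_shoot_uptake(0.0, 70.0, 30.0, 1.0, traits, aux) == 0.0

    def test_total_at_least_apoplastic(self, traits, aux):
        rh, na, dvs, tr = 75.0, 30.0, 0.8, 4.0
        total = su.daily_shoot_uptake(tr, rh, na, dvs, traits, aux)
        jv = su.bypass_water_flux(tr, su.relative_bypass_water(rh))
        f = su.suberin_deposition_response(na, aux.max_na_ext, traits.sub_dep_eff)
        sc = su.suberin_content(dvs, f, traits.sc_max)
        ap = su.apoplastic_na_uptake(jv, su.relative_bypass_flow(sc, traits, aux), na)
        assert total >= ap > 0.0

    def test_dimensional_consistency_oracle(self, traits, aux):
        """One day's uptake recomputed from first principles (litres x mg/L)."""
        rh, na, dvs, tr = 75.0, 30.0, 0.8, 4.0
        # independent arithmetic: litres of bypass water, Na mass per litre,
        # suberin discount, apoplastic share of the total
        litres_transpired = tr * 1.0e4
        apoplastic_fraction_of_water = (-0.0275 * rh + 3.92) / 100.0
        mg_per_litre = na * 22.99
        f_sc = min((na / aux.max_na_ext) / (1.0 - traits.sub_dep_eff), 1.0)
        sc = traits.sc_max * dvs * (0.5 * (1 - f_sc) + 1) / ((1 - f_sc) + dvs)
        frac = (min(max(sc, aux.sc_min), traits.sc_max) - aux.sc_min) / (
            traits.sc_max - aux.sc_min
        )
        suberin_discount = math.exp(frac * math.log(traits.rrbf_min / 100.0))
        share = aux.bypass_share(rh) / 100.0
        expected = litres_transpired * apoplastic_fraction_of_water * mg_per_litre * suberin_discount / share
        got = su.daily_shoot_uptake(tr, rh, na, dvs, traits, aux)
        assert got == pytest.approx(expected, rel=1e-9)
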
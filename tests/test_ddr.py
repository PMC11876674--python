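"""DDR kinetics: repair modulation, conversion, damage balance, death rates."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddrtgi.ddr import (
    DDRParams,
    DamageState,
    conversion_rate,
    damage_derivatives,
    damage_steady_state,
    delayed_kill_rate,
    dsb_repair_rate,
    kill_rate,
    repair_modulation,
    ssb_repair_rate,
)


class TestRepairModulation:
    def test_intact_pathway_is_half(self):
        assert repair_modulation(0.0) == pytest.approx(0.5, abs=0)

    def test_full_inhibition_tends_to_zero(self):
        assert repair_modulation(800.0) == 0.0  # exp underflow floor
        assert repair_modulation(50.0) < 1e-20

    def test_ln3_gives_quarter(self):
        assert repair_modulation(math.log(3)) == pytest.approx(0.25, rel=1e-12)

    @given(a=st.floats(0.0, 100.0), b=st.floats(0.0, 100.0))
    def test_monotone_decreasing_and_bounded(self, a, b):
        sa, sb = repair_modulation(a), repair_modulation(b)
        assert 0.0 <= sa <= 0.5
        if a < b:
            assert sa >= sb


class TestConversionRate:
    def test_baseline_without_fork_effect(self):
        assert conversion_rate(0.05, 0.0) == pytest.approx(0.05)

    def test_fork_effect_accelerates(self):
        assert conversion_rate(0.05, 3.0) == pytest.approx(0.2)

    def test_ceiling_at_one(self):
        assert conversion_rate(0.1, 100.0) == 1.0


class TestRepairRates:
    def test_no_drug_no_deficiency_gives_baseline(self):
        p = DDRParams()
        assert ssb_repair_rate(p, 0.0, 0.0) == pytest.approx(p.rep_ssb)
        assert dsb_repair_rate(p, 0.0, 0.0) == pytest.approx(p.rep_dsb)

    def test_parpi_monotherapy_ssb_floor_50pct(self):
        # parallel ATR pathway intact: disruption capped at 50%
        p = DDRParams(def1=0.0, def2=0.0)
        assert ssb_repair_rate(p, 1e3, 0.0) == pytest.approx(0.5 * p.rep_ssb, rel=1e-9)

    def test_total_pathway_loss_gives_zero(self):
        p = DDRParams(def2=1.0)
        assert ssb_repair_rate(p, 1e3, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_hrd_background_reduces_dsb_repair(self):
        p = DDRParams(def3=0.0, def4=0.2)
        assert dsb_repair_rate(p, 0.0, 0.0) == pytest.approx(0.9 * p.rep_dsb)

    def test_deficiency_sums_with_drug_disruption(self):
        # PARPi saturation + innate HRD: total DSB disruption exceeds 50%
        p = DDRParams(def4=0.2)
        assert dsb_repair_rate(p, 1e3, 0.0) == pytest.approx(0.4 * p.rep_dsb, rel=1e-9)

    @given(
        i1=st.floats(0.0, 50.0),
        i2=st.floats(0.0, 50.0),
        d=st.floats(0.0, 1.0),
    )
    def test_monotone_nonincreasing_in_effects_and_deficiencies(self, i1, i2, d):
        p0 = DDRParams()
        pd = DDRParams(def1=d)
        assert ssb_repair_rate(p0, i1 + i2, 0.0) <= ssb_repair_rate(p0, i1, 0.0)
        assert ssb_repair_rate(pd, i1, 0.0) <= ssb_repair_rate(p0, i1, 0.0)
        assert dsb_repair_rate(DDRParams(def4=d), i1, i2) <= dsb_repair_rate(
            DDRParams(), i1, i2
        )

    def test_deficiencies_clamped_to_unit_interval(self):
        assert DDRParams(def4=1.7).def4 == 1.0
        assert DDRParams(def1=-0.3).def1 == 0.0


class TestDamageBalance:
    def test_pure_generation_grows_linearly(self):
        p = DDRParams(r_ssb=0.0005, r_dsb=0.0)
        s = DamageState(0.0, 0.0)
        dssb, _ = damage_derivatives(p, s, 0.0, 0.0, 0.0)
        assert dssb * 100.0 == pytest.approx(0.05)  # SSB after 100 h

    def test_conversion_flux_conserved_between_species(self):
        p = DDRParams(r_ssb=0.0, r_dsb=0.0)
        s = DamageState(ssb=2.0, dsb=0.5)
        dssb, ddsb = damage_derivatives(p, s, 0.3, 0.0, 0.0)
        assert dssb == pytest.approx(-ddsb)

    def test_integration_converges_to_closed_form_steady_state(self):
        # RK4 on the damage ODEs vs the algebraic fixed point
        p = DDRParams()
        rc, rs, rd = 0.002, 0.25, 0.45
        ssb_star, dsb_star = damage_steady_state(p, rc, rs, rd)
        s = DamageState(0.0, 0.0)
        dt = 0.05
        for _ in range(int(400 / dt)):
            def f(ssb, dsb):
                return damage_derivatives(p, DamageState(ssb, dsb), rc, rs, rd)

            k1 = f(s.ssb, s.dsb)
            k2 = f(s.ssb + dt / 2 * k1[0], s.dsb + dt / 2 * k1[1])
            k3 = f(s.ssb + dt / 2 * k2[0], s.dsb + dt / 2 * k2[1])
            k4 = f(s.ssb + dt * k3[0], s.dsb + dt * k3[1])
            s = DamageState(
                s.ssb + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]),
                s.dsb + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
            )
            assert s.ssb >= 0 and s.dsb >= 0
        assert s.ssb == pytest.approx(ssb_star, rel=1e-6)
        assert s.dsb == pytest.approx(dsb_star, rel=1e-6)


class TestDeathRates:
    def test_no_dsb_no_immediate_death(self):
        assert kill_rate(DDRParams(), "S", DamageState(5.0, 0.0)) == 0.0

    def test_immediate_death_linear_in_dsb(self):
        p = DDRParams(r_kill_phase={"G1": 0.0, "S": 0.002, "G2": 0.0, "M": 0.0})
        s = DamageState(0.0, 5.0)
        assert kill_rate(p, "S", s) == pytest.approx(0.01)
        assert kill_rate(p, "S", DamageState(0.0, 10.0)) == pytest.approx(0.02)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            kill_rate(DDRParams(), "G0", DamageState(0.0, 1.0))

    def test_delayed_death_zero_without_damage(self):
        assert delayed_kill_rate(DDRParams(), 3.0, DamageState(0.0, 0.0)) == 0.0

    def test_delayed_death_arithmetic(self):
        p = DDRParams(r_delay_kill=0.001)
        assert delayed_kill_rate(p, 0.0, DamageState(5.0, 1.0)) == pytest.approx(0.002)

    def test_ssb_weight_is_one_fifth_of_dsb(self):
        p = DDRParams(r_delay_kill=0.7)
        at_ssb = delayed_kill_rate(p, 0.0, DamageState(1.0, 0.0))
        at_dsb = delayed_kill_rate(p, 0.0, DamageState(0.0, 1.0))
        assert at_ssb / at_dsb == pytest.approx(0.2, rel=1e-12)
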
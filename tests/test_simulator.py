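"""Coupled simulator behaviour: growth fidelity, synergy, scans, numerics."""

import numpy as np
import pytest

from ddrtgi import (
    DDRParams,
    GrowthParams,
    Scenario,
    TumourSpec,
    dose_response_scan,
    hbcx9,
    panel_tumour,
    simulate,
)
from conftest import make_arm

DT = 0.5  # h; step-size convergence is asserted separately


@pytest.fixture(scope="module")
def hbcx9_arms():
    """Vehicle, monotherapy and combination arms for the first HBCx-9 study."""
    tum = hbcx9(1)
    arms = {
        "vehicle": make_arm(tum),
        "parpi": make_arm(tum, ("rucaparib", "50 mg/kg qd x35d")),
        "atri": make_arm(tum, ("gartisertib", "3 mg/kg qd x35d")),
        "combo": make_arm(
            tum,
            ("rucaparib", "50 mg/kg qd x35d"),
            ("gartisertib", "3 mg/kg qd x35d"),
        ),
    }
    return {k: simulate(sc, dt_max=DT).series for k, sc in arms.items()}


class TestVehicleGrowth:
    def test_vehicle_volume_nondecreasing(self, hbcx9_arms):
        assert np.all(np.diff(hbcx9_arms["vehicle"].volumes) >= 0)

    def test_unconstrained_growth_doubles_at_t_doub(self):
        # huge shell: no quiescence; asymptotic doubling time = t_doub
        tum = TumourSpec(DDRParams(), GrowthParams(t_doub=27.0, v0=1.0,
                                                   shell_thickness=1e9))
        res = simulate(Scenario(tum, [], horizon_days=28.0), dt_max=DT).series
        slope = np.polyfit(res.days[-10:] * 24.0, np.log2(res.volumes[-10:]), 1)[0]
        assert 1.0 / slope == pytest.approx(27.0, rel=0.01)

    def test_simulation_deterministic(self, hbcx9_arms):
        tum = hbcx9(1)
        sc = make_arm(tum, ("rucaparib", "50 mg/kg qd x35d"))
        again = simulate(sc, dt_max=DT).series
        assert np.array_equal(again.volumes, hbcx9_arms["parpi"].volumes)


class TestEmergentSynergy:
    def test_combination_beats_both_monotherapies_everywhere(self, hbcx9_arms):
        lo = np.minimum(hbcx9_arms["parpi"].volumes, hbcx9_arms["atri"].volumes)
        assert np.all(hbcx9_arms["combo"].volumes <= lo * (1 + 1e-9))

    def test_monotherapies_do_not_beat_vehicle_upward(self, hbcx9_arms):
        for arm in ("parpi", "atri", "combo"):
            assert np.all(
                hbcx9_arms[arm].volumes
                <= hbcx9_arms["vehicle"].volumes * (1 + 1e-9)
            )

    def test_hrd_strengthens_parpi_monotherapy(self):
        # raising def4 under PARPi monotherapy strictly lowers final volume
        finals = []
        for def4 in (0.0, 0.8):
            tum = hbcx9(1).with_(def4=def4)
            sc = make_arm(tum, ("talazoparib", "0.3 mg/kg qd x28d"), horizon=28)
            finals.append(simulate(sc, dt_max=DT).series.final_volume)
        assert finals[1] < finals[0]

    def test_atri_on_top_of_parpi_never_lowers_dsb(self):
        tum = hbcx9(1)
        mono = make_arm(tum, ("talazoparib", "0.3 mg/kg qd x21d"), horizon=21)
        combo = make_arm(
            tum,
            ("talazoparib", "0.3 mg/kg qd x21d"),
            ("gartisertib", "3 mg/kg qd x21d"),
            horizon=21,
        )
        tr_m = simulate(mono, dt_max=DT, record_trace=True).trace
        tr_c = simulate(combo, dt_max=DT, record_trace=True).trace
        assert np.all(tr_c["dsb"].to_numpy() >= tr_m["dsb"].to_numpy() * (1 - 1e-9))


class TestPotencyOrdering:
    def test_talazoparib_outperforms_rucaparib_at_equal_exposure(self):
        # same PK and schedule for both agents: only mechanism params differ
        from ddrtgi import DRUGS, Treatment, parse_regimen
        from ddrtgi.params import DEFAULT_PK

        pk = DEFAULT_PK["rucaparib"]
        sched = parse_regimen("0.5 mg/kg qd x28d", drug_id="x")
        finals = {}
        for name in ("rucaparib", "talazoparib"):
            sc = Scenario(hbcx9(1), [Treatment(DRUGS[name], pk, sched)], 28.0)
            finals[name] = simulate(sc, dt_max=DT).series.final_volume
        assert finals["talazoparib"] < finals["rucaparib"]

    def test_repair_inhibition_saturates_at_high_exposure(self):
        # doubling an already saturating dose changes repair rates by < 1%
        from ddrtgi.ddr import repair_modulation, ssb_repair_rate

        tum = hbcx9(1)
        rates = []
        for dose in ("5 mg/kg qd x14d", "10 mg/kg qd x14d"):
            sc = make_arm(tum, ("talazoparib", dose), horizon=14)
            tr = simulate(sc, dt_max=DT, record_trace=True).trace
            mid = tr[(tr.t_h > 48) & (tr.t_h < 14 * 24)]
            rates.append(
                np.array([ssb_repair_rate(tum.ddr, i, 0.0) for i in mid["I_p_ssb"]])
            )
        rel = np.abs(rates[1] - rates[0]) / rates[0]
        assert np.max(rel) < 0.01


class TestDoseResponseScan:
    def test_zero_dose_reproduces_vehicle(self):
        tum = panel_tumour("BRCA-mut-a")
        sc = make_arm(tum, ("talazoparib", "0.3 mg/kg qd x28d"), horizon=28)
        veh = simulate(make_arm(tum, horizon=28), dt_max=DT).series
        df = dose_response_scan(sc, "talazoparib", [0.0, 0.3], dt_max=DT)
        assert df.loc[df.dose == 0.0, "final_volume_mm3"].iloc[0] == pytest.approx(
            veh.final_volume, rel=1e-12
        )

    def test_final_volume_nonincreasing_in_dose(self):
        tum = panel_tumour("BRCA-mut-a")
        sc = make_arm(tum, ("talazoparib", "0.3 mg/kg qd x28d"), horizon=28)
        df = dose_response_scan(sc, "talazoparib", [0.0, 0.03, 0.3, 3.0], dt_max=DT)
        assert np.all(np.diff(df["final_volume_mm3"]) <= 1e-9)

    def test_atri_backbone_lowers_parpi_stasis_dose(self):
        # dose-reduction logic: combination reaches stasis at lower PARPi dose
        tum = hbcx9(1).with_(def4=0.5)
        grid = [0.01, 0.1, 1.0, 10.0]
        mono = make_arm(tum, ("talazoparib", "0.3 mg/kg qd x28d"), horizon=28)
        combo = make_arm(
            tum,
            ("talazoparib", "0.3 mg/kg qd x28d"),
            ("gartisertib", "3 mg/kg qd x28d"),
            horizon=28,
        )
        med_mono = dose_response_scan(mono, "talazoparib", grid, dt_max=DT).attrs[
            "min_effective_dose"
        ]
        med_combo = dose_response_scan(combo, "talazoparib", grid, dt_max=DT).attrs[
            "min_effective_dose"
        ]
        if np.isnan(med_mono):
            med_mono = np.inf
        assert med_combo <= med_mono


class TestNumerics:
    def test_step_size_convergence(self):
        tum = hbcx9(1)
        sc = make_arm(
            tum,
            ("rucaparib", "50 mg/kg qd x21d"),
            ("gartisertib", "3 mg/kg qd x21d"),
            horizon=21,
        )
        coarse = simulate(sc, dt_max=1.0).series.volumes
        fine = simulate(sc, dt_max=0.5).series.volumes
        assert np.max(np.abs(coarse - fine) / fine) < 0.005

    def test_state_never_negative(self):
        tum = panel_tumour("BRCA-mut-a")
        sc = make_arm(
            tum,
            ("talazoparib", "1 mg/kg qd x21d"),
            ("gartisertib", "10 mg/kg qd x21d"),
            horizon=21,
        )
        tr = simulate(sc, dt_max=DT, record_trace=True).trace
        for col in ("volume_mm3", "ssb", "dsb", "live", "doomed", "quiescent", "dead"):
            assert np.all(tr[col].to_numpy() >= 0)

    def test_horizon_must_cover_last_dose(self):
        tum = hbcx9(1)
        with pytest.raises(ValueError):
            make_arm(tum, ("rucaparib", "50 mg/kg qd x35d"), horizon=20)

    def test_two_parpis_rejected(self):
        from ddrtgi import DRUGS, Treatment, parse_regimen
        from ddrtgi.params import DEFAULT_PK

        sched = parse_regimen("1 mg/kg qd x7d", drug_id="x")
        trs = [
            Treatment(DRUGS["rucaparib"], DEFAULT_PK["rucaparib"], sched),
            Treatment(DRUGS["talazoparib"], DEFAULT_PK["talazoparib"], sched),
        ]
        with pytest.raises(ValueError):
            Scenario(hbcx9(1), trs, 14.0)
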
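"""YAML study configuration -> scenarios.

A config file describes one study::

    tumour: {t_doub: 27, def4: 0.2, v0: 100}      # DDR + growth fields mixed
    drugs:                                        # optional custom mechanisms
      mydrug: {kind: parpi, i_p_ssb: 5, i_p_fork: 0.5, cl_p: 0.15, cl_p_fork: 0.45}
    pk:                                           # optional per-drug PK
      rucaparib: {ka: 2.0, ke: 0.3, v_f: 2.0}
    horizon_days: 42
    output_days: [0, 3, 7, ...]                   # optional, default daily
    arms:
      vehicle: {}
      rucaparib_qd: {rucaparib: "50 mg/kg qd x35d"}
      combo:
        rucaparib: "50 mg/kg qd x35d"
        gartisertib: "3 mg/kg qd x35d"

Drug names resolve against the built-in mechanisms (rucaparib, talazoparib,
gartisertib) unless redefined under ``drugs``; PK falls back to the built-in
synthetic defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .ddr import DDRParams
from .effects import atri, parpi
from .growth import GrowthParams
from .regimen import PKParams, parse_regimen
from .simulate import Scenario, Treatment, TumourSpec

__all__ = ["load_study", "tumour_from_dict"]


def tumour_from_dict(d: dict) -> TumourSpec:
    """Build a tumour bundle from a flat dict of DDR and growth fields."""
    ddr_names = set(DDRParams.__dataclass_fields__)
    growth_names = set(GrowthParams.__dataclass_fields__)
    ddr_kw = {k: v for k, v in d.items() if k in ddr_names}
    growth_kw = {k: v for k, v in d.items() if k in growth_names}
    unknown = set(d) - ddr_names - growth_names
    if unknown:
        raise ValueError(f"unknown tumour parameters: {sorted(unknown)}")
    return TumourSpec(DDRParams(**ddr_kw), GrowthParams(**growth_kw))


def _drug_from_dict(name: str, d: dict):
    kind = d.get("kind")
    if kind == "parpi":
        return parpi(name, d["i_p_ssb"], d["i_p_fork"], d["cl_p"], d["cl_p_fork"],
                     i_p_dsb=d.get("i_p_dsb"))
    if kind == "atri":
        return atri(name, d["i_a_ssb"], d["o_a"], d["cl_a"], i_a_dsb=d.get("i_a_dsb"))
    raise ValueError(f"drug {name!r}: kind must be 'parpi' or 'atri'")


def load_study(path: str | Path) -> dict:
    """Load a study config; returns {arm name: Scenario}."""
    from .params import DEFAULT_PK, DRUGS

    cfg = yaml.safe_load(Path(path).read_text())
    tumour = tumour_from_dict(cfg.get("tumour", {}))
    horizon = float(cfg.get("horizon_days", 42.0))
    output_days = cfg.get("output_days")

    drugs = dict(DRUGS)
    for name, d in (cfg.get("drugs") or {}).items():
        drugs[name] = _drug_from_dict(name, d)
    pk = dict(DEFAULT_PK)
    for name, d in (cfg.get("pk") or {}).items():
        pk[name] = PKParams(**d)

    scenarios = {}
    for arm, regimens in (cfg.get("arms") or {}).items():
        treatments = []
        for drug_name, expr in (regimens or {}).items():
            if drug_name not in drugs:
                raise ValueError(f"arm {arm!r}: unknown drug {drug_name!r}")
            if drug_name not in pk:
                raise ValueError(f"arm {arm!r}: no PK parameters for {drug_name!r}")
            schedule = parse_regimen(expr, drug_id=drug_name)
            if len(schedule):
                treatments.append(Treatment(drugs[drug_name], pk[drug_name], schedule))
        scenarios[arm] = Scenario(tumour, treatments, horizon, output_days)
    return scenarios
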
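"""Built-in parameter sets: drug mechanisms, tumour models, default PK.

Drug mechanism-of-action parameters (unit potencies and effect clearances)
and HBCx-9 tumour parameters are the calibrated preclinical values for
rucaparib, talazoparib and gartisertib.  Plasma PK parameters are NOT part
of that calibration: the values in :data:`DEFAULT_PK` are synthetic
placeholders with plausible small-molecule oral kinetics in mouse, supplied
so that end-to-end simulations run out of the box; replace them with real
PK fits for quantitative work.
"""

from __future__ import annotations

from .ddr import DDRParams
from .effects import DrugParams, atri, parpi
from .growth import GrowthParams
from .regimen import PKParams
from .simulate import TumourSpec

__all__ = [
    "RUCAPARIB",
    "TALAZOPARIB",
    "GARTISERTIB",
    "DRUGS",
    "DEFAULT_PK",
    "HBCX9_STUDIES",
    "hbcx9",
    "PDX_PANEL",
    "panel_tumour",
]

# PARPi: i_p_dsb defaults to i_p_ssb; cl_p shared by the SSB/DSB channels.
RUCAPARIB = parpi("rucaparib", i_p_ssb=5.0, i_p_fork=0.5, cl_p=0.15, cl_p_fork=0.45)
TALAZOPARIB = parpi("talazoparib", i_p_ssb=100.0, i_p_fork=170.0, cl_p=0.15, cl_p_fork=0.45)
# ATRi: i_a_dsb defaults to i_a_ssb/2; one shared effect clearance.
GARTISERTIB = atri("gartisertib", i_a_ssb=7.0, o_a=20.0, cl_a=0.15)

DRUGS: dict[str, DrugParams] = {
    d.drug_id: d for d in (RUCAPARIB, TALAZOPARIB, GARTISERTIB)
}

#: Synthetic one-compartment PK defaults (ka, ke in 1/h; V/F in L/kg) — not
#: calibrated values; see module docstring.
DEFAULT_PK: dict[str, PKParams] = {
    "rucaparib": PKParams(ka=2.0, ke=0.3, v_f=2.0),
    "talazoparib": PKParams(ka=2.0, ke=0.2, v_f=5.0),
    "gartisertib": PKParams(ka=1.5, ke=0.25, v_f=3.0),
}

#: Tumour-specific (t_doub hours, def4) pairs for the four HBCx-9 calibration
#: studies; def1-3 = 0 and r_ssb = 5e-4 DAU/h in all four.
HBCX9_STUDIES: dict[int, dict] = {
    1: {"t_doub": 27.0, "def4": 0.20},
    2: {"t_doub": 31.0, "def4": 0.20},
    3: {"t_doub": 34.0, "def4": 0.10},
    4: {"t_doub": 33.0, "def4": 0.30},
}


def hbcx9(study: int = 1, v0: float = 100.0) -> TumourSpec:
    """Tumour bundle for one of the four HBCx-9 calibration studies."""
    try:
        p = HBCX9_STUDIES[study]
    except KeyError:
        raise ValueError(f"study must be one of {sorted(HBCX9_STUDIES)}") from None
    return TumourSpec(
        ddr=DDRParams(r_ssb=5e-4, def4=p["def4"]),
        growth=GrowthParams(t_doub=p["t_doub"], v0=v0),
    )


#: Virtual TNBC PDX panel grouped by genetic background.  BRCA-mutant models
#: carry a strongly impaired HR pathway (def4 > 0.8); BRCA-wild-type HRD+
#: models mid-range def4; HRD- models def4 = 0 with reduced endogenous SSB
#: generation (a more competent DDR system).  t_doub spreads the growth rates.
PDX_PANEL: dict[str, dict] = {
    "BRCA-mut-a": {"group": "BRCA-mutant", "t_doub": 28.0, "def4": 0.92, "r_ssb": 5e-4},
    "BRCA-mut-b": {"group": "BRCA-mutant", "t_doub": 35.0, "def4": 0.88, "r_ssb": 5e-4},
    "BRCA-mut-c": {"group": "BRCA-mutant", "t_doub": 31.0, "def4": 0.60, "r_ssb": 5e-4},
    "HRDpos-a": {"group": "BRCA-wt HRD+", "t_doub": 27.0, "def4": 0.50, "r_ssb": 5e-4},
    "HRDpos-b": {"group": "BRCA-wt HRD+", "t_doub": 33.0, "def4": 0.30, "r_ssb": 5e-4},
    "HRDpos-c": {"group": "BRCA-wt HRD+", "t_doub": 30.0, "def4": 0.80, "def3": 0.3,
                 "r_ssb": 5e-4},
    "HRDneg-a": {"group": "HRD-", "t_doub": 25.0, "def4": 0.0, "r_ssb": 2e-4},
    "HRDneg-b": {"group": "HRD-", "t_doub": 36.0, "def4": 0.0, "r_ssb": 2e-4},
    "HRDneg-c": {"group": "HRD-", "t_doub": 30.0, "def4": 0.0, "r_ssb": 3e-4},
}


def panel_tumour(name: str, v0: float = 100.0) -> TumourSpec:
    """Tumour bundle for one member of the virtual PDX panel."""
    try:
        p = dict(PDX_PANEL[name])
    except KeyError:
        raise ValueError(f"unknown PDX {name!r}; choose from {sorted(PDX_PANEL)}") from None
    p.pop("group")
    t_doub = p.pop("t_doub")
    return TumourSpec(ddr=DDRParams(**p), growth=GrowthParams(t_doub=t_doub, v0=v0))
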
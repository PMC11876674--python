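# ddrtgi

Semi-mechanistic PK-PD simulation of in vivo tumour growth inhibition (TGI)
by PARP and ATR inhibitors, for preclinical modellers who need to explore
dosing regimens, drug combinations and tumour genetic backgrounds in silico
before committing to mouse studies.

## The model

Plasma concentration `C(t)` from a one-compartment oral PK model drives six
slow drug-effect compartments (PARPi: SSB-repair inhibition `I_p_ssb`,
DSB-repair inhibition `I_p_dsb`, fork effect `I_p_fork`; ATRi: `I_a_ssb`,
`I_a_dsb`, checkpoint override `O_a`):

    dX/dt = u_x C(t) − Cl_x X

Effects act on a two-species DNA-damage system over the proliferating cells
(single- and double-strand breaks, in arbitrary damage units):

    dSSB/dt = r_ssb − R_conv SSB − R_ssb SSB
    dDSB/dt = r_dsb + R_conv SSB − R_dsb DSB

with S-phase-gated conversion `R_conv = min(1, r_conv (1 + I_p_fork))` and
dual-pathway repair, one PARP-mediated and one ATR-mediated branch per
damage type, each weakened by drug effect and genetic deficiency:

    R_ssb = rep_ssb [(1−def1) σ(I_p_ssb) + (1−def2) σ(I_a_ssb)]
    R_dsb = rep_dsb [(1−def3) σ(I_p_dsb) + (1−def4) σ(I_a_dsb)]
    σ(I)  = e^−I / (1 + e^−I)

Since `σ(0) = 1/2`, fully inhibiting one pathway removes at most 50% of
repair while its parallel partner is intact: synthetic lethality and
PARPi+ATRi synergy emerge from the pathway structure, with no explicit
interaction factor.  `def4` abstracts homologous-recombination deficiency
(BRCA/HRD status).  Damage kills cells immediately (`r_kill^(phase) DSB`,
phase-dependent) and through delayed death
`(r_delay_kill + O_a)(0.2 SSB + DSB)`, in which cells keep dividing for a
few generations before dying.  The tumour itself is a sphere with a
proliferating shell and quiescent core, its cell cycle discretised into
transit-compartment chains, and volume read out from total cell-equivalents.

The package bundles calibrated mechanism parameters for rucaparib,
talazoparib and gartisertib, four HBCx-9 tumour parameter sets, a virtual
TNBC PDX panel, a calibration engine that fits tumour-specific parameters
(`t_doub`, `def1–4`, `r_ssb`) to TGI time series with drug parameters held
fixed, and a synthetic-study generator (arm structure, inter-animal
variability, observation noise, welfare drop-out).

## Worked example

```python
from ddrtgi import DRUGS, Scenario, Treatment, hbcx9, parse_regimen, simulate
from ddrtgi.params import DEFAULT_PK

tumour = hbcx9(1)          # t_doub = 27 h, def4 = 20%
def arm(*drugs):
    ts = [Treatment(DRUGS[n], DEFAULT_PK[n], parse_regimen(r, drug_id=n))
          for n, r in drugs]
    return Scenario(tumour, ts, horizon_days=42)

for name, sc in {
    "vehicle":     arm(),
    "rucaparib":   arm(("rucaparib", "50 mg/kg qd x35d")),
    "gartisertib": arm(("gartisertib", "3 mg/kg qd x35d")),
    "combination": arm(("rucaparib", "50 mg/kg qd x35d"),
                       ("gartisertib", "3 mg/kg qd x35d")),
}.items():
    s = simulate(sc, dt_max=0.5).series
    print(name, round(s.volumes[14]), round(s.final_volume))
```

prints (day-14 and day-42 volumes, mm³):

```
vehicle 572 4124
rucaparib 533 3689
gartisertib 461 2677
combination 129 94
```

Neither monotherapy controls this HR-intermediate tumour — the PARPi alone
can disrupt at most half of SSB repair, and the ATRi alone leaves the
PARP-mediated branch intact — but the combination impairs both branches of
both repair pathways at once and regresses the tumour below its 100 mm³
starting volume.  `examples/` contains this script plus dose-response
scanning, the PDX panel, and synthetic-study generation + parameter
recovery; `examples/study_hbcx9.yaml` drives the equivalent CLI
(`ddrtgi simulate --config examples/study_hbcx9.yaml --arm combo_qd --out tgi.csv`).

Note the shipped plasma-PK parameter values are synthetic defaults with
plausible mouse oral kinetics (see `ddrtgi.params.DEFAULT_PK`); substitute
fitted PK models for quantitative exposure work.

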
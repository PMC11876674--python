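"""Simulate vehicle, monotherapy and combination arms in HBCx-9.

Builds the first HBCx-9 parameter set (t_doub = 27 h, def4 = 20%), doses
rucaparib 50 mg/kg qd and gartisertib 3 mg/kg qd for 35 days, and prints the
tumour volume at a few milestones.  The combination regresses the tumour
although neither monotherapy does: both DSB repair pathways are impaired at
once, so damage accumulates and drives immediate and delayed cell death —
synergy emerges from the pathway structure with no interaction factor.
"""

import numpy as np

from ddrtgi import DRUGS, Scenario, Treatment, hbcx9, parse_regimen, simulate
from ddrtgi.params import DEFAULT_PK


def arm(tumour, *drugs, horizon=42.0):
    treatments = [
        Treatment(DRUGS[n], DEFAULT_PK[n], parse_regimen(expr, drug_id=n))
        for n, expr in drugs
    ]
    return Scenario(tumour, treatments, horizon)


tumour = hbcx9(1)
arms = {
    "vehicle": arm(tumour),
    "rucaparib 50 qd": arm(tumour, ("rucaparib", "50 mg/kg qd x35d")),
    "gartisertib 3 qd": arm(tumour, ("gartisertib", "3 mg/kg qd x35d")),
    "combination": arm(
        tumour,
        ("rucaparib", "50 mg/kg qd x35d"),
        ("gartisertib", "3 mg/kg qd x35d"),
    ),
}

print(f"{'arm':<18}{'day 7':>9}{'day 14':>9}{'day 28':>9}{'day 42':>9}   (mm^3)")
for name, sc in arms.items():
    s = simulate(sc, dt_max=0.5).series
    idx = np.searchsorted(s.days, [7, 14, 28, 42])
    print(f"{name:<18}" + "".join(f"{s.volumes[i]:>9.0f}" for i in idx))

print(
    "\nDosing ends at day 35; the combination arm regresses below the"
    " 100 mm^3 starting volume while both monotherapies track the vehicle."
)
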
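"""Generate a synthetic TGI study and recover the tumour parameters.

Simulates a 3-arm mouse study (vehicle, PARPi, combination; 5 animals per
arm, lognormal inter-animal variability on doubling time, multiplicative
observation noise, drop-out at 2000 mm^3) from known tumour parameters,
then refits cell doubling time and the HR deficiency def4 to the arm means.
Drug mechanism parameters are held fixed structurally — only tumour biology
is free, mirroring how such models are calibrated across studies.
"""

import numpy as np

from ddrtgi import DRUGS, Scenario, TGITimeSeries, Treatment, TumourSpec, parse_regimen
from ddrtgi.calibrate import FitSpec, fit
from ddrtgi.ddr import DDRParams
from ddrtgi.growth import GrowthParams
from ddrtgi.params import DEFAULT_PK
from ddrtgi.synth import StudyDesign, generate_study

truth = {"t_doub": 30.0, "def4": 0.5}
tumour = TumourSpec(DDRParams(def4=truth["def4"]), GrowthParams(t_doub=truth["t_doub"]))
days = np.arange(0.0, 29.0, 4.0)


def arm(*drugs):
    trs = [
        Treatment(DRUGS[n], DEFAULT_PK[n], parse_regimen(e, drug_id=n))
        for n, e in drugs
    ]
    return Scenario(tumour, trs, 28.0, days)


arms = {
    "vehicle": arm(),
    "parpi": arm(("talazoparib", "0.3 mg/kg qd x28d")),
    "combo": arm(
        ("talazoparib", "0.3 mg/kg qd x28d"), ("gartisertib", "10 mg/kg qd x28d")
    ),
}
design = StudyDesign(arms=arms, n_animals=5, observation_days=days, seed=7, dt_max=0.5)
animals, summary = generate_study(design)
print(f"generated {len(animals)} observations from {design.n_animals} animals x {len(arms)} arms")

datasets = [
    (TGITimeSeries(sub["day"].to_numpy(), sub["mean"].to_numpy()), arms[name])
    for name, sub in summary.groupby("arm")
]
res = fit(FitSpec(["t_doub", "def4"], datasets, n_starts=1, max_nfev=60, dt_max=0.5))

print(f"objective (log10-volume RMSE): {res.objective:.4f}")
for name, est in res.estimates.items():
    print(f"  {name:7s} estimate {est:7.3f}   truth {truth[name]:7.3f}")
print(
    "\nThe vehicle arm pins the doubling time; the PARPi arm's response"
    " identifies def4.  Estimates land within the noise of a 5-animal study."
)
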
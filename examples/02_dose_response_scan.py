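"""Dose-response scan: how far can the PARPi dose drop next to an ATRi?

Scans talazoparib doses in an HR-intermediate tumour (def4 = 0.5), alone and
on top of a fixed gartisertib backbone, and reports the smallest dose that
achieves stasis (final volume at or below the starting 100 mm^3).  The
backbone impairs the parallel repair pathway, so much less PARP inhibition
is needed for the same effect.
"""

from ddrtgi import DRUGS, Scenario, Treatment, dose_response_scan, hbcx9, parse_regimen
from ddrtgi.params import DEFAULT_PK

tumour = hbcx9(1).with_(def4=0.5)
doses = [0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0]


def scenario(with_backbone: bool) -> Scenario:
    treatments = [
        Treatment(
            DRUGS["talazoparib"],
            DEFAULT_PK["talazoparib"],
            parse_regimen("0.3 mg/kg qd x28d", drug_id="talazoparib"),
        )
    ]
    if with_backbone:
        treatments.append(
            Treatment(
                DRUGS["gartisertib"],
                DEFAULT_PK["gartisertib"],
                parse_regimen("3 mg/kg qd x28d", drug_id="gartisertib"),
            )
        )
    return Scenario(tumour, treatments, 28.0)


for label, backbone in [("talazoparib alone", False), ("+ gartisertib 3 qd", True)]:
    df = dose_response_scan(scenario(backbone), "talazoparib", doses, dt_max=0.5)
    med = df.attrs["min_effective_dose"]
    print(f"\n{label}")
    for _, row in df.iterrows():
        flag = " <- stasis" if row.stasis and row.dose > 0 else ""
        print(f"  {row.dose:6.2f} mg/kg -> day-28 volume {row.final_volume_mm3:8.1f} mm^3{flag}")
    print(f"  minimum dose achieving stasis: {med} mg/kg")
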
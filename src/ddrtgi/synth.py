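"""Synthetic TGI study generator.

Emulates the structure of preclinical mouse TGI studies: several treatment
arms of N = 7-9 animals observed over a few weeks, with inter-animal
variability (lognormal multiplier on cell doubling time — the dominant
source of within-arm spread), multiplicative lognormal observation noise on
measured volumes, and drop-out once an animal's tumour exceeds a welfare
volume cap, after which it contributes no further records.

All randomness flows from one seeded generator per study; animals are drawn
in a fixed order, so a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import Scenario, Treatment, simulate

__all__ = ["StudyDesign", "generate_study"]


@dataclass
class StudyDesign:
    """Design of one synthetic study.

    ``arms`` maps arm name -> Scenario.  ``noise_sd`` is the residual
    lognormal observation noise in log10 units; ``t_doub_sd`` the lognormal
    (natural-log) sd of the per-animal doubling-time multiplier;
    ``dropout_volume`` the censoring cap in mm^3.
    """

    arms: dict
    n_animals: int = 7
    observation_days: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 43.0, 3.0)
    )
    noise_sd: float = 0.05
    t_doub_sd: float = 0.10
    dropout_volume: float = 2000.0
    seed: int = 0
    dt_max: float = 0.5

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.noise_sd < 0 or self.t_doub_sd < 0:
            raise ValueError("noise and variability must be >= 0")
        if self.dropout_volume <= 0:
            raise ValueError("dropout_volume must be > 0")
        self.observation_days = np.asarray(self.observation_days, dtype=float)


def _animal_scenario(sc: Scenario, t_doub_mult: float, days: np.ndarray) -> Scenario:
    tumour = sc.tumour.with_(t_doub=sc.tumour.growth.t_doub * t_doub_mult)
    return Scenario(tumour, sc.treatments, sc.horizon_days, days)


def generate_study(design: StudyDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every animal of every arm and summarise per arm.

    Returns ``(animals, summary)``: per-animal long table with columns
    study, arm, animal_id, day, volume_mm3 (records after the first
    cap-exceeding day are censored), and an arm-level summary with n, mean
    and SEM over surviving animals per day.
    """
    rng = np.random.default_rng(design.seed)
    days = design.observation_days
    rows = []
    for arm_name, sc in design.arms.items():
        if np.any(days > sc.horizon_days):
            raise ValueError(f"observation days exceed horizon of arm {arm_name!r}")
        for animal in range(design.n_animals):
            mult = float(np.exp(rng.normal(0.0, design.t_doub_sd)))
            res = simulate(_animal_scenario(sc, mult, days), dt_max=design.dt_max)
            noise = rng.normal(0.0, design.noise_sd, size=days.size)
            observed = res.series.volumes * 10.0**noise
            over = np.nonzero(observed > design.dropout_volume)[0]
            last = over[0] if over.size else days.size - 1
            for i in range(last + 1):
                rows.append(
                    {
                        "arm": arm_name,
                        "animal_id": f"{arm_name}-{animal + 1:02d}",
                        "day": days[i],
                        "volume_mm3": observed[i],
                    }
                )
    animals = pd.DataFrame(rows)
    summary = (
        animals.groupby(["arm", "day"], sort=False)["volume_mm3"]
        .agg(n="count", mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    return animals, summary
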
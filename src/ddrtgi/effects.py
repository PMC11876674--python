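"""Drug-effect compartments linking plasma PK to pharmacodynamic action.

Every pharmacodynamic action of a PARP or ATR inhibitor is mediated by an
abstract effect level X(t) obeying

    dX/dt = u_x * C(t) - Cl_x * X,

where C(t) is the drug's plasma concentration, u_x the unit potency of the
effect and Cl_x its first-order clearance.  Because Cl_x is generally slower
than the drug's elimination, effects are temporally dissociated from PK and
persist after washout — which is what lets intermittent regimens retain
activity between dosing weeks.

Six effect channels exist.  A PARP inhibitor drives SSB-repair inhibition,
DSB-repair inhibition and a replication-fork effect; an ATR inhibitor drives
SSB-repair inhibition, DSB-repair inhibition and a cell-cycle checkpoint
override.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CHANNELS",
    "PARPI_CHANNELS",
    "ATRI_CHANNELS",
    "DrugParams",
    "parpi",
    "atri",
    "EffectParams",
    "effect_derivative",
    "effect_step_exact",
]

#: Canonical channel order used throughout the simulator.
CHANNELS = ("I_p_ssb", "I_p_dsb", "I_p_fork", "I_a_ssb", "I_a_dsb", "O_a")
PARPI_CHANNELS = CHANNELS[:3]
ATRI_CHANNELS = CHANNELS[3:]

CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}


@dataclass(frozen=True)
class EffectParams:
    """Potency/clearance pair for one effect channel of one agent."""

    channel: str
    drug_id: str
    u_x: float  # effect units per (mg/L) per h
    cl_x: float  # 1/h

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.u_x < 0:
            raise ValueError("unit potency u_x must be >= 0")
        if self.cl_x <= 0:
            raise ValueError("effect clearance cl_x must be > 0")


@dataclass(frozen=True)
class DrugParams:
    """Mechanism-of-action parameters for one agent.

    ``kind`` is "parpi" or "atri"; ``potencies`` and ``clearances`` map the
    agent's three channels to u_x and Cl_x values.  Use :func:`parpi` /
    :func:`atri` to build instances with the standard coupling defaults.
    """

    drug_id: str
    kind: str
    potencies: dict = field(default_factory=dict)
    clearances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = PARPI_CHANNELS if self.kind == "parpi" else ATRI_CHANNELS
        if self.kind not in ("parpi", "atri"):
            raise ValueError("kind must be 'parpi' or 'atri'")
        if set(self.potencies) != set(expected) or set(self.clearances) != set(expected):
            raise ValueError(f"{self.kind} must drive exactly channels {expected}")
        for ch in expected:
            EffectParams(ch, self.drug_id, self.potencies[ch], self.clearances[ch])

    def effect_params(self) -> list[EffectParams]:
        return [
            EffectParams(ch, self.drug_id, self.potencies[ch], self.clearances[ch])
            for ch in (PARPI_CHANNELS if self.kind == "parpi" else ATRI_CHANNELS)
        ]

    def scaled_potency(self, factor: float) -> "DrugParams":
        """Copy with all unit potencies multiplied by ``factor`` (>= 0)."""
        return DrugParams(
            self.drug_id,
            self.kind,
            {k: v * factor for k, v in self.potencies.items()},
            dict(self.clearances),
        )


def parpi(
    drug_id: str,
    i_p_ssb: float,
    i_p_fork: float,
    cl_p: float,
    cl_p_fork: float,
    i_p_dsb: float | None = None,
) -> DrugParams:
    """PARP inhibitor: by default the DSB repair-inhibition potency equals the
    SSB one (shared catalytic/trapping action), and SSB/DSB channels share
    the clearance ``cl_p`` while the fork effect clears at ``cl_p_fork``."""
    if i_p_dsb is None:
        i_p_dsb = i_p_ssb
    return DrugParams(
        drug_id,
        "parpi",
        {"I_p_ssb": i_p_ssb, "I_p_dsb": i_p_dsb, "I_p_fork": i_p_fork},
        {"I_p_ssb": cl_p, "I_p_dsb": cl_p, "I_p_fork": cl_p_fork},
    )


def atri(
    drug_id: str,
    i_a_ssb: float,
    o_a: float,
    cl_a: float,
    i_a_dsb: float | None = None,
) -> DrugParams:
    """ATR inhibitor: by default the DSB repair-inhibition potency is half the
    SSB one (ATM signalling partially backs up DSB repair under ATR loss);
    all three channels share the clearance ``cl_a``."""
    if i_a_dsb is None:
        i_a_dsb = i_a_ssb / 2.0
    return DrugParams(
        drug_id,
        "atri",
        {"I_a_ssb": i_a_ssb, "I_a_dsb": i_a_dsb, "O_a": o_a},
        {"I_a_ssb": cl_a, "I_a_dsb": cl_a, "O_a": cl_a},
    )


def effect_derivative(params: EffectParams, c: float, x: float) -> float:
    """dX/dt = u_x*C - Cl_x*X for one channel."""
    return params.u_x * c - params.cl_x * x


def effect_step_exact(u: float, cl: float, c: float, x0: float, dt: float) -> float:
    """Exact update of dX/dt = u*C - Cl*X over ``dt`` with constant C.

    Closed-form piecewise-exponential solution; serves as the oracle for the
    numerically integrated effect compartments.
    """
    x_ss = u * c / cl
    return x_ss + (x0 - x_ss) * np.exp(-cl * dt)
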
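"""DNA-damage-response kinetics: damage generation, conversion, repair, death.

The model tracks two population-average damage species over the proliferating
cells of the tumour, single-strand breaks (SSB) and double-strand breaks
(DSB), both in arbitrary damage units (DAU):

    dSSB/dt = r_ssb - R_conv(t)*SSB - R_ssb(t)*SSB
    dDSB/dt = r_dsb + R_conv(t)*SSB - R_dsb(t)*DSB

Endogenous damage is generated at fixed rates r_ssb and r_dsb; SSB is
converted to DSB in S phase at a drug-accelerated, capped rate R_conv; each
damage type is repaired by two parallel pathways, one PARP-mediated and one
ATR-mediated:

    R_ssb = rep_ssb * ((1-def1)*sigma(I_p_ssb) + (1-def2)*sigma(I_a_ssb))
    R_dsb = rep_dsb * ((1-def3)*sigma(I_p_dsb) + (1-def4)*sigma(I_a_dsb))

with sigma(I) = e^{-I}/(1+e^{-I}).  sigma(0) = 1/2, so each intact pathway
contributes half the baseline rate and fully inhibiting one pathway can
remove at most 50% of repair while its parallel partner is intact — the
structural origin of synthetic lethality: efficacy requires losing BOTH
pathways, by mutation (def_i) and/or by drug.  def4 abstracts homologous
recombination deficiency and applies through the whole cell cycle.

Damage kills cells two ways: immediate phase-dependent death at rate
r_kill^(phase)*DSB, and delayed (mitotic-catastrophe-like) death at rate
(r_delay_kill + O_a)*(0.2*SSB + DSB), where O_a is the ATRi checkpoint
override acting in phases S to M; delayed-death cells keep dividing for a
few generations before dying.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PHASES",
    "DDRParams",
    "DamageState",
    "repair_modulation",
    "conversion_rate",
    "ssb_repair_rate",
    "dsb_repair_rate",
    "damage_derivatives",
    "damage_steady_state",
    "kill_rate",
    "delayed_kill_rate",
]

PHASES = ("G1", "S", "G2", "M")

# Baseline rates other than r_ssb/def1-4 are not tumour-specific observables;
# the defaults are synthetic values chosen so that the undrugged damage steady
# state is small (SSB* ~ 1e-3 DAU) and vehicle growth is unperturbed.
_DEFAULT_R_KILL = {"G1": 10.0, "S": 50.0, "G2": 25.0, "M": 50.0}


@dataclass(frozen=True)
class DDRParams:
    """Tumour-side DDR parameters.

    Rates are per hour; damage in DAU.  ``def1``..``def4`` are the pathway
    deficiencies in [0, 1] (0 = fully functional, 1 = total loss); values
    outside the range are clamped at construction.  ``n_gen`` is the number
    of divisions a delayed-death ("doomed") cell completes before dying.
    """

    r_ssb: float = 5e-4  # endogenous SSB generation (DAU/h)
    r_dsb: float = 1e-6  # endogenous DSB generation (DAU/h), synthetic default
    r_conv: float = 0.005  # baseline S-phase SSB->DSB conversion (1/h), synthetic
    rep_ssb: float = 0.5  # baseline SSB repair (1/h), synthetic default
    rep_dsb: float = 1.0  # baseline DSB repair (1/h), synthetic default
    def1: float = 0.0
    def2: float = 0.0
    def3: float = 0.0
    def4: float = 0.0
    r_kill_phase: dict = field(default_factory=lambda: dict(_DEFAULT_R_KILL))
    r_delay_kill: float = 0.01  # 1/DAU/h, synthetic default
    n_gen: int = 3

    def __post_init__(self) -> None:
        for name in ("r_ssb", "r_dsb", "r_conv", "rep_ssb", "rep_dsb", "r_delay_kill"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("def1", "def2", "def3", "def4"):
            object.__setattr__(self, name, float(np.clip(getattr(self, name), 0.0, 1.0)))
        if set(self.r_kill_phase) != set(PHASES):
            raise ValueError(f"r_kill_phase must map exactly the phases {PHASES}")
        if any(v < 0 for v in self.r_kill_phase.values()):
            raise ValueError("phase kill rates must be >= 0")
        if self.n_gen < 1:
            raise ValueError("n_gen must be >= 1")

    def with_(self, **kwargs) -> "DDRParams":
        return replace(self, **kwargs)


@dataclass
class DamageState:
    """Population-average SSB and DSB levels (DAU) over proliferating cells."""

    ssb: float = 0.0
    dsb: float = 0.0

    def __post_init__(self) -> None:
        if self.ssb < 0 or self.dsb < 0:
            raise ValueError("damage levels must be >= 0")


def repair_modulation(i):
    """Repair-disruption factor sigma(I) = e^{-I}/(1+e^{-I}) in (0, 1/2].

    sigma(0) = 1/2 (intact pathway at its half-share of baseline repair) and
    sigma -> 0 as the inhibitory effect level grows; monotone decreasing.
    """
    i = np.asarray(i, dtype=float)
    out = np.exp(-i) / (1.0 + np.exp(-i))
    return float(out) if out.ndim == 0 else out


def conversion_rate(r_conv: float, i_p_fork: float) -> float:
    """S-phase SSB->DSB conversion rate min(1, r_conv*(1+I_p_fork)), 1/h."""
    return min(1.0, r_conv * (1.0 + i_p_fork))


def ssb_repair_rate(p: DDRParams, i_p_ssb: float, i_a_ssb_gated: float) -> float:
    """Total SSB repair rate (1/h) from the two parallel pathways.

    ``i_a_ssb_gated`` must already carry the S-phase occupancy gate (ATR's
    SSB role is replication-stress response, so it acts in S phase only).
    """
    return p.rep_ssb * (
        (1.0 - p.def1) * repair_modulation(i_p_ssb)
        + (1.0 - p.def2) * repair_modulation(i_a_ssb_gated)
    )


def dsb_repair_rate(p: DDRParams, i_p_dsb: float, i_a_dsb: float) -> float:
    """Total DSB repair rate (1/h); def4 (HRD) applies in all phases."""
    return p.rep_dsb * (
        (1.0 - p.def3) * repair_modulation(i_p_dsb)
        + (1.0 - p.def4) * repair_modulation(i_a_dsb)
    )


def damage_derivatives(
    p: DDRParams,
    s: DamageState,
    r_conv_gated: float,
    r_ssb_rate: float,
    r_dsb_rate: float,
) -> tuple[float, float]:
    """(dSSB/dt, dDSB/dt); the conversion flux leaves SSB and enters DSB.

    ``r_conv_gated`` must already carry the S-phase occupancy gate.
    """
    conv_flux = r_conv_gated * s.ssb
    dssb = p.r_ssb - conv_flux - r_ssb_rate * s.ssb
    ddsb = p.r_dsb + conv_flux - r_dsb_rate * s.dsb
    return dssb, ddsb


def damage_steady_state(
    p: DDRParams, r_conv_gated: float, r_ssb_rate: float, r_dsb_rate: float
) -> tuple[float, float]:
    """Closed-form fixed point of the damage system under constant rates.

    SSB* = r_ssb/(R_conv+R_ssb); DSB* = (r_dsb + R_conv*SSB*)/R_dsb.
    Used as the independent oracle for the numerical integration.
    """
    ssb_star = p.r_ssb / (r_conv_gated + r_ssb_rate)
    dsb_star = (p.r_dsb + r_conv_gated * ssb_star) / r_dsb_rate
    return ssb_star, dsb_star


def kill_rate(p: DDRParams, phase: str, s: DamageState) -> float:
    """Immediate DSB-induced death hazard (1/h) for cells in ``phase``."""
    try:
        r = p.r_kill_phase[phase]
    except KeyError:
        raise ValueError(f"unknown cell-cycle phase {phase!r}") from None
    return r * s.dsb


def delayed_kill_rate(p: DDRParams, o_a_gated: float, s: DamageState) -> float:
    """Delayed-death hazard (1/h): (r_delay_kill + O_a)*(0.2*SSB + DSB).

    SSB contributes with weight 0.2 relative to DSB.  ``o_a_gated`` must
    already carry the S-to-M occupancy gate of the checkpoint override.
    """
    return (p.r_delay_kill + o_a_gated) * (0.2 * s.ssb + s.dsb)
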
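"""Coupled PK -> effect -> DDR -> tumour-growth simulator.

One scenario couples, for up to one PARP inhibitor and one ATR inhibitor:

* analytic plasma concentrations C(t) (superposition over the dose schedule),
* six first-order drug-effect compartments X(t),
* population-average SSB/DSB damage with drug-modulated repair/conversion,
* a cell-cycle-structured tumour (transit-compartment chain, doomed-cohort
  delayed death, quiescent core, first-order clearance of dead material).

Phase-restricted actions use continuous occupancy gating: the S-phase gate is
the current S occupancy fraction among live proliferating cells, the S-to-M
gate the S+G2+M fraction.  The mean model is deterministic; integration is
fixed-step classical RK4 with steps aligned to dose events and output times,
and the state is clamped non-negative after each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import growth as growth_mod
from .ddr import (
    DDRParams,
    PHASES,
    conversion_rate,
    damage_steady_state,
    dsb_repair_rate,
    ssb_repair_rate,
)
from .effects import ATRI_CHANNELS, CHANNEL_INDEX, CHANNELS, DrugParams
from .growth import GrowthParams, TumourState, phase_transition_rates, proliferating_fraction
from .regimen import ConcentrationProfile, DoseSchedule, PKParams

__all__ = [
    "TumourSpec",
    "Treatment",
    "Scenario",
    "TGITimeSeries",
    "SimulationResult",
    "simulate",
    "dose_response_scan",
]


@dataclass(frozen=True)
class TumourSpec:
    """Tumour parameter bundle: DDR kinetics plus growth/geometry."""

    ddr: DDRParams = field(default_factory=DDRParams)
    growth: GrowthParams = field(default_factory=GrowthParams)

    def with_(self, **kwargs) -> "TumourSpec":
        """Copy with updated fields, dispatched to the DDR or growth block."""
        ddr_fields = {k: v for k, v in kwargs.items() if hasattr(self.ddr, k)}
        growth_fields = {k: v for k, v in kwargs.items() if hasattr(self.growth, k)}
        unknown = set(kwargs) - set(ddr_fields) - set(growth_fields)
        if unknown:
            raise ValueError(f"unknown tumour parameters: {sorted(unknown)}")
        return TumourSpec(
            ddr=replace(self.ddr, **ddr_fields),
            growth=replace(self.growth, **growth_fields),
        )


@dataclass(frozen=True)
class Treatment:
    """One agent in a scenario: mechanism, PK and dose schedule."""

    drug: DrugParams
    pk: PKParams
    schedule: DoseSchedule


@dataclass
class Scenario:
    """A simulatable treatment arm."""

    tumour: TumourSpec
    treatments: list = field(default_factory=list)
    horizon_days: float = 42.0
    output_days: np.ndarray | None = None

    def __post_init__(self) -> None:
        kinds = [t.drug.kind for t in self.treatments]
        if kinds.count("parpi") > 1 or kinds.count("atri") > 1:
            raise ValueError("at most one PARPi and one ATRi per scenario")
        last = max((t.schedule.last_dose_time for t in self.treatments), default=0.0)
        if self.horizon_days * 24.0 < last:
            raise ValueError("horizon must cover the last dose")
        if self.output_days is None:
            self.output_days = np.arange(0.0, self.horizon_days + 1e-9, 1.0)
        self.output_days = np.asarray(self.output_days, dtype=float)
        if np.any(np.diff(self.output_days) <= 0):
            raise ValueError("output days must be strictly increasing")
        if self.output_days[0] < 0 or self.output_days[-1] > self.horizon_days + 1e-9:
            raise ValueError("output days must lie within [0, horizon]")


@dataclass
class TGITimeSeries:
    """Tumour-volume time course: days since study start vs mm^3."""

    days: np.ndarray
    volumes: np.ndarray
    sem: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.days.shape != self.volumes.shape:
            raise ValueError("days and volumes must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be >= 0")

    @property
    def final_volume(self) -> float:
        return float(self.volumes[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"day": self.days, "volume_mm3": self.volumes})
        if self.sem is not None:
            df["sem"] = self.sem
        if self.label:
            df.insert(0, "arm", self.label)
        return df


@dataclass
class SimulationResult:
    """Output of :func:`simulate`: the volume series plus the state trace."""

    series: TGITimeSeries
    trace: pd.DataFrame | None = None


class _CompiledScenario:
    """Precomputed arrays for the RHS of one scenario."""

    def __init__(self, sc: Scenario):
        ddr, g = sc.tumour.ddr, sc.tumour.growth
        self.ddr, self.growth = ddr, g
        self.n_stages = g.n_stages
        self.n_gen = ddr.n_gen
        k = phase_transition_rates(g)
        self.k = k
        ns = self.n_stages

        # Cycling matrix for [live | doomed gen0..gen-1] (doomed row 0 is the
        # freshly committed cohort; the final cohort's mitotic exit dies).
        dim = ns * (1 + self.n_gen)
        a = np.zeros((dim, dim))
        for blk in range(1 + self.n_gen):
            o = blk * ns
            for j in range(ns):
                a[o + j, o + j] -= k[j]
                if j + 1 < ns:
                    a[o + j + 1, o + j] += k[j]
            if blk == 0:
                a[o, o + ns - 1] += 2.0 * k[-1]  # live mitosis doubles into G1
            elif blk < self.n_gen:
                # doomed mitosis doubles into the next (fewer-divisions-left) cohort
                a[o + ns, o + ns - 1] += 2.0 * k[-1]
            # final doomed cohort: mitotic exit handled as death in the RHS
        self.cycle_matrix = a
        self.final_doomed_mexit = ns * self.n_gen + ns - 1  # flat index

        phases = np.array(g.stage_phases())
        self.s_mask = phases == "S"
        self.sm_mask = np.isin(phases, ("S", "G2", "M"))
        self.r_kill_stage = np.array([ddr.r_kill_phase[p] for p in phases])

        # Effect-channel potency/clearance vectors and channel->drug mapping.
        self.u = np.zeros(len(CHANNELS))
        self.cl = np.ones(len(CHANNELS))
        self.channel_drug = np.full(len(CHANNELS), -1)
        self.profiles = []
        for di, tr in enumerate(sc.treatments):
            for ep in tr.drug.effect_params():
                ci = CHANNEL_INDEX[ep.channel]
                self.u[ci] = ep.u_x
                self.cl[ci] = ep.cl_x
                self.channel_drug[ci] = di
            self.profiles.append(ConcentrationProfile(tr.pk, tr.schedule))

    def channel_conc(self, t: float) -> np.ndarray:
        out = np.zeros(len(CHANNELS))
        if self.profiles:
            c_drug = [prof(t) for prof in self.profiles]
            for ci, di in enumerate(self.channel_drug):
                if di >= 0:
                    out[ci] = c_drug[di]
        return out


def _rhs(t: float, y: np.ndarray, cs: _CompiledScenario) -> np.ndarray:
    ddr, g = cs.ddr, cs.growth
    ns = cs.n_stages
    nb = 1 + cs.n_gen  # cycling blocks: live + doomed cohorts
    x = y[:6]
    ssb, dsb = y[6], y[7]
    cells = y[8 : 8 + ns * nb]
    live = cells[:ns]
    q = y[8 + ns * nb : 8 + ns * nb + nb]  # quiescent pool per block
    dead = y[-1]

    dy = np.empty_like(y)

    # Effect compartments.
    dy[:6] = cs.u * cs.channel_conc(t) - cs.cl * x

    # Occupancy gates over live proliferating cells.
    p_live = live.sum()
    if p_live > 0:
        s_frac = live[cs.s_mask].sum() / p_live
        sm_frac = live[cs.sm_mask].sum() / p_live
    else:
        s_frac = sm_frac = 0.0

    r_conv_gated = conversion_rate(ddr.r_conv, max(x[2], 0.0)) * s_frac
    r_ssb = ssb_repair_rate(ddr, max(x[0], 0.0), max(x[3], 0.0) * s_frac)
    r_dsb = dsb_repair_rate(ddr, max(x[1], 0.0), max(x[4], 0.0))

    ssb_c, dsb_c = max(ssb, 0.0), max(dsb, 0.0)
    conv_flux = r_conv_gated * ssb_c
    dy[6] = ddr.r_ssb - conv_flux - r_ssb * ssb_c
    dy[7] = ddr.r_dsb + conv_flux - r_dsb * dsb_c

    # Cycling (division, cohort progression) for live + doomed cells.
    dcells = cs.cycle_matrix @ cells
    death_flux = cs.k[-1] * cells[cs.final_doomed_mexit]  # last doomed mitosis

    # Immediate (phase-dependent) and delayed death on live cells only.
    kill_stage = cs.r_kill_stage * dsb_c
    r_delay = (ddr.r_delay_kill + max(x[5], 0.0) * sm_frac) * (0.2 * ssb_c + dsb_c)
    immediate = kill_stage * live
    to_doomed = r_delay * live
    dcells[:ns] -= immediate + to_doomed
    dcells[ns : 2 * ns] += to_doomed

    # Shell/core exchange: relax the cycling population (live and doomed
    # alike) toward the geometric shell capacity; excess is drafted from G1
    # sub-compartments into per-cohort quiescent pools and re-enters G1 when
    # the tumour shrinks.
    p_cyc = cells.sum()
    q_tot = q.sum()
    vol = (p_cyc + q_tot + dead) / g.cell_density
    frac = proliferating_fraction(vol, g)
    excess = p_cyc - frac * (p_cyc + q_tot)
    dq = np.zeros(nb)
    if excess > 0:
        g1 = cells.reshape(nb, ns)[:, : g.n_sub]  # G1 stages of each block
        g1_tot = g1.sum()
        if g1_tot > 0:
            j = g.quiescence_rate * min(excess, g1_tot)
            draft = j * g1 / g1_tot
            dcells.reshape(nb, ns)[:, : g.n_sub] -= draft
            dq += draft.sum(axis=1)
    elif excess < 0 and q_tot > 0:
        j = g.quiescence_rate * min(-excess, q_tot)
        back = j * q / q_tot
        dcells.reshape(nb, ns)[:, 0] += back
        dq -= back

    dy[8 : 8 + ns * nb] = dcells
    dy[8 + ns * nb : 8 + ns * nb + nb] = dq
    dy[-1] = immediate.sum() + death_flux - g.core_clearance * dead
    return dy


def _time_grid(sc: Scenario, dt_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Integration knots: dose events + output times, subdivided to dt_max."""
    t_end = sc.horizon_days * 24.0
    knots = {0.0, t_end}
    knots.update(np.asarray(sc.output_days) * 24.0)
    for tr in sc.treatments:
        knots.update(tt for tt in tr.schedule.times if tt < t_end)
    knots = np.array(sorted(k for k in knots if 0.0 <= k <= t_end))
    grid = [np.array([0.0])]
    for a, b in zip(knots[:-1], knots[1:]):
        n = max(1, int(np.ceil((b - a) / dt_max)))
        grid.append(np.linspace(a, b, n + 1)[1:])
    return np.concatenate(grid), knots


def simulate(
    sc: Scenario,
    dt_max: float = 0.1,
    record_trace: bool = False,
) -> SimulationResult:
    """Integrate a scenario and return tumour volume on its output grid.

    ``dt_max`` (hours) is the maximum RK4 step; steps are aligned to dose
    events and observation days.  The mean model is deterministic.
    """
    if dt_max <= 0:
        raise ValueError("dt_max must be > 0")
    cs = _CompiledScenario(sc)
    ddr, g = cs.ddr, cs.growth
    ns = cs.n_stages

    state0 = growth_mod.initial_state(g, ddr.n_gen)
    # Damage starts at its undrugged steady state.
    dist = growth_mod.steady_stage_distribution(cs.k)
    s_frac0 = dist[cs.s_mask].sum()
    ssb0, dsb0 = damage_steady_state(
        ddr,
        min(1.0, ddr.r_conv) * s_frac0,
        ssb_repair_rate(ddr, 0.0, 0.0),
        dsb_repair_rate(ddr, 0.0, 0.0),
    )

    q0 = np.zeros(1 + ddr.n_gen)
    q0[0] = state0.quiescent
    y = np.concatenate(
        [
            np.zeros(6),
            [ssb0, dsb0],
            state0.live,
            state0.doomed.ravel(),
            q0,
            [state0.dead],
        ]
    )

    times, _ = _time_grid(sc, dt_max)
    out_times = np.asarray(sc.output_days) * 24.0
    out_idx = np.searchsorted(times, out_times)
    vols = np.empty(out_times.size)
    trace_rows = [] if record_trace else None

    def volume(yv: np.ndarray) -> float:
        return yv[8:].sum() / g.cell_density

    next_out = 0
    for i, t in enumerate(times):
        if next_out < out_times.size and i == out_idx[next_out]:
            vols[next_out] = volume(y)
            next_out += 1
        if record_trace:
            nb = 1 + ddr.n_gen
            trace_rows.append(
                {
                    "t_h": t,
                    "volume_mm3": volume(y),
                    "ssb": y[6],
                    "dsb": y[7],
                    "live": y[8 : 8 + ns].sum(),
                    "doomed": y[8 + ns : 8 + ns * nb].sum(),
                    "quiescent": y[8 + ns * nb : 8 + ns * nb + nb].sum(),
                    "dead": y[-1],
                    **{ch: y[ci] for ci, ch in enumerate(CHANNELS)},
                }
            )
        if i + 1 == times.size:
            break
        h = times[i + 1] - t
        k1 = _rhs(t, y, cs)
        k2 = _rhs(t + h / 2, y + h / 2 * k1, cs)
        k3 = _rhs(t + h / 2, y + h / 2 * k2, cs)
        k4 = _rhs(t + h, y + h * k3, cs)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        np.maximum(y, 0.0, out=y)
        if not np.all(np.isfinite(y)):
            raise RuntimeError(f"solver failure at t={t:.2f} h: non-finite state")

    series = TGITimeSeries(sc.output_days, vols)
    trace = pd.DataFrame(trace_rows) if record_trace else None
    return SimulationResult(series, trace)


def dose_response_scan(
    sc: Scenario,
    drug_id: str,
    dose_grid,
    dt_max: float = 0.5,
) -> pd.DataFrame:
    """Final tumour volume across a dose grid for one drug in the scenario.

    Every event dose of ``drug_id``'s schedule is scaled to the grid value
    (interpreting each grid entry as the per-administration dose in mg/kg,
    relative to the schedule's first event).  Dose 0 removes the drug and
    reproduces the remaining-arms scenario exactly.  The returned frame has
    columns dose, final_volume_mm3 and a ``stasis`` flag (final volume <=
    initial volume); the smallest dose achieving stasis is in
    ``df.attrs["min_effective_dose"]`` (NaN if none).
    """
    dose_grid = np.asarray(list(dose_grid), dtype=float)
    if dose_grid.size == 0 or np.any(dose_grid < 0):
        raise ValueError("dose grid must be non-empty and non-negative")
    target = [tr for tr in sc.treatments if tr.schedule.drug_id == drug_id]
    if len(target) != 1:
        raise ValueError(f"scenario must contain exactly one treatment for {drug_id!r}")
    base = target[0]
    ref_dose = base.schedule.doses[0] if len(base.schedule) else 1.0
    others = [tr for tr in sc.treatments if tr is not base]

    rows = []
    for dose in dose_grid:
        if dose == 0.0:
            trs = list(others)
        else:
            trs = others + [replace(base, schedule=base.schedule.scaled(dose / ref_dose))]
        sub = Scenario(sc.tumour, trs, sc.horizon_days, sc.output_days)
        res = simulate(sub, dt_max=dt_max)
        rows.append({"dose": dose, "final_volume_mm3": res.series.final_volume})
    df = pd.DataFrame(rows).sort_values("dose", ignore_index=True)
    df["stasis"] = df["final_volume_mm3"] <= sc.tumour.growth.v0
    eff = df.loc[df["stasis"] & (df["dose"] > 0), "dose"]
    df.attrs["min_effective_dose"] = float(eff.iloc[0]) if len(eff) else float("nan")
    return df
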
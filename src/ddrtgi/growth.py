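"""Cell-cycle-structured virtual tumour with a proliferating shell.

The tumour is a sphere with an outer shell of proliferating cells and an
inner core that is quiescent or necrotic.  Proliferating cells progress
through G1 -> S -> G2 -> M; mitotic exit doubles cells back into G1.  Each
phase is discretised into a chain of first-order sub-compartments (transit
compartments), which gives realistic dispersion of cell-cycle transit times.

Transit rates are calibrated at construction so that the asymptotic
population doubling time of an unconstrained tumour equals ``t_doub``
exactly: for a cyclic chain with stage rates k_j and doubling at mitotic
exit, the Malthusian rate lambda solves  prod_j (1 + lambda/k_j) = 2, and a
naive choice k_j = n_sub/(f_phase * t_doub) (mean transit = t_doub) yields a
doubling time a few percent short of t_doub; a single scalar rescaling of
all k_j fixes lambda = ln 2 / t_doub.

Volume is cell count over a fixed packing density; cells in excess of the
shell's carrying fraction are drafted into a quiescent core pool and
re-enter G1 if the tumour shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .ddr import PHASES

__all__ = [
    "GrowthParams",
    "TumourState",
    "phase_transition_rates",
    "growth_rate",
    "steady_stage_distribution",
    "proliferating_fraction",
    "volume_from_state",
    "apply_death",
]

_DEFAULT_PHASE_FRACTIONS = {"G1": 0.40, "S": 0.39, "G2": 0.15, "M": 0.06}


@dataclass(frozen=True)
class GrowthParams:
    """Geometry and cell-cycle parameters of the virtual tumour.

    ``t_doub`` is the asymptotic population doubling time in hours;
    ``phase_fractions`` split the cycle time across G1/S/G2/M;
    ``shell_thickness`` (mm) sets the depth of the proliferating rim;
    ``cell_density`` converts cell-equivalents to mm^3; ``v0`` is the
    initial tumour volume (mm^3); ``core_clearance`` (1/h) removes dead
    material; ``quiescence_rate`` (1/h) sets how fast the shell/core
    partition relaxes to its geometric target.
    """

    t_doub: float = 30.0
    phase_fractions: dict = field(default_factory=lambda: dict(_DEFAULT_PHASE_FRACTIONS))
    n_sub: int = 3
    shell_thickness: float = 0.2
    cell_density: float = 1e6
    v0: float = 100.0
    core_clearance: float = 0.01
    quiescence_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.t_doub <= 0:
            raise ValueError("t_doub must be > 0")
        if set(self.phase_fractions) != set(PHASES):
            raise ValueError(f"phase_fractions must map exactly {PHASES}")
        fr = np.array([self.phase_fractions[p] for p in PHASES])
        if np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError("phase fractions must be positive and sum to 1")
        if self.n_sub < 1:
            raise ValueError("n_sub must be >= 1")
        for name in ("shell_thickness", "cell_density", "v0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.core_clearance < 0 or self.quiescence_rate < 0:
            raise ValueError("rates must be >= 0")

    @property
    def n_stages(self) -> int:
        return self.n_sub * len(PHASES)

    def stage_phases(self) -> list[str]:
        """Phase label of each of the ``n_stages`` sub-compartments, in order."""
        return [p for p in PHASES for _ in range(self.n_sub)]


def _raw_stage_rates(g: GrowthParams) -> np.ndarray:
    """Uncalibrated stage exit rates n_sub/(f_phase * t_doub), 1/h."""
    return np.array(
        [g.n_sub / (g.phase_fractions[p] * g.t_doub) for p in PHASES for _ in range(g.n_sub)]
    )


def growth_rate(stage_rates: np.ndarray) -> float:
    """Malthusian rate lambda of the cyclic doubling chain: prod(1+lam/k)=2."""
    k = np.asarray(stage_rates, dtype=float)

    def f(lam: float) -> float:
        return np.sum(np.log1p(lam / k)) - np.log(2.0)

    hi = np.log(2.0) * k.min()  # f(hi) >= n*log1p(ln2/n_max...) > log 2 guard below
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-15)


def phase_transition_rates(g: GrowthParams) -> np.ndarray:
    """Calibrated stage exit rates (1/h) so the doubling time is exactly t_doub.

    All raw rates are scaled by one factor s solving
    prod_j (1 + ln2/(t_doub * s * k_j)) = 2.
    """
    k_raw = _raw_stage_rates(g)
    lam_target = np.log(2.0) / g.t_doub

    def f(s: float) -> float:
        return np.sum(np.log1p(lam_target / (s * k_raw))) - np.log(2.0)

    s = brentq(f, 0.5, 2.0, xtol=1e-15, rtol=1e-15)
    return s * k_raw


def steady_stage_distribution(stage_rates: np.ndarray, lam: float | None = None) -> np.ndarray:
    """Stage occupancy (sums to 1) during steady exponential growth.

    The balanced-growth eigenvector satisfies k_{j-1} n_{j-1} = (k_j+lam) n_j
    around the cycle, with the mitotic doubling closing the loop.
    """
    k = np.asarray(stage_rates, dtype=float)
    if lam is None:
        lam = growth_rate(k)
    n = np.empty_like(k)
    n[0] = 1.0
    for j in range(1, k.size):
        n[j] = n[j - 1] * k[j - 1] / (k[j] + lam)
    return n / n.sum()


def proliferating_fraction(volume: float, g: GrowthParams) -> float:
    """Fraction of the (spherical) tumour within the proliferating shell.

    1.0 while the radius is below the shell thickness d, afterwards the
    shell/total volume ratio (r^3-(r-d)^3)/r^3 — monotonically decreasing
    in volume.
    """
    if volume < 0:
        raise ValueError("volume must be >= 0")
    if volume == 0.0:
        return 1.0
    r = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    d = g.shell_thickness
    if r <= d:
        return 1.0
    return 1.0 - ((r - d) / r) ** 3


@dataclass
class TumourState:
    """Cell pools of the virtual tumour.

    ``live``: proliferating (viable) cells per cell-cycle stage;
    ``doomed``: cells committed to delayed death, per remaining-division
    cohort and stage (row 0 = freshly committed, last row = final division);
    ``quiescent``: core pool; ``dead``: dead-but-uncleared material, all in
    cell-equivalents.
    """

    live: np.ndarray
    doomed: np.ndarray
    quiescent: float = 0.0
    dead: float = 0.0

    def __post_init__(self) -> None:
        self.live = np.asarray(self.live, dtype=float)
        self.doomed = np.asarray(self.doomed, dtype=float)
        if self.doomed.ndim != 2 or self.doomed.shape[1] != self.live.size:
            raise ValueError("doomed must be (n_gen, n_stages)")
        if (
            np.any(self.live < 0)
            or np.any(self.doomed < 0)
            or self.quiescent < 0
            or self.dead < 0
        ):
            raise ValueError("all cell counts must be >= 0")

    @property
    def total_cells(self) -> float:
        return float(self.live.sum() + self.doomed.sum() + self.quiescent + self.dead)


def volume_from_state(state: TumourState, g: GrowthParams) -> float:
    """Tumour volume (mm^3): all cell-equivalent pools over packing density."""
    return state.total_cells / g.cell_density


def initial_state(g: GrowthParams, n_gen: int) -> TumourState:
    """State at study start: v0 worth of cells, split into shell (at the
    asynchronous steady-growth stage distribution) and quiescent core per the
    shell geometry; no doomed or dead material."""
    n_total = g.v0 * g.cell_density
    frac = proliferating_fraction(g.v0, g)
    dist = steady_stage_distribution(phase_transition_rates(g))
    return TumourState(
        live=n_total * frac * dist,
        doomed=np.zeros((n_gen, g.n_stages)),
        quiescent=n_total * (1.0 - frac),
        dead=0.0,
    )


def apply_death(
    state: TumourState,
    r_kill_stage: np.ndarray,
    r_delay_kill: float,
    dt: float,
) -> TumourState:
    """One exact constant-hazard death step over ``dt`` hours (no cycling).

    Immediate death removes live cells into the dead pool at per-stage hazard
    ``r_kill_stage``; delayed death moves live cells into the freshly
    committed doomed cohort at uniform hazard ``r_delay_kill``.  Competing
    exponential hazards are split proportionally.  This is the unit-step
    primitive; the simulator integrates death jointly with cycling.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    r_kill_stage = np.asarray(r_kill_stage, dtype=float)
    total = r_kill_stage + r_delay_kill
    surv = np.exp(-total * dt)
    lost = state.live * (1.0 - surv)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_kill = np.where(total > 0, r_kill_stage / np.where(total > 0, total, 1.0), 0.0)
    killed = lost * frac_kill
    doomed_new = lost - killed
    doomed = state.doomed.copy()
    doomed[0] += doomed_new
    return TumourState(
        live=state.live * surv,
        doomed=doomed,
        quiescent=state.quiescent,
        dead=state.dead + killed.sum(),
    )
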
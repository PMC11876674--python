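"""Calibration of tumour-specific parameters against TGI time series.

Drug mechanism parameters are held fixed structurally — only tumour-side
parameters (cell doubling time t_doub, pathway deficiencies def1-def4,
endogenous SSB generation r_ssb) are exposed to the optimiser, mirroring the
strategy of fixing an agent's mechanism across studies and letting tumour
biology vary.  def1-def3 default to zero and are only freed explicitly.

The objective is the root-mean-square error of log10 tumour volume over
matched observation days, averaged over arms: tumour volumes have a
multiplicative error structure, and arm means (not individual animals) are
fitted.  Optimisation is bounded trust-region least squares on the log10
residual vector, with seeded multistart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .simulate import Scenario, TGITimeSeries, simulate

__all__ = ["DEFAULT_BOUNDS", "FitSpec", "FitResult", "loss", "fit"]

#: Default box bounds for the free tumour parameters.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "t_doub": (15.0, 60.0),
    "def1": (0.0, 1.0),
    "def2": (0.0, 1.0),
    "def3": (0.0, 1.0),
    "def4": (0.0, 1.0),
    "r_ssb": (1e-5, 1e-2),
}


@dataclass
class FitSpec:
    """What to fit: free parameters, data, and optimiser options.

    ``datasets`` is a list of (observed arm-mean TGITimeSeries, Scenario)
    pairs; every scenario shares the same tumour parameter bundle with the
    free parameters substituted in.
    """

    free_parameters: list
    datasets: list
    bounds: dict = field(default_factory=dict)
    n_starts: int = 3
    seed: int = 0
    max_nfev: int = 500
    dt_max: float = 0.5

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one (observed, scenario) dataset is required")
        for name in self.free_parameters:
            if name not in DEFAULT_BOUNDS and name not in self.bounds:
                raise ValueError(f"no bounds known for free parameter {name!r}")
        self.bounds = {**{k: DEFAULT_BOUNDS[k] for k in self.free_parameters
                          if k in DEFAULT_BOUNDS}, **self.bounds}


@dataclass
class FitResult:
    """Best parameter estimates and fit diagnostics."""

    estimates: dict
    objective: float
    residual_rms_per_arm: list
    converged: bool
    n_evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "objective": self.objective,
            "residual_rms_per_arm": self.residual_rms_per_arm,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
        }


def loss(sim: TGITimeSeries, obs: TGITimeSeries) -> float:
    """RMSE of log10(volume) over the days common to both series.

    Symmetric in its arguments; raises if the series share no days or
    contain non-positive volumes on shared days.
    """
    common, ia, ib = np.intersect1d(sim.days, obs.days, return_indices=True)
    if common.size == 0:
        raise ValueError("series share no observation days")
    vs, vo = sim.volumes[ia], obs.volumes[ib]
    if np.any(vs <= 0) or np.any(vo <= 0):
        raise ValueError("volumes must be > 0 on matched days for log-scale loss")
    return float(np.sqrt(np.mean((np.log10(vs) - np.log10(vo)) ** 2)))


def _residuals(spec: FitSpec, values: dict) -> list[np.ndarray]:
    out = []
    for obs, sc in spec.datasets:
        sc2 = Scenario(
            sc.tumour.with_(**values), sc.treatments, sc.horizon_days, sc.output_days
        )
        sim = simulate(sc2, dt_max=spec.dt_max).series
        common, ia, ib = np.intersect1d(sim.days, obs.days, return_indices=True)
        if common.size == 0:
            raise ValueError("simulated and observed series share no days")
        vs = np.maximum(sim.volumes[ia], 1e-6)
        out.append(np.log10(vs) - np.log10(obs.volumes[ib]))
    return out


def objective_at(spec: FitSpec, values: dict) -> float:
    """Mean-over-arms log10-RMSE at a given parameter point."""
    res = _residuals(spec, values)
    return float(np.mean([np.sqrt(np.mean(r**2)) for r in res]))


def fit(spec: FitSpec, x0: dict | None = None) -> FitResult:
    """Jointly fit the free tumour parameters to all arms of all datasets.

    With an empty free set the initial tumour parameters are returned with
    the loss of the initial simulation.  Non-convergence is flagged on the
    result, never raised.  Drug parameters are untouchable by construction:
    only tumour-bundle fields can be named free.
    """
    if not spec.free_parameters:
        obj = objective_at(spec, {})
        rms = [float(np.sqrt(np.mean(r**2))) for r in _residuals(spec, {})]
        return FitResult({}, obj, rms, converged=True, n_evaluations=1)

    names = list(spec.free_parameters)
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])
    rng = np.random.default_rng(spec.seed)

    n_eval = 0

    def resid_vec(x: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        return np.concatenate(_residuals(spec, dict(zip(names, x))))

    starts = []
    if x0 is not None:
        starts.append(np.clip([x0[n] for n in names], lo, hi))
    base = spec.datasets[0][1].tumour
    defaults = []
    for i, n in enumerate(names):
        v = getattr(base.ddr, n) if hasattr(base.ddr, n) else getattr(base.growth, n)
        defaults.append(float(np.clip(v, lo[i], hi[i])))
    starts.append(np.array(defaults, dtype=float))
    while len(starts) < spec.n_starts + (x0 is not None):
        starts.append(lo + rng.random(len(names)) * (hi - lo))

    best = None
    budget = spec.max_nfev
    for s in starts:
        if budget <= 0:
            break
        res = least_squares(
            resid_vec, s, bounds=(lo, hi), max_nfev=budget,
            xtol=1e-10, ftol=1e-10, diff_step=1e-3,
        )
        budget = spec.max_nfev - n_eval
        if best is None or res.cost < best.cost:
            best = res

    values = dict(zip(names, best.x))
    per_arm = [float(np.sqrt(np.mean(r**2))) for r in _residuals(spec, values)]
    return FitResult(
        estimates={n: float(v) for n, v in values.items()},
        objective=float(np.mean(per_arm)),
        residual_rms_per_arm=per_arm,
        converged=bool(best.success),
        n_evaluations=n_eval,
    )
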
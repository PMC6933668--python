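"""Parameter estimation from batch time-series by constrained least squares.

The nine model parameters (four rate coefficients, five adsorption
quantities, and the initial facile fraction) are fit to measured glucose,
xylose, and insoluble-solids time series by minimizing a scale-normalized
sum of squared residuals with a derivative-free simplex search
(Nelder–Mead).  Box bounds are enforced by smooth reparameterization: each
free parameter is mapped to an unconstrained coordinate through a logit of
its (linearly or logarithmically) scaled position inside its bounds, so the
simplex never leaves the feasible box.  Because the search is local, the
fit is multi-started from seeded log-uniform perturbations of the initial
guess and the best minimizer is returned, with bound-activity flags for
parameters that finish on a box edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .params import ModelParams
from .reactors import BatchCondition, SolverError, simulate_batch
from .slurry import DomainError

__all__ = [
    "Dataset",
    "ParamSpec",
    "FitOptions",
    "FitResult",
    "default_param_specs",
    "objective",
    "fit",
]

#: Observable labels accepted in datasets.
OBSERVABLES = ("glucose_g_per_L", "xylose_g_per_L", "f_is")

#: Residual scale for insoluble-solids observations (fraction units).
F_IS_SCALE = 0.01

_PENALTY = 1e6


@dataclass(frozen=True)
class Dataset:
    """Observations for one batch condition.

    ``observations`` holds columns ``time_h``, ``observable`` (one of
    ``glucose_g_per_L``, ``xylose_g_per_L``, ``f_is``), ``value`` and an
    optional ``weight``.
    """

    condition: BatchCondition
    observations: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        obs = self.observations
        required = {"time_h", "observable", "value"}
        missing = required - set(obs.columns)
        if missing:
            raise DomainError(f"dataset missing columns: {sorted(missing)}")
        bad = set(obs["observable"]) - set(OBSERVABLES)
        if bad:
            raise DomainError(f"unknown observables: {sorted(bad)}")
        if (obs["value"] < 0).any():
            raise DomainError("observation values must be non-negative")
        if (obs["time_h"] < 0).any() or (
            obs["time_h"] > self.condition.duration_h
        ).any():
            raise DomainError("observation times outside the simulation horizon")
        if "weight" not in obs.columns:
            obs = obs.copy()
            obs["weight"] = 1.0
            object.__setattr__(self, "observations", obs)


@dataclass(frozen=True)
class ParamSpec:
    """Bounds, transform, and free/fixed status for one fittable parameter.

    ``transform`` is ``"logit"`` (linear position in the box) or
    ``"log-logit"`` (logarithmic position, for parameters spanning decades).
    """

    name: str
    lower: float
    upper: float
    transform: str = "logit"
    free: bool = True

    def to_unconstrained(self, x: float) -> float:
        if self.transform == "log-logit":
            z = (math.log(x) - math.log(self.lower)) / (
                math.log(self.upper) - math.log(self.lower)
            )
        else:
            z = (x - self.lower) / (self.upper - self.lower)
        z = min(max(z, 1e-9), 1.0 - 1e-9)
        return math.log(z / (1.0 - z))

    def from_unconstrained(self, u: float) -> float:
        z = 1.0 / (1.0 + math.exp(-u))
        if self.transform == "log-logit":
            return math.exp(
                math.log(self.lower)
                + z * (math.log(self.upper) - math.log(self.lower))
            )
        return self.lower + z * (self.upper - self.lower)

    def clip(self, x: float) -> float:
        return min(max(x, self.lower), self.upper)

    def on_bound(self, x: float, rel: float = 1e-6) -> bool:
        span = self.upper - self.lower
        tol_lo = rel * (abs(self.lower) if self.lower != 0 else span)
        tol_hi = rel * abs(self.upper)
        return abs(x - self.lower) <= tol_lo or abs(x - self.upper) <= tol_hi


def default_param_specs(tie_kR_kF: bool = True) -> list[ParamSpec]:
    """Default fit space: bounds and transforms for every fittable parameter.

    With the k_R = k_F tie active, k_F is fixed (it follows k_R), leaving
    eight free parameters.
    """
    return [
        ParamSpec("k_R", 1.0, 1e6, "log-logit"),
        ParamSpec("k_F", 1.0, 1e6, "log-logit", free=not tie_kR_kF),
        ParamSpec("k_X", 1.0, 1e4, "log-logit"),
        ParamSpec("k_L", 0.0, 1e4, "logit"),
        ParamSpec("K_dR", 1e-4, 10.0, "log-logit"),
        ParamSpec("kappa_RF", 0.1, 50.0, "log-logit"),
        ParamSpec("kappa_RX", 0.1, 50.0, "log-logit"),
        ParamSpec("kappa_RL", 0.1, 50.0, "log-logit"),
        ParamSpec("kappa_Rs", 0.1, 50.0, "log-logit"),
        ParamSpec("y_F0", 0.0, 1.0, "logit"),
    ]


@dataclass
class FitOptions:
    """Search configuration (all surfaced, nothing hidden).

    Multi-start Nelder–Mead: ``n_starts`` seeded log-uniform perturbations of
    the initial guess by up to ±``perturb`` (relative), a bounded simplex run
    from each, then a longer polish from the best.  ``sim_rtol``/``sim_atol``
    are the ODE tolerances used inside the objective (looser than the
    simulators' reporting defaults, for speed).
    """

    n_starts: int = 8
    perturb: float = 0.5
    perturb_all: bool = False  # also perturb the first start (else it is init)
    seed: int = 0
    maxfev_start: int = 1200
    maxfev_polish: int = 4000
    fatol: float = 1e-14
    xatol: float = 1e-8
    sim_rtol: float = 1e-7
    sim_atol: float = 1e-11


@dataclass
class FitResult:
    """Best-fit parameters with full search provenance."""

    params: ModelParams
    objective: float
    residuals: dict[str, pd.DataFrame]
    bound_active: dict[str, bool]
    diagnostics: dict
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = [
            {"parameter": n, "value": self.params.get(n), "on_bound": b}
            for n, b in self.bound_active.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def _simulate_observables(
    cond: BatchCondition,
    times: np.ndarray,
    params: ModelParams,
    rtol: float,
    atol: float,
) -> dict[str, np.ndarray]:
    t_eval = np.unique(np.concatenate([[0.0], times]))
    traj = simulate_batch(cond, params, t_eval=t_eval, rtol=rtol, atol=atol)
    idx = np.searchsorted(t_eval, times)
    return {
        "glucose_g_per_L": traj.c_g[idx],
        "xylose_g_per_L": traj.c_x[idx],
        "f_is": traj.f_is[idx],
        "_times": t_eval[idx],
    }


def _dataset_residuals(
    ds: Dataset, model: dict[str, np.ndarray], obs_times: np.ndarray
) -> pd.DataFrame:
    obs = ds.observations
    pred = np.empty(len(obs))
    scale = np.empty(len(obs))
    for name in OBSERVABLES:
        mask = (obs["observable"] == name).to_numpy()
        if not mask.any():
            continue
        t = obs.loc[mask, "time_h"].to_numpy()
        pred[mask] = np.interp(t, obs_times, model[name])
        if name == "f_is":
            scale[mask] = F_IS_SCALE
        else:
            m = float(obs.loc[mask, "value"].abs().max())
            scale[mask] = m if m > 0 else 1.0
    out = obs.copy()
    out["model"] = pred
    out["residual"] = (pred - obs["value"].to_numpy()) / scale
    return out


def objective(
    params: ModelParams,
    datasets: Sequence[Dataset],
    rtol: float = 1e-7,
    atol: float = 1e-11,
    return_residuals: bool = False,
):
    """Weighted, scale-normalized sum of squared residuals over all datasets.

    Glucose and xylose residuals (g/L) are divided by each dataset's maximum
    observed value of that sugar; insoluble-solids residuals by 0.01, making
    the objective unit-free.  Failed simulations contribute a large finite
    penalty instead of raising.
    """
    if not datasets:
        raise DomainError("objective requires at least one dataset")
    # one simulation per distinct condition, shared across replicate datasets
    sims: dict[BatchCondition, dict[str, np.ndarray] | None] = {}
    times_by_cond: dict[BatchCondition, np.ndarray] = {}
    for ds in datasets:
        cond = ds.condition
        t = ds.observations["time_h"].to_numpy(dtype=float)
        if cond in times_by_cond:
            times_by_cond[cond] = np.union1d(times_by_cond[cond], t)
        else:
            times_by_cond[cond] = np.unique(t)
    for cond, times in times_by_cond.items():
        try:
            sims[cond] = _simulate_observables(cond, times, params, rtol, atol)
        except (SolverError, DomainError, OverflowError):
            sims[cond] = None

    total = 0.0
    residuals: dict[str, pd.DataFrame] = {}
    for i, ds in enumerate(datasets):
        model = sims[ds.condition]
        if model is None:
            total += _PENALTY
            continue
        res = _dataset_residuals(ds, model, times_by_cond[ds.condition])
        total += float((res["weight"] * res["residual"] ** 2).sum())
        if return_residuals:
            residuals[ds.label or f"dataset_{i}"] = res
    if return_residuals:
        return total, residuals
    return total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _apply_vector(
    base: ModelParams, specs: list[ParamSpec], u: np.ndarray
) -> ModelParams:
    free = [s for s in specs if s.free]
    values = {s.name: s.from_unconstrained(ui) for s, ui in zip(free, u)}
    return base.with_values(**values)


def fit(
    datasets: Sequence[Dataset],
    init: ModelParams | None = None,
    specs: Iterable[ParamSpec] | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Multi-start constrained simplex fit of the model to batch datasets.

    ``init`` seeds the search (defaults to the package's reference parameter
    set); ``specs`` defines bounds, transforms and free/fixed status.  The
    result is invariant to dataset ordering, and each start's trajectory is
    recorded in ``diagnostics``.
    """
    if not datasets:
        raise DomainError("fit requires at least one dataset")
    init = init or ModelParams()
    options = options or FitOptions()
    specs = list(specs) if specs is not None else default_param_specs(
        tie_kR_kF=init.rates.tie_kR_kF
    )
    free = [s for s in specs if s.free]
    if not free:
        raise DomainError("no free parameters to fit")

    rng = np.random.default_rng(options.seed)

    def fun(u: np.ndarray) -> float:
        try:
            p = _apply_vector(init, specs, u)
        except DomainError:
            return _PENALTY
        return objective(
            p, datasets, rtol=options.sim_rtol, atol=options.sim_atol
        )

    u0 = np.array([s.to_unconstrained(s.clip(init.get(s.name))) for s in free])
    starts = [] if options.perturb_all else [u0]
    while len(starts) < options.n_starts:
        factors = np.exp(
            rng.uniform(
                math.log(1.0 - options.perturb),
                math.log(1.0 + options.perturb),
                size=len(free),
            )
        )
        perturbed = [
            s.to_unconstrained(s.clip(init.get(s.name) * f))
            for s, f in zip(free, factors)
        ]
        starts.append(np.array(perturbed))

    per_start = []
    best_u, best_f = None, math.inf
    for k, u_start in enumerate(starts):
        res = minimize(
            fun,
            u_start,
            method="Nelder-Mead",
            options={
                "maxfev": options.maxfev_start,
                "fatol": options.fatol,
                "xatol": options.xatol,
                "adaptive": True,
            },
        )
        per_start.append(
            {
                "start": k,
                "objective": float(res.fun),
                "nfev": int(res.nfev),
                "converged": bool(res.success),
                "message": str(res.message),
            }
        )
        if res.fun < best_f:
            best_f, best_u = float(res.fun), res.x

    polish = minimize(
        fun,
        best_u,
        method="Nelder-Mead",
        options={
            "maxfev": options.maxfev_polish,
            "fatol": options.fatol,
            "xatol": options.xatol,
            "adaptive": True,
        },
    )
    if polish.fun <= best_f:
        best_f, best_u = float(polish.fun), polish.x

    best_params = _apply_vector(init, specs, best_u)

    # Active-set refinement: a parameter that converged close to a box edge is
    # snapped exactly onto it when doing so does not worsen the objective —
    # the simplex approaches a boundary optimum only asymptotically in the
    # unconstrained coordinates.
    snapped = {}
    for s in free:
        x = best_params.get(s.name)
        for bound in (s.lower, s.upper):
            ref = abs(bound) if bound != 0 else (s.upper - s.lower)
            if x != bound and abs(x - bound) <= 1e-3 * ref:
                snapped[s.name] = bound
    if snapped:
        trial = best_params.with_values(**snapped)
        f_trial = objective(
            trial, datasets, rtol=options.sim_rtol, atol=options.sim_atol
        )
        if f_trial <= best_f + max(1e-9 * best_f, 1e-15):
            best_params, best_f = trial, f_trial
            best_u = np.array(
                [s.to_unconstrained(best_params.get(s.name)) for s in free]
            )
    _, residuals = objective(
        best_params,
        datasets,
        rtol=options.sim_rtol,
        atol=options.sim_atol,
        return_residuals=True,
    )
    bound_active = {
        s.name: s.on_bound(best_params.get(s.name)) for s in free
    }
    diagnostics = {
        "starts": per_start,
        "polish_nfev": int(polish.nfev),
        "polish_message": str(polish.message),
        "n_free": len(free),
        "free_names": [s.name for s in free],
        "bounds": {s.name: [s.lower, s.upper] for s in free},
        "n_starts": options.n_starts,
        "perturb": options.perturb,
    }
    return FitResult(
        params=best_params,
        objective=best_f,
        residuals=residuals,
        bound_active=bound_active,
        diagnostics=diagnostics,
        seed=options.seed,
    )
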
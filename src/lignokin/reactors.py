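"""Batch and continuous membrane-CSTR simulation.

The state vector tracks nine slurry mass fractions::

    [f_GR, f_GF, f_X, f_L, f_O, f_g, f_x, f_sL, f_ET]

In a batch reactor the seven reacting species follow their mass-basis
reaction rates while the inert solids and total enzyme are constant.  In the
continuous reactor (CEH-CSTR) four streams are added: a pretreated-slurry
feed, an enzyme-solution feed, a solids-free membrane permeate, and a
whole-slurry purge that keeps the reactor mass constant.  Insoluble species
leave only through the purge; soluble species also leave through the
permeate at their liquid-phase concentration (the 1/ε_l enrichment factor);
soluble enzyme pools (free + sugar-inhibited + lignin-inhibited) cross the
membrane with a rejection coefficient η_E while adsorbed enzyme is fully
retained with the solids.

The algebraic enzyme partition is substituted in closed form inside the ODE
right-hand side, so the system is an ordinary (not differential-algebraic)
ODE integrated with a stiff-capable method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ModelParams
from .slurry import DomainError, SlurryState

__all__ = [
    "BatchCondition",
    "StreamSpec",
    "Trajectory",
    "SolverError",
    "STATE_NAMES",
    "TRAJECTORY_COLUMNS",
    "initial_state",
    "batch_rhs",
    "simulate_batch",
    "conversion",
    "cstr_rhs",
    "simulate_ceh",
    "residence_time",
    "purge_from_closure",
]

STATE_NAMES = ("f_GR", "f_GF", "f_X", "f_L", "f_O", "f_g", "f_x", "f_sL", "f_ET")

TRAJECTORY_COLUMNS = [
    "time_h",
    "f_GR",
    "f_GF",
    "f_X",
    "f_L",
    "f_O",
    "f_g",
    "f_x",
    "f_sL",
    "f_ET",
    "f_is",
    "c_g_g_per_L",
    "c_x_g_per_L",
    "X_t",
]


class SolverError(RuntimeError):
    """ODE integration failed; the message carries the solver diagnostics."""


class ConfigError(ValueError):
    """Inconsistent reactor/stream configuration."""


@dataclass(frozen=True)
class BatchCondition:
    """One batch experiment: slurry make-up, enzyme dose, and duration.

    ``w_G/w_X/w_L/w_O`` are weight fractions *of the insoluble solids* (they
    must sum to 1); ``lambda_E`` is the enzyme loading in kg enzyme protein
    per kg initial glucan (so 20 mg/g = 0.020); background soluble
    concentrations are kg per m³ of liquid.
    """

    f_is0: float = 0.10
    w_G: float = 0.62
    w_X: float = 0.06
    w_L: float = 0.22
    w_O: float = 0.10
    lambda_E: float = 0.020
    rho_g: float = 0.0
    rho_x: float = 0.0
    rho_sL: float = 0.0
    duration_h: float = 168.0

    def __post_init__(self) -> None:
        w_sum = self.w_G + self.w_X + self.w_L + self.w_O
        if abs(w_sum - 1.0) > 1e-9:
            raise DomainError(f"solids weight fractions sum to {w_sum}, not 1")
        if any(w < 0 for w in (self.w_G, self.w_X, self.w_L, self.w_O)):
            raise DomainError("solids weight fractions must be non-negative")
        if not (0.0 <= self.f_is0 < 1.0):
            raise DomainError("f_is0 must lie in [0, 1)")
        if self.lambda_E < 0:
            raise DomainError("enzyme loading must be non-negative")
        if any(r < 0 for r in (self.rho_g, self.rho_x, self.rho_sL)):
            raise DomainError("background concentrations must be non-negative")


@dataclass(frozen=True)
class StreamSpec:
    """Streams and holdup of the continuous membrane reactor.

    Flows in kg/h; ``m_p_out=None`` computes the purge from the constant-mass
    closure ṁ_p = ṁ_s + ṁ_e − ṁ_m.  ``feed`` describes the pretreated-slurry
    feed composition (its ``lambda_E`` is ignored — enzyme enters through the
    enzyme-solution stream at ``c_E_feed`` kg/m³).  ``eta_E`` is the membrane
    rejection coefficient applied to the soluble enzyme pools.
    """

    m_s_in: float
    m_e_in: float
    m_m_out: float
    m_p_out: float | None = None
    m_T: float = 5.0
    feed: BatchCondition = field(default_factory=BatchCondition)
    c_E_feed: float = 0.0
    eta_E: float = 0.5
    startup_h: float = 6.0

    def __post_init__(self) -> None:
        for name in ("m_s_in", "m_e_in", "m_m_out"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.m_T <= 0:
            raise ConfigError("reactor holdup m_T must be positive")
        if not (0.0 <= self.eta_E <= 1.0):
            raise ConfigError("eta_E must lie in [0, 1]")
        if self.m_p_out is None:
            object.__setattr__(
                self,
                "m_p_out",
                purge_from_closure(self.m_s_in, self.m_e_in, self.m_m_out),
            )
        else:
            total_in = self.m_s_in + self.m_e_in
            total_out = self.m_m_out + self.m_p_out
            scale = max(total_in, total_out, 1e-300)
            if abs(total_in - total_out) / scale > 1e-6:
                raise ConfigError(
                    f"stream mass closure violated: in={total_in} kg/h, "
                    f"out={total_out} kg/h"
                )


def purge_from_closure(m_s_in: float, m_e_in: float, m_m_out: float) -> float:
    """Purge rate that closes the constant-mass balance (kg/h)."""
    purge = m_s_in + m_e_in - m_m_out
    if purge < 0:
        raise ConfigError(
            f"infeasible streams: permeate {m_m_out} kg/h exceeds total feed "
            f"{m_s_in + m_e_in} kg/h"
        )
    return purge


def residence_time(streams: StreamSpec) -> float:
    """Nominal residence time m_T / ṁ_p (h); inf when the purge is zero."""
    if streams.m_p_out == 0:
        return math.inf
    return streams.m_T / streams.m_p_out


# ---------------------------------------------------------------------------
# Initial conditions
# ---------------------------------------------------------------------------


def initial_state(
    cond: BatchCondition, params: ModelParams | None = None
) -> SlurryState:
    """Slurry state at t = 0 for a batch condition.

    The glucan pool is split facile/recalcitrant by the model's ``y_F0``;
    enzyme mass fraction is loading × initial glucan fraction; background
    soluble concentrations (per m³ liquid) are converted to slurry mass
    fractions through the liquid volume fraction.
    """
    params = params or ModelParams()
    f_G0 = cond.w_G * cond.f_is0
    state_insol = SlurryState(
        f_GF=params.y_F0 * f_G0,
        f_GR=(1.0 - params.y_F0) * f_G0,
        f_X=cond.w_X * cond.f_is0,
        f_L=cond.w_L * cond.f_is0,
        f_O=cond.w_O * cond.f_is0,
    )
    from .slurry import liquid_volume_fraction, slurry_density

    rho_T = slurry_density(state_insol, params.density)
    eps_l = liquid_volume_fraction(state_insol, params.density)
    return state_insol.replace(
        f_g=cond.rho_g * eps_l / rho_T,
        f_x=cond.rho_x * eps_l / rho_T,
        f_sL=cond.rho_sL * eps_l / rho_T,
        f_ET=cond.lambda_E * f_G0,
    )


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------


def _mass_rates_raw(y: Sequence[float], p: ModelParams) -> tuple[float, ...]:
    """(R_GR, R_GF, R_X, R_L, R_g, R_x, R_sL) at state vector ``y``.

    Plain-float hot path shared by both reactor RHS functions.  Negative
    excursions from the integrator are clipped to zero before the partition;
    every substrate's consumption rate is itself proportional to that
    substrate's concentration, so rates vanish smoothly at depletion.
    """
    f_GR = y[0] if y[0] > 0.0 else 0.0
    f_GF = y[1] if y[1] > 0.0 else 0.0
    f_X = y[2] if y[2] > 0.0 else 0.0
    f_L = y[3] if y[3] > 0.0 else 0.0
    f_O = y[4] if y[4] > 0.0 else 0.0
    f_g = y[5] if y[5] > 0.0 else 0.0
    f_x = y[6] if y[6] > 0.0 else 0.0
    f_sL = y[7] if y[7] > 0.0 else 0.0
    f_ET = y[8] if y[8] > 0.0 else 0.0

    cat = p.catalog
    dens = p.density
    f_is = f_GR + f_GF + f_X + f_L + f_O
    f_l = 1.0 - f_is
    if f_l <= 0.0:
        raise SolverError("slurry dried out: f_is reached 1")
    if dens.use_constant_density:
        rho_T = dens.rho_liquid
    else:
        rho_T = 1.0 / (f_is / dens.rho_solids + f_l / dens.rho_liquid)
    eps_l = rho_T / dens.rho_liquid * f_l

    c_GR = f_GR * rho_T / cat.mw_glucan
    c_GF = f_GF * rho_T / cat.mw_glucan
    c_X = f_X * rho_T / cat.mw_xylan
    c_L = f_L * rho_T / cat.mw_lignin
    c_ss = (f_g / cat.mw_glucose + f_x / cat.mw_xylose) * rho_T / eps_l
    c_sL = f_sL * rho_T / (cat.mw_soluble_lignin * eps_l)
    c_ET = f_ET * rho_T / cat.mw_enzyme

    ads = p.adsorption
    dprime = (
        c_GR
        + ads.kappa_RF * c_GF
        + ads.kappa_RX * c_X
        + eps_l * (ads.K_dR + ads.kappa_RL * c_sL + ads.kappa_Rs * c_ss)
    )
    if dprime <= 0.0 or c_ET == 0.0:
        return (0.0,) * 7
    scale = c_ET / dprime
    rates = p.rates
    r_GR = -rates.k_R * scale * c_GR
    r_GF = -rates.k_F * scale * ads.kappa_RF * c_GF
    r_X = -rates.k_X * scale * ads.kappa_RX * c_X
    r_L = rates.k_L * c_L * (r_GR + r_X)
    s = 1.0 / rho_T
    return (
        cat.mw_glucan * r_GR * s,
        cat.mw_glucan * r_GF * s,
        cat.mw_xylan * r_X * s,
        cat.mw_lignin * r_L * s,
        -cat.mw_glucose * (r_GR + r_GF) * s,
        -cat.mw_xylose * r_X * s,
        -cat.mw_soluble_lignin * r_L * s,
    )


def batch_rhs(y: Sequence[float], params: ModelParams) -> np.ndarray:
    """d(state)/dt for a well-mixed batch reactor.

    Inert solids and total enzyme have zero derivative.
    """
    R_GR, R_GF, R_X, R_L, R_g, R_x, R_sL = _mass_rates_raw(y, params)
    return np.array([R_GR, R_GF, R_X, R_L, 0.0, R_g, R_x, R_sL, 0.0])


from functools import lru_cache


@lru_cache(maxsize=64)
def _feed_state(streams: StreamSpec, params: ModelParams) -> SlurryState:
    """Composition of the pretreated-slurry feed as a slurry state (no enzyme)."""
    f = streams.feed
    return initial_state(
        BatchCondition(
            f_is0=f.f_is0,
            w_G=f.w_G,
            w_X=f.w_X,
            w_L=f.w_L,
            w_O=f.w_O,
            lambda_E=0.0,
            rho_g=f.rho_g,
            rho_x=f.rho_x,
            rho_sL=f.rho_sL,
        ),
        params,
    )


def cstr_rhs(
    y: Sequence[float], streams: StreamSpec, params: ModelParams
) -> np.ndarray:
    """d(state)/dt for the continuous membrane reactor.

    Reduces term-by-term to :func:`batch_rhs` when every flow is zero.
    """
    R = _mass_rates_raw(y, params)
    cat, dens = params.catalog, params.density

    f_is = sum(max(v, 0.0) for v in y[:5])
    f_l = 1.0 - f_is
    if dens.use_constant_density:
        rho_T = dens.rho_liquid
    else:
        rho_T = 1.0 / (f_is / dens.rho_solids + f_l / dens.rho_liquid)
    eps_l = rho_T / dens.rho_liquid * f_l

    feed = _feed_state(streams, params)
    f_E_feed = streams.c_E_feed / dens.rho_liquid

    d_s = streams.m_s_in / streams.m_T
    d_e = streams.m_e_in / streams.m_T
    d_p = streams.m_p_out / streams.m_T
    d_m = streams.m_m_out / streams.m_T

    # soluble-enzyme mass fraction (free + sugar- and lignin-inhibited pools)
    f_GR, f_GF, f_X = (max(y[i], 0.0) for i in (0, 1, 2))
    f_g, f_x, f_sL, f_ET = (max(y[i], 0.0) for i in (5, 6, 7, 8))
    ads = params.adsorption
    c_GR = f_GR * rho_T / cat.mw_glucan
    c_GF = f_GF * rho_T / cat.mw_glucan
    c_X = f_X * rho_T / cat.mw_xylan
    c_ss = (f_g / cat.mw_glucose + f_x / cat.mw_xylose) * rho_T / eps_l
    c_sL = f_sL * rho_T / (cat.mw_soluble_lignin * eps_l)
    dprime = (
        c_GR
        + ads.kappa_RF * c_GF
        + ads.kappa_RX * c_X
        + eps_l * (ads.K_dR + ads.kappa_RL * c_sL + ads.kappa_Rs * c_ss)
    )
    if dprime > 0.0:
        soluble_frac = eps_l * (
            ads.K_dR + ads.kappa_RL * c_sL + ads.kappa_Rs * c_ss
        ) / dprime
    else:
        soluble_frac = 1.0
    f_E_soluble = f_ET * soluble_frac

    dy = np.empty(9)
    # insolubles: feed in, purge out, reaction
    dy[0] = d_s * feed.f_GR - d_p * y[0] + R[0]
    dy[1] = d_s * feed.f_GF - d_p * y[1] + R[1]
    dy[2] = d_s * feed.f_X - d_p * y[2] + R[2]
    dy[3] = d_s * feed.f_L - d_p * y[3] + R[3]
    dy[4] = d_s * feed.f_O - d_p * y[4]
    # solubles: feed, purge, permeate (liquid-phase enrichment 1/eps_l), reaction
    dy[5] = d_s * feed.f_g - d_p * y[5] - d_m * y[5] / eps_l + R[4]
    dy[6] = d_s * feed.f_x - d_p * y[6] - d_m * y[6] / eps_l + R[5]
    dy[7] = d_s * feed.f_sL - d_p * y[7] - d_m * y[7] / eps_l + R[6]
    # enzyme: enzyme-solution feed, purge, partial permeation of soluble pools
    dy[8] = d_e * f_E_feed - d_p * y[8] - d_m * streams.eta_E * f_E_soluble / eps_l
    return dy


# ---------------------------------------------------------------------------
# Trajectories and integration
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time series of slurry states plus derived observables."""

    t: np.ndarray
    y: np.ndarray  # shape (n_times, 9), columns per STATE_NAMES
    condition: BatchCondition
    params: ModelParams
    switch_time: float | None = None  # batch→continuous handover, CEH only

    @property
    def f_is(self) -> np.ndarray:
        return self.y[:, :5].sum(axis=1)

    def _rho_eps(self) -> tuple[np.ndarray, np.ndarray]:
        dens = self.params.density
        f_l = 1.0 - self.f_is
        if dens.use_constant_density:
            rho_T = np.full_like(f_l, dens.rho_liquid)
        else:
            rho_T = 1.0 / (self.f_is / dens.rho_solids + f_l / dens.rho_liquid)
        return rho_T, rho_T / dens.rho_liquid * f_l

    @property
    def c_g(self) -> np.ndarray:
        """Glucose concentration, kg/m³ liquid (≡ g/L)."""
        rho_T, eps_l = self._rho_eps()
        return self.y[:, 5] * rho_T / eps_l

    @property
    def c_x(self) -> np.ndarray:
        """Xylose concentration, kg/m³ liquid (≡ g/L)."""
        rho_T, eps_l = self._rho_eps()
        return self.y[:, 6] * rho_T / eps_l

    @property
    def X_t(self) -> np.ndarray:
        return conversion(self, self.condition)

    def state_at(self, index: int) -> SlurryState:
        return SlurryState(**dict(zip(STATE_NAMES, self.y[index])))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.t)
        df["f_is"] = self.f_is
        df["c_g_g_per_L"] = self.c_g
        df["c_x_g_per_L"] = self.c_x
        df["X_t"] = self.X_t
        return df[TRAJECTORY_COLUMNS]


def conversion(traj: Trajectory, cond: BatchCondition) -> np.ndarray:
    """Total carbohydrate conversion X_t along a trajectory.

    X_t = [r_g·(f_g − f_g0) + r_x·(f_x − f_x0)] / [f_is0·(w_G + w_X)], where
    r_g and r_x deflate each sugar's mass by the hydration water it gained,
    so complete conversion of all glucan + xylan gives X_t = 1.
    """
    denom = cond.f_is0 * (cond.w_G + cond.w_X)
    if denom <= 0:
        raise DomainError("no carbohydrate in the initial solids: X_t undefined")
    cat = traj.params.catalog
    f_g0, f_x0 = traj.y[0, 5], traj.y[0, 6]
    return (
        cat.r_g * (traj.y[:, 5] - f_g0) + cat.r_x * (traj.y[:, 6] - f_x0)
    ) / denom


_DEFAULT_RTOL = 1e-8
_DEFAULT_ATOL = 1e-12


def _integrate(
    rhs,
    y0: np.ndarray,
    t_span: tuple[float, float],
    t_eval: np.ndarray,
    rtol: float,
    atol: float,
) -> np.ndarray:
    sol = solve_ivp(
        rhs,
        t_span,
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(
            f"ODE integration failed over t={t_span}: {sol.message} "
            f"(nfev={sol.nfev})"
        )
    Y = sol.y.T
    if (Y < 0).any():
        worst = float(Y.min())
        if worst < -1e-9:
            logging.getLogger(__name__).warning(
                "clipped negative state excursion (min %.3e) to zero", worst
            )
        Y = np.where(Y < 0, 0.0, Y)
    return Y


def simulate_batch(
    cond: BatchCondition,
    params: ModelParams | None = None,
    t_eval: Sequence[float] | None = None,
    rtol: float = _DEFAULT_RTOL,
    atol: float = _DEFAULT_ATOL,
) -> Trajectory:
    """Integrate a batch hydrolysis over ``cond.duration_h``.

    ``t_eval`` defaults to a half-hour output grid.
    """
    params = params or ModelParams()
    y0 = np.array(
        [getattr(initial_state(cond, params), n) for n in STATE_NAMES]
    )
    if t_eval is None:
        t_eval = np.linspace(0.0, cond.duration_h, int(cond.duration_h * 2) + 1)
    t_eval = np.asarray(t_eval, dtype=float)
    Y = _integrate(
        lambda t, y: batch_rhs(y, params),
        y0,
        (0.0, float(cond.duration_h)),
        t_eval,
        rtol,
        atol,
    )
    return Trajectory(t=t_eval, y=Y, condition=cond, params=params)


def simulate_ceh(
    streams: StreamSpec,
    startup: BatchCondition,
    params: ModelParams | None = None,
    duration_h: float = 72.0,
    dt_out: float = 0.5,
    rtol: float = _DEFAULT_RTOL,
    atol: float = _DEFAULT_ATOL,
) -> Trajectory:
    """Batch startup followed by continuous membrane-reactor operation.

    The reactor is first run as a batch for ``streams.startup_h`` hours from
    the ``startup`` charge, then the four streams are switched on for
    ``duration_h`` hours.  The returned trajectory spans both phases with
    ``switch_time`` marking the handover.
    """
    params = params or ModelParams()
    t_switch = streams.startup_h
    y0 = np.array(
        [getattr(initial_state(startup, params), n) for n in STATE_NAMES]
    )
    t1 = np.linspace(0.0, t_switch, max(int(t_switch / dt_out), 1) + 1)
    Y1 = _integrate(
        lambda t, y: batch_rhs(y, params), y0, (0.0, t_switch), t1, rtol, atol
    )
    t2 = np.linspace(
        t_switch, t_switch + duration_h, max(int(duration_h / dt_out), 1) + 1
    )
    Y2 = _integrate(
        lambda t, y: cstr_rhs(y, streams, params),
        Y1[-1],
        (t_switch, t_switch + duration_h),
        t2,
        rtol,
        atol,
    )
    t = np.concatenate([t1, t2[1:]])
    Y = np.vstack([Y1, Y2[1:]])
    return Trajectory(
        t=t, y=Y, condition=startup, params=params, switch_time=t_switch
    )
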
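"""Synthetic experimental designs and noisy fixture datasets.

This module encodes the laboratory study designs the package is exercised
against — a seven-condition batch campaign (solids loading, enzyme dose, and
exogenous glucose varied one at a time around a duplicated reference
condition) and three continuous membrane-reactor runs at increasing target
solids — and generates measurement-like datasets from model simulations with
a configurable multiplicative noise layer.

Background liquor concentrations of the pretreated feedstock (dissolved
xylose, glucose, and soluble lignin carried in from pretreatment) are fixture
conventions, not measured values: defaults are 15 g/L xylose, 5 g/L glucose,
1 g/L soluble lignin, all configurable and recorded in dataset labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import Dataset
from .params import ModelParams
from .reactors import BatchCondition, StreamSpec, Trajectory, simulate_batch, simulate_ceh

__all__ = [
    "NoiseModel",
    "CEHRun",
    "CEHDataset",
    "SUGAR_SAMPLE_TIMES",
    "FIS_SAMPLE_TIMES",
    "DEFAULT_BACKGROUND",
    "batch_design",
    "ceh_design",
    "generate_batch_set",
    "generate_ceh_set",
]

#: Sampling grid (h) for soluble sugars in the batch campaign.
SUGAR_SAMPLE_TIMES = (4.0, 8.0, 24.0, 28.0, 72.0, 120.0, 168.0)
#: Sampling grid (h) for insoluble solids in the batch campaign.
FIS_SAMPLE_TIMES = (24.0, 168.0)

#: Background liquor concentrations (kg/m³ liquid): glucose, xylose, soluble
#: lignin.  Fixture conventions (see module docstring).
DEFAULT_BACKGROUND = {"rho_g": 5.0, "rho_x": 15.0, "rho_sL": 1.0}

#: Batch campaign rows: (f_is0, enzyme loading mg/g glucan, added glucose g/L).
#: The first row is the reference condition, run in duplicate.
_BATCH_ROWS = (
    (0.10, 20.0, 0.0),
    (0.075, 20.0, 0.0),
    (0.05, 20.0, 0.0),
    (0.10, 15.0, 0.0),
    (0.10, 10.0, 0.0),
    (0.10, 20.0, 20.0),
    (0.10, 20.0, 50.0),
)

#: Pretreated-solids composition: weight fractions of the insoluble solids.
SOLIDS_COMPOSITION = {"w_G": 0.62, "w_X": 0.06, "w_L": 0.22, "w_O": 0.10}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise, truncated at zero.

    Relative standard deviations per observable class; sugar assays scale
    with concentration, hence the multiplicative law.  A fixed seed makes
    regeneration bit-exact.
    """

    rel_sd_sugars: float = 0.03
    rel_sd_fis: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rel_sd_sugars < 0 or self.rel_sd_fis < 0:
            raise ValueError("noise standard deviations must be non-negative")

    def apply(self, values: np.ndarray, rel_sd: float, rng: np.random.Generator) -> np.ndarray:
        if rel_sd == 0.0:
            return np.asarray(values, dtype=float)
        noisy = values * (1.0 + rel_sd * rng.standard_normal(len(values)))
        return np.maximum(noisy, 0.0)


def batch_design(
    background: dict[str, float] | None = None,
    duration_h: float = 168.0,
) -> list[BatchCondition]:
    """The seven batch conditions (reference first, not yet duplicated)."""
    bg = dict(DEFAULT_BACKGROUND)
    if background:
        bg.update(background)
    conditions = []
    for f_is0, loading_mg_g, added_glucose in _BATCH_ROWS:
        conditions.append(
            BatchCondition(
                f_is0=f_is0,
                lambda_E=loading_mg_g * 1e-3,
                rho_g=bg["rho_g"] + added_glucose,
                rho_x=bg["rho_x"],
                rho_sL=bg["rho_sL"],
                duration_h=duration_h,
                **SOLIDS_COMPOSITION,
            )
        )
    return conditions


@dataclass(frozen=True)
class CEHRun:
    """One continuous run: stream rates, feed make-up, and startup charge."""

    name: str
    target_f_is: float
    streams: StreamSpec
    startup: BatchCondition

    @property
    def nominal_residence_time_h(self) -> float:
        return self.streams.m_T / self.streams.m_p_out


def ceh_design(background: dict[str, float] | None = None) -> list[CEHRun]:
    """The three continuous membrane-reactor runs.

    Flows in kg/h; the purge closes the constant-mass balance.  Enzyme
    loading is 10 mg/g glucan throughout; the startup charge is a batch at
    the run's target insoluble-solids fraction.
    """
    bg = dict(DEFAULT_BACKGROUND)
    if background:
        bg.update(background)
    soluble = {"rho_g": bg["rho_g"], "rho_x": bg["rho_x"], "rho_sL": bg["rho_sL"]}
    rows = (
        # name, target f_is, m_e_in, c_E_feed g/L, m_s_in, feed f_is, m_m_out
        ("I", 0.05, 0.138, 0.89, 0.42, 0.05, 0.276),
        ("II", 0.075, 0.072, 2.7, 0.426, 0.075, 0.222),
        ("III", 0.085, 0.054, 3.6, 0.348, 0.10, 0.152),
    )
    runs = []
    for name, target, m_e, c_E, m_s, feed_fis, m_m in rows:
        feed = BatchCondition(
            f_is0=feed_fis, lambda_E=0.0, **SOLIDS_COMPOSITION, **soluble
        )
        startup = BatchCondition(
            f_is0=target, lambda_E=0.010, **SOLIDS_COMPOSITION, **soluble
        )
        runs.append(
            CEHRun(
                name=name,
                target_f_is=target,
                streams=StreamSpec(
                    m_s_in=m_s,
                    m_e_in=m_e,
                    m_m_out=m_m,
                    m_T=5.0,
                    feed=feed,
                    c_E_feed=c_E,
                    eta_E=0.5,
                    startup_h=6.0,
                ),
                startup=startup,
            )
        )
    return runs


def _observe(
    traj: Trajectory, sugar_times: np.ndarray, fis_times: np.ndarray
) -> pd.DataFrame:
    c_g = np.interp(sugar_times, traj.t, traj.c_g)
    c_x = np.interp(sugar_times, traj.t, traj.c_x)
    f_is = np.interp(fis_times, traj.t, traj.f_is)
    return pd.DataFrame(
        {
            "time_h": np.concatenate([sugar_times, sugar_times, fis_times]),
            "observable": (
                ["glucose_g_per_L"] * len(sugar_times)
                + ["xylose_g_per_L"] * len(sugar_times)
                + ["f_is"] * len(fis_times)
            ),
            "value": np.concatenate([c_g, c_x, f_is]),
        }
    )


def _add_noise(obs: pd.DataFrame, noise: NoiseModel, rng: np.random.Generator) -> pd.DataFrame:
    out = obs.copy()
    sugars = out["observable"].isin(["glucose_g_per_L", "xylose_g_per_L"]).to_numpy()
    vals = out["value"].to_numpy(dtype=float)
    vals[sugars] = noise.apply(vals[sugars], noise.rel_sd_sugars, rng)
    vals[~sugars] = noise.apply(vals[~sugars], noise.rel_sd_fis, rng)
    out["value"] = vals
    return out


def generate_batch_set(
    params: ModelParams | None = None,
    noise: NoiseModel | None = None,
    background: dict[str, float] | None = None,
    n_reference_replicates: int = 2,
) -> list[Dataset]:
    """Simulate the batch campaign and return one dataset per run.

    The reference condition appears ``n_reference_replicates`` times (noise
    redrawn per replicate; identical data when noise is zero).  With a zero
    noise model, values are the exact model output at the sampling grid.
    """
    params = params or ModelParams()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    sugar_t = np.asarray(SUGAR_SAMPLE_TIMES)
    fis_t = np.asarray(FIS_SAMPLE_TIMES)
    t_eval = np.unique(np.concatenate([[0.0], sugar_t, fis_t]))

    datasets = []
    for i, cond in enumerate(batch_design(background)):
        traj = simulate_batch(cond, params, t_eval=t_eval)
        clean = _observe(traj, sugar_t, fis_t)
        replicates = n_reference_replicates if i == 0 else 1
        for rep in range(replicates):
            label = f"batch_{i}" + (f"_rep{rep}" if replicates > 1 else "")
            datasets.append(
                Dataset(
                    condition=cond,
                    observations=_add_noise(clean, noise, rng),
                    label=label,
                )
            )
    return datasets


@dataclass(frozen=True)
class CEHDataset:
    """Sampled observations from one continuous run, with its full design."""

    run: CEHRun
    observations: pd.DataFrame
    trajectory: Trajectory = field(repr=False, compare=False, default=None)


def generate_ceh_set(
    params: ModelParams | None = None,
    noise: NoiseModel | None = None,
    background: dict[str, float] | None = None,
    duration_h: float = 72.0,
    sample_every_h: float = 7.0,
) -> list[CEHDataset]:
    """Simulate the three continuous runs and sample the reactor contents.

    Sampling starts after the batch-startup window and repeats every
    ``sample_every_h`` hours over ``duration_h`` hours of continuous
    operation; the returned trajectory includes the startup phase.
    """
    params = params or ModelParams()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed + 1)
    out = []
    for run in ceh_design(background):
        traj = simulate_ceh(
            run.streams, run.startup, params, duration_h=duration_h
        )
        t0 = run.streams.startup_h
        times = np.arange(t0, t0 + duration_h + 1e-9, sample_every_h)
        obs = _observe(traj, times, times)
        out.append(
            CEHDataset(
                run=run,
                observations=_add_noise(obs, noise, rng),
                trajectory=traj,
            )
        )
    return out
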
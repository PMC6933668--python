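"""Configuration loading and CSV interchange.

One YAML config format and one CSV dialect (UTF-8, '.' decimal separator,
units embedded in column names) are used everywhere so artifacts round-trip
bit-stably between the simulators, the fitter, and the data generator.
Unknown config keys are rejected, and every validation error names the
offending key.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import OBSERVABLES, Dataset, FitOptions
from .kinetics import RateParams
from .params import ModelParams
from .partition import AdsorptionParams
from .reactors import (
    TRAJECTORY_COLUMNS,
    BatchCondition,
    StreamSpec,
    Trajectory,
)
from .slurry import DensitySpec, DomainError, SpeciesCatalog
from .synthetic import NoiseModel

__all__ = [
    "RunConfig",
    "ConfigSchemaError",
    "MissingColumnError",
    "NonNumericError",
    "NonMonotoneTimeError",
    "load_config",
    "save_config",
    "read_dataset_csv",
    "write_dataset_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
]

SCHEMA_VERSION = "1"


class ConfigSchemaError(ValueError):
    """Config violates the schema; the message names the offending key."""


class MissingColumnError(ValueError):
    pass


class NonNumericError(ValueError):
    pass


class NonMonotoneTimeError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration: model parameters plus scenario blocks."""

    params: ModelParams
    batch: BatchCondition | None = None
    ceh: StreamSpec | None = None
    ceh_duration_h: float = 72.0
    fit: FitOptions = field(default_factory=FitOptions)
    noise: NoiseModel = field(default_factory=NoiseModel)
    defaults_applied: list[str] = field(default_factory=list)
    config_hash: str = ""


_BLOCKS = (
    "schema_version",
    "species",
    "density",
    "kinetics",
    "adsorption",
    "substrate",
    "batch",
    "ceh",
    "fit",
    "noise",
)


def _build(block: str, raw: dict, cls, key_map: dict[str, str], defaults_log: list[str]):
    """Instantiate a config dataclass, rejecting unknown keys by name."""
    raw = dict(raw or {})
    unknown = set(raw) - set(key_map)
    if unknown:
        raise ConfigSchemaError(
            f"unknown key(s) in `{block}:`: {sorted(unknown)}; "
            f"expected {sorted(key_map)}"
        )
    kwargs = {}
    for cfg_key, attr in key_map.items():
        if cfg_key in raw:
            kwargs[attr] = raw[cfg_key]
        else:
            defaults_log.append(f"{block}.{cfg_key}")
    try:
        return cls(**kwargs)
    except (DomainError, ValueError, TypeError) as exc:
        raise ConfigSchemaError(f"invalid `{block}:` block: {exc}") from exc


_SPECIES_KEYS = {
    k: k
    for k in (
        "mw_glucan",
        "mw_xylan",
        "mw_glucose",
        "mw_xylose",
        "mw_lignin",
        "mw_soluble_lignin",
        "mw_enzyme",
    )
}
_DENSITY_KEYS = {
    "rho_liquid_kg_per_m3": "rho_liquid",
    "rho_solids_kg_per_m3": "rho_solids",
    "use_constant_density": "use_constant_density",
}
_KINETICS_KEYS = {
    "k_R_per_h": "k_R",
    "k_F_per_h": "k_F",
    "k_X_per_h": "k_X",
    "k_L_m3_per_kmol": "k_L",
    "tie_kR_kF": "tie_kR_kF",
}
_ADSORPTION_KEYS = {
    "K_dR_kmol_per_m3": "K_dR",
    "kappa_RF": "kappa_RF",
    "kappa_RX": "kappa_RX",
    "kappa_RL": "kappa_RL",
    "kappa_Rs": "kappa_Rs",
}
_BATCH_KEYS = {
    "f_is0": "f_is0",
    "w_G": "w_G",
    "w_X": "w_X",
    "w_L": "w_L",
    "w_O": "w_O",
    "lambda_E_mg_per_g": "lambda_E",
    "rho_g_g_per_L": "rho_g",
    "rho_x_g_per_L": "rho_x",
    "rho_sL_g_per_L": "rho_sL",
    "duration_h": "duration_h",
}
_FIT_KEYS = {
    k: k
    for k in (
        "n_starts",
        "perturb",
        "perturb_all",
        "seed",
        "maxfev_start",
        "maxfev_polish",
        "fatol",
        "xatol",
        "sim_rtol",
        "sim_atol",
    )
}
_NOISE_KEYS = {k: k for k in ("rel_sd_sugars", "rel_sd_fis", "seed")}


def _parse_batch(block: str, raw: dict, defaults_log: list[str]) -> BatchCondition:
    raw = dict(raw or {})
    if "lambda_E_mg_per_g" in raw:
        raw["lambda_E_mg_per_g"] = float(raw["lambda_E_mg_per_g"]) * 1e-3
    return _build(block, raw, BatchCondition, _BATCH_KEYS, defaults_log)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Missing blocks fall back to package defaults; every defaulted key is
    recorded in ``defaults_applied`` so runs are auditable.  Unknown keys at
    any level raise :class:`ConfigSchemaError` naming the key.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigSchemaError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigSchemaError("top level of the config must be a mapping")
    unknown = set(raw) - set(_BLOCKS)
    if unknown:
        raise ConfigSchemaError(
            f"unknown top-level block(s): {sorted(unknown)}; "
            f"expected {sorted(_BLOCKS)}"
        )
    version = str(raw.get("schema_version", SCHEMA_VERSION))
    if version != SCHEMA_VERSION:
        raise ConfigSchemaError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})"
        )

    log: list[str] = []
    catalog = _build("species", raw.get("species"), SpeciesCatalog, _SPECIES_KEYS, log)
    density = _build("density", raw.get("density"), DensitySpec, _DENSITY_KEYS, log)
    rates = _build("kinetics", raw.get("kinetics"), RateParams, _KINETICS_KEYS, log)
    adsorption = _build(
        "adsorption", raw.get("adsorption"), AdsorptionParams, _ADSORPTION_KEYS, log
    )
    substrate = dict(raw.get("substrate") or {})
    unknown = set(substrate) - {"y_F0"}
    if unknown:
        raise ConfigSchemaError(f"unknown key(s) in `substrate:`: {sorted(unknown)}")
    y_F0 = substrate.get("y_F0", 0.60)
    if "y_F0" not in substrate:
        log.append("substrate.y_F0")
    try:
        params = ModelParams(
            rates=rates, adsorption=adsorption, y_F0=y_F0,
            catalog=catalog, density=density,
        )
    except DomainError as exc:
        raise ConfigSchemaError(f"invalid `substrate.y_F0`: {exc}") from exc

    batch = None
    if "batch" in raw:
        batch = _parse_batch("batch", raw["batch"], log)

    ceh = None
    ceh_duration = 72.0
    if "ceh" in raw:
        ceh_raw = dict(raw["ceh"])
        ceh_keys = {
            "m_s_in_kg_per_h": "m_s_in",
            "m_e_in_kg_per_h": "m_e_in",
            "m_m_out_kg_per_h": "m_m_out",
            "m_p_out_kg_per_h": "m_p_out",
            "m_T_kg": "m_T",
            "c_E_feed_g_per_L": "c_E_feed",
            "eta_E": "eta_E",
            "startup_h": "startup_h",
        }
        ceh_duration = float(ceh_raw.pop("duration_h", 72.0))
        feed_raw = ceh_raw.pop("feed", None)
        unknown = set(ceh_raw) - set(ceh_keys)
        if unknown:
            raise ConfigSchemaError(
                f"unknown key(s) in `ceh:`: {sorted(unknown)}; "
                f"expected {sorted(ceh_keys) + ['feed', 'duration_h']}"
            )
        kwargs = {attr: ceh_raw[k] for k, attr in ceh_keys.items() if k in ceh_raw}
        for k, attr in ceh_keys.items():
            if k not in ceh_raw and attr != "m_p_out":
                log.append(f"ceh.{k}")
        kwargs["feed"] = _parse_batch("ceh.feed", feed_raw, log)
        try:
            ceh = StreamSpec(**kwargs)
        except (DomainError, ValueError) as exc:
            raise ConfigSchemaError(f"invalid `ceh:` block: {exc}") from exc

    fit = _build("fit", raw.get("fit"), FitOptions, _FIT_KEYS, log)
    noise = _build("noise", raw.get("noise"), NoiseModel, _NOISE_KEYS, log)

    return RunConfig(
        params=params,
        batch=batch,
        ceh=ceh,
        ceh_duration_h=ceh_duration,
        fit=fit,
        noise=noise,
        defaults_applied=log,
        config_hash=hashlib.sha256(text.encode()).hexdigest()[:16],
    )


def _batch_to_dict(cond: BatchCondition) -> dict:
    inv = {attr: key for key, attr in _BATCH_KEYS.items()}
    out = {}
    for attr, key in inv.items():
        v = getattr(cond, attr)
        out[key] = v * 1e3 if attr == "lambda_E" else v
    return out


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a RunConfig back to YAML; ``load_config`` of the result is an
    identity on every validated field."""
    doc: dict = {"schema_version": SCHEMA_VERSION}
    cat, dens = cfg.params.catalog, cfg.params.density
    doc["species"] = {k: getattr(cat, a) for k, a in _SPECIES_KEYS.items()}
    doc["density"] = {k: getattr(dens, a) for k, a in _DENSITY_KEYS.items()}
    doc["kinetics"] = {k: getattr(cfg.params.rates, a) for k, a in _KINETICS_KEYS.items()}
    doc["adsorption"] = {
        k: getattr(cfg.params.adsorption, a) for k, a in _ADSORPTION_KEYS.items()
    }
    doc["substrate"] = {"y_F0": cfg.params.y_F0}
    if cfg.batch is not None:
        doc["batch"] = _batch_to_dict(cfg.batch)
    if cfg.ceh is not None:
        doc["ceh"] = {
            "m_s_in_kg_per_h": cfg.ceh.m_s_in,
            "m_e_in_kg_per_h": cfg.ceh.m_e_in,
            "m_m_out_kg_per_h": cfg.ceh.m_m_out,
            "m_p_out_kg_per_h": cfg.ceh.m_p_out,
            "m_T_kg": cfg.ceh.m_T,
            "c_E_feed_g_per_L": cfg.ceh.c_E_feed,
            "eta_E": cfg.ceh.eta_E,
            "startup_h": cfg.ceh.startup_h,
            "duration_h": cfg.ceh_duration_h,
            "feed": _batch_to_dict(cfg.ceh.feed),
        }
    doc["fit"] = {k: getattr(cfg.fit, a) for k, a in _FIT_KEYS.items()}
    doc["noise"] = {k: getattr(cfg.noise, a) for k, a in _NOISE_KEYS.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_DATASET_COLUMNS = ["time_h", "observable", "value", "weight"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise ConfigSchemaError(f"{path}: empty observation file")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")
    return df


def _require_numeric(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        if coerced.isna().any() and not df[c].isna().any():
            raise NonNumericError(f"{path}: non-numeric value in column {c!r}")
        df[c] = coerced


def read_dataset_csv(path: str | Path, condition: BatchCondition | None = None) -> Dataset:
    """Read a long-form observation CSV into a :class:`Dataset`.

    Columns: ``time_h``, ``observable`` (glucose_g_per_L / xylose_g_per_L /
    f_is), ``value``, optional ``weight``.
    """
    df = _read_csv(path, ["time_h", "observable", "value"])
    _require_numeric(df, ["time_h", "value"], path)
    if "weight" not in df.columns:
        df["weight"] = 1.0
    return Dataset(
        condition=condition or BatchCondition(),
        observations=df[_DATASET_COLUMNS],
        label=Path(path).stem,
    )


def write_dataset_csv(ds: Dataset, path: str | Path) -> None:
    ds.observations[_DATASET_COLUMNS].to_csv(
        path, index=False, float_format="%.15g"
    )


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the canonical column order, 15 significant digits."""
    traj.to_frame().to_csv(path, index=False, float_format="%.15g")


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV back, validating the dialect."""
    df = _read_csv(path, TRAJECTORY_COLUMNS)
    _require_numeric(df, TRAJECTORY_COLUMNS, path)
    t = df["time_h"].to_numpy()
    if np.any(np.diff(t) < 0):
        raise NonMonotoneTimeError(f"{path}: time_h is not monotone non-decreasing")
    return df
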
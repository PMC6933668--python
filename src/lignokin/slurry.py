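"""Species catalog, slurry state, and concentration-basis algebra.

A hydrolysis slurry is described by mass fractions of each tracked species
relative to the *total* slurry mass.  Insoluble species (facile and
recalcitrant glucan, xylan, lignin, inert solids) make up the insoluble-solids
fraction ``f_is``; everything else (water, dissolved sugars, soluble lignin,
enzyme) is the liquid fraction ``f_l = 1 - f_is``.

Three concentration bases are used and interconverted here:

* mass fraction ``f_i`` (kg species / kg slurry),
* slurry-basis molar concentration ``c̃_i`` (kmol / m³ slurry),
* liquid-basis molar concentration ``c_i`` (kmol / m³ liquid),

related by ``f_i = MW_i · c̃_i / ρ_T`` and ``c̃_i = ε_l · c_i`` where ``ε_l``
is the volume fraction of liquid and ``ρ_T`` the slurry density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "SpeciesCatalog",
    "SlurryState",
    "DensitySpec",
    "slurry_density",
    "liquid_volume_fraction",
    "mass_fraction_to_slurry_molar",
    "slurry_molar_to_mass_fraction",
    "slurry_to_liquid_molar",
    "liquid_to_slurry_molar",
]

#: Lignin representative monomer molecular-weight range reported in the
#: literature (Da); values outside trigger a warning unless overridden.
LIGNIN_MW_RANGE = (188.0, 211.0)


class DomainError(ValueError):
    """A physically invalid quantity (negative fraction, zero MW, ...)."""


@dataclass(frozen=True)
class SpeciesCatalog:
    """Monomer molecular weights (kg/kmol) for all tracked species.

    Glucan and xylan use anhydro-monomer weights (the polymer repeat unit);
    the hydrolyzed sugars carry one extra water.  Lignin chemistry is not
    resolved: a single representative monomer weight is used for both
    insoluble and soluble lignin.  The lumped enzyme cocktail is assigned a
    single molecular weight ``mw_enzyme``; only the product of ``mw_enzyme``
    with the rate coefficients is observable, so any fixed choice gives a
    self-consistent model (see docs/methods.md).
    """

    mw_glucan: float = 162.14  # anhydroglucose
    mw_xylan: float = 132.12  # anhydroxylose
    mw_glucose: float = 180.16
    mw_xylose: float = 150.13
    mw_lignin: float = 200.0
    mw_soluble_lignin: float = 200.0
    mw_enzyme: float = 65000.0

    def __post_init__(self) -> None:
        for name in (
            "mw_glucan",
            "mw_xylan",
            "mw_glucose",
            "mw_xylose",
            "mw_lignin",
            "mw_soluble_lignin",
            "mw_enzyme",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if not (self.r_g < 1.0 and self.r_x < 1.0):
            raise DomainError(
                "monomer molecular weight must be below the hydrated sugar's"
            )
        lo, hi = LIGNIN_MW_RANGE
        for name in ("mw_lignin", "mw_soluble_lignin"):
            mw = getattr(self, name)
            if not (lo <= mw <= hi):
                warnings.warn(
                    f"{name}={mw} outside the representative range "
                    f"[{lo}, {hi}] Da",
                    stacklevel=2,
                )

    @property
    def r_g(self) -> float:
        """Glucan-monomer to glucose molecular-weight ratio."""
        return self.mw_glucan / self.mw_glucose

    @property
    def r_x(self) -> float:
        """Xylan-monomer to xylose molecular-weight ratio."""
        return self.mw_xylan / self.mw_xylose


@dataclass(frozen=True)
class DensitySpec:
    """Liquid and insoluble-solids (skeletal) densities, kg/m³.

    With ``use_constant_density`` (the default) the slurry density is
    approximated by the liquid density — accurate to <5% for f_is < 0.15 and
    ρ_is < 1400 kg/m³.  Otherwise the harmonic mixture rule is applied.
    """

    rho_liquid: float = 1000.0
    rho_solids: float = 1400.0
    use_constant_density: bool = True

    def __post_init__(self) -> None:
        if self.rho_liquid <= 0 or self.rho_solids <= 0:
            raise DomainError("densities must be strictly positive")
        if self.rho_solids < self.rho_liquid:
            warnings.warn(
                "skeletal solids density below liquid density is atypical",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SlurryState:
    """Mass fractions of all tracked species on a total-slurry basis.

    ``f_GR``/``f_GF`` split glucan into recalcitrant and facile populations;
    ``f_O`` is inert insoluble material (ash plus unresolved structural
    carbohydrate) that contributes to ``f_is`` but never reacts.
    """

    f_GR: float = 0.0
    f_GF: float = 0.0
    f_X: float = 0.0
    f_L: float = 0.0
    f_O: float = 0.0
    f_g: float = 0.0
    f_x: float = 0.0
    f_sL: float = 0.0
    f_ET: float = 0.0

    SPECIES = ("f_GR", "f_GF", "f_X", "f_L", "f_O", "f_g", "f_x", "f_sL", "f_ET")

    def __post_init__(self) -> None:
        total = 0.0
        for name in self.SPECIES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name}={v} outside [0, 1]")
            total += v
        if total > 1.0 + 1e-9:
            raise DomainError(f"species fractions sum to {total} > 1")
        if not (0.0 <= self.f_is < 1.0):
            raise DomainError(f"f_is={self.f_is} outside [0, 1)")

    @property
    def f_is(self) -> float:
        """Insoluble-solids mass fraction (glucan + xylan + lignin + inerts)."""
        return self.f_GR + self.f_GF + self.f_X + self.f_L + self.f_O

    @property
    def f_l(self) -> float:
        """Liquid mass fraction."""
        return 1.0 - self.f_is

    def replace(self, **kwargs: float) -> "SlurryState":
        return replace(self, **kwargs)


def slurry_density(state: SlurryState, dens: DensitySpec) -> float:
    """Total slurry density ρ_T (kg/m³).

    Harmonic mixture of the solids skeletal density and the liquid density,
    weighted by mass fraction; reduces to ρ_l in constant-density mode.
    """
    if dens.use_constant_density:
        return dens.rho_liquid
    return 1.0 / (state.f_is / dens.rho_solids + state.f_l / dens.rho_liquid)


def liquid_volume_fraction(state: SlurryState, dens: DensitySpec) -> float:
    """Volume fraction of liquid ε_l = (ρ_T/ρ_l)·f_l, in (0, 1]."""
    eps = slurry_density(state, dens) / dens.rho_liquid * state.f_l
    if eps <= 0.0:
        raise DomainError("degenerate slurry: no liquid phase")
    return eps


def mass_fraction_to_slurry_molar(f_i: float, mw_i: float, rho_T: float) -> float:
    """c̃_i = f_i · ρ_T / MW_i (kmol/m³ slurry)."""
    if mw_i <= 0:
        raise DomainError("molecular weight must be strictly positive")
    return f_i * rho_T / mw_i


def slurry_molar_to_mass_fraction(c_tilde: float, mw_i: float, rho_T: float) -> float:
    """Inverse of :func:`mass_fraction_to_slurry_molar`."""
    if mw_i <= 0:
        raise DomainError("molecular weight must be strictly positive")
    return mw_i * c_tilde / rho_T


def slurry_to_liquid_molar(c_tilde: float, eps_l: float) -> float:
    """c_i = c̃_i / ε_l (kmol/m³ liquid)."""
    if eps_l <= 0.0:
        raise DomainError("degenerate slurry: zero liquid volume fraction")
    return c_tilde / eps_l


def liquid_to_slurry_molar(c_i: float, eps_l: float) -> float:
    """c̃_i = ε_l · c_i (kmol/m³ slurry)."""
    if not (0.0 < eps_l <= 1.0):
        raise DomainError("liquid volume fraction must lie in (0, 1]")
    return eps_l * c_i
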
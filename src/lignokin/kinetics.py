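"""Reaction rates: first-order hydrolysis by adsorbed enzyme, plus
carbohydrate-coupled lignin solubilization.

Substrate digestion is first order in the adsorbed-enzyme concentration:
``-r̃_GR = k_R·c̃_EGR`` and likewise for facile glucan and xylan.  Products
mirror their substrates molar-for-molar (glucose from both glucan pools,
xylose from xylan).  Insoluble lignin is solubilized in proportion to the
combined recalcitrant-glucan and xylan molar rates, scaled by the local
lignin concentration:

    r̃_L = k_L · c̃_L · (r̃_GR + r̃_X)   (≤ 0, since both rates are ≤ 0).

Mass-basis rates are the molar rates scaled by each species' own molecular
weight over the slurry density; because the sugars carry one extra water,
total tracked mass grows as hydrolysis proceeds (the water is implicit).
"""

from __future__ import annotations

from dataclasses import dataclass

from .partition import EnzymePartition
from .slurry import DomainError, SpeciesCatalog

__all__ = ["RateParams", "RateVector", "molar_rates", "mass_rates"]


@dataclass(frozen=True)
class RateParams:
    """Hydrolysis-rate coefficients.

    k_R, k_F, k_X are first-order coefficients (1/h) in the respective
    adsorbed-enzyme concentration; k_L (m³ liquid/kmol) couples lignin
    solubilization to carbohydrate digestion.  ``tie_kR_kF`` enforces the
    equal-intrinsic-rate assumption (rate difference between glucan
    populations attributed entirely to accessibility): k_F follows k_R.
    """

    k_R: float = 14713.0
    k_F: float = 14713.0
    k_X: float = 10000.0
    k_L: float = 729.5
    tie_kR_kF: bool = True

    def __post_init__(self) -> None:
        for name in ("k_R", "k_F", "k_X", "k_L"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if self.tie_kR_kF and self.k_F != self.k_R:
            object.__setattr__(self, "k_F", self.k_R)


@dataclass(frozen=True)
class RateVector:
    """Reaction rates for one slurry state.

    ``r_*`` are slurry-basis molar rates, kmol/(m³ slurry·h); ``R_*`` are
    mass rates, kg/(kg slurry·h).  Substrate rates are ≤ 0, products ≥ 0.
    """

    r_GR: float = 0.0
    r_GF: float = 0.0
    r_X: float = 0.0
    r_L: float = 0.0
    r_g: float = 0.0
    r_x: float = 0.0
    r_sL: float = 0.0
    R_GR: float = 0.0
    R_GF: float = 0.0
    R_X: float = 0.0
    R_L: float = 0.0
    R_g: float = 0.0
    R_x: float = 0.0
    R_sL: float = 0.0


def molar_rates(
    enzyme: EnzymePartition,
    c_L: float,
    rates: RateParams,
    include_facile_in_lignin: bool = False,
) -> RateVector:
    """Slurry-basis molar rates from an enzyme partition.

    ``c_L`` is the insoluble-lignin slurry-molar concentration.  By default
    lignin solubilization is driven by the recalcitrant-glucan and xylan
    rates only; ``include_facile_in_lignin`` adds the facile-glucan rate as
    an exploratory variant.
    """
    if c_L < 0:
        raise DomainError("c_L must be non-negative")
    r_GR = -rates.k_R * enzyme.c_EGR
    r_GF = -rates.k_F * enzyme.c_EGF
    r_X = -rates.k_X * enzyme.c_EX
    driver = r_GR + r_X + (r_GF if include_facile_in_lignin else 0.0)
    r_L = rates.k_L * c_L * driver
    return RateVector(
        r_GR=r_GR,
        r_GF=r_GF,
        r_X=r_X,
        r_L=r_L,
        r_g=-(r_GR + r_GF),
        r_x=-r_X,
        r_sL=-r_L,
    )


def mass_rates(molar: RateVector, catalog: SpeciesCatalog, rho_T: float) -> RateVector:
    """Attach mass-basis rates R_i = MW_i · r̃_i / ρ_T to a molar rate vector.

    Soluble lignin uses the representative lignin monomer weight, matching
    the insoluble pool it comes from.
    """
    s = 1.0 / rho_T
    return RateVector(
        r_GR=molar.r_GR,
        r_GF=molar.r_GF,
        r_X=molar.r_X,
        r_L=molar.r_L,
        r_g=molar.r_g,
        r_x=molar.r_x,
        r_sL=molar.r_sL,
        R_GR=catalog.mw_glucan * molar.r_GR * s,
        R_GF=catalog.mw_glucan * molar.r_GF * s,
        R_X=catalog.mw_xylan * molar.r_X * s,
        R_L=catalog.mw_lignin * molar.r_L * s,
        R_g=catalog.mw_glucose * molar.r_g * s,
        R_x=catalog.mw_xylose * molar.r_x * s,
        R_sL=catalog.mw_soluble_lignin * molar.r_sL * s,
    )
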
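"""Equilibrium partitioning of the lumped enzyme cocktail.

Total enzyme is split six ways at adsorption equilibrium: free in solution,
adsorbed to facile glucan, to recalcitrant glucan, to xylan, unproductively
bound by soluble lignin, and competitively inhibited by soluble sugars
(glucose + xylose).  Each equilibrium is a dissociation relation
``K = c_Ef · c_substrate / c_complex``; dividing through by the
recalcitrant-glucan relation gives dimensionless affinity ratios

    κ_RF = K_dR/K_dF,  κ_RX = K_dR/K_dX,  κ_RL = K_dR/K_IL,  κ_Rs = K_dR/K_Is,

so the model is parameterized by one absolute scale (K_dR) and four ratios.
The closed-form solution divides total enzyme by the partition denominator

    𝒟 = 1 + κ_RF·λ_FR + κ_RX·λ_XR + (ε_l/c̃_GR)(K_dR + κ_RL·c_sL + κ_Rs·c_ss)

with λ_FR = c̃_GF/c̃_GR, λ_XR = c̃_X/c̃_GR.  Internally the regularized form
𝒟′ = c̃_GR·𝒟 is used so that substrate depletion (c̃_GR → 0) stays finite.

κ_RF > 1 admits an accessibility reading: only a fraction α = 1/κ_RF of
recalcitrant glucan is reachable by enzyme, the intrinsic (accessible-site)
affinity being identical for both glucan populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .slurry import (
    DensitySpec,
    DomainError,
    SlurryState,
    SpeciesCatalog,
    liquid_volume_fraction,
    mass_fraction_to_slurry_molar,
    slurry_density,
)

__all__ = [
    "AdsorptionParams",
    "EnzymePartition",
    "DegeneratePartitionError",
    "partition_denominator",
    "partition_enzyme",
    "partition_from_concentrations",
    "accessibility",
]


class DegeneratePartitionError(DomainError):
    """Enzyme has no adsorption sites, no inhibitors and no free-pool scale."""


@dataclass(frozen=True)
class AdsorptionParams:
    """Adsorption/inhibition equilibrium parameters.

    K_dR is the dissociation coefficient for enzyme on recalcitrant glucan
    (kmol/m³ liquid); lower values mean stronger binding.  The κ ratios
    relate every other species' affinity to recalcitrant glucan; larger κ
    means relatively stronger binding to that species.
    """

    K_dR: float = 0.05
    kappa_RF: float = 9.34
    kappa_RX: float = 11.3
    kappa_RL: float = 50.0
    kappa_Rs: float = 50.0

    def __post_init__(self) -> None:
        if self.K_dR <= 0:
            raise DomainError("K_dR must be strictly positive")
        for name in ("kappa_RF", "kappa_RX", "kappa_RL", "kappa_Rs"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EnzymePartition:
    """Six-way enzyme split, all on the slurry-molar basis (kmol/m³ slurry).

    The free and inhibited pools live in the liquid phase; they are stored
    here on the slurry basis (multiplied by ε_l) so that the closure
    c̃_Ef + c̃_EGF + c̃_EGR + c̃_EX + c̃_EsL + c̃_Ess = c̃_ET holds in one basis.
    """

    c_Ef: float
    c_EGR: float
    c_EGF: float
    c_EX: float
    c_EsL: float
    c_Ess: float

    @property
    def total(self) -> float:
        return (
            self.c_Ef + self.c_EGR + self.c_EGF + self.c_EX + self.c_EsL + self.c_Ess
        )

    @property
    def soluble(self) -> float:
        """Membrane-permeable pools: free + sugar-inhibited + lignin-inhibited."""
        return self.c_Ef + self.c_EsL + self.c_Ess


def _regularized_denominator(
    c_GR: float,
    c_GF: float,
    c_X: float,
    c_sL: float,
    c_ss: float,
    eps_l: float,
    params: AdsorptionParams,
) -> float:
    """𝒟′ = c̃_GR·𝒟, finite in the c̃_GR → 0 limit."""
    return (
        c_GR
        + params.kappa_RF * c_GF
        + params.kappa_RX * c_X
        + eps_l * (params.K_dR + params.kappa_RL * c_sL + params.kappa_Rs * c_ss)
    )


def partition_denominator(
    c_GR: float,
    c_GF: float,
    c_X: float,
    c_sL: float,
    c_ss: float,
    eps_l: float,
    params: AdsorptionParams,
) -> float:
    """Dimensionless partition denominator 𝒟 (≥ 1 whenever c̃_GR > 0).

    Substrate arguments are slurry-basis molar (kmol/m³ slurry); the
    inhibitor concentrations ``c_sL`` and ``c_ss`` are liquid-basis.
    """
    for name, v in (
        ("c_GR", c_GR),
        ("c_GF", c_GF),
        ("c_X", c_X),
        ("c_sL", c_sL),
        ("c_ss", c_ss),
    ):
        if v < 0:
            raise DomainError(f"{name} must be non-negative")
    if not (0.0 < eps_l <= 1.0):
        raise DomainError("eps_l must lie in (0, 1]")
    dprime = _regularized_denominator(c_GR, c_GF, c_X, c_sL, c_ss, eps_l, params)
    if dprime == 0.0:
        raise DegeneratePartitionError(
            "no substrate, no inhibitors and K_dR-term vanished: the enzyme "
            "partition is undefined"
        )
    if c_GR == 0.0:
        return float("inf")
    return dprime / c_GR


def partition_from_concentrations(
    c_ET: float,
    c_GR: float,
    c_GF: float,
    c_X: float,
    c_sL: float,
    c_ss: float,
    eps_l: float,
    params: AdsorptionParams,
) -> EnzymePartition:
    """Closed-form six-way partition from slurry-molar substrate and
    liquid-molar inhibitor concentrations.

    Linear in ``c_ET``; satisfies the closure exactly by construction.
    """
    if c_ET < 0:
        raise DomainError("c_ET must be non-negative")
    dprime = _regularized_denominator(c_GR, c_GF, c_X, c_sL, c_ss, eps_l, params)
    if dprime == 0.0:
        raise DegeneratePartitionError(
            "enzyme partition undefined: all binding terms vanish"
        )
    scale = c_ET / dprime
    return EnzymePartition(
        c_EGR=scale * c_GR,
        c_EGF=scale * params.kappa_RF * c_GF,
        c_EX=scale * params.kappa_RX * c_X,
        c_Ef=scale * eps_l * params.K_dR,
        c_EsL=scale * eps_l * params.kappa_RL * c_sL,
        c_Ess=scale * eps_l * params.kappa_Rs * c_ss,
    )


def partition_enzyme(
    state: SlurryState,
    params: AdsorptionParams,
    catalog: SpeciesCatalog | None = None,
    dens: DensitySpec | None = None,
) -> EnzymePartition:
    """Partition the total enzyme of a slurry state at adsorption equilibrium.

    Converts the state's mass fractions to molar concentrations (slurry basis
    for substrates, liquid basis for the soluble inhibitors — soluble sugars
    are the plain molar sum of glucose and xylose) and applies the closed
    form.
    """
    catalog = catalog or SpeciesCatalog()
    dens = dens or DensitySpec()
    rho_T = slurry_density(state, dens)
    eps_l = liquid_volume_fraction(state, dens)
    to_molar = lambda f, mw: mass_fraction_to_slurry_molar(f, mw, rho_T)  # noqa: E731
    c_ss = (
        to_molar(state.f_g, catalog.mw_glucose) + to_molar(state.f_x, catalog.mw_xylose)
    ) / eps_l
    c_sL = to_molar(state.f_sL, catalog.mw_soluble_lignin) / eps_l
    return partition_from_concentrations(
        c_ET=to_molar(state.f_ET, catalog.mw_enzyme),
        c_GR=to_molar(state.f_GR, catalog.mw_glucan),
        c_GF=to_molar(state.f_GF, catalog.mw_glucan),
        c_X=to_molar(state.f_X, catalog.mw_xylan),
        c_sL=c_sL,
        c_ss=c_ss,
        eps_l=eps_l,
        params=params,
    )


def accessibility(params: AdsorptionParams) -> float:
    """Accessible fraction α = 1/κ_RF of recalcitrant glucan.

    Meaningful only when κ_RF ≥ 1 (warns otherwise but still returns the
    reciprocal).
    """
    if params.kappa_RF < 1.0:
        warnings.warn(
            "kappa_RF < 1: the accessibility interpretation alpha = 1/kappa_RF "
            "does not hold",
            stacklevel=2,
        )
    if params.kappa_RF == 0.0:
        raise DomainError("kappa_RF must be positive to define accessibility")
    return 1.0 / params.kappa_RF
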
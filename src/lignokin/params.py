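"""Bundled model parameters.

:class:`ModelParams` collects everything the simulators need: the
hydrolysis-rate coefficients, the adsorption/inhibition equilibria, the
initial facile fraction of glucan ``y_F0``, and the fixed physical constants
(molecular weights, densities).  The defaults are the best-fit parameter set
for deacetylated, dilute-acid-pretreated corn stover hydrolyzed by a lumped
commercial cellulase cocktail at 50 °C, pH 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

from .kinetics import RateParams
from .partition import AdsorptionParams
from .slurry import DensitySpec, DomainError, SpeciesCatalog

__all__ = ["ModelParams"]


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set for the two-phase hydrolysis model."""

    rates: RateParams = field(default_factory=RateParams)
    adsorption: AdsorptionParams = field(default_factory=AdsorptionParams)
    y_F0: float = 0.60
    catalog: SpeciesCatalog = field(default_factory=SpeciesCatalog)
    density: DensitySpec = field(default_factory=DensitySpec)

    def __post_init__(self) -> None:
        if not (0.0 <= self.y_F0 <= 1.0):
            raise DomainError("y_F0 must lie in [0, 1]")

    # Names of the fittable scalar parameters, in canonical order.
    FITTABLE = (
        "k_R",
        "k_F",
        "k_X",
        "k_L",
        "K_dR",
        "kappa_RF",
        "kappa_RX",
        "kappa_RL",
        "kappa_Rs",
        "y_F0",
    )

    def get(self, name: str) -> float:
        if hasattr(self.rates, name):
            return getattr(self.rates, name)
        if hasattr(self.adsorption, name):
            return getattr(self.adsorption, name)
        if name == "y_F0":
            return self.y_F0
        raise KeyError(name)

    def with_values(self, **values: float) -> "ModelParams":
        """Return a copy with the named scalar parameters replaced.

        With the k_R = k_F tie active, setting ``k_R`` updates both.
        """
        rate_kw: dict[str, Any] = {}
        ads_kw: dict[str, Any] = {}
        top_kw: dict[str, Any] = {}
        for name, v in values.items():
            if name in ("k_R", "k_F", "k_X", "k_L", "tie_kR_kF"):
                rate_kw[name] = v
            elif name in ("K_dR", "kappa_RF", "kappa_RX", "kappa_RL", "kappa_Rs"):
                ads_kw[name] = v
            elif name == "y_F0":
                top_kw[name] = v
            else:
                raise KeyError(f"unknown model parameter: {name}")
        new = self
        if rate_kw:
            new = replace(new, rates=replace(self.rates, **rate_kw))
        if ads_kw:
            new = replace(new, adsorption=replace(self.adsorption, **ads_kw))
        if top_kw:
            new = replace(new, **top_kw)
        return new

    def scaled(self, name: str, factor: float) -> "ModelParams":
        """Copy with one parameter multiplied by ``factor`` (sensitivity sweeps)."""
        return self.with_values(**{name: self.get(name) * factor})
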
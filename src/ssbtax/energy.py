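"""Energy-intake and equilibrium body-weight response.

Volume changes are converted to kcal/day with per-category energy densities,
then to a long-run population body-weight change through the energy-balance
equilibrium rule: a sustained 1% change in total energy intake moves
equilibrium body weight by about 0.7%.  BMI shifts proportionally to weight
(height held fixed), which is the sole bridge between kg and BMI units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .demand import CATEGORIES

#: default energy densities, kcal per 100 ml
DEFAULT_DENSITIES: dict[str, float] = {"ssb": 48.0, "fruit_juice": 45.0, "milk": 59.0}


@dataclass(frozen=True)
class EnergyDensity:
    """kcal per 100 ml for each beverage category."""

    kcal_per_100ml: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES)
    )

    def __post_init__(self) -> None:
        for cat, v in self.kcal_per_100ml.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown beverage category {cat!r}")
            if v <= 0:
                raise ValueError(f"energy density for {cat} must be > 0")

    def kcal_per_ml(self, category: str) -> float:
        if category not in self.kcal_per_100ml:
            raise KeyError(f"no energy density for category {category!r}")
        return self.kcal_per_100ml[category] / 100.0


@dataclass(frozen=True)
class WeightResponse:
    """Equilibrium elasticity of body weight to total energy intake.

    Default 0.7: percent weight change per percent energy-intake change.
    """

    elasticity_weight_energy: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 < self.elasticity_weight_energy <= 1.0:
            raise ValueError("elasticity_weight_energy must be in (0, 1]")


def energy_change(
    volume_changes: Mapping[str, float], densities: EnergyDensity | None = None
) -> float:
    """Daily energy-intake change ΔE = Σ_c Δml_c × kcal/ml_c (kcal/day)."""
    densities = densities or EnergyDensity()
    total = 0.0
    for cat, dml in volume_changes.items():
        total += dml * densities.kcal_per_ml(cat)
    return total


def apply_caloric_compensation(gross_kcal: float, fraction: float) -> float:
    """Retain (1 − fraction) of a gross caloric change.

    Implements the substitution-as-calories assumption: a given fraction of
    the calories removed by the tax is compensated through other beverages
    and foods.  Applied only under ``substitution_mode='caloric_fraction'``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("compensation fraction must be in [0, 1]")
    return gross_kcal * (1.0 - fraction)


def equilibrium_weight_change(
    delta_e: float,
    total_e: float,
    weight: float,
    resp: WeightResponse | None = None,
) -> float:
    """Long-run weight change Δw = 0.7 × (ΔE / E) × w (kg)."""
    if total_e <= 0:
        raise ValueError("total energy intake must be > 0")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    resp = resp or WeightResponse()
    return resp.elasticity_weight_energy * (delta_e / total_e) * weight


def bmi_change(delta_w: float, weight: float, bmi_mean: float) -> float:
    """BMI change implied by a weight change at fixed height.

    Relative BMI change equals relative weight change, so
    Δbmi = bmi_mean × Δw / w.
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    return bmi_mean * (delta_w / weight)
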
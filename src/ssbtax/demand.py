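"""Beverage demand response to a price change induced by an SSB tax.

A value-added tax of rate ``r`` with pass-through ``p`` raises the consumer
price by ``Δp = r·p``.  Demand responds through marginal (linear) price
elasticities: a good with own-price elasticity ``ε`` and baseline consumption
``q`` changes by ``Δq = ε·Δp·q`` ml/day.  Untaxed substitutes (fruit juice,
milk) may respond through cross-price elasticities.

Two consumption-dependent elasticity adjustments induce heterogeneity across
age–sex cohorts:

* own-price adjustment: ``ε_age = γ · ε · (θ̄_sex / θ_sex,age)`` — heavy
  consumers react *less* elastically (addiction/habit formation), with γ a
  scaling factor chosen so the within-sex mean of the adjusted elasticities
  recovers ε;
* cross-price adjustment: ``ε_cross,age = ε_cross · (θ_sex,age / θ̄_sex)`` —
  heavy SSB consumers are *more* likely to substitute to juice.

θ denotes baseline SSB intake (ml/day); θ̄_sex is the sex-level mean over age
bands (unweighted by default, population-weighted optionally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: canonical beverage categories, in fixed order
CATEGORIES: tuple[str, ...] = ("ssb", "fruit_juice", "milk")

OWN_PE_MODES = ("marginal", "consumption_adjusted", "alternative_meta")
SUBSTITUTION_MODES = ("none", "cross_pe", "adjusted_cross_pe", "caloric_fraction")
SCENARIO_NAMES = ("main", "M1", "M2", "M3", "M4a", "M4b", "M4c", "S1", "S2", "S3")


class Param(NamedTuple):
    """A point estimate with its standard error (for Monte Carlo sampling)."""

    mean: float
    se: float = 0.0


@dataclass(frozen=True)
class TaxPolicy:
    """A value-added tax on beverages.

    Parameters
    ----------
    rate
        Tax rate as a fraction of price (0.20 = 20% VAT).
    pass_through
        Fraction of the tax passed from producers to consumer prices.
    taxed_categories
        Which categories the tax applies to; SSBs are always taxed when the
        rate is positive, fruit juice optionally (the juice-inclusive
        scenario).
    """

    rate: float
    pass_through: float = 0.82
    taxed_categories: frozenset[str] = frozenset({"ssb"})

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"tax rate must be in [0, 1], got {self.rate}")
        if not 0.0 <= self.pass_through <= 1.0:
            raise ValueError(f"pass_through must be in [0, 1], got {self.pass_through}")
        bad = set(self.taxed_categories) - {"ssb", "fruit_juice"}
        if bad:
            raise ValueError(f"untaxable categories: {sorted(bad)}")
        if self.rate > 0 and "ssb" not in self.taxed_categories:
            raise ValueError("SSBs must be taxed whenever the rate is positive")
        object.__setattr__(self, "taxed_categories", frozenset(self.taxed_categories))


@dataclass(frozen=True)
class ElasticitySet:
    """Price elasticities of beverage demand (dimensionless, with SEs).

    ``own_pe_ssb`` is the meta-analytic marginal own-price elasticity of
    SSBs; ``alt_own_pe_ssb`` the estimate from an alternative meta-analysis
    of intervention/prospective studies, stored signed (applied as a demand
    decrease even though its source prints the magnitude).
    """

    own_pe_ssb: Param = Param(-1.299, 0.107)
    cross_pe_juice: Param = Param(0.388, 0.15)
    cross_pe_milk: Param = Param(0.129, 0.08)
    alt_own_pe_ssb: Param = Param(-0.674, 0.08)

    def __post_init__(self) -> None:
        if self.own_pe_ssb.mean >= 0:
            raise ValueError("own_pe_ssb must be negative as applied")
        if self.alt_own_pe_ssb.mean >= 0:
            raise ValueError("alt_own_pe_ssb must be negative as applied")
        if self.cross_pe_juice.mean < 0 or self.cross_pe_milk.mean < 0:
            raise ValueError("cross-price elasticities must be >= 0 as applied")


@dataclass(frozen=True)
class ScenarioConfig:
    """A named bundle of tax policy and behavioural-response assumptions.

    The ten presets (see :func:`ssbtax.synth.reference_scenarios`) are the
    main 20% tax, assumption modifications M1–M4c, and policy scenarios
    S1–S3.  Arbitrary combinations are allowed but flagged in the log as
    non-preset configurations.
    """

    name: str
    policy: TaxPolicy
    own_pe_mode: str = "marginal"
    gamma: float | str = 0.5
    underreporting_factor: float = 1.0
    substitution_mode: str = "none"
    compensation_fraction: float = 0.61
    theta_bar_weighting: str = "unweighted"
    #: if True, total energy intake is inflated alongside SSB volume under
    #: underreporting correction (off by default; see docs/methods.md)
    inflate_energy_with_underreporting: bool = False

    def __post_init__(self) -> None:
        if self.own_pe_mode not in OWN_PE_MODES:
            raise ValueError(f"own_pe_mode must be one of {OWN_PE_MODES}")
        if self.substitution_mode not in SUBSTITUTION_MODES:
            raise ValueError(f"substitution_mode must be one of {SUBSTITUTION_MODES}")
        if self.theta_bar_weighting not in ("unweighted", "population"):
            raise ValueError("theta_bar_weighting must be 'unweighted' or 'population'")
        if isinstance(self.gamma, str) and self.gamma != "solve":
            raise ValueError("gamma must be a number or 'solve'")
        if self.underreporting_factor < 1.0:
            raise ValueError("underreporting_factor must be >= 1")
        if not 0.0 <= self.compensation_fraction <= 1.0:
            raise ValueError("compensation_fraction must be in [0, 1]")
        if "fruit_juice" in self.policy.taxed_categories and self.substitution_mode in (
            "cross_pe",
            "adjusted_cross_pe",
        ):
            raise ValueError(
                "taxing fruit juice together with SSB->juice cross-price "
                "substitution is undefined"
            )
        if self.name not in SCENARIO_NAMES:
            logger.info("non-preset scenario configuration %r", self.name)


@dataclass(frozen=True)
class CohortStratum:
    """One sex × 5-year age band cell of the adult population."""

    sex: str
    age_lo: int
    age_hi: int
    population: float
    intake_ml_day: Mapping[str, Param]
    energy_kcal_day: float
    weight_kg: float
    bmi_mean: float
    bmi_sd: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.population < 0:
            raise ValueError("population must be >= 0")
        if self.energy_kcal_day <= 0:
            raise ValueError("energy_kcal_day must be > 0")
        if self.bmi_sd <= 0:
            raise ValueError("bmi_sd must be > 0")
        if self.weight_kg <= 0:
            raise ValueError("weight_kg must be > 0")
        for cat, p in self.intake_ml_day.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown beverage category {cat!r}")
            if p.mean < 0:
                raise ValueError(f"{cat} intake must be >= 0 in {self.label}")

    @property
    def label(self) -> str:
        return f"{self.sex} {self.age_lo}-{self.age_hi}"

    @property
    def midpoint_age(self) -> int:
        return (self.age_lo + self.age_hi + 1) // 2


def effective_price_change(policy: TaxPolicy) -> float:
    """Relative consumer price increase Δp = rate × pass-through."""
    return policy.rate * policy.pass_through


def consumption_change(
    baseline_ml: float, pe: float, dp: float, clamp: bool = True
) -> float:
    """Marginal (linear) demand response Δq = pe · Δp · q in ml/day.

    Post-change consumption ``baseline + Δq`` is clamped at 0: large adjusted
    elasticities can otherwise drive consumption negative.  A warning is
    logged when clamping bites.
    """
    if baseline_ml < 0:
        raise ValueError("baseline consumption must be >= 0")
    delta = pe * dp * baseline_ml
    if clamp and baseline_ml + delta < 0.0:
        logger.warning(
            "post-tax consumption clamped at 0 (baseline %.1f ml, pe %.3f, dp %.3f)",
            baseline_ml,
            pe,
            dp,
        )
        delta = -baseline_ml
    return delta


def _theta_bar(
    theta: np.ndarray, weights: np.ndarray | None, labels: Sequence[str] | None
) -> float:
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        idx = int(np.argmax(theta <= 0))
        name = labels[idx] if labels is not None else f"index {idx}"
        raise ValueError(f"zero/negative SSB intake in stratum {name}: cannot adjust")
    if weights is None:
        return float(theta.mean())
    return float(np.average(theta, weights=np.asarray(weights, dtype=float)))


def adjust_own_pe(
    theta: Iterable[float],
    delta_own: float,
    gamma: float,
    weights: Iterable[float] | None = None,
    labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Consumption-adjusted own-price elasticities for one sex.

    ``ε_age = γ · ε · (θ̄ / θ_age)``: above-average consumers get smaller
    |elasticity|.  ``theta`` are age-band SSB intakes within one sex; θ̄ is
    their mean (population-weighted if ``weights`` given).  Any zero intake
    raises, naming the stratum.
    """
    theta = np.asarray(list(theta), dtype=float)
    w = None if weights is None else list(weights)
    tbar = _theta_bar(theta, None if w is None else np.asarray(w), labels)
    return gamma * delta_own * (tbar / theta)


def solve_gamma(
    theta: Iterable[float], weights: Iterable[float] | None = None
) -> float:
    """γ such that the (chosen-weighting) mean adjusted own-PE equals ε.

    With ratios ``r_age = θ̄/θ_age``, the mean of ``γ·ε·r_age`` equals ε iff
    ``γ = 1 / mean(r_age)``.
    """
    theta = np.asarray(list(theta), dtype=float)
    w = None if weights is None else np.asarray(list(weights), dtype=float)
    tbar = _theta_bar(theta, w, None)
    ratios = tbar / theta
    mean_ratio = ratios.mean() if w is None else np.average(ratios, weights=w)
    return float(1.0 / mean_ratio)


def adjust_cross_pe(
    theta: Iterable[float],
    delta_cross: float,
    weights: Iterable[float] | None = None,
) -> np.ndarray:
    """Consumption-adjusted cross-price elasticities (SSB price -> juice demand).

    ``ε_cross,age = ε_cross · (θ_age / θ̄)``: heavy SSB consumers substitute
    more.  Zero SSB intake yields zero substitution pull (no error).  The milk
    cross-elasticity is never adjusted (small value, low consumption).
    """
    theta = np.asarray(list(theta), dtype=float)
    w = None if weights is None else np.asarray(list(weights), dtype=float)
    if w is None:
        tbar = float(theta.mean())
    else:
        tbar = float(np.average(theta, weights=w))
    if tbar <= 0:
        raise ValueError("sex-level mean SSB intake must be > 0")
    return delta_cross * (theta / tbar)


def apply_underreporting(stratum: CohortStratum, factor: float) -> CohortStratum:
    """Scale self-reported SSB intake (mean and SE) by an underreporting factor.

    Other beverage categories and total energy intake are untouched.
    """
    if factor < 1.0:
        raise ValueError("underreporting factor must be >= 1")
    intake = dict(stratum.intake_ml_day)
    ssb = intake["ssb"]
    intake["ssb"] = Param(ssb.mean * factor, ssb.se * factor)
    return CohortStratum(
        sex=stratum.sex,
        age_lo=stratum.age_lo,
        age_hi=stratum.age_hi,
        population=stratum.population,
        intake_ml_day=intake,
        energy_kcal_day=stratum.energy_kcal_day,
        weight_kg=stratum.weight_kg,
        bmi_mean=stratum.bmi_mean,
        bmi_sd=stratum.bmi_sd,
    )


def scenario_volume_changes(
    config: ScenarioConfig,
    stratum: CohortStratum,
    elasticities: ElasticitySet,
    own_pe: float | None = None,
    cross_pe_juice: float | None = None,
) -> dict[str, float]:
    """Per-category daily volume changes (ml/day) for one stratum.

    ``own_pe`` / ``cross_pe_juice`` override the elasticities actually
    applied; they are required for the consumption-adjusted modes, whose
    age-specific values depend on the whole sex's intake profile and are
    computed by the caller (see :class:`ssbtax.engine.ScenarioEngine`).

    The underreporting factor is applied to the SSB baseline here, so the
    returned SSB change already reflects the inflated consumption level.
    """
    dp = effective_price_change(config.policy)
    if own_pe is None:
        if config.own_pe_mode == "marginal":
            own_pe = elasticities.own_pe_ssb.mean
        elif config.own_pe_mode == "alternative_meta":
            own_pe = elasticities.alt_own_pe_ssb.mean
        else:
            raise ValueError(
                "consumption_adjusted mode requires the per-age own_pe "
                "computed from the full sex profile (adjust_own_pe)"
            )

    ssb_base = stratum.intake_ml_day["ssb"].mean * config.underreporting_factor
    juice_base = stratum.intake_ml_day["fruit_juice"].mean
    milk_base = stratum.intake_ml_day["milk"].mean

    deltas = {c: 0.0 for c in CATEGORIES}
    deltas["ssb"] = consumption_change(ssb_base, own_pe, dp)

    if "fruit_juice" in config.policy.taxed_categories:
        # juice taxed at the same *average* own-price elasticity as SSBs;
        # no SSB<->juice cross effects apply in this design
        deltas["fruit_juice"] = consumption_change(
            juice_base, elasticities.own_pe_ssb.mean, dp
        )
    elif config.substitution_mode in ("cross_pe", "adjusted_cross_pe"):
        cpe_j = (
            elasticities.cross_pe_juice.mean
            if config.substitution_mode == "cross_pe"
            else cross_pe_juice
        )
        if cpe_j is None:
            raise ValueError(
                "adjusted_cross_pe mode requires the per-age cross_pe_juice "
                "(adjust_cross_pe)"
            )
        deltas["fruit_juice"] = consumption_change(juice_base, cpe_j, dp)
        deltas["milk"] = consumption_change(milk_base, elasticities.cross_pe_milk.mean, dp)
    # 'none' and 'caloric_fraction': volumes change only for SSBs; under
    # caloric_fraction the compensation is applied downstream on calories.
    return deltas
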
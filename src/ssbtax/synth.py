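"""Synthetic cohort, epidemiology and economic inputs.

The survey and insurance data behind the original German analysis are
restricted, so this module generates complete, internally consistent input
tables that emulate their *statistical structure* — SSB intake peaking at
20–24 and declining steeply with age, higher in men; fruit-juice and milk
intake flat; BMI means rising from ~24 to ~28 with age with right skew; T2DM
incidence log-linear in age; Gompertz-like all-cause mortality.  Magnitudes
are realistic German-adult values but make no claim of reproducing the
original population.

T2DM prevalence is produced by forward-running the package's own
illness–death recursion on the generated incidence/mortality, so prevalence
is steady-state-consistent with the life table by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demand import ScenarioConfig, TaxPolicy
from .mslt import AGE_MAX, AGE_MIN, DiseaseEpi, EconParams, RRSchedule

BANDS: list[tuple[int, int]] = [(lo, lo + 4) for lo in range(AGE_MIN, AGE_MAX, 5)]


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic world; defaults are the stated conditions."""

    seed: int = 0
    total_population: int = 1_000_000
    #: male SSB intake at 20–24, ml/day
    ssb_peak_male: float = 420.0
    #: per-band multiplicative decline range for SSB intake
    ssb_decline_range: tuple[float, float] = (0.80, 0.92)
    #: female/male SSB ratio (jittered ±2% per band)
    female_ssb_scale_range: tuple[float, float] = (0.55, 0.70)
    juice_ml: float = 165.0
    milk_ml: float = 150.0
    intake_se_frac: float = 0.07
    energy_young_male: float = 2600.0
    energy_old_male: float = 2100.0
    energy_young_female: float = 2050.0
    energy_old_female: float = 1700.0
    height_m: tuple[float, float] = (1.78, 1.65)  # male, female
    bmi_young: float = 24.0
    bmi_rise: float = 4.5
    bmi_sd_young: float = 3.8
    bmi_sd_slope: float = 0.01
    #: T2DM incidence at age 20 and log-linear slope per year (to age 80)
    t2dm_inc20: float = 5e-4
    t2dm_inc_slope: float = 0.068
    t2dm_prev20: float = 0.005
    #: Gompertz all-cause mortality: rate at 20 and slope per year
    acm20: float = 6e-4
    acm_slope: float = 0.075
    male_mortality_factor: float = 1.4
    male_incidence_factor: float = 1.2
    #: mortality hazard ratio of T2DM; excess rate = (hr − 1) × acm
    t2dm_mortality_hr: float = 1.8
    pyld_bg20: float = 0.02
    pyld_bg_slope: float = 0.0012
    dw_t2dm: float = 0.049
    cost_with_t2dm: float = 4900.0
    cost_without_t2dm: float = 2500.0
    discount_rate: float = 0.03
    zero_disease: bool = False


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    raw = weights / weights.sum() * total
    floors = np.floor(raw).astype(int)
    rem = total - floors.sum()
    order = np.argsort(raw - floors)[::-1]
    floors[order[:rem]] += 1
    return floors


def generate_cohorts(params: SyntheticParams | None = None) -> pd.DataFrame:
    """16 age bands × 2 sexes of beverage, energy and anthropometry data.

    Deterministic given the seed.  SSB intake is strictly decreasing in age
    within each sex and male >= female at every age.
    """
    p = params or SyntheticParams()
    rng = np.random.default_rng(p.seed)
    n_bands = len(BANDS)

    # population age structure: plateau to 55, then thinning; women
    # increasingly over-represented at high ages
    age_w = np.array(
        [1.0 if lo < 55 else 0.82 ** ((lo - 50) / 5) for lo, _ in BANDS]
    )
    female_frac = np.clip(0.5 + 0.004 * (np.array([lo for lo, _ in BANDS]) - 55), 0.5, 0.72)
    w = np.concatenate([age_w * (1 - female_frac), age_w * female_frac])
    pops = _largest_remainder(w, p.total_population)

    decline = rng.uniform(*p.ssb_decline_range, size=n_bands - 1)
    ssb_male = p.ssb_peak_male * np.concatenate([[1.0], np.cumprod(decline)])
    scale0 = rng.uniform(*p.female_ssb_scale_range)
    scale = scale0 * (1.0 + rng.uniform(-0.02, 0.02, size=n_bands))
    ssb_female = ssb_male * scale

    juice = {
        "male": p.juice_ml * (1.0 + rng.uniform(-0.15, 0.15, size=n_bands)),
        "female": p.juice_ml * 1.05 * (1.0 + rng.uniform(-0.15, 0.15, size=n_bands)),
    }
    milk = {
        s: p.milk_ml * (1.0 + rng.uniform(-0.15, 0.15, size=n_bands))
        for s in ("male", "female")
    }

    mids = np.array([(lo + hi + 1) // 2 for lo, hi in BANDS], dtype=float)
    frac = (mids - mids[0]) / (mids[-1] - mids[0])
    energy = {
        "male": p.energy_young_male + (p.energy_old_male - p.energy_young_male) * frac,
        "female": p.energy_young_female
        + (p.energy_old_female - p.energy_young_female) * frac,
    }
    bmi_curve = p.bmi_young + p.bmi_rise * (1.0 - np.exp(-(mids - mids[0]) / 20.0))
    bmi_sd = p.bmi_sd_young + p.bmi_sd_slope * (mids - mids[0])

    rows = []
    for si, sex in enumerate(("male", "female")):
        ssb = ssb_male if sex == "male" else ssb_female
        e_jit = 1.0 + rng.uniform(-0.03, 0.03, size=n_bands)
        b_jit = 1.0 + rng.uniform(-0.015, 0.015, size=n_bands)
        bmi = (bmi_curve - (0.4 if sex == "female" else 0.0)) * b_jit
        height = p.height_m[si]
        for bi, (lo, hi) in enumerate(BANDS):
            rows.append(
                {
                    "sex": sex,
                    "age_lo": lo,
                    "age_hi": hi,
                    "population": int(pops[bi if sex == "male" else n_bands + bi]),
                    "ssb_ml": round(ssb[bi], 3),
                    "ssb_se": round(ssb[bi] * p.intake_se_frac, 3),
                    "juice_ml": round(juice[sex][bi], 3),
                    "juice_se": round(juice[sex][bi] * p.intake_se_frac, 3),
                    "milk_ml": round(milk[sex][bi], 3),
                    "milk_se": round(milk[sex][bi] * p.intake_se_frac, 3),
                    "energy_kcal": round(energy[sex][bi] * e_jit[bi], 2),
                    "weight_kg": round(bmi[bi] * height**2, 2),
                    "bmi_mean": round(bmi[bi], 3),
                    "bmi_sd": round(bmi_sd[bi], 3),
                }
            )
    return pd.DataFrame(rows)


def generate_epi(params: SyntheticParams | None = None) -> DiseaseEpi:
    """T2DM epidemiology by sex and single year of age (20–99).

    Incidence is log-linear in age up to 80 and constant after; mortality is
    Gompertz; prevalence comes from forward-running the illness–death
    recursion on the generated rates (so it is consistent with the MSLT).
    """
    p = params or SyntheticParams()
    ages = np.arange(AGE_MIN, AGE_MAX)
    rows = []
    for sex in ("male", "female"):
        m_fac = p.male_mortality_factor if sex == "male" else 1.0
        i_fac = p.male_incidence_factor if sex == "male" else 1.0
        inc = p.t2dm_inc20 * i_fac * np.exp(p.t2dm_inc_slope * (np.minimum(ages, 80) - AGE_MIN))
        acm = p.acm20 * m_fac * np.exp(p.acm_slope * (ages - AGE_MIN))
        excess = (p.t2dm_mortality_hr - 1.0) * acm
        pyld = p.pyld_bg20 + p.pyld_bg_slope * (ages - AGE_MIN)
        if p.zero_disease:
            inc = np.zeros_like(inc)
            excess = np.zeros_like(excess)
            prev = np.zeros_like(inc)
        else:
            prev = _forward_prevalence(inc, acm, excess, p.t2dm_prev20)
        for a, i_, pr, ex, m_, py in zip(ages, inc, prev, excess, acm, pyld):
            rows.append(
                {
                    "sex": sex,
                    "age": int(a),
                    "incidence": float(i_),
                    "prevalence": float(pr),
                    "excess_mortality": float(ex),
                    "acm": float(m_),
                    "pyld_bg": float(py),
                }
            )
    return DiseaseEpi(table=pd.DataFrame(rows), dw_t2dm=p.dw_t2dm)


def _forward_prevalence(
    inc: np.ndarray, acm: np.ndarray, excess: np.ndarray, prev20: float
) -> np.ndarray:
    """Prevalence by age from the same competing-hazard recursion as the MSLT."""
    s, c = 1.0 - prev20, prev20
    prev = np.empty(inc.shape[0])
    for j in range(inc.shape[0]):
        prev[j] = c / (s + c)
        tot = inc[j] + acm[j]
        exits = s * -math.expm1(-tot)
        new_cases = exits * (inc[j] / tot if tot > 0 else 0.0)
        deaths_c = c * -math.expm1(-(acm[j] + excess[j]))
        s = s - exits
        c = c - deaths_c + new_cases
    return prev


def default_rr_schedule() -> RRSchedule:
    """Age-stratified relative risk of T2DM per +1 BMI unit."""
    return RRSchedule()


def default_econ(params: SyntheticParams | None = None) -> EconParams:
    p = params or SyntheticParams()
    return EconParams(
        cost_with_t2dm=p.cost_with_t2dm,
        cost_without_t2dm=p.cost_without_t2dm,
        discount_rate=p.discount_rate,
        base_year=2011,
    )


def reference_scenarios(
    rate: float = 0.20, pass_through: float = 0.82
) -> dict[str, ScenarioConfig]:
    """The ten named configurations: main, M1–M4c, S1–S3."""
    ssb_only = frozenset({"ssb"})
    main_policy = TaxPolicy(rate=rate, pass_through=pass_through, taxed_categories=ssb_only)

    def cfg(name: str, **kw) -> ScenarioConfig:
        kw.setdefault("policy", main_policy)
        return ScenarioConfig(name=name, **kw)

    return {
        "main": cfg("main"),
        "M1": cfg("M1", own_pe_mode="consumption_adjusted", gamma=0.5),
        "M2": cfg("M2", own_pe_mode="alternative_meta"),
        "M3": cfg("M3", underreporting_factor=1.86),
        "M4a": cfg("M4a", substitution_mode="cross_pe"),
        "M4b": cfg("M4b", substitution_mode="adjusted_cross_pe"),
        "M4c": cfg("M4c", substitution_mode="caloric_fraction", compensation_fraction=0.61),
        "S1": cfg("S1", policy=TaxPolicy(rate=0.10, pass_through=pass_through, taxed_categories=ssb_only)),
        "S2": cfg("S2", policy=TaxPolicy(rate=0.30, pass_through=pass_through, taxed_categories=ssb_only)),
        "S3": cfg(
            "S3",
            policy=TaxPolicy(
                rate=rate,
                pass_through=pass_through,
                taxed_categories=frozenset({"ssb", "fruit_juice"}),
            ),
        ),
    }
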
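"""Scenario engine: the full tax → consumption → weight → T2DM pipeline.

:class:`ScenarioEngine` binds one synthetic (or user-supplied) world —
cohort table, T2DM epidemiology, relative-risk schedule, economic
parameters — and evaluates any :class:`~ssbtax.demand.ScenarioConfig`
against the do-nothing base case.  All per-stratum arithmetic is vectorized
across the ~32 sex × age-band strata so a 2,000-iteration Monte Carlo over
all ten presets stays cheap; the scalar operations in :mod:`ssbtax.demand`,
:mod:`ssbtax.energy`, :mod:`ssbtax.bmi` and :mod:`ssbtax.mslt` define the
semantics the engine reproduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import demand, mslt
from .bmi import DEFAULT_THRESHOLDS
from .demand import CATEGORIES, ElasticitySet, ScenarioConfig
from .energy import EnergyDensity, WeightResponse
from .mslt import AGE_MIN, N_CYCLES, DiseaseEpi, EconParams, RRSchedule

logger = logging.getLogger(__name__)

#: outcome keys reported for every scenario evaluation, in fixed order
OUTCOME_KEYS: tuple[str, ...] = (
    "d_overweight_cases_male",
    "d_overweight_cases_female",
    "d_overweight_cases_total",
    "d_obese_cases_male",
    "d_obese_cases_female",
    "d_obese_cases_total",
    "d_overweight_pp_male",
    "d_overweight_pp_female",
    "d_obese_pp_male",
    "d_obese_pp_female",
    "mean_weight_change_kg",
    "incident_cases_averted",
    "prevalent_years_averted",
    "dalys_averted",
    "costs_saved",
)


@dataclass
class ParameterDraw:
    """One joint draw of all sampled parameters (defaults = point estimates)."""

    intake_ml: np.ndarray  # (n, 3) means per stratum, category order CATEGORIES
    own_pe: float
    alt_own_pe: float
    cross_pe_juice: float
    cross_pe_milk: float
    #: None means "use the scenario policy's pass-through"
    pass_through: float | None
    rr_values: np.ndarray  # per RR age group
    dw_t2dm: float
    cost_with: float
    cost_without: float


class ScenarioEngine:
    """Evaluate tax scenarios on a fixed population/epidemiology world."""

    def __init__(
        self,
        cohorts: pd.DataFrame,
        epi: DiseaseEpi,
        rr_schedule: RRSchedule | None = None,
        econ: EconParams | None = None,
        elasticities: ElasticitySet | None = None,
        densities: EnergyDensity | None = None,
        weight_response: WeightResponse | None = None,
        thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
        bmi_shift_preserve: str = "sd",
    ) -> None:
        self.cohorts = cohorts.reset_index(drop=True)
        self.epi = epi
        self.rr_schedule = rr_schedule or RRSchedule()
        self.econ = econ or EconParams(cost_with_t2dm=4900.0, cost_without_t2dm=2500.0)
        self.elasticities = elasticities or ElasticitySet()
        self.densities = densities or EnergyDensity()
        self.weight_response = weight_response or WeightResponse()
        self.thresholds = thresholds
        if bmi_shift_preserve not in ("sd", "cv"):
            raise ValueError("bmi_shift_preserve must be 'sd' or 'cv'")
        self.bmi_shift_preserve = bmi_shift_preserve

        df = self.cohorts
        self.n = len(df)
        self.sex = df["sex"].to_numpy()
        self.is_male = self.sex == "male"
        self.labels = [
            f"{s} {lo}-{hi}"
            for s, lo, hi in zip(df["sex"], df["age_lo"], df["age_hi"])
        ]
        self.pop = df["population"].to_numpy(dtype=float)
        self.entry_age = ((df["age_lo"] + df["age_hi"] + 1) // 2).to_numpy(dtype=int)
        self.entry_col = self.entry_age - AGE_MIN
        self.intake_mean = np.column_stack(
            [df["ssb_ml"], df["juice_ml"], df["milk_ml"]]
        ).astype(float)
        self.intake_se = np.column_stack(
            [df["ssb_se"], df["juice_se"], df["milk_se"]]
        ).astype(float)
        self.energy = df["energy_kcal"].to_numpy(dtype=float)
        self.weight = df["weight_kg"].to_numpy(dtype=float)
        self.bmi_mean = df["bmi_mean"].to_numpy(dtype=float)
        self.bmi_sd = df["bmi_sd"].to_numpy(dtype=float)
        self.mu_pre, self.sigma_pre = _lognormal_params(self.bmi_mean, self.bmi_sd)

        # (n, 80) hazard/pYLD matrices aligned on single-year age 20..99
        self.haz_inc = np.vstack([epi.rates(s, "incidence") for s in self.sex])
        self.haz_acm = np.vstack([epi.rates(s, "acm") for s in self.sex])
        self.haz_exc = np.vstack([epi.rates(s, "excess_mortality") for s in self.sex])
        self.pyld = np.vstack([epi.rates(s, "pyld_bg") for s in self.sex])
        self.prev0 = np.array(
            [epi.rates(s, "prevalence")[c] for s, c in zip(self.sex, self.entry_col)]
        )

        cols = np.arange(N_CYCLES)[None, :]
        t = cols - self.entry_col[:, None]
        active = t >= 0
        self.disc = np.where(
            active, (1.0 + self.econ.discount_rate) ** -np.maximum(t, 0), 0.0
        )
        self.rr_group_idx = np.array(
            [
                max(
                    np.searchsorted(self.rr_schedule.age_breaks, a, side="right") - 1, 0
                )
                for a in self.entry_age
            ]
        )
        self.density_vec = np.array(
            [self.densities.kcal_per_ml(c) for c in CATEGORIES]
        )
        self._base: dict[str, np.ndarray] | None = None

    # -- base case ---------------------------------------------------------

    @property
    def base_traces(self) -> dict[str, np.ndarray]:
        """Do-nothing MSLT traces; independent of any sampled parameter."""
        if self._base is None:
            self._base = mslt.life_table_matrix(
                self.pop,
                self.prev0,
                self.entry_col,
                self.haz_inc,
                self.haz_acm,
                self.haz_exc,
                np.zeros(self.n),
            )
        return self._base

    # -- parameters --------------------------------------------------------

    def default_params(self) -> ParameterDraw:
        e = self.elasticities
        return ParameterDraw(
            intake_ml=self.intake_mean.copy(),
            own_pe=e.own_pe_ssb.mean,
            alt_own_pe=e.alt_own_pe_ssb.mean,
            cross_pe_juice=e.cross_pe_juice.mean,
            cross_pe_milk=e.cross_pe_milk.mean,
            pass_through=None,
            rr_values=np.array(self.rr_schedule.rr_per_bmi_unit, dtype=float),
            dw_t2dm=self.epi.dw_t2dm,
            cost_with=self.econ.cost_with_t2dm,
            cost_without=self.econ.cost_without_t2dm,
        )

    # -- stages ------------------------------------------------------------

    def volume_deltas(self, config: ScenarioConfig, p: ParameterDraw) -> np.ndarray:
        """(n, 3) ml/day changes per stratum and category."""
        pass_through = (
            config.policy.pass_through if p.pass_through is None else p.pass_through
        )
        dp = config.policy.rate * pass_through
        theta = p.intake_ml[:, 0]
        juice = p.intake_ml[:, 1]
        milk = p.intake_ml[:, 2]

        own = self._resolve_own_pe(config, p, theta)
        ssb_base = theta * config.underreporting_factor
        d_ssb = own * dp * ssb_base
        d_ssb = self._clamp(d_ssb, ssb_base, "ssb")

        d_juice = np.zeros(self.n)
        d_milk = np.zeros(self.n)
        if "fruit_juice" in config.policy.taxed_categories:
            d_juice = self._clamp(p.own_pe * dp * juice, juice, "fruit_juice")
        elif config.substitution_mode == "cross_pe":
            d_juice = self._clamp(p.cross_pe_juice * dp * juice, juice, "fruit_juice")
            d_milk = self._clamp(p.cross_pe_milk * dp * milk, milk, "milk")
        elif config.substitution_mode == "adjusted_cross_pe":
            cpe = np.empty(self.n)
            for male in (True, False):
                m = self.is_male == male
                cpe[m] = demand.adjust_cross_pe(
                    theta[m],
                    p.cross_pe_juice,
                    weights=self.pop[m]
                    if config.theta_bar_weighting == "population"
                    else None,
                )
            d_juice = self._clamp(cpe * dp * juice, juice, "fruit_juice")
            d_milk = self._clamp(p.cross_pe_milk * dp * milk, milk, "milk")
        return np.column_stack([d_ssb, d_juice, d_milk])

    def _resolve_own_pe(
        self, config: ScenarioConfig, p: ParameterDraw, theta: np.ndarray
    ) -> np.ndarray:
        if config.own_pe_mode == "marginal":
            return np.full(self.n, p.own_pe)
        if config.own_pe_mode == "alternative_meta":
            return np.full(self.n, p.alt_own_pe)
        out = np.empty(self.n)
        for male in (True, False):
            m = self.is_male == male
            w = self.pop[m] if config.theta_bar_weighting == "population" else None
            gamma = (
                demand.solve_gamma(theta[m], weights=w)
                if config.gamma == "solve"
                else float(config.gamma)
            )
            out[m] = demand.adjust_own_pe(
                theta[m],
                p.own_pe,
                gamma,
                weights=w,
                labels=[l for l, mm in zip(self.labels, m) if mm],
            )
        return out

    def _clamp(self, delta: np.ndarray, baseline: np.ndarray, cat: str) -> np.ndarray:
        floor = -baseline
        if np.any(delta < floor):
            logger.warning(
                "post-tax %s consumption clamped at 0 in %d strata",
                cat,
                int(np.sum(delta < floor)),
            )
            delta = np.maximum(delta, floor)
        return delta

    def energy_weight_deltas(
        self, config: ScenarioConfig, p: ParameterDraw, deltas_ml: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """ΔE (kcal/day), Δw (kg), Δbmi per stratum."""
        d_e = deltas_ml @ self.density_vec
        if config.substitution_mode == "caloric_fraction":
            d_e = d_e * (1.0 - config.compensation_fraction)
        total_e = self.energy
        if (
            config.inflate_energy_with_underreporting
            and config.underreporting_factor > 1.0
        ):
            total_e = total_e + (config.underreporting_factor - 1.0) * p.intake_ml[
                :, 0
            ] * self.density_vec[0]
        d_w = self.weight_response.elasticity_weight_energy * (d_e / total_e) * self.weight
        d_bmi = self.bmi_mean * d_w / self.weight
        return d_e, d_w, d_bmi

    def _band_prevalences(
        self, mu: np.ndarray, sigma: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.thresholds
        z_lo = (np.log(lo) - mu) / sigma
        z_hi = (np.log(hi) - mu) / sigma
        p_lo = ndtr(z_lo)
        p_hi = ndtr(z_hi)
        return p_hi - p_lo, 1.0 - p_hi  # overweight band, obese band

    # -- full evaluation ---------------------------------------------------

    def evaluate(
        self,
        config: ScenarioConfig,
        params: ParameterDraw | None = None,
        detail: bool = False,
    ):
        """Run the full pipeline for one scenario vs. the do-nothing base.

        Returns a dict of aggregate outcomes (keys :data:`OUTCOME_KEYS`);
        with ``detail=True`` also a per-stratum DataFrame.
        """
        p = params or self.default_params()

        deltas_ml = self.volume_deltas(config, p)
        d_e, d_w, d_bmi = self.energy_weight_deltas(config, p, deltas_ml)

        post_mean = self.bmi_mean + d_bmi
        if np.any(post_mean <= 0):
            raise ValueError("BMI shift drives a stratum mean below zero")
        post_sd = (
            self.bmi_sd
            if self.bmi_shift_preserve == "sd"
            else self.bmi_sd * post_mean / self.bmi_mean
        )
        mu_post, sigma_post = _lognormal_params(post_mean, post_sd)

        ow_pre, ob_pre = self._band_prevalences(self.mu_pre, self.sigma_pre)
        ow_post, ob_post = self._band_prevalences(mu_post, sigma_post)
        d_ow = ow_pre - ow_post
        d_ob = ob_pre - ob_post

        rr = p.rr_values[self.rr_group_idx]
        pifs = mslt.pif_vec(
            rr,
            self.mu_pre,
            self.sigma_pre,
            mu_post,
            sigma_post,
            x_ref=self.rr_schedule.x_ref,
        )

        base = self.base_traces
        inter = mslt.life_table_matrix(
            self.pop,
            self.prev0,
            self.entry_col,
            self.haz_inc,
            self.haz_acm,
            self.haz_exc,
            pifs,
        )
        alive_b = base["S"] + base["C"]
        alive_i = inter["S"] + inter["C"]
        d_alive = alive_i - alive_b
        d_prev_t = inter["C"] - base["C"]

        haly_diff = d_alive * (1.0 - self.pyld) - d_prev_t * p.dw_t2dm
        dalys = np.sum(haly_diff * self.disc, axis=1)
        excess_cost = p.cost_with - p.cost_without
        cost_diff = (-d_prev_t) * excess_cost + (-d_alive) * p.cost_without
        costs = np.sum(cost_diff * self.disc, axis=1)
        incid = np.sum(base["incident"] - inter["incident"], axis=1)
        prev_years = np.sum(base["C"] - inter["C"], axis=1)

        male = self.is_male
        out = {
            "d_overweight_cases_male": float(np.sum(self.pop[male] * d_ow[male])),
            "d_overweight_cases_female": float(np.sum(self.pop[~male] * d_ow[~male])),
            "d_obese_cases_male": float(np.sum(self.pop[male] * d_ob[male])),
            "d_obese_cases_female": float(np.sum(self.pop[~male] * d_ob[~male])),
            "d_overweight_pp_male": 100.0 * _wavg(d_ow[male], self.pop[male]),
            "d_overweight_pp_female": 100.0 * _wavg(d_ow[~male], self.pop[~male]),
            "d_obese_pp_male": 100.0 * _wavg(d_ob[male], self.pop[male]),
            "d_obese_pp_female": 100.0 * _wavg(d_ob[~male], self.pop[~male]),
            "mean_weight_change_kg": _wavg(d_w, self.pop),
            "incident_cases_averted": float(incid.sum()),
            "prevalent_years_averted": float(prev_years.sum()),
            "dalys_averted": float(dalys.sum()),
            "costs_saved": float(costs.sum()),
        }
        out["d_overweight_cases_total"] = (
            out["d_overweight_cases_male"] + out["d_overweight_cases_female"]
        )
        out["d_obese_cases_total"] = (
            out["d_obese_cases_male"] + out["d_obese_cases_female"]
        )
        out = {k: out[k] for k in OUTCOME_KEYS}
        if not detail:
            return out
        per_stratum = pd.DataFrame(
            {
                "sex": self.sex,
                "age_lo": self.cohorts["age_lo"],
                "age_hi": self.cohorts["age_hi"],
                "population": self.pop,
                "delta_ssb_ml": deltas_ml[:, 0],
                "delta_juice_ml": deltas_ml[:, 1],
                "delta_milk_ml": deltas_ml[:, 2],
                "delta_kcal": d_e,
                "delta_weight_kg": d_w,
                "delta_bmi": d_bmi,
                "d_prev_overweight_pp": 100.0 * d_ow,
                "d_prev_obese_pp": 100.0 * d_ob,
                "d_cases_overweight": self.pop * d_ow,
                "d_cases_obese": self.pop * d_ob,
                "pif": pifs,
                "incident_cases_averted": incid,
                "prevalent_years_averted": prev_years,
                "dalys_averted": dalys,
                "costs_saved": costs,
            }
        )
        return out, per_stratum

    def point_run(self, config: ScenarioConfig, detail: bool = False):
        """Deterministic run at the point estimates of all parameters."""
        return self.evaluate(config, params=None, detail=detail)


def _wavg(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.average(values, weights=weights))


def _lognormal_params(mean: np.ndarray, sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sigma2 = np.log1p((sd / mean) ** 2)
    sigma = np.sqrt(sigma2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, sigma
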
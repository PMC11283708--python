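"""Proportional multi-state life table (MSLT) for type-2 diabetes.

Closed cohorts (one per sex × 5-year age band, entering at the band midpoint)
move through three states in annual cycles up to age 100:

    alive without T2DM  --incidence-->  alive with T2DM  --> dead
           |                                             ^
           +------------- all-cause mortality -----------+
                     (diseased add excess mortality)

The intervention lowers incidence by a potential impact fraction (PIF)
derived from the shift in the BMI distribution, with the relative risk of
T2DM incidence per BMI unit stratified by age:

    PIF = 1 - ∫ RR(x) f_post(x) dx / ∫ RR(x) f_pre(x) dx,
    RR(x) = rr^(x - x_ref)

The PIF applies from the first cycle and is constant thereafter (full tax
effectiveness in year one).  Differences vs. the do-nothing base case give
incident cases averted, prevalent disease-years averted, DALYs averted, and
healthcare costs saved, the latter two discounted at 3%/year.

Within each cycle, competing exits from a state are resolved with the joint
exponential survival exp(-sum of hazards) applied to cycle-start occupancy,
exits split proportionally to hazards — so for constant hazards the
disease-free survivorship is exactly exp(-(i + m)·t).  No half-cycle
correction (annual bookkeeping).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate

#: simulated single-year ages: cohorts occupy [AGE_MIN, AGE_MAX) in annual cycles
AGE_MIN = 20
AGE_MAX = 100
N_CYCLES = AGE_MAX - AGE_MIN

#: BMI integration domain for the PIF quadrature
BMI_RANGE = (10.0, 70.0)
_Z_CLIP = 12.0

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_legendre(order: int) -> tuple[np.ndarray, np.ndarray]:
    if order not in _GL_CACHE:
        _GL_CACHE[order] = np.polynomial.legendre.leggauss(order)
    return _GL_CACHE[order]


@dataclass(frozen=True)
class RRSchedule:
    """Relative risk of T2DM incidence per +1 BMI unit, by age group.

    ``age_breaks`` are group lower bounds (ascending, first <= 20); the RR is
    constant within a group and held at the last value above the oldest
    tabulated group.  ``x_ref`` is the reference BMI; the PIF is invariant to
    it (it cancels in the ratio).
    """

    age_breaks: tuple[int, ...] = (20, 40, 60, 80)
    rr_per_bmi_unit: tuple[float, ...] = (1.27, 1.18, 1.10, 1.06)
    x_ref: float = 25.0

    def __post_init__(self) -> None:
        if len(self.age_breaks) != len(self.rr_per_bmi_unit):
            raise ValueError("age_breaks and rr_per_bmi_unit must align")
        if list(self.age_breaks) != sorted(self.age_breaks):
            raise ValueError("age_breaks must be ascending")
        if any(rr <= 0 for rr in self.rr_per_bmi_unit):
            raise ValueError("relative risks must be > 0")

    def rr_at(self, age: float) -> float:
        idx = bisect.bisect_right(self.age_breaks, age) - 1
        return self.rr_per_bmi_unit[max(idx, 0)]

    def with_values(self, rr_values: Sequence[float]) -> "RRSchedule":
        return RRSchedule(self.age_breaks, tuple(float(r) for r in rr_values), self.x_ref)


@dataclass
class DiseaseEpi:
    """T2DM epidemiology by sex and single year of age (20–99).

    ``table`` columns: sex, age, incidence (rate/person-year among the
    disease-free), prevalence (fraction, for cohort initialization),
    excess_mortality (added rate among the diseased), acm (all-cause
    mortality rate), pyld_bg (background prevalent-YLD rate per person,
    excluding T2DM disability).  ``dw_t2dm`` is the T2DM disability weight.
    Remission is fixed at zero.
    """

    table: pd.DataFrame
    dw_t2dm: float = 0.049

    RATE_COLS = ("incidence", "prevalence", "excess_mortality", "acm", "pyld_bg")

    def __post_init__(self) -> None:
        required = {"sex", "age", *self.RATE_COLS}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"epi table missing columns: {sorted(missing)}")
        if not 0.0 < self.dw_t2dm < 1.0:
            raise ValueError("dw_t2dm must be in (0, 1)")
        for col in self.RATE_COLS:
            vals = self.table[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise ValueError(f"epi column {col!r} must be finite and >= 0")
        for col in ("prevalence", "pyld_bg"):
            if np.any(self.table[col].to_numpy(dtype=float) > 1):
                raise ValueError(f"epi column {col!r} must be <= 1")
        for sex in ("male", "female"):
            ages = set(self.table.loc[self.table.sex == sex, "age"].astype(int))
            needed = set(range(AGE_MIN, AGE_MAX))
            if not needed <= ages:
                raise ValueError(
                    f"epi table for {sex} must cover single ages "
                    f"{AGE_MIN}..{AGE_MAX - 1}; missing {sorted(needed - ages)[:5]}..."
                )
        self._by_sex: dict[str, dict[str, np.ndarray]] = {}
        for sex in ("male", "female"):
            sub = (
                self.table[self.table.sex == sex]
                .astype({"age": int})
                .set_index("age")
                .sort_index()
            )
            self._by_sex[sex] = {
                col: sub.loc[range(AGE_MIN, AGE_MAX), col].to_numpy(dtype=float)
                for col in self.RATE_COLS
            }

    def rates(self, sex: str, column: str) -> np.ndarray:
        """(80,) array of ``column`` over ages 20..99 for ``sex``."""
        return self._by_sex[sex][column]


@dataclass(frozen=True)
class EconParams:
    """Healthcare cost and discounting parameters."""

    cost_with_t2dm: float
    cost_without_t2dm: float
    discount_rate: float = 0.03
    base_year: int = 2011

    def __post_init__(self) -> None:
        import logging

        if self.cost_with_t2dm < 0 or self.cost_without_t2dm < 0:
            raise ValueError("costs must be >= 0")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if self.cost_with_t2dm < self.cost_without_t2dm:
            logging.getLogger(__name__).warning(
                "cost_with_t2dm < cost_without_t2dm: check inputs"
            )

    @property
    def excess_cost(self) -> float:
        return self.cost_with_t2dm - self.cost_without_t2dm


# ---------------------------------------------------------------------------
# Potential impact fraction
# ---------------------------------------------------------------------------

def rr_integral_vec(
    rr: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    x_ref: float,
    order: int = 200,
    bmi_range: tuple[float, float] = BMI_RANGE,
) -> np.ndarray:
    """∫ rr^(x − x_ref) f(x) dx over ``bmi_range`` for log-normal f, vectorized.

    Integrated in the standardized log variable z = (ln x − mu)/sigma, which
    is well conditioned for any sigma; z-limits follow from the BMI range,
    clipped at ±12.  sigma == 0 entries are treated as point masses.
    """
    rr = np.atleast_1d(np.asarray(rr, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    lo, hi = bmi_range
    out = np.empty(rr.shape, dtype=float)

    degenerate = sigma == 0.0
    if degenerate.any():
        mean = np.exp(mu[degenerate])
        inside = (mean >= lo) & (mean <= hi)
        out[degenerate] = np.where(inside, rr[degenerate] ** (mean - x_ref), 0.0)

    active = ~degenerate
    if active.any():
        nodes, weights = _gauss_legendre(order)
        mu_a = mu[active][:, None]
        sig_a = sigma[active][:, None]
        z_lo = np.maximum((math.log(lo) - mu_a) / sig_a, -_Z_CLIP)
        z_hi = np.minimum((math.log(hi) - mu_a) / sig_a, _Z_CLIP)
        half = (z_hi - z_lo) / 2.0
        mid = (z_hi + z_lo) / 2.0
        z = mid + half * nodes[None, :]
        x = np.exp(mu_a + sig_a * z)
        logrr = np.log(rr[active])[:, None]
        integrand = np.exp((x - x_ref) * logrr - 0.5 * z**2) / math.sqrt(2.0 * math.pi)
        out[active] = (integrand @ weights) * half[:, 0]
    return out


def _rr_integral_quad(
    rr: float, mu: float, sigma: float, x_ref: float,
    bmi_range: tuple[float, float] = BMI_RANGE,
) -> float:
    """Adaptive-quadrature version of :func:`rr_integral_vec` (oracle path)."""
    if sigma == 0.0:
        mean = math.exp(mu)
        return rr ** (mean - x_ref) if bmi_range[0] <= mean <= bmi_range[1] else 0.0
    lo, hi = bmi_range
    z_lo = max((math.log(lo) - mu) / sigma, -_Z_CLIP)
    z_hi = min((math.log(hi) - mu) / sigma, _Z_CLIP)
    logrr = math.log(rr)

    def integrand(z: float) -> float:
        x = math.exp(mu + sigma * z)
        return math.exp((x - x_ref) * logrr - 0.5 * z * z) / math.sqrt(2.0 * math.pi)

    val, err = integrate.quad(
        integrand, z_lo, z_hi, epsabs=1e-13, epsrel=1e-12, limit=300
    )
    if not math.isfinite(val) or err > 1e-8 * max(1.0, abs(val)):
        raise ArithmeticError(
            f"PIF quadrature failed to converge: value={val}, err={err}, "
            f"rr={rr}, mu={mu}, sigma={sigma}"
        )
    return val


def pif(rr, pre, post, method: str = "fixed", order: int = 200) -> float:
    """Potential impact fraction of a BMI-distribution shift on incidence.

    Parameters
    ----------
    rr
        Relative risk per +1 BMI unit (for this age group), or an
        :class:`RRSchedule` entry value.
    pre, post
        :class:`ssbtax.bmi.BMIDistribution` before/after the intervention.
    method
        'fixed' (vectorizable Gauss–Legendre, default) or 'quad' (adaptive).

    PIF <= 1 always; negative values indicate a risk increase.  rr == 1 or
    post == pre gives exactly 0.
    """
    rr = float(rr)
    if rr <= 0:
        raise ValueError("rr must be > 0")
    if rr == 1.0:
        return 0.0
    x_ref = 25.0
    if method == "quad":
        num = _rr_integral_quad(rr, post.mu, post.sigma, x_ref)
        den = _rr_integral_quad(rr, pre.mu, pre.sigma, x_ref)
    elif method == "fixed":
        vals = rr_integral_vec(
            np.array([rr, rr]),
            np.array([post.mu, pre.mu]),
            np.array([post.sigma, pre.sigma]),
            x_ref,
            order=order,
        )
        num, den = float(vals[0]), float(vals[1])
    else:
        raise ValueError("method must be 'fixed' or 'quad'")
    if den <= 0:
        raise ArithmeticError("PIF denominator integral is not positive")
    return 1.0 - num / den


def pif_vec(
    rr: np.ndarray,
    mu_pre: np.ndarray,
    sigma_pre: np.ndarray,
    mu_post: np.ndarray,
    sigma_post: np.ndarray,
    x_ref: float = 25.0,
    order: int = 200,
) -> np.ndarray:
    """Vectorized PIF over strata (see :func:`pif`)."""
    num = rr_integral_vec(rr, mu_post, sigma_post, x_ref, order=order)
    den = rr_integral_vec(rr, mu_pre, sigma_pre, x_ref, order=order)
    if np.any(den <= 0):
        raise ArithmeticError("PIF denominator integral is not positive")
    out = 1.0 - num / den
    # identical pre/post parameters must give exactly zero
    same = (mu_pre == mu_post) & (sigma_pre == sigma_post)
    out[same] = 0.0
    rr = np.atleast_1d(np.asarray(rr, dtype=float))
    out[rr == 1.0] = 0.0
    return out


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTableTrace:
    """Per-cycle state occupancy of one cohort (start-of-cycle bookkeeping).

    ``ages[t]`` is the age whose year [age, age+1) cycle ``t`` covers;
    occupancy arrays hold the cycle-start person counts, ``incident`` the
    within-cycle new-case flow.
    """

    entry_age: int
    ages: np.ndarray
    alive_without: np.ndarray
    alive_with: np.ndarray
    incident: np.ndarray

    @property
    def alive(self) -> np.ndarray:
        return self.alive_without + self.alive_with

    @property
    def life_years(self) -> float:
        return float(self.alive.sum())

    @property
    def prevalent_years(self) -> float:
        return float(self.alive_with.sum())


def life_table_matrix(
    pop: np.ndarray,
    prev0: np.ndarray,
    entry_col: np.ndarray,
    haz_inc: np.ndarray,
    haz_acm: np.ndarray,
    haz_excess: np.ndarray,
    pif_by_stratum: np.ndarray,
    check_conservation: bool = True,
) -> dict[str, np.ndarray]:
    """Run the MSLT for all strata at once, age-aligned.

    All matrices are (n, 80) with column j covering age 20+j; ``entry_col``
    gives each cohort's entry column (midpoint age − 20).  Returns cycle-start
    occupancy traces ``S`` (disease-free), ``C`` (with T2DM) and the incident
    flow, each (n, 80).  Persons are conserved each cycle to 1e−9 relative.
    """
    for name, h in (("incidence", haz_inc), ("acm", haz_acm), ("excess", haz_excess)):
        if not np.all(np.isfinite(h)) or np.any(h < 0):
            raise ValueError(f"{name} hazards must be finite and >= 0")
    n = pop.shape[0]
    S = np.zeros(n)
    C = np.zeros(n)
    D = np.zeros(n)
    S_tr = np.zeros((n, N_CYCLES))
    C_tr = np.zeros((n, N_CYCLES))
    inc_tr = np.zeros((n, N_CYCLES))
    one_minus_pif = 1.0 - pif_by_stratum
    for j in range(N_CYCLES):
        entering = entry_col == j
        if entering.any():
            S[entering] = pop[entering] * (1.0 - prev0[entering])
            C[entering] = pop[entering] * prev0[entering]
        S_tr[:, j] = S
        C_tr[:, j] = C
        i = haz_inc[:, j] * one_minus_pif
        m = haz_acm[:, j]
        tot = i + m
        safe_tot = np.where(tot > 0.0, tot, 1.0)
        exits = S * -np.expm1(-tot)
        new_cases = exits * (i / safe_tot)
        deaths_s = exits - new_cases
        deaths_c = C * -np.expm1(-(m + haz_excess[:, j]))
        S = S - exits
        C = C - deaths_c + new_cases
        D = D + deaths_s + deaths_c
        inc_tr[:, j] = new_cases
    if check_conservation:
        started = entry_col < N_CYCLES
        total = S + C + D
        err = np.abs(total[started] - pop[started]) / np.maximum(pop[started], 1.0)
        if np.any(err > 1e-9):
            raise ArithmeticError(
                f"person conservation violated: max relative error {err.max():.2e}"
            )
    return {"S": S_tr, "C": C_tr, "incident": inc_tr}


def run_life_table(
    population: float,
    prevalence0: float,
    entry_age: int,
    incidence: np.ndarray,
    acm: np.ndarray,
    excess_mortality: np.ndarray,
    pif_value: float = 0.0,
    horizon_age: int = AGE_MAX,
) -> LifeTableTrace:
    """Single-cohort MSLT from ``entry_age`` to ``horizon_age``.

    Rate arrays are indexed by single-year age starting at 20 and must cover
    ages ``entry_age .. horizon_age − 1``.
    """
    if not AGE_MIN <= entry_age < horizon_age <= AGE_MAX:
        raise ValueError(f"entry_age must be in [{AGE_MIN}, {horizon_age})")

    def pad(a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        if a.shape[0] < N_CYCLES:
            a = np.concatenate([a, np.full(N_CYCLES - a.shape[0], a[-1])])
        return a[:N_CYCLES][None, :]

    res = life_table_matrix(
        pop=np.array([float(population)]),
        prev0=np.array([float(prevalence0)]),
        entry_col=np.array([entry_age - AGE_MIN]),
        haz_inc=pad(incidence),
        haz_acm=pad(acm),
        haz_excess=pad(excess_mortality),
        pif_by_stratum=np.array([float(pif_value)]),
    )
    cols = slice(entry_age - AGE_MIN, horizon_age - AGE_MIN)
    return LifeTableTrace(
        entry_age=entry_age,
        ages=np.arange(entry_age, horizon_age),
        alive_without=res["S"][0, cols].copy(),
        alive_with=res["C"][0, cols].copy(),
        incident=res["incident"][0, cols].copy(),
    )


# ---------------------------------------------------------------------------
# Valuation
# ---------------------------------------------------------------------------

def discount(stream: np.ndarray, rate: float, t0: int = 0) -> float:
    """Present value Σ_t v_t / (1 + rate)^(t0 + t); year 0 undiscounted."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    stream = np.asarray(stream, dtype=float)
    t = np.arange(t0, t0 + stream.shape[0])
    return float(np.sum(stream / (1.0 + rate) ** t))


def _check_traces(base: LifeTableTrace, intervention: LifeTableTrace) -> None:
    if base.entry_age != intervention.entry_age or base.ages.shape != intervention.ages.shape:
        raise ValueError("base and intervention traces must come from identical cohorts")


def dalys_averted(
    base: LifeTableTrace,
    intervention: LifeTableTrace,
    pyld_bg: np.ndarray,
    dw_t2dm: float,
    discount_rate: float = 0.03,
) -> float:
    """Discounted DALYs averted by the intervention.

    Per cycle, health-adjusted life years are
    ``HALY = alive × (1 − pyld_bg) − prevalent_T2DM × dw``; the background
    pYLD rate excludes T2DM disability so the two terms do not double count.
    DALYs averted = Σ discounted (HALY_int − HALY_base).
    """
    _check_traces(base, intervention)
    pyld = np.asarray(pyld_bg, dtype=float)[: base.ages.shape[0]]
    haly_b = base.alive * (1.0 - pyld) - base.alive_with * dw_t2dm
    haly_i = intervention.alive * (1.0 - pyld) - intervention.alive_with * dw_t2dm
    return discount(haly_i - haly_b, discount_rate)


def costs_saved(
    base: LifeTableTrace,
    intervention: LifeTableTrace,
    econ: EconParams,
) -> float:
    """Discounted healthcare costs saved, net of longer-survival costs.

    Per cycle, scenario cost = prevalent × cost_with + (alive − prevalent) ×
    cost_without; savings = Σ discounted (cost_base − cost_int).  Extra
    survivors in the intervention incur cost_without, automatically
    offsetting savings.
    """
    _check_traces(base, intervention)
    d_prev = base.alive_with - intervention.alive_with
    d_alive = base.alive - intervention.alive
    per_cycle = d_prev * econ.excess_cost + d_alive * econ.cost_without_t2dm
    return discount(per_cycle, econ.discount_rate)
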
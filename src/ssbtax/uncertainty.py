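"""Monte Carlo propagation of parameter uncertainty; 95% uncertainty intervals.

One joint parameter draw feeds the whole chain (demand → weight → MSLT) per
iteration, preserving correlations between stages; the same draw is applied
to every scenario in the run (common random numbers), so scenario ratios are
paired.  Uncertainty intervals are empirical 2.5th/97.5th percentiles with
linear interpolation.

Sampled quantities and families:

* beverage intake means: normal(mean, SE), redrawn if negative;
* own/cross/alternative price elasticities: normal(mean, SE), cross-PEs
  redrawn if negative (they must be >= 0 as applied);
* tax pass-through: normal truncated to [0, 1] (by redraw);
* RR per BMI unit: log-normal around the point value (CV-parameterized);
* T2DM disability weight: beta matched to mean/SD;
* healthcare costs: gamma (CV-parameterized).

Dispersion defaults are declared package choices (the original appendix
specifics are not public) and are all configurable on the spec object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demand import ScenarioConfig
from .engine import OUTCOME_KEYS, ParameterDraw, ScenarioEngine


@dataclass
class UncertaintySpec:
    """Monte Carlo settings: iteration count, seed, and dispersions."""

    n_iterations: int = 2000
    seed: int = 0
    intake_se_scale: float = 1.0
    elasticity_se_scale: float = 1.0
    pass_through_sd: float = 0.05
    rr_cv: float = 0.05
    dw_sd: float = 0.005
    cost_cv: float = 0.10
    max_redraws: int = 100
    keep_draws: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be >= 2")
        for name in ("intake_se_scale", "elasticity_se_scale", "pass_through_sd",
                     "rr_cv", "dw_sd", "cost_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, factor: float) -> "UncertaintySpec":
        """Copy with every dispersion multiplied by ``factor``."""
        return UncertaintySpec(
            n_iterations=self.n_iterations,
            seed=self.seed,
            intake_se_scale=self.intake_se_scale * factor,
            elasticity_se_scale=self.elasticity_se_scale * factor,
            pass_through_sd=self.pass_through_sd * factor,
            rr_cv=self.rr_cv * factor,
            dw_sd=self.dw_sd * factor,
            cost_cv=self.cost_cv * factor,
            max_redraws=self.max_redraws,
            keep_draws=self.keep_draws,
        )


@dataclass
class UncertaintyResult:
    """Per-outcome mean and 95% UI; optionally the raw draws."""

    scenario: str
    mean: dict[str, float]
    lo95: dict[str, float]
    hi95: dict[str, float]
    draws: pd.DataFrame | None = None

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "lo95": self.lo95, "hi95": self.hi95}
        ).loc[list(OUTCOME_KEYS)]


def percentile_interval(
    draws: np.ndarray, lo: float = 2.5, hi: float = 97.5
) -> tuple[float, float]:
    """Empirical percentile interval with linear interpolation."""
    return (
        float(np.percentile(draws, lo, method="linear")),
        float(np.percentile(draws, hi, method="linear")),
    )


def _redraw_nonneg(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: np.ndarray,
    max_redraws: int,
    upper: float | None = None,
) -> np.ndarray:
    """Normal draws redrawn elementwise until within [0, upper]."""
    out = rng.normal(mean, sd)
    bad = (out < 0) | ((out > upper) if upper is not None else False)
    tries = 0
    while np.any(bad):
        tries += 1
        if tries > max_redraws:
            raise RuntimeError(
                f"could not draw a valid value within {max_redraws} retries"
            )
        out = np.where(bad, rng.normal(mean, sd), out)
        bad = (out < 0) | ((out > upper) if upper is not None else False)
    return out


def sample_params(
    engine: ScenarioEngine, spec: UncertaintySpec, rng: np.random.Generator
) -> ParameterDraw:
    """Draw one joint parameter set for the full pipeline."""
    e = engine.elasticities
    intake = _redraw_nonneg(
        rng,
        engine.intake_mean,
        engine.intake_se * spec.intake_se_scale,
        spec.max_redraws,
    )
    s = spec.elasticity_se_scale
    own = float(rng.normal(e.own_pe_ssb.mean, e.own_pe_ssb.se * s))
    alt = float(rng.normal(e.alt_own_pe_ssb.mean, e.alt_own_pe_ssb.se * s))
    cj = float(
        _redraw_nonneg(
            rng,
            np.array([e.cross_pe_juice.mean]),
            np.array([e.cross_pe_juice.se * s]),
            spec.max_redraws,
        )[0]
    )
    cm = float(
        _redraw_nonneg(
            rng,
            np.array([e.cross_pe_milk.mean]),
            np.array([e.cross_pe_milk.se * s]),
            spec.max_redraws,
        )[0]
    )
    # pass-through around the point value used by all presets
    pt_mean = 0.82
    if spec.pass_through_sd == 0.0:
        pt = None  # fall back to each policy's own pass-through
    else:
        pt = float(
            _redraw_nonneg(
                rng,
                np.array([pt_mean]),
                np.array([spec.pass_through_sd]),
                spec.max_redraws,
                upper=1.0,
            )[0]
        )
    rr_point = np.array(engine.rr_schedule.rr_per_bmi_unit, dtype=float)
    if spec.rr_cv == 0.0:
        rr_vals = rr_point
    else:
        sig = math.sqrt(math.log1p(spec.rr_cv**2))
        rr_vals = rr_point * np.exp(rng.normal(0.0, sig, size=rr_point.shape) - sig**2 / 2)
    dw_mean = engine.epi.dw_t2dm
    if spec.dw_sd == 0.0:
        dw = dw_mean
    else:
        var = spec.dw_sd**2
        common = dw_mean * (1.0 - dw_mean) / var - 1.0
        if common <= 0:
            raise ValueError("dw_sd too large for a beta distribution at this mean")
        dw = float(rng.beta(dw_mean * common, (1.0 - dw_mean) * common))
    if spec.cost_cv == 0.0:
        cw, co = engine.econ.cost_with_t2dm, engine.econ.cost_without_t2dm
    else:
        shape = 1.0 / spec.cost_cv**2
        cw = float(rng.gamma(shape, engine.econ.cost_with_t2dm / shape))
        co = float(rng.gamma(shape, engine.econ.cost_without_t2dm / shape))
    return ParameterDraw(
        intake_ml=intake,
        own_pe=own,
        alt_own_pe=alt,
        cross_pe_juice=cj,
        cross_pe_milk=cm,
        pass_through=pt,
        rr_values=rr_vals,
        dw_t2dm=dw,
        cost_with=cw,
        cost_without=co,
    )


def run_monte_carlo(
    engine: ScenarioEngine,
    configs: list[ScenarioConfig],
    spec: UncertaintySpec,
) -> dict[str, UncertaintyResult]:
    """Full-pipeline Monte Carlo over scenarios with common random numbers.

    Identical (seed, spec, inputs) give bit-identical results.
    """
    rng = np.random.default_rng(spec.seed)
    draws: dict[str, list[dict[str, float]]] = {c.name: [] for c in configs}
    for _ in range(spec.n_iterations):
        p = sample_params(engine, spec, rng)
        for cfg in configs:
            draws[cfg.name].append(engine.evaluate(cfg, params=p))
    results: dict[str, UncertaintyResult] = {}
    for cfg in configs:
        df = pd.DataFrame(draws[cfg.name], columns=list(OUTCOME_KEYS))
        mean = {k: float(df[k].mean()) for k in OUTCOME_KEYS}
        lo: dict[str, float] = {}
        hi: dict[str, float] = {}
        for k in OUTCOME_KEYS:
            lo[k], hi[k] = percentile_interval(df[k].to_numpy())
        results[cfg.name] = UncertaintyResult(
            scenario=cfg.name,
            mean=mean,
            lo95=lo,
            hi95=hi,
            draws=df if spec.keep_draws else None,
        )
    return results


def summarize(
    results: dict[str, UncertaintyResult],
    outcome: str = "costs_saved",
    main: str = "main",
) -> pd.DataFrame:
    """Comparison table: each scenario's outcome and its ratio to the main run.

    Ratio UIs come from the paired per-iteration draws when retained
    (common random numbers), otherwise only the ratio of means is reported.
    """
    if main not in results:
        raise ValueError(f"missing main scenario {main!r} in results")
    main_res = results[main]
    main_mean = main_res.mean[outcome]
    rows = []
    for name, res in results.items():
        row = {
            "scenario": name,
            "mean": res.mean[outcome],
            "lo95": res.lo95[outcome],
            "hi95": res.hi95[outcome],
            "ratio_to_main": (
                res.mean[outcome] / main_mean if main_mean != 0 else math.nan
            ),
        }
        if res.draws is not None and main_res.draws is not None:
            denom = main_res.draws[outcome].to_numpy()
            num = res.draws[outcome].to_numpy()
            ok = denom != 0
            if ok.all() and len(num) == len(denom):
                r_lo, r_hi = percentile_interval(num / denom)
                row["ratio_lo95"], row["ratio_hi95"] = r_lo, r_hi
        rows.append(row)
    return pd.DataFrame(rows).set_index("scenario")
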
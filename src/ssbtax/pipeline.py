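"""Input handling, validation, and scenario orchestration.

Ties the stages together in pipeline order (demand → energy/weight → BMI
population → MSLT), reads/writes the CSV and YAML interchange formats, and
stamps every output directory with a :class:`RunManifest` so runs are
auditable pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demand import ElasticitySet, Param, ScenarioConfig, TaxPolicy
from .energy import DEFAULT_DENSITIES, EnergyDensity, WeightResponse
from .engine import ScenarioEngine
from .mslt import AGE_MAX, AGE_MIN, DiseaseEpi, EconParams, RRSchedule
from .synth import reference_scenarios

COHORT_COLUMNS = [
    "sex", "age_lo", "age_hi", "population",
    "ssb_ml", "ssb_se", "juice_ml", "juice_se", "milk_ml", "milk_se",
    "energy_kcal", "weight_kg", "bmi_mean", "bmi_sd",
]
EPI_COLUMNS = [
    "sex", "age", "incidence", "prevalence", "excess_mortality", "acm", "pyld_bg",
]


def default_config() -> dict[str, Any]:
    """All tunable parameters with their package defaults."""
    return {
        "elasticities": {
            "own_pe_ssb": {"mean": -1.299, "se": 0.107},
            "cross_pe_juice": {"mean": 0.388, "se": 0.15},
            "cross_pe_milk": {"mean": 0.129, "se": 0.08},
            "alt_own_pe_ssb": {"mean": -0.674, "se": 0.08},
        },
        "tax": {"rate": 0.20, "pass_through": 0.82},
        "densities_kcal_per_100ml": dict(DEFAULT_DENSITIES),
        "weight_response": 0.7,
        "bmi_thresholds": {"overweight": 25.0, "obese": 30.0},
        "bmi_shift_preserve": "sd",
        "rr_schedule": {
            "age_breaks": [20, 40, 60, 80],
            "rr_per_bmi_unit": [1.27, 1.18, 1.10, 1.06],
            "x_ref": 25.0,
        },
        "dw_t2dm": 0.049,
        "econ": {
            "cost_with": 4900.0,
            "cost_without": 2500.0,
            "discount_rate": 0.03,
            "base_year": 2011,
        },
        "units": {"intake": "ml/day", "energy": "kcal/day", "currency": "EUR-2011"},
    }


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Merge a YAML config file over the defaults (shallow, per section)."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def build_components(
    cfg: dict[str, Any],
) -> tuple[ElasticitySet, EnergyDensity, WeightResponse, RRSchedule, EconParams]:
    el = cfg["elasticities"]

    def param(d: dict) -> Param:
        return Param(float(d["mean"]), float(d.get("se", 0.0)))

    elasticities = ElasticitySet(
        own_pe_ssb=param(el["own_pe_ssb"]),
        cross_pe_juice=param(el["cross_pe_juice"]),
        cross_pe_milk=param(el["cross_pe_milk"]),
        alt_own_pe_ssb=param(el["alt_own_pe_ssb"]),
    )
    densities = EnergyDensity(dict(cfg["densities_kcal_per_100ml"]))
    wr = WeightResponse(float(cfg["weight_response"]))
    rr = cfg["rr_schedule"]
    schedule = RRSchedule(
        age_breaks=tuple(int(a) for a in rr["age_breaks"]),
        rr_per_bmi_unit=tuple(float(v) for v in rr["rr_per_bmi_unit"]),
        x_ref=float(rr["x_ref"]),
    )
    ec = cfg["econ"]
    econ = EconParams(
        cost_with_t2dm=float(ec["cost_with"]),
        cost_without_t2dm=float(ec["cost_without"]),
        discount_rate=float(ec["discount_rate"]),
        base_year=int(ec["base_year"]),
    )
    return elasticities, densities, wr, schedule, econ


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_cohorts(df: pd.DataFrame) -> list[str]:
    """Type/invariant checks; each problem named with row and column."""
    errors: list[str] = []
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        return [f"cohort table missing columns: {sorted(missing)}"]
    for idx, row in df.iterrows():
        where = f"row {idx} ({row['sex']} {row['age_lo']}-{row['age_hi']})"
        if row["sex"] not in ("male", "female"):
            errors.append(f"{where}: sex must be male/female")
        for col in ("ssb_ml", "juice_ml", "milk_ml", "population"):
            if row[col] < 0:
                errors.append(f"{where}: column {col} is negative ({row[col]})")
        for col, cond in (("energy_kcal", row["energy_kcal"] <= 0),
                          ("bmi_sd", row["bmi_sd"] <= 0),
                          ("bmi_mean", row["bmi_mean"] <= 0),
                          ("weight_kg", row["weight_kg"] <= 0)):
            if cond:
                errors.append(f"{where}: column {col} must be positive")
    for sex in ("male", "female"):
        bands = {
            (int(lo), int(hi))
            for lo, hi in df.loc[df.sex == sex, ["age_lo", "age_hi"]].itertuples(
                index=False
            )
        }
        expected = {(lo, lo + 4) for lo in range(AGE_MIN, AGE_MAX, 5)}
        for band in sorted(expected - bands):
            errors.append(f"{sex}: missing age band {band[0]}-{band[1]}")
    return errors


def validate_epi(df: pd.DataFrame) -> list[str]:
    errors: list[str] = []
    missing = set(EPI_COLUMNS) - set(df.columns)
    if missing:
        return [f"epi table missing columns: {sorted(missing)}"]
    for col in ("incidence", "prevalence", "excess_mortality", "acm", "pyld_bg"):
        bad = df.index[(df[col] < 0) | ~np.isfinite(df[col])]
        for idx in bad:
            errors.append(f"row {idx}: column {col} must be finite and >= 0")
    for col in ("prevalence", "pyld_bg"):
        for idx in df.index[df[col] > 1]:
            errors.append(f"row {idx}: column {col} must be <= 1")
    for sex in ("male", "female"):
        ages = set(df.loc[df.sex == sex, "age"].astype(int))
        gaps = sorted(set(range(AGE_MIN, AGE_MAX)) - ages)
        if gaps:
            errors.append(f"{sex}: missing single-year ages {gaps[:5]}...")
    return errors


def validate_inputs(cohort_csv: str | Path, epi_csv: str | Path) -> list[str]:
    """Validate both input tables; empty report means clean."""
    report: list[str] = []
    report += [f"cohorts: {e}" for e in validate_cohorts(pd.read_csv(cohort_csv))]
    report += [f"epi: {e}" for e in validate_epi(pd.read_csv(epi_csv))]
    return report


def read_cohorts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    errors = validate_cohorts(df)
    if errors:
        raise ValueError("invalid cohort table:\n" + "\n".join(errors))
    return df


def read_epi(path: str | Path, dw_t2dm: float = 0.049) -> DiseaseEpi:
    df = pd.read_csv(path)
    errors = validate_epi(df)
    if errors:
        raise ValueError("invalid epi table:\n" + "\n".join(errors))
    return DiseaseEpi(table=df, dw_t2dm=dw_t2dm)


# ---------------------------------------------------------------------------
# Manifest and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance stamp written next to every result set."""

    scenarios: list[str]
    inputs: dict[str, str]
    config_hash: str
    seed: int | None
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


def _config_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def make_engine(
    cohort_csv: str | Path, epi_csv: str | Path, cfg: dict[str, Any] | None = None
) -> ScenarioEngine:
    cfg = cfg or default_config()
    elasticities, densities, wr, schedule, econ = build_components(cfg)
    cohorts = read_cohorts(cohort_csv)
    epi = read_epi(epi_csv, dw_t2dm=float(cfg["dw_t2dm"]))
    thr = cfg["bmi_thresholds"]
    return ScenarioEngine(
        cohorts=cohorts,
        epi=epi,
        rr_schedule=schedule,
        econ=econ,
        elasticities=elasticities,
        densities=densities,
        weight_response=wr,
        thresholds=(float(thr["overweight"]), float(thr["obese"])),
        bmi_shift_preserve=str(cfg["bmi_shift_preserve"]),
    )


def resolve_scenario(name: str, cfg: dict[str, Any]) -> ScenarioConfig:
    tax = cfg.get("tax", {})
    presets = reference_scenarios(
        rate=float(tax.get("rate", 0.20)),
        pass_through=float(tax.get("pass_through", 0.82)),
    )
    if name not in presets:
        raise KeyError(f"unknown scenario {name!r}; presets: {sorted(presets)}")
    return presets[name]


def run_scenario(
    cohort_csv: str | Path,
    epi_csv: str | Path,
    config_path: str | Path | None,
    scenario_name: str,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, float]:
    """Deterministic point run of one scenario; writes result CSVs + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path)
    engine = make_engine(cohort_csv, epi_csv, cfg)
    config = resolve_scenario(scenario_name, cfg)
    totals, per_stratum = engine.point_run(config, detail=True)
    per_stratum.to_csv(out / f"{scenario_name}_strata.csv", index=False)
    pd.Series(totals, name="value").rename_axis("outcome").to_csv(
        out / f"{scenario_name}_totals.csv"
    )
    RunManifest(
        scenarios=[scenario_name],
        inputs={"cohorts": str(cohort_csv), "epi": str(epi_csv)},
        config_hash=_config_hash(cfg),
        seed=seed,
    ).write(out)
    return totals


def run_all(
    cohort_csv: str | Path,
    epi_csv: str | Path,
    config_path: str | Path | None,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Point runs of all ten presets plus a cross-scenario comparison table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path)
    engine = make_engine(cohort_csv, epi_csv, cfg)
    tax = cfg.get("tax", {})
    presets = reference_scenarios(
        rate=float(tax.get("rate", 0.20)),
        pass_through=float(tax.get("pass_through", 0.82)),
    )
    rows = {}
    for name, config in presets.items():
        totals, per_stratum = engine.point_run(config, detail=True)
        per_stratum.to_csv(out / f"{name}_strata.csv", index=False)
        rows[name] = totals
    table = pd.DataFrame(rows).T.rename_axis("scenario")
    table.to_csv(out / "comparison.csv")
    RunManifest(
        scenarios=list(presets),
        inputs={"cohorts": str(cohort_csv), "epi": str(epi_csv)},
        config_hash=_config_hash(cfg),
        seed=None,
    ).write(out)
    return table
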
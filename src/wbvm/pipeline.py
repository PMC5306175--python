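"""End-to-end orchestration: panel -> cohort -> IO trend -> incidence ->
monetization, with artifact and manifest emission.

The valuation run executes the stages in order, logging every filter count,
model convergence status and fallback.  Every run can write its artifacts
(correlation matrix, multipliers, incidence models, component tables, the
final report) plus a manifest carrying the config hash, seed and counts, so
re-runs are auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_prep import FactorMap, prepare_cohort
from .definitions import DISEASED_ANNUAL_SAVINGS, DISEASES, FACTORS
from .incidence import fit_all_incidence, incidence_delta
from .io_trend import (CorrelationIOModel, IOSettings, build_roster,
                       expected_at_risk_count, fit_io_model, year_tables)
from .monetization import (ValuationReport, assemble_report,
                           relative_cost_table, value_diseased,
                           value_incidence, value_newly_diseased,
                           value_nondiseased)
from .regression_comparator import run_comparator as _run_comparator_tables
from .synthetic_data import PopulationConfig, SyntheticPanel, generate_population

__all__ = ["RunConfig", "ValuationRun", "run_valuation", "run_comparator",
           "load_panel"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    input_path: str | None = None
    synthetic: dict[str, Any] | None = None
    seed: int = 0
    out_dir: str | None = None
    cpi_factors: dict[int, float] = field(default_factory=dict)
    io: IOSettings = field(default_factory=IOSettings)
    incidence_mode: str = "linear_predictor"
    weighting: str = "inverse_risk_count"
    diseased_annual_rate: float = DISEASED_ANNUAL_SAVINGS
    small_cell_min: int = 5
    age_limit: float = 65.0
    min_months: int = 6
    comparator_link: str = "logit"
    comparator_mode: str = "predicted"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        io_raw = raw.pop("io", {})
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.io = IOSettings(**io_raw)
        cfg.cpi_factors = {int(k): float(v)
                           for k, v in (cfg.cpi_factors or {}).items()}
        return cfg

    def digest(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ValuationRun:
    report: ValuationReport
    io_model: CorrelationIOModel
    cohort: pd.DataFrame
    exclusion_log: dict[str, int]
    avoided_counts: dict[str, float]
    deltas: list
    manifest: dict[str, Any]


def load_panel(config: RunConfig) -> pd.DataFrame:
    """Read the input panel, or generate it when a synthetic block is set."""
    if config.input_path:
        return pd.read_csv(config.input_path)
    syn = dict(config.synthetic or {})
    syn.setdefault("seed", config.seed)
    return generate_population(PopulationConfig(**syn)).frame


def _expected_prevalences(io_model: CorrelationIOModel,
                          y1: pd.DataFrame) -> dict[str, float]:
    """Counterfactual follow-up factor prevalences from the multipliers."""
    out = {}
    for f in FACTORS:
        m = float(io_model.multipliers.get(f"factor_{f}", 0.0))
        base = float(y1[f"factor_{f}"].mean())
        out[f"factor_{f}"] = float(np.clip(base * (1.0 + m), 0.0, 1.0))
    return out


def run_valuation(config: RunConfig) -> ValuationRun:
    """Execute the full valuation and assemble the savings report."""
    panel = load_panel(config)
    cohort, excl = prepare_cohort(
        panel, FactorMap.default() if _uses_default_items(panel) else
        _infer_factor_map(panel),
        cpi_factors=config.cpi_factors,
        age_limit=config.age_limit, min_months=config.min_months)
    y1, y2 = year_tables(cohort)
    n = len(y1)
    if n == 0:
        raise RuntimeError("cohort_prep: eligibility removed every member")

    io_model = fit_io_model(cohort, settings=config.io)

    dis_cols = [f"dis_{d}" for d in DISEASES]
    new_cols = [f"new_{d}" for d in DISEASES]
    # component precedence: diseased > newly_diseased > nondiseased
    diseased_y1 = y1[dis_cols].sum(axis=1) > 0
    newly = (y2[new_cols].sum(axis=1) > 0) & ~diseased_y1
    nondiseased = ~diseased_y1 & ~newly

    # --- nondiseased component: avoided at-risk counts x marginal cost
    costs = relative_cost_table(y1)
    sub1, sub2 = y1[nondiseased], y2[nondiseased]
    avoided: dict[str, float] = {}
    for f in FACTORS:
        m = float(io_model.multipliers.get(f"factor_{f}", 0.0))
        observed_y1 = float(sub1[f"factor_{f}"].sum())
        expected_y2 = expected_at_risk_count(observed_y1, m)
        avoided[f] = expected_y2 - float(sub2[f"factor_{f}"].sum())
    comp_nond = value_nondiseased(avoided, costs, sub1, cohort_n=n,
                                  weighting=config.weighting)

    # --- incidence component
    models = fit_all_incidence(y1, y2)
    expected_prev = _expected_prevalences(io_model, y1)
    deltas = []
    for d, model in models.items():
        nond_d = y1[y1[f"dis_{d}"] == 0]
        actual_prev = {f"factor_{f}":
                       float(y2.loc[nond_d.index, f"factor_{f}"].mean())
                       for f in FACTORS}
        deltas.append(incidence_delta(model, nond_d, expected_prev,
                                      actual_prev,
                                      mode=config.incidence_mode))
    comp_inc = value_incidence(deltas, y1)

    # --- newly diseased and diseased components
    comp_new = value_newly_diseased(y1, y2,
                                    small_cell_min=config.small_cell_min,
                                    eligible=y2.index[newly])
    engaged = y1["engaged"].astype(bool).to_dict()
    comp_dis = value_diseased(list(y1.index[diseased_y1]), engaged,
                              annual_rate=config.diseased_annual_rate)

    report = assemble_report({
        "nondiseased": comp_nond,
        "incidence": comp_inc,
        "newly_diseased": comp_new,
        "diseased": comp_dis,
    }, cohort_n=n)

    manifest = {
        "wbvm_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_panel_members": int(panel["member_id"].nunique()),
        "n_cohort": n,
        "exclusions": excl,
        "io_damping": io_model.damping,
        "mean_risk_trend": io_model.mean_trend,
        "zip_converged": bool(io_model.zip_model.converged)
        if io_model.zip_model else None,
        "incidence_models_fit": sorted(models),
        "grand_total": report.grand_total,
        "grand_pppy": report.grand_pppy,
    }
    run = ValuationRun(report=report, io_model=io_model, cohort=cohort,
                       exclusion_log=excl, avoided_counts=avoided,
                       deltas=deltas, manifest=manifest)
    if config.out_dir:
        _write_artifacts(run, models, costs, Path(config.out_dir))
    return run


def run_comparator(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Regression-only valuation on the same prepared cohort."""
    panel = load_panel(config)
    cohort, _ = prepare_cohort(
        panel, FactorMap.default() if _uses_default_items(panel) else
        _infer_factor_map(panel),
        cpi_factors=config.cpi_factors,
        age_limit=config.age_limit, min_months=config.min_months)
    y1, y2 = year_tables(cohort)
    table, totals = _run_comparator_tables(
        y1, y2, link=config.comparator_link, mode=config.comparator_mode)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "comparator_table.csv")
        (out / "comparator_totals.json").write_text(
            json.dumps(totals, indent=2))
    return table, totals


def _uses_default_items(panel: pd.DataFrame) -> bool:
    default = FactorMap.default()
    return set(default.items) <= set(panel.columns)


def _infer_factor_map(panel: pd.DataFrame) -> FactorMap:
    mapping: dict[str, frozenset[str]] = {}
    for f in FACTORS:
        items = frozenset(c for c in panel.columns
                          if c.startswith(f + "_r"))
        if not items:
            raise ValueError(
                f"no item columns found for factor {f} and the default "
                "item schema does not match the input")
        mapping[f] = items
    return FactorMap(mapping)


def _write_artifacts(run: ValuationRun, models, costs, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    run.io_model.rho_matrix.to_csv(out / "rho_matrix.csv")
    run.io_model.multipliers.rename("multiplier").to_csv(
        out / "multipliers.csv")
    costs.as_frame().to_csv(out / "relative_costs.csv")
    mdir = out / "incidence_models"
    mdir.mkdir(exist_ok=True)
    for d, m in models.items():
        m.to_json(mdir / f"{d}.json")
    comp = run.report.components["nondiseased"]
    if comp.detail is not None:
        comp.detail.to_csv(out / "nondiseased_detail.csv")
    run.report.as_frame().to_csv(out / "report.csv", index=False)
    (out / "report.json").write_text(json.dumps({
        "components": {
            name: {"n_applied": c.n_applied,
                   "pppy_savings": round(c.pppy_savings, 2),
                   "sd": round(c.sd, 3),
                   "total": round(c.total, 2)}
            for name, c in run.report.components.items()},
        "grand_total": run.report.grand_total,
        "grand_pppy": run.report.grand_pppy,
        "cohort_n": run.report.cohort_n,
    }, indent=2))
    (out / "manifest.json").write_text(
        json.dumps(run.manifest, indent=2, default=str))
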
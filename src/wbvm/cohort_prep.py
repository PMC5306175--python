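"""Raw member-year records -> analysis cohort.

Four concerns live here: eligibility filtering (adult, under 65 in both
study years, at least six eligible enrollment months per year, both annual
assessments completed), aggregation of binary risk items into the eight
well-being factors (a member is at risk for a factor if *any* constituent
item is at risk), reconciliation of self-reported and claims-based disease
indicators (an observed claims flag supersedes self-report), and deflation
of costs to base-year dollars with a supplied medical-CPI factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .definitions import DEFAULT_ITEMS_PER_FACTOR, DISEASES, FACTORS, item_names

__all__ = [
    "FactorMap",
    "aggregate_factors",
    "reconcile_disease",
    "reconcile_disease_frame",
    "apply_eligibility",
    "deflate_cost",
    "derive_newly_diseased",
    "prepare_cohort",
]

MISSING = None  #: sentinel for an unobserved claims indicator


@dataclass(frozen=True)
class FactorMap:
    """Factor name -> set of item column names; sets must be disjoint."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for factor, items in self.mapping.items():
            if not items:
                raise ValueError(f"factor {factor!r} maps to no items")
            overlap = seen & set(items)
            if overlap:
                raise ValueError(
                    f"items {sorted(overlap)} appear in more than one factor")
            seen |= set(items)

    @classmethod
    def default(cls, items_per_factor: Mapping[str, int] | None = None
                ) -> "FactorMap":
        counts = dict(items_per_factor or DEFAULT_ITEMS_PER_FACTOR)
        return cls({f: frozenset(item_names(f, counts[f])) for f in FACTORS})

    @property
    def factors(self) -> list[str]:
        return list(self.mapping)

    @property
    def items(self) -> list[str]:
        return sorted(set().union(*self.mapping.values()))


def aggregate_factors(records: pd.DataFrame, fmap: FactorMap) -> pd.DataFrame:
    """Add ``factor_<name>`` columns: OR over each factor's mapped items."""
    missing = [c for c in fmap.items if c not in records.columns]
    if missing:
        raise KeyError(
            f"risk items referenced by the factor map are absent from the "
            f"records: {missing}")
    out = records.copy()
    for factor, items in fmap.mapping.items():
        out[f"factor_{factor}"] = (
            out[sorted(items)].astype(int).max(axis=1))
    return out


def reconcile_disease(self_report: Mapping[str, bool],
                      claims: Mapping[str, object]) -> dict[str, bool]:
    """Per-disease reconciliation: an observed claims flag wins.

    ``claims`` values may be True/False or ``None``/NaN for "no claims
    observation"; in the missing case the self-report stands.
    """
    if set(self_report) != set(claims):
        raise KeyError(
            f"disease keys differ: {sorted(set(self_report) ^ set(claims))}")
    out: dict[str, bool] = {}
    for d, sr in self_report.items():
        clm = claims[d]
        observed = clm is not None and not (
            isinstance(clm, float) and np.isnan(clm))
        out[d] = bool(clm) if observed else bool(sr)
    return out


def reconcile_disease_frame(records: pd.DataFrame,
                            diseases: tuple[str, ...] = DISEASES
                            ) -> pd.DataFrame:
    """Vectorized reconciliation: ``dis_<d>`` from ``sr_<d>``/``clm_<d>``."""
    out = records.copy()
    for d in diseases:
        clm = out[f"clm_{d}"]
        out[f"dis_{d}"] = clm.fillna(out[f"sr_{d}"]).astype(int)
    return out


def derive_newly_diseased(records: pd.DataFrame,
                          diseases: tuple[str, ...] = DISEASES
                          ) -> pd.DataFrame:
    """Add year-2 ``new_<d>`` flags: present at follow-up, absent at baseline."""
    out = records.copy()
    y1 = out[out["year"] == 1].set_index("member_id")
    for d in diseases:
        base = out["member_id"].map(y1[f"dis_{d}"]).fillna(0).astype(int)
        out[f"new_{d}"] = ((out["year"] == 2)
                           & (out[f"dis_{d}"] == 1)
                           & (base == 0)).astype(int)
    return out


def apply_eligibility(panel: pd.DataFrame, *, age_limit: float = 65.0,
                      min_months: int = 6,
                      years: tuple[int, int] = (1, 2)
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain members meeting all study criteria; log exclusions by reason.

    Criteria, applied to each member in a fixed precedence order so counts
    are reproducible: (1) both annual assessments present, (2) age under
    ``age_limit`` at both assessments, (3) at least ``min_months`` eligible
    enrollment months in each year.  A member failing several rules is
    counted once, under the first failed rule.
    """
    log = {"assessments": 0, "age": 0, "enrollment": 0}
    if panel.empty:
        warnings.warn("empty panel: eligibility produced an empty cohort")
        return panel.copy(), log
    by_member = panel.groupby("member_id")
    has_both = by_member["year"].agg(
        lambda y: set(years) <= set(y.tolist()))
    in_years = panel[panel["year"].isin(years)]
    max_age = in_years.groupby("member_id")["age"].max()
    min_mon = in_years.groupby("member_id")["eligible_months"].min()

    members = has_both.index
    fail_assess = ~has_both
    fail_age = ~fail_assess & (max_age >= age_limit)
    fail_enroll = ~fail_assess & ~fail_age & (min_mon < min_months)
    log["assessments"] = int(fail_assess.sum())
    log["age"] = int(fail_age.sum())
    log["enrollment"] = int(fail_enroll.sum())
    keep = members[~(fail_assess | fail_age | fail_enroll)]
    cohort = panel[panel["member_id"].isin(set(keep))
                   & panel["year"].isin(years)].copy()
    if cohort.empty:
        warnings.warn("eligibility removed every member")
    return cohort, log


def deflate_cost(cost, cpi_factor: float):
    """Re-express cost in base-year dollars: cost / cpi_factor."""
    if cpi_factor <= 0:
        raise ValueError(f"cpi_factor must be positive, got {cpi_factor}")
    return cost / cpi_factor


def prepare_cohort(panel: pd.DataFrame, fmap: FactorMap | None = None,
                   cpi_factors: Mapping[int, float] | None = None,
                   *, age_limit: float = 65.0, min_months: int = 6
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full preparation: eligibility -> factors -> disease -> deflation.

    Returns the prepared long-format cohort (one row per member-year with
    ``factor_*``, ``dis_*`` and ``new_*`` columns, costs in base-year
    dollars) and the exclusion log.
    """
    fmap = fmap or FactorMap.default()
    cohort, log = apply_eligibility(panel, age_limit=age_limit,
                                    min_months=min_months)
    cohort = aggregate_factors(cohort, fmap)
    cohort = reconcile_disease_frame(cohort)
    cohort = derive_newly_diseased(cohort)
    if cpi_factors:
        for year, f in cpi_factors.items():
            mask = cohort["year"] == year
            cohort.loc[mask, "pppy_cost"] = deflate_cost(
                cohort.loc[mask, "pppy_cost"], f)
    return cohort, log
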
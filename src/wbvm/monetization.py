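"""Monetization of risk and incidence changes: the four savings components.

Sources of value (each member contributes to at most one member-assigned
component, preventing double counting):

* **nondiseased** — avoided/reduced at-risk factor counts among non-diseased
  members valued at each factor's marginal cost (the excess annual cost of
  members with at least one risk in the factor over members with no risks
  and no disease).
* **incidence** — avoided disease onsets valued at the net annual cost of
  having the disease (mean diseased cost minus mean non-diseased cost);
  population-level, not assigned to individual members.
* **newly_diseased** — risk resolution among members who became diseased in
  the follow-up year, valued through within-disease percent cost differences
  by risk presence times the average diseased annual cost.
* **diseased** — a published per-engaged-diseased-member annual savings
  constant (US$294.07, a 4.73 % savings rate) applied to actively engaged
  diseased members.

Dollar totals are carried in integer cents internally; display rounding is
half-up to whole dollars for totals and to cents for per-person-per-year
(PPPY) figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .definitions import DISEASED_ANNUAL_SAVINGS, DISEASES, FACTORS
from .incidence import IncidenceDelta

__all__ = [
    "RelativeCostTable",
    "ValuationComponent",
    "ValuationReport",
    "relative_cost_table",
    "value_nondiseased",
    "value_incidence",
    "value_newly_diseased",
    "value_diseased",
    "assemble_report",
    "net_disease_cost",
]


def _cents(x: float) -> int:
    """Round a dollar amount to integer cents, half-up."""
    return int(Decimal(repr(float(x))).scaleb(2)
               .to_integral_value(rounding=ROUND_HALF_UP))


def round_dollars(x: float) -> float:
    return float(Decimal(repr(float(x))).to_integral_value(ROUND_HALF_UP))


@dataclass
class RelativeCostTable:
    """Per-factor excess cost of being at risk, vs no-risk-no-disease."""

    reference_pppy: float
    ratios: pd.Series        # percent excess / 100 (e.g. 0.44 for 44 %)
    marginal_cost: pd.Series  # dollars: ratio * reference PPPY

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "relative_cost_pct": (self.ratios * 100).round(1),
            "marginal_cost_usd": self.marginal_cost.round(2),
        })


@dataclass
class ValuationComponent:
    name: str
    n_applied: int
    pppy_savings: float
    total_cents: int
    sd: float
    members: frozenset = field(default_factory=frozenset)
    detail: pd.DataFrame | None = None

    @property
    def total(self) -> float:
        return self.total_cents / 100.0


@dataclass
class ValuationReport:
    components: dict[str, ValuationComponent]
    cohort_n: int
    grand_total_cents: int
    grand_pppy: float

    @property
    def grand_total(self) -> float:
        return self.grand_total_cents / 100.0

    def as_frame(self) -> pd.DataFrame:
        rows = [{
            "source_of_value": c.name,
            "pppy_savings": round(c.pppy_savings, 2),
            "sd": round(c.sd, 3),
            "n_applied": c.n_applied,
            "total": round_dollars(c.total),
        } for c in self.components.values()]
        return pd.DataFrame(rows)


def relative_cost_table(cohort_y1: pd.DataFrame,
                        factors: Sequence[str] = FACTORS,
                        diseases: Sequence[str] = DISEASES
                        ) -> RelativeCostTable:
    """Excess annual cost of at-risk members per factor.

    Reference group: members with no at-risk factor and no disease in the
    baseline year.
    """
    factor_cols = [f"factor_{f}" for f in factors]
    dis_cols = [f"dis_{d}" for d in diseases]
    ref_mask = (cohort_y1[factor_cols].sum(axis=1) == 0) \
        & (cohort_y1[dis_cols].sum(axis=1) == 0)
    if not ref_mask.any():
        raise ValueError("no members with no risks and no disease: "
                         "reference cost undefined")
    ref = float(cohort_y1.loc[ref_mask, "pppy_cost"].mean())
    ratios = {}
    for f in factors:
        at_risk = cohort_y1[cohort_y1[f"factor_{f}"] == 1]
        with_risk = float(at_risk["pppy_cost"].mean()) if len(at_risk) else ref
        ratios[f] = with_risk / ref - 1.0
    ratios = pd.Series(ratios)
    return RelativeCostTable(
        reference_pppy=ref,
        ratios=ratios,
        marginal_cost=ratios * ref,
    )


def value_nondiseased(avoided_counts: Mapping[str, float],
                      costs: RelativeCostTable,
                      cohort_y1_nondiseased: pd.DataFrame,
                      cohort_n: int,
                      weighting: str = "inverse_risk_count"
                      ) -> ValuationComponent:
    """Savings from avoided/reduced risks among the non-diseased.

    Per-factor savings are avoided count x factor marginal cost.  The
    component total is a weighted summation over members: each at-risk
    member's share of a factor's savings is down-weighted by 1/(number of
    at-risk factors) so a multi-risk member's cost basis is not counted once
    per factor (``weighting="equal"`` disables the adjustment, making the
    total exactly the sum of count x cost).  Negative avoided counts
    (dissavings from a risk-prevalence increase) keep their sign.
    """
    factor_cols = {f: f"factor_{f}" for f in costs.ratios.index}
    df = cohort_y1_nondiseased
    risk_count = df[list(factor_cols.values())].sum(axis=1)
    if weighting == "inverse_risk_count":
        w = 1.0 / risk_count.replace(0, np.nan)
    elif weighting == "equal":
        w = pd.Series(1.0, index=df.index)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    member_savings = pd.Series(0.0, index=df.index)
    rows = []
    for f, col in factor_cols.items():
        avoided = float(avoided_counts.get(f, 0.0))
        dollars = float(costs.marginal_cost[f])
        factor_total = avoided * dollars
        at_risk = df[col] == 1
        n_at_risk = int(at_risk.sum())
        if n_at_risk:
            share = factor_total / n_at_risk
            member_savings[at_risk] += share * w[at_risk].fillna(1.0)
        rows.append({"factor": f, "avoided": avoided,
                     "marginal_cost_usd": dollars,
                     "total_usd": factor_total,
                     "pppy_usd": factor_total / cohort_n})
    total_c = _cents(member_savings.sum())
    n_applied = int(len(df))
    return ValuationComponent(
        name="nondiseased",
        n_applied=n_applied,
        pppy_savings=total_c / 100.0 / n_applied if n_applied else 0.0,
        total_cents=total_c,
        sd=float(member_savings.std(ddof=1)) if n_applied > 1 else 0.0,
        members=frozenset(df.index),
        detail=pd.DataFrame(rows).set_index("factor"),
    )


def net_disease_cost(cohort_y1: pd.DataFrame, disease: str) -> float:
    """Mean annual cost of the diseased minus the non-diseased (baseline)."""
    dis = cohort_y1[cohort_y1[f"dis_{disease}"] == 1]
    if dis.empty:
        raise ValueError(f"no prevalent {disease} members: "
                         "net cost undefined")
    dis_cols = [f"dis_{d}" for d in DISEASES]
    nond = cohort_y1[cohort_y1[dis_cols].sum(axis=1) == 0]
    return float(dis["pppy_cost"].mean()) - float(nond["pppy_cost"].mean())


def value_incidence(deltas: Sequence[IncidenceDelta],
                    cohort_y1: pd.DataFrame) -> ValuationComponent:
    """Savings from avoided disease onsets.

    Dollars per disease = unrounded avoided count x net baseline cost of the
    disease; the applied population is the rounded total avoided count.
    When fewer than one whole onset is avoided, only the total is reported
    (PPPY set to 0).
    """
    rows, nets, weights = [], [], []
    total = 0.0
    for delta in deltas:
        try:
            net = net_disease_cost(cohort_y1, delta.disease)
        except ValueError as exc:
            warnings.warn(str(exc) + "; disease skipped")
            continue
        dollars = delta.avoided * net
        total += dollars
        nets.append(net)
        weights.append(max(delta.avoided, 0.0))
        rows.append({"disease": delta.disease,
                     "avoided": delta.avoided,
                     "net_cost_usd": net,
                     "total_usd": dollars})
    n_avoided = int(round(sum(d.avoided for d in deltas)))
    total_c = _cents(total)
    pppy = total_c / 100.0 / n_avoided if n_avoided >= 1 else 0.0
    if sum(weights) > 0:
        nets_arr = np.asarray(nets)
        w = np.asarray(weights) / sum(weights)
        mean = float(w @ nets_arr)
        sd = float(np.sqrt(w @ (nets_arr - mean) ** 2))
    else:
        sd = 0.0
    return ValuationComponent(
        name="incidence",
        n_applied=n_avoided,
        pppy_savings=pppy,
        total_cents=total_c,
        sd=sd,
        members=frozenset(),  # population-level, not member-assigned
        detail=pd.DataFrame(rows).set_index("disease") if rows else None,
    )


def value_newly_diseased(y1: pd.DataFrame, y2: pd.DataFrame,
                         small_cell_min: int = 5,
                         factors: Sequence[str] = FACTORS,
                         diseases: Sequence[str] = DISEASES,
                         eligible: pd.Index | None = None
                         ) -> ValuationComponent:
    """Savings from risk resolution among newly diseased members.

    For each disease x factor cell, the percent cost difference between
    newly diseased members with and without the factor risk (follow-up
    year) is multiplied by the average diseased annual cost; a member whose
    factor risk resolved (at risk at baseline, not at follow-up) accrues
    that amount.  Cells with fewer than ``small_cell_min`` members on either
    side fall back to the pooled (all new onsets) percent difference for the
    factor, logged via a warning.
    """
    new_cols = [f"new_{d}" for d in diseases]
    newly_mask = y2[new_cols].sum(axis=1) > 0
    members = y2.index[newly_mask]
    if eligible is not None:
        members = members.intersection(eligible)
    if len(members) == 0:
        warnings.warn("no newly diseased members: component is zero")
        return ValuationComponent("newly_diseased", 0, 0.0, 0, 0.0)
    dis_cols = [f"dis_{d}" for d in DISEASES]
    diseased_y2 = y2[y2[dis_cols].sum(axis=1) > 0]
    avg_diseased_pppy = float(diseased_y2["pppy_cost"].mean())

    def pct_diff(frame: pd.DataFrame, factor_col: str) -> float | None:
        with_risk = frame.loc[frame[factor_col] == 1, "pppy_cost"]
        without = frame.loc[frame[factor_col] == 0, "pppy_cost"]
        if len(with_risk) < small_cell_min or len(without) < small_cell_min \
                or without.mean() == 0:
            return None
        return float(with_risk.mean() / without.mean() - 1.0)

    newly_y2 = y2.loc[members]
    newly_y1 = y1.loc[members]
    member_savings = pd.Series(0.0, index=members)
    for f in factors:
        col = f"factor_{f}"
        pooled = pct_diff(newly_y2, col)
        for d in diseases:
            with_d = newly_y2[newly_y2[f"new_{d}"] == 1]
            if with_d.empty:
                continue
            diff = pct_diff(with_d, col)
            if diff is None:
                if pooled is None:
                    continue
                warnings.warn(
                    f"small cell for {d} x {f}: pooled percent difference "
                    "used")
                diff = pooled
            resolved = (newly_y1[col] == 1) & (newly_y2[col] == 0) \
                & (newly_y2[f"new_{d}"] == 1)
            member_savings[resolved] += diff * avg_diseased_pppy
    total_c = _cents(member_savings.sum())
    n = int(len(members))
    return ValuationComponent(
        name="newly_diseased",
        n_applied=n,
        pppy_savings=total_c / 100.0 / n,
        total_cents=total_c,
        sd=float(member_savings.std(ddof=1)) if n > 1 else 0.0,
        members=frozenset(members),
    )


def value_diseased(diseased_members: Sequence, engaged_flags: Mapping,
                   annual_rate: float = DISEASED_ANNUAL_SAVINGS
                   ) -> ValuationComponent:
    """Published per-engaged-member savings applied to engaged diseased.

    ``annual_rate`` (default US$294.07) is credited to every actively
    engaged diseased member; the component PPPY is reported over the full
    diseased population.
    """
    if annual_rate <= 0:
        raise ValueError("annual_rate must be positive")
    members = list(diseased_members)
    n_dis = len(members)
    engaged = [m for m in members if engaged_flags[m]]
    total_c = _cents(annual_rate) * len(engaged)
    per_member = pd.Series(
        [annual_rate if engaged_flags[m] else 0.0 for m in members],
        index=members)
    return ValuationComponent(
        name="diseased",
        n_applied=n_dis,
        pppy_savings=total_c / 100.0 / n_dis if n_dis else 0.0,
        total_cents=total_c,
        sd=float(per_member.std(ddof=1)) if n_dis > 1 else 0.0,
        members=frozenset(members),
    )


def assemble_report(components: Mapping[str, ValuationComponent],
                    cohort_n: int) -> ValuationReport:
    """Sum the four components; enforce one savings rate per member.

    Member-assigned components (diseased, newly_diseased, nondiseased) must
    be pairwise disjoint; the incidence component is population-level.
    Grand total is exact integer-cent addition; grand PPPY is total over the
    full cohort, rounded to cents.
    """
    expected = {"nondiseased", "incidence", "newly_diseased", "diseased"}
    if set(components) != expected:
        raise ValueError(f"expected components {sorted(expected)}, "
                         f"got {sorted(components)}")
    assigned: dict = {}
    offenders = []
    for name in ("diseased", "newly_diseased", "nondiseased"):
        for m in components[name].members:
            if m in assigned:
                offenders.append((m, assigned[m], name))
            assigned[m] = name
    if offenders:
        raise ValueError(
            "members assigned to more than one savings component: "
            f"{offenders[:10]}{'...' if len(offenders) > 10 else ''}")
    grand_c = sum(c.total_cents for c in components.values())
    pppy = round(grand_c / 100.0 / cohort_n, 2) if cohort_n else 0.0
    return ValuationReport(
        components=dict(components),
        cohort_n=cohort_n,
        grand_total_cents=grand_c,
        grand_pppy=pppy,
    )
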
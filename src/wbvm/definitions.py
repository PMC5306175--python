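"""Shared vocabulary: factor and disease names, default calibration marginals.

The eight well-being factors aggregate 50+ binary assessment items; a member
is "at risk" for a factor when any constituent item is at risk.  The five
chronic conditions are ascertained from administrative claims.  Default
marginals describe a mid-size employer population observed over two
consecutive years (baseline year 1, follow-up year 2) under a well-being
improvement program.
"""

from __future__ import annotations

FACTORS: tuple[str, ...] = (
    "current_health",
    "health_maintenance",
    "mental_health",
    "negative_affect",
    "positive_affect",
    "financial_support",
    "financial_status",
    "strengths",
)

DISEASES: tuple[str, ...] = (
    "diabetes",
    "copd",
    "asthma",
    "cad",
    "heart_failure",
)

# Baseline (year 1) at-risk prevalence per factor.
DEFAULT_FACTOR_PREVALENCE: dict[str, float] = {
    "current_health": 0.572,
    "health_maintenance": 0.729,
    "mental_health": 0.255,
    "negative_affect": 0.534,
    "positive_affect": 0.203,
    "financial_support": 0.239,
    "financial_status": 0.230,
    "strengths": 0.171,
}

# Observed year-over-year multiplicative trend in factor prevalence
# (follow-up prevalence / baseline prevalence) under the program.
DEFAULT_RISK_TREND: dict[str, float] = {
    "current_health": 0.583 / 0.572,
    "health_maintenance": 0.709 / 0.729,
    "mental_health": 0.225 / 0.255,
    "negative_affect": 0.521 / 0.534,
    "positive_affect": 0.180 / 0.203,
    "financial_support": 0.231 / 0.239,
    "financial_status": 0.207 / 0.230,
    "strengths": 0.158 / 0.171,
}

# Baseline disease prevalence.
DEFAULT_DISEASE_PREVALENCE: dict[str, float] = {
    "diabetes": 0.050,
    "copd": 0.016,
    "asthma": 0.095,
    "cad": 0.008,
    "heart_failure": 0.002,
}

# Annual incidence among the baseline non-diseased (for each condition), set
# so that the expected newly-diseased share of the whole population matches
# the observed follow-up marginals (0.8 % diabetes, 0.5 % COPD, 1.4 % asthma,
# 0.3 % CAD, 0.1 % heart failure).
DEFAULT_DISEASE_INCIDENCE: dict[str, float] = {
    "diabetes": 0.008 / (1 - 0.050),
    "copd": 0.005 / (1 - 0.016),
    "asthma": 0.014 / (1 - 0.095),
    "cad": 0.003 / (1 - 0.008),
    "heart_failure": 0.001 / (1 - 0.002),
}

# Items per factor: 47 items in total, so that an item-level input roster
# (items + 5 conditions + age) has 53 entries.
DEFAULT_ITEMS_PER_FACTOR: dict[str, int] = {
    "current_health": 6,
    "health_maintenance": 6,
    "mental_health": 6,
    "negative_affect": 6,
    "positive_affect": 6,
    "financial_support": 6,
    "financial_status": 6,
    "strengths": 5,
}

# Multiplicative effects on expected annual cost.
DEFAULT_COST_MULTIPLIERS: dict[str, float] = {
    # conditions
    "diabetes": 3.0,
    "copd": 2.5,
    "asthma": 1.5,
    "cad": 3.0,
    "heart_failure": 4.0,
    # at-risk factors
    "current_health": 1.25,
    "health_maintenance": 1.08,
    "mental_health": 1.05,
    "negative_affect": 1.05,
    "positive_affect": 1.05,
    "financial_support": 1.20,
    "financial_status": 1.15,
    "strengths": 1.02,
}

#: Savings applied per engaged diseased member per year (published
#: matching-based estimate; 4.73 % savings rate).
DISEASED_ANNUAL_SAVINGS: float = 294.07


def item_names(factor: str, n_items: int) -> list[str]:
    """Canonical item column stems for a factor (``<factor>_r1`` ...)."""
    return [f"{factor}_r{i}" for i in range(1, n_items + 1)]
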
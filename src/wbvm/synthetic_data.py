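"""Synthetic two-year assessment + claims panels with known generating truth.

Real well-being assessment (WBA) and administrative-claims data are
proprietary, so every downstream stage of the valuation pipeline is exercised
on panels drawn here.  The generator emulates the marginal structure of a
mid-size employer cohort observed over two consecutive years: correlated
binary risk items grouped into eight factors, five claims-ascertained chronic
conditions with monotone two-year progression, heavy-tailed annual costs, and
demographics.

Construction
------------
Binary risk items are realized through a Gaussian copula: each member draws a
vector of factor-level latents with a target cross-factor correlation, item
latents load on their factor latent with a configurable within-factor
correlation, and items are thresholded at the Gaussian quantile that yields
the requested marginal rate.  Year-2 latents are an AR(1) step from year 1
(temporal persistence) with thresholds moved according to the configured true
risk trend.  Disease prevalence and incidence are logistic in the member's
at-risk factor count, with intercepts solved numerically so population rates
hit their targets exactly in expectation.  Costs are lognormal with
multiplicative disease/at-risk effects and a point mass at zero.

All distributional choices beyond the stated marginals are stand-ins: the
joint law of risks, disease and cost in real claims data is unknown.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .definitions import (
    DEFAULT_COST_MULTIPLIERS,
    DEFAULT_DISEASE_INCIDENCE,
    DEFAULT_DISEASE_PREVALENCE,
    DEFAULT_FACTOR_PREVALENCE,
    DEFAULT_ITEMS_PER_FACTOR,
    DEFAULT_RISK_TREND,
    DISEASES,
    FACTORS,
    item_names,
)

__all__ = [
    "PopulationConfig",
    "SyntheticPanel",
    "generate_population",
    "generate_item_matrix",
    "implied_factor_prevalence",
    "item_rate_for_factor_prevalence",
]

# Gauss-Hermite rule reused by the threshold solver.
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(96)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _default_cross_factor_corr() -> np.ndarray:
    # Compound symmetry: every pair of factor latents correlated at 0.25.
    c = np.full((len(FACTORS), len(FACTORS)), 0.25)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class PopulationConfig:
    """Generating parameters for a two-year synthetic panel.

    Defaults reproduce the marginal profile of the reference employer cohort
    (n = 6,170): mean age 44.6 (SD 10.2), 68.7 % female, factor at-risk
    prevalences between 17 % and 73 %, disease prevalences between 0.2 % and
    9.5 %, and a mean annual cost of ~US$2,113 with SD several times the mean.
    """

    n_members: int = 6170
    seed: int = 0
    mean_age: float = 44.6
    sd_age: float = 10.23
    min_age: float = 18.0
    max_age: float = 65.0
    pct_female: float = 0.687
    factor_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_PREVALENCE))
    items_per_factor: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ITEMS_PER_FACTOR))
    within_factor_item_corr: float = 0.5
    cross_factor_corr: np.ndarray = field(
        default_factory=_default_cross_factor_corr)
    temporal_autocorr: float = 0.6
    disease_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_PREVALENCE))
    disease_incidence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_INCIDENCE))
    #: log-odds increase in disease risk per at-risk factor
    disease_risk_slope: float = 0.25
    risk_trend_true: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_TREND))
    #: lognormal log-scale mean; None = solve so the cost mean hits
    #: cost_mean_year1 / cost_mean_year2
    cost_location: float | None = None
    cost_scale: float = 1.6
    cost_mean_year1: float = 2113.16
    cost_mean_year2: float = 2243.19
    zero_cost_rate: float = 0.10
    cost_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COST_MULTIPLIERS))
    enrollment_months_mean: float = 9.7
    enrollment_months_sd: float = 4.39
    #: share of members actively engaged with the program
    engaged_rate: float = 0.21
    #: probability a true disease is omitted from self-report
    self_report_false_negative: float = 0.15
    #: probability the claims-based flag is unobserved (blank)
    claims_missing_rate: float = 0.0

    def validate(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        props = {
            "pct_female": self.pct_female,
            "within_factor_item_corr": self.within_factor_item_corr,
            "zero_cost_rate": self.zero_cost_rate,
            "engaged_rate": self.engaged_rate,
            "self_report_false_negative": self.self_report_false_negative,
            "claims_missing_rate": self.claims_missing_rate,
            **{f"factor_prevalence[{k}]": v
               for k, v in self.factor_prevalence.items()},
            **{f"disease_prevalence[{k}]": v
               for k, v in self.disease_prevalence.items()},
            **{f"disease_incidence[{k}]": v
               for k, v in self.disease_incidence.items()},
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} is not a proportion in [0, 1]")
        if not 0.0 <= self.within_factor_item_corr < 1.0 + 1e-12:
            raise ValueError("within_factor_item_corr must lie in [0, 1]")
        if not -1.0 < self.temporal_autocorr < 1.0 + 1e-12:
            raise ValueError("temporal_autocorr must lie in (-1, 1]")
        for k, v in self.items_per_factor.items():
            if v < 1:
                raise ValueError(f"items_per_factor[{k}] must be >= 1")
        c = np.asarray(self.cross_factor_corr, dtype=float)
        if c.shape != (len(FACTORS), len(FACTORS)):
            raise ValueError("cross_factor_corr must be 8x8")
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError(
                "cross_factor_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError(
                "cross_factor_corr is not positive semi-definite")

    def truth_dict(self) -> dict[str, Any]:
        """Generating parameters serialized for recovery tests."""
        d: dict[str, Any] = {}
        for key, value in self.__dict__.items():
            if isinstance(value, np.ndarray):
                d[key] = value.tolist()
            else:
                d[key] = value
        return d


@dataclass
class SyntheticPanel:
    """A linked two-year panel plus the parameters that generated it."""

    frame: pd.DataFrame
    truth: dict[str, Any]

    def year(self, year: int) -> pd.DataFrame:
        return self.frame[self.frame["year"] == year].set_index("member_id")

    def to_csv(self, path: str | Path, truth_path: str | Path | None = None) -> None:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        if truth_path is None:
            truth_path = path.with_suffix(".truth.json")
        Path(truth_path).write_text(json.dumps(self.truth, indent=2, default=float))


# ---------------------------------------------------------------------------
# copula threshold machinery


def implied_factor_prevalence(p_item: float, n_items: int,
                              within_corr: float) -> float:
    """P(any of ``n_items`` exchangeable items at risk) under the copula.

    Items share a single Gaussian factor with loading sqrt(within_corr); each
    has marginal rate ``p_item``.  Evaluated by Gauss-Hermite quadrature over
    the shared factor; exact limits: independence gives 1-(1-p)^k, perfect
    correlation gives p.
    """
    if not 0.0 <= p_item <= 1.0:
        raise ValueError("p_item must lie in [0, 1]")
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if p_item in (0.0, 1.0) or n_items == 1:
        return p_item if n_items == 1 or p_item in (0.0, 1.0) else p_item
    if within_corr >= 1.0 - 1e-12:
        return p_item
    if within_corr <= 1e-12:
        return 1.0 - (1.0 - p_item) ** n_items
    t = stats.norm.ppf(p_item)
    load = np.sqrt(within_corr)
    resid = np.sqrt(1.0 - within_corr)
    cond_not = stats.norm.sf((t - load * _GH_NODES) / resid)
    return float(1.0 - np.sum(_GH_WEIGHTS * cond_not ** n_items))


def item_rate_for_factor_prevalence(p_factor: float, n_items: int,
                                    within_corr: float) -> float:
    """Invert :func:`implied_factor_prevalence` for the item marginal rate."""
    if not 0.0 <= p_factor <= 1.0:
        raise ValueError("p_factor must lie in [0, 1]")
    if p_factor in (0.0, 1.0) or n_items == 1 or within_corr >= 1.0 - 1e-12:
        return p_factor
    f = lambda p: implied_factor_prevalence(p, n_items, within_corr) - p_factor
    return float(optimize.brentq(f, 1e-12, p_factor, xtol=1e-12))


def _draw_items(rng: np.random.Generator, factor_latent: np.ndarray,
                item_rates: Mapping[str, float],
                items_per_factor: Mapping[str, int],
                within_corr: float) -> pd.DataFrame:
    """Threshold item latents ``sqrt(w)*z_f + sqrt(1-w)*e`` per member."""
    n = factor_latent.shape[0]
    load = np.sqrt(within_corr)
    resid = np.sqrt(max(0.0, 1.0 - within_corr))
    cols: dict[str, np.ndarray] = {}
    for j, factor in enumerate(FACTORS):
        k = items_per_factor[factor]
        thr = stats.norm.ppf(np.clip(item_rates[factor], 1e-12, 1 - 1e-12))
        noise = rng.standard_normal((n, k))
        u = load * factor_latent[:, [j]] + resid * noise
        flags = (u < thr).astype(np.int8)
        if item_rates[factor] == 0.0:
            flags[:] = 0
        for i, name in enumerate(item_names(factor, k)):
            cols[name] = flags[:, i]
    return pd.DataFrame(cols)


def generate_item_matrix(n: int, factor_prevalence: Mapping[str, float],
                         items_per_factor: Mapping[str, int],
                         within_factor_item_corr: float, seed: int,
                         cross_factor_corr: np.ndarray | None = None,
                         calibrate_to_factor: bool = False,
                         ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw a correlated binary item table for one period.

    By default each item's marginal at-risk rate equals the rate supplied for
    its factor, and the returned dict reports the implied factor-level
    "any item" prevalence (a deterministic function of item rate, item count
    and within-factor correlation).  With ``calibrate_to_factor=True`` the
    item rates are instead inverted so the factor-level prevalence hits the
    supplied rate — the mode :func:`generate_population` uses.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for fac, k in items_per_factor.items():
        if k < 1:
            raise ValueError(f"items_per_factor[{fac}] must be >= 1")
    if cross_factor_corr is None:
        cross_factor_corr = _default_cross_factor_corr()
    cross_factor_corr = np.asarray(cross_factor_corr, dtype=float)
    eig = np.linalg.eigvalsh(cross_factor_corr)
    if eig.min() < -1e-10:
        raise ValueError(
            "cross_factor_corr is not positive semi-definite "
            f"(minimum eigenvalue {eig.min():.3g})")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(
        cross_factor_corr + 1e-12 * np.eye(len(FACTORS)))
    z = rng.standard_normal((n, len(FACTORS))) @ chol.T
    if calibrate_to_factor:
        item_rates = {
            f: item_rate_for_factor_prevalence(
                factor_prevalence[f], items_per_factor[f],
                within_factor_item_corr)
            for f in FACTORS}
    else:
        item_rates = {f: factor_prevalence[f] for f in FACTORS}
    implied = {
        f: implied_factor_prevalence(item_rates[f], items_per_factor[f],
                                     within_factor_item_corr)
        for f in FACTORS}
    items = _draw_items(rng, z, item_rates, items_per_factor,
                        within_factor_item_corr)
    return items, implied


# ---------------------------------------------------------------------------
# calibration solvers


def _solve_truncnorm_loc(target_mean: float, sd: float, lo: float,
                         hi: float) -> float:
    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    return float(optimize.brentq(
        lambda loc: trunc_mean(loc) - target_mean,
        target_mean - 5 * sd, target_mean + 5 * sd, xtol=1e-10))


def _solve_logistic_intercept(target_rate: float, slope: float,
                              counts: np.ndarray) -> float:
    """Intercept a with mean(expit(a + slope*count)) = target over members."""
    if target_rate <= 0.0:
        return -np.inf
    f = lambda a: special.expit(a + slope * counts).mean() - target_rate
    return float(optimize.brentq(f, -40.0, 20.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# the generator


def generate_population(config: PopulationConfig) -> SyntheticPanel:
    """Generate a linked two-year member panel.

    Returns one row per member-year in the delimited schema consumed by
    cohort preparation: demographics, enrollment months, per-item at-risk
    flags (``<factor>_rK``), self-report (``sr_*``) and claims (``clm_*``)
    disease indicators, annual cost and engagement.  Identical
    (config, seed) pairs give byte-identical output.
    """
    config.validate()
    n = config.n_members
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_demo, rng_items1, rng_items2, rng_dis, rng_cost, rng_months, \
        rng_engage, rng_report = (np.random.default_rng(s) for s in streams)

    # demographics
    loc = _solve_truncnorm_loc(config.mean_age, config.sd_age,
                               config.min_age, config.max_age)
    a = (config.min_age - loc) / config.sd_age
    b = (config.max_age - loc) / config.sd_age
    age1 = stats.truncnorm.rvs(a, b, loc=loc, scale=config.sd_age,
                               size=n, random_state=rng_demo)
    female = rng_demo.random(n) < config.pct_female

    # factor latents, AR(1) across years
    chol = np.linalg.cholesky(
        np.asarray(config.cross_factor_corr, float)
        + 1e-12 * np.eye(len(FACTORS)))
    z1 = rng_items1.standard_normal((n, len(FACTORS))) @ chol.T
    tau = config.temporal_autocorr
    innov = rng_items2.standard_normal((n, len(FACTORS))) @ chol.T
    z2 = tau * z1 + np.sqrt(1.0 - tau ** 2) * innov

    w = config.within_factor_item_corr
    item_rates_y1 = {
        f: item_rate_for_factor_prevalence(
            config.factor_prevalence[f], config.items_per_factor[f], w)
        for f in FACTORS}
    prev_y2 = {
        f: float(np.clip(config.factor_prevalence[f]
                         * config.risk_trend_true.get(f, 1.0), 0.0, 1.0))
        for f in FACTORS}
    item_rates_y2 = {
        f: item_rate_for_factor_prevalence(
            prev_y2[f], config.items_per_factor[f], w)
        for f in FACTORS}
    items1 = _draw_items(rng_items1, z1, item_rates_y1,
                         config.items_per_factor, w)
    items2 = _draw_items(rng_items2, z2, item_rates_y2,
                         config.items_per_factor, w)

    def factor_flags(items: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame({
            f: items[item_names(f, config.items_per_factor[f])].max(axis=1)
            for f in FACTORS})

    flags1, flags2 = factor_flags(items1), factor_flags(items2)
    count1 = flags1.sum(axis=1).to_numpy()
    count2 = flags2.sum(axis=1).to_numpy()

    # disease: prevalence at baseline, incidence among the non-diseased,
    # monotone progression into year 2
    slope = config.disease_risk_slope
    dis1: dict[str, np.ndarray] = {}
    dis2: dict[str, np.ndarray] = {}
    new2: dict[str, np.ndarray] = {}
    intercepts: dict[str, dict[str, float]] = {"prevalence": {}, "incidence": {}}
    for d in DISEASES:
        a0 = _solve_logistic_intercept(config.disease_prevalence[d], slope,
                                       count1)
        p_prev = special.expit(a0 + slope * count1) \
            if np.isfinite(a0) else np.zeros(n)
        has1 = rng_dis.random(n) < p_prev
        nond = ~has1
        if nond.any() and config.disease_incidence[d] > 0:
            a1 = _solve_logistic_intercept(config.disease_incidence[d], slope,
                                           count1[nond])
            p_inc = special.expit(a1 + slope * count1) \
                if np.isfinite(a1) else np.zeros(n)
        else:
            a1, p_inc = -np.inf, np.zeros(n)
        incident = nond & (rng_dis.random(n) < p_inc)
        dis1[d] = has1
        new2[d] = incident
        dis2[d] = has1 | incident
        intercepts["prevalence"][d] = a0
        intercepts["incidence"][d] = a1

    # costs: lognormal * multiplicative effects, point mass at zero
    def draw_costs(rng: np.random.Generator, flags: pd.DataFrame,
                   dis: dict[str, np.ndarray], mean_target: float) -> tuple:
        mult = np.ones(n)
        for f in FACTORS:
            m = config.cost_multipliers.get(f, 1.0)
            mult *= np.where(flags[f].to_numpy().astype(bool), m, 1.0)
        for d in DISEASES:
            m = config.cost_multipliers.get(d, 1.0)
            mult *= np.where(dis[d], m, 1.0)
        sigma = config.cost_scale
        if config.cost_location is None:
            mu = (np.log(mean_target / ((1 - config.zero_cost_rate)
                                        * mult.mean()))
                  - 0.5 * sigma ** 2)
        else:
            mu = config.cost_location
        base = np.exp(mu + sigma * rng.standard_normal(n))
        zero = rng.random(n) < config.zero_cost_rate
        return np.where(zero, 0.0, base * mult), float(mu)

    cost1, mu1 = draw_costs(rng_cost, flags1, dis1, config.cost_mean_year1)
    cost2, mu2 = draw_costs(rng_cost, flags2, dis2, config.cost_mean_year2)

    months = np.clip(np.round(
        rng_months.normal(config.enrollment_months_mean,
                          config.enrollment_months_sd, size=(n, 2))),
        0, 12).astype(int)
    engaged = rng_engage.random(n) < config.engaged_rate

    member_id = np.array([f"M{i:06d}" for i in range(n)])

    def year_frame(year: int, age: np.ndarray, items: pd.DataFrame,
                   dis: dict[str, np.ndarray], cost: np.ndarray,
                   mon: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame({
            "member_id": member_id,
            "year": year,
            "age": np.round(age, 2),
            "female": female.astype(int),
            "eligible_months": mon,
            "pppy_cost": np.round(cost, 2),
            "engaged": engaged.astype(int),
        })
        df = pd.concat([df, items.set_index(df.index)], axis=1)
        for d in DISEASES:
            miss = rng_report.random(n) < config.claims_missing_rate
            fneg = rng_report.random(n) < config.self_report_false_negative
            df[f"sr_{d}"] = (dis[d] & ~fneg).astype(int)
            clm = dis[d].astype(float)
            clm[miss] = np.nan
            df[f"clm_{d}"] = clm
        return df

    frame = pd.concat([
        year_frame(1, age1, items1, dis1, cost1, months[:, 0]),
        year_frame(2, age1 + 1.0, items2, dis2, cost2, months[:, 1]),
    ], ignore_index=True)

    truth = config.truth_dict()
    truth["solved"] = {
        "item_rates_year1": item_rates_y1,
        "item_rates_year2": item_rates_y2,
        "factor_prevalence_year2": prev_y2,
        "disease_intercepts": intercepts,
        "cost_log_location": {"year1": mu1, "year2": mu2},
        "age_truncnorm_loc": loc,
    }
    if frame["pppy_cost"].lt(0).any():  # pragma: no cover - defensive
        warnings.warn("negative synthetic costs generated")
    return SyntheticPanel(frame=frame, truth=truth)
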
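"""Cross-year correlation input-output model and risk-trend forecasting.

The counterfactual ("absent intervention") risk level is forecast by
borrowing the open input-output model of regional economics.  Inputs are the
well-being risks, the chronic-condition flags, and age.  Interdependencies
between inputs are measured as Spearman rank correlations between each
input's baseline distribution and every input's follow-up distribution,
aggregated into a square matrix A.  A final-demand vector d of expected
follow-up levels is built from a zero-inflated-Poisson (ZIP) forecast of
each member's follow-up risk count, and the system

    x = (I - alpha*A)^{-1} d

is solved for the final-demand estimates x (alpha is a damping factor that
guarantees invertibility; the diagonal of A is zeroed so an input does not
feed back on itself).  Because the inputs mix prevalences with age in years,
the solve is performed in baseline-normalized units by default: d is divided
elementwise by the observed baseline levels, and the estimates are rescaled
afterwards.  Per-input multipliers are the expected one-year growth rates

    m_i = x_i / observed_i - 1,

so the expected follow-up at-risk count for an input is
``observed_count * (1 + m_i)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.discrete.count_model import ZeroInflatedPoisson

from .definitions import DISEASES, FACTORS

__all__ = [
    "InputRoster",
    "IOSettings",
    "CorrelationIOModel",
    "ZipTrendModel",
    "ZipConvergenceError",
    "year_tables",
    "build_roster",
    "compute_cross_year_rho",
    "fit_zip_trend",
    "trend_per_input",
    "solve_io",
    "compute_multipliers",
    "expected_at_risk_count",
    "fit_io_model",
]


class ZipConvergenceError(RuntimeError):
    """ZIP maximum-likelihood fit failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def year_tables(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a long cohort into aligned year-1/year-2 wide tables."""
    y1 = cohort[cohort["year"] == 1].set_index("member_id").sort_index()
    y2 = cohort[cohort["year"] == 2].set_index("member_id").sort_index()
    common = y1.index.intersection(y2.index)
    return y1.loc[common], y2.loc[common]


@dataclass
class InputRoster:
    """Ordered list of IO-model inputs with their observed two-year levels."""

    inputs: list[str]
    risk_inputs: list[str]
    observed_baseline: pd.Series
    observed_followup: pd.Series

    def __post_init__(self) -> None:
        for name in self.risk_inputs:
            if name not in self.inputs:
                raise ValueError(f"risk input {name!r} not in roster")
        binary = [c for c in self.inputs if c != "age"]
        lo = self.observed_baseline[binary]
        if ((lo < 0) | (lo > 1)).any():
            raise ValueError("prevalence entries must lie in [0, 1]")


def build_roster(y1: pd.DataFrame, y2: pd.DataFrame,
                 level: str = "factor",
                 include_diseases: bool = True,
                 include_age: bool = True) -> InputRoster:
    """Assemble the default roster at factor or item granularity."""
    if level == "factor":
        risk_cols = [f"factor_{f}" for f in FACTORS]
    elif level == "item":
        risk_cols = [c for c in y1.columns
                     if any(c.startswith(f + "_r") for f in FACTORS)]
    else:
        raise ValueError(f"unknown roster level {level!r}")
    cols = list(risk_cols)
    if include_diseases:
        cols += [f"dis_{d}" for d in DISEASES]
    if include_age:
        cols.append("age")
    return InputRoster(
        inputs=cols,
        risk_inputs=risk_cols,
        observed_baseline=y1[cols].mean(),
        observed_followup=y2[cols].mean(),
    )


def compute_cross_year_rho(y1: pd.DataFrame, y2: pd.DataFrame,
                           inputs: Sequence[str]) -> pd.DataFrame:
    """Spearman rho between input i at baseline and input j at follow-up.

    Midranks handle ties.  An input with zero variance in either year has
    its corresponding row/column zeroed (the correlation is undefined) with
    a warning.
    """
    if len(y1) < 3:
        raise ValueError("need at least 3 members with both years observed")
    a = y1[list(inputs)].to_numpy(float)
    b = y2[list(inputs)].to_numpy(float)
    ra = rankdata(a, axis=0)
    rb = rankdata(b, axis=0)
    ra -= ra.mean(axis=0)
    rb -= rb.mean(axis=0)
    sa = np.sqrt((ra ** 2).sum(axis=0))
    sb = np.sqrt((rb ** 2).sum(axis=0))
    dead = (sa == 0) | (sb == 0)
    if dead.any():
        names = [inputs[i] for i in np.flatnonzero(dead)]
        warnings.warn(
            f"zero-variance inputs {names}: correlations set to 0")
    sa[sa == 0] = 1.0
    sb[sb == 0] = 1.0
    rho = (ra.T @ rb) / np.outer(sa, sb)
    rho[dead, :] = 0.0
    rho[:, dead] = 0.0
    return pd.DataFrame(rho, index=list(inputs), columns=list(inputs))


@dataclass
class ZipTrendModel:
    """Fitted ZIP forecast of each member's follow-up risk count."""

    count_coefficients: pd.Series
    zero_inflation_coefficients: pd.Series
    expected_counts: pd.Series  # fitted mixture mean per member
    converged: bool
    loglike: float


def fit_zip_trend(baseline_covariates: pd.DataFrame,
                  followup_risk_counts: pd.Series,
                  maxiter: int = 500) -> ZipTrendModel:
    """ML fit of a zero-inflated Poisson for follow-up risk counts.

    Logit zero-inflation and log-link count part, both over the supplied
    baseline covariates (an intercept is added).  The fitted per-member
    expected count is the mixture mean (1 - pi_i) * lambda_i.
    """
    y = np.asarray(followup_risk_counts, float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("risk counts must be non-negative integers")
    if (y == 0).all():
        raise ValueError("degenerate response: all follow-up counts are zero")
    X = sm.add_constant(baseline_covariates.astype(float), has_constant="add")
    if len(y) <= 2 * X.shape[1]:
        raise ValueError("sample size does not exceed parameter count")
    model = ZeroInflatedPoisson(y, X, exog_infl=X, inflation="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=maxiter, disp=0)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged and not np.isfinite(res.llf):
        raise ZipConvergenceError(
            "zero-inflated Poisson fit did not converge",
            diagnostics=dict(res.mle_retvals))
    k = X.shape[1]
    names = list(X.columns)
    params = np.asarray(res.params, float)
    infl = pd.Series(params[:k], index=names, name="zero_inflation")
    count = pd.Series(params[k:], index=names, name="count")
    mean = res.predict(which="mean")
    return ZipTrendModel(
        count_coefficients=count,
        zero_inflation_coefficients=infl,
        expected_counts=pd.Series(np.asarray(mean, float),
                                  index=baseline_covariates.index),
        converged=converged,
        loglike=float(res.llf),
    )


def trend_per_input(zip_model: ZipTrendModel, baseline_counts: pd.Series,
                    roster: InputRoster,
                    zero_baseline_rule: str = "exclude",
                    statistic: str = "mean_of_ratios"
                    ) -> tuple[pd.Series, float]:
    """Population risk trend and the per-input trend vector.

    Each member's trend is the ZIP-estimated follow-up count divided by the
    actual baseline count; the population trend is the mean of member
    trends.  Members with a zero baseline count are excluded from the
    average by default (``zero_baseline_rule="estimate"`` instead uses the
    estimated count itself as the member's trend).

    With ``statistic="ratio_of_means"`` the population trend is instead the
    mean estimated count divided by the mean baseline count.  The
    mean-of-ratios statistic is upward-biased whenever many members carry
    only one or two baseline risks (a member predicted to regress from one
    risk toward the population mean contributes a ratio of 2 or more), so
    the aggregate ratio is the statistic the pipeline uses by default.

    Risk inputs receive the population trend; non-risk inputs (conditions,
    age) keep trend 1.
    """
    base = np.asarray(baseline_counts, float)
    est = np.asarray(zip_model.expected_counts.loc[baseline_counts.index],
                     float)
    nz = base > 0
    if not nz.any():
        raise ValueError("all baseline risk counts are zero")
    if statistic == "mean_of_ratios":
        if zero_baseline_rule == "exclude":
            member_trends = est[nz] / base[nz]
        elif zero_baseline_rule == "estimate":
            member_trends = np.where(nz, est / np.where(nz, base, 1.0), est)
        else:
            raise ValueError(
                f"unknown zero_baseline_rule {zero_baseline_rule!r}")
        mean_trend = float(np.mean(member_trends))
    elif statistic == "ratio_of_means":
        mean_trend = float(est.mean() / base.mean())
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    trend = pd.Series(1.0, index=roster.inputs)
    trend[roster.risk_inputs] = mean_trend
    return trend, mean_trend


def solve_io(rho_matrix, final_demand, damping: float = 1.0,
             zero_diagonal: bool = True, ridge: float = 1e-8) -> np.ndarray:
    """Solve the open-model system x = (I - alpha*A)^{-1} d.

    The diagonal of A is zeroed (no self-feedback) unless disabled.  If
    (I - alpha*A) is numerically singular, a small ridge eps*I is added and
    a warning issued.
    """
    A = np.array(rho_matrix, dtype=float)
    d = np.asarray(final_demand, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("rho matrix must be square")
    if A.shape[0] != d.shape[0]:
        raise ValueError("demand vector not conformable with matrix")
    if zero_diagonal:
        np.fill_diagonal(A, 0.0)
    M = np.eye(A.shape[0]) - damping * A
    try:
        cond = np.linalg.cond(M)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            f"(I - alpha*A) numerically singular (cond={cond:.3g}); "
            f"adding ridge {ridge:g}*I")
        M = M + ridge * np.eye(A.shape[0])
    return np.linalg.solve(M, d)


def compute_multipliers(final_demand_estimates, observed_baseline,
                        normalization: str = "growth") -> np.ndarray:
    """Per-input multipliers from estimates and observed baseline levels.

    ``growth`` (default) returns estimate/observed - 1, the expected
    one-year growth rate; ``ratio`` returns the raw ratio.  Inputs observed
    at exactly zero get NaN with a warning (the ratio is undefined).
    """
    est = np.asarray(final_demand_estimates, float)
    obs = np.asarray(observed_baseline, float)
    undefined = obs == 0
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} input(s) observed at zero: multiplier "
            "undefined (NaN)")
    ratio = np.divide(est, obs, out=np.full_like(est, np.nan),
                      where=~undefined)
    if normalization == "growth":
        return ratio - 1.0
    if normalization == "ratio":
        return ratio
    raise ValueError(f"unknown normalization {normalization!r}")


def expected_at_risk_count(observed_y1_count: float, m: float) -> float:
    """Expected follow-up at-risk member count: observed * (1 + growth)."""
    if observed_y1_count < 0:
        raise ValueError("count must be non-negative")
    return observed_y1_count * (1.0 + m)


@dataclass
class IOSettings:
    """Configuration for the IO solve and multiplier normalization."""

    damping: float | str = "auto"
    #: with damping="auto", alpha is set so spectral radius of alpha*A
    #: equals this target (or 1.0 if A is already contracting enough).
    #: The default contraction reproduces one-year expected risk growth
    #: rates in the low-teens-percent range typical of non-intervened
    #: working-age populations.
    spectral_target: float = 0.13
    normalize: bool = True
    multiplier_normalization: str = "growth"
    zero_baseline_rule: str = "exclude"
    trend_statistic: str = "ratio_of_means"
    #: "expected" = ZIP-trend final demand (default for valuation);
    #: "actual" = observed follow-up distribution
    final_demand: str = "expected"


@dataclass
class CorrelationIOModel:
    roster: InputRoster
    rho_matrix: pd.DataFrame
    final_demand: pd.Series
    final_demand_estimates: pd.Series
    multipliers: pd.Series
    mean_trend: float
    damping: float
    zip_model: ZipTrendModel | None = None

    def factor_multipliers(self) -> pd.Series:
        keep = [c for c in self.roster.risk_inputs
                if c in self.multipliers.index]
        return self.multipliers[keep]


def _resolve_damping(A: np.ndarray, settings: IOSettings) -> float:
    if settings.damping != "auto":
        return float(settings.damping)
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    sr = float(np.max(np.abs(np.linalg.eigvals(A))))
    if sr <= settings.spectral_target or sr == 0.0:
        return 1.0
    return settings.spectral_target / sr


def fit_io_model(cohort: pd.DataFrame, roster: InputRoster | None = None,
                 settings: IOSettings | None = None,
                 zip_covariates: Sequence[str] | None = None
                 ) -> CorrelationIOModel:
    """End-to-end IO model: rho matrix, ZIP trend, solve, multipliers."""
    settings = settings or IOSettings()
    y1, y2 = year_tables(cohort)
    if roster is None:
        roster = build_roster(y1, y2)
    rho = compute_cross_year_rho(y1, y2, roster.inputs)

    item_cols = [c for c in y1.columns
                 if any(c.startswith(f + "_r") for f in FACTORS)]
    count_cols = item_cols if item_cols else roster.risk_inputs
    if zip_covariates is None:
        # per-factor baseline risk counts + conditions + demographics
        X = pd.DataFrame(index=y1.index)
        for f in FACTORS:
            fac_items = [c for c in item_cols if c.startswith(f + "_r")]
            if fac_items:
                X[f"count_{f}"] = y1[fac_items].sum(axis=1)
            elif f"factor_{f}" in y1.columns:
                X[f"count_{f}"] = y1[f"factor_{f}"]
        for d in DISEASES:
            if f"dis_{d}" in y1.columns:
                X[f"dis_{d}"] = y1[f"dis_{d}"]
        for c in ("age", "female"):
            if c in y1.columns:
                X[c] = y1[c]
    else:
        X = y1[[c for c in zip_covariates if c in y1.columns]]
    zm = fit_zip_trend(X, y2[count_cols].sum(axis=1))
    trend, mean_trend = trend_per_input(
        zm, y1[count_cols].sum(axis=1), roster,
        zero_baseline_rule=settings.zero_baseline_rule,
        statistic=settings.trend_statistic)

    obs = roster.observed_baseline
    if settings.final_demand == "expected":
        demand = trend * obs
    elif settings.final_demand == "actual":
        demand = roster.observed_followup.copy()
    else:
        raise ValueError(f"unknown final_demand {settings.final_demand!r}")

    A = rho.to_numpy()
    alpha = _resolve_damping(A, settings)
    if settings.normalize:
        safe_obs = obs.replace(0.0, np.nan)
        x = solve_io(A, (demand / safe_obs).fillna(0.0).to_numpy(),
                     damping=alpha)
        estimates = pd.Series(x, index=roster.inputs) * obs
    else:
        x = solve_io(A, demand.to_numpy(), damping=alpha)
        estimates = pd.Series(x, index=roster.inputs)
    mult = compute_multipliers(estimates.to_numpy(), obs.to_numpy(),
                               normalization=settings.multiplier_normalization)
    return CorrelationIOModel(
        roster=roster,
        rho_matrix=rho,
        final_demand=demand,
        final_demand_estimates=estimates,
        multipliers=pd.Series(mult, index=roster.inputs),
        mean_trend=mean_trend,
        damping=alpha,
        zip_model=zm,
    )
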
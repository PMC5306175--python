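"""Regression-only valuation comparator.

An alternative, regression-only accounting of the value of risk change, in
the tradition of cross-sectional health-risk cost models.  Eight
cross-sectional models (one per well-being factor) regress the factor's
at-risk flag on the other seven factors, age, gender and disease burden
(count of the five condition flags), all measured in the same period; the
next-year risk is forecast by advancing each member's age one year.  A
cross-sectional linear model of annual cost on demographics, disease burden
and the forecasted risks then prices risk change: for each factor, the
difference between predicted follow-up and baseline cost among movers
(members whose at-risk status changed in the direction of the expected
prevalence change) times the expected prevalence change times the cohort
size gives the factor's total yearly cost (negative = savings).

Because each coefficient is a linearly independent marginal effect, this
comparator cannot separate the sources of value the main model decomposes,
and it ignores risk interdependencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .definitions import DISEASES, FACTORS

__all__ = [
    "RiskForecastModel",
    "CostChangeRow",
    "fit_risk_forecasts",
    "fit_cost_model",
    "cost_of_risk_change",
    "run_comparator",
]


def _disease_burden(df: pd.DataFrame) -> pd.Series:
    return df[[f"dis_{d}" for d in DISEASES]].sum(axis=1)


@dataclass
class RiskForecastModel:
    factor: str
    coefficients: pd.Series
    link: str
    forecast: pd.Series  # next-year at-risk probability per member

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xd = sm.add_constant(X[self.coefficients.index.drop("const")],
                             has_constant="add").astype(float)
        eta = Xd.to_numpy() @ self.coefficients.loc[Xd.columns].to_numpy()
        if self.link == "logit":
            from scipy.special import expit
            return expit(eta)
        return np.clip(eta, 0.0, 1.0)


@dataclass
class CostChangeRow:
    factor: str
    cost_of_change: float            # $ per person per year, signed
    expected_prevalence_change: float  # percentage points / 100
    total: float                     # $; positive = cost, negative = savings


def _forecast_design(y1: pd.DataFrame, target: str) -> pd.DataFrame:
    other = [f"factor_{f}" for f in FACTORS if f != target]
    X = y1[other + ["age", "female"]].astype(float).copy()
    X["disease_burden"] = _disease_burden(y1).astype(float)
    return X


def fit_risk_forecasts(y1: pd.DataFrame, link: str = "logit"
                       ) -> dict[str, RiskForecastModel]:
    """One cross-sectional model per factor; forecast with age + 1."""
    for f in FACTORS:
        if y1[f"factor_{f}"].nunique() < 2:
            raise ValueError(
                f"factor {f} has no variation: forecast model undefined")
    models: dict[str, RiskForecastModel] = {}
    for f in FACTORS:
        target = y1[f"factor_{f}"].astype(float)
        X = _forecast_design(y1, f)
        Xd = sm.add_constant(X, has_constant="add")
        if link == "logit":
            try:
                res = sm.Logit(target, Xd).fit(disp=0, maxiter=200)
            except Exception as exc:
                raise RuntimeError(
                    f"risk forecast for {f} failed (separation?): {exc}"
                ) from exc
            params = pd.Series(res.params, index=Xd.columns)
        elif link == "linear":
            res = sm.OLS(target, Xd).fit()
            params = pd.Series(res.params, index=Xd.columns)
        else:
            raise ValueError(f"unknown link {link!r}")
        model = RiskForecastModel(factor=f, coefficients=params, link=link,
                                  forecast=pd.Series(dtype=float))
        X_next = X.copy()
        X_next["age"] = X_next["age"] + 1.0
        model.forecast = pd.Series(model.predict(X_next), index=y1.index)
        models[f] = model
    return models


def fit_cost_model(y1: pd.DataFrame, forecasts: pd.DataFrame):
    """OLS of annual cost on demographics, burden and forecasted risks.

    ``forecasts`` holds one column per factor (``factor_<f>``) with the
    risk values to price — forecast probabilities, or observed flags when
    predicting a realized year.
    """
    X = forecasts[[f"factor_{f}" for f in FACTORS]].astype(float).copy()
    X["age"] = y1["age"].astype(float)
    X["female"] = y1["female"].astype(float)
    X["disease_burden"] = _disease_burden(y1).astype(float)
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        raise ValueError("cost-model design is rank deficient")
    return sm.OLS(y1["pppy_cost"].astype(float), Xd).fit()


def _predict_cost(cost_model, y1: pd.DataFrame,
                  risks: pd.DataFrame) -> pd.Series:
    X = risks[[f"factor_{f}" for f in FACTORS]].astype(float).copy()
    X["age"] = y1["age"].astype(float)
    X["female"] = y1["female"].astype(float)
    X["disease_burden"] = _disease_burden(y1).astype(float)
    Xd = sm.add_constant(X, has_constant="add")[
        list(cost_model.params.index)]
    return pd.Series(cost_model.predict(Xd), index=y1.index)


def cost_of_risk_change(y1: pd.DataFrame, y2: pd.DataFrame,
                        forecasts: dict[str, RiskForecastModel],
                        cost_model, mode: str = "predicted"
                        ) -> tuple[list[CostChangeRow], dict]:
    """Per-factor cost of expected prevalence change, plus totals.

    For each factor the expected prevalence change is the mean forecasted
    next-year probability minus the observed baseline prevalence.  Movers
    in the direction of the change (into risk for an increase, out of risk
    for a decrease, judged from observed year-1 -> year-2 flags) price the
    change: cost_of_change is their mean predicted follow-up cost minus
    mean baseline cost (``mode="observed"`` uses observed baseline costs
    instead of predicted).  Row total = cost_of_change x prevalence change
    x cohort n; positive totals are costs, negative are savings.
    """
    n = len(y1)
    fc_frame = pd.DataFrame(
        {f"factor_{f}": m.forecast for f, m in forecasts.items()})
    y2_hat = _predict_cost(cost_model, y1, fc_frame)
    if mode == "predicted":
        y1_hat = _predict_cost(
            cost_model, y1, y1[[f"factor_{f}" for f in FACTORS]])
    elif mode == "observed":
        y1_hat = y1["pppy_cost"].astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows: list[CostChangeRow] = []
    for f in FACTORS:
        col = f"factor_{f}"
        d_prev = float(fc_frame[col].mean() - y1[col].mean())
        into = (y1[col] == 0) & (y2[col] == 1)
        outof = (y1[col] == 1) & (y2[col] == 0)
        movers = into if d_prev >= 0 else outof
        if not movers.any():
            warnings.warn(f"factor {f}: no movers; row zeroed")
            rows.append(CostChangeRow(f, 0.0, d_prev, 0.0))
            continue
        cost = float(y2_hat[movers].mean() - y1_hat[movers].mean())
        rows.append(CostChangeRow(
            factor=f,
            cost_of_change=cost,
            expected_prevalence_change=d_prev,
            total=cost * d_prev * n,
        ))
    total = sum(r.total for r in rows)
    return rows, {"total": total, "pppy": total / n if n else 0.0, "n": n}


def run_comparator(y1: pd.DataFrame, y2: pd.DataFrame,
                   link: str = "logit", mode: str = "predicted"
                   ) -> tuple[pd.DataFrame, dict]:
    """Fit forecasts and the cost model, return the cost-change table."""
    forecasts = fit_risk_forecasts(y1, link=link)
    fc_frame = pd.DataFrame(
        {f"factor_{f}": m.forecast for f, m in forecasts.items()})
    cm = fit_cost_model(y1, fc_frame)
    rows, totals = cost_of_risk_change(y1, y2, forecasts, cm, mode=mode)
    table = pd.DataFrame([{
        "factor": r.factor,
        "cost_of_change_pppy": round(r.cost_of_change, 2),
        "expected_prevalence_change_pct":
            round(100 * r.expected_prevalence_change, 2),
        "total_yearly": round(r.total, 2),
    } for r in rows]).set_index("factor")
    return table, totals
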
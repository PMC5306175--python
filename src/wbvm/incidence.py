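"""Logistic disease-incidence models and avoided-incidence estimation.

For each of the five chronic conditions a logistic model is fit on the
baseline non-diseased members, with the year-2 new-onset flag as the
response.  Covariates: intercept, natural-log age, gender, the other four
condition flags, and the eight well-being factor flags.  The fitted model is
then evaluated under two factor-prevalence scenarios — the IO-forecast
(expected, non-intervened) prevalences and the actually observed follow-up
prevalences — holding each member's demographics and co-morbidities at their
observed values.  The difference in mean predicted incidence, multiplied by
the number of non-diseased members, is the estimate of incidences avoided.

Scenario evaluation substitutes the scenario prevalence for the binary
factor flags directly in the linear predictor (the expectation of the
predictor over independent Bernoulli flags).  An exact Bernoulli-mixture
evaluation, which averages the predicted probability over all flag
combinations, is available via ``mode="bernoulli"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .definitions import DISEASES, FACTORS

__all__ = [
    "IncidenceModel",
    "IncidenceDelta",
    "SeparationError",
    "fit_incidence",
    "odds_ratio",
    "incidence_delta",
    "incidence_covariates",
    "fit_all_incidence",
    "REFERENCE_DIABETES_COEFFICIENTS",
]

#: Published reference coefficient set for a diabetes-incidence model of this
#: form (intercept, at-risk factor flags, co-morbidities, gender, ln age),
#: used in prediction-path tests.  The published table prints an odds ratio
#: of 2.89 next to the asthma beta of 0.227, which is internally inconsistent
#: (exp(0.227) = 1.25); odds ratios here are always derived from the betas.
REFERENCE_DIABETES_COEFFICIENTS: dict[str, float] = {
    "const": -11.51,
    "factor_current_health": 1.28,
    "dis_copd": 0.358,
    "female": -0.0002,
    "ln_age": 1.40,
    "dis_asthma": 0.227,
    "factor_health_maintenance": 0.270,
    "factor_financial_support": 0.771,
}


class SeparationError(RuntimeError):
    """The logistic design separates the outcome perfectly."""


@dataclass
class IncidenceModel:
    """Per-disease logistic incidence model."""

    disease: str
    coefficients: pd.Series
    wald: pd.Series      # squared z statistic per coefficient
    p_values: pd.Series
    std_errors: pd.Series
    covariates: list[str]
    n_obs: int
    n_events: int

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        Xd = sm.add_constant(X[self.covariates].astype(float),
                             has_constant="add")
        return Xd.to_numpy() @ self.coefficients.loc[Xd.columns].to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(X))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "disease": self.disease,
            "covariates": self.covariates,
            "coefficients": self.coefficients.to_dict(),
            "wald": self.wald.to_dict(),
            "p_values": self.p_values.to_dict(),
            "odds_ratios": {k: odds_ratio(v)
                            for k, v in self.coefficients.items()},
            "n_obs": self.n_obs,
            "n_events": self.n_events,
        }, indent=2))


@dataclass
class IncidenceDelta:
    """Avoided incidences for one disease under expected vs actual risks."""

    disease: str
    p_actual: float
    p_expected: float
    delta_p: float
    n_nondiseased: int
    avoided: float


def incidence_covariates(disease: str,
                         factors: Sequence[str] = FACTORS,
                         diseases: Sequence[str] = DISEASES) -> list[str]:
    """Covariate columns for one disease's model (excludes the disease)."""
    others = [f"dis_{d}" for d in diseases if d != disease]
    return ["ln_age", "female"] + others + [f"factor_{f}" for f in factors]


def fit_incidence(covariates: pd.DataFrame, events: pd.Series,
                  disease: str, maxiter: int = 200,
                  columns: list[str] | None = None) -> IncidenceModel:
    """ML logistic fit of new-onset disease on baseline covariates.

    ``covariates`` must contain the columns from
    :func:`incidence_covariates` (``ln_age`` is derived from ``age`` when
    absent); ``columns`` overrides the covariate list.  Raises
    :class:`SeparationError` on complete separation, naming the separating
    covariate, and ``ValueError`` when no events exist.
    """
    X = covariates.copy()
    if "ln_age" not in X.columns and "age" in X.columns:
        X["ln_age"] = np.log(X["age"].astype(float))
    cols = [c for c in (columns or incidence_covariates(disease))
            if c in X.columns]
    y = np.asarray(events, float)
    if y.sum() == 0:
        raise ValueError(f"no {disease} events: incidence model undefined")
    Xd = sm.add_constant(X[cols].astype(float), has_constant="add")
    for c in cols:
        v = Xd[c].to_numpy()
        if np.all(v == v[0]):
            raise SeparationError(
                f"covariate {c!r} is constant: design is rank deficient")
        lo, hi = v[y == 0], v[y == 1]
        if len(lo) and len(hi) and (lo.max() < hi.min()
                                    or hi.max() < lo.min()):
            raise SeparationError(
                f"covariate {c!r} separates {disease} onset perfectly")
    try:
        res = sm.Logit(y, Xd).fit(disp=0, maxiter=maxiter)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise SeparationError(
            f"logistic fit for {disease} failed: {exc}") from exc
    if np.abs(res.params).max() > 50:
        big = Xd.columns[int(np.argmax(np.abs(res.params)))]
        raise SeparationError(
            f"covariate {big!r} drives a diverging coefficient "
            f"(quasi-separation) in the {disease} model")
    z = res.params / res.bse
    return IncidenceModel(
        disease=disease,
        coefficients=pd.Series(res.params, index=Xd.columns),
        wald=pd.Series(np.asarray(z) ** 2, index=Xd.columns),
        p_values=pd.Series(res.pvalues, index=Xd.columns),
        std_errors=pd.Series(res.bse, index=Xd.columns),
        covariates=cols,
        n_obs=int(len(y)),
        n_events=int(y.sum()),
    )


def odds_ratio(beta: float) -> float:
    """exp(beta): multiplicative odds change for a unit covariate change."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float(np.exp(beta))


def _scenario_frame(X: pd.DataFrame, prevalences: Mapping[str, float]
                    ) -> pd.DataFrame:
    out = X.copy()
    for f, p in prevalences.items():
        col = f if f.startswith("factor_") else f"factor_{f}"
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {col} outside [0, 1]: {p}")
        if col in out.columns:
            out[col] = float(p)
    return out


def _bernoulli_mixture_mean(model: IncidenceModel, X: pd.DataFrame,
                            prevalences: Mapping[str, float]) -> float:
    cols = [c for c in model.covariates if c.startswith("factor_")]
    prev = {c if c.startswith("factor_") else f"factor_{c}": p
            for c, p in prevalences.items()}
    base = X.copy()
    total = np.zeros(len(X))
    for combo in product((0, 1), repeat=len(cols)):
        wgt = 1.0
        for c, v in zip(cols, combo):
            p = prev.get(c)
            if p is None:
                continue
            wgt *= p if v else (1.0 - p)
            base[c] = v
        total += wgt * model.predict(base)
    return float(total.mean())


def incidence_delta(model: IncidenceModel, cohort: pd.DataFrame,
                    expected_prevalence: Mapping[str, float],
                    actual_prevalence: Mapping[str, float],
                    mode: str = "linear_predictor") -> IncidenceDelta:
    """Avoided incidences from expected-vs-actual factor prevalences.

    ``cohort`` holds the baseline non-diseased members' covariates
    (demographics and co-morbidities are used at observed values).  Both
    prevalence maps must cover the eight factors, as proportions.
    """
    X = cohort.copy()
    if "ln_age" not in X.columns and "age" in X.columns:
        X["ln_age"] = np.log(X["age"].astype(float))
    if mode == "linear_predictor":
        p_exp = float(model.predict(
            _scenario_frame(X, expected_prevalence)).mean())
        p_act = float(model.predict(
            _scenario_frame(X, actual_prevalence)).mean())
    elif mode == "bernoulli":
        for pm in (expected_prevalence, actual_prevalence):
            for f, p in pm.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence for {f} outside [0, 1]")
        p_exp = _bernoulli_mixture_mean(model, X, expected_prevalence)
        p_act = _bernoulli_mixture_mean(model, X, actual_prevalence)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = int(len(cohort))
    delta = p_exp - p_act
    return IncidenceDelta(
        disease=model.disease,
        p_actual=p_act,
        p_expected=p_exp,
        delta_p=delta,
        n_nondiseased=n,
        avoided=delta * n,
    )


def _screen_sparse(X: pd.DataFrame, cols: list[str], events: np.ndarray,
                   min_cell: int) -> tuple[list[str], list[str]]:
    """Drop binary covariates whose carrier x event cross-cells are too thin.

    A binary covariate with no (or almost no) event-carriers or
    nonevent-carriers drives a diverging coefficient; rare co-morbidity
    flags at low event counts are the usual culprits.
    """
    keep, dropped = [], []
    for c in cols:
        v = X[c].to_numpy(float)
        if set(np.unique(v)) <= {0.0, 1.0} and c != "female":
            carriers = v == 1
            if (carriers.sum() < min_cell
                    or events[carriers].sum() < 1
                    or (1 - events[carriers]).sum() < 1):
                dropped.append(c)
                continue
        keep.append(c)
    return keep, dropped


def fit_all_incidence(y1: pd.DataFrame, y2: pd.DataFrame,
                      diseases: Sequence[str] = DISEASES,
                      min_cell: int = 10) -> dict[str, IncidenceModel]:
    """Fit every disease's model on its baseline non-diseased members.

    Sparse binary covariates (fewer than ``min_cell`` carriers, or no event
    variation among carriers) are dropped per disease with a warning before
    fitting.  Diseases whose fit still fails (no events, separation at very
    low event counts) are skipped with a warning rather than aborting the
    pipeline.
    """
    import warnings

    models: dict[str, IncidenceModel] = {}
    for d in diseases:
        nond = y1[y1[f"dis_{d}"] == 0]
        events = y2.loc[nond.index, f"dis_{d}"].to_numpy(float)
        cols = [c for c in incidence_covariates(d) if c in nond.columns]
        cols, dropped = _screen_sparse(nond, cols, events, min_cell)
        if dropped:
            warnings.warn(
                f"incidence model for {d}: sparse covariates dropped "
                f"{dropped}")
        try:
            models[d] = fit_incidence(nond, y2.loc[nond.index, f"dis_{d}"],
                                      d, columns=cols)
        except (SeparationError, ValueError) as exc:
            warnings.warn(f"incidence model for {d} skipped: {exc}")
    return models
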
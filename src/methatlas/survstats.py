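"""Survival and association statistics used throughout model evaluation.

Kaplan-Meier curves, Cox proportional-hazards fits (Efron ties by default),
log-rank tests, ROC/AUC, Pearson correlation, and chi-squared association.
Implementations delegate to lifelines / scipy / scikit-learn; this module
owns the result containers and the validation contracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .datamodel import ValidationError


@dataclass
class KMCurve:
    """Product-limit survival estimate: S(0)=1, right-continuous, non-increasing."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """Per-covariate Cox PH estimates with Wald CIs on the log-HR scale."""

    table: pd.DataFrame  # term, coef, hr, ci_low, ci_high, se, p
    log_likelihood: float
    n: int
    n_events: int
    flags: dict

    def hr(self, term: str) -> float:
        return float(self.table.loc[term, "hr"])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimator; subjects censored at an event time remain at risk
    through that event."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time < 0).any():
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_["KM_estimate"]
    ev = kmf.event_table
    event_times = ev.index.to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=float)
    surv = sf.reindex(ev.index).to_numpy(dtype=float)
    censor_times = np.unique(time[event == 0])
    return KMCurve(event_times, at_risk, surv, censor_times)


def cox_fit(covariates: pd.DataFrame, time, event, ties: str = "efron",
            penalizer: float = 0.0) -> CoxFit:
    """Cox PH regression by partial-likelihood Newton-Raphson.

    ``covariates`` must be numeric and full rank after any one-hot encoding
    done by the caller.  Constant columns are non-estimable and flagged rather
    than fit; monotone-likelihood (perfect separation) is surfaced as a
    lifelines warning and flagged.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError("ties must be 'efron' or 'breslow'")
    covariates = pd.DataFrame(covariates).astype(float)
    flags = {}
    const = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if const:
        flags["non_estimable"] = const
        covariates = covariates.drop(columns=const)
        if covariates.shape[1] == 0:
            raise ValidationError(f"all covariates constant: {const}")
    df = covariates.copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)
    fitter = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fitter.fit(df, duration_col="_time", event_col="_event",
                       fit_options={"precision": 1e-10})
        for w in caught:
            if "complete separation" in str(w.message) or "convergence" in str(w.message).lower():
                flags.setdefault("warnings", []).append(str(w.message))
    except ConvergenceError as exc:
        raise ValidationError(f"Cox fit did not converge: {exc}") from exc
    summ = fitter.summary
    table = pd.DataFrame({
        "coef": summ["coef"],
        "hr": summ["exp(coef)"],
        "ci_low": np.exp(summ["coef lower 95%"]),
        "ci_high": np.exp(summ["coef upper 95%"]),
        "se": summ["se(coef)"],
        "p": summ["p"],
    })
    table.index.name = "term"
    return CoxFit(table, float(fitter.log_likelihood_), int(df.shape[0]),
                  int(df["_event"].sum()), flags)


def logrank(time, event, group):
    """Two-sided log-rank test across >=2 groups; returns (statistic, p)."""
    group = pd.Series(group).astype(str)
    counts = group.value_counts()
    if counts.size < 2:
        raise ValidationError("log-rank needs at least two groups")
    res = multivariate_logrank_test(np.asarray(time, float), group,
                                    np.asarray(event, int))
    return float(res.test_statistic), float(res.p_value)


def roc_auc(binary_outcome, score) -> float:
    """AUC as the Mann-Whitney probability with half credit for ties.

    Accepts binary scores (categorical high/low mode) or continuous scores.
    """
    y = np.asarray(binary_outcome, dtype=int)
    s = np.asarray(score, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("both outcome classes must be present")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, s))


def pearson(x, y):
    """Pearson correlation with a two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def chi2_association(table, correction: bool = False):
    """Pearson chi-squared test of independence on an r x c contingency table."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValidationError("negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("empty row or column in contingency table")
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        raise ValidationError("expected cell count of zero")
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)
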
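"""Prognostic CpG signature: risk-adjusted Cox EWAS, penalized-Cox stability
selection, and the linear M-value hazard score.

The procedure mirrors the discovery recipe for a compact survival signature:

1. per-CpG Cox proportional-hazards regression of 5-year overall survival on
   the CpG M-value plus adjustment covariates (EWAS), with administrative
   censoring at the horizon;
2. candidate CpGs selected at a genome-wide p-value threshold;
3. repeated L1-penalized Cox fits (each iteration reshuffles 10-fold CV used
   to pick the penalty by held-out partial likelihood); CpGs with non-zero
   coefficients in at least 95% of iterations are kept;
4. a joint unpenalized Cox refit of the kept CpGs defines the linear hazard
   score ``score = sum_i coef_i * M_i``, dichotomized at the median of the
   training scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.model_selection import KFold

from .datamodel import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EwasResult:
    """One Cox PH fit per CpG: log hazard per M-value unit, SE, z, Wald p."""

    table: pd.DataFrame  # index probe_id; coef, se, z, p, converged
    covariates: list
    n_samples: int
    n_events: int


@dataclass
class SignatureModel:
    """Ordered (probe, coefficient) pairs plus the score dichotomization cutoff."""

    entries: pd.Series  # probe_id -> coefficient (non-zero)
    cutoff: float
    selection_frequencies: pd.Series

    def __post_init__(self) -> None:
        if (self.entries == 0).any():
            raise ValidationError("signature coefficients must be non-zero")
        if not np.isfinite(self.cutoff):
            raise ValidationError("cutoff must be finite")

    @property
    def probe_ids(self) -> list:
        return list(self.entries.index)

    def to_dict(self) -> dict:
        return {
            "probes": self.probe_ids,
            "coefficients": [float(c) for c in self.entries],
            "cutoff": float(self.cutoff),
            "selection_frequencies": {
                k: float(v) for k, v in self.selection_frequencies.items()
            },
        }


def truncate_horizon(time, event, horizon: float = 60.0):
    """Administrative censoring at the horizon: events after it become censored."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    t = np.minimum(time, horizon)
    e = np.where(time <= horizon, event, 0)
    return t, e


def cox_ewas(mvalues: pd.DataFrame, time, event,
             adjustment_covariates: pd.DataFrame | None = None,
             horizon: float = 60.0) -> EwasResult:
    """Per-CpG Cox PH regression of time-to-death on (M-value + covariates).

    ``adjustment_covariates`` must already be numerically encoded (e.g. risk
    group as indicator columns).  Non-converging or degenerate CpGs are
    flagged with p = 1 rather than aborting the scan.
    """
    if mvalues.isna().to_numpy().any():
        raise ValidationError("EWAS requires complete M-values")
    t, e = truncate_horizon(time, event, horizon)
    if e.sum() < 10:
        raise ValidationError(f"need >=10 events within the horizon, got {int(e.sum())}")
    cov = pd.DataFrame(index=mvalues.index)
    cov_names: list = []
    if adjustment_covariates is not None:
        cov = pd.DataFrame(adjustment_covariates).astype(float)
        cov.index = mvalues.index
        cov_names = list(cov.columns)
    rows = []
    base = cov.copy()
    base["_time"] = t
    base["_event"] = e
    for probe in mvalues.columns:
        x = mvalues[probe].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            rows.append((probe, np.nan, np.nan, np.nan, 1.0, False))
            continue
        df = base.copy()
        df.insert(0, "_cpg", x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = CoxPHFitter().fit(df, duration_col="_time", event_col="_event",
                                        fit_options={"precision": 1e-10})
            s = fit.summary.loc["_cpg"]
            rows.append((probe, float(s["coef"]), float(s["se(coef)"]),
                         float(s["z"]), float(s["p"]), True))
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("EWAS fit failed for %s: %s", probe, exc)
            rows.append((probe, np.nan, np.nan, np.nan, 1.0, False))
    table = pd.DataFrame(rows, columns=["probe_id", "coef", "se", "z", "p", "converged"])
    table = table.set_index("probe_id")
    return EwasResult(table, cov_names, int(len(t)), int(e.sum()))


def select_candidates(ewas: EwasResult, alpha: float = 1e-5) -> list:
    """Probes with Wald p strictly below ``alpha``, sorted by p ascending."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    hits = ewas.table[ewas.table["p"] < alpha].sort_values("p")
    if hits.empty:
        warnings.warn(f"no CpG passed the EWAS threshold alpha={alpha}", stacklevel=2)
    return list(hits.index)


def _breslow_loglik(X: np.ndarray, t: np.ndarray, e: np.ndarray,
                    beta: np.ndarray) -> float:
    """Breslow partial log-likelihood used to score held-out folds."""
    eta = X @ beta
    order = np.argsort(-t)  # descending time: cumulative sums give risk sets
    eta, tt, ee = eta[order], t[order], e[order]
    log_cum = np.logaddexp.accumulate(eta)
    # with ties in t the risk set must include all subjects with equal time
    # walk backwards to propagate the cumulative value across ties
    for i in range(len(tt) - 2, -1, -1):
        if tt[i] == tt[i + 1]:
            log_cum[i] = log_cum[i + 1]
    return float(np.sum(ee * (eta - log_cum)))


def _cv_chosen_alpha(X: np.ndarray, t: np.ndarray, e: np.ndarray,
                     alphas: np.ndarray, n_folds: int,
                     rng: np.random.Generator, tol: float) -> float:
    """Lasso penalty maximizing mean held-out partial log-likelihood."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    folds = KFold(n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for train, test in folds.split(X):
        if e[train].sum() == 0 or e[test].sum() == 0:
            continue
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                       fit_baseline_model=False, tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X[train], Surv.from_arrays(e[train].astype(bool), t[train]))
            except (ArithmeticError, ValueError):
                continue
        fitted = np.asarray(model.alphas_)
        for j, a in enumerate(alphas):
            k = int(np.argmin(np.abs(fitted - a)))
            scores[j] += _breslow_loglik(X[test], t[test], e[test], model.coef_[:, k])
            counts[j] += 1
    if counts.max() == 0:
        raise ValidationError("penalized Cox CV failed on every fold")
    mean = np.where(counts > 0, scores / np.maximum(counts, 1), -np.inf)
    return float(alphas[int(np.argmax(mean))])


def stability_select(mvalues_candidates: pd.DataFrame, time, event,
                     n_iter: int = 1000, n_folds: int = 10,
                     freq_threshold: float = 0.95, seed: int = 0,
                     horizon: float = 60.0, penalty_rule: str = "subsample",
                     subsample_fraction: float = 0.5,
                     support_cap: int | None = None,
                     n_alphas: int = 40, alpha_min_ratio: float = 0.005,
                     selection_tol: float = 1e-4,
                     ridge_fallback: float = 1e-4) -> SignatureModel:
    """Stability selection over repeated penalized Cox fits.

    Default procedure (``penalty_rule="subsample"``): each iteration fits the
    lasso path on a random half of the cohort and records the support at the
    largest penalty admitting at least ``support_cap`` candidates (default
    15% of the candidate count).  Candidates with non-zero frequency
    >= ``freq_threshold`` across iterations form the signature.  Half-sample
    perturbation is what gives the frequency rule its selectivity: refits of
    near-identical data reproduce the same support, so chance associations
    would pass any frequency threshold.

    ``penalty_rule="cv"`` is the literal variant: each iteration reshuffles a
    ``n_folds``-fold split of the full cohort, picks the penalty by maximum
    mean held-out partial log-likelihood, refits on the full cohort, and
    records the support.

    Final coefficients come from a joint unpenalized Cox refit of the kept
    CpGs (ridge-stabilized on singularity); the cutoff is the median training
    hazard score.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if mvalues_candidates.shape[1] < 2:
        raise ValidationError("need at least 2 candidate CpGs")
    if penalty_rule not in ("subsample", "cv"):
        raise ValidationError("penalty_rule must be 'subsample' or 'cv'")
    t, e = truncate_horizon(time, event, horizon)
    if e.sum() < n_folds:
        raise ValidationError("need at least one event per CV fold")
    X = mvalues_candidates.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    y_all = Surv.from_arrays(e.astype(bool), t)
    n, p = Xc.shape
    q = support_cap if support_cap is not None else max(2, int(np.ceil(0.15 * p)))

    # shared penalty grid from the full-cohort lasso path
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=alpha_min_ratio,
                                  fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path.fit(Xc, y_all)
    alphas = np.asarray(path.alphas_)

    rng = np.random.default_rng(seed)
    hits = np.zeros(p)
    n_done = 0
    for _ in range(n_iter):
        if penalty_rule == "subsample":
            idx = rng.permutation(n)[: max(n_folds, int(n * subsample_fraction))]
            if e[idx].sum() < 2:
                continue
            model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                           fit_baseline_model=False, tol=selection_tol)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xc[idx], Surv.from_arrays(e[idx].astype(bool), t[idx]))
            sizes = (model.coef_ != 0.0).sum(axis=0)
            reach = np.where(sizes >= q)[0]
            j = int(reach[0]) if len(reach) else model.coef_.shape[1] - 1
            hits += (model.coef_[:, j] != 0.0)
        else:
            best = _cv_chosen_alpha(Xc, t, e, alphas, n_folds, rng, selection_tol)
            model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[best],
                                           fit_baseline_model=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xc, y_all)
            hits += (model.coef_[:, 0] != 0.0)
        n_done += 1
    if n_done == 0:
        raise ValidationError("no stability-selection iteration could be fitted")
    freqs = pd.Series(hits / n_done, index=mvalues_candidates.columns)
    kept = list(freqs.index[freqs >= freq_threshold])
    if not kept:
        raise ValidationError(
            f"no candidate reached selection frequency {freq_threshold}; "
            f"max observed {freqs.max():.3f} — consider lowering the threshold"
        )

    df = mvalues_candidates[kept].copy()
    df["_time"] = t
    df["_event"] = e
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = CoxPHFitter(penalizer=0.0).fit(df, duration_col="_time", event_col="_event")
    except (ConvergenceError, np.linalg.LinAlgError):
        logger.warning("unpenalized refit singular; using ridge penalizer %g", ridge_fallback)
        fit = CoxPHFitter(penalizer=ridge_fallback, l1_ratio=0.0).fit(
            df, duration_col="_time", event_col="_event")
    coefs = fit.summary["coef"]
    coefs = coefs[coefs != 0.0]
    entries = pd.Series(coefs.to_numpy(), index=coefs.index)
    scores = hazard_score_frame(entries, mvalues_candidates)
    cutoff = float(np.median(scores))
    return SignatureModel(entries=entries, cutoff=cutoff,
                          selection_frequencies=freqs)


def hazard_score_frame(entries: pd.Series, mvalues: pd.DataFrame) -> pd.Series:
    missing = [p for p in entries.index if p not in mvalues.columns]
    if missing:
        raise ValidationError(f"signature probe(s) absent from matrix: {missing[:5]}")
    sub = mvalues[list(entries.index)].to_numpy(dtype=float)
    return pd.Series(sub @ entries.to_numpy(), index=mvalues.index)


def hazard_score(signature: SignatureModel, mvalues: pd.DataFrame) -> pd.Series:
    """Linear hazard score: score_s = sum_i coef_i * M_{s,i}."""
    return hazard_score_frame(signature.entries, mvalues)


def dichotomize(scores, cutoff: float) -> pd.Series:
    """Score strictly above the cutoff -> "high"; at or below -> "low"."""
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    s = pd.Series(scores)
    return pd.Series(np.where(s > cutoff, "high", "low"), index=s.index)
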
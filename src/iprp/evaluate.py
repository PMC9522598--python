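"""Survival evaluation: Kaplan-Meier, log-rank, time-dependent ROC, concordance.

The time-dependent ROC at horizon t uses the cumulative-case / dynamic-
control definition: cases are samples with an observed event by t, controls
are samples still at risk past t, and both are weighted by inverse
probability of censoring from the Kaplan-Meier estimator of the censoring
distribution (cases at G(T-), controls at G(t)) — the Uno-type estimator.
Tied scores contribute 1/2. Significance of an observed AUC is assessed by
permuting scores across samples, with the add-one p-value estimator
(1 + #{AUC_perm >= AUC_obs}) / (n_perm + 1) so p is never exactly zero.

The cross-cohort score-distribution check is a one-way ANOVA of risk scores
on cohort label — a robustness diagnostic rather than a formal hypothesis
test: pair-encoded scores should be distributed near-identically across
cohorts regardless of batch effects, while unpaired expression-sum scores
shift location from cohort to cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class KMEstimate:
    times: np.ndarray  # step-change grid, starts at 0
    survival: np.ndarray  # product-limit S(t), starts at 1
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


@dataclass(frozen=True)
class TimeROC:
    horizon: float
    auc: float
    sensitivity: np.ndarray  # per threshold (descending score)
    specificity: np.ndarray
    n_cases: int
    n_controls: int
    permutation_p: float | None = None


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMEstimate:
    """Product-limit Kaplan-Meier estimate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise EvaluationError("empty survival data")
    if (times < 0).any():
        raise EvaluationError("negative survival times")
    kmf = KaplanMeierFitter().fit(times, events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    return KMEstimate(times=grid, survival=surv, at_risk=at_risk)


def logrank_test(groups: np.ndarray, times: np.ndarray, events: np.ndarray) -> tuple[float, float]:
    """Standard (unweighted) log-rank chi-square across >= 2 groups."""
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise EvaluationError("log-rank test needs at least 2 groups")
    if np.sum(events) < 1:
        raise EvaluationError("log-rank test needs at least one event")
    res = multivariate_logrank_test(np.asarray(times, float), groups, np.asarray(events, int))
    return float(res.test_statistic), float(res.p_value)


def _censoring_survival(times: np.ndarray, events: np.ndarray) -> KaplanMeierFitter:
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(times, 1 - np.asarray(events, int))
    return kmf


def _ipcw_case_control(times, events, horizon):
    """Masks and IPC weights for cumulative cases / dynamic controls at t."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    case = (times <= horizon) & (events == 1)
    control = times > horizon
    if case.sum() == 0:
        raise EvaluationError(f"no events observed by t={horizon}")
    if control.sum() == 0:
        raise EvaluationError(f"no samples at risk past t={horizon}")
    kmf_c = _censoring_survival(times, events)
    sf = kmf_c.survival_function_["KM_estimate"]
    grid = sf.index.to_numpy(dtype=float)
    vals = sf.to_numpy(dtype=float)

    def G(x: np.ndarray, left: bool) -> np.ndarray:
        side = "left" if left else "right"
        idx = np.searchsorted(grid, x, side=side) - 1
        idx = np.clip(idx, 0, len(vals) - 1)
        out = vals[idx]
        out[x < grid[0]] = 1.0
        return out

    w_case = np.zeros(len(times))
    w_ctrl = np.zeros(len(times))
    g_case = G(times[case], left=True)  # G(T-)
    g_t = G(np.array([horizon]), left=False)[0]  # G(t)
    if g_t <= 0 or (g_case <= 0).any():
        raise EvaluationError("censoring survival reaches zero before the horizon")
    w_case[case] = 1.0 / g_case
    w_ctrl[control] = 1.0 / g_t
    return case, control, w_case, w_ctrl


def _weighted_auc(scores, case, control, w_case, w_ctrl) -> float:
    """Weighted probability that a case outscores a control (ties count 1/2)."""
    s_case, wc = scores[case], w_case[case]
    s_ctrl, wk = scores[control], w_ctrl[control]
    order = np.argsort(s_ctrl, kind="mergesort")
    s_sorted, w_sorted = s_ctrl[order], wk[order]
    cum_w = np.concatenate(([0.0], np.cumsum(w_sorted)))
    lo = np.searchsorted(s_sorted, s_case, side="left")
    hi = np.searchsorted(s_sorted, s_case, side="right")
    below = cum_w[lo]
    tied = cum_w[hi] - cum_w[lo]
    num = float(np.sum(wc * (below + 0.5 * tied)))
    den = float(np.sum(wc) * np.sum(wk))
    return num / den


def time_dependent_auc(
    scores: np.ndarray, times: np.ndarray, events: np.ndarray, horizon: float
) -> TimeROC:
    """Cumulative/dynamic time-dependent ROC with IPC weighting at one horizon."""
    scores = np.asarray(scores, dtype=float)
    case, control, w_case, w_ctrl = _ipcw_case_control(times, events, horizon)
    auc = _weighted_auc(scores, case, control, w_case, w_ctrl)
    # ROC grid over descending unique score thresholds
    thresholds = np.unique(scores)[::-1]
    wc_tot = w_case[case].sum()
    wk_tot = w_ctrl[control].sum()
    sens = np.array([np.sum(w_case[case & (scores > c)]) / wc_tot for c in thresholds])
    spec = np.array([np.sum(w_ctrl[control & (scores <= c)]) / wk_tot for c in thresholds])
    return TimeROC(
        horizon=float(horizon),
        auc=float(auc),
        sensitivity=sens,
        specificity=spec,
        n_cases=int(case.sum()),
        n_controls=int(control.sum()),
    )


def permutation_test_auc(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    horizon: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the observed time-dependent AUC (add-one estimator)."""
    if n_perm < 1:
        raise EvaluationError("n_perm must be at least 1")
    if n_perm < 100:
        logger.warning("permutation test with n_perm=%d (< 100) is coarse", n_perm)
    scores = np.asarray(scores, dtype=float)
    case, control, w_case, w_ctrl = _ipcw_case_control(times, events, horizon)
    observed = _weighted_auc(scores, case, control, w_case, w_ctrl)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(scores)
        if _weighted_auc(perm, case, control, w_case, w_ctrl) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def concordance_index(scores: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Harrell's C for a risk score (higher score should mean shorter survival)."""
    try:
        return float(_lifelines_cindex(np.asarray(times, float), -np.asarray(scores, float),
                                       np.asarray(events, int)))
    except ZeroDivisionError as exc:
        raise EvaluationError("no comparable pairs for concordance") from exc


def cross_cohort_distribution_test(scores_by_cohort: dict[str, np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA of risk scores on cohort label (robustness diagnostic).

    Returns (F, p). Identical per-cohort distributions give F near 0; if the
    pooled data are exactly constant, (0.0, 1.0) is returned by convention.
    """
    if len(scores_by_cohort) < 2:
        raise EvaluationError("need at least 2 cohorts")
    arrays = [np.asarray(v, dtype=float) for v in scores_by_cohort.values()]
    for name, arr in zip(scores_by_cohort, arrays):
        if len(arr) < 2:
            raise EvaluationError(f"cohort {name!r} has fewer than 2 scores")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*arrays)
    if not np.isfinite(F):
        return 0.0, 1.0
    return max(float(F), 0.0), float(p)
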
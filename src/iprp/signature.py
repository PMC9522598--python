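"""Signature construction: the feature-selection cascade ending in a pair-Cox model.

The cascade mirrors the standard gene-pair signature workflow:

1. consensus-cluster the training cohort on two curated gene sets and label
   the clusters by survival;
2. form the double-favourable (FF) / double-unfavourable (UU) groups and
   screen differentially expressed genes between them (Wilcoxon + BH);
3. univariate Cox screen of the DEGs (keep BH-adjusted Wald p < 0.05);
4. L1-penalized Cox (LASSO) on the surviving genes, penalty chosen at the
   minimum cross-validated partial-likelihood deviance;
5. enumerate all pairs of the selected genes, apply the one-hot ordering
   encoding and the 0.2-0.8 prevalence filter;
6. a second LASSO on the pair indicators;
7. bidirectional (add/drop) AIC-stepwise multivariate Cox on the remaining
   pairs — the surviving terms with their fitted coefficients form the
   signature, and the risk cutoff is the median training RiskScore
   exp(sum of coef * indicator).

Each stage can only shrink the candidate set; a stage that empties it
raises :class:`PipelineStageError` naming the stage.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .cohort_io import Cohort
from .grouping import (
    assign_joint_groups,
    consensus_cluster,
    deg_screen,
    label_clusters_by_survival,
)
from .pairs import GenePair, encode_matrix, enumerate_pairs, prevalence_filter

logger = logging.getLogger(__name__)


class SignatureError(ValueError):
    pass


class PipelineStageError(SignatureError):
    """A cascade stage emptied the candidate set (or could not run)."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass(frozen=True)
class CoxEffect:
    feature: str
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    p_adj: float | None = None

    def __post_init__(self) -> None:
        if not math.isclose(self.hr, math.exp(self.coef), rel_tol=1e-9):
            raise SignatureError(f"HR must equal exp(coef) for {self.feature}")


@dataclass(frozen=True)
class SignatureModel:
    """Ordered gene-pair terms with Cox coefficients plus a risk cutoff."""

    name: str
    terms: tuple[tuple[GenePair, float], ...]
    cutoff: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.terms) == 0:
            raise SignatureError("a signature needs at least one pair term")
        for pair, coef in self.terms:
            if not math.isfinite(coef):
                raise SignatureError(f"non-finite coefficient for {pair.label}")
        if not (self.cutoff > 0):
            raise SignatureError("risk cutoff must be positive")

    @property
    def pairs(self) -> list[GenePair]:
        return [p for p, _ in self.terms]

    @property
    def genes(self) -> list[str]:
        seen: list[str] = []
        for p, _ in self.terms:
            for g in (p.gene_a, p.gene_b):
                if g not in seen:
                    seen.append(g)
        return seen

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cutoff": self.cutoff,
            "terms": [{"pair": p.label, "coef": c} for p, c in self.terms],
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        terms = tuple((GenePair.parse(t["pair"]), float(t["coef"])) for t in d["terms"])
        return cls(d["name"], terms, float(d["cutoff"]), d.get("provenance", {}))

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SignatureConfig:
    """Tunable cascade parameters (defaults are the conventional choices)."""

    k_range: tuple[int, ...] = (2, 3, 4, 5)
    n_resamples: int = 100
    subsample_frac: float = 0.8
    delta_area_threshold: float = 0.1
    fc_threshold: float = 1.0
    fdr_threshold: float = 0.001
    univariate_alpha: float = 0.05
    lasso_folds: int = 10
    prevalence_low: float = 0.2
    prevalence_high: float = 0.8
    stepwise_direction: str = "both"
    seed: int = 0
    name: str = "pair-signature"


# --- Cox helpers ----------------------------------------------------------


def _safe_cox_fit(
    features: pd.DataFrame, times: np.ndarray, events: np.ndarray
) -> CoxPHFitter | None:
    """Fit a Cox PH model, falling back to a tiny ridge penalty; None on failure."""
    data = features.copy()
    data["_T"] = times
    data["_E"] = events
    for penalizer in (0.0, 1e-4):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter(penalizer=penalizer)
                cph.fit(data, duration_col="_T", event_col="_E")
            return cph
        except Exception:
            continue
    return None


def cox_partial_loglik(lp: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Breslow partial log-likelihood of fixed linear predictors."""
    lp = np.asarray(lp, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    order = np.argsort(-times, kind="stable")
    t, e, l = times[order], events[order], lp[order]
    clse = np.logaddexp.accumulate(l)
    n = len(t)
    is_new = np.r_[True, t[1:] != t[:-1]]
    block_id = np.cumsum(is_new) - 1
    block_last = np.zeros(block_id[-1] + 1, dtype=int)
    block_last[block_id] = np.arange(n)  # later writes win -> last index per tie block
    denom = clse[block_last[block_id]]
    mask = e == 1
    return float(np.sum(l[mask] - denom[mask]))


def univariate_cox_screen(
    features: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    alpha: float = 0.05,
) -> list[CoxEffect]:
    """Per-feature univariate Cox fits; keep BH-adjusted Wald p < alpha.

    Constant features are skipped (logged). Returns the selected effects
    sorted by adjusted p.
    """
    if len(features) < 10:
        raise SignatureError("univariate screen needs at least 10 samples")
    if np.sum(events) < 1:
        raise SignatureError("univariate screen needs at least one event")
    effects: list[dict] = []
    skipped = 0
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            skipped += 1
            continue
        cph = _safe_cox_fit(features[[col]], times, events)
        if cph is None:
            skipped += 1
            continue
        row = cph.summary.loc[col]
        effects.append(
            {
                "feature": col,
                "coef": float(row["coef"]),
                "ci_low": float(row["exp(coef) lower 95%"]),
                "ci_high": float(row["exp(coef) upper 95%"]),
                "p": float(row["p"]),
            }
        )
    if skipped:
        logger.info("univariate screen: skipped %d constant/ill-conditioned features", skipped)
    if not effects:
        return []
    pvals = np.array([e["p"] for e in effects])
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    selected = []
    for e, pa in zip(effects, padj):
        if pa < alpha:
            selected.append(
                CoxEffect(
                    feature=e["feature"],
                    coef=e["coef"],
                    hr=math.exp(e["coef"]),
                    ci_low=e["ci_low"],
                    ci_high=e["ci_high"],
                    p=e["p"],
                    p_adj=float(pa),
                )
            )
    selected.sort(key=lambda c: c.p_adj)
    return selected


def lasso_cox_select(
    features: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    alphas: list[float] | None = None,
) -> list[str]:
    """L1-penalized Cox feature selection at the minimum-CV-deviance penalty.

    The penalty path comes from the coordinate-descent path on the full
    data (or ``alphas`` if given); per-fold held-out deviance is minus
    twice the Breslow partial log-likelihood of the held-out samples at
    the training-fold coefficients. Returns features with nonzero
    coefficients at the selected penalty, in column order.
    """
    if features.shape[1] < 2 and alphas is None:
        if features.shape[1] == 1:
            # single feature: keep it if the unpenalized fit supports it
            return list(features.columns)
        raise SignatureError("lasso needs at least one feature")
    if np.sum(events) == 0:
        raise SignatureError("degenerate survival: all samples censored")
    keep_cols = [c for c in features.columns if np.ptp(features[c].to_numpy(dtype=float)) > 0]
    X = features[keep_cols].to_numpy(dtype=float)
    y = Surv.from_arrays(event=np.asarray(events, bool), time=np.asarray(times, float))

    def fit_path(Xf, yf, path):
        est = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            alphas=path,
            alpha_min_ratio=0.01,
            n_alphas=50,
            max_iter=200000,
            fit_baseline_model=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xf, yf)
        return est

    full = fit_path(X, y, alphas)
    path = list(full.alphas_)
    if len(path) == 1:
        coefs = full.coef_[:, 0]
        support = [c for c, b in zip(keep_cols, coefs) if b != 0]
        return support

    n = len(times)
    folds = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    deviance = np.zeros(len(path))
    for train_idx, test_idx in folds.split(X):
        if np.sum(np.asarray(events)[train_idx]) == 0:
            continue
        try:
            fold_est = fit_path(X[train_idx], y[train_idx], path)
        except Exception:
            continue
        coef_by_alpha = {a: fold_est.coef_[:, i] for i, a in enumerate(fold_est.alphas_)}
        for i, a in enumerate(path):
            beta = coef_by_alpha.get(a)
            if beta is None:
                continue
            lp_test = X[test_idx] @ beta
            if np.sum(np.asarray(events)[test_idx]) == 0:
                continue
            deviance[i] += -2.0 * cox_partial_loglik(
                lp_test, np.asarray(times)[test_idx], np.asarray(events)[test_idx]
            )
    best_idx = int(np.argmin(deviance))
    beta = full.coef_[:, best_idx]
    support = [c for c, b in zip(keep_cols, beta) if b != 0]
    logger.info(
        "lasso: selected penalty %.5g (%d of %d features nonzero)",
        path[best_idx], len(support), len(keep_cols),
    )
    return support


def _drop_collinear(features: pd.DataFrame) -> pd.DataFrame:
    """Drop constant columns and later members of (near-)perfectly correlated pairs."""
    cols = [c for c in features.columns if np.ptp(features[c].to_numpy(dtype=float)) > 0]
    kept: list[str] = []
    for c in cols:
        x = features[c].to_numpy(dtype=float)
        redundant = False
        for k in kept:
            r = np.corrcoef(x, features[k].to_numpy(dtype=float))[0, 1]
            if abs(r) > 1 - 1e-10:
                redundant = True
                break
        if not redundant:
            kept.append(c)
    if len(kept) < len(features.columns):
        logger.info("dropped %d constant/collinear features", len(features.columns) - len(kept))
    return features[kept]


def stepwise_cox(
    features: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    direction: str = "both",
    max_steps: int = 100,
) -> tuple[list[tuple[str, float]], CoxPHFitter]:
    """AIC-guided stepwise multivariate Cox starting from the full candidate set.

    ``direction='both'`` considers both dropping a current feature and
    re-adding a previously dropped one at every step; ``'backward'``
    considers drops only. Returns the final (feature, coefficient) list
    and the fitted model.
    """
    if direction not in ("both", "backward"):
        raise SignatureError(f"unknown stepwise direction {direction!r}")
    if features.shape[1] < 1:
        raise SignatureError("stepwise needs at least one candidate feature")
    features = _drop_collinear(features)
    pool = list(features.columns)
    current = list(pool)

    fit = _safe_cox_fit(features[current], times, events)
    while fit is None and len(current) > 1:
        # drop the first feature whose removal lets the fit converge
        for f in list(current):
            trial = [c for c in current if c != f]
            fit = _safe_cox_fit(features[trial], times, events)
            if fit is not None:
                logger.info("stepwise: dropped non-converging feature %s", f)
                current = trial
                break
        else:
            raise SignatureError("multivariate Cox fit failed for every feature subset")
    if fit is None:
        raise SignatureError("multivariate Cox fit failed")
    best_aic = fit.AIC_partial_

    for _ in range(max_steps):
        moves: list[tuple[str, str]] = [("drop", f) for f in current if len(current) > 1]
        if direction == "both":
            moves += [("add", f) for f in pool if f not in current]
        best_move = None
        best_move_aic = best_aic
        best_move_fit = None
        for kind, f in moves:
            trial = [c for c in current if c != f] if kind == "drop" else current + [f]
            trial_fit = _safe_cox_fit(features[trial], times, events)
            if trial_fit is None:
                continue
            if trial_fit.AIC_partial_ < best_move_aic - 1e-8:
                best_move = (kind, f, trial)
                best_move_aic = trial_fit.AIC_partial_
                best_move_fit = trial_fit
        if best_move is None:
            break
        _, _, current = best_move
        best_aic = best_move_aic
        fit = best_move_fit

    terms = [(f, float(fit.params_[f])) for f in current]
    return terms, fit


# --- the full cascade -----------------------------------------------------


def build_signature(
    training: Cohort,
    gene_sets: dict[str, list[str]],
    config: SignatureConfig = SignatureConfig(),
) -> SignatureModel:
    """Run the full cascade on a training cohort and return the fitted signature.

    ``gene_sets`` maps two set names (e.g. pyroptosis-like / immune-like) to
    gene-id lists used for the consensus-clustering stage. Deterministic
    given (data, config.seed).
    """
    if len(gene_sets) != 2:
        raise SignatureError("build_signature expects exactly two gene sets for clustering")
    expr = training.expression
    times = training.clinical.os_time
    events = training.clinical.os_event
    if events.sum() == 0:
        raise PipelineStageError("clustering", "training cohort has no events")
    provenance: dict = {"n_samples": training.n_samples, "n_events": int(events.sum())}

    # stage 1: consensus clustering on each gene set + survival labelling
    joint_inputs = []
    for i, (set_name, genes) in enumerate(gene_sets.items()):
        res = consensus_cluster(
            expr.subset_genes(genes),
            k_range=config.k_range,
            n_resamples=config.n_resamples,
            subsample_frac=config.subsample_frac,
            seed=config.seed + 17 * (i + 1),
            delta_area_threshold=config.delta_area_threshold,
        )
        surv = label_clusters_by_survival(res.labels, training.clinical)
        joint_inputs.append((res.labels, surv.favorability))
        provenance[f"clusters_{set_name}"] = res.chosen_k
    joint = assign_joint_groups(
        joint_inputs[0][0], joint_inputs[1][0], joint_inputs[0][1], joint_inputs[1][1]
    )
    counts = joint.counts
    provenance["n_FF"] = int(counts.get("FF", 0))
    provenance["n_UU"] = int(counts.get("UU", 0))
    if counts.get("FF", 0) < 3 or counts.get("UU", 0) < 3:
        raise PipelineStageError("joint_grouping", f"FF/UU groups too small: {counts}")

    # stage 2: DEG screen FF vs UU
    degs = deg_screen(
        expr, joint.labels, ("FF", "UU"), config.fc_threshold, config.fdr_threshold
    )
    provenance["n_degs"] = len(degs)
    if not degs:
        raise PipelineStageError("deg_screen", "no differentially expressed genes")
    deg_genes = [d.gene_id for d in degs]

    # stage 3: univariate Cox screen on DEG expression
    feats = expr.data.loc[deg_genes].T
    uni = univariate_cox_screen(feats, times, events, alpha=config.univariate_alpha)
    provenance["n_univariate"] = len(uni)
    if not uni:
        raise PipelineStageError("univariate_screen", "no genes pass the univariate screen")
    uni_genes = [e.feature for e in uni]

    # stage 4: gene-level LASSO
    gene_support = lasso_cox_select(
        expr.data.loc[uni_genes].T, times, events, n_folds=config.lasso_folds, seed=config.seed
    )
    provenance["n_lasso_genes"] = len(gene_support)
    if len(gene_support) < 2:
        raise PipelineStageError("gene_lasso", f"fewer than 2 genes selected ({len(gene_support)})")

    # stage 5: pairing, encoding, prevalence filter
    pairs = enumerate_pairs(gene_support)
    provenance["n_pairs_enumerated"] = len(pairs)
    pim = encode_matrix(expr, pairs)
    pim = prevalence_filter(pim, config.prevalence_low, config.prevalence_high)
    provenance["n_pairs_prevalence"] = len(pim.pairs)
    if len(pim.pairs) == 0:
        raise PipelineStageError("prevalence_filter", "no pairs with informative prevalence")

    # stage 6: pair-level LASSO
    pair_df = pim.to_frame().T.astype(float)
    pair_support = lasso_cox_select(
        pair_df, times, events, n_folds=config.lasso_folds, seed=config.seed + 1
    )
    provenance["n_lasso_pairs"] = len(pair_support)
    if not pair_support:
        raise PipelineStageError("pair_lasso", "no pairs selected by LASSO")

    # stage 7: bidirectional stepwise multivariate Cox
    terms_raw, _ = stepwise_cox(
        pair_df[pair_support], times, events, direction=config.stepwise_direction
    )
    provenance["n_final_pairs"] = len(terms_raw)
    if not terms_raw:
        raise PipelineStageError("stepwise_cox", "stepwise eliminated every pair")
    terms = tuple((GenePair.parse(f), c) for f, c in terms_raw)

    # stage 8: training-median cutoff
    lp = np.zeros(training.n_samples)
    for (pair, coef), label in zip(terms, [f for f, _ in terms_raw]):
        lp += coef * pair_df[label].to_numpy(dtype=float)
    risk = np.exp(lp)
    cutoff = float(np.median(risk))
    provenance["stage_trail"] = [
        provenance["n_degs"], provenance["n_univariate"], provenance["n_lasso_genes"],
        provenance["n_pairs_enumerated"], provenance["n_pairs_prevalence"],
        provenance["n_lasso_pairs"], provenance["n_final_pairs"],
    ]
    logger.info("signature cascade trail: %s", provenance["stage_trail"])
    return SignatureModel(name=config.name, terms=terms, cutoff=cutoff, provenance=provenance)
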
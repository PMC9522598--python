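"""Independent prognostic analysis and the points-based survival nomogram.

A nomogram is an exact re-parameterization of a multivariate Cox model:
each factor's contribution beta_i * x_i, over its observed training range,
is mapped linearly onto a 0-100 point scale such that the factor with the
largest contribution range spans exactly 0-100. Total points map back to
the linear predictor, and survival at a fixed horizon t follows from the
baseline survival: S(t | x) = S_ref(t) ^ exp(lp_x - lp_ref). Points are
kept continuous (not rounded), so nomogram predictions agree with the
underlying Cox model's own predictions to floating-point accuracy.

Categorical factors (e.g. ethnicity, ELN2017 class) get one point value
per level; continuous factors (age, risk score) are mapped over their
observed training range, with out-of-range inputs clamped (warned).
Missing clinical values are handled by complete-case analysis, with the
number of dropped samples logged.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .signature import CoxEffect, SignatureError, _safe_cox_fit

logger = logging.getLogger(__name__)


class NomogramError(ValueError):
    pass


def _build_design(df: pd.DataFrame, covariates: list[str]) -> tuple[pd.DataFrame, dict]:
    """Design matrix with reference-level dummies for categorical covariates.

    Returns (design, factor_info) where factor_info maps each covariate to
    {"kind": "continuous"} or {"kind": "categorical", "levels": [...],
    "columns": {level: column}} (reference level has no column).
    """
    design = pd.DataFrame(index=df.index)
    info: dict[str, dict] = {}
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique().tolist())
            if len(levels) < 2:
                logger.warning("covariate %s is constant; dropped", cov)
                continue
            columns = {}
            for level in levels[1:]:
                name = f"{cov}[{level}]"
                design[name] = (col == level).astype(float)
                columns[level] = name
            info[cov] = {"kind": "categorical", "levels": levels, "columns": columns}
        else:
            x = col.to_numpy(dtype=float)
            if np.ptp(x[~np.isnan(x)]) == 0:
                logger.warning("covariate %s is constant; dropped", cov)
                continue
            design[cov] = col.astype(float)
            info[cov] = {"kind": "continuous"}
    return design, info


def prognostic_analysis(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "os_time",
    event_col: str = "os_event",
    mode: str = "multivariate",
) -> list[CoxEffect]:
    """Univariate (one Cox per covariate) or joint multivariate prognostic analysis.

    Complete-case: rows with missing values in the used covariates are
    dropped (counts logged). Categorical covariates are expanded to
    reference-coded dummies and reported per level.
    """
    if mode not in ("univariate", "multivariate"):
        raise NomogramError(f"unknown mode {mode!r}")

    def effects_for(cov_list: list[str]) -> list[CoxEffect]:
        sub = df[cov_list + [duration_col, event_col]].dropna()
        n_dropped = len(df) - len(sub)
        if n_dropped:
            logger.info("complete-case analysis dropped %d of %d samples", n_dropped, len(df))
        if mode == "multivariate" and (len(sub) < 20 or sub[event_col].sum() < 1):
            raise NomogramError("multivariate analysis needs >= 20 complete-case samples with events")
        design, _ = _build_design(sub, cov_list)
        if design.shape[1] == 0:
            raise NomogramError("no usable covariates after dropping constants")
        fit = _safe_cox_fit(design, sub[duration_col].to_numpy(), sub[event_col].to_numpy())
        if fit is None:
            raise NomogramError(f"Cox fit failed for covariates {cov_list}")
        out = []
        for name, row in fit.summary.iterrows():
            out.append(
                CoxEffect(
                    feature=name,
                    coef=float(row["coef"]),
                    hr=float(np.exp(row["coef"])),
                    ci_low=float(row["exp(coef) lower 95%"]),
                    ci_high=float(row["exp(coef) upper 95%"]),
                    p=float(row["p"]),
                )
            )
        return out

    if mode == "multivariate":
        return effects_for(list(covariates))
    results: list[CoxEffect] = []
    for cov in covariates:
        results.extend(effects_for([cov]))
    return results


@dataclass(frozen=True)
class NomogramFactor:
    name: str
    kind: str  # "continuous" | "categorical"
    # continuous: beta plus observed range; categorical: per-level coefficient
    beta: float = 0.0
    obs_min: float = 0.0
    obs_max: float = 0.0
    level_coefs: dict = field(default_factory=dict)

    def contribution(self, value) -> float:
        if self.kind == "continuous":
            x = float(value)
            if x < self.obs_min or x > self.obs_max:
                logger.warning(
                    "factor %s: value %g outside training range [%g, %g]; clamped",
                    self.name, x, self.obs_min, self.obs_max,
                )
                x = min(max(x, self.obs_min), self.obs_max)
            return self.beta * x
        if value not in self.level_coefs:
            raise NomogramError(
                f"factor {self.name}: unknown level {value!r} (known: {sorted(self.level_coefs)})"
            )
        return float(self.level_coefs[value])

    @property
    def contribution_range(self) -> tuple[float, float]:
        if self.kind == "continuous":
            lo, hi = self.beta * self.obs_min, self.beta * self.obs_max
        else:
            vals = list(self.level_coefs.values())
            lo, hi = min(vals), max(vals)
        return (min(lo, hi), max(lo, hi))


@dataclass(frozen=True)
class NomogramModel:
    """Point maps per factor plus total-points -> survival curves at fixed horizons."""

    factors: tuple[NomogramFactor, ...]
    horizons: tuple[float, ...]
    baseline_survival: tuple[float, ...]  # S_ref(t) at each horizon, at lp_ref
    lp_ref: float  # linear predictor of the all-minimum-contribution reference
    points_per_lp: float  # points = (contribution - min) * points_per_lp

    def factor_points(self, factor: NomogramFactor, value) -> float:
        lo, _ = factor.contribution_range
        return (factor.contribution(value) - lo) * self.points_per_lp

    def max_points(self, factor: NomogramFactor) -> float:
        lo, hi = factor.contribution_range
        return (hi - lo) * self.points_per_lp

    def survival_from_points(self, total_points: float) -> np.ndarray:
        lp = self.lp_ref + total_points / self.points_per_lp
        base = np.asarray(self.baseline_survival, dtype=float)
        return base ** np.exp(lp - self.lp_ref)

    def to_dict(self) -> dict:
        return {
            "horizons": list(self.horizons),
            "baseline_survival": list(self.baseline_survival),
            "lp_ref": self.lp_ref,
            "points_per_lp": self.points_per_lp,
            "factors": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "beta": f.beta,
                    "obs_min": f.obs_min,
                    "obs_max": f.obs_max,
                    "level_coefs": f.level_coefs,
                }
                for f in self.factors
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "NomogramModel":
        factors = tuple(
            NomogramFactor(
                name=f["name"], kind=f["kind"], beta=f["beta"],
                obs_min=f["obs_min"], obs_max=f["obs_max"], level_coefs=f["level_coefs"],
            )
            for f in d["factors"]
        )
        return cls(
            factors=factors,
            horizons=tuple(d["horizons"]),
            baseline_survival=tuple(d["baseline_survival"]),
            lp_ref=float(d["lp_ref"]),
            points_per_lp=float(d["points_per_lp"]),
        )


@dataclass(frozen=True)
class FittedPrognosticCox:
    """A fitted multivariate Cox model plus the design information needed downstream."""

    model: CoxPHFitter
    design: pd.DataFrame
    factor_info: dict
    duration_col: str
    event_col: str
    data: pd.DataFrame  # complete-case rows used for the fit


def fit_prognostic_cox(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "os_time",
    event_col: str = "os_event",
) -> FittedPrognosticCox:
    """Fit the multivariate Cox model underlying a nomogram (complete cases)."""
    sub = df[covariates + [duration_col, event_col]].dropna()
    n_dropped = len(df) - len(sub)
    if n_dropped:
        logger.info("nomogram fit: complete-case analysis dropped %d samples", n_dropped)
    design, info = _build_design(sub, covariates)
    if design.shape[1] == 0:
        raise NomogramError("no usable covariates for the nomogram")
    fit = _safe_cox_fit(design, sub[duration_col].to_numpy(), sub[event_col].to_numpy())
    if fit is None:
        raise NomogramError("multivariate Cox fit failed")
    return FittedPrognosticCox(fit, design, info, duration_col, event_col, sub)


def build_nomogram(
    fitted: FittedPrognosticCox, horizons: tuple[float, ...] = (365.0, 730.0, 1095.0)
) -> NomogramModel:
    """Map a fitted Cox model onto the 0-100 point scale at the given horizons.

    The factor with the largest contribution range spans exactly 0-100
    points; zero-range factors contribute 0 points (flagged). Baseline
    survival at the horizons comes from the model's own survival-function
    prediction (Breslow baseline) for an explicit reference patient, so the
    nomogram reproduces the Cox model's predictions exactly.
    """
    params = fitted.model.params_
    factors: list[NomogramFactor] = []
    for cov, info in fitted.factor_info.items():
        if info["kind"] == "continuous":
            x = fitted.design[cov].to_numpy(dtype=float)
            factors.append(
                NomogramFactor(
                    name=cov, kind="continuous", beta=float(params[cov]),
                    obs_min=float(np.min(x)), obs_max=float(np.max(x)),
                )
            )
        else:
            level_coefs = {info["levels"][0]: 0.0}
            for level, colname in info["columns"].items():
                level_coefs[level] = float(params[colname])
            factors.append(NomogramFactor(name=cov, kind="categorical", level_coefs=level_coefs))

    ranges = {f.name: f.contribution_range[1] - f.contribution_range[0] for f in factors}
    max_range = max(ranges.values())
    if max_range <= 0:
        raise NomogramError("every factor has zero contribution range")
    for name, r in ranges.items():
        if r == 0:
            logger.warning("nomogram factor %s has zero contribution range (0 points)", name)
    points_per_lp = 100.0 / max_range

    # reference patient: minimum contribution for every factor
    ref_row = {}
    for f in factors:
        if f.kind == "continuous":
            ref_row[f.name] = f.obs_min if f.beta >= 0 else f.obs_max
        else:
            ref_level = min(f.level_coefs, key=f.level_coefs.get)
            for level, colname in fitted.factor_info[f.name]["columns"].items():
                ref_row[colname] = 1.0 if level == ref_level else 0.0
    ref_design = pd.DataFrame([ref_row], columns=fitted.design.columns).fillna(0.0)
    lp_ref = float(sum(f.contribution_range[0] for f in factors))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sf = fitted.model.predict_survival_function(ref_design, times=list(horizons))
    baseline = tuple(float(v) for v in sf.iloc[:, 0].to_numpy())
    return NomogramModel(
        factors=tuple(factors),
        horizons=tuple(float(h) for h in horizons),
        baseline_survival=baseline,
        lp_ref=lp_ref,
        points_per_lp=points_per_lp,
    )


def predict_outcome(nomogram: NomogramModel, record: dict) -> dict:
    """Per-horizon mortality probabilities plus total points for one patient.

    ``record`` maps factor name -> value; a missing factor raises an error
    naming it. Mortality = 1 - survival; higher points always mean higher
    mortality at every horizon.
    """
    total = 0.0
    per_factor = {}
    for f in nomogram.factors:
        if f.name not in record:
            raise NomogramError(f"missing factor {f.name!r} in patient record")
        pts = nomogram.factor_points(f, record[f.name])
        per_factor[f.name] = pts
        total += pts
    surv = nomogram.survival_from_points(total)
    return {
        "total_points": total,
        "factor_points": per_factor,
        "mortality": {h: float(1.0 - s) for h, s in zip(nomogram.horizons, surv)},
        "survival": {h: float(s) for h, s in zip(nomogram.horizons, surv)},
    }
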
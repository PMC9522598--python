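"""IPRP risk scoring: the frozen published model and generic signature scoring.

The published IPRP (immunity and pyroptosis related prognostic) signature
is a fixed linear model over 10 gene-pair ordering indicators spanning 15
genes. Per sample,

    Sum       = sum_i coef_i * [expr(A_i) > expr(B_i)]
    RiskScore = exp(Sum)

and a sample is called high risk iff RiskScore strictly exceeds the cutoff
(0.684 for the published model — the median training risk score). Ties at
the cutoff are assigned to the low-risk group, keeping the high-risk call
conservative. Because the indicators depend only on within-sample gene
orderings, the score is invariant to any strictly increasing per-sample
transform of the expression data; no normalisation is required and gene
symbols are matched case-sensitively (alias resolution is the caller's
responsibility).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix
from .pairs import GenePair, encode_matrix
from .signature import SignatureModel

_PUBLISHED_TERMS: tuple[tuple[str, float], ...] = (
    ("COL9A2|NPDC1", -0.384),
    ("PLXNC1|SLC24A3", 0.438),
    ("FZD6|MYO1B", 0.441),
    ("TCF4|TAF1C", 0.362),
    ("TAF1C|ACSL3", -0.569),
    ("ACSL3|CRTAP", 0.433),
    ("ACSL3|IGLL1", 0.378),
    ("ACSL3|DNMT3B", -0.788),
    ("CYP2E1|MYO1B", -0.277),
    ("SLC36A1|FSTL1", -0.465),
)

PUBLISHED_CUTOFF = 0.684


class ScoringError(ValueError):
    pass


def published_iprp_model() -> SignatureModel:
    """The published 10-pair / 15-gene IPRP signature with cutoff 0.684.

    Pair orientations are exactly as printed in the risk-score formula
    (orientation matters: e.g. TAF1C|ACSL3 and the ACSL3|* pairs coexist).
    """
    terms = tuple((GenePair.parse(label), coef) for label, coef in _PUBLISHED_TERMS)
    return SignatureModel(
        name="IPRP",
        terms=terms,
        cutoff=PUBLISHED_CUTOFF,
        provenance={"source": "published model, frozen"},
    )


@dataclass(frozen=True)
class RiskResult:
    """Per-sample Sum, RiskScore = exp(Sum), and high/low risk group."""

    table: pd.DataFrame  # index sample_id; columns: sum, risk_score, risk_group
    cutoff: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def sums(self) -> np.ndarray:
        return self.table["sum"].to_numpy(dtype=float)

    @property
    def risk_scores(self) -> np.ndarray:
        return self.table["risk_score"].to_numpy(dtype=float)

    @property
    def risk_groups(self) -> np.ndarray:
        return self.table["risk_group"].to_numpy()


def score_cohort(expr: ExpressionMatrix, model: SignatureModel | None = None) -> RiskResult:
    """Score every sample of an expression matrix with a pair signature.

    Defaults to the published IPRP model. All signature genes must be
    present; otherwise an error lists every absent gene.
    """
    if model is None:
        model = published_iprp_model()
    missing = sorted(set(model.genes) - set(expr.gene_ids))
    if missing:
        raise ScoringError(
            f"expression matrix is missing {len(missing)} signature gene(s): {missing}"
        )
    pim = encode_matrix(expr, model.pairs)
    coefs = np.array([c for _, c in model.terms], dtype=float)
    sums = coefs @ pim.values.astype(float)
    scores = np.exp(sums)
    groups = stratify_scores(scores, model.cutoff)
    table = pd.DataFrame(
        {"sum": sums, "risk_score": scores, "risk_group": groups},
        index=pd.Index(expr.sample_ids, name="sample_id"),
    )
    return RiskResult(table=table, cutoff=model.cutoff)


def stratify_scores(scores: np.ndarray, cutoff: float) -> np.ndarray:
    """'high' iff score > cutoff, else 'low' (ties are low)."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ScoringError("risk scores must be finite")
    if not (cutoff > 0):
        raise ScoringError("cutoff must be positive")
    return np.where(scores > cutoff, "high", "low")


def stratify(risk: RiskResult, cutoff: float | None = None) -> pd.Series:
    """Re-stratify a RiskResult, optionally at an overridden cutoff (e.g. in-cohort median)."""
    c = risk.cutoff if cutoff is None else float(cutoff)
    return pd.Series(stratify_scores(risk.risk_scores, c), index=risk.sample_ids)
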
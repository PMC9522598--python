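"""One-hot gene-pair (relative expression ordering) encoding.

The binary feature "A|B" equals 1 within a sample iff expression(A) >
expression(B), and 0 otherwise (ties included, per the "<=" branch of the
encoding rule — no epsilon tolerance; floating-point equality is taken
literally). Because the indicator depends only on the within-sample
ordering of two genes, it is invariant to any strictly increasing
per-sample transform of expression, which is what makes pair signatures
robust to batch and platform effects.

Pairs whose "1" frequency in a training set falls outside [0.2, 0.8]
carry little classification information and are removed by
:func:`prevalence_filter` (inclusive bounds: the rule deletes frequencies
strictly below 0.2 or strictly above 0.8).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix

logger = logging.getLogger(__name__)


class PairEncodingError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GenePair:
    """Ordered gene pair; the feature is 1 iff expr(gene_a) > expr(gene_b)."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise PairEncodingError(f"gene pair must involve two distinct genes, got {self.gene_a!r} twice")

    @property
    def label(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"

    @classmethod
    def parse(cls, label: str) -> "GenePair":
        parts = label.split("|")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise PairEncodingError(f"cannot parse gene pair label {label!r} (expected 'GENEA|GENEB')")
        return cls(parts[0], parts[1])

    def reversed(self) -> "GenePair":
        return GenePair(self.gene_b, self.gene_a)


@dataclass(frozen=True)
class PairIndicatorMatrix:
    """Binary pairs x samples matrix of ordering indicators."""

    pairs: tuple[GenePair, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # uint8, shape (n_pairs, n_samples)

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise PairEncodingError("duplicate gene pairs in indicator matrix")
        if self.values.shape != (len(self.pairs), len(self.sample_ids)):
            raise PairEncodingError("indicator matrix shape inconsistent with pair/sample lists")
        if not np.isin(self.values, (0, 1)).all():
            raise PairEncodingError("indicator values must be 0 or 1")

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=list(self.sample_ids))

    def prevalence(self) -> np.ndarray:
        """Per-pair frequency of the '1' label across samples."""
        return self.values.mean(axis=1)


def enumerate_pairs(gene_ids: list[str]) -> list[GenePair]:
    """All unordered pairs of genes, each emitted once, oriented lexicographically.

    Canonical orientation (gene_a < gene_b) is a labelling convention only:
    downstream Cox coefficient signs absorb the orientation. n genes yield
    n(n-1)/2 pairs.
    """
    if len(set(gene_ids)) != len(gene_ids):
        raise PairEncodingError("duplicate gene ids passed to enumerate_pairs")
    if len(gene_ids) < 2:
        raise PairEncodingError("need at least 2 genes to form pairs")
    return [GenePair(a, b) for a, b in itertools.combinations(sorted(gene_ids), 2)]


def encode_indicator(expr_a: float, expr_b: float) -> int:
    """1 iff expr_a > expr_b, else 0 (ties map to 0)."""
    if not (math.isfinite(expr_a) and math.isfinite(expr_b)):
        raise PairEncodingError("expression values must be finite")
    return int(expr_a > expr_b)


def encode_matrix(expr: ExpressionMatrix, pairs: list[GenePair]) -> PairIndicatorMatrix:
    """Apply the ordering indicator per sample for every requested pair."""
    if not pairs:
        raise PairEncodingError("no gene pairs to encode")
    needed = {g for p in pairs for g in (p.gene_a, p.gene_b)}
    missing = sorted(needed - set(expr.gene_ids))
    if missing:
        raise PairEncodingError(f"genes absent from expression matrix: {missing}")
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    ia = np.array([pos[p.gene_a] for p in pairs])
    ib = np.array([pos[p.gene_b] for p in pairs])
    vals = expr.values
    indicators = (vals[ia, :] > vals[ib, :]).astype(np.uint8)
    return PairIndicatorMatrix(tuple(pairs), tuple(expr.sample_ids), indicators)


def prevalence_filter(
    pim: PairIndicatorMatrix, low: float = 0.2, high: float = 0.8
) -> PairIndicatorMatrix:
    """Keep pairs whose '1' frequency f satisfies low <= f <= high."""
    if not (0.0 <= low < high <= 1.0):
        raise PairEncodingError(f"invalid prevalence bounds [{low}, {high}]")
    freq = pim.prevalence()
    keep = (freq >= low) & (freq <= high)
    n_kept = int(keep.sum())
    logger.info(
        "prevalence filter [%g, %g]: kept %d of %d pairs", low, high, n_kept, len(pim.pairs)
    )
    if n_kept == 0:
        return PairIndicatorMatrix((), pim.sample_ids, np.zeros((0, len(pim.sample_ids)), dtype=np.uint8))
    kept_pairs = tuple(p for p, k in zip(pim.pairs, keep) if k)
    return PairIndicatorMatrix(kept_pairs, pim.sample_ids, pim.values[keep])
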
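"""Expression matrices, clinical tables, and cohort assembly.

A *cohort* pairs a genes-by-samples expression matrix with per-sample
overall-survival records (time, event) and optional clinical covariates
(age, prior non-myeloid malignancy, ethnicity, ELN2017 class). Expression
is accepted on any monotone scale — by convention log2, but no transform
is ever applied internally, because the downstream gene-pair encoding is
invariant to any strictly increasing within-sample transform.

All files are UTF-8 tab-separated text: expression with genes as rows and
a header row of sample ids; clinical with one row per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_CLINICAL_COLUMNS = ("os_time", "os_event")
OPTIONAL_CLINICAL_COLUMNS = ("age", "prior_malignancy", "ethnicity", "eln2017", "cohort")


class CohortError(ValueError):
    """Raised for malformed expression matrices, clinical tables or cohorts."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued genes x samples matrix with unique row/column identifiers."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise CohortError("expression matrix is empty")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise CohortError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CohortError("expression matrix contains non-numeric values")
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortError(
                f"non-finite expression value at gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise CohortError(f"genes absent from expression matrix: {missing}")
        return ExpressionMatrix(self.data.loc[gene_ids])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise CohortError(f"samples absent from expression matrix: {missing}")
        return ExpressionMatrix(self.data[sample_ids])


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample survival record plus optional covariates, indexed by sample id."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0:
            raise CohortError("clinical table is empty")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate sample ids in clinical table: {dups[:5]}")
        for col in REQUIRED_CLINICAL_COLUMNS:
            if col not in df.columns:
                raise CohortError(f"clinical table missing required column {col!r}")
        os_time = pd.to_numeric(df["os_time"], errors="coerce")
        if os_time.isna().any() or not np.isfinite(os_time.to_numpy()).all():
            bad = df.index[os_time.isna()].tolist()
            raise CohortError(f"non-numeric os_time for samples: {bad[:5]}")
        if (os_time <= 0).any():
            bad = df.index[os_time <= 0].tolist()
            raise CohortError(f"os_time must be > 0; offending samples: {bad[:5]}")
        os_event = df["os_event"]
        if not os_event.isin([0, 1]).all():
            bad = df.index[~os_event.isin([0, 1])].tolist()
            raise CohortError(f"os_event must be 0 or 1; offending samples: {bad[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def os_time(self) -> np.ndarray:
        return self.data["os_time"].to_numpy(dtype=float)

    @property
    def os_event(self) -> np.ndarray:
        return self.data["os_event"].to_numpy(dtype=int)

    def subset_samples(self, sample_ids: list[str]) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise CohortError(f"samples absent from clinical table: {missing}")
        return ClinicalTable(self.data.loc[sample_ids])


@dataclass(frozen=True)
class Cohort:
    """Named bundle of expression and clinical data over the same samples, same order."""

    name: str
    expression: ExpressionMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.clinical.sample_ids:
            raise CohortError(
                f"cohort {self.name!r}: expression and clinical sample ids differ "
                "or are ordered differently; use assemble_cohort()"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples


def read_expression(path, transpose: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (first column gene ids, header sample ids).

    Duplicate gene ids are collapsed by arithmetic mean (deterministic and
    order-independent); the number of collapsed rows is logged. ``transpose=True``
    accepts samples-as-rows files.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - message path
        raise CohortError(f"could not read expression file {path}: {exc}") from exc
    if transpose:
        raw = raw.T
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.isna()
    bad |= raw.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise CohortError(
            f"non-numeric or missing value at gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} in {path}"
        )
    n_dup = int(numeric.index.duplicated().sum())
    if n_dup:
        logger.info("collapsing %d duplicate gene rows by mean in %s", n_dup, path)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric.astype(float))


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path) -> ClinicalTable:
    """Read a tab-delimited clinical table with required columns sample_id, os_time, os_event."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - message path
        raise CohortError(f"could not read clinical file {path}: {exc}") from exc
    if "sample_id" not in df.columns:
        raise CohortError(f"clinical table {path} missing required column 'sample_id'")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.data.to_csv(path, sep="\t", index_label="sample_id")


def assemble_cohort(name: str, expr: ExpressionMatrix, clin: ClinicalTable) -> Cohort:
    """Restrict expression and clinical data to their shared samples, identically ordered.

    Sample order follows the expression matrix. Idempotent: reassembling an
    assembled cohort changes nothing.
    """
    shared = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    if not shared:
        raise CohortError(
            f"cohort {name!r}: no shared samples between expression "
            f"({expr.n_samples}) and clinical ({len(clin.sample_ids)})"
        )
    dropped_expr = expr.n_samples - len(shared)
    dropped_clin = len(clin.sample_ids) - len(shared)
    if dropped_expr or dropped_clin:
        logger.info(
            "cohort %s: dropped %d expression-only and %d clinical-only samples",
            name, dropped_expr, dropped_clin,
        )
    return Cohort(name, expr.subset_samples(shared), clin.subset_samples(shared))
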
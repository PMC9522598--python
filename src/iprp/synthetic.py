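"""Synthetic multi-cohort AML-like data with planted gene-pair prognostic structure.

The generator emulates the data regime the pair-signature workflow assumes:

* a handful of *planted gene pairs* whose within-sample ordering drives the
  hazard of death under a proportional-hazards model with Weibull baseline
  and independent exponential censoring;
* two disjoint *cluster gene sets* (stand-ins for curated pyroptosis- and
  immune-related lists) whose expression carries a 3-cluster structure
  correlated with risk, so that consensus clustering, survival labelling of
  clusters, and the FF/UU differential-expression screen all have a real
  signal path;
* per-cohort *batch effects*: strictly monotone per-sample transforms
  (affine with positive slope, optionally composed with an exp / cube /
  within-sample rank warp) that shift and warp raw expression while leaving
  every pair ordering untouched;
* clinical covariates (age, prior malignancy, ethnicity, an ELN2017-like
  class) with known Cox coefficients for the nomogram stage.

A per-patient severity latent ``u ~ Uniform(0, 1)`` couples the planted pair
indicators to the cluster structure: indicator j is Bernoulli with success
probability ``prevalence_j + coupling * sign(coef_j) * (u - 1/2)``, and
cluster membership follows noisy tertiles of ``u``. Marginal indicator
prevalence therefore equals the requested prevalence, while favourable
clusters genuinely enrich for protective orderings.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; cohorts derive independent sub-streams from
their index, and the cross-cohort structural parameters (cluster centroids)
derive from the seed alone so that every cohort shares them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort_io import ClinicalTable, Cohort, ExpressionMatrix
from .pairs import GenePair

_WARPS = {
    None: lambda x: x,
    "exp": lambda x: np.exp(x / 4.0),
    "cube": lambda x: x**3,
}


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedPair:
    """An ordered gene pair whose indicator (1 iff a > b) multiplies the hazard by exp(coef)."""

    gene_a: str
    gene_b: str
    coef: float
    prevalence: float = 0.5


@dataclass(frozen=True)
class BatchTransform:
    """Strictly increasing per-sample transform: affine then optional warp.

    ``warp`` is one of None, "exp" (exp(x/4)), "cube" (x^3) or "rank"
    (within-sample ranks) — all strictly monotone, so pair encodings are
    unchanged by construction.
    """

    slope: float = 1.0
    offset: float = 0.0
    warp: str | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise SyntheticSpecError(f"batch transform slope must be positive, got {self.slope}")
        if self.warp not in _WARPS and self.warp != "rank":
            raise SyntheticSpecError(f"unknown warp {self.warp!r}")

    def apply(self, values: np.ndarray) -> np.ndarray:
        out = self.slope * values + self.offset
        if self.warp == "rank":
            # within-sample (column) ranks; strictly increasing a.s. for continuous data
            out = stats.rankdata(out, axis=0).astype(float)
        else:
            out = _WARPS[self.warp](out)
        return out


def _default_planted_pairs() -> tuple[PlantedPair, ...]:
    return (
        PlantedPair("PGA1", "PGB1", 1.0),
        PlantedPair("PGA2", "PGB2", -1.0),
        PlantedPair("PGA3", "PGB3", 0.9),
    )


def _default_batch_models() -> tuple[BatchTransform, ...]:
    return (
        BatchTransform(),
        BatchTransform(slope=1.5, offset=3.0),
        BatchTransform(slope=0.8, offset=-2.0),
        BatchTransform(slope=1.0, offset=0.0, warp="exp"),
        BatchTransform(slope=1.2, offset=1.0, warp="cube"),
    )


def _default_clinical_betas() -> dict[str, float]:
    return {"age": 0.03, "prior_malignancy": 0.5}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one multi-cohort simulation.

    ``n_genes`` counts all genes: planted pair genes, the two cluster gene
    sets (``cluster_set_size`` each) and i.i.d. Gaussian background genes
    filling the remainder. Times are in days.
    """

    n_genes: int = 300
    n_samples: int = 250
    n_cohorts: int = 5
    planted_pairs: tuple[PlantedPair, ...] = field(default_factory=_default_planted_pairs)
    clinical_betas: dict[str, float] = field(default_factory=_default_clinical_betas)
    weibull_shape: float = 1.2
    weibull_scale: float = 1500.0
    censor_rate: float = 0.3
    batch_models: tuple[BatchTransform, ...] = field(default_factory=_default_batch_models)
    seed: int = 0
    # expression model
    baseline_expression: float = 7.0
    background_sd: float = 1.0
    pair_separation: float = 2.5
    pair_noise_sd: float = 0.3
    cluster_set_size: int = 15
    n_clusters: int = 3
    centroid_sd: float = 2.0
    cluster_noise_sd: float = 1.0
    severity_coupling: float = 0.8
    cluster_label_noise: float = 0.1

    def __post_init__(self) -> None:
        for p in self.planted_pairs:
            if not math.isfinite(p.coef):
                raise SyntheticSpecError(f"planted coefficient for {p.gene_a}|{p.gene_b} not finite")
            if not (0.2 < p.prevalence < 0.8):
                raise SyntheticSpecError(
                    f"infeasible prevalence {p.prevalence} for {p.gene_a}|{p.gene_b}: "
                    "planted prevalence must lie in (0.2, 0.8)"
                )
        if not (0.0 <= self.censor_rate < 1.0):
            raise SyntheticSpecError("censor_rate must be in [0, 1)")
        if self.n_samples < 10:
            raise SyntheticSpecError("n_samples must be at least 10")
        n_special = 2 * len(self.planted_pairs) + 2 * self.cluster_set_size
        if self.n_genes < n_special + 10:
            raise SyntheticSpecError(
                f"n_genes={self.n_genes} too small for {n_special} structured genes plus background"
            )

    @property
    def pyroptosis_like_genes(self) -> list[str]:
        return [f"PYR{i:02d}" for i in range(1, self.cluster_set_size + 1)]

    @property
    def immune_like_genes(self) -> list[str]:
        return [f"IMM{i:02d}" for i in range(1, self.cluster_set_size + 1)]

    @property
    def pair_genes(self) -> list[str]:
        out: list[str] = []
        for p in self.planted_pairs:
            out.extend([p.gene_a, p.gene_b])
        return out

    @property
    def background_genes(self) -> list[str]:
        n_bg = self.n_genes - len(self.pair_genes) - 2 * self.cluster_set_size
        return [f"BG{i:04d}" for i in range(1, n_bg + 1)]

    @property
    def gene_universe(self) -> list[str]:
        return self.pair_genes + self.pyroptosis_like_genes + self.immune_like_genes + self.background_genes


@dataclass(frozen=True)
class GroundTruth:
    """Oracle information for one generated cohort."""

    pairs: tuple[GenePair, ...]
    coefs: tuple[float, ...]
    indicators: pd.DataFrame  # pairs x samples, the latent 0/1 orderings
    linear_predictor: pd.Series  # per-sample Sum of coef * indicator + clinical terms
    severity: pd.Series
    cluster_labels: dict[str, pd.Series]  # gene-set name -> per-sample cluster id (1..k)
    uncensored_time: pd.Series


def _structural_rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7]))


def _censoring_rate_for(times: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate whose expected censored fraction is censor_rate."""
    if censor_rate <= 0:
        return 0.0

    def f(rate: float) -> float:
        return float(np.mean(1.0 - np.exp(-rate * times))) - censor_rate

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 10
        if hi > 1e9:  # pragma: no cover - defensive
            break
    return float(optimize.brentq(f, lo, hi))


def generate_cohort(spec: SyntheticSpec, cohort_index: int = 0) -> tuple[Cohort, GroundTruth]:
    """Generate one cohort (no batch transform) plus its ground truth.

    Fully reproducible from ``(spec.seed, cohort_index)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1000 + int(cohort_index)]))
    n = spec.n_samples
    name = f"SIM{cohort_index}"
    sample_ids = [f"{name}_S{i:04d}" for i in range(n)]

    # severity latent couples pair indicators, cluster structure and ELN-like class
    u = rng.uniform(0.0, 1.0, size=n)

    # planted pair indicators
    pairs = tuple(GenePair(p.gene_a, p.gene_b) for p in spec.planted_pairs)
    coefs = tuple(float(p.coef) for p in spec.planted_pairs)
    z = np.zeros((len(pairs), n), dtype=np.uint8)
    for j, p in enumerate(spec.planted_pairs):
        prob = np.clip(p.prevalence + spec.severity_coupling * np.sign(p.coef) * (u - 0.5), 0.02, 0.98)
        z[j] = rng.uniform(size=n) < prob

    # expression ------------------------------------------------------------
    expr = pd.DataFrame(
        0.0, index=spec.gene_universe, columns=sample_ids, dtype=float
    )
    b = spec.baseline_expression
    # pair genes: ordering set by the latent indicator, separation >> noise
    for j, p in enumerate(spec.planted_pairs):
        delta = (z[j].astype(float) - 0.5) * spec.pair_separation
        expr.loc[p.gene_a] = b + delta + rng.normal(0, spec.pair_noise_sd, n)
        expr.loc[p.gene_b] = b - delta + rng.normal(0, spec.pair_noise_sd, n)

    # cluster gene sets: centroids shared across cohorts (structural rng)
    srng = _structural_rng(spec)
    cluster_labels: dict[str, pd.Series] = {}
    for set_name, genes in (
        ("pyroptosis_like", spec.pyroptosis_like_genes),
        ("immune_like", spec.immune_like_genes),
    ):
        centroids = b + srng.normal(0, spec.centroid_sd, size=(spec.n_clusters, len(genes)))
        u_tilde = np.clip(u + rng.normal(0, spec.cluster_label_noise, n), 0, 1)
        edges = np.linspace(0, 1, spec.n_clusters + 1)[1:-1]
        labels = np.digitize(u_tilde, edges)  # 0..k-1, increasing severity
        noise = rng.normal(0, spec.cluster_noise_sd, size=(len(genes), n))
        expr.loc[genes] = centroids[labels].T + noise
        cluster_labels[set_name] = pd.Series(labels + 1, index=sample_ids)

    # background genes
    bg = spec.background_genes
    expr.loc[bg] = rng.normal(b, spec.background_sd, size=(len(bg), n))

    # clinical covariates ---------------------------------------------------
    age = np.clip(rng.normal(60, 10, n), 18, 90)
    prior = (rng.uniform(size=n) < 0.15).astype(int)
    ethnicity = rng.choice(["groupA", "groupB", "groupC"], size=n, p=[0.7, 0.2, 0.1])
    eln_levels = np.array(["Favorable", "Intermediate", "Adverse"])
    eln = eln_levels[np.digitize(u, [1 / 3, 2 / 3])]

    lp = z.T.astype(float) @ np.asarray(coefs)
    betas = dict(spec.clinical_betas)
    lp = lp + betas.get("age", 0.0) * (age - 60.0) + betas.get("prior_malignancy", 0.0) * prior

    # survival: Weibull-baseline PH by inverse transform ---------------------
    uu = rng.uniform(size=n)
    T = spec.weibull_scale * (-np.log(uu) / np.exp(lp)) ** (1.0 / spec.weibull_shape)
    T = np.maximum(T, 1e-3)
    if spec.censor_rate > 0:
        rate = _censoring_rate_for(T, spec.censor_rate)
        C = rng.exponential(1.0 / rate, size=n)
    else:
        C = np.full(n, np.inf)
    os_time = np.minimum(T, C)
    os_event = (T <= C).astype(int)

    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "age": age,
            "prior_malignancy": prior,
            "ethnicity": ethnicity,
            "eln2017": eln,
            "cohort": name,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    cohort = Cohort(name, ExpressionMatrix(expr), ClinicalTable(clinical))
    truth = GroundTruth(
        pairs=pairs,
        coefs=coefs,
        indicators=pd.DataFrame(z, index=[p.label for p in pairs], columns=sample_ids),
        linear_predictor=pd.Series(lp, index=sample_ids),
        severity=pd.Series(u, index=sample_ids),
        cluster_labels=cluster_labels,
        uncensored_time=pd.Series(T, index=sample_ids),
    )
    return cohort, truth


def apply_batch_transform(expr: ExpressionMatrix, transform: BatchTransform) -> ExpressionMatrix:
    """Apply a strictly monotone per-sample batch transform; shape and ids unchanged."""
    out = transform.apply(expr.values)
    return ExpressionMatrix(pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids))


def generate_multicohort_suite(spec: SyntheticSpec) -> list[tuple[Cohort, GroundTruth]]:
    """Generate ``n_cohorts`` cohorts sharing planted pairs but with distinct batch models.

    Sample ids are globally unique (cohort-name prefixes).
    """
    if spec.n_cohorts < 2:
        raise SyntheticSpecError("a multi-cohort suite needs n_cohorts >= 2")
    suite = []
    for i in range(spec.n_cohorts):
        cohort, truth = generate_cohort(spec, i)
        bt = spec.batch_models[i % len(spec.batch_models)]
        batched = Cohort(cohort.name, apply_batch_transform(cohort.expression, bt), cohort.clinical)
        suite.append((batched, truth))
    return suite


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    """Copy of the spec with a different master seed."""
    return replace(spec, seed=int(seed))
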
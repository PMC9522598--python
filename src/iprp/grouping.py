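"""Prognostic grouping: consensus clustering, survival labelling, FF/UU, DEG screen.

Patients are consensus-clustered separately on two curated gene sets
(pyroptosis-related and immune-related in the intended application). For
each candidate k, the data are repeatedly subsampled and k-means-clustered;
the consensus matrix stores, for every sample pair, the fraction of
co-subsampled runs in which the pair co-clustered. The number of clusters
is chosen from the relative increase in area under the consensus CDF.
Clusters are then ordered by survival (restricted-mean survival time, with
a one-vs-rest log-rank test for the best cluster), and patients favourable
under both gene sets form the FF group, unfavourable under both the UU
group. Differential expression between FF and UU uses a two-sided Wilcoxon
rank-sum test per gene with Benjamini-Hochberg correction; the default
screen keeps |log2FC| > 1 and FDR < 0.001, with log2FC the difference of
group means on the (log-scale) expression matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .cohort_io import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)


class GroupingError(ValueError):
    pass


@dataclass(frozen=True)
class ConsensusResult:
    k_range: tuple[int, ...]
    consensus_matrices: dict[int, np.ndarray]  # k -> samples x samples in [0,1]
    cdf_areas: dict[int, float]
    delta_areas: dict[int, float]  # relative increase in CDF area vs k-1
    chosen_k: int
    labels: pd.Series  # per-sample cluster id in 1..chosen_k


@dataclass(frozen=True)
class ClusterSurvivalLabels:
    favorability: dict[int, str]  # cluster id -> "favorable" | "unfavorable"
    rmst: dict[int, float]
    logrank_p: float  # best cluster vs rest
    tied: bool


@dataclass(frozen=True)
class JointGroupAssignment:
    labels: pd.Series  # per-sample in {"FF", "UU", "other"}

    @property
    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def samples(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])


@dataclass(frozen=True)
class DEGResult:
    gene_id: str
    log2_fc: float
    p_value: float
    fdr: float
    direction: str  # "up" | "down" relative to the first group


def _consensus_cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus values."""
    iu = np.triu_indices_from(consensus, k=1)
    x = np.sort(consensus[iu])
    m = x.size
    grid = np.concatenate(([0.0], x, [1.0]))
    cdf = np.concatenate(([0.0], (np.arange(m) + 1) / m, [1.0]))
    return float(np.sum(np.diff(grid) * cdf[:-1]))


def consensus_cluster(
    expr_subset: ExpressionMatrix,
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    n_resamples: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    delta_area_threshold: float = 0.1,
    chosen_k_override: int | None = None,
) -> ConsensusResult:
    """Subsampled k-means consensus clustering of samples on a gene subset.

    Gene rows are z-scored before clustering. The chosen k is the largest k
    in ``k_range`` whose relative CDF-area increase over k-1 exceeds
    ``delta_area_threshold`` (the smallest k counts as always exceeding);
    ``chosen_k_override`` forces a specific k. Final labels come from
    average-linkage hierarchical clustering of the consensus matrix.
    """
    ks = tuple(sorted(set(int(k) for k in k_range)))
    if ks[0] < 2:
        raise GroupingError("k_range minimum must be at least 2")
    n = expr_subset.n_samples
    if expr_subset.n_genes < 2:
        raise GroupingError("need at least 2 genes for clustering")
    if n < 3 * ks[-1]:
        raise GroupingError(f"too few samples ({n}) for k up to {ks[-1]}")

    vals = expr_subset.values
    sd = vals.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    X = ((vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]).T  # samples x genes

    rng = np.random.default_rng(seed)
    n_sub = max(int(round(subsample_frac * n)), ks[-1] + 1)
    matrices: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    for k in ks:
        together = np.zeros((n, n))
        cosampled = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=n_sub, replace=False)
            km = KMeans(n_clusters=k, n_init=4, random_state=int(rng.integers(2**31 - 1)))
            lab = km.fit_predict(X[idx])
            same = (lab[:, None] == lab[None, :]).astype(float)
            cosampled[np.ix_(idx, idx)] += 1.0
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(cosampled > 0, together / np.maximum(cosampled, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0
        matrices[k] = consensus
        areas[k] = _consensus_cdf_area(consensus)

    deltas: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else 0.0

    if chosen_k_override is not None:
        chosen_k = int(chosen_k_override)
        if chosen_k not in ks:
            raise GroupingError(f"chosen_k_override {chosen_k} not in k_range {ks}")
    else:
        exceeding = [k for i, k in enumerate(ks) if i == 0 or deltas[k] > delta_area_threshold]
        chosen_k = max(exceeding)
    logger.info("consensus clustering: CDF areas %s, chosen k=%d", areas, chosen_k)

    dist = 1.0 - matrices[chosen_k]
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=chosen_k, criterion="maxclust")
    return ConsensusResult(
        k_range=ks,
        consensus_matrices=matrices,
        cdf_areas=areas,
        delta_areas=deltas,
        chosen_k=chosen_k,
        labels=pd.Series(labels, index=expr_subset.sample_ids),
    )


def label_clusters_by_survival(labels: pd.Series, clinical: ClinicalTable) -> ClusterSurvivalLabels:
    """Order clusters by restricted-mean survival; best one is 'favorable'.

    The favourable call is backed by a one-vs-rest log-rank test of the best
    cluster against the pooled remainder; a p-value near 1 flags a tie.
    """
    clin = clinical.data.loc[labels.index]
    times = clin["os_time"].to_numpy(dtype=float)
    events = clin["os_event"].to_numpy(dtype=int)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise GroupingError("survival labelling needs at least 2 clusters")
    horizon = float(times.max())
    rmst: dict[int, float] = {}
    for c in clusters:
        mask = (labels == c).to_numpy()
        if events[mask].sum() == 0 and times[mask].sum() == 0:
            raise GroupingError(f"cluster {c} has zero events and zero follow-up")
        kmf = KaplanMeierFitter().fit(times[mask], events[mask])
        rmst[int(c)] = float(restricted_mean_survival_time(kmf, t=horizon))
    best = max(rmst, key=rmst.get)
    onevsrest = np.where(labels.to_numpy() == best, "best", "rest")
    res = multivariate_logrank_test(times, onevsrest, events)
    p = float(res.p_value)
    favorability = {c: ("favorable" if c == best else "unfavorable") for c in rmst}
    return ClusterSurvivalLabels(favorability=favorability, rmst=rmst, logrank_p=p, tied=p > 0.99)


def assign_joint_groups(
    labels_a: pd.Series,
    labels_b: pd.Series,
    favorability_a: dict[int, str],
    favorability_b: dict[int, str],
) -> JointGroupAssignment:
    """FF = favourable under both clusterings; UU = unfavourable under both."""
    if set(labels_a.index) != set(labels_b.index):
        raise GroupingError("joint grouping requires identical sample universes")
    labels_b = labels_b.loc[labels_a.index]
    fav_a = labels_a.map(lambda c: favorability_a[int(c)] == "favorable")
    fav_b = labels_b.map(lambda c: favorability_b[int(c)] == "favorable")
    out = pd.Series("other", index=labels_a.index)
    out[fav_a & fav_b] = "FF"
    out[~fav_a & ~fav_b] = "UU"
    return JointGroupAssignment(out)


def clustering_association_test(labels1: pd.Series, labels2: pd.Series) -> tuple[float, float]:
    """Pearson chi-square test of association between two clusterings."""
    if set(labels1.index) != set(labels2.index):
        raise GroupingError("association test requires identical sample universes")
    labels2 = labels2.loc[labels1.index]
    if labels1.nunique() < 2 or labels2.nunique() < 2:
        raise GroupingError("association test requires >= 2 categories in each labelling")
    table = pd.crosstab(labels1, labels2)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def deg_screen(
    expr: ExpressionMatrix,
    group_labels: pd.Series,
    groups: tuple[str, str] = ("FF", "UU"),
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.001,
) -> list[DEGResult]:
    """Wilcoxon rank-sum DEG screen between two groups with a BH/FC gate.

    log2FC is mean(first group) - mean(second group) on the already
    log-scale matrix; 'up' means higher in the first group. BH correction
    runs across all genes before the |log2FC| > fc_threshold and
    FDR < fdr_threshold filter.
    """
    g1, g2 = groups
    ids1 = [s for s in expr.sample_ids if group_labels.get(s) == g1]
    ids2 = [s for s in expr.sample_ids if group_labels.get(s) == g2]
    if len(ids1) < 3 or len(ids2) < 3:
        raise GroupingError(
            f"DEG screen needs >= 3 samples per group, got {g1}={len(ids1)}, {g2}={len(ids2)}"
        )
    x1 = expr.data[ids1].to_numpy()
    x2 = expr.data[ids2].to_numpy()
    log2fc = x1.mean(axis=1) - x2.mean(axis=1)
    pvals = np.ones(expr.n_genes)
    for i in range(expr.n_genes):
        a, b = x1[i], x2[i]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[i] = 1.0
            continue
        pvals[i] = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    results = []
    for i, gene in enumerate(expr.gene_ids):
        if abs(log2fc[i]) > fc_threshold and fdr[i] < fdr_threshold:
            results.append(
                DEGResult(
                    gene_id=gene,
                    log2_fc=float(log2fc[i]),
                    p_value=float(pvals[i]),
                    fdr=float(fdr[i]),
                    direction="up" if log2fc[i] > 0 else "down",
                )
            )
    logger.info("DEG screen %s vs %s: %d of %d genes pass", g1, g2, len(results), expr.n_genes)
    return results
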
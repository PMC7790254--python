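"""External and internal cluster-validity indices.

External criteria compare two partitions of the same persons (Cohen's kappa
after optimal label alignment, Rand index, Hubert–Arabie adjusted Rand).
Internal criteria score a partition from the data alone: C-index,
Baker–Hubert Gamma, G+, the generalized Dunn index GDI31, point-biserial,
mean silhouette, S_Dbw, and AIC/BIC under a classification likelihood.

Pair-based indices operate on the full set of n(n-1)/2 pairwise Euclidean
distances split into within-cluster and between-cluster pairs; tied
within/between comparisons count toward neither s_plus nor s_minus.
All functions report ``nan`` where an index is undefined for the instance.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from sklearn.metrics import (
    adjusted_rand_score,
    cohen_kappa_score,
    rand_score,
    silhouette_score,
)

from .engines import ClusterSolution

logger = logging.getLogger(__name__)

#: Optimization direction of every index ("min" = smaller is better).
INDEX_DIRECTIONS = {
    "c_index": "min",
    "gdi31": "max",
    "gamma": "max",
    "g_plus": "min",
    "point_biserial": "max",
    "silhouette": "max",
    "s_dbw": "min",
    "aic": "min",
    "bic": "min",
    "kappa": "max",
    "rand": "max",
    "adjusted_rand": "max",
}

INTERNAL_INDICES = (
    "c_index", "gdi31", "gamma", "g_plus", "point_biserial",
    "silhouette", "s_dbw", "aic", "bic",
)
EXTERNAL_INDICES = ("kappa", "rand", "adjusted_rand")


def _as_labels(partition) -> np.ndarray:
    labels = np.asarray(partition)
    if labels.ndim != 1:
        raise ValueError("a partition must be a 1-D label vector")
    return labels


def _as_matrix(data) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


# -- external criteria -------------------------------------------------------


def align_labels(a, b) -> dict:
    """One-to-one mapping from b's labels onto a's maximizing agreement.

    Solved by optimal assignment on the contingency table, padded with empty
    labels when the cluster counts differ; surplus b-labels map to fresh
    labels beyond a's.
    """
    a, b = _as_labels(a), _as_labels(b)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same persons")
    a_vals, a_codes = np.unique(a, return_inverse=True)
    b_vals, b_codes = np.unique(b, return_inverse=True)
    table = np.zeros((len(b_vals), len(a_vals)))
    np.add.at(table, (b_codes, a_codes), 1)
    size = max(table.shape)
    padded = np.zeros((size, size))
    padded[: table.shape[0], : table.shape[1]] = table
    rows, cols = linear_sum_assignment(padded, maximize=True)
    # fresh labels for b-clusters assigned to padding columns
    fresh = _fresh_labels(a_vals, table.shape[0])
    mapping = {}
    for r, c in zip(rows, cols):
        if r >= table.shape[0]:
            continue
        mapping[b_vals[r]] = a_vals[c] if c < table.shape[1] else next(fresh)
    return mapping


def _fresh_labels(existing, count):
    if np.issubdtype(np.asarray(existing).dtype, np.number):
        start = int(np.max(existing)) + 1
        yield from range(start, start + count)
    else:
        for i in range(count):
            yield f"_unmatched_{i}"


def apply_mapping(b, mapping: dict) -> np.ndarray:
    b = _as_labels(b)
    return np.asarray([mapping[v] for v in b])


def cohen_kappa(a, b, aligned: bool = False) -> float:
    """Cohen's kappa between two partitions.

    Unless ``aligned``, b's labels are first matched one-to-one onto a's by
    optimal assignment (independent clusterings share no label space).
    Degenerate case p_e = 1 (one shared category) is defined as 1 for
    identical partitions and 0 otherwise.
    """
    a, b = _as_labels(a), _as_labels(b)
    if not aligned:
        b = apply_mapping(b, align_labels(a, b))
    if len(set(a) | set(b)) < 2:
        logger.info("kappa on single-category partitions; defined by identity")
        return 1.0 if np.array_equal(a, b) else 0.0
    return float(cohen_kappa_score(a, b))


def rand_index(a, b) -> float:
    """Proportion of concordant person pairs (co-membership agreement)."""
    a, b = _as_labels(a), _as_labels(b)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same persons")
    if len(a) < 2:
        raise ValueError("Rand index needs at least two persons")
    return float(rand_score(a, b))


def adjusted_rand(a, b) -> float:
    """Hubert–Arabie chance-corrected Rand index.

    Degenerate expectation (e.g. both partitions a single cluster) is
    defined as 1 for identical partitions and 0 otherwise.
    """
    a, b = _as_labels(a), _as_labels(b)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same persons")
    return float(adjusted_rand_score(a, b))


# -- pair-distance substrate -------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PairCounts:
    """Within/between pair-distance comparison counts.

    ``s_plus`` counts (within, between) distance pairs with within < between,
    ``s_minus`` those with within > between; ties count in neither.
    """

    s_plus: int
    s_minus: int
    n_w: int
    n_b: int
    n_t: int

    def __post_init__(self) -> None:
        if self.n_w + self.n_b != self.n_t:
            raise ValueError("n_w + n_b must equal n_t")
        if self.s_plus + self.s_minus > self.n_w * self.n_b:
            raise ValueError("s_plus + s_minus cannot exceed n_w * n_b")


def _split_distances(
    data, partition, distances: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise distances split into (within, between) arrays.

    ``distances`` may carry a precomputed condensed distance matrix to
    amortize the O(n^2) computation across several indices.
    """
    x = _as_matrix(data)
    labels = _as_labels(partition)
    n = x.shape[0]
    if labels.shape[0] != n:
        raise ValueError("partition length must match data rows")
    d = pdist(x) if distances is None else distances
    iu0, iu1 = np.triu_indices(n, k=1)
    within = labels[iu0] == labels[iu1]
    return d[within], d[~within]


def pair_counts(data, partition, distances: np.ndarray | None = None) -> PairCounts:
    """Exhaustive within-vs-between distance comparisons (tie-excluded)."""
    dw, db = _split_distances(data, partition, distances)
    n_w, n_b = len(dw), len(db)
    if n_w == 0 or n_b == 0:
        raise ValueError("need at least one within pair and one between pair")
    sorted_b = np.sort(db)
    # for each within distance: between distances strictly above / below it
    s_plus = int((n_b - np.searchsorted(sorted_b, dw, side="right")).sum())
    s_minus = int(np.searchsorted(sorted_b, dw, side="left").sum())
    return PairCounts(
        s_plus=s_plus, s_minus=s_minus, n_w=n_w, n_b=n_b, n_t=n_w + n_b
    )


def gamma_gplus(pc: PairCounts) -> tuple[float, float]:
    """Baker–Hubert Gamma and the G+ index from pair-comparison counts.

    Gamma = (s+ - s-)/(s+ + s-); undefined (nan) when every comparison is
    tied.  G+ = 2 s- / (n_t (n_t - 1)).
    """
    concordance = pc.s_plus + pc.s_minus
    if concordance == 0:
        logger.info("gamma undefined: all distance comparisons tied")
        gamma = float("nan")
    else:
        gamma = (pc.s_plus - pc.s_minus) / concordance
    g_plus = 2.0 * pc.s_minus / (pc.n_t * (pc.n_t - 1))
    return gamma, g_plus


def c_index(data, partition, distances: np.ndarray | None = None) -> float:
    """Hubert–Levin C-index: (S - S_min)/(S_max - S_min) over within-pair
    distance sums; 0 when all pairwise distances are equal."""
    dw, db = _split_distances(data, partition, distances)
    n_w = len(dw)
    if n_w == 0:
        raise ValueError("C-index needs at least one within-cluster pair")
    all_d = np.sort(np.concatenate([dw, db]))
    s = float(dw.sum())
    s_min = float(all_d[:n_w].sum())
    s_max = float(all_d[-n_w:].sum())
    if s_max == s_min:
        logger.info("C-index degenerate: all pairwise distances equal; defined 0")
        return 0.0
    return (s - s_min) / (s_max - s_min)


def gdi31(data, partition) -> float:
    """Generalized Dunn index 31: minimum mean between-cluster point
    distance over cluster pairs, divided by the maximum intra-cluster
    diameter.  Singletons have diameter 0; all-singleton partitions are
    undefined (nan)."""
    x = _as_matrix(data)
    labels = _as_labels(partition)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("GDI31 needs at least two clusters")
    groups = [x[labels == c] for c in uniq]
    diameters = [float(pdist(g).max()) if len(g) > 1 else 0.0 for g in groups]
    max_diameter = max(diameters)
    if max_diameter == 0.0:
        logger.info("GDI31 undefined: all clusters have zero diameter")
        return float("nan")
    min_delta = np.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            diff = groups[i][:, None, :] - groups[j][None, :, :]
            mean_between = float(np.sqrt((diff**2).sum(axis=2)).mean())
            min_delta = min(min_delta, mean_between)
    return min_delta / max_diameter


def point_biserial(data, partition, distances: np.ndarray | None = None) -> float:
    """Point-biserial index: the correlation between pair distance and the
    between-pair indicator, written as
    (mean_between - mean_within) * sqrt(n_w n_b / n_t^2) / SD(all distances).
    Higher is better; nan for zero distance variance."""
    dw, db = _split_distances(data, partition, distances)
    n_w, n_b = len(dw), len(db)
    if n_w == 0 or n_b == 0:
        raise ValueError("point-biserial needs within and between pairs")
    all_d = np.concatenate([dw, db])
    sd = float(all_d.std())  # population SD over all pairs
    if sd == 0.0:
        logger.info("point-biserial undefined: zero distance variance")
        return float("nan")
    n_t = n_w + n_b
    return float((db.mean() - dw.mean()) * np.sqrt(n_w * n_b / n_t**2) / sd)


def silhouette_mean(data, partition) -> float:
    """Mean silhouette width over all points (singletons score 0)."""
    x = _as_matrix(data)
    labels = _as_labels(partition)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least two clusters")
    return float(silhouette_score(x, labels))


def s_dbw(data, partition) -> float:
    """S_Dbw of Halkidi & Vazirgiannis: average normalized cluster scatter
    plus inter-cluster density at pair midpoints, with the average-stdev
    neighborhood radius.  Lower is better; nan for zero total scatter."""
    x = _as_matrix(data)
    labels = _as_labels(partition)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("S_Dbw needs at least two clusters")
    sigma_total = x.var(axis=0)
    norm_total = float(np.linalg.norm(sigma_total))
    if norm_total == 0.0:
        logger.info("S_Dbw undefined: zero total scatter")
        return float("nan")
    groups = [x[labels == c] for c in uniq]
    centers = np.stack([g.mean(axis=0) for g in groups])
    sigma_norms = [float(np.linalg.norm(g.var(axis=0))) for g in groups]
    scat = float(np.mean(sigma_norms)) / norm_total
    stdev = np.sqrt(sum(sigma_norms)) / k

    def density(point: np.ndarray, members: np.ndarray) -> int:
        return int((np.linalg.norm(members - point, axis=1) <= stdev).sum())

    dens = 0.0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            union = np.vstack([groups[i], groups[j]])
            denom = max(density(centers[i], union), density(centers[j], union))
            if denom == 0:
                continue
            midpoint = 0.5 * (centers[i] + centers[j])
            dens += density(midpoint, union) / denom
    dens_bw = dens / (k * (k - 1))
    return scat + dens_bw


def partition_aic_bic(data, solution: ClusterSolution) -> tuple[float, float]:
    """AIC and BIC for a cluster solution.

    LPA solutions use their own mixture log-likelihood and parameter count.
    Hard partitions use a classification (complete-data) likelihood:
    Gaussian components at the cluster means with a shared spherical
    variance equal to the pooled within-cluster variance, plus the
    multinomial assignment term sum_k m_k ln(m_k/n) — required for
    consistency with the parameter count p = d*k (means) + 1 (variance)
    + (k-1) weights, and what keeps BIC from rewarding spurious splits.
    """
    x = _as_matrix(data)
    n, d = x.shape
    extras = solution.fit_extras
    if solution.algorithm == "lpa" and "log_likelihood" in extras:
        loglik = float(extras["log_likelihood"])
        p = int(extras["n_params"])
    else:
        labels = solution.labels
        ssw = 0.0
        weight_term = 0.0
        for c in range(1, solution.k + 1):
            g = x[labels == c]
            ssw += float(((g - g.mean(axis=0)) ** 2).sum())
            weight_term += len(g) * np.log(len(g) / n)
        sigma2 = ssw / (n * d)
        if sigma2 <= 0.0:
            raise ValueError("pooled within-cluster variance is zero (degenerate)")
        loglik = weight_term - 0.5 * n * d * (np.log(2.0 * np.pi * sigma2) + 1.0)
        p = d * solution.k + 1 + (solution.k - 1)
    aic = -2.0 * loglik + 2.0 * p
    bic = -2.0 * loglik + p * np.log(n)
    return float(aic), float(bic)


# -- report assembly ---------------------------------------------------------


def compute_validity(
    data,
    solution: ClusterSolution,
    comparison=None,
    comparison_aligned: bool = False,
) -> dict[str, float]:
    """The full index battery for one solution (external part only when a
    comparison partition is given)."""
    labels = solution.labels
    distances = pdist(_as_matrix(data))
    pc = pair_counts(data, labels, distances)
    gamma, g_plus = gamma_gplus(pc)
    aic, bic = partition_aic_bic(data, solution)
    report = {
        "c_index": c_index(data, labels, distances),
        "gdi31": gdi31(data, labels),
        "gamma": gamma,
        "g_plus": g_plus,
        "point_biserial": point_biserial(data, labels, distances),
        "silhouette": silhouette_mean(data, labels),
        "s_dbw": s_dbw(data, labels),
        "aic": aic,
        "bic": bic,
    }
    if comparison is not None:
        report["kappa"] = cohen_kappa(labels, comparison, aligned=comparison_aligned)
        report["rand"] = rand_index(labels, comparison)
        report["adjusted_rand"] = adjusted_rand(labels, comparison)
    return report


def validity_table(reports: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Assemble named per-solution reports into an indices x solutions table
    with an optimization-direction column."""
    frame = pd.DataFrame(reports)
    frame["direction"] = [INDEX_DIRECTIONS.get(i, "") for i in frame.index]
    return frame
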
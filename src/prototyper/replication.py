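"""Split-half replication protocol with SVM reclassification.

The reliability pipeline: draw resamples of the full sample, split each into
random halves, cluster both halves with every engine at every k, reclassify
each half's members with a support-vector classifier trained on the opposite
half's solution, and score the agreement between each half's own labels and
its SVM-predicted labels with Cohen's kappa, the Rand index and the adjusted
Rand index.  Averaged kappa gates the candidate set (cross-algorithm mean >=
0.6 by default); the internal validity battery then votes on the retained
solutions, and the winning solution's prototypes can be compared across
waves (stability).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.svm import SVC

from . import indices
from .engines import (
    ClusterSolution,
    EngineError,
    LPA_FAMILIES,
    lpa_fit,
    rbf_affinity,
    spectral_cluster,
    spectral_embedding,
    ward_kmeans,
    ward_linkage,
)

logger = logging.getLogger(__name__)

ALGORITHMS = ("ward_kmeans", "lpa", "spectral")
EXTERNAL_METRICS = ("kappa", "rand", "adjusted_rand")


@dataclasses.dataclass(frozen=True)
class SVMConfig:
    """One-vs-rest soft-margin SVM settings for reclassification.

    Defaults: RBF kernel, C = 1, gamma = 1 / (n_features * feature variance)
    (sklearn's "scale", which on the five trait z-scores equals
    1 / (5 * variance)).
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"


@dataclasses.dataclass(frozen=True)
class ProtocolConfig:
    """Configuration of the split-half replication protocol."""

    n_resamples: int = 20
    k_range: tuple[int, ...] = tuple(range(3, 11))
    algorithms: tuple[str, ...] = ALGORITHMS
    kappa_gate: float = 0.6
    svm: SVMConfig = SVMConfig()
    seed: int = 0
    sample_fraction: float = 1.0
    lpa_families: tuple[str, ...] = LPA_FAMILIES
    spectral_bandwidth: float | None = None

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")
        if min(self.k_range) < 2:
            raise ValueError("k_range must start at 2 or above")
        if not 0.0 <= self.kappa_gate <= 1.0:
            raise ValueError("kappa_gate must lie in [0, 1]")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must lie in (0, 1]")


@dataclasses.dataclass
class ReplicationResult:
    """Averaged external criteria per (algorithm, k) plus raw values.

    ``summary`` is indexed by (algorithm, k) with mean kappa/rand/adjusted
    Rand over n_resamples x 2 half-comparisons; ``raw`` keeps the individual
    half values; ``failures`` lists engine failures excluded from averages.
    """

    summary: pd.DataFrame
    raw: pd.DataFrame
    config: ProtocolConfig
    failures: list[dict[str, Any]] = dataclasses.field(default_factory=list)

    @property
    def n_solutions(self) -> int:
        """Number of successfully fitted clustering solutions."""
        return len(self.raw)


def svm_reclassify(
    train_z,
    train_labels,
    test_z,
    svm_config: SVMConfig = SVMConfig(),
) -> np.ndarray:
    """Assign test persons to training clusters by one-vs-rest SVM.

    One soft-margin classifier per training cluster; each test person takes
    the cluster whose classifier yields the largest decision value.  A
    training cluster with fewer than two members is handled by a
    nearest-centroid fallback (logged): test points whose nearest training
    centroid is such a cluster take its label, everyone else is decided by
    the SVM classifiers (margins and distances are not on a common scale,
    so the two rules are kept separate rather than mixed in one argmax).
    """
    x_train = np.asarray(train_z, dtype=float)
    x_test = np.asarray(test_z, dtype=float)
    labels = np.asarray(train_labels)
    clusters = np.unique(labels)
    if len(clusters) == 1:
        return np.full(len(x_test), clusters[0])
    centroids = np.stack([x_train[labels == c].mean(axis=0) for c in clusters])
    tiny = np.array([(labels == c).sum() < 2 for c in clusters])
    decisions = np.full((len(x_test), len(clusters)), -np.inf)
    for j, c in enumerate(clusters):
        if tiny[j]:
            logger.info("cluster %r has < 2 members; nearest-centroid fallback", c)
            continue
        clf = SVC(
            kernel=svm_config.kernel, C=svm_config.C, gamma=svm_config.gamma,
            cache_size=500,
        )
        clf.fit(x_train, (labels == c).astype(int))
        raw = clf.decision_function(x_test)
        # decision_function is positive toward classes_[1]
        decisions[:, j] = raw if clf.classes_[1] == 1 else -raw
    assigned = clusters[np.argmax(decisions, axis=1)]
    if tiny.any():
        centroid_d = np.linalg.norm(
            x_test[:, None, :] - centroids[None, :, :], axis=2
        )
        nearest = np.argmin(centroid_d, axis=1)
        take_fallback = tiny[nearest]
        assigned[take_fallback] = clusters[nearest[take_fallback]]
    return assigned


def _fit_engine(
    algorithm: str,
    x: np.ndarray,
    k: int,
    config: ProtocolConfig,
    shared: dict[str, Any],
    seed: int,
) -> ClusterSolution:
    if algorithm == "ward_kmeans":
        if "linkage" not in shared:
            shared["linkage"] = ward_linkage(x)
        return ward_kmeans(x, k, seed=seed, linkage_matrix=shared["linkage"])
    if algorithm == "spectral":
        if "embedding" not in shared:
            k_max = max(config.k_range)
            shared["embedding"] = spectral_embedding(
                rbf_affinity(x, config.spectral_bandwidth), k_max
            )
        return spectral_cluster(
            x, k, bandwidth=config.spectral_bandwidth, seed=seed,
            embedding=shared["embedding"],
        )
    if algorithm == "lpa":
        return lpa_fit(x, k, families=config.lpa_families, seed=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def run_replication(z, config: ProtocolConfig) -> ReplicationResult:
    """Run the full split-half protocol.

    For each resample: permute the (optionally subsampled) sample, split it
    50/50, fit every engine at every k on both halves, cross-reclassify by
    SVM, and score kappa/Rand/adjusted Rand between each half's own labels
    and its predictions.  Values are averaged per sample (mean of the two
    halves) and then across samples.
    """
    x = np.asarray(z, dtype=float)
    n = x.shape[0]
    if n < 4 * max(config.k_range):
        raise ValueError(
            f"sample of {n} too small for k up to {max(config.k_range)}"
        )
    rng = np.random.default_rng(config.seed)
    rows = []
    failures: list[dict[str, Any]] = []
    for resample in range(config.n_resamples):
        perm = rng.permutation(n)
        if config.sample_fraction < 1.0:
            perm = perm[: max(2, int(round(config.sample_fraction * n)))]
        half = len(perm) // 2
        parts = (perm[:half], perm[half:])
        data = (x[parts[0]], x[parts[1]])
        shared: list[dict[str, dict[str, Any]]] = [{}, {}]
        for algorithm in config.algorithms:
            for side in (0, 1):
                shared[side].setdefault(algorithm, {})
            for k in config.k_range:
                sols: list[ClusterSolution | None] = [None, None]
                for side in (0, 1):
                    seed = int(
                        np.random.SeedSequence(
                            [config.seed, resample, side, k,
                             ALGORITHMS.index(algorithm)]
                        ).generate_state(1)[0] % (2**31)
                    )
                    try:
                        sols[side] = _fit_engine(
                            algorithm, data[side], k, config,
                            shared[side][algorithm], seed,
                        )
                    except (EngineError, ValueError) as exc:
                        logger.warning(
                            "%s k=%d failed on resample %d half %d: %s",
                            algorithm, k, resample, side, exc,
                        )
                        failures.append(
                            {"algorithm": algorithm, "k": k,
                             "resample": resample, "half": side,
                             "error": str(exc)}
                        )
                if sols[0] is None or sols[1] is None:
                    continue
                for side in (0, 1):
                    own = sols[side]
                    other = sols[1 - side]
                    predicted = svm_reclassify(
                        data[1 - side], other.labels, data[side], config.svm
                    )
                    rows.append(
                        {
                            "algorithm": algorithm,
                            "k": k,
                            "resample": resample,
                            "half": side,
                            "kappa": indices.cohen_kappa(own.labels, predicted),
                            "rand": indices.rand_index(own.labels, predicted),
                            "adjusted_rand": indices.adjusted_rand(
                                own.labels, predicted
                            ),
                        }
                    )
    raw = pd.DataFrame(rows)
    if raw.empty:
        raise RuntimeError("every clustering attempt failed")
    per_sample = (
        raw.groupby(["algorithm", "k", "resample"])[list(EXTERNAL_METRICS)].mean()
    )
    summary = per_sample.groupby(["algorithm", "k"]).mean()
    return ReplicationResult(summary=summary, raw=raw, config=config,
                             failures=failures)


def screen_by_kappa(
    result: ReplicationResult, gate: float | None = None
) -> list[tuple[str, int]]:
    """Retain the (algorithm, k) solutions whose k survives the kappa gate.

    Kappa is averaged across algorithms per k; a k is retained iff that
    cross-algorithm mean is >= the gate.  An empty retained set falls back
    to the single best k (warning logged).
    """
    if gate is None:
        gate = result.config.kappa_gate
    mean_by_k = result.summary["kappa"].groupby("k").mean()
    retained_k = [int(k) for k, v in mean_by_k.items() if v >= gate]
    if not retained_k:
        best = int(mean_by_k.idxmax())
        logger.warning(
            "no k passed the kappa gate %.2f; falling back to best k=%d",
            gate, best,
        )
        retained_k = [best]
    algorithms = result.summary.index.get_level_values("algorithm").unique()
    return [(a, k) for a in algorithms for k in retained_k
            if (a, k) in result.summary.index]


def vote_count(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, tuple[str, int]]:
    """Vote-count model selection over retained solutions.

    ``table``: rows = validity indices, columns = MultiIndex (algorithm, k)
    of retained solutions; every row's direction comes from
    :data:`indices.INDEX_DIRECTIONS`.  For each index, the best solution
    within each algorithm earns a within-algorithm vote and the single best
    across all solutions earns a between-algorithm vote (missing values
    abstain; exact ties share the vote).  The winner has the most
    between-algorithm votes; ties break by within-algorithm votes, then by
    smaller k.
    """
    if table.shape[1] < 2:
        raise ValueError("vote counting needs at least two solutions")
    directed = table.loc[[i for i in table.index if i in indices.INDEX_DIRECTIONS]]
    within = pd.Series(0, index=table.columns, dtype=int)
    between = pd.Series(0, index=table.columns, dtype=int)
    for index_name, row in directed.iterrows():
        direction = indices.INDEX_DIRECTIONS[index_name]
        values = row.astype(float)
        if values.isna().all():
            logger.info("index %s missing everywhere; abstains", index_name)
            continue
        best_global = values.min() if direction == "min" else values.max()
        between[values == best_global] += 1
        for algorithm, sub in values.groupby(level="algorithm"):
            if sub.isna().all():
                continue
            best_local = sub.min() if direction == "min" else sub.max()
            within[sub[sub == best_local].index] += 1
    votes = pd.DataFrame({"within_algorithm": within, "between_algorithm": between})
    order = sorted(
        votes.index,
        key=lambda col: (-votes.loc[col, "between_algorithm"],
                         -votes.loc[col, "within_algorithm"], col[1], col[0]),
    )
    winner = order[0]
    return votes, (str(winner[0]), int(winner[1]))


def evaluate_retained(
    z,
    retained: Sequence[tuple[str, int]],
    config: ProtocolConfig,
    external: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, int], ClusterSolution]]:
    """Fit each retained (algorithm, k) on the full sample and assemble the
    validity battery table used for vote counting.

    External criteria (kappa/Rand/adjusted Rand), when supplied from a
    :class:`ReplicationResult` summary, are appended to the internal rows.
    """
    x = np.asarray(z, dtype=float)
    shared: dict[str, dict[str, Any]] = {}
    solutions: dict[tuple[str, int], ClusterSolution] = {}
    reports: dict[tuple[str, int], dict[str, float]] = {}
    for algorithm, k in retained:
        shared.setdefault(algorithm, {})
        seed = int(
            np.random.SeedSequence([config.seed, 97, k,
                                    ALGORITHMS.index(algorithm)])
            .generate_state(1)[0] % (2**31)
        )
        solution = _fit_engine(algorithm, x, k, config, shared[algorithm], seed)
        solutions[(algorithm, k)] = solution
        reports[(algorithm, k)] = indices.compute_validity(x, solution)
    table = pd.DataFrame(reports)
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["algorithm", "k"])
    if external is not None:
        ext = external.loc[[key for key in table.columns
                            if key in external.index]].T
        ext.columns = pd.MultiIndex.from_tuples(ext.columns,
                                                names=["algorithm", "k"])
        table = pd.concat([table, ext])
    return table, solutions


def select_model(z, config: ProtocolConfig) -> dict[str, Any]:
    """The full selection pipeline: replication, gate, battery, votes.

    Returns a dict with the replication result, the retained set, the
    validity table, the vote table, the winning (algorithm, k), and the
    winning full-sample solution.
    """
    replication = run_replication(z, config)
    retained = screen_by_kappa(replication)
    table, solutions = evaluate_retained(
        z, retained, config, external=replication.summary
    )
    votes, winner = vote_count(table)
    return {
        "replication": replication,
        "retained": retained,
        "validity_table": table,
        "votes": votes,
        "winner": winner,
        "solution": solutions[winner],
        "solutions": solutions,
    }


# -- cross-wave stability ----------------------------------------------------


@dataclasses.dataclass
class StabilityReport:
    """Agreement between a reference solution and a fresh wave's solution."""

    matching: dict[int, int]
    profile_distances: dict[int, float]
    overall: dict[str, float]
    per_type_kappa: dict[int, float]
    unmatched: list[int]
    new_solution: ClusterSolution


def stability_compare(
    solution_ref: ClusterSolution,
    z_ref,
    z_new,
    config: ProtocolConfig,
) -> StabilityReport:
    """Cluster a new wave with the reference engine/k and score agreement.

    The new wave is clustered with the reference solution's algorithm and k;
    new prototypes are matched one-to-one to reference prototypes by minimal
    profile-similarity D (optimal assignment on Euclidean center distances).
    New-wave members are also allocated to reference types by an SVM trained
    on the reference solution; overall kappa/Rand/adjusted Rand and one-vs-
    rest kappa per matched type are reported.  A k mismatch matches on
    min(k) and flags the unmatched types.
    """
    x_ref = np.asarray(z_ref, dtype=float)
    x_new = np.asarray(z_new, dtype=float)
    shared: dict[str, Any] = {}
    seed = int(
        np.random.SeedSequence([config.seed, 131]).generate_state(1)[0] % (2**31)
    )
    new_solution = _fit_engine(
        solution_ref.algorithm, x_new, solution_ref.k, config, shared, seed
    )
    d_matrix = np.linalg.norm(
        new_solution.centers[:, None, :] - solution_ref.centers[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(d_matrix)
    matching = {int(r + 1): int(c + 1) for r, c in zip(rows, cols)}
    profile_distances = {
        int(c + 1): float(d_matrix[r, c]) for r, c in zip(rows, cols)
    }
    unmatched = [c for c in range(1, new_solution.k + 1) if c not in matching]
    matched_labels = np.asarray(
        [matching.get(lab, -lab) for lab in new_solution.labels]
    )
    predicted = svm_reclassify(x_ref, solution_ref.labels, x_new, config.svm)
    overall = {
        "kappa": indices.cohen_kappa(matched_labels, predicted, aligned=True),
        "rand": indices.rand_index(matched_labels, predicted),
        "adjusted_rand": indices.adjusted_rand(matched_labels, predicted),
    }
    per_type = {}
    for ref_type in sorted(set(matching.values())):
        per_type[ref_type] = indices.cohen_kappa(
            (matched_labels == ref_type).astype(int),
            (predicted == ref_type).astype(int),
            aligned=True,
        )
    return StabilityReport(
        matching=matching,
        profile_distances=profile_distances,
        overall=overall,
        per_type_kappa=per_type,
        unmatched=unmatched,
        new_solution=new_solution,
    )
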
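"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately use naive double loops over
explicit pair enumerations — independent of the vectorized implementations
they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import prototyper as pt


# -- brute-force oracles -----------------------------------------------------


def oracle_pair_comparisons(x: np.ndarray, labels: np.ndarray):
    """Enumerate every (within, between) pair-distance comparison."""
    n = len(x)
    within, between = [], []
    for i, j in itertools.combinations(range(n), 2):
        d = float(np.linalg.norm(x[i] - x[j]))
        (within if labels[i] == labels[j] else between).append(d)
    s_plus = sum(1 for w in within for b in between if w < b)
    s_minus = sum(1 for w in within for b in between if w > b)
    return s_plus, s_minus, within, between


def oracle_c_index(x: np.ndarray, labels: np.ndarray) -> float:
    _, _, within, between = oracle_pair_comparisons(x, labels)
    all_d = sorted(within + between)
    nw = len(within)
    s, s_min, s_max = sum(within), sum(all_d[:nw]), sum(all_d[-nw:])
    return (s - s_min) / (s_max - s_min)


def oracle_gdi31(x: np.ndarray, labels: np.ndarray) -> float:
    clusters = sorted(set(labels))
    diam = 0.0
    for c in clusters:
        pts = x[labels == c]
        for a, b in itertools.combinations(range(len(pts)), 2):
            diam = max(diam, float(np.linalg.norm(pts[a] - pts[b])))
    delta = np.inf
    for ci, cj in itertools.combinations(clusters, 2):
        pi, pj = x[labels == ci], x[labels == cj]
        dists = [float(np.linalg.norm(a - b)) for a in pi for b in pj]
        delta = min(delta, sum(dists) / len(dists))
    return delta / diam


def oracle_point_biserial(x: np.ndarray, labels: np.ndarray) -> float:
    """Pearson correlation between pair distance and the between-indicator."""
    n = len(x)
    dist, indicator = [], []
    for i, j in itertools.combinations(range(n), 2):
        dist.append(float(np.linalg.norm(x[i] - x[j])))
        indicator.append(0.0 if labels[i] == labels[j] else 1.0)
    return float(np.corrcoef(dist, indicator)[0, 1])


def oracle_silhouette(x: np.ndarray, labels: np.ndarray) -> float:
    n = len(x)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not own:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(x[i] - x[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(x[i] - x[j])
                     for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def oracle_rand(a: np.ndarray, b: np.ndarray) -> float:
    n = len(a)
    concordant = total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += 1
        if (a[i] == a[j]) == (b[i] == b[j]):
            concordant += 1
    return concordant / total


def oracle_adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """Hubert–Arabie closed form from the contingency table."""
    from math import comb

    a_vals, b_vals = sorted(set(a)), sorted(set(b))
    table = np.zeros((len(a_vals), len(b_vals)), dtype=int)
    for x, y in zip(a, b):
        table[a_vals.index(x), b_vals.index(y)] += 1
    sum_ij = sum(comb(int(v), 2) for v in table.ravel())
    sum_a = sum(comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in table.sum(axis=0))
    n_pairs = comb(len(a), 2)
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if np.array_equal(a, b) else 0.0
    return (sum_ij - expected) / (max_index - expected)


def oracle_kappa(a: np.ndarray, b: np.ndarray) -> float:
    cats = sorted(set(a) | set(b))
    n = len(a)
    p_o = np.mean([x == y for x, y in zip(a, b)])
    p_e = sum(
        np.mean([x == c for x in a]) * np.mean([y == c for y in b])
        for c in cats
    )
    return (p_o - p_e) / (1 - p_e)


def random_labeled_instance(rng: np.random.Generator, n_max: int = 30,
                            k_max: int = 4, d: int = 3):
    """A random data matrix with a random non-degenerate partition."""
    n = int(rng.integers(6, n_max + 1))
    k = int(rng.integers(2, min(k_max, n // 2) + 1))
    x = rng.normal(size=(n, d)) + rng.integers(0, 3, size=(n, 1)) * 1.5
    while True:
        labels = rng.integers(1, k + 1, size=n)
        if len(set(labels)) == k:
            return x, labels


# -- fixtures ----------------------------------------------------------------


@pytest.fixture(scope="session")
def planted_sample():
    """Default-config synthetic sample scored and standardized (n=2000)."""
    config = pt.GeneratorConfig(n_persons=2000, within_sd=0.4, seed=12345)
    items, truth = pt.generate_population(config)
    traits = pt.score_traits(items)
    z, moments = pt.zstandardize(traits)
    return {"config": config, "items": items, "truth": truth,
            "traits": traits, "z": z, "moments": moments}


@pytest.fixture(scope="session")
def two_far_clusters():
    """The worked 1-D instance {0,1} vs {10,11}."""
    x = np.array([[0.0], [1.0], [10.0], [11.0]])
    labels = np.array([1, 1, 2, 2])
    return x, labels


@pytest.fixture(scope="session")
def ring_data():
    """Two concentric rings: non-convex clusters in 2-D."""
    rng = np.random.default_rng(7)
    n = 120
    angles = rng.uniform(0, 2 * np.pi, size=2 * n)
    radii = np.concatenate([
        np.full(n, 1.0), np.full(n, 3.0)
    ]) + rng.normal(scale=0.05, size=2 * n)
    x = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    labels = np.repeat([1, 2], n)
    return x, labels
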
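"""The three clustering engines under a uniform contract.

* ``ward_kmeans`` — Ward agglomeration cut at k, cluster means seeding a
  single Lloyd's k-means run (the classic two-step procedure of the
  person-centered literature).
* ``lpa_fit`` — latent profile analysis: Gaussian mixtures over a small set
  of covariance families, best family by BIC, hard labels by maximum
  posterior.
* ``spectral_cluster`` — Ng–Jordan–Weiss normalized spectral clustering with
  an RBF affinity.

All engines return a :class:`ClusterSolution` with 1-based labels, centers
recomputed as per-cluster means, and algorithm-specific fit extras.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Any, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

#: Covariance families explored by latent profile analysis.  "spherical-equal"
#: shares one scalar variance across components and dimensions;
#: "spherical-varying" gives each component its own scalar variance.
LPA_FAMILIES = ("spherical-equal", "spherical-varying", "diagonal", "full")

_SKLEARN_COV = {
    "spherical-varying": "spherical",
    "diagonal": "diag",
    "full": "full",
}


class EngineError(RuntimeError):
    """A clustering engine could not produce a valid solution."""


@dataclasses.dataclass
class ClusterSolution:
    """A fitted partition: algorithm id, k, labels, centers and sizes.

    Labels are integers in ``1..k`` with no empty cluster; ``centers`` are
    recomputed per-cluster feature means (never trusted from the fitter);
    label integers carry no meaning beyond identity.
    """

    algorithm: str
    k: int
    labels: np.ndarray
    centers: np.ndarray
    sizes: np.ndarray
    fit_extras: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, self.k + 1)):
            raise EngineError(
                f"labels must cover 1..{self.k} with no empty cluster, got {uniq}"
            )


def _as_matrix(z: pd.DataFrame | np.ndarray) -> np.ndarray:
    x = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) else np.asarray(z, float)
    if x.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if np.isnan(x).any():
        raise ValueError("feature matrix must be complete (no NaN)")
    return x


def _relabel_dense(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Map arbitrary label values onto 1..k preserving first appearance."""
    uniq = np.unique(labels)
    lookup = {v: i + 1 for i, v in enumerate(uniq)}
    return np.array([lookup[v] for v in labels], dtype=int), len(uniq)


def _finalize(
    algorithm: str, x: np.ndarray, labels: np.ndarray, extras: dict[str, Any]
) -> ClusterSolution:
    labels, k = _relabel_dense(labels)
    centers = np.stack([x[labels == c].mean(axis=0) for c in range(1, k + 1)])
    sizes = np.bincount(labels, minlength=k + 1)[1:]
    return ClusterSolution(
        algorithm=algorithm, k=k, labels=labels, centers=centers, sizes=sizes,
        fit_extras=extras,
    )


# -- Ward followed by k-means ------------------------------------------------


def ward_kmeans(
    z: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    *,
    linkage_matrix: np.ndarray | None = None,
) -> ClusterSolution:
    """Ward agglomeration cut at ``k``, refined by Lloyd's k-means.

    The Ward cut's cluster means are the single k-means initialization;
    Lloyd iterations run to a 1e-6 center-movement tolerance (cap 300).
    A precomputed Ward ``linkage_matrix`` may be passed to amortize the
    agglomeration across several values of k.
    """
    x = _as_matrix(z)
    n = x.shape[0]
    if k < 2 or n <= k:
        if k == n:
            # degenerate: every point its own cluster
            return _finalize("ward_kmeans", x, np.arange(1, n + 1), {"inertia": 0.0})
        raise EngineError(f"need 2 <= k <= n, got k={k}, n={n}")
    if linkage_matrix is None:
        linkage_matrix = ward_linkage(x)
    ward_labels = fcluster(linkage_matrix, t=k, criterion="maxclust")
    init = np.stack([x[ward_labels == c].mean(axis=0) for c in np.unique(ward_labels)])
    if init.shape[0] != k:
        raise EngineError(f"Ward cut produced {init.shape[0]} clusters instead of {k}")
    km = KMeans(
        n_clusters=k, init=init, n_init=1, max_iter=300, tol=1e-6, random_state=seed
    ).fit(x)
    return _finalize(
        "ward_kmeans", x, km.labels_ + 1, {"inertia": float(km.inertia_)}
    )


def ward_linkage(x: np.ndarray) -> np.ndarray:
    """Ward linkage on Euclidean distances (reusable across cut levels)."""
    return linkage(x, method="ward")


# -- Latent profile analysis -------------------------------------------------


def _fit_spherical_equal(
    x: np.ndarray, k: int, seed: int, max_iter: int = 200, tol: float = 1e-5
) -> dict[str, Any]:
    """EM for a Gaussian mixture with one shared spherical variance.

    Initialized from k-means; the shared variance is floored at 1e-6 of the
    total variance to avoid degeneracy.
    """
    n, d = x.shape
    rng = np.random.default_rng(seed)
    km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(x)
    means = km.cluster_centers_.copy()
    weights = np.bincount(km.labels_, minlength=k).astype(float) / n
    weights = np.clip(weights, 1e-10, None)
    weights /= weights.sum()
    total_var = float(x.var(axis=0).sum() / d)
    var = max(total_var, 1e-12)
    floor = 1e-6 * total_var
    loglik = -np.inf
    for _ in range(max_iter):
        sq = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        log_prob = (
            -0.5 * sq / var - 0.5 * d * np.log(2 * np.pi * var) + np.log(weights)
        )
        norm = logsumexp(log_prob, axis=1)
        new_loglik = float(norm.sum())
        resp = np.exp(log_prob - norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            # re-seed a collapsed component at a random point
            dead = nk < 1e-10
            means[dead] = x[rng.integers(0, n, size=int(dead.sum()))]
            nk = np.clip(nk, 1e-10, None)
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        sq = ((x[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        var = max(float((resp * sq).sum() / (n * d)), floor)
        if abs(new_loglik - loglik) < tol * n:
            loglik = new_loglik
            break
        loglik = new_loglik
    posterior = resp
    # parameters: k*d means + 1 variance + (k-1) weights
    n_params = k * d + 1 + (k - 1)
    return {
        "labels": posterior.argmax(axis=1) + 1,
        "log_likelihood": loglik,
        "n_params": n_params,
        "posterior": posterior,
        "means": means,
        "variance": var,
        "weights": weights,
    }


def _lpa_n_params(family: str, k: int, d: int) -> int:
    mean_w = k * d + (k - 1)
    cov = {
        "spherical-equal": 1,
        "spherical-varying": k,
        "diagonal": k * d,
        "full": k * d * (d + 1) // 2,
    }[family]
    return mean_w + cov


def lpa_fit(
    z: pd.DataFrame | np.ndarray,
    k: int,
    families: Sequence[str] = LPA_FAMILIES,
    seed: int = 0,
) -> ClusterSolution:
    """Latent profile analysis: Gaussian mixture EM per covariance family,
    best family by BIC, hard assignment by maximum posterior probability."""
    x = _as_matrix(z)
    n, d = x.shape
    if not 1 <= k < n:
        raise EngineError(f"need 1 <= k < n, got k={k}, n={n}")
    unknown = set(families) - set(LPA_FAMILIES)
    if unknown:
        raise EngineError(f"unknown LPA families: {sorted(unknown)}")
    best: dict[str, Any] | None = None
    for family in families:
        if family == "spherical-equal":
            fit = _fit_spherical_equal(x, k, seed)
        else:
            gm = GaussianMixture(
                n_components=k,
                covariance_type=_SKLEARN_COV[family],
                n_init=2,
                random_state=seed,
                reg_covar=1e-6,
            ).fit(x)
            posterior = gm.predict_proba(x)
            fit = {
                "labels": gm.predict(x) + 1,
                "log_likelihood": float(gm.score(x) * n),
                "n_params": _lpa_n_params(family, k, d),
                "posterior": posterior,
                "means": gm.means_,
            }
        fit["family"] = family
        fit["bic"] = -2.0 * fit["log_likelihood"] + fit["n_params"] * np.log(n)
        fit["aic"] = -2.0 * fit["log_likelihood"] + 2.0 * fit["n_params"]
        if best is None or fit["bic"] < best["bic"]:
            best = fit
    assert best is not None
    labels = np.asarray(best["labels"])
    extras = {
        "family": best["family"],
        "log_likelihood": best["log_likelihood"],
        "n_params": best["n_params"],
        "aic": best["aic"],
        "bic": best["bic"],
        "posterior": best["posterior"],
    }
    return _finalize("lpa", x, labels, extras)


# -- Spectral clustering -----------------------------------------------------


def rbf_affinity(x: np.ndarray, bandwidth: float | None = None) -> np.ndarray:
    """Gaussian affinity ``exp(-d^2 / (2 sigma^2))`` with zero diagonal.

    Default bandwidth sigma = median pairwise Euclidean distance.
    """
    sq = np.sum(x**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T), 0.0)
    if bandwidth is None:
        d = np.sqrt(d2[np.triu_indices_from(d2, k=1)])
        bandwidth = float(np.median(d))
    if bandwidth <= 0:
        raise EngineError("affinity bandwidth must be positive")
    w = np.exp(-d2 / (2.0 * bandwidth**2))
    np.fill_diagonal(w, 0.0)
    return w


def spectral_embedding(
    affinity: np.ndarray, n_components: int
) -> np.ndarray:
    """Row-normalized first eigenvectors of the symmetric normalized
    Laplacian (the Ng–Jordan–Weiss embedding)."""
    degrees = affinity.sum(axis=1)
    if np.any(degrees <= 1e-300):
        raise EngineError(
            "similarity graph is disconnected (isolated vertex); "
            "increase the bandwidth or adjust the graph configuration"
        )
    inv_sqrt = 1.0 / np.sqrt(degrees)
    m = affinity * inv_sqrt[:, None] * inv_sqrt[None, :]
    # eigenvectors of L_sym = I - M for the smallest eigenvalues are the
    # top eigenvectors of M
    n = m.shape[0]
    eigvals, eigvecs = scipy.linalg.eigh(
        m, subset_by_index=[n - n_components, n - 1]
    )
    # connectivity check: multiplicity of eigenvalue 1 of M equals the
    # number of connected components
    if n_components >= 2 and eigvals[-2] > 1.0 - 1e-12:
        logger.warning("similarity graph appears to have multiple components")
    embedding = eigvecs[:, ::-1]
    norms = np.linalg.norm(embedding, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return embedding / norms


def spectral_cluster(
    z: pd.DataFrame | np.ndarray,
    k: int,
    bandwidth: float | None = None,
    seed: int = 0,
    *,
    embedding: np.ndarray | None = None,
) -> ClusterSolution:
    """Ng–Jordan–Weiss spectral clustering.

    RBF affinity (bandwidth = median pairwise distance unless given),
    symmetric normalized Laplacian, first k eigenvectors row-normalized,
    k-means with 10 restarts on the embedding.  A precomputed ``embedding``
    with >= k columns may be passed to amortize the eigendecomposition
    across several values of k.
    """
    x = _as_matrix(z)
    n = x.shape[0]
    if k < 2 or n <= k:
        raise EngineError(f"need 2 <= k <= n, got k={k}, n={n}")
    if embedding is None:
        embedding = spectral_embedding(rbf_affinity(x, bandwidth), k)
    if embedding.shape[1] < k:
        raise EngineError("precomputed embedding has fewer than k components")
    emb = embedding[:, :k]
    emb = emb / np.maximum(np.linalg.norm(emb, axis=1, keepdims=True), 1e-300)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
    return _finalize(
        "spectral", x, km.labels_ + 1,
        {"embedding_dim": k, "bandwidth": bandwidth},
    )
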
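"""Initial factor matrices for every (method family x strategy) pair.

Factorisation methods converge to local optima, so the starting point
matters.  Six strategies are provided: uninformed random matrices,
prototype-based clustering (K-means and fuzzy C-means), and feature
extraction (PCA, FastICA, and a short alternating-least-squares NMF run).

Two method families consume these initialisations differently.  The
non-negative family (euc, als, alspg, alsobs) needs ``W0`` (d x k) and
``H0`` (k x n), both non-negative; negative entries produced by PCA, ICA or
clustering are truncated to zero.  The convex family needs ``H0`` (k x n)
and ``A0`` (n x k), both *strictly* positive — multiplicative updates can
never escape an exact zero — which is guaranteed by the ``+ 0.2 E`` offset
in the construction formulas (``E`` is the all-ones matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import FastICA

from .errors import ValidationError
from .spectra_io import SpectrumTable

NONNEG_METHODS = ("euc", "als", "alspg", "alsobs")
STRATEGIES = ("random", "kmeans", "fcm", "pca", "fastica", "nmf_als")


@dataclass
class InitState:
    """Initial matrices for a factorisation run.

    ``W0`` is absent for the convex family (W is determined by ``V @ A``);
    ``A0`` is absent for the non-negative family.
    """

    W0: np.ndarray | None
    H0: np.ndarray
    A0: np.ndarray | None
    strategy: str
    method_family: str
    seed: int

    def validate(self, d: int, n: int, k: int) -> None:
        if self.H0.shape != (k, n):
            raise ValidationError(f"H0 shape {self.H0.shape} != {(k, n)}")
        if self.method_family == "convex":
            if self.A0 is None or self.A0.shape != (n, k):
                raise ValidationError("convex family requires A0 of shape (n, k)")
            if self.A0.min() <= 0 or self.H0.min() <= 0:
                raise ValidationError("convex family requires strictly positive H0 and A0")
        else:
            if self.W0 is None or self.W0.shape != (d, k):
                raise ValidationError("nonneg family requires W0 of shape (d, k)")
            if self.W0.min() < 0 or self.H0.min() < 0:
                raise ValidationError("nonneg family requires non-negative W0 and H0")


# ---------------------------------------------------------------------------
# fuzzy C-means (Bezdek), seeded multi-restart

def fuzzy_c_means(
    X: np.ndarray,
    k: int,
    fuzzifier: float = 2.0,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy C-means on rows of ``X`` (n points x d features).

    Returns ``(centers, memberships)`` with centers ``(k, d)`` and the fuzzy
    partition matrix ``(n, k)``, rows summing to one.  Best of
    ``n_restarts`` seeded restarts by the fuzzy objective.
    """
    n = X.shape[0]
    if n < k:
        raise ValidationError(f"cannot form {k} clusters from {n} points")
    m = float(fuzzifier)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        U = rng.random((n, k)) + 1e-9
        U /= U.sum(axis=1, keepdims=True)
        obj_prev = np.inf
        for _ in range(max_iter):
            Um = U**m
            centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            d2 = np.maximum(d2, 1e-12)
            inv = d2 ** (-1.0 / (m - 1.0))
            U = inv / inv.sum(axis=1, keepdims=True)
            obj = float((U**m * d2).sum())
            if abs(obj_prev - obj) < tol:
                break
            obj_prev = obj
        if best is None or obj < best[0]:
            best = (obj, centers, U)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# convex-family constructions

def indicator_to_convex_init(
    cluster_matrix: np.ndarray, cluster_sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Build (H0, A0) for convex factorisation from a cluster indicator.

    With ``C`` the (n x k) hard or fuzzy membership matrix, ``E`` all ones
    and ``D = diag(cluster sizes)``::

        H0 = (C + 0.2 E)^T          (k x n)
        A0 = (C + 0.2 E) D^{-1}     (n x k)

    Both are strictly positive by construction.
    """
    C = np.atleast_2d(np.asarray(cluster_matrix, dtype=float))
    sizes = np.asarray(cluster_sizes, dtype=float).ravel()
    if C.min() < 0 or C.max() > 1:
        raise ValidationError("cluster matrix entries must lie in [0, 1]")
    if sizes.shape[0] != C.shape[1]:
        raise ValidationError("one cluster size per cluster column required")
    if np.any(sizes <= 0):
        raise ValidationError("every cluster must be non-empty")
    offset = C + 0.2
    return offset.T.copy(), offset / sizes[None, :]


def mean_of_nonzeros(X: np.ndarray) -> float:
    """Sum of absolute values divided by the number of nonzero elements."""
    nnz = np.count_nonzero(X)
    if nnz == 0:
        raise ValidationError("matrix has no nonzero elements")
    return float(np.abs(X).sum() / nnz)


def basis_to_convex_init(H_candidate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Build (H0, A0) for convex factorisation from a basis-derived candidate.

    The candidate mixing matrix (k x n), as produced by PCA, FastICA or an
    NMF pre-run, may carry negative entries.  They are truncated and the
    all-ones offset is added, ``H0 = max(Hc, 0) + 0.2 E``; then
    ``A = H0^T (H0 H0^T)^{-1}`` (pseudo-inverse when singular) is split to
    its positive part and re-offset::

        A0 = (A)^+ + 0.2 <(A)^+> E

    where ``<X>`` is the mean absolute value over the nonzero entries of X.
    """
    Hc = np.atleast_2d(np.asarray(H_candidate, dtype=float))
    if not np.any(Hc):
        raise ValidationError("candidate H is identically zero")
    H0 = np.maximum(Hc, 0.0) + 0.2
    G = H0 @ H0.T
    try:
        A = H0.T @ np.linalg.inv(G)
    except np.linalg.LinAlgError:
        A = H0.T @ np.linalg.pinv(G)
    if not np.all(np.isfinite(A)):
        A = H0.T @ np.linalg.pinv(G)
    Apos = np.maximum(A, 0.0)
    A0 = Apos + 0.2 * mean_of_nonzeros(Apos)
    return H0, A0


# ---------------------------------------------------------------------------
# strategy implementations (shared candidates)

def _kmeans_fit(X: np.ndarray, k: int, seed: int) -> KMeans:
    if np.unique(X, axis=0).shape[0] < k:
        raise ValidationError(f"fewer than {k} distinct cases; cannot cluster")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31))
    km.fit(X)
    return km

def _pca_candidate(V: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """SVD of the row-mean-centred data: W candidate = scaled left singular
    vectors (principal axes), H candidate = right singular vectors."""
    Vc = V - V.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Vc, full_matrices=False)
    return U[:, :k] * s[:k], Vt[:k, :]

def _fastica_candidate(V: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    ica = FastICA(n_components=k, random_state=seed % (2**31), max_iter=1000, tol=1e-4)
    S = ica.fit_transform(V)          # (d, k) independent component spectra
    return S, ica.mixing_.T           # mixing (n, k) -> H candidate (k, n)

def _nmf_als_candidate(V: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    from . import nmf_core  # deferred: nmf_core is downstream of this module

    Vn = np.abs(V)
    rng = np.random.default_rng(seed)
    W = rng.random((V.shape[0], k)) + 1e-6
    H = rng.random((k, V.shape[1])) + 1e-6
    f_prev = nmf_core.reconstruction_error(Vn, W, H)
    for _ in range(200):
        W, H = nmf_core.update_als(W, H, Vn)
        f = nmf_core.reconstruction_error(Vn, W, H)
        if abs(f_prev - f) < 1e-5:
            break
        f_prev = f
    return W, H


def initialize(
    table: SpectrumTable,
    k: int,
    strategy: str,
    method_family: str,
    seed: int,
    fcm_fuzzifier: float = 2.0,
) -> InitState:
    """Produce an :class:`InitState` for the requested strategy and family.

    The same seed and inputs always return bit-identical matrices.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}")
    if method_family not in ("nonneg", "convex"):
        raise ValidationError(f"unknown method family {method_family!r}")
    V = table.intensities
    d, n = V.shape
    if not 1 <= k < d:
        raise ValidationError(f"number of sources k={k} must satisfy 1 <= k < d={d}")
    if n < k:
        raise ValidationError(f"need at least k={k} cases, got n={n}")

    rng = np.random.default_rng(seed)
    W0: np.ndarray | None = None
    A0: np.ndarray | None = None

    if strategy == "random":
        # uniform (0,1); the tiny floor keeps convex multiplicative updates
        # strictly positive
        H0 = rng.random((k, n)) + 1e-9
        if method_family == "convex":
            A0 = rng.random((n, k)) + 1e-9
        else:
            W0 = rng.random((d, k)) + 1e-9
    elif strategy == "kmeans":
        km = _kmeans_fit(V.T, k, seed)
        if method_family == "convex":
            C = np.zeros((n, k))
            C[np.arange(n), km.labels_] = 1.0
            sizes = np.bincount(km.labels_, minlength=k).astype(float)
            if np.any(sizes == 0):
                raise ValidationError("K-means produced an empty cluster")
            H0, A0 = indicator_to_convex_init(C, sizes)
        else:
            W0 = km.cluster_centers_.T.copy()
            W0 = np.maximum(W0, 0.0)
            # H rows hold Euclidean distances from every case to each centroid
            H0 = np.linalg.norm(
                V.T[:, None, :] - km.cluster_centers_[None, :, :], axis=2
            ).T
    elif strategy == "fcm":
        centers, U = fuzzy_c_means(V.T, k, fuzzifier=fcm_fuzzifier, seed=seed)
        if method_family == "convex":
            # soft cluster sizes: column sums of the fuzzy partition, the
            # natural fuzzy analogue of "points per cluster" (and never zero)
            sizes = U.sum(axis=0)
            H0, A0 = indicator_to_convex_init(U, sizes)
        else:
            W0 = np.maximum(centers.T.copy(), 0.0)
            H0 = U.T.copy()
    else:
        if strategy == "pca":
            Wc, Hc = _pca_candidate(V, k)
        elif strategy == "fastica":
            Wc, Hc = _fastica_candidate(V, k, seed)
        else:  # nmf_als
            Wc, Hc = _nmf_als_candidate(V, k, seed)
        if method_family == "convex":
            H0, A0 = basis_to_convex_init(Hc)
        else:
            W0 = np.maximum(Wc, 0.0)
            H0 = np.maximum(Hc, 0.0)

    state = InitState(W0=W0, H0=H0, A0=A0, strategy=strategy,
                      method_family=method_family, seed=seed)
    state.validate(d, n, k)
    return state
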
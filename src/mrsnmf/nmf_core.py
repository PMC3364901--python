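"""The five factorisation algorithms and their convergence control.

All methods minimise the half-squared-Frobenius reconstruction error

    f(W, H) = 1/2 ||V - W H||_F^2

subject to non-negativity constraints that differ by method:

``euc``
    Multiplicative updates (Lee-Seung); monotone descent, non-negative W
    and H, columns of W rescaled to sum to one after each update.
``als``
    Alternating least squares: exact unconstrained LS for one factor with
    the other fixed, negatives zeroed afterwards.
``alspg``
    Alternating non-negative LS solved by projected gradient descent with
    backtracking line search.
``alsobs``
    ALS where, instead of plain zeroing, pruned (negative) coordinates are
    removed with an Optimal-Brain-Surgeon second-order correction that
    re-adjusts the surviving coordinates using the inverse LS Hessian.
``convex``
    Convex NMF (Ding et al. style): W = V A with A >= 0, H >= 0, V of
    arbitrary sign.  Updates are multiplicative in A and H and depend on V
    only through the Gram matrix G = V^T V, split into positive and
    negative parts.

Iteration stops when the absolute change in f between consecutive
iterations drops below the tolerance (default 1e-5) or the iteration cap
is hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .initializations import InitState
from .preprocess import to_nonnegative
from .spectra_io import SpectrumTable

_EPS = 1e-12

METHODS = ("euc", "als", "alspg", "alsobs", "convex")


@dataclass
class FactorizationOptions:
    """Tunable knobs shared by the factorisation drivers.

    ``tolerance`` is the absolute change in the objective below which the
    run is declared converged.  ``pg_*`` control the projected-gradient
    backtracking line search (initial step, shrink ratio, sufficient
    decrease constant).
    """

    tolerance: float = 1e-5
    max_iterations: int = 2000
    pg_initial_step: float = 1.0
    pg_beta: float = 0.1
    pg_sigma: float = 0.01
    pg_max_backtracks: int = 20

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValidationError("tolerance must be >= 0")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass
class FactorizationResult:
    """Outcome of a factorisation run: V ~ W H (and W = V A for convex)."""

    W: np.ndarray
    H: np.ndarray
    A: np.ndarray | None
    method: str
    init_strategy: str
    seed: int
    error_trace: np.ndarray
    iterations: int
    tolerance: float
    converged: bool
    nonnegative_transformed: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.W.shape[1]

    @property
    def final_error(self) -> float:
        return float(self.error_trace[-1])


def reconstruction_error(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Half the squared Frobenius norm of the residual V - W H."""
    V, W, H = np.atleast_2d(V), np.atleast_2d(W), np.atleast_2d(H)
    if W.shape[0] != V.shape[0] or H.shape[1] != V.shape[1] or W.shape[1] != H.shape[0]:
        raise ValidationError(
            f"shapes do not conform: V{V.shape}, W{W.shape}, H{H.shape}"
        )
    R = V - W @ H
    return 0.5 * float(np.sum(R * R))


# ---------------------------------------------------------------------------
# euc: multiplicative updates

def update_euc(W: np.ndarray, H: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative update of (W, H), W first.

    After the W update its columns are rescaled to sum to one, with the
    inverse scaling applied to the rows of H so the product W H (and hence
    the objective) is unchanged.  The H update uses the freshly updated W.
    """
    if V.min() < 0 or W.min() < 0 or H.min() < 0:
        raise ValidationError("euc updates require non-negative V, W, H")
    W = W * (V @ H.T) / (W @ (H @ H.T) + _EPS)
    col = W.sum(axis=0)
    col = np.where(col == 0, 1.0, col)
    W = W / col
    H = H * col[:, None]
    H = H * (W.T @ V) / ((W.T @ W) @ H + _EPS)
    return W, H


# ---------------------------------------------------------------------------
# als: exact alternating least squares with clipping

def _ls_solve_W(H: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Unconstrained minimiser of f over W: V H^T (H H^T)^{-1}."""
    G = H @ H.T
    try:
        return np.linalg.solve(G, H @ V.T).T
    except np.linalg.LinAlgError:
        return (np.linalg.pinv(G) @ H @ V.T).T


def _ls_solve_H(W: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Unconstrained minimiser of f over H: (W^T W)^{-1} W^T V."""
    G = W.T @ W
    try:
        return np.linalg.solve(G, W.T @ V)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(G) @ W.T @ V


def update_als(W: np.ndarray, H: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One ALS sweep: LS solve for W, zero negatives; same for H against
    the updated W."""
    W = np.maximum(_ls_solve_W(H, V), 0.0)
    H = np.maximum(_ls_solve_H(W, V), 0.0)
    return W, H


# ---------------------------------------------------------------------------
# alspg: projected gradient sub-problems

def _pg_step(
    X: np.ndarray,
    grad_fn,
    obj_fn,
    options: FactorizationOptions,
) -> tuple[np.ndarray, bool]:
    """One projected-gradient step with Armijo backtracking.

    Returns the new iterate and whether the line search succeeded; on
    failure the input is returned unchanged.
    """
    g = grad_fn(X)
    f0 = obj_fn(X)
    alpha = options.pg_initial_step
    for _ in range(options.pg_max_backtracks):
        Xn = np.maximum(X - alpha * g, 0.0)
        dX = Xn - X
        if obj_fn(Xn) - f0 <= options.pg_sigma * float(np.sum(g * dX)):
            return Xn, True
        alpha *= options.pg_beta
    return X, False


def update_alspg(
    W: np.ndarray,
    H: np.ndarray,
    V: np.ndarray,
    options: FactorizationOptions | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One alternating projected-gradient sweep (W first, then H).

    Each sub-step is H <- P[H - alpha W^T(W H - V)] (and symmetrically for
    W), with P the projection onto the non-negative orthant and alpha from
    a backtracking line search that enforces sufficient decrease.  The
    third return value reports line-search success on both sub-steps.
    """
    options = options or FactorizationOptions()
    W, ok_w = _pg_step(
        W,
        grad_fn=lambda X: (X @ H - V) @ H.T,
        obj_fn=lambda X: reconstruction_error(V, X, H),
        options=options,
    )
    H, ok_h = _pg_step(
        H,
        grad_fn=lambda X: W.T @ (W @ X - V),
        obj_fn=lambda X: reconstruction_error(V, W, X),
        options=options,
    )
    return W, H, ok_w and ok_h


# ---------------------------------------------------------------------------
# alsobs: ALS with Optimal-Brain-Surgeon pruning

def _obs_adjust_rows(B: np.ndarray, Hess: np.ndarray) -> np.ndarray:
    """Prune negative coordinates of each row of the LS solution ``B`` with
    OBS second-order corrections.

    Each row solves an independent LS problem with the shared Hessian
    ``Hess``.  Pruning a coordinate q applies the correction
    ``-B_q * Hinv[:, q] / Hinv[q, q]`` to the row (which zeroes B_q exactly
    and re-optimises the survivors); coordinates are pruned most-negative
    first, with the Hessian inverse recomputed on the remaining free set so
    every prune is an exact equality-constrained re-solve.  Raises
    LinAlgError on a singular Hessian (callers fall back to clipping).
    """
    k = Hess.shape[0]
    out = B.copy()
    base_inv = np.linalg.inv(Hess)  # raises if singular
    for i in range(B.shape[0]):
        row = out[i]
        if row.min() >= 0:
            continue
        free = np.arange(k)
        Hinv = base_inv
        while True:
            neg = np.nonzero(row[free] < 0)[0]
            if neg.size == 0:
                break
            q = neg[np.argmin(row[free][neg])]
            if Hinv[q, q] == 0:
                raise np.linalg.LinAlgError("degenerate OBS pivot")
            row[free] += -row[free][q] * Hinv[:, q] / Hinv[q, q]
            row[free[q]] = 0.0
            free = np.delete(free, q)
            if free.size == 0:
                break
            Hinv = np.linalg.inv(Hess[np.ix_(free, free)])
        out[i] = np.maximum(row, 0.0)  # clear any residual round-off negatives
    return out


def update_alsobs(
    W: np.ndarray,
    H: np.ndarray,
    V: np.ndarray,
    options: FactorizationOptions | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One ALS sweep where negatives are pruned via OBS re-adjustment.

    When no coordinate is negative the output equals :func:`update_als`
    exactly; on a singular Hessian the sweep falls back to plain clipping
    with a warning.
    """
    W_ls = _ls_solve_W(H, V)
    try:
        W = _obs_adjust_rows(W_ls, H @ H.T)
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian in OBS step for W; falling back to clipping")
        W = np.maximum(W_ls, 0.0)
    H_ls = _ls_solve_H(W, V)
    try:
        H = _obs_adjust_rows(H_ls.T, W.T @ W).T
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian in OBS step for H; falling back to clipping")
        H = np.maximum(H_ls, 0.0)
    return W, H


# ---------------------------------------------------------------------------
# convex: multiplicative updates on A and H with sign-split Gram matrix

def split_signs(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positive/negative part decomposition: M = M_pos - M_neg, both >= 0."""
    M = np.asarray(M, dtype=float)
    return np.maximum(M, 0.0), np.maximum(-M, 0.0)


def update_convex(
    A: np.ndarray,
    H: np.ndarray,
    V: np.ndarray | None = None,
    G: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One convex-NMF multiplicative update of (H, A), H first.

    With G = V^T V split into G+ and G-::

        H^T <- H^T * sqrt[ (G+ A + H^T A^T G- A) / (G- A + H^T A^T G+ A) ]
        A   <- A   * sqrt[ (G+ H^T + G- A H H^T) / (G- H^T + G+ A H H^T) ]

    ``G`` may be passed precomputed (it is constant within a run).
    """
    if G is None:
        if V is None:
            raise ValidationError("either V or its Gram matrix G is required")
        G = V.T @ V
    Gp, Gn = split_signs(G)
    Ht = H.T
    num = Gp @ A + Ht @ (A.T @ (Gn @ A))
    den = Gn @ A + Ht @ (A.T @ (Gp @ A))
    Ht = Ht * np.sqrt(num / (den + _EPS))
    H = Ht.T
    HHt = H @ Ht
    num = Gp @ Ht + Gn @ (A @ HHt)
    den = Gn @ Ht + Gp @ (A @ HHt)
    A = A * np.sqrt(num / (den + _EPS))
    return A, H


# ---------------------------------------------------------------------------
# driver

def factorize(
    table: SpectrumTable,
    k: int,
    method: str,
    init: InitState,
    options: FactorizationOptions | None = None,
) -> FactorizationResult:
    """Iterate the chosen method until the error change falls below tolerance.

    Non-convex-family methods require non-negative data; mixed-sign input
    is passed through the absolute-value transform first and the result is
    flagged.  Convex factorisation consumes the data as-is and maintains
    W = V A throughout.
    """
    options = options or FactorizationOptions()
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    d, n = table.d, table.n
    if not 1 <= k < d:
        raise ValidationError(f"number of sources k={k} must satisfy 1 <= k < d={d}")
    family = "convex" if method == "convex" else "nonneg"
    if init.method_family != family:
        raise ValidationError(
            f"init built for family {init.method_family!r} cannot drive method {method!r}"
        )
    init.validate(d, n, k)

    transformed = False
    if method != "convex" and table.intensities.min() < 0:
        table = to_nonnegative(table)
        transformed = True
    V = table.intensities

    run_warnings: list[str] = []
    trace: list[float] = []

    if method == "convex":
        A, H = init.A0.copy(), init.H0.copy()
        G = V.T @ V
        f_prev = reconstruction_error(V, V @ A, H)
        trace.append(f_prev)
        converged = False
        it = 0
        for it in range(1, options.max_iterations + 1):
            A, H = update_convex(A, H, G=G)
            f = reconstruction_error(V, V @ A, H)
            trace.append(f)
            if abs(f_prev - f) < options.tolerance:
                converged = True
                break
            f_prev = f
        W = V @ A
        return FactorizationResult(
            W=W, H=H, A=A, method=method, init_strategy=init.strategy,
            seed=init.seed, error_trace=np.asarray(trace), iterations=it,
            tolerance=options.tolerance, converged=converged,
            nonnegative_transformed=transformed, warnings=run_warnings,
        )

    W, H = init.W0.copy(), init.H0.copy()
    f_prev = reconstruction_error(V, W, H)
    trace.append(f_prev)
    converged = False
    it = 0
    for it in range(1, options.max_iterations + 1):
        if method == "euc":
            W, H = update_euc(W, H, V)
        elif method == "als":
            W, H = update_als(W, H, V)
        elif method == "alspg":
            W, H, ok = update_alspg(W, H, V, options)
            if not ok:
                run_warnings.append(f"iteration {it}: projected-gradient line search stalled")
        else:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                W, H = update_alsobs(W, H, V, options)
            run_warnings.extend(str(c.message) for c in caught)
        f = reconstruction_error(V, W, H)
        trace.append(f)
        if abs(f_prev - f) < options.tolerance:
            converged = True
            break
        f_prev = f
    return FactorizationResult(
        W=W, H=H, A=None, method=method, init_strategy=init.strategy,
        seed=init.seed, error_trace=np.asarray(trace), iterations=it,
        tolerance=options.tolerance, converged=converged,
        nonnegative_transformed=transformed, warnings=run_warnings,
    )
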
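"""Max-cut solvers for conflict graphs.

The learning step needs, per module, a bipartition of the 2^{n_m} input
configurations maximising the total weight of crossing edges (the 0-1
quadratic program ``max sum_{u<v} w_uv (x_u + x_v - 2 x_u x_v)``).  Two
routes are provided:

* **exact** — vectorised enumeration of all 2^{n-1} partitions (the cut is
  complement-invariant so vertex 1 is pinned to side 0).  Fast up to ~20
  vertices, which covers modules with up to ~5 inputs exactly.
* **sdp_rounded** — the Goemans–Williamson scheme: solve the semidefinite
  relaxation, round with random hyperplanes, keep the best cut.  The
  relaxation is solved by low-rank (Burer–Monteiro) factorisation: unit
  vectors ``v_i`` in rank ``k > sqrt(2n)`` optimised with L-BFGS, for which
  the factorised landscape generically has no spurious local optima.  Each
  distinct rounded partition is refined by single-vertex-swap local search
  (optional, on by default), which can only improve the cut.

Randomised rounding carries the classical expected guarantee of 0.87 times
the optimum; best-of-R rounding plus local search clears it in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import minimize

from .conflict import ConflictGraph
from .exceptions import CapacityError, InvalidInputError

logger = logging.getLogger(__name__)

#: Largest vertex count routed to the exact solver by default.
DEFAULT_EXACT_CAP = 20
DEFAULT_N_ROUNDINGS = 1000


@dataclass
class MaxCutConfig:
    """Solver settings shared by the dispatch entry point."""

    exact_cap: int = DEFAULT_EXACT_CAP
    n_roundings: int = DEFAULT_N_ROUNDINGS
    local_search: bool = True
    seed: Optional[int] = None


@dataclass
class CutSolution:
    """A vertex bipartition and its cut value.

    ``assignment[u] = 1`` places vertex ``u+1`` in the cut's side-1 set.
    ``method`` records how the cut was obtained (``exact`` or
    ``sdp_rounded``, the latter suffixed ``+ls`` when local search ran).
    """

    assignment: np.ndarray
    cut_value: float
    method: str
    n_roundings: Optional[int] = None
    seed: Optional[int] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int8)


def _weights(graph: Union[ConflictGraph, np.ndarray]) -> np.ndarray:
    W = graph.weights if isinstance(graph, ConflictGraph) else np.asarray(graph)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvalidInputError("weight matrix must be square")
    if not np.allclose(W, W.T):
        raise InvalidInputError("weight matrix must be symmetric")
    if (np.asarray(W) < 0).any():
        raise InvalidInputError("negative edge weights are not supported")
    return np.asarray(W, dtype=np.float64)


def cut_value(graph: Union[ConflictGraph, np.ndarray], assignment) -> float:
    """Evaluate ``sum_{u<v} w_uv (x_u + x_v - 2 x_u x_v)`` for a partition."""
    W = _weights(graph)
    x = np.asarray(assignment, dtype=np.float64)
    return float(x @ W @ (1.0 - x))


def solve_maxcut_exact(
    graph: Union[ConflictGraph, np.ndarray], cap: int = DEFAULT_EXACT_CAP
) -> CutSolution:
    """Globally optimal cut by enumeration of all partitions with x_1 = 0.

    Ties are broken toward the lexicographically smallest assignment, making
    fitted models reproducible.
    """
    W = _weights(graph)
    n = W.shape[0]
    if n > cap:
        raise CapacityError(
            f"{n} vertices exceeds the exact-solver cap of {cap}; "
            "use solve_maxcut_sdp"
        )
    if n == 1:
        return CutSolution(np.zeros(1), 0.0, "exact")

    best_value = -1.0
    best_bits: Optional[np.ndarray] = None
    free = n - 1  # vertex 1 pinned to side 0
    shifts = np.arange(free - 1, -1, -1, dtype=np.uint32)
    chunk = 1 << 16
    for start in range(0, 1 << free, chunk):
        idx = np.arange(start, min(start + chunk, 1 << free), dtype=np.uint32)
        bits = ((idx[:, None] >> shifts[None, :]) & 1).astype(np.float64)
        X = np.concatenate([np.zeros((len(idx), 1)), bits], axis=1)
        values = np.einsum("ij,jk,ik->i", X, W, 1.0 - X)
        top = int(np.argmax(values))  # first max = lexicographically smallest
        if values[top] > best_value:
            best_value = float(values[top])
            best_bits = X[top]
    assert best_bits is not None
    return CutSolution(best_bits, best_value, "exact")


# ---- Goemans–Williamson route ---------------------------------------------


def _solve_relaxation(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Solve the max-cut SDP via low-rank factorisation.

    Returns unit row-vectors V (n x k) maximising sum w_ij (1 - v_i.v_j)/2,
    i.e. minimising <W, V V^T>.
    """
    n = W.shape[0]
    k = min(n, int(np.ceil(np.sqrt(2 * n))) + 1)

    def objective(u_flat: np.ndarray):
        U = u_flat.reshape(n, k)
        norms = np.linalg.norm(U, axis=1, keepdims=True)
        V = U / norms
        G = W @ V
        value = float(np.sum(G * V))
        # gradient of v_i = u_i/|u_i| chain rule: project G rows off v_i
        grad_v = 2.0 * G
        grad_u = (grad_v - np.sum(grad_v * V, axis=1, keepdims=True) * V) / norms
        return value, grad_u.ravel()

    best_val = np.inf
    best_V = None
    for _ in range(2):  # cheap restarts guard against rare bad basins
        u0 = rng.standard_normal((n, k)).ravel()
        res = minimize(
            objective, u0, jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if res.fun < best_val:
            best_val = res.fun
            best_V = res.x.reshape(n, k)
    if best_V is None or not np.isfinite(best_val):
        raise ArithmeticError("SDP relaxation failed to converge")
    return best_V / np.linalg.norm(best_V, axis=1, keepdims=True)


def _local_search(W: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Greedy single-vertex swaps until no flip improves the cut."""
    x = x.astype(np.float64).copy()
    d = W.sum(axis=1)
    while True:
        s = W @ x
        delta = (1.0 - 2.0 * x) * (d - 2.0 * s)
        u = int(np.argmax(delta))
        if delta[u] <= 1e-9:
            return x
        x[u] = 1.0 - x[u]


def _canonical(x: np.ndarray) -> np.ndarray:
    """Complement-normalise so vertex 1 sits on side 0."""
    x = x.astype(np.int8)
    return (1 - x) if x[0] == 1 else x


def solve_maxcut_sdp(
    graph: Union[ConflictGraph, np.ndarray],
    seed: Optional[int] = None,
    n_roundings: int = DEFAULT_N_ROUNDINGS,
    local_search: bool = True,
) -> CutSolution:
    """Semidefinite relaxation + randomized hyperplane rounding.

    Draws ``n_roundings`` random hyperplanes, rounds each to a partition,
    optionally refines every distinct partition by 1-swap local search, and
    returns the best cut found (ties broken lexicographically on the
    canonicalised assignment).  Deterministic given ``seed``.
    """
    W = _weights(graph)
    n = W.shape[0]
    if n < 2:
        raise InvalidInputError("SDP solver needs at least 2 vertices")
    if n_roundings < 1:
        raise InvalidInputError("n_roundings must be >= 1")
    method = "sdp_rounded+ls" if local_search else "sdp_rounded"
    if W.sum() == 0:
        return CutSolution(
            np.zeros(n), 0.0, method, n_roundings, seed, degenerate=True
        )
    rng = np.random.default_rng(seed)
    V = _solve_relaxation(W, rng)
    sdp_objective = 0.25 * float(np.sum(W * (1.0 - V @ V.T)))

    R = rng.standard_normal((V.shape[1], n_roundings))
    cuts = (V @ R > 0).T.astype(np.int8)  # n_roundings x n
    cuts ^= cuts[:, :1]  # canonical: vertex 1 on side 0
    candidates = np.unique(cuts, axis=0)

    best: Optional[np.ndarray] = None
    best_value = -1.0
    for x in candidates:
        if local_search:
            x = _canonical(_local_search(W, x.astype(np.float64)))
        value = cut_value(W, x)
        if value > best_value + 1e-9 or (
            abs(value - best_value) <= 1e-9
            and best is not None
            and tuple(x) < tuple(best)
        ):
            best_value = value
            best = np.asarray(x, dtype=np.int8)
    assert best is not None
    logger.debug(
        "maxcut sdp: n=%d sdp_objective=%.3f best_cut=%.3f gap=%.3f",
        n, sdp_objective, best_value, sdp_objective - best_value,
    )
    return CutSolution(best, best_value, method, n_roundings, seed)


def solve_maxcut(
    graph: Union[ConflictGraph, np.ndarray],
    config: Optional[MaxCutConfig] = None,
) -> CutSolution:
    """Dispatch: exact enumeration up to ``config.exact_cap`` vertices,
    otherwise the SDP route."""
    config = config or MaxCutConfig()
    W = _weights(graph)
    if W.shape[0] <= config.exact_cap:
        return solve_maxcut_exact(W, cap=config.exact_cap)
    return solve_maxcut_sdp(
        W,
        seed=config.seed,
        n_roundings=config.n_roundings,
        local_search=config.local_search,
    )
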
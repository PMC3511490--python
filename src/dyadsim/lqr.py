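"""Discrete-time LQR synthesis: stationary Riccati solutions and gains.

The stationary gain is obtained by iterating the finite-horizon Riccati
backward recursion

    K_k = (R + B' P_k B)^{-1} B' P_k A
    P_{k+1} = Q + A' P_k (A - B K_k)

until the GAIN stops changing.  Gain convergence, rather than value
convergence, is the stopping rule on purpose: the rigidly coupled dyad has
uncontrollable difference modes on the unit circle (both agents' kinematic
copies are driven by the same total force, so ``v1 - v2`` and ``e1 - e2``
are constants of the motion).  When such a mode carries state weight the
value matrix P grows without bound along it, yet the feedback gain still
converges — and equals, on the rigid-coupling manifold, the stabilizing
solution of the reduced well-posed problem.  For indefinite Q (competition
costs) a stationary solution need not exist at all and a plain finite
horizon is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .behaviors import CostWeights, build_Q
from .dyad import DyadSystem

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 100_000


class DareError(RuntimeError):
    """Raised when no (gain-)convergent Riccati solution is found."""


@dataclass(frozen=True)
class RiccatiSolution:
    """Value matrix ``P``, gain ``K``, iteration count and final residuals.

    ``p_converged`` is False when only the gain converged (marginal
    uncontrollable modes observable in the cost); ``residual`` is then the
    gain residual rather than the DARE fixed-point residual.
    """

    P: np.ndarray
    K: np.ndarray
    iterations: int
    residual: float
    p_converged: bool = True


def _riccati_iterate(
    A: np.ndarray, B: np.ndarray, Q: np.ndarray, R: np.ndarray,
    tol: float, max_iter: int,
) -> RiccatiSolution:
    P = Q.astype(float).copy()
    K = None
    p_res = np.inf
    # the cost takes several steps to propagate through the kinematic/muscle
    # chain, during which the gain sits at zero: never accept gain-stationarity
    # before the horizon exceeds a few state dimensions
    warmup = 5 * A.shape[0]
    for i in range(1, max_iter + 1):
        BtP = B.T @ P
        M = R + BtP @ B
        try:
            Knew = np.linalg.solve(M, BtP @ A)
        except np.linalg.LinAlgError as exc:
            raise DareError(f"singular (R + B'PB) at iteration {i}") from exc
        Pnew = Q + A.T @ P @ (A - B @ Knew)
        Pnew = 0.5 * (Pnew + Pnew.T)
        if not np.all(np.isfinite(Pnew)):
            raise DareError(f"Riccati recursion diverged at iteration {i}")
        p_res = np.max(np.abs(Pnew - P)) / (1.0 + np.max(np.abs(Pnew)))
        if K is not None:
            k_res = np.max(np.abs(Knew - K)) / (1.0 + np.max(np.abs(Knew)))
            if p_res < tol:
                return RiccatiSolution(Pnew, Knew, i, p_res, p_converged=True)
            if k_res < tol and i > warmup:
                return RiccatiSolution(Pnew, Knew, i, k_res, p_converged=False)
        K, P = Knew, Pnew
    raise DareError(
        f"no convergence after {max_iter} iterations (residual {p_res:.3e})")


def solve_dare(
    A: np.ndarray, B: np.ndarray, Q: np.ndarray, R: np.ndarray,
    tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
    horizon: int = 2000,
) -> RiccatiSolution:
    """Stationary discrete-time Riccati solution and optimal gain.

    ``R`` must be positive definite.  For positive semidefinite Q the result
    satisfies the DARE fixed point to ``tol`` (or, for the rigidly coupled
    dyad's marginal modes, gain-stationarity to ``tol``; see module
    docstring).  Indefinite Q — competition costs — is solved as a plain
    finite-horizon problem of length ``horizon`` with zero terminal weight,
    with a warning that stationary existence is not guaranteed.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float).reshape(A.shape[0], -1)
    Q = np.asarray(Q, float)
    R = np.atleast_2d(np.asarray(R, float))
    if A.shape[0] != A.shape[1] or Q.shape != A.shape or R.shape[0] != B.shape[1]:
        raise ValueError("inconsistent dimensions")
    if np.any(np.linalg.eigvalsh(R) <= 0):
        raise ValueError("R must be positive definite")
    if np.any(np.diag(Q) < 0):
        warnings.warn(
            "indefinite Q: stationary Riccati solution not guaranteed; "
            "using a finite-horizon recursion", stacklevel=2)
        gains, P = _backward_pass(A, B, Q, R, horizon)
        return RiccatiSolution(P, gains[0], horizon, np.inf, p_converged=False)
    _check_stabilizable(A, B)
    return _riccati_iterate(A, B, Q, R, tol, max_iter)


def _check_stabilizable(A: np.ndarray, B: np.ndarray) -> None:
    """Reject systems with strictly unstable uncontrollable modes (PBH)."""
    eigvals, vl = np.linalg.eig(A.T)
    for lam, w in zip(eigvals, vl.T):
        if abs(lam) > 1.0 + 1e-9 and np.max(np.abs(w.conj() @ B)) < 1e-12:
            raise DareError(
                f"(A, B) not stabilizable: uncontrollable eigenvalue {lam:.4f}")


def _backward_pass(
    A: np.ndarray, B: np.ndarray, Q: np.ndarray, R: np.ndarray, N: int
) -> tuple[list[np.ndarray], np.ndarray]:
    P = np.zeros_like(A)  # zero terminal weight
    gains: list[np.ndarray] = []
    for _ in range(N):
        BtP = B.T @ P
        M = R + BtP @ B
        try:
            K = np.linalg.solve(M, BtP @ A)
        except np.linalg.LinAlgError as exc:
            raise DareError("singular (R + B'PB) in backward pass") from exc
        gains.append(K)
        P = Q + A.T @ P @ (A - B @ K)
        P = 0.5 * (P + P.T)
        if not np.all(np.isfinite(P)):
            raise DareError("finite-horizon backward pass diverged")
    gains.reverse()
    return gains, P


def finite_horizon_gains(
    A: np.ndarray, B: np.ndarray, Q: np.ndarray, R: np.ndarray, N: int
) -> list[np.ndarray]:
    """Gain sequence K_0..K_{N-1} of the N-step problem (zero terminal weight).

    K_0 converges to the stationary gain as N grows; this is the brute-force
    oracle the stationary solver is tested against.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    A = np.asarray(A, float)
    B = np.asarray(B, float).reshape(A.shape[0], -1)
    gains, _ = _backward_pass(A, B, np.asarray(Q, float),
                              np.atleast_2d(np.asarray(R, float)), N)
    return gains


def agent_gain(
    sys: DyadSystem, w: CostWeights, agent: int,
    tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Stationary feedback gain of one agent on the full dyad state.

    Each agent's gain is synthesized independently on the joint transition
    matrix with its own input column, state weights and effort weight — the
    partner's input is treated as zero during synthesis; both loops are then
    closed simultaneously in simulation.
    """
    B = sys.B1 if agent == 1 else sys.B2
    Q, R = build_Q(w, agent)
    sol = solve_dare(sys.A, B, Q, R, tol=tol, max_iter=max_iter)
    return sol.K
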
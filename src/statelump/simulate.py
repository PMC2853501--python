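"""Stiff-capable simulation and the balanced-truncation baseline.

Linear models with constant input are integrated exactly through the
matrix exponential of the augmented system; a stiff ODE solver path is
kept as an independent cross-check.  Balanced truncation operates on the
stable part of the system (the zero eigenvalue of a closed network is
split off first) with the initial condition recast as an impulsive
input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.integrate import solve_ivp

from .model import LinearODEModel, Trajectory

__all__ = [
    "simulate",
    "default_time_grid",
    "StateSpace",
    "to_statespace",
    "stable_part",
    "hankel_singular_values",
    "balanced_truncate",
    "impulse_response",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12


def default_time_grid(model: LinearODEModel, n_points: int = 400) -> np.ndarray:
    """A grid spanning the slow time-scale of the model."""
    slow = [r.value for r in model.reactions if r.value > 0]
    k = min(slow) if slow else 1.0
    t_end = 5.0 / k
    return np.linspace(0.0, t_end, n_points)


def _constant_input(model: LinearODEModel, u) -> np.ndarray:
    if u is None:
        u = model.u_default if model.u_default is not None else np.zeros(model.n_inputs)
    return np.asarray(u, float).ravel()


def simulate(
    model: LinearODEModel,
    t_grid: np.ndarray,
    *,
    u: np.ndarray | None = None,
    method: str = "expm",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate ``dx/dt = A x + B u`` (constant ``u``) from ``x0``.

    ``method='expm'`` uses the exact matrix-exponential propagator of the
    augmented affine system; ``method='stiff'`` uses a BDF solver.  The
    two must agree to solver tolerance on linear systems.
    """
    t = np.asarray(t_grid, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    uvec = _constant_input(model, u)
    c = model.B @ uvec if model.n_inputs else np.zeros(model.n_states)
    n = model.n_states

    if method == "expm":
        X = np.empty((t.shape[0], n))
        x = model.x0.astype(float).copy()
        t0 = t[0]
        if t0 != 0.0:
            x = _propagate(model.A, c, x, t0)
        X[0] = x
        props: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        for i in range(1, t.shape[0]):
            dt = t[i] - t[i - 1]
            key = round(dt, 15)
            if key not in props:
                props[key] = _affine_propagator(model.A, c, dt)
            P, q = props[key]
            x = P @ x + q
            X[i] = x
    elif method == "stiff":
        def rhs(_t, x):
            return model.A @ x + c

        sol = solve_ivp(
            rhs,
            (t[0], t[-1]),
            model.x0.astype(float),
            method="BDF",
            t_eval=t,
            rtol=rtol,
            atol=atol,
            jac=lambda _t, _x: model.A,
        )
        if not sol.success:
            raise RuntimeError(f"stiff solver failed: {sol.message}")
        X = sol.y.T
    else:
        raise ValueError(f"unknown method {method!r}")

    Y = X @ model.C.T + (model.D @ uvec)[None, :]
    return Trajectory(t, X, Y)


def _affine_propagator(A: np.ndarray, c: np.ndarray, dt: float):
    """Exact one-step propagator of dx/dt = A x + c over dt."""
    n = A.shape[0]
    if not np.any(c):
        P = linalg.expm(A * dt)
        return P, np.zeros(n)
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A * dt
    M[:n, n] = c * dt
    E = linalg.expm(M)
    return E[:n, :n], E[:n, n]


def _propagate(A, c, x, dt):
    P, q = _affine_propagator(A, c, dt)
    return P @ x + q


def export_trajectory_csv(traj: Trajectory, path: str, state_names=None) -> None:
    names = state_names or [f"x{i + 1}" for i in range(traj.n_states)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        n_out = traj.outputs.shape[1] if traj.outputs is not None else 0
        w.writerow(["t"] + names + [f"y{j + 1}" for j in range(n_out)])
        for i, t in enumerate(traj.times):
            row = [t] + list(traj.states[i])
            if traj.outputs is not None:
                row += list(traj.outputs[i])
            w.writerow(row)


# ---------------------------------------------------------------------------
# balanced truncation baseline
# ---------------------------------------------------------------------------


@dataclass
class StateSpace:
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray

    @property
    def n(self) -> int:
        return self.A.shape[0]


def to_statespace(model: LinearODEModel, use_x0_as_input: bool = True) -> StateSpace:
    """Input-output form; a non-zero x0 becomes an impulsive input column."""
    B = model.B.copy()
    if use_x0_as_input and np.any(model.x0):
        B = np.hstack([B, model.x0[:, None]])
    if B.shape[1] == 0:
        raise ValueError("model has neither inputs nor an initial condition")
    D = np.zeros((model.C.shape[0], B.shape[1]))
    D[:, : model.D.shape[1]] = model.D
    return StateSpace(model.A.copy(), B, model.C.copy(), D)


def stable_part(ss: StateSpace, tol: float | None = None):
    """Split off non-stable modes (Re >= -tol) via an ordered Schur form.

    Returns ``(stable, unstable, n_unstable)`` where both subsystems are
    decoupled through a Sylvester-based block diagonalisation.
    """
    n = ss.n
    scale = max(np.abs(ss.A).max(), 1.0)
    if tol is None:
        tol = 1e-9 * scale
    T, Z, sdim = linalg.schur(
        ss.A, output="real", sort=lambda re, im: re < -tol
    )
    k = sdim  # stable block size, ordered first
    if k == n:
        return ss, None, 0
    T11, T12, T22 = T[:k, :k], T[:k, k:], T[k:, k:]
    # decouple: X solves T11 X - X T22 = -T12
    if k > 0:
        X = linalg.solve_sylvester(T11, -T22, -T12)
    else:
        X = np.zeros((0, n - k))
    # similarity W = Z @ [[I, X], [0, I]]; inverse applies [[I, -X], [0, I]]
    Bt = Z.T @ ss.B
    Ct = ss.C @ Z
    B1 = Bt[:k] - X @ Bt[k:]
    B2 = Bt[k:]
    C1 = Ct[:, :k]
    C2 = Ct[:, k:] + C1 @ X
    stable = StateSpace(T11, B1, C1, ss.D.copy())
    unstable = StateSpace(T22, B2, C2, np.zeros_like(ss.D))
    return stable, unstable, n - k


def _gramian_factors(ss: StateSpace):
    P = linalg.solve_continuous_lyapunov(ss.A, -ss.B @ ss.B.T)
    Q = linalg.solve_continuous_lyapunov(ss.A.T, -ss.C.T @ ss.C)

    def factor(M):
        M = (M + M.T) / 2
        w, V = np.linalg.eigh(M)
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)

    return factor(P), factor(Q)


def hankel_singular_values(model: LinearODEModel) -> tuple[np.ndarray, int]:
    """HSVs of the stable part, non-increasing; plus the non-stable count.

    For a closed network the zero eigenvalue (conservation mode) is not
    stable and is split off before the Gramians are solved; its would-be
    singular value is unbounded and reported through the count instead.
    """
    ss = to_statespace(model)
    stab, _unstab, n_unstable = stable_part(ss)
    if stab.n == 0:
        return np.array([]), n_unstable
    R, L = _gramian_factors(stab)
    sv = np.linalg.svd(L.T @ R, compute_uv=False)
    return np.sort(sv)[::-1], n_unstable


def balanced_truncate(model: LinearODEModel, order: int) -> StateSpace:
    """Square-root balanced truncation of the stable part.

    ``order`` counts all retained states; the non-stable part is always
    kept, so ``order`` must be at least its dimension and at most n.
    """
    ss = to_statespace(model)
    if order > ss.n:
        raise ValueError("order exceeds the model dimension")
    if order == ss.n:
        return ss  # nothing truncated; balancing may hit rank-deficient Gramians
    stab, unstab, n_unstable = stable_part(ss)
    k = order - n_unstable
    if k < 0:
        raise ValueError(
            f"order {order} is below the non-stable dimension {n_unstable}"
        )
    if k > stab.n:
        raise ValueError("order exceeds the stable subspace dimension")
    if k == 0:
        Ar, Br, Cr = (np.zeros((0, 0)), np.zeros((0, ss.B.shape[1])),
                      np.zeros((ss.C.shape[0], 0)))
    else:
        R, L = _gramian_factors(stab)
        U, sv, Vt = np.linalg.svd(L.T @ R)
        sv_k = sv[:k]
        if sv_k[-1] <= 0:
            raise ValueError("requested order reaches zero Hankel singular values")
        S_inv_sqrt = np.diag(1.0 / np.sqrt(sv_k))
        Tl = S_inv_sqrt @ U[:, :k].T @ L.T  # maps x -> balanced (left)
        Tr = R @ Vt[:k].T @ S_inv_sqrt  # balanced -> x (right)
        Ar = Tl @ stab.A @ Tr
        Br = Tl @ stab.B
        Cr = stab.C @ Tr
    if unstab is None:
        return StateSpace(Ar, Br, Cr, ss.D.copy())
    nu = unstab.n
    A = np.block([
        [unstab.A, np.zeros((nu, k))],
        [np.zeros((k, nu)), Ar],
    ])
    B = np.vstack([unstab.B, Br])
    C = np.hstack([unstab.C, Cr])
    return StateSpace(A, B, C, ss.D.copy())


def impulse_response(ss: StateSpace, t_grid: np.ndarray, channel: int = -1) -> np.ndarray:
    """y(t) = C expm(A t) B[:, channel] (the impulse of one input column)."""
    t = np.asarray(t_grid, float)
    b = ss.B[:, channel]
    Y = np.empty((t.shape[0], ss.C.shape[0]))
    x = b.copy() if t[0] == 0 else linalg.expm(ss.A * t[0]) @ b
    Y[0] = ss.C @ x
    props: dict[float, np.ndarray] = {}
    for i in range(1, t.shape[0]):
        dt = round(t[i] - t[i - 1], 15)
        if dt not in props:
            props[dt] = linalg.expm(ss.A * dt)
        x = props[dt] @ x
        Y[i] = ss.C @ x
    return Y
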
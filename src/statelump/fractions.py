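"""Quasi-steady-state fraction parameters for lumped state pools.

For a pool of states ``x_l`` with internal dynamics ``dx_l/dt = A_l x_l
+ b`` (``b`` collecting slow inflows), the quasi-steady-state assumption
gives ``x_qss = -A_l^{-1} b`` and fractions ``eta_i = x_qss_i / sum``.

A pool without outflow reactions has a conserved moiety (the pool total)
and a singular ``A_l``; the moiety relation ``sum(x_l) = xhat`` then
replaces the last balance row.  The solved fractions are independent of
``xhat`` and hence time-invariant.  The moiety-style solve is also the
solver of choice for pools whose slow inflows are neglected, which is
how the reduction pipeline uses it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .model import LinearODEModel
from .timescale import Lump

__all__ = [
    "LumpSystem",
    "FractionParameterSet",
    "build_lump_system",
    "solve_qss_invertible",
    "solve_qss_moiety",
    "solve_lump",
    "fractions_symbolic",
    "solve_scheme_fractions",
]

#: relative rcond for the SVD rank test
RANK_RCOND = 1e-10


@dataclass
class LumpSystem:
    lump_states: list[int]
    A_l: np.ndarray
    b: np.ndarray  # slow inflow vector B_l u_l (may be all zero)
    has_moiety: bool
    structurally_closed: bool
    rank_structural_disagreement: bool = False

    @property
    def m(self) -> int:
        return len(self.lump_states)


@dataclass
class FractionParameterSet:
    lump_states: list[int]
    eta: np.ndarray
    eta_symbolic: list[sp.Expr] | None = None
    lump_id: str = ""
    notes: list[str] = field(default_factory=list)

    def as_map(self) -> dict[int, float]:
        return {s: float(e) for s, e in zip(self.lump_states, self.eta)}


def build_lump_system(
    model: LinearODEModel,
    lump_states: list[int],
    *,
    u: np.ndarray | None = None,
    x_external: np.ndarray | None = None,
    drop_slow_outflux: float | None = None,
) -> LumpSystem:
    """Extract the pool sub-system from the full model.

    ``A_l`` keeps the full diagonal loss terms (reactions leaving the
    pool included), unless ``drop_slow_outflux`` is given: then loss
    terms from out-of-pool reactions with rate <= that threshold are
    zeroed (the "treat tiny leaks as absent" approximation, which makes
    a nearly closed pool exactly closed).

    ``b`` collects inflows from model inputs (``B u``) and from slow
    reactions whose source lies outside the pool, evaluated at
    ``x_external`` (zero by default, i.e. slow inflows neglected).
    """
    m = len(lump_states)
    if m < 2:
        raise ValueError("a lump must contain at least two states")
    if len(set(lump_states)) != m:
        raise ValueError("duplicate states in lump")
    pos = {s: i for i, s in enumerate(lump_states)}

    A_l = np.zeros((m, m))
    structurally_closed = True
    for r in model.reactions:
        src_in = r.source in pos
        tgt_in = (not r.is_external) and int(r.target) in pos
        if src_in:
            if tgt_in:
                A_l[pos[int(r.target)], pos[r.source]] += r.value
                A_l[pos[r.source], pos[r.source]] -= r.value
            else:
                structurally_closed = False
                if drop_slow_outflux is None or r.value > drop_slow_outflux:
                    A_l[pos[r.source], pos[r.source]] -= r.value

    b = np.zeros(m)
    if u is None:
        u = np.zeros(model.n_inputs)
    Bu = model.B @ np.asarray(u, float).ravel()
    for i, s in enumerate(lump_states):
        b[i] += Bu[s]
    if x_external is not None:
        x_external = np.asarray(x_external, float).ravel()
        for r in model.reactions:
            if r.is_external:
                continue
            if r.source not in pos and int(r.target) in pos:
                b[pos[int(r.target)]] += r.value * x_external[r.source]

    sv = np.linalg.svd(A_l, compute_uv=False)
    numerically_singular = bool(sv[-1] < RANK_RCOND * sv[0])
    return LumpSystem(
        lump_states=list(lump_states),
        A_l=A_l,
        b=b,
        has_moiety=numerically_singular,
        structurally_closed=structurally_closed,
        rank_structural_disagreement=(numerically_singular != structurally_closed),
    )


def solve_qss_invertible(ls: LumpSystem) -> FractionParameterSet:
    """eta from x_qss = -A_l^{-1} b; requires a non-zero inflow vector."""
    if ls.has_moiety:
        raise ValueError("A_l is singular; use solve_qss_moiety")
    if not np.any(ls.b):
        raise ValueError(
            "zero inflow with invertible A_l gives an all-zero QSS; "
            "fractions are undefined (use the moiety solve if the pool "
            "is (nearly) closed)"
        )
    x_qss = -np.linalg.solve(ls.A_l, ls.b)
    total = x_qss.sum()
    if total == 0:
        raise ValueError("QSS pool total is zero; fractions undefined")
    return FractionParameterSet(ls.lump_states, x_qss / total)


def solve_qss_moiety(ls: LumpSystem, *, warn_on_inflow: bool = True) -> FractionParameterSet:
    """Replace the last balance row by the moiety row and solve at xhat=1.

    Valid whenever slow inflows are negligible.  If ``b`` is non-zero
    the fractions would depend on the pool total; a diagnostic is raised
    instead of silently normalising.
    """
    m = ls.m
    A_bar = ls.A_l.copy()
    A_bar[-1, :] = 1.0
    b_bar = -ls.b.copy()
    b_bar[-1] = 1.0  # xhat = 1
    notes: list[str] = []
    if np.any(ls.b):
        msg = (
            "moiety solve with non-zero slow inflow: fractions depend on "
            "the pool total and are not exactly time-invariant"
        )
        if warn_on_inflow:
            warnings.warn(msg)
        notes.append(msg)
    try:
        eta = np.linalg.solve(A_bar, b_bar)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "moiety system singular (disconnected pool?): " + str(exc)
        ) from exc
    if abs(eta.sum() - 1.0) > 1e-8:
        raise ValueError("moiety solve failed to normalise the fractions")
    return FractionParameterSet(ls.lump_states, eta, notes=notes)


def solve_lump(ls: LumpSystem) -> FractionParameterSet:
    """Dispatch: moiety solve for zero-inflow or singular pools."""
    if ls.has_moiety or not np.any(ls.b):
        return solve_qss_moiety(ls)
    return solve_qss_invertible(ls)


# ---------------------------------------------------------------------------
# symbolic path
# ---------------------------------------------------------------------------

def _symbolic_lump_matrix(
    model: LinearODEModel,
    lump_states: list[int],
    drop_slow_outflux: float | None,
) -> tuple[sp.Matrix, dict[sp.Symbol, float]]:
    m = len(lump_states)
    pos = {s: i for i, s in enumerate(lump_states)}
    A_l = sp.zeros(m, m)
    subs: dict[sp.Symbol, float] = {}
    for r in model.reactions:
        if r.source not in pos:
            continue
        k = sp.Symbol(r.name, positive=True)
        subs[k] = r.value
        tgt_in = (not r.is_external) and int(r.target) in pos
        if tgt_in:
            A_l[pos[int(r.target)], pos[r.source]] += k
            A_l[pos[r.source], pos[r.source]] -= k
        elif drop_slow_outflux is None or r.value > drop_slow_outflux:
            A_l[pos[r.source], pos[r.source]] -= k
    return A_l, subs


def fractions_symbolic(
    model: LinearODEModel,
    lump_states: list[int],
    *,
    drop_slow_outflux: float | None = None,
    max_symbolic_size: int = 12,
    simplify: bool = True,
) -> FractionParameterSet:
    """Closed-form fractions in the rate constants via the moiety solve.

    The pool total appears as a symbol ``xhat`` on the right-hand side;
    after division it must cancel, which is checked.  Pools larger than
    ``max_symbolic_size`` fall back to the numeric solver with a warning
    (symbolic inversion cost grows quickly).
    """
    m = len(lump_states)
    ls = build_lump_system(model, lump_states, drop_slow_outflux=drop_slow_outflux)
    if m > max_symbolic_size:
        warnings.warn(
            f"lump of size {m} exceeds the symbolic limit; numeric fallback"
        )
        return solve_qss_moiety(ls)

    A_l, subs = _symbolic_lump_matrix(model, lump_states, drop_slow_outflux)
    xhat = sp.Symbol("xhat", positive=True)
    A_bar = A_l.copy()
    for j in range(m):
        A_bar[m - 1, j] = sp.Integer(1)
    b_bar = sp.zeros(m, 1)
    b_bar[m - 1, 0] = xhat
    sol = A_bar.solve(b_bar)
    eta_sym = [sp.cancel(sol[i, 0] / xhat) for i in range(m)]
    if simplify:
        eta_sym = [sp.simplify(e) for e in eta_sym]
    for e in eta_sym:
        if xhat in e.free_symbols:
            raise ValueError(
                "fractions depend on the pool total (pool has inflows?)"
            )
    eta_num = np.array([float(e.subs(subs)) for e in eta_sym])
    fp = FractionParameterSet(ls.lump_states, eta_num, eta_symbolic=eta_sym)
    check = solve_qss_moiety(ls, warn_on_inflow=False)
    if np.max(np.abs(check.eta - eta_num)) > 1e-9:
        raise AssertionError("symbolic and numeric fractions disagree beyond 1e-9")
    return fp


def solve_scheme_fractions(
    model: LinearODEModel,
    lumps: list[Lump],
    *,
    drop_slow_outflux: float | None = None,
    symbolic: bool = False,
) -> dict[int, FractionParameterSet]:
    """Solve fractions for every lump of a scheme (pipeline entry point).

    Slow inflows are neglected (the moiety-style solve), matching the
    quasi-steady-state premise: the internal distribution of a pool is
    set by its own reactions, with the sink-cluster row carrying the
    moiety relation (members are ordered sink-last by construction).
    """
    out: dict[int, FractionParameterSet] = {}
    for li, lump in enumerate(lumps):
        if symbolic:
            fp = fractions_symbolic(
                model, lump.members, drop_slow_outflux=drop_slow_outflux
            )
        else:
            ls = build_lump_system(
                model, lump.members, drop_slow_outflux=drop_slow_outflux
            )
            fp = solve_qss_moiety(ls)
        fp.lump_id = f"L{li + 1}"
        # structurally transient members must carry (numerically) no mass
        for s in lump.transient:
            i = lump.members.index(s)
            if abs(fp.eta[i]) > 1e-12:
                fp.notes.append(
                    f"transient state {model.state_names[s]} has eta={fp.eta[i]:g}"
                )
            fp.eta[i] = 0.0
        out[li] = fp
    return out
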
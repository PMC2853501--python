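"""State-dependent fraction parameters for mass-action carrier lumps.

The demonstrated nonlinear extension: a pool of carrier-containing
species forms a conserved moiety; the fast reversible reactions inside
the pool are user-designated.  Because every mass-action term contains
the moiety in exactly one factor, the quasi-steady-state balances of the
fast reactions are *linear* in the pool species, with coefficients that
only involve pool-external species and rate constants.  Solving the
balances together with the moiety row yields fractions eta that depend
on the external species — and, evaluated for the designated
rate-limiting trans-membrane reaction, the classic carrier-mediated
influx/efflux rate laws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

__all__ = [
    "MassActionReaction",
    "MassActionModel",
    "CarrierLump",
    "NonlinearQSSSystem",
    "StateDependentFractions",
    "build_nonlinear_qss_system",
    "solve_fractions_symbolic",
    "derive_flux_expressions",
    "simulate_mass_action",
]


@dataclass(frozen=True)
class MassActionReaction:
    """A (possibly reversible) mass-action reaction.

    Forward rate ``kf * prod(reactants)``; backward ``kb *
    prod(products)`` when ``kb`` is given.  ``fast`` marks reactions that
    equilibrate on the fast time-scale (designated by the user; automatic
    detection for nonlinear models is out of scope).
    """

    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    kf_name: str
    kf: float
    kb_name: str | None = None
    kb: float | None = None
    fast: bool = False

    @property
    def reversible(self) -> bool:
        return self.kb is not None


@dataclass
class MassActionModel:
    species: list[str]
    reactions: list[MassActionReaction]
    external: list[str]  # clamped species, treated as parameters
    x0: dict[str, float] = field(default_factory=dict)

    @property
    def dynamic_species(self) -> list[str]:
        return [s for s in self.species if s not in self.external]

    def rate_symbols(self) -> dict[str, float]:
        out = {}
        for r in self.reactions:
            out[r.kf_name] = r.kf
            if r.reversible:
                out[r.kb_name] = r.kb
        return out


@dataclass
class CarrierLump:
    lump_species: list[str]
    total_symbol: str  # name of the conserved pool total
    external_species: list[str]
    rate_limiting: str  # reaction name of the slow trans-membrane step


@dataclass
class NonlinearQSSSystem:
    lump: CarrierLump
    matrix: sp.Matrix  # m x m, entries external-only
    rhs: sp.Matrix  # last entry is the pool total symbol
    unknowns: list[sp.Symbol]
    xhat: sp.Symbol


@dataclass
class StateDependentFractions:
    lump_species: list[str]
    eta: dict[str, sp.Expr]
    common_denominator: sp.Expr

    def evaluate(self, values: dict[str, float]) -> dict[str, float]:
        subs = {sp.Symbol(k, positive=True): v for k, v in values.items()}
        return {s: float(e.subs(subs)) for s, e in self.eta.items()}


def _sym(name: str) -> sp.Symbol:
    return sp.Symbol(name, positive=True)


def _flux(r: MassActionReaction, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    fwd = _sym(r.kf_name)
    for s in r.reactants:
        fwd *= symbols[s]
    if not r.reversible:
        return fwd
    bwd = _sym(r.kb_name)
    for s in r.products:
        bwd *= symbols[s]
    return fwd - bwd


def build_nonlinear_qss_system(model: MassActionModel, lump: CarrierLump) -> NonlinearQSSSystem:
    """Assemble the linear-in-the-pool QSS system.

    Rows: the fast-reaction balance of every pool species except the
    last, then the moiety row (pool species sum to the pool total) —
    the same shape as the linear moiety solve, but with external species
    appearing in the matrix entries.

    Rejects models whose terms are not degree-1 in the pool (then the
    balances would not be linear and the pool total would not factor
    out).
    """
    pool = list(lump.lump_species)
    if len(pool) < 2:
        raise ValueError("carrier lump needs at least two species")
    symbols = {s: _sym(s) for s in model.species}
    unknowns = [symbols[s] for s in pool]

    for r in model.reactions:
        n_react = sum(1 for s in r.reactants if s in pool)
        n_prod = sum(1 for s in r.products if s in pool)
        if (n_react and n_react != 1) or (n_prod and n_prod != 1):
            raise ValueError(
                f"reaction {r.name}: mass-action term is not degree-1 in the pool"
            )
        if r.reversible and n_react != n_prod:
            raise ValueError(
                f"reaction {r.name}: pool species must appear on both sides "
                "or neither for a reversible pool reaction"
            )

    balances: dict[str, sp.Expr] = {s: sp.Integer(0) for s in pool}
    for r in model.reactions:
        if not r.fast:
            continue
        v = _flux(r, symbols)
        for s in r.reactants:
            if s in balances:
                balances[s] -= v
        for s in r.products:
            if s in balances:
                balances[s] += v

    m = len(pool)
    xhat = _sym(lump.total_symbol)
    rows = []
    rhs = []
    for s in pool[:-1]:
        row = [sp.expand(balances[s]).coeff(u, 1) for u in unknowns]
        resid = sp.expand(balances[s] - sum(c * u for c, u in zip(row, unknowns)))
        if sp.simplify(resid) != 0:
            raise ValueError(f"balance of {s} is not linear in the pool species")
        for c in row:
            bad = set(map(str, c.free_symbols)) & set(pool)
            if bad:
                raise ValueError(
                    f"matrix entry for {s} contains pool species {sorted(bad)}"
                )
        rows.append(row)
        rhs.append(sp.Integer(0))
    rows.append([sp.Integer(1)] * m)
    rhs.append(xhat)
    return NonlinearQSSSystem(
        lump, sp.Matrix(rows), sp.Matrix(rhs), unknowns, xhat
    )


def solve_fractions_symbolic(system: NonlinearQSSSystem) -> StateDependentFractions:
    """Invert the QSS matrix symbolically; fractions must sum to one."""
    sol = system.matrix.solve(system.rhs)
    eta = {}
    for s, i in zip(system.lump.lump_species, range(len(system.unknowns))):
        e = sp.cancel(sol[i, 0] / system.xhat)
        if system.xhat in e.free_symbols:
            raise ValueError("fractions depend on the pool total; lump invalid")
        eta[s] = sp.simplify(e)
    total = sp.simplify(sum(eta.values()))
    if total != 1:
        raise AssertionError(f"fractions sum to {total}, not 1")
    denom = sp.denom(sp.together(next(iter(eta.values()))))
    return StateDependentFractions(list(system.lump.lump_species), eta, denom)


def derive_flux_expressions(
    fractions: StateDependentFractions,
    model: MassActionModel,
    lump: CarrierLump,
    r_max: sp.Symbol | float | None = None,
) -> tuple[sp.Expr, sp.Expr]:
    """Influx/efflux laws of the rate-limiting trans-membrane reaction.

    With the whole carrier pool conserved, the largest possible rate of
    the designated reaction is attained when all carrier sits in its
    substrate state; the realised rates are that maximum times the
    fraction occupying the outward- (influx) or inward-facing (efflux)
    glucose-bound state: ``r_in = r_max * eta_out``, ``r_eff = r_max *
    eta_in``.
    """
    r = next((x for x in model.reactions if x.name == lump.rate_limiting), None)
    if r is None:
        raise ValueError(f"rate-limiting reaction {lump.rate_limiting!r} not found")
    pool = set(lump.lump_species)
    src = [s for s in r.reactants if s in pool]
    dst = [s for s in r.products if s in pool]
    if len(src) != 1 or len(dst) != 1:
        raise ValueError("rate-limiting reaction must move one pool species")
    if not r.reversible:
        raise ValueError("rate-limiting reaction must be reversible")
    if r_max is None:
        r_max = _sym("r_max")
    return r_max * fractions.eta[src[0]], r_max * fractions.eta[dst[0]]


def simulate_mass_action(
    model: MassActionModel,
    t_grid: np.ndarray,
    *,
    clamped: dict[str, float] | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-14,
) -> dict[str, np.ndarray]:
    """Integrate the full nonlinear ODEs with the external species clamped."""
    clamped = dict(clamped or {})
    for s in model.external:
        clamped.setdefault(s, model.x0.get(s, 0.0))
    dyn = [s for s in model.species if s not in clamped]
    idx = {s: i for i, s in enumerate(dyn)}

    def conc(s, x):
        return clamped[s] if s in clamped else x[idx[s]]

    def rhs(_t, x):
        dx = np.zeros(len(dyn))
        for r in model.reactions:
            v = r.kf
            for s in r.reactants:
                v *= conc(s, x)
            if r.reversible:
                b = r.kb
                for s in r.products:
                    b *= conc(s, x)
                v -= b
            for s in r.reactants:
                if s in idx:
                    dx[idx[s]] -= v
            for s in r.products:
                if s in idx:
                    dx[idx[s]] += v
        return dx

    x0 = np.array([model.x0.get(s, 0.0) for s in dyn])
    t = np.asarray(t_grid, float)
    sol = solve_ivp(rhs, (t[0], t[-1]), x0, method="BDF", t_eval=t, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"mass-action simulation failed: {sol.message}")
    out = {s: sol.y[i] for s, i in idx.items()}
    for s, v in clamped.items():
        out[s] = np.full_like(t, v)
    return out
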
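"""Build the reduced ("zoomed-out") model from a lumping scheme.

Parameter translation: a reaction from pool member ``i`` to a state
outside the pool keeps its flux ``k * x_i = k * eta_i * xhat``, so the
reduced rate constant out of the pool is ``sum_i k_i * eta_i``.
Reactions *into* a pool keep their rate constant unchanged (the flux
simply targets the pool total).  Initial conditions and output rows sum
accordingly: ``xhat0 = sum x0_i`` and ``C_hat = sum C_i * eta_i``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import EXTERNAL, LinearODEModel, ReactionSpec, build_from_reactions
from .timescale import LumpingScheme, build_lumping_scheme
from .fractions import FractionParameterSet, solve_scheme_fractions

__all__ = [
    "BackTranslationMap",
    "ReducedModel",
    "translate_parameters",
    "build_reduced_model",
    "reduce_model",
    "reduce_at_scales",
]


@dataclass
class Rule:
    """Back-translation rule for one original state."""

    kind: str  # fraction | identity | zero | constant
    reduced_index: int | None = None
    eta: float = 0.0
    constant: float = 0.0


@dataclass
class BackTranslationMap:
    n_original: int
    n_reduced: int
    rules: list[Rule]
    original_names: list[str]
    reduced_names: list[str]

    def to_dict(self) -> dict:
        return {
            "n_original": self.n_original,
            "n_reduced": self.n_reduced,
            "reduced_names": self.reduced_names,
            "rules": [
                {
                    "state": self.original_names[i],
                    "kind": r.kind,
                    "reduced_state": (
                        None if r.reduced_index is None else self.reduced_names[r.reduced_index]
                    ),
                    "eta": r.eta,
                    "constant": r.constant,
                }
                for i, r in enumerate(self.rules)
            ],
        }

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, data: dict) -> "BackTranslationMap":
        reduced = list(data["reduced_names"])
        rpos = {n: i for i, n in enumerate(reduced)}
        rules, names = [], []
        for rd in data["rules"]:
            names.append(rd["state"])
            rules.append(
                Rule(
                    kind=rd["kind"],
                    reduced_index=(None if rd["reduced_state"] is None else rpos[rd["reduced_state"]]),
                    eta=float(rd["eta"]),
                    constant=float(rd["constant"]),
                )
            )
        return cls(int(data["n_original"]), int(data["n_reduced"]), rules, names, reduced)


@dataclass
class ReducedModel:
    model: LinearODEModel
    scheme: LumpingScheme
    etas: dict[int, FractionParameterSet]
    lump_names: list[str]
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.model.n_states


def _reduced_layout(scheme: LumpingScheme, state_names: list[str]):
    """Reduced state ordering: lumps first, then singletons, then slow."""
    names: list[str] = []
    where: dict[int, int] = {}  # original state -> reduced index
    for li, lump in enumerate(scheme.lumps):
        names.append(f"L{li + 1}")
        for s in lump.members:
            where[s] = li
    for s in scheme.singletons:
        where[s] = len(names)
        names.append(state_names[s])
    slow_index: dict[int, int] = {}
    for s in scheme.slow_states:
        slow_index[s] = len(names)
        where[s] = len(names)
        names.append(state_names[s])
    return names, where, slow_index


def translate_parameters(
    model: LinearODEModel,
    scheme: LumpingScheme,
    etas: dict[int, FractionParameterSet],
) -> tuple[list[ReactionSpec], dict[str, str]]:
    """Translated reduced reactions plus a provenance formula per rate."""
    for li in range(len(scheme.lumps)):
        if li not in etas:
            raise ValueError(f"missing fraction parameters for lump L{li + 1}")
    names, where, _ = _reduced_layout(scheme, model.state_names)
    eliminated = set(scheme.eliminated)
    eta_of: dict[int, float] = {}
    for li, lump in enumerate(scheme.lumps):
        eta_of.update(etas[li].as_map())

    acc: dict[tuple[int, int | str], float] = {}
    formulas: dict[tuple[int, int | str], list[str]] = {}
    for r in model.reactions:
        if r.source in eliminated:
            continue
        if not r.is_external and int(r.target) in eliminated:
            continue  # vanishing flux into an eliminated state: dropped
        rs = where[r.source]
        rt = EXTERNAL if r.is_external else where[int(r.target)]
        if rs == rt:
            continue  # internal to one reduced state
        if r.source in eta_of:
            k = r.value * eta_of[r.source]
            term = f"{r.name}*eta({model.state_names[r.source]})"
        else:
            k = r.value
            term = r.name
        key = (rs, rt)
        acc[key] = acc.get(key, 0.0) + k
        formulas.setdefault(key, []).append(term)

    reactions: list[ReactionSpec] = []
    provenance: dict[str, str] = {}
    for (rs, rt), k in sorted(acc.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        tname = "EXTERNAL" if rt == EXTERNAL else names[rt]
        rname = f"kr_{names[rs]}_{tname}"
        reactions.append(ReactionSpec(rs, rt, rname, k))
        provenance[rname] = " + ".join(formulas[(rs, rt)])
    return reactions, provenance


def build_reduced_model(
    model: LinearODEModel,
    scheme: LumpingScheme,
    etas: dict[int, FractionParameterSet],
) -> tuple[ReducedModel, BackTranslationMap]:
    scheme.check_partition(model.n_states)
    names, where, slow_index = _reduced_layout(scheme, model.state_names)
    n_red = len(names)
    reactions, provenance = translate_parameters(model, scheme, etas)

    # frozen slow states: outgoing reactions become constant inflows at
    # their x0, incoming reactions are ignored (the state does not move)
    const = np.zeros(n_red)
    kept: list[ReactionSpec] = []
    slow_set = set(scheme.slow_states)
    slow_red = set(slow_index.values())
    orig_of_slow_red = {v: k for k, v in slow_index.items()}
    for r in reactions:
        if r.source in slow_red:
            if not r.is_external:
                const[int(r.target)] += r.value * model.x0[orig_of_slow_red[r.source]]
            continue
        if not r.is_external and int(r.target) in slow_red:
            continue
        kept.append(r)

    x0_red = np.zeros(n_red)
    for s in range(model.n_states):
        if s in set(scheme.eliminated):
            continue
        x0_red[where[s]] += model.x0[s]

    eta_of: dict[int, float] = {}
    for li in range(len(scheme.lumps)):
        eta_of.update(etas[li].as_map())

    l = model.n_outputs
    C_red = np.zeros((l, n_red))
    for s in range(model.n_states):
        if s in set(scheme.eliminated):
            continue
        w = eta_of.get(s, 1.0)
        C_red[:, where[s]] += model.C[:, s] * w

    # inputs: original inputs pass through; slow-state constants become an
    # extra always-on input column
    m = model.n_inputs
    B_rows = np.zeros((n_red, m))
    for s in range(model.n_states):
        if s in set(scheme.eliminated) or s in slow_set:
            continue
        B_rows[where[s], :] += model.B[s, :]
    if np.any(const):
        B_red = np.hstack([B_rows, const[:, None]])
        D_red = np.hstack([model.D, np.zeros((l, 1))])
        u_default = np.concatenate([np.zeros(m), [1.0]])
    else:
        B_red = B_rows
        D_red = model.D.copy()
        u_default = None

    red = build_from_reactions(
        kept, n_red, B=B_red, C=C_red, D=D_red, x0=x0_red, state_names=names
    )
    # freeze slow states: no dynamics of their own
    for s in scheme.slow_states:
        i = where[s]
        red.A[i, :] = 0.0
        red.A[:, i] = 0.0
        red.x0[i] = model.x0[s]
    if u_default is not None:
        red.u_default = u_default

    rules: list[Rule] = [None] * model.n_states  # type: ignore[list-item]
    for li, lump in enumerate(scheme.lumps):
        for s in lump.members:
            if s in lump.transient:
                rules[s] = Rule("zero", reduced_index=li)
            else:
                rules[s] = Rule("fraction", reduced_index=li, eta=eta_of[s])
    for s in scheme.singletons:
        rules[s] = Rule("identity", reduced_index=where[s])
    for s in scheme.slow_states:
        rules[s] = Rule("constant", reduced_index=where[s], constant=float(model.x0[s]))
    for s in scheme.eliminated:
        rules[s] = Rule("zero", reduced_index=None)

    btmap = BackTranslationMap(model.n_states, n_red, rules, list(model.state_names), names)
    lump_names = [f"L{li + 1}" for li in range(len(scheme.lumps))]
    return ReducedModel(red, scheme, etas, lump_names, provenance), btmap


def reduce_model(
    model: LinearODEModel,
    epsilon: float,
    *,
    slow_margin: float = 1e-3,
    eliminate_threshold: float | None = None,
    reference_trajectory=None,
    drop_slow_outflux: float | None = None,
    symbolic: bool = False,
) -> tuple[ReducedModel, BackTranslationMap]:
    """Full pipeline: scheme -> fractions -> reduced model + map."""
    scheme = build_lumping_scheme(
        model,
        epsilon,
        slow_margin=slow_margin,
        eliminate_threshold=eliminate_threshold,
        reference_trajectory=reference_trajectory,
    )
    etas = solve_scheme_fractions(
        model, scheme.lumps, drop_slow_outflux=drop_slow_outflux, symbolic=symbolic
    )
    return build_reduced_model(model, scheme, etas)


def reduce_at_scales(
    model: LinearODEModel, epsilons: list[float], **kwargs
) -> list[tuple[float, tuple[ReducedModel, BackTranslationMap] | Exception]]:
    """One independent reduction per threshold; failures are collected."""
    if len(set(epsilons)) != len(epsilons) or any(e <= 0 for e in epsilons):
        raise ValueError("epsilons must be positive and distinct")
    out = []
    for eps in epsilons:
        try:
            out.append((eps, reduce_model(model, eps, **kwargs)))
        except Exception as exc:  # noqa: BLE001 - sweep must not abort
            out.append((eps, exc))
    return out
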
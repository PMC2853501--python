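"""Linear mono-molecular ODE models and their reaction-network form.

A model is a first-order reaction network: every reaction converts one
state into another (or degrades it to the environment) at a rate that is
first order in the source state.  Assembling the rate constants into the
system matrix ``A`` gives the linear ODE

    dx/dt = A x + B u,    y = C x + D u,    x(0) = x0.

State names are 1-based (``x1`` ...) in all I/O to match the usual
convention for compartment/probability models; indices are 0-based
internally.
"""

from __future__ import annotations

import csv
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EXTERNAL",
    "ReactionSpec",
    "LinearODEModel",
    "Trajectory",
    "build_from_reactions",
    "load_model",
    "write_model",
    "validate_model",
]

#: Sentinel target for degradation / outflow reactions.
EXTERNAL = "EXTERNAL"


@dataclass(frozen=True)
class ReactionSpec:
    """One first-order reaction ``source -> target`` with rate ``k * x_source``.

    ``target`` may be :data:`EXTERNAL` for a pure outflow; such reactions
    only enter the diagonal of ``A``.
    """

    source: int
    target: int | str
    name: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"reaction {self.name}: negative rate {self.value}")
        if self.target == self.source:
            raise ValueError(f"reaction {self.name}: source == target == {self.source}")

    @property
    def is_external(self) -> bool:
        return self.target == EXTERNAL


@dataclass
class Trajectory:
    """A simulated time course: states (n_t, n) and outputs (n_t, l)."""

    times: np.ndarray
    states: np.ndarray
    outputs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("state rows must match the time grid")
        if self.outputs is not None:
            self.outputs = np.asarray(self.outputs, dtype=float)
            if self.outputs.shape[0] != self.times.shape[0]:
                raise ValueError("output rows must match the time grid")

    @property
    def n_states(self) -> int:
        return self.states.shape[1]


@dataclass
class LinearODEModel:
    """A linear state-space model built from a mono-molecular reaction list."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    x0: np.ndarray
    state_names: list[str]
    reactions: list[ReactionSpec] = field(default_factory=list)
    #: rate-constant name -> (target row or None for EXTERNAL, source col)
    parameter_map: dict[str, tuple[int | None, int]] = field(default_factory=dict)
    #: constant input applied when no explicit input signal is given
    u_default: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.C.shape[0]

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def is_closed(self, tol: float = 1e-12) -> bool:
        """True when every column of ``A`` sums to zero and ``B`` is zero."""
        col = np.abs(self.A.sum(axis=0)).max() if self.n_states else 0.0
        return col < tol * max(1.0, np.abs(self.A).max(initial=0.0)) and not np.any(self.B)

    def rate_constants(self) -> dict[str, float]:
        return {r.name: r.value for r in self.reactions}

    def copy(self) -> "LinearODEModel":
        return replace(
            self,
            A=self.A.copy(),
            B=self.B.copy(),
            C=self.C.copy(),
            D=self.D.copy(),
            x0=self.x0.copy(),
            state_names=list(self.state_names),
            reactions=list(self.reactions),
            parameter_map=dict(self.parameter_map),
            u_default=None if self.u_default is None else self.u_default.copy(),
        )


def build_from_reactions(
    reactions: list[ReactionSpec],
    n_states: int,
    B: np.ndarray | None = None,
    C: np.ndarray | None = None,
    D: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    state_names: list[str] | None = None,
) -> LinearODEModel:
    """Assemble the system matrix from first-order reactions.

    Off-diagonal ``A[i, j]`` is the sum of rate constants of reactions
    ``j -> i``; diagonal ``A[j, j]`` is minus the total rate leaving state
    ``j``.  A closed network (no EXTERNAL targets) therefore has zero
    column sums.
    """
    if state_names is None:
        state_names = [f"x{i + 1}" for i in range(n_states)]
    if len(state_names) != n_states:
        raise ValueError("state_names length must equal n_states")

    A = np.zeros((n_states, n_states))
    pmap: dict[str, tuple[int | None, int]] = {}
    seen: set[tuple[int, int | str, str]] = set()
    for r in reactions:
        if not 0 <= r.source < n_states:
            raise ValueError(f"reaction {r.name}: source index {r.source} out of range")
        if not r.is_external and not 0 <= int(r.target) < n_states:
            raise ValueError(f"reaction {r.name}: target index {r.target} out of range")
        key = (r.source, r.target, r.name)
        if key in seen:
            raise ValueError(f"duplicate reaction {r.name} ({r.source}->{r.target})")
        seen.add(key)
        A[r.source, r.source] -= r.value
        if r.is_external:
            pmap[r.name] = (None, r.source)
        else:
            A[int(r.target), r.source] += r.value
            pmap[r.name] = (int(r.target), r.source)

    B = np.zeros((n_states, 1)) if B is None else np.atleast_2d(np.asarray(B, float))
    if B.shape[0] != n_states:
        B = B.reshape(n_states, -1)
    C = np.zeros((1, n_states)) if C is None else np.atleast_2d(np.asarray(C, float))
    m, l = B.shape[1], C.shape[0]
    D = np.zeros((l, m)) if D is None else np.atleast_2d(np.asarray(D, float))
    x0 = np.zeros(n_states) if x0 is None else np.asarray(x0, float).ravel()
    if C.shape[1] != n_states or x0.shape[0] != n_states or D.shape != (l, m):
        raise ValueError("inconsistent B/C/D/x0 dimensions")

    return LinearODEModel(
        A=A, B=B, C=C, D=D, x0=x0,
        state_names=state_names, reactions=list(reactions), parameter_map=pmap,
    )


# ---------------------------------------------------------------------------
# native JSON dialect (format of record; round-trip safe)
# ---------------------------------------------------------------------------

def _model_to_dict(model: LinearODEModel) -> dict:
    return {
        "format": "statelump-model",
        "version": 1,
        "units": "1/s",
        "n_states": model.n_states,
        "state_names": model.state_names,
        "reactions": [
            {
                "source": model.state_names[r.source],
                "target": (EXTERNAL if r.is_external else model.state_names[int(r.target)]),
                "name": r.name,
                "value": r.value,
            }
            for r in model.reactions
        ],
        "B": model.B.tolist(),
        "C": model.C.tolist(),
        "D": model.D.tolist(),
        "x0": model.x0.tolist(),
    }


def _model_from_dict(data: dict) -> LinearODEModel:
    names = list(data["state_names"])
    idx = {s: i for i, s in enumerate(names)}
    reactions = [
        ReactionSpec(
            source=idx[r["source"]],
            target=(EXTERNAL if r["target"] == EXTERNAL else idx[r["target"]]),
            name=r["name"],
            value=float(r["value"]),
        )
        for r in data["reactions"]
    ]
    return build_from_reactions(
        reactions,
        n_states=int(data["n_states"]),
        B=np.array(data["B"], float),
        C=np.array(data["C"], float),
        D=np.array(data["D"], float),
        x0=np.array(data["x0"], float),
        state_names=names,
    )


# ---------------------------------------------------------------------------
# SBML (read-only, first-order mass action)
# ---------------------------------------------------------------------------

def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _load_sbml(path: str) -> LinearODEModel:
    tree = ET.parse(path)
    root = tree.getroot()
    sbml_model = next(el for el in root.iter() if _strip(el.tag) == "model")

    species, x0_list = [], []
    for el in sbml_model.iter():
        if _strip(el.tag) == "species":
            if el.get("boundaryCondition") == "true":
                continue
            species.append(el.get("id"))
            x0_list.append(float(el.get("initialAmount") or el.get("initialConcentration") or 0.0))
    idx = {s: i for i, s in enumerate(species)}

    params = {}
    for el in sbml_model.iter():
        if _strip(el.tag) == "parameter" and el.get("id") is not None:
            params[el.get("id")] = float(el.get("value", "nan"))

    reactions: list[ReactionSpec] = []
    for rx in (el for el in sbml_model.iter() if _strip(el.tag) == "reaction"):
        rid = rx.get("id", "?")
        reactants = [
            sr.get("species")
            for lst in rx if _strip(lst.tag) == "listOfReactants"
            for sr in lst if _strip(sr.tag) == "speciesReference"
        ]
        products = [
            sr.get("species")
            for lst in rx if _strip(lst.tag) == "listOfProducts"
            for sr in lst if _strip(sr.tag) == "speciesReference"
        ]
        if len(reactants) != 1 or len(products) > 1:
            raise ValueError(f"reaction {rid}: not mono-molecular")
        klaw = next((el for el in rx.iter() if _strip(el.tag) == "kineticLaw"), None)
        if klaw is None:
            raise ValueError(f"reaction {rid}: missing kinetic law")
        local = dict(params)
        for el in klaw.iter():
            if _strip(el.tag) in ("parameter", "localParameter") and el.get("id"):
                local[el.get("id")] = float(el.get("value", "nan"))
        math = next((el for el in klaw.iter() if _strip(el.tag) == "math"), None)
        kname, kval = _first_order_rate(math, reactants[0], local, rid)
        target = idx[products[0]] if products else EXTERNAL
        reactions.append(ReactionSpec(idx[reactants[0]], target, kname, kval))

    model = build_from_reactions(reactions, len(species), x0=np.array(x0_list), state_names=species)
    return model


def _first_order_rate(math_el, reactant: str, params: dict, rid: str) -> tuple[str, float]:
    """Accept only rate laws of the form ``k * species``; reject anything else."""
    if math_el is None:
        raise ValueError(f"reaction {rid}: empty kinetic law")
    apply_el = next((c for c in math_el if _strip(c.tag) == "apply"), None)
    if apply_el is None:
        raise ValueError(f"reaction {rid}: kinetic law is not 'k * species'")
    children = list(apply_el)
    if not children or _strip(children[0].tag) != "times" or len(children) != 3:
        raise ValueError(f"reaction {rid}: kinetic law is not first-order mass action")
    symbols = []
    for c in children[1:]:
        if _strip(c.tag) != "ci":
            raise ValueError(f"reaction {rid}: kinetic law is not first-order mass action")
        symbols.append((c.text or "").strip())
    syms = set(symbols)
    if reactant not in syms:
        raise ValueError(f"reaction {rid}: rate law does not use the reactant")
    syms.discard(reactant)
    if len(syms) != 1:
        raise ValueError(f"reaction {rid}: rate law is not 'k * {reactant}'")
    kname = syms.pop()
    if kname not in params:
        raise ValueError(f"reaction {rid}: unknown rate constant {kname}")
    return kname, params[kname]


def load_model(path: str, fmt: str | None = None) -> LinearODEModel:
    """Load a model from the native JSON dialect or from SBML (read-only)."""
    if fmt is None:
        fmt = "sbml" if str(path).endswith((".xml", ".sbml")) else "native_json"
    if fmt == "native_json":
        with open(path) as fh:
            return _model_from_dict(json.load(fh))
    if fmt == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_model(model: LinearODEModel, path: str, fmt: str = "native_json") -> None:
    if fmt != "native_json":
        raise ValueError("only the native JSON dialect is writable")
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=1)
        fh.write("\n")


def export_matrix_csv(model: LinearODEModel, path: str) -> None:
    """Write ``A`` as CSV with state names for inspection."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + model.state_names)
        for i, row in enumerate(model.A):
            w.writerow([model.state_names[i]] + list(row))


def validate_model(model: LinearODEModel, tol: float = 1e-12) -> list[str]:
    """Diagnostics: closedness, probability-model status, disconnected states."""
    diags: list[str] = []
    scale = max(1.0, np.abs(model.A).max(initial=0.0))
    colsum = np.abs(model.A.sum(axis=0)).max(initial=0.0)
    closed = colsum < tol * scale and not np.any(model.B)
    has_external = any(r.is_external for r in model.reactions)
    if closed:
        total = model.x0.sum()
        if np.all(model.x0 >= 0) and abs(total - 1.0) < 1e-9:
            diags.append("closed probability model")
        else:
            diags.append("closed model")
            if abs(total - 1.0) >= 1e-9:
                diags.append(f"warning: x0 sums to {total:g}, not 1")
    else:
        diags.append("open model" + (" (EXTERNAL outflow)" if has_external else ""))
    if np.any(model.x0 < 0):
        diags.append("warning: negative initial state")
    touched = set()
    for r in model.reactions:
        touched.add(r.source)
        if not r.is_external:
            touched.add(int(r.target))
    for i in range(model.n_states):
        if i not in touched and not np.any(model.B[i]):
            diags.append(f"disconnected state {model.state_names[i]}")
    return diags
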
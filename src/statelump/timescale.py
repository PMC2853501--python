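"""Fast/slow decomposition and graph analysis of reaction networks.

The lump-identification procedure:

1. split the rate constants at a threshold ``epsilon`` and form the fast
   contribution ``A_f`` of the system matrix;
2. find the weakly connected groups of the fast graph (each group with at
   least two states is a candidate pool of rapidly equilibrating states);
3. find the strong components of each group on the *directed* fast edges;
4. classify strong components as sink clusters (no fast edge leaves the
   component) or non-sink components, and decide for every non-sink
   component whether it joins a sink cluster's pool;
5. flag states that are slow on the time-scale of interest (all incoming
   and outgoing rates far below ``epsilon``; via Gershgorin discs such
   states correspond to eigenvalues near zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import LinearODEModel, Trajectory

__all__ = [
    "FastSlowSplit",
    "DGFR",
    "StrongComponent",
    "Lump",
    "LumpingScheme",
    "split_fast_slow",
    "connectivity_matrix",
    "find_dgfrs",
    "strong_components",
    "classify_sink_clusters",
    "assign_nonsink_states",
    "slow_states",
    "negligible_states",
    "eliminate_negligible",
    "build_lumping_scheme",
    "suggest_epsilon",
]


@dataclass
class FastSlowSplit:
    """A = A_f + A_s where A_f collects rate constants above ``epsilon``."""

    epsilon: float
    A_f: np.ndarray
    A_s: np.ndarray
    fast_parameters: set[str]
    slow_parameters: set[str]
    fast_edges: list[tuple[int, int]] = field(default_factory=list)  # (source, target)
    slow_edges: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class DGFR:
    """A group of states weakly connected through fast reactions."""

    member_states: frozenset[int]
    fast_edges: list[tuple[int, int]]


@dataclass
class StrongComponent:
    member_states: frozenset[int]
    is_sink_cluster: bool | None = None


@dataclass
class Lump:
    """One pool of states containing exactly one sink cluster.

    ``members`` is ordered with the sink-cluster states *last* so the
    moiety row replaces a sink-state balance in the fraction solve.
    ``transient`` members have no slow path from the sink cluster and get
    a zero back-translated value.
    """

    members: list[int]
    sink_cluster: frozenset[int]
    transient: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.sink_cluster <= set(self.members):
            raise ValueError("sink cluster must be inside the lump")


@dataclass
class LumpingScheme:
    epsilon: float
    lumps: list[Lump]
    singletons: list[int]
    eliminated: list[int]
    slow_states: list[int]
    decisions: list[str] = field(default_factory=list)

    def all_states(self) -> list[int]:
        out: list[int] = []
        for l in self.lumps:
            out.extend(l.members)
        out.extend(self.singletons)
        out.extend(self.eliminated)
        out.extend(self.slow_states)
        return out

    def check_partition(self, n_states: int) -> None:
        states = self.all_states()
        if sorted(states) != list(range(n_states)):
            raise ValueError("lumping scheme does not partition the state set")

    def n_reduced(self) -> int:
        return len(self.lumps) + len(self.singletons) + len(self.slow_states)

    def to_dict(self, state_names: list[str] | None = None) -> dict:
        name = (lambda i: state_names[i]) if state_names else (lambda i: i)
        return {
            "epsilon": self.epsilon,
            "lumps": [
                {
                    "members": [name(i) for i in l.members],
                    "sink_cluster": sorted(name(i) for i in l.sink_cluster),
                    "transient": sorted(name(i) for i in l.transient),
                }
                for l in self.lumps
            ],
            "singletons": [name(i) for i in self.singletons],
            "eliminated": [name(i) for i in self.eliminated],
            "slow_states": [name(i) for i in self.slow_states],
            "decisions": self.decisions,
        }

    def write_report(self, path: str, state_names: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(state_names), fh, indent=1)
            fh.write("\n")


# ---------------------------------------------------------------------------


def split_fast_slow(model: LinearODEModel, epsilon: float) -> FastSlowSplit:
    """Partition reactions at rate ``epsilon``; assemble A_f and A_s."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n = model.n_states
    A_f = np.zeros((n, n))
    A_s = np.zeros((n, n))
    fast_p: set[str] = set()
    slow_p: set[str] = set()
    fast_e: list[tuple[int, int]] = []
    slow_e: list[tuple[int, int]] = []
    for r in model.reactions:
        M = A_f if r.value > epsilon else A_s
        M[r.source, r.source] -= r.value
        if not r.is_external:
            M[int(r.target), r.source] += r.value
            (fast_e if r.value > epsilon else slow_e).append((r.source, int(r.target)))
        (fast_p if r.value > epsilon else slow_p).add(r.name)
    return FastSlowSplit(epsilon, A_f, A_s, fast_p, slow_p, fast_e, slow_e)


def connectivity_matrix(A_f: np.ndarray) -> np.ndarray:
    """Boolean total-connectivity matrix of the symmetrised fast graph.

    ``M[i, j] = 1`` iff ``A_f[i, j]`` or ``A_f[j, i]`` is non-zero
    (off-diagonal); the returned matrix is the boolean sum of the powers
    ``M^1 .. M^(n-1)``, true exactly when i and j share an undirected
    fast path.
    """
    A_f = np.asarray(A_f)
    n = A_f.shape[0]
    if A_f.shape != (n, n):
        raise ValueError("A_f must be square")
    off = (A_f != 0) | (A_f.T != 0)
    np.fill_diagonal(off, False)
    M = off.astype(bool)
    Mc = np.zeros_like(M)
    P = np.eye(n, dtype=bool)
    for _ in range(max(n - 1, 0)):
        P = P @ M
        Mc |= P
    return Mc


def find_dgfrs(split: FastSlowSplit) -> list[DGFR]:
    """Weakly connected fast groups with at least two states."""
    n = split.A_f.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((s, t) for s, t in split.fast_edges)
    out = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        edges = [(s, t) for s, t in split.fast_edges if s in comp]
        out.append(DGFR(frozenset(comp), edges))
    out.sort(key=lambda d: min(d.member_states))
    return out


def strong_components(dgfr: DGFR) -> list[StrongComponent]:
    if not dgfr.member_states:
        raise ValueError("empty DGFR")
    g = nx.DiGraph()
    g.add_nodes_from(dgfr.member_states)
    g.add_edges_from(dgfr.fast_edges)
    comps = [StrongComponent(frozenset(c)) for c in nx.strongly_connected_components(g)]
    comps.sort(key=lambda c: min(c.member_states))
    return comps


def classify_sink_clusters(dgfr: DGFR, components: list[StrongComponent]) -> list[StrongComponent]:
    """A component is a sink cluster iff no fast edge leaves it."""
    for comp in components:
        leaves = any(s in comp.member_states and t not in comp.member_states
                     for s, t in dgfr.fast_edges)
        comp.is_sink_cluster = not leaves
    return components


def _fast_reachable_sinks(
    comp: StrongComponent, components: list[StrongComponent], dgfr: DGFR
) -> list[StrongComponent]:
    g = nx.DiGraph()
    g.add_nodes_from(dgfr.member_states)
    g.add_edges_from(dgfr.fast_edges)
    reach: set[int] = set()
    for s in comp.member_states:
        reach |= nx.descendants(g, s)
    return [c for c in components if c.is_sink_cluster and c.member_states & reach]


def _slow_reachable(model: LinearODEModel, split: FastSlowSplit, sources: frozenset[int]) -> set[int]:
    g = nx.DiGraph()
    g.add_nodes_from(range(model.n_states))
    g.add_edges_from(split.slow_edges)
    reach: set[int] = set()
    for s in sources:
        reach |= nx.descendants(g, s)
    return reach


def assign_nonsink_states(
    dgfr: DGFR,
    components: list[StrongComponent],
    model: LinearODEModel,
    split: FastSlowSplit,
) -> tuple[dict[frozenset[int], str | frozenset[int]], list[str]]:
    """Decide the fate of every non-sink strong component.

    Returns a map from component member set to either the sink cluster it
    is pooled with, or ``"keep_separate"``, plus a human-readable log.

    Rules: a non-sink component whose fast paths lead to exactly one sink
    cluster joins that cluster's pool.  With several reachable sink
    clusters it is kept separate, unless a slow path leads back to it
    from exactly one of them, in which case it joins that one.
    """
    log: list[str] = []
    decisions: dict[frozenset[int], str | frozenset[int]] = {}
    for comp in components:
        if comp.is_sink_cluster:
            continue
        sinks = _fast_reachable_sinks(comp, components, dgfr)
        label = "{" + ",".join(model.state_names[i] for i in sorted(comp.member_states)) + "}"
        if len(sinks) == 0:
            decisions[comp.member_states] = "keep_separate"
            log.append(f"non-sink SC {label}: no reachable sink cluster, kept separate")
        elif len(sinks) == 1:
            decisions[comp.member_states] = sinks[0].member_states
            log.append(f"non-sink SC {label}: fast paths to one sink cluster, pooled with it")
        else:
            returners = [
                s for s in sinks
                if _slow_reachable(model, split, s.member_states) & comp.member_states
            ]
            if len(returners) == 1:
                decisions[comp.member_states] = returners[0].member_states
                tgt = "{" + ",".join(model.state_names[i] for i in sorted(returners[0].member_states)) + "}"
                log.append(
                    f"non-sink SC {label}: fast paths to {len(sinks)} sink clusters, "
                    f"slow return path from {tgt} only -> pooled with {tgt}"
                )
            else:
                decisions[comp.member_states] = "keep_separate"
                why = "no" if not returners else f"{len(returners)}"
                log.append(
                    f"non-sink SC {label}: fast paths to {len(sinks)} sink clusters, "
                    f"{why} unique slow return path -> kept separate"
                )
    return decisions, log


def slow_states(model: LinearODEModel, epsilon: float, slow_margin: float = 1e-3) -> set[int]:
    """States whose every incoming and outgoing rate is << epsilon.

    The Gershgorin discs of such states are small and centred near zero,
    so the associated eigenvalues are slow; the state is effectively
    constant on the 1/epsilon time-scale.  A state with no reactions at
    all is constant too but is reported as a singleton elsewhere.
    """
    cut = epsilon * slow_margin
    n = model.n_states
    max_in = np.zeros(n)
    max_out = np.zeros(n)
    touched = np.zeros(n, dtype=bool)
    for r in model.reactions:
        touched[r.source] = True
        max_out[r.source] = max(max_out[r.source], r.value)
        if not r.is_external:
            touched[int(r.target)] = True
            max_in[int(r.target)] = max(max_in[int(r.target)], r.value)
    return {i for i in range(n) if touched[i] and max_in[i] < cut and max_out[i] < cut}


def negligible_states(
    model: LinearODEModel, trajectory: Trajectory, threshold: float
) -> set[int]:
    """States removable without affecting the dynamics.

    A state is negligible when its simulated magnitude never exceeds
    ``threshold`` *and* every reaction feeding it originates from a state
    that is itself below the threshold (so the state is only reached
    through vanishing fluxes).  Closed under iteration.
    """
    if threshold <= 0:
        return set()
    maxima = np.abs(trajectory.states).max(axis=0)
    tiny = {i for i in range(model.n_states) if maxima[i] < threshold}
    feeders: dict[int, set[int]] = {i: set() for i in range(model.n_states)}
    for r in model.reactions:
        if not r.is_external:
            feeders[int(r.target)].add(r.source)
    has_input = {i for i in range(model.n_states) if np.any(model.B[i])}
    # tiny states fed from significant states carry real, if small, flux
    # and stay in their pools; only tiny-fed tiny states are removable
    return {i for i in tiny if i not in has_input and feeders[i] <= tiny}


def eliminate_negligible(
    model: LinearODEModel,
    scheme: LumpingScheme,
    trajectory: Trajectory,
    threshold: float = 1e-5,
) -> LumpingScheme:
    """Move negligible states of an existing scheme into ``eliminated``."""
    removable = negligible_states(model, trajectory, threshold)
    if not removable:
        return scheme
    lumps: list[Lump] = []
    eliminated = list(scheme.eliminated)
    decisions = list(scheme.decisions)
    for l in scheme.lumps:
        kept = [i for i in l.members if i not in removable]
        gone = [i for i in l.members if i in removable]
        eliminated.extend(gone)
        sink = frozenset(s for s in l.sink_cluster if s not in removable)
        if len(kept) >= 2 and sink:
            lumps.append(Lump(kept, sink, l.transient & set(kept)))
        else:
            eliminated.extend(kept)
        if gone:
            names = ",".join(model.state_names[i] for i in sorted(gone))
            decisions.append(f"eliminated negligible states {names} (max < {threshold:g})")
    singles = [i for i in scheme.singletons if i not in removable]
    eliminated.extend(i for i in scheme.singletons if i in removable)
    slow = [i for i in scheme.slow_states if i not in removable]
    eliminated.extend(i for i in scheme.slow_states if i in removable)
    out = LumpingScheme(scheme.epsilon, lumps, singles, sorted(set(eliminated)), slow, decisions)
    out.check_partition(model.n_states)
    return out


def suggest_epsilon(model: LinearODEModel) -> float:
    """Heuristic threshold: geometric middle of the largest log10 gap."""
    ks = sorted({r.value for r in model.reactions if r.value > 0})
    if len(ks) < 2:
        raise ValueError("need at least two distinct positive rates")
    logs = np.log10(ks)
    gaps = np.diff(logs)
    i = int(np.argmax(gaps))
    return float(10 ** ((logs[i] + logs[i + 1]) / 2))


def build_lumping_scheme(
    model: LinearODEModel,
    epsilon: float,
    *,
    slow_margin: float = 1e-3,
    eliminate_threshold: float | None = None,
    reference_trajectory: Trajectory | None = None,
) -> LumpingScheme:
    """Run the full lump-identification procedure.

    Negligible-state elimination is opt-in: pass ``eliminate_threshold``
    (and a reference trajectory of the original model, or one is
    simulated internally).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    decisions: list[str] = [f"epsilon = {epsilon:g} 1/s"]

    removable: set[int] = set()
    if eliminate_threshold is not None:
        if reference_trajectory is None:
            from .simulate import simulate, default_time_grid
            reference_trajectory = simulate(model, default_time_grid(model))
        removable = negligible_states(model, reference_trajectory, eliminate_threshold)
        if removable:
            names = ",".join(model.state_names[i] for i in sorted(removable))
            decisions.append(
                f"negligible-state elimination (threshold {eliminate_threshold:g}): {names}"
            )

    split = split_fast_slow(model, epsilon)
    # drop removable states, then keep groups that still have >= 2 states
    pruned: list[DGFR] = []
    for d in find_dgfrs(split):
        members = d.member_states - removable
        if len(members) < 2:
            continue
        pruned.append(DGFR(members, [(s, t) for s, t in d.fast_edges
                                     if s in members and t in members]))
    dgfrs = pruned

    lumps: list[Lump] = []
    in_lump: set[int] = set()
    singles_extra: list[int] = []
    for d in dgfrs:
        comps = classify_sink_clusters(d, strong_components(d))
        assign, log = assign_nonsink_states(d, comps, model, split)
        decisions.extend(log)
        pools: dict[frozenset[int], list[frozenset[int]]] = {
            c.member_states: [] for c in comps if c.is_sink_cluster
        }
        for members, target in assign.items():
            if target == "keep_separate":
                singles_extra.extend(sorted(members))
            else:
                pools[target].append(members)
        slow_reach_cache: dict[frozenset[int], set[int]] = {}
        for sink, extras in pools.items():
            members = set(sink)
            for m in extras:
                members |= m
            if len(members) < 2:
                singles_extra.extend(sorted(members))
                continue
            if sink not in slow_reach_cache:
                slow_reach_cache[sink] = _slow_reachable(model, split, sink)
            returned = slow_reach_cache[sink]
            transient = frozenset(
                i for i in members if i not in sink and i not in returned
            )
            ordered = sorted(members - sink) + sorted(sink)
            lumps.append(Lump(ordered, frozenset(sink), transient))
            in_lump |= members
            decisions.append(
                "lump {"
                + ",".join(model.state_names[i] for i in ordered)
                + "} with sink cluster {"
                + ",".join(model.state_names[i] for i in sorted(sink))
                + "}"
                + (
                    " (zero-value members: "
                    + ",".join(model.state_names[i] for i in sorted(transient))
                    + ")"
                    if transient
                    else ""
                )
            )

    # A5 only applies when fast dynamics exist; with no fast reactions at
    # all the model is returned unchanged rather than frozen wholesale
    if split.fast_parameters:
        slow = slow_states(model, epsilon, slow_margin) - in_lump - removable
    else:
        slow = set()
    if slow:
        decisions.append(
            "slow states (frozen at x0): "
            + ",".join(model.state_names[i] for i in sorted(slow))
        )
    singles = [
        i for i in range(model.n_states)
        if i not in in_lump and i not in removable and i not in slow
    ]
    singles = sorted(set(singles) | set(singles_extra))
    scheme = LumpingScheme(
        epsilon, lumps, singles, sorted(removable), sorted(slow), decisions
    )
    scheme.check_partition(model.n_states)
    return scheme


def export_dot(model: LinearODEModel, split: FastSlowSplit, path: str) -> None:
    """Graphviz DOT of the reaction graph; fast edges bold."""
    lines = ["digraph fastgraph {"]
    for i, name in enumerate(model.state_names):
        lines.append(f'  {name};')
    for r in model.reactions:
        if r.is_external:
            continue
        style = "bold" if r.value > split.epsilon else "dashed"
        lines.append(
            f'  {model.state_names[r.source]} -> {model.state_names[int(r.target)]} '
            f'[style={style}, label="{r.name}"];'
        )
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
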
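"""Packaged benchmark models and a synthetic planted-lump generator.

The 6-state photosynthesis model ships with its reference rate
constants verbatim.  The 26-state model's wiring reproduces the known
structural facts of the reference network: five fast groups at a
1000/s threshold, six single-state sinks (x1, x3, x8, x10, x16, x18),
the ambiguous fast connectors x24 and x25 and their resolutions, the
negligible satellite groups fed by x21/x22, and a cyclic six-pool
reduced structure; individual rate values are repository-chosen where
no reference value is available.  A checksum test guards the fixture
against accidental edits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .model import LinearODEModel, ReactionSpec, build_from_reactions
from .nonlinear import CarrierLump, MassActionModel, MassActionReaction
from .timescale import Lump, LumpingScheme

__all__ = [
    "photosynthesis_6state",
    "photosynthesis_26state",
    "glucose_transport",
    "PlantedNetworkSpec",
    "planted_network",
]


def _r(src_1based: int, tgt_1based: int, name: str, value: float) -> ReactionSpec:
    return ReactionSpec(src_1based - 1, tgt_1based - 1, name, value)


def photosynthesis_6state() -> LinearODEModel:
    """Six-state fluorescence model; all probability starts in x2.

    Rate constant ``k_pq`` drives the reaction from state q to state p.
    The output reads the initially excited state x2 (the emitting
    configuration).
    """
    reactions = [
        _r(2, 1, "k12", 6.72),
        _r(3, 1, "k13", 6.72),
        _r(2, 3, "k32", 1920.0),
        _r(3, 2, "k23", 2500.0),
        _r(3, 4, "k43", 50000.0),
        _r(4, 3, "k34", 50000.0),
        _r(4, 5, "k54", 25000.0),
        _r(5, 4, "k45", 6700.0),
        _r(5, 6, "k65", 480.0),
        _r(6, 5, "k56", 240.0),
    ]
    x0 = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])
    C = np.array([[0.0, 1.0, 0.0, 0.0, 0.0, 0.0]])
    return build_from_reactions(reactions, 6, C=C, x0=x0)


#: fast rates are > 1000/s; everything else operates on the seconds scale
_REACTIONS_26 = [
    # pool 1: sink x1, reversible partner x2, fast connector x24
    _r(2, 1, "kf_1_2", 2.0e4),
    _r(1, 2, "ks_2_1", 5.0),
    _r(24, 1, "kf_1_24", 3.0e4),
    _r(24, 3, "kf_3_24", 1.0e4),
    _r(1, 24, "ks_24_1", 2.0),
    # pool 2: sink x3, partner x5, transient x4 (note: no x4 -> x3 reaction)
    _r(5, 3, "kf_3_5", 1.5e4),
    _r(3, 5, "ks_5_3", 4.0),
    _r(4, 5, "kf_5_4", 1.2e4),
    # pool 3: sink x8, partner x9, fast connector x25, transient x6
    _r(9, 8, "kf_8_9", 2.5e4),
    _r(8, 9, "ks_9_8", 4.5),
    _r(25, 8, "kf_8_25", 2.8e4),
    _r(25, 10, "kf_10_25", 9.0e3),
    _r(8, 25, "ks_25_8", 1.8),
    _r(6, 8, "kf_8_6", 1.3e4),
    # pool 4: sink x10, partner x11, transient x12
    _r(11, 10, "kf_10_11", 2.2e4),
    _r(10, 11, "ks_11_10", 5.5),
    _r(12, 10, "kf_10_12", 1.1e4),
    # pool 5: sink x16, partner x17, low-occupancy feeder x21, transient x7
    _r(17, 16, "kf_16_17", 1.8e4),
    _r(16, 17, "ks_17_16", 4.5),
    _r(7, 16, "kf_16_7", 1.6e4),
    _r(21, 17, "kf_17_21", 2.0e5),
    _r(21, 19, "kf_19_21", 1.2e4),
    _r(16, 21, "ks_21_16", 0.45),
    # pool 6: sink x18, partner x19, second partner x20, feeder x22, transient x23
    _r(19, 18, "kf_18_19", 2.1e4),
    _r(18, 19, "ks_19_18", 6.0),
    _r(20, 18, "kf_18_20", 9.0e3),
    _r(18, 20, "ks_20_18", 1.2),
    _r(22, 19, "kf_19_22", 1.5e5),
    _r(18, 22, "ks_22_18", 0.55),
    _r(23, 18, "kf_18_23", 1.4e4),
    # slow ring between the pools (each edge leaves a sink state)
    _r(1, 3, "ks_3_1", 3.0),
    _r(1, 4, "ks_4_1", 0.05),
    _r(3, 6, "ks_6_3", 2.5),
    _r(8, 12, "ks_12_8", 4.0),
    _r(10, 7, "ks_7_10", 3.5),
    _r(16, 23, "ks_23_16", 2.8),
    _r(18, 1, "ks_1_18", 3.2),
    # slow escapes from the low-occupancy states (reference entries)
    _r(21, 3, "k_min1", 0.8),
    _r(21, 4, "k_y2", 0.6),
    # satellite groups fed only by x21 / x22 (negligible occupancy)
    _r(21, 13, "ks_13_21", 0.3),
    _r(13, 14, "kf_14_13", 2.0e4),
    _r(14, 16, "ks_16_14", 0.6),
    _r(22, 15, "ks_15_22", 0.35),
    _r(15, 26, "kf_26_15", 1.8e4),
    _r(26, 18, "ks_18_26", 0.7),
]


def photosynthesis_26state() -> LinearODEModel:
    """26-state fluorescence model; all probability starts in x1.

    Note ``A[2, 20] = k_min1`` and ``A[3, 20] = k_y2`` (0-based), and
    ``A[2, 3] = 0``: there is no reaction from x4 to x3.
    """
    x0 = np.zeros(26)
    x0[0] = 1.0
    C = np.zeros((1, 26))
    for state_1based, w in [(1, 1.0), (3, 0.7), (8, 0.5), (10, 0.4), (16, 0.25), (18, 0.12)]:
        C[0, state_1based - 1] = w
    return build_from_reactions(_REACTIONS_26, 26, C=C, x0=x0)


def glucose_transport() -> MassActionModel:
    """Carrier-mediated glucose transport across the yeast membrane.

    Five carrier states (free outward-facing, glucose-bound on either
    face, free inward-facing, free in-membrane) form a conserved pool;
    extracellular and intracellular glucose are clamped externals.  The
    glucose-bound translocation step is the designated rate-limiting
    reaction; binding, release and the free-carrier return path are
    fast.  Rate constants are repository-chosen placeholders (no
    reference values are available) with a symmetric carrier by default.
    """
    reactions = [
        MassActionReaction(
            "bind_out", ("G_out", "E_out"), ("EG_out",),
            "k1f", 2.0e4, "k1b", 2.0e4, fast=True,
        ),
        MassActionReaction(
            "translocate_bound", ("EG_out",), ("EG_in",),
            "ktf", 1.0, "ktb", 1.0, fast=False,
        ),
        MassActionReaction(
            "release_in", ("EG_in",), ("E_in", "G_in"),
            "k2f", 3.0e4, "k2b", 3.0e4, fast=True,
        ),
        MassActionReaction(
            "return_inner", ("E_in",), ("E_mem",),
            "k3f", 1.5e4, "k3b", 1.5e4, fast=True,
        ),
        MassActionReaction(
            "return_outer", ("E_mem",), ("E_out",),
            "k4f", 2.5e4, "k4b", 2.5e4, fast=True,
        ),
    ]
    return MassActionModel(
        species=["G_out", "E_out", "EG_out", "EG_in", "E_in", "E_mem", "G_in"],
        reactions=reactions,
        external=["G_out", "G_in"],
        x0={"E_out": 1.0, "G_out": 1.0, "G_in": 0.2},
    )


def glucose_carrier_lump() -> CarrierLump:
    return CarrierLump(
        lump_species=["E_out", "EG_out", "EG_in", "E_in", "E_mem"],
        total_symbol="E_tot",
        external_species=["G_out", "G_in"],
        rate_limiting="translocate_bound",
    )


# ---------------------------------------------------------------------------
# synthetic planted networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedNetworkSpec:
    n_states: int
    lump_sizes: tuple[int, ...]
    fast_scale: float = 1e4
    slow_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.lump_sizes) > self.n_states:
            raise ValueError("lumps larger than the state count")
        if any(s < 2 for s in self.lump_sizes):
            raise ValueError("each planted lump needs at least two states")
        if self.fast_scale / self.slow_scale < 10:
            raise ValueError("separation ratio must be at least 10")


def planted_network(
    spec: PlantedNetworkSpec,
) -> tuple[LinearODEModel, LumpingScheme, list[np.ndarray]]:
    """A closed network with known lumps and known fractions.

    Every planted lump is one strongly connected fast cluster (a fast
    cycle plus random fast chords), so the whole lump is its own sink
    cluster and the correct scheme is unique.  Slow edges connect the
    lumps (and any leftover singleton states) in a ring plus random
    chords; they attach only to lump members, i.e. sink-cluster states.
    True fractions come from the null space of each lump's internal fast
    matrix at generation time.
    """
    rng = np.random.default_rng(spec.seed)
    groups: list[list[int]] = []
    cursor = 0
    for size in spec.lump_sizes:
        groups.append(list(range(cursor, cursor + size)))
        cursor += size
    singles = list(range(cursor, spec.n_states))

    reactions: list[ReactionSpec] = []
    counter = 0

    def add(src: int, tgt: int, scale: float, tag: str) -> None:
        nonlocal counter
        counter += 1
        value = float(scale * rng.uniform(0.5, 2.0))
        reactions.append(ReactionSpec(src, tgt, f"{tag}{counter}", value))

    for g in groups:
        order = list(g)
        rng.shuffle(order)
        for a, b in zip(order, order[1:] + order[:1]):
            add(a, b, spec.fast_scale, "kf")
        extra = rng.integers(0, len(g))
        for _ in range(int(extra)):
            a, b = rng.choice(g, size=2, replace=False)
            add(int(a), int(b), spec.fast_scale, "kf")

    units: list[list[int]] = groups + [[s] for s in singles]
    if len(units) >= 2:
        for u, v in zip(units, units[1:] + units[:1]):
            add(int(rng.choice(u)), int(rng.choice(v)), spec.slow_scale, "ks")
        for _ in range(len(units)):
            u, v = rng.choice(len(units), size=2, replace=False)
            add(int(rng.choice(units[u])), int(rng.choice(units[v])), spec.slow_scale, "ks")

    x0 = rng.dirichlet(np.ones(spec.n_states))
    C = np.zeros((1, spec.n_states))
    C[0, :] = rng.uniform(0.0, 1.0, spec.n_states)
    model = build_from_reactions(reactions, spec.n_states, C=C, x0=x0)

    lumps = [Lump(list(g), frozenset(g)) for g in groups]
    scheme = LumpingScheme(
        epsilon=float(np.sqrt(spec.fast_scale * spec.slow_scale)),
        lumps=lumps,
        singletons=singles,
        eliminated=[],
        slow_states=[],
    )

    etas: list[np.ndarray] = []
    for g in groups:
        pos = {s: i for i, s in enumerate(g)}
        A_int = np.zeros((len(g), len(g)))
        for r in reactions:
            if r.source in pos and not r.is_external and int(r.target) in pos \
                    and r.name.startswith("kf"):
                A_int[pos[int(r.target)], pos[r.source]] += r.value
                A_int[pos[r.source], pos[r.source]] -= r.value
        ns = null_space(A_int)
        if ns.shape[1] != 1:
            raise RuntimeError("planted lump does not have a unique stationary vector")
        v = ns[:, 0]
        v = v / v.sum()
        etas.append(np.abs(v))
    return model, scheme, etas
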
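"""Reconstruct original-model trajectories from a reduced simulation.

The reconstruction is purely algebraic — no new simulation: a lumped
member is its fraction of the pool total, a singleton is copied, frozen
states are constant, eliminated states are zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import LinearODEModel, Trajectory
from .reduction import BackTranslationMap

__all__ = ["ComparisonReport", "back_translate", "compare_trajectories"]


def back_translate(
    reduced_traj: Trajectory,
    btmap: BackTranslationMap,
    original_model: LinearODEModel | None = None,
) -> Trajectory:
    """Apply the per-state rules; optionally re-evaluate the output map."""
    if reduced_traj.n_states != btmap.n_reduced:
        raise ValueError(
            f"trajectory has {reduced_traj.n_states} states, map expects "
            f"{btmap.n_reduced}"
        )
    nt = reduced_traj.times.shape[0]
    X = np.zeros((nt, btmap.n_original))
    for i, rule in enumerate(btmap.rules):
        if rule.kind == "fraction":
            X[:, i] = rule.eta * reduced_traj.states[:, rule.reduced_index]
        elif rule.kind == "identity":
            X[:, i] = reduced_traj.states[:, rule.reduced_index]
        elif rule.kind == "constant":
            X[:, i] = rule.constant
        elif rule.kind == "zero":
            X[:, i] = 0.0
        else:
            raise ValueError(f"unknown rule kind {rule.kind!r}")
    outputs = None
    if original_model is not None:
        outputs = X @ original_model.C.T
    return Trajectory(reduced_traj.times.copy(), X, outputs)


@dataclass
class ComparisonReport:
    state_names: list[str]
    max_abs_error: np.ndarray
    rel_l2_error: np.ndarray
    output_max_abs: np.ndarray | None
    output_rel_l2: np.ndarray | None
    zero_rule_states: list[int]
    t_window: tuple[float, float]
    worst_rel_l2: float = field(init=False)

    def __post_init__(self) -> None:
        mask = np.ones(len(self.state_names), dtype=bool)
        mask[self.zero_rule_states] = False
        self.worst_rel_l2 = float(self.rel_l2_error[mask].max()) if mask.any() else 0.0

    def to_dict(self) -> dict:
        return {
            "t_window": list(self.t_window),
            "worst_rel_l2": self.worst_rel_l2,
            "states": [
                {
                    "state": n,
                    "max_abs_error": float(self.max_abs_error[i]),
                    "rel_l2_error": float(self.rel_l2_error[i]),
                    "zero_rule": i in set(self.zero_rule_states),
                }
                for i, n in enumerate(self.state_names)
            ],
            "outputs": (
                None
                if self.output_rel_l2 is None
                else [
                    {"max_abs_error": float(a), "rel_l2_error": float(r)}
                    for a, r in zip(self.output_max_abs, self.output_rel_l2)
                ]
            ),
        }

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def _rel_l2(truth: np.ndarray, est: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    num = np.linalg.norm(truth - est, axis=0)
    den = np.maximum(np.linalg.norm(truth, axis=0), floor)
    return num / den


def compare_trajectories(
    truth: Trajectory,
    estimate: Trajectory,
    *,
    t_min: float | None = None,
    state_names: list[str] | None = None,
    zero_rule_states: list[int] | None = None,
    rel_floor: float = 1e-12,
) -> ComparisonReport:
    """Per-state and per-output error metrics on a common time window.

    The estimate is interpolated onto the truth grid if the grids differ
    (their ranges must overlap).  ``t_min`` excludes an initial boundary
    layer where the quasi-steady-state assumption does not hold yet.
    """
    t = truth.times
    if estimate.times.shape != t.shape or not np.allclose(estimate.times, t):
        lo = max(t[0], estimate.times[0])
        hi = min(t[-1], estimate.times[-1])
        if hi <= lo:
            raise ValueError("trajectories cover disjoint time ranges")
        keep = (t >= lo) & (t <= hi)
        t = t[keep]
        truth_states = truth.states[keep]
        est_states = np.column_stack(
            [np.interp(t, estimate.times, estimate.states[:, j])
             for j in range(estimate.n_states)]
        )
        truth_out = truth.outputs[keep] if truth.outputs is not None else None
        est_out = (
            np.column_stack(
                [np.interp(t, estimate.times, estimate.outputs[:, j])
                 for j in range(estimate.outputs.shape[1])]
            )
            if estimate.outputs is not None
            else None
        )
    else:
        truth_states, est_states = truth.states, estimate.states
        truth_out, est_out = truth.outputs, estimate.outputs

    if truth_states.shape[1] != est_states.shape[1]:
        raise ValueError("state dimension mismatch")

    if t_min is not None:
        keep = t >= t_min
        t = t[keep]
        truth_states, est_states = truth_states[keep], est_states[keep]
        if truth_out is not None:
            truth_out = truth_out[keep]
        if est_out is not None:
            est_out = est_out[keep]

    names = state_names or [f"x{i + 1}" for i in range(truth_states.shape[1])]
    max_abs = np.abs(truth_states - est_states).max(axis=0)
    rel_l2 = _rel_l2(truth_states, est_states, rel_floor)
    out_abs = out_rel = None
    if truth_out is not None and est_out is not None:
        out_abs = np.abs(truth_out - est_out).max(axis=0)
        out_rel = _rel_l2(truth_out, est_out, rel_floor)
    return ComparisonReport(
        state_names=names,
        max_abs_error=max_abs,
        rel_l2_error=rel_l2,
        output_max_abs=out_abs,
        output_rel_l2=out_rel,
        zero_rule_states=list(zero_rule_states or []),
        t_window=(float(t[0]), float(t[-1])),
    )
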
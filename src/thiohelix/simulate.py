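"""Synthetic conformational ensembles in helical-parameter space.

The generator emulates the statistical structure of long MD trajectories of
duplex nucleic acids: per-step base-pair step parameters fluctuate with
independent Gaussian noise, and selected steps can follow a two-state
(high/low twist) Markov mean process — the signature reported for CpG steps
in phosphorothioated B-DNA.  Frames are rebuilt rigidly: each residue moves
with its base-pair frame, so re-analysis of a generated frame returns
exactly the perturbed parameters.

Randomness uses counter-based Philox streams keyed on (seed, frame), so
frame *i* is reproducible independently of the others; the Markov state
sequence, which is inherently sequential, has its own stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .core import ResidueKey, Structure, Trajectory
from .frames import PairFrame, detect_pairing, pair_frames_for
from .helical import STEP_COLUMNS, StepParams, rebuild_from_steps, step_parameters

__all__ = ["TwoStateSpec", "TrajectorySpec", "generate_trajectory"]

_MARKOV_STREAM = 2**62  # frame-stream keys are frame indices, far below this


@dataclass(frozen=True)
class TwoStateSpec:
    """Symmetric two-state Markov process on the twist mean of some steps."""

    low_mean: float
    high_mean: float
    switch_prob: float
    steps: FrozenSet[int]  # 1-based step indices

    def __post_init__(self):
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1]")
        object.__setattr__(self, "steps", frozenset(int(s) for s in self.steps))


@dataclass(frozen=True)
class TrajectorySpec:
    """Ensemble recipe: frame count, per-parameter Gaussian SDs, seed."""

    n_frames: int
    sigma: Dict[str, float] = field(default_factory=dict)
    twist_two_state: Optional[TwoStateSpec] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        for k, v in self.sigma.items():
            if k not in STEP_COLUMNS:
                raise ValueError(
                    f"unknown sigma key {k!r}; valid: {STEP_COLUMNS}")
            if v < 0:
                raise ValueError(f"sigma[{k!r}] must be >= 0")


def _local_coordinates(structure: Structure, frames: List[PairFrame]):
    """Express every residue's atoms in its pair frame."""
    residue_of_pair: Dict[ResidueKey, int] = {}
    for i, f in enumerate(frames):
        for key in f.residues:
            residue_of_pair[key] = i
    unpaired = [k for k in structure.residue_keys() if k not in residue_of_pair]
    if unpaired:
        raise ValueError(f"cannot perturb structure with unpaired residues: {unpaired}")
    local = np.empty_like(structure.coords)
    pair_index = np.empty(structure.n_atoms, int)
    for row, (s, i) in enumerate(zip(structure.strand_ids, structure.res_indices)):
        p = residue_of_pair[(s, int(i))]
        pair_index[row] = p
        f = frames[p]
        local[row] = f.axes.T @ (structure.coords[row] - f.origin)
    return local, pair_index


def markov_state_sequence(n: int, switch_prob: float,
                          rng: np.random.Generator) -> np.ndarray:
    """0/1 state sequence of the symmetric two-state chain."""
    states = np.empty(n, dtype=int)
    states[0] = int(rng.random() < 0.5)
    flips = rng.random(n - 1) < switch_prob if n > 1 else []
    for i, flip in enumerate(flips, start=1):
        states[i] = states[i - 1] ^ int(flip)
    return states


def generate_trajectory(structure: Structure, spec: TrajectorySpec,
                        pairing=None) -> Trajectory:
    """Gaussian-fluctuation ensemble around an analyzable duplex structure.

    Deterministic given ``spec.seed``; with all SDs zero and no two-state
    process every frame equals the input structure.
    """
    if pairing is None:
        pairing = detect_pairing(structure)
    frames = pair_frames_for(structure, pairing)
    if len(frames) < 2:
        raise ValueError("need at least two base pairs")
    local, pair_index = _local_coordinates(structure, frames)
    pair_rows = [np.nonzero(pair_index == p)[0] for p in range(len(frames))]
    base_steps = [step_parameters(frames[i], frames[i + 1])
                  for i in range(len(frames) - 1)]
    n_steps = len(base_steps)

    ts = spec.twist_two_state
    if ts is not None:
        bad = [s for s in ts.steps if not 1 <= s <= n_steps]
        if bad:
            raise ValueError(f"two-state step indices out of range: {bad}")
        markov_rng = np.random.Generator(
            np.random.Philox(key=np.array([spec.seed, _MARKOV_STREAM],
                                          dtype=np.uint64)))
        states = markov_state_sequence(spec.n_frames, ts.switch_prob, markov_rng)
    else:
        states = None

    sigma = np.array([spec.sigma.get(c, 0.0) for c in STEP_COLUMNS])
    out_frames = []
    for f in range(spec.n_frames):
        rng = np.random.Generator(
            np.random.Philox(key=np.array([spec.seed, f], dtype=np.uint64)))
        noise = rng.normal(0.0, 1.0, size=(n_steps, 6)) * sigma
        steps = []
        for i, b in enumerate(base_steps):
            vals = dict(zip(STEP_COLUMNS, b.as_array() + noise[i]))
            if states is not None and (i + 1) in ts.steps:
                mean = ts.high_mean if states[f] else ts.low_mean
                vals["twist"] = mean + noise[i][STEP_COLUMNS.index("twist")]
            steps.append(StepParams(**vals))
        new_frames = rebuild_from_steps(frames[0], steps)
        coords = np.empty_like(local)
        for p, rows in enumerate(pair_rows):
            nf = new_frames[p]
            coords[rows] = local[rows] @ nf.axes.T + nf.origin
        s = structure.copy()
        s.coords = coords
        out_frames.append(s)
    return Trajectory(frames=out_frames)
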
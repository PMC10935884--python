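"""Synthetic fingerprint trajectories with planted metastable structure.

Real MD fingerprint time series look like long blocks of a constant
"binding mode" fingerprint — a metastable state dwelling for hundreds to
thousands of frames, occasionally revisited — overlaid with rare
single-frame transient contacts.  This generator plants exactly that
structure so every pipeline stage can be tested against a known ground
truth: a state sequence with configurable dwell times plus per-frame,
per-column transient noise.

By default the planted states form a nested chain: a persistent core of
interactions shared by every state, with each successive state adding one
peripheral contact, and the random dwell schedule walks between
neighbouring states only.  Under this geometry a state transition changes
a single column, so however the centred-window mean of that column crosses
the occurrence threshold (noise can shift the crossing by a frame), the
filtered trajectory only ever passes through planted fingerprints and
recovery is exact.  States with several mutually exclusive interactions
(supported via explicit ``states``) instead produce short-lived chimeric
fingerprints around each transition — exactly the threshold sensitivity
the parameter sweep is designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import FingerprintFrameSet, InteractionKey

__all__ = ["SyntheticSpec", "default_columns", "nested_states", "generate"]

_RESIDUE_NAMES = (
    "ARG", "TYR", "ASN", "HIS", "ILE", "TRP", "CYS", "GLY", "PHE", "VAL",
    "GLN", "ASP", "GLU", "LEU", "MET", "SER", "THR", "LYS", "PRO", "ALA",
)
# the 15 renderable interaction types (glyph vocabulary)
_GLYPH_TYPES = (
    "Hydrophobic", "HBAcceptor", "HBDonor", "Anionic", "Cationic",
    "CationPi", "PiCation", "PiStacking", "EdgeToFace", "FaceToFace",
    "MetalAcceptor", "MetalDonor", "XBAcceptor", "XBDonor", "VdWContact",
)


def default_columns(n_columns: int, ligand: str = "LIG1") -> tuple[InteractionKey, ...]:
    """Plausible residue/interaction columns cycling through every glyph type."""
    cols = []
    for i in range(n_columns):
        name = _RESIDUE_NAMES[i % len(_RESIDUE_NAMES)]
        number = 90 + 7 * i
        itype = _GLYPH_TYPES[i % len(_GLYPH_TYPES)]
        cols.append(InteractionKey(ligand, f"{name}{number}", itype))
    return tuple(cols)


def nested_states(n_states: int, n_columns: int, core_fraction: float = 0.3) -> np.ndarray:
    """Nested chain of state fingerprints over ``n_columns`` columns.

    State 0 is the core; each later state adds exactly one peripheral
    contact, so consecutive binding modes differ by a single interaction
    forming or breaking.  The remaining columns are off in every state,
    leaving room for transient noise.
    """
    if n_states < 1:
        raise ValueError("need at least one state")
    core = max(1, int(round(core_fraction * n_columns)))
    if core + n_states - 1 > n_columns:
        raise ValueError(f"{n_columns} columns cannot host {n_states} nested states")
    states = np.zeros((n_states, n_columns), dtype=np.uint8)
    states[:, :core] = 1
    for s in range(1, n_states):
        states[s, : core + s] = 1
    return states


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic fingerprint trajectory.

    ``dwell_schedule`` lists (state_index, run_length) blocks per
    replicate and must sum to ``n_frames``; if omitted, a schedule is
    drawn with geometric dwell times of mean ``mean_dwell`` (state changes
    step to a uniformly chosen different state).  ``transient_rate`` is
    the per-frame, per-column probability of a spurious one-frame 0->1
    flip; ``dropout_rate`` optionally adds 1->0 dropouts.
    """

    n_frames: int = 1000
    n_replicates: int = 1
    n_columns: int = 20
    n_states: int = 3
    states: np.ndarray | None = None
    dwell_schedule: Sequence[tuple[int, int]] | None = None
    mean_dwell: float = 200.0
    transient_rate: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0
    ligand: str = "LIG1"
    columns: Sequence[InteractionKey] | None = None

    def resolved_states(self, rng) -> np.ndarray:
        if self.states is not None:
            states = np.asarray(self.states, dtype=np.uint8)
            if states.ndim != 2 or states.shape[1] != self.n_columns:
                raise ValueError("states must be a (n_states, n_columns) matrix")
            if len({s.tobytes() for s in states}) != len(states):
                raise ValueError("planted states must be pairwise distinct")
            return states
        return nested_states(self.n_states, self.n_columns)

    def resolved_schedule(self, n_states: int, rng) -> list[tuple[int, int]]:
        if self.dwell_schedule is not None:
            schedule = [(int(s), int(r)) for s, r in self.dwell_schedule]
            if any(r <= 0 for _, r in schedule):
                raise ValueError("run lengths must be positive")
            if any(not 0 <= s < n_states for s, _ in schedule):
                raise ValueError("schedule references an unknown state index")
            if sum(r for _, r in schedule) != self.n_frames:
                raise ValueError(
                    "dwell schedule run lengths must sum to n_frames "
                    f"({self.n_frames}), got {sum(r for _, r in schedule)}"
                )
            return schedule
        schedule: list[tuple[int, int]] = []
        remaining = self.n_frames
        state = int(rng.integers(n_states))
        while remaining > 0:
            run = min(remaining, max(1, int(rng.geometric(1.0 / self.mean_dwell))))
            schedule.append((state, run))
            remaining -= run
            if n_states > 1:
                # nearest-neighbour walk along the state chain: binding
                # modes evolve by forming or breaking one contact at a time
                if state == 0:
                    state = 1
                elif state == n_states - 1:
                    state -= 1
                else:
                    state += 1 if rng.random() < 0.5 else -1
        return schedule


def _isolate_single_frame(mask: np.ndarray) -> np.ndarray:
    """Drop flips that would touch two consecutive frames in one column."""
    keep = mask.copy()
    keep[1:] &= ~mask[:-1]
    return keep


def generate(spec: SyntheticSpec) -> tuple[FingerprintFrameSet, np.ndarray]:
    """Generate a fingerprint set plus the intended per-frame state indices.

    Returns ``(fset, ground_truth)`` where ``ground_truth[r * n_frames + i]``
    is the planted state index of frame ``i`` of replicate ``r`` (rows in
    the same concatenated order as ``fset``).  Reproducible for a fixed
    ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    states = spec.resolved_states(rng)
    columns = (
        tuple(spec.columns)
        if spec.columns is not None
        else default_columns(spec.n_columns, spec.ligand)
    )
    if len(columns) != states.shape[1]:
        raise ValueError("column list length must match state vector length")
    bit_blocks, frame_blocks, truth_blocks = [], [], []
    for rep in range(spec.n_replicates):
        schedule = spec.resolved_schedule(len(states), rng)
        truth = np.concatenate(
            [np.full(run, s, dtype=np.int64) for s, run in schedule]
        )
        bits = states[truth].copy()
        if spec.transient_rate > 0:
            flips = _isolate_single_frame(
                (rng.random(bits.shape) < spec.transient_rate) & (bits == 0)
            )
            bits[flips] = 1
        if spec.dropout_rate > 0:
            drops = _isolate_single_frame(
                (rng.random(bits.shape) < spec.dropout_rate) & (states[truth] == 1)
            )
            bits[drops] = 0
        frames = np.column_stack(
            [np.full(spec.n_frames, rep, dtype=np.int64),
             np.arange(spec.n_frames, dtype=np.int64)]
        )
        bit_blocks.append(bits)
        frame_blocks.append(frames)
        truth_blocks.append(truth)
    fset = FingerprintFrameSet(
        columns, np.vstack(frame_blocks), np.vstack(bit_blocks)
    )
    return fset, np.concatenate(truth_blocks)
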
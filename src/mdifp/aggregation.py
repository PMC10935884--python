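"""Aggregation of per-frame fingerprints into representative sets.

Two complementary reductions are provided:

* **interaction-based** — collapse every identical fingerprint regardless
  of when it occurs.  Yields the set of unique fingerprints with total
  occurrence counts; temporal order is lost.
* **time-based** — collapse only identical fingerprints that occur
  immediately after each other (run-length encoding).  Preserves temporal
  order; a metastable state revisited later appears as a fresh entry.

Both assign sequential integer ids in first-occurrence order and remember,
per aggregated fingerprint, the source (replicate, frame) rows it
summarises.  The classic single-frame summary — a bit set wherever a
column occurs in strictly more than 30% of all frames — is also provided
(:func:`occ_frame`) as the baseline the aggregation modes improve on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FingerprintFrameSet, InteractionKey

__all__ = [
    "AggregatedFingerprintSet",
    "aggregate_by_interaction",
    "aggregate_by_time",
    "occ_frame",
    "find_identical_within",
]


@dataclass
class AggregatedFingerprintSet:
    """Aggregated fingerprints with ids, occurrence counts and members.

    ``ifps`` is a (k, n_columns) 0/1 matrix, one row per aggregated
    fingerprint in id order; ``counts[i]`` is the number of source frames
    summarised by row ``i`` and ``members[i]`` the (replicate, frame)
    array of those source rows.  In ``time`` mode each members entry is one
    contiguous run; in ``interaction`` mode rows are pairwise distinct.
    """

    mode: str
    columns: tuple[InteractionKey, ...]
    ifps: np.ndarray
    counts: np.ndarray
    members: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.mode not in ("interaction", "time"):
            raise ValueError(f"unknown aggregation mode {self.mode!r}")
        self.columns = tuple(self.columns)
        self.ifps = np.asarray(self.ifps, dtype=np.uint8).reshape(-1, len(self.columns))
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.ifps) or len(self.members) != len(self.ifps):
            raise ValueError("ifps, counts and members lengths differ")
        if any(c != len(m) for c, m in zip(self.counts, self.members)):
            raise ValueError("counts do not match member list lengths")

    @property
    def ids(self) -> np.ndarray:
        return np.arange(len(self.ifps))

    @property
    def n_source_frames(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.ifps)

    def with_columns(self, columns, ifps) -> "AggregatedFingerprintSet":
        """Rebuild over a new column space (hook for column-space merging)."""
        return AggregatedFingerprintSet(
            self.mode, tuple(columns), ifps, self.counts.copy(),
            [m.copy() for m in self.members],
        )

    def expand(self) -> FingerprintFrameSet:
        """Reconstruct the per-frame set this aggregation summarises."""
        order = (
            np.concatenate(self.members) if self.members else np.empty((0, 2), np.int64)
        )
        bits = np.repeat(self.ifps, self.counts, axis=0)
        # restore the original temporal order before validation
        idx = np.lexsort((order[:, 1], order[:, 0]))
        return FingerprintFrameSet(self.columns, order[idx], bits[idx])

    # -- serialisation -----------------------------------------------------

    def to_json(self, path=None) -> str:
        """Serialise to the documented JSON layout (ids, counts, members)."""
        payload = {
            "mode": self.mode,
            "columns": [
                {"ligand": k.ligand, "residue": k.residue,
                 "interaction_type": k.interaction_type}
                for k in self.columns
            ],
            "ifps": [
                {
                    "id": int(i),
                    "count": int(self.counts[i]),
                    "bits": "".join(map(str, self.ifps[i].tolist())),
                    "members": [[int(r), int(f)] for r, f in self.members[i]],
                }
                for i in range(len(self))
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "AggregatedFingerprintSet":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        columns = tuple(
            InteractionKey(c["ligand"], c["residue"], c["interaction_type"])
            for c in payload["columns"]
        )
        entries = payload["ifps"]
        ifps = np.array(
            [[int(ch) for ch in e["bits"]] for e in entries], dtype=np.uint8
        ).reshape(len(entries), len(columns))
        counts = np.array([e["count"] for e in entries], dtype=np.int64)
        members = [np.array(e["members"], dtype=np.int64).reshape(-1, 2) for e in entries]
        return cls(payload["mode"], columns, ifps, counts, members)

    def to_table(self, path=None) -> pd.DataFrame:
        """Flat table: id, count, run_start, run_end, bit string.

        ``run_start``/``run_end`` are the first and last member frame
        numbers (a true contiguous run in time mode; the first/last
        occurrence in interaction mode).
        """
        df = pd.DataFrame(
            {
                "id": self.ids,
                "count": self.counts,
                "run_start": [int(m[0, 1]) for m in self.members],
                "run_end": [int(m[-1, 1]) for m in self.members],
                "bits": ["".join(map(str, row.tolist())) for row in self.ifps],
            }
        )
        if path is not None:
            df.to_csv(path, index=False)
        return df


def aggregate_by_interaction(fset: FingerprintFrameSet) -> AggregatedFingerprintSet:
    """Collapse identical fingerprints independent of the temporal dimension.

    Ids follow first-occurrence order; counts are total occurrences over
    the whole (concatenated) trajectory.
    """
    if fset.n_frames < 1:
        raise ValueError("aggregation requires at least one frame")
    _, first, inverse = np.unique(
        fset.bits, axis=0, return_index=True, return_inverse=True
    )
    # np.unique orders lexicographically; re-rank by first occurrence
    rank = np.argsort(np.argsort(first, kind="stable"), kind="stable")
    order = np.argsort(first, kind="stable")
    labels = rank[inverse]
    ifps = fset.bits[first[order]]
    members = [fset.frames[labels == i] for i in range(len(first))]
    counts = np.array([len(m) for m in members], dtype=np.int64)
    return AggregatedFingerprintSet("interaction", fset.columns, ifps, counts, members)


def aggregate_by_time(
    fset: FingerprintFrameSet, per_replicate: bool = False
) -> AggregatedFingerprintSet:
    """Run-length encode the fingerprint sequence.

    One entry per maximal run of identical consecutive frames, in temporal
    order over the concatenated trajectory.  With ``per_replicate=True``
    runs are additionally cut at replicate boundaries.
    """
    if fset.n_frames < 1:
        raise ValueError("aggregation requires at least one frame")
    changed = np.any(fset.bits[1:] != fset.bits[:-1], axis=1)
    if per_replicate:
        changed |= fset.frames[1:, 0] != fset.frames[:-1, 0]
    starts = np.concatenate([[0], np.flatnonzero(changed) + 1])
    ends = np.concatenate([starts[1:], [fset.n_frames]])
    ifps = fset.bits[starts]
    members = [fset.frames[s:e] for s, e in zip(starts, ends)]
    counts = ends - starts
    return AggregatedFingerprintSet("time", fset.columns, ifps, counts, members)


def occ_frame(fset: FingerprintFrameSet, occurrence_threshold: float = 0.30) -> np.ndarray:
    """Single representative fingerprint from whole-trajectory occupancy.

    Bit i is set iff column i is present in strictly more than
    ``occurrence_threshold`` of all frames (default: the conventional
    more-than-30% rule).
    """
    if fset.n_frames < 1:
        raise ValueError("occ_frame requires at least one frame")
    if not 0.0 <= occurrence_threshold < 1.0:
        raise ValueError(
            f"occurrence_threshold must be in [0, 1), got {occurrence_threshold}"
        )
    return (fset.bits.mean(axis=0) > occurrence_threshold).astype(np.uint8)


def find_identical_within(agg: AggregatedFingerprintSet) -> list[tuple[int, int]]:
    """All unordered id pairs (i, j), i < j, with zero differing bits.

    Non-empty only for time-aggregated sets, where revisited states appear
    as separate runs; interaction aggregation leaves no duplicates.
    """
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(agg.ifps):
        groups.setdefault(row.tobytes(), []).append(i)
    pairs = [
        (ids[a], ids[b])
        for ids in groups.values()
        for a in range(len(ids))
        for b in range(a + 1, len(ids))
    ]
    return sorted(pairs)
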
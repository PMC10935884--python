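"""Sliding-window smoothing and occurrence-threshold filtering.

Raw per-frame fingerprints are noisy: numerical integration error and
genuinely transient contacts produce interactions that flicker on for a
frame or two.  Two user-tunable filters remove them:

* **x1** — a sliding-window fraction of the trajectory length.  Each bit is
  replaced by the mean of its column over a window of
  ``max(1, round(x1 * n_frames))`` frames centred on the current frame, so
  interactions close in time are considered together.
* **x2** — an occurrence threshold in [0, 1).  The windowed mean is mapped
  back to a bit: present (1) iff the mean is strictly greater than x2.

The window shrinks at the trajectory ends so that the number of
fingerprints always equals the number of frames.  For an even window width
``w`` the window spans ``(w - 1) // 2`` frames before and ``w // 2`` frames
after the current one.

A parameter sweep over a grid of (x1, x2) values reports how many
fingerprints and how many distinct interactions survive each setting under
both aggregation modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FingerprintFrameSet, InteractionKey

__all__ = [
    "FilterConfig",
    "SmoothedMatrix",
    "SweepResult",
    "DEFAULT_X1_GRID",
    "DEFAULT_X2_GRID",
    "smooth",
    "binarize",
    "apply_filters",
    "surviving_interactions",
    "sweep",
]

#: Window fractions evaluated by default: 0.5%..10% of the trajectory.
DEFAULT_X1_GRID: tuple[float, ...] = (0.005, 0.01, 0.015, 0.02, 0.025, 0.05, 0.075, 0.10)
#: Occurrence thresholds evaluated by default.
DEFAULT_X2_GRID: tuple[float, ...] = (
    0.00, 0.01, 0.02, 0.025, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40,
)


@dataclass(frozen=True)
class FilterConfig:
    """Filter settings: window fraction x1 and occurrence threshold x2."""

    x1_fraction: float = 0.01
    x2_threshold: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 < self.x1_fraction <= 1.0:
            raise ValueError(f"x1_fraction must be in (0, 1], got {self.x1_fraction}")
        if not 0.0 <= self.x2_threshold < 1.0:
            raise ValueError(f"x2_threshold must be in [0, 1), got {self.x2_threshold}")

    def window_frames(self, n_frames: int) -> int:
        """Window width in frames: round-half-to-even of x1*n, floored at 1."""
        return max(1, round(self.x1_fraction * n_frames))


@dataclass
class SmoothedMatrix:
    """Windowed mean occurrence per frame and column, values in [0, 1]."""

    columns: tuple[InteractionKey, ...]
    frames: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.frames), len(self.columns)):
            raise ValueError("smoothed matrix shape mismatch")


def _centred_mean(bits: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling mean per column; edge windows shrink to what exists."""
    n = bits.shape[0]
    before, after = (window - 1) // 2, window // 2
    csum = np.zeros((n + 1, bits.shape[1]), dtype=np.float64)
    np.cumsum(bits, axis=0, out=csum[1:])
    lo = np.clip(np.arange(n) - before, 0, n)
    hi = np.clip(np.arange(n) + after + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)[:, None]


def smooth(
    fset: FingerprintFrameSet, config: FilterConfig, per_replicate: bool = False
) -> SmoothedMatrix:
    """Apply the centred sliding-window mean (x1 filter) to every column.

    By default the window slides across concatenated replicates, matching
    their treatment as a single entity; ``per_replicate=True`` restarts the
    window at each replicate boundary so independent simulations are never
    mixed inside one window.
    """
    if fset.n_frames < 1:
        raise ValueError("smooth requires at least one frame")
    window = config.window_frames(fset.n_frames)
    if window > fset.n_frames:
        raise ValueError(
            f"window of {window} frames exceeds trajectory length {fset.n_frames}"
        )
    if per_replicate:
        out = np.empty(fset.bits.shape, dtype=np.float64)
        for rep in fset.replicate_ids:
            sel = fset.frames[:, 0] == rep
            out[sel] = _centred_mean(fset.bits[sel], min(window, int(sel.sum())))
        values = out
    else:
        values = _centred_mean(fset.bits, window)
    return SmoothedMatrix(fset.columns, fset.frames.copy(), values)


def binarize(matrix: SmoothedMatrix, x2_threshold: float) -> FingerprintFrameSet:
    """Map windowed means back to bits: present iff mean > x2 (strict)."""
    if not 0.0 <= x2_threshold < 1.0:
        raise ValueError(f"x2_threshold must be in [0, 1), got {x2_threshold}")
    bits = (matrix.values > x2_threshold).astype(np.uint8)
    return FingerprintFrameSet(matrix.columns, matrix.frames.copy(), bits)


def apply_filters(
    fset: FingerprintFrameSet, config: FilterConfig, per_replicate: bool = False
) -> FingerprintFrameSet:
    """Smooth with the x1 window, then binarise at the x2 threshold."""
    return binarize(smooth(fset, config, per_replicate), config.x2_threshold)


def surviving_interactions(fset: FingerprintFrameSet) -> list[InteractionKey]:
    """Columns with at least one present bit, in set order."""
    present = fset.bits.any(axis=0)
    return [k for k, p in zip(fset.columns, present) if p]


@dataclass
class SweepResult:
    """Grid of (x1, x2, mode) -> (n_ifps, n_interactions)."""

    entries: dict[tuple[float, float, str], tuple[int, int]] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"x1": x1, "x2": x2, "mode": mode, "n_ifps": n_ifps,
             "n_interactions": n_int}
            for (x1, x2, mode), (n_ifps, n_int) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["x1", "x2", "mode", "n_ifps", "n_interactions"])

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sweep(
    fset: FingerprintFrameSet,
    x1_list: Sequence[float] | None = None,
    x2_list: Sequence[float] | None = None,
    modes: Sequence[str] = ("interaction", "time"),
    per_replicate: bool = False,
) -> SweepResult:
    """Count fingerprints and interactions over an (x1, x2) filter grid.

    For every grid point the filtered set is aggregated in each requested
    mode and the number of aggregated fingerprints plus the number of
    surviving interactions is recorded.  The interaction count is a
    property of the filtered bit matrix alone, so it is identical across
    aggregation modes.
    """
    from .aggregation import aggregate_by_interaction, aggregate_by_time

    x1_list = list(x1_list) if x1_list is not None else list(DEFAULT_X1_GRID)
    x2_list = list(x2_list) if x2_list is not None else list(DEFAULT_X2_GRID)
    modes = list(modes)
    if not x1_list or not x2_list or not modes:
        raise ValueError("sweep grids and mode list must be non-empty")
    aggregators = {"interaction": aggregate_by_interaction, "time": aggregate_by_time}
    unknown = [m for m in modes if m not in aggregators]
    if unknown:
        raise ValueError(f"unknown aggregation mode(s): {unknown}")
    result = SweepResult()
    for x1 in x1_list:
        smoothed = smooth(fset, FilterConfig(x1, 0.0), per_replicate)
        for x2 in x2_list:
            filtered = binarize(smoothed, x2)
            n_int = len(surviving_interactions(filtered))
            for mode in modes:
                agg = aggregators[mode](filtered)
                result.entries[(x1, x2, mode)] = (len(agg.ids), n_int)
    return result
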
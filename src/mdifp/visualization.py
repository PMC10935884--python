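"""Plot suite for aggregated fingerprint analysis.

Covers the standard views for a single simulation — pairwise-difference
heatmap (viridis), difference histogram, occurrence line plot,
identical-fingerprint link plot, per-residue circular chart and star-graph
interaction networks — plus the six-line figure relating two simulations.
Interaction types are encoded by glyph shape and colour; star-graph node
coordinates can be saved to a text file and reloaded so that successive
renders (and renders of different fingerprints) keep residues in identical
positions.

All functions return a :class:`matplotlib.figure.Figure` and never mutate
their inputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from .aggregation import AggregatedFingerprintSet, find_identical_within
from .comparison import SimilarityClassification
from .core import FingerprintFrameSet, InteractionKey

__all__ = [
    "GlyphSpec",
    "DEFAULT_GLYPHS",
    "NetworkLayout",
    "plot_difference_matrix",
    "plot_difference_histogram",
    "plot_occurrence",
    "plot_identical_links",
    "plot_residue_circular_chart",
    "render_network",
    "render_network_sequence",
    "plot_cross_set_comparison",
]

#: Default interaction-type encoding: (glyph shape, colour name).
DEFAULT_GLYPHS: dict[str, tuple[str, str]] = {
    "Hydrophobic": ("Circle", "Blue"),
    "HBAcceptor": ("Square", "Blue"),
    "HBDonor": ("Square", "Red"),
    "Anionic": ("Arrow-down", "Blue"),
    "Cationic": ("Arrow-down", "Red"),
    "CationPi": ("Arrow-left", "Red"),
    "PiCation": ("Arrow-left", "Blue"),
    "PiStacking": ("Arrow-up", "Blue"),
    "EdgeToFace": ("Arrow-right", "Red"),
    "FaceToFace": ("Arrow-right", "Blue"),
    "MetalAcceptor": ("Tick-up", "Red"),
    "MetalDonor": ("Tick-up", "Blue"),
    "XBAcceptor": ("Tick-down", "Red"),
    "XBDonor": ("Tick-down", "Blue"),
    "VdWContact": ("Circle", "Red"),
}

_MARKERS = {
    "Circle": "o",
    "Square": "s",
    "Arrow-down": "v",
    "Arrow-left": "<",
    "Arrow-up": "^",
    "Arrow-right": ">",
    "Tick-up": 2,     # matplotlib TICKUP
    "Tick-down": 3,   # matplotlib TICKDOWN
}

#: Documented default RGB values for the two-colour glyph vocabulary.
_COLOURS = {"Blue": "#1f77b4", "Red": "#d62728"}


@dataclass(frozen=True)
class GlyphSpec:
    """Interaction-type -> (glyph shape, colour) encoding."""

    mapping: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_GLYPHS)
    )

    def __post_init__(self) -> None:
        for itype, (shape, colour) in self.mapping.items():
            if shape not in _MARKERS:
                raise ValueError(f"unknown glyph shape {shape!r} for {itype}")
            if colour not in _COLOURS:
                raise ValueError(f"unknown glyph colour {colour!r} for {itype}")

    def marker(self, interaction_type: str):
        if interaction_type not in self.mapping:
            raise ValueError(
                f"no glyph defined for interaction type {interaction_type!r}"
            )
        shape, colour = self.mapping[interaction_type]
        return _MARKERS[shape], _COLOURS[colour]


@dataclass
class NetworkLayout:
    """Star-graph node coordinates, persistable to delimited text.

    The ligand sits at the origin; residues are placed on a circle ordered
    by residue sequence number.  Loading a saved layout reproduces node
    positions exactly across renders.
    """

    positions: dict[str, tuple[float, float]]
    ligand: str = "LIG"

    @classmethod
    def star(cls, columns, ligand: str | None = None, radius: float = 1.0) -> "NetworkLayout":
        keys = list(columns)
        if ligand is None:
            ligand = keys[0].ligand if keys else "LIG"
        residues = sorted(
            {k.residue for k in keys},
            key=lambda r: (InteractionKey(ligand, r, "Interaction").residue_number, r),
        )
        positions: dict[str, tuple[float, float]] = {ligand: (0.0, 0.0)}
        for i, res in enumerate(residues):
            angle = 2.0 * np.pi * i / max(1, len(residues))
            positions[res] = (radius * np.cos(angle), radius * np.sin(angle))
        return cls(positions, ligand)

    def save(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["node", "x", "y"])
            for node, (x, y) in self.positions.items():
                writer.writerow([node, repr(float(x)), repr(float(y))])

    @classmethod
    def load(cls, path, ligand: str | None = None) -> "NetworkLayout":
        positions: dict[str, tuple[float, float]] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            for row in reader:
                positions[row[0]] = (float(row[1]), float(row[2]))
        if ligand is None:
            ligand = next(iter(positions))
        return cls(positions, ligand)


# ---------------------------------------------------------------------------
# Within-simulation views
# ---------------------------------------------------------------------------


def plot_difference_matrix(matrix, colormap: str = "viridis"):
    """Heatmap of pairwise bit differences in aggregated-id order."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"difference matrix must be square, got shape {m.shape}")
    fig, ax = plt.subplots()
    im = ax.imshow(m, cmap=colormap, vmin=0, vmax=max(1, m.max()), origin="upper")
    ax.set_xlabel("IFP id")
    ax.set_ylabel("IFP id")
    fig.colorbar(im, ax=ax, label="number of differences")
    return fig

def plot_difference_histogram(matrix):
    """Histogram of the upper-triangle pairwise difference counts."""
    m = np.asarray(matrix)
    vals = m[np.triu_indices(m.shape[0], k=1)]
    fig, ax = plt.subplots()
    if vals.size:
        ax.hist(vals, bins=np.arange(vals.max() + 2) - 0.5, edgecolor="black")
    ax.set_xlabel("number of differences")
    ax.set_ylabel("IFP pairs")
    return fig

def plot_occurrence(agg: AggregatedFingerprintSet, annotate_top: int = 3):
    """Occurrence count per aggregated fingerprint, top entries marked.

    Ties among equal counts are broken toward the lower id.
    """
    counts = agg.counts
    fig, ax = plt.subplots()
    ax.plot(agg.ids, counts, lw=0.8)
    top = sorted(range(len(counts)), key=lambda i: (-counts[i], i))[:annotate_top]
    for i in top:
        ax.annotate(
            f"IFP {i}", (i, counts[i]), textcoords="offset points",
            xytext=(0, 18), ha="center",
            arrowprops={"arrowstyle": "->", "color": "black"},
        )
    ax.set_xlabel("IFP id")
    ax.set_ylabel("occurrence")
    return fig

def plot_identical_links(agg: AggregatedFingerprintSet):
    """Link identical fingerprints within a set by vertical connections.

    Two horizontal lines carry the temporal order (labelled with frame
    numbers); every zero-difference pair is drawn as a line between its two
    positions.  Interaction-aggregated sets produce no links.
    """
    n = len(agg)
    fig, ax = plt.subplots(figsize=(8, 2.4))
    ax.hlines([0.0, 1.0], -0.5, n - 0.5, color="black", lw=1)
    for i, j in find_identical_within(agg):
        ax.plot([i, j], [1.0, 0.0], color="tab:blue", lw=0.6)
    ticks = np.unique(np.linspace(0, max(0, n - 1), min(n, 8), dtype=int)) if n else []
    ax.set_xticks(ticks)
    ax.set_xticklabels([str(int(agg.members[i][0, 1])) for i in ticks])
    ax.set_yticks([0.0, 1.0])
    ax.set_yticklabels(["frame", "frame"])
    ax.set_xlabel("start frame of aggregated IFP")
    return fig


def _timeline(obj) -> tuple[np.ndarray, tuple[InteractionKey, ...]]:
    if isinstance(obj, FingerprintFrameSet):
        return obj.bits, obj.columns
    if isinstance(obj, AggregatedFingerprintSet):
        return np.repeat(obj.ifps, obj.counts, axis=0), obj.columns
    raise TypeError("expected a FingerprintFrameSet or AggregatedFingerprintSet")

def plot_residue_circular_chart(obj, residue: str):
    """Polar summary of one residue: angle is time, one ring per type.

    Each interaction type of the residue occupies one ring; filled arcs
    mark the stretches of the trajectory where the interaction is present
    (arc extent proportional to the fraction of frames).
    """
    bits, columns = _timeline(obj)
    col_idx = [i for i, k in enumerate(columns) if k.residue == residue]
    if not col_idx:
        raise ValueError(f"residue {residue!r} not found in the column keys")
    n = bits.shape[0]
    fig = plt.figure()
    ax = fig.add_subplot(projection="polar")
    for ring, i in enumerate(col_idx):
        series = bits[:, i]
        # maximal runs of presence -> arcs
        padded = np.concatenate([[0], series, [0]])
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1)
        r = 1.0 + ring
        for s, e in zip(starts, ends):
            theta = np.linspace(2 * np.pi * s / n, 2 * np.pi * e / n, max(2, e - s))
            ax.plot(theta, np.full_like(theta, r), lw=6, solid_capstyle="butt")
        ax.text(0.0, r + 0.35, columns[i].interaction_type, fontsize=7)
    ax.set_rticks([])
    ax.set_title(residue)
    return fig


# ---------------------------------------------------------------------------
# Star-graph networks
# ---------------------------------------------------------------------------


def render_network(
    ifp,
    columns,
    layout: NetworkLayout | None = None,
    glyphs: GlyphSpec | None = None,
    show_unconnected: bool = True,
    ax=None,
):
    """Star graph of one fingerprint: ligand centred, residues around it.

    Each on-bit draws an edge from the ligand to the residue, carrying the
    glyph/colour of its interaction type at the edge midpoint.  Residues
    without any on-bit are shown unconnected (or omitted with
    ``show_unconnected=False``).  A layout loaded from file is reused
    verbatim, keeping residue positions identical across renders.
    """
    bits = np.asarray(ifp).ravel()
    columns = list(columns)
    if len(bits) != len(columns):
        raise ValueError("fingerprint length does not match column list")
    glyphs = glyphs or GlyphSpec()
    layout = layout or NetworkLayout.star(columns)
    residues = sorted({k.residue for k in columns})
    missing = [r for r in residues if r not in layout.positions]
    if missing:
        raise ValueError(f"layout lacks node positions for residues: {missing}")
    if ax is None:
        fig, ax = plt.subplots()
    else:
        fig = ax.figure
    graph = nx.Graph()
    graph.add_node(layout.ligand)
    on = [(k, j) for j, k in enumerate(columns) if bits[j]]
    connected = {k.residue for k, _ in on}
    shown = residues if show_unconnected else sorted(connected)
    graph.add_nodes_from(shown)
    graph.add_edges_from((layout.ligand, r) for r in connected)
    pos = {node: layout.positions[node] for node in graph.nodes}
    pos[layout.ligand] = layout.positions.get(layout.ligand, (0.0, 0.0))
    nx.draw_networkx_edges(graph, pos, ax=ax, edge_color="0.6")
    nx.draw_networkx_nodes(
        graph, pos, ax=ax, node_color="white", edgecolors="black", node_size=900
    )
    nx.draw_networkx_labels(graph, pos, ax=ax, font_size=7)
    # glyphs sit along the edge, fanned out when one residue has several
    per_res: dict[str, list] = {}
    for k, j in on:
        per_res.setdefault(k.residue, []).append(k)
    for res, keys in per_res.items():
        x0, y0 = pos[layout.ligand]
        x1, y1 = pos[res]
        for m, k in enumerate(keys):
            frac = 0.35 + 0.5 * (m + 1) / (len(keys) + 1)
            marker, colour = glyphs.marker(k.interaction_type)
            ax.plot(
                [x0 + frac * (x1 - x0)], [y0 + frac * (y1 - y0)],
                marker=marker, color=colour, markersize=9, linestyle="none",
            )
    ax.set_axis_off()
    ax.set_aspect("equal")
    return fig

def render_network_sequence(
    agg: AggregatedFingerprintSet,
    out_path,
    layout: NetworkLayout | None = None,
    glyphs: GlyphSpec | None = None,
    out_format: str = "images",
    dpi: int = 80,
) -> list[Path]:
    """Render every aggregated fingerprint as one network frame.

    ``out_format="images"`` writes ``ifp_<id>.png`` files into the
    ``out_path`` directory; ``"gif"`` writes one animated GIF at
    ``out_path``.  Each frame pairs the star graph with an occurrence line
    plot marking the current fingerprint's id and count.  Frames follow
    aggregated-id order.
    """
    import imageio.v3 as iio

    layout = layout or NetworkLayout.star(agg.columns)
    out_path = Path(out_path)
    if out_format not in ("images", "gif"):
        raise ValueError(f"unknown output format {out_format!r}")
    if out_format == "images":
        out_path.mkdir(parents=True, exist_ok=True)
    frames, written = [], []
    width = len(str(max(1, len(agg) - 1)))
    for i in range(len(agg)):
        fig = plt.figure(figsize=(6, 6))
        ax_net = fig.add_axes([0.0, 0.28, 1.0, 0.7])
        ax_occ = fig.add_axes([0.12, 0.06, 0.8, 0.16])
        render_network(agg.ifps[i], agg.columns, layout, glyphs, ax=ax_net)
        ax_occ.plot(agg.ids, agg.counts, lw=0.8)
        ax_occ.plot([i], [agg.counts[i]], "ro")
        ax_occ.set_xlabel(f"IFP {i} (occurrence {int(agg.counts[i])})", fontsize=8)
        fig.canvas.draw()
        if out_format == "images":
            target = out_path / f"ifp_{i:0{width}d}.png"
            fig.savefig(target, dpi=dpi)
            written.append(target)
        else:
            buf = np.asarray(fig.canvas.buffer_rgba())[..., :3]
            frames.append(buf.copy())
        plt.close(fig)
    if out_format == "gif":
        iio.imwrite(out_path, np.stack(frames), duration=500, loop=0)
        written.append(out_path)
    return written


# ---------------------------------------------------------------------------
# Cross-simulation comparison
# ---------------------------------------------------------------------------


def plot_cross_set_comparison(
    a: AggregatedFingerprintSet,
    b: AggregatedFingerprintSet,
    classification: SimilarityClassification,
):
    """Six-line figure relating two simulations' aggregated fingerprints.

    Set A occupies three dark-blue horizontal lines (a, b, c), set B three
    bright-blue lines (d, e, f); the x-axis is the fingerprint id within
    each set.  Identical fingerprints within A connect lines a-b, within B
    lines e-f.  Between the sets, identical-class pairs are drawn black and
    similar-class pairs red between lines c and d.
    """
    if classification.shape != (len(a), len(b)):
        raise ValueError(
            f"classification shape {classification.shape} does not match "
            f"set sizes ({len(a)}, {len(b)})"
        )
    dark, bright = "#08306b", "#6baed6"
    ys = {"a": 6.0, "b": 5.0, "c": 4.0, "d": 3.0, "e": 2.0, "f": 1.0}
    span = max(len(a), len(b), 1) - 0.5
    fig, ax = plt.subplots(figsize=(9, 4))
    for line, y in ys.items():
        colour = dark if line in "abc" else bright
        ax.hlines(y, -0.5, span, color=colour, lw=1.5)
        ax.text(-0.02, y, line, transform=ax.get_yaxis_transform(),
                ha="right", va="center", fontsize=9)
    for i, j in find_identical_within(a):
        ax.plot([i, j], [ys["a"], ys["b"]], color=dark, lw=0.5)
    for i, j in find_identical_within(b):
        ax.plot([i, j], [ys["e"], ys["f"]], color=bright, lw=0.5)
    for colour, cls in (("red", "similar"), ("black", "identical")):
        for i, js in classification.memberships_a.get(cls, {}).items():
            for j in js:
                ax.plot([i, j], [ys["c"], ys["d"]], color=colour, lw=0.5)
    ax.set_yticks([])
    ax.set_xlabel("IFP number")
    ax.set_xlim(-0.5, span)
    return fig
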
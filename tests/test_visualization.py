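"""Glyph encoding, layout persistence and the plot suite."""

import numpy as np
import pytest
import matplotlib.pyplot as plt

from mdifp import (
    DEFAULT_GLYPHS,
    FingerprintFrameSet,
    GlyphSpec,
    NetworkLayout,
    aggregate_by_interaction,
    aggregate_by_time,
    classify,
    cross_set_similarity_matrix,
    difference_matrix,
    plot_cross_set_comparison,
    plot_difference_histogram,
    plot_difference_matrix,
    plot_identical_links,
    plot_occurrence,
    plot_residue_circular_chart,
    render_network,
    render_network_sequence,
)
from mdifp.synthetic import SyntheticSpec, default_columns, generate
from tests.conftest import random_frame_set


@pytest.fixture(autouse=True)
def close_figures():
    yield
    plt.close("all")


@pytest.fixture
def small_agg(rng):
    cols = default_columns(15)
    return aggregate_by_time(random_frame_set(rng, 30, cols))


class TestGlyphSpec:
    def test_default_map_covers_the_fifteen_renderable_types(self):
        assert len(DEFAULT_GLYPHS) == 15
        spec = GlyphSpec()
        for itype in DEFAULT_GLYPHS:
            marker, colour = spec.marker(itype)
            assert marker is not None and colour.startswith("#")

    def test_paired_types_share_shape_and_differ_in_colour(self):
        for first, second in [
            ("HBAcceptor", "HBDonor"), ("Anionic", "Cationic"),
            ("CationPi", "PiCation"), ("EdgeToFace", "FaceToFace"),
            ("MetalAcceptor", "MetalDonor"), ("XBAcceptor", "XBDonor"),
        ]:
            s1, c1 = DEFAULT_GLYPHS[first]
            s2, c2 = DEFAULT_GLYPHS[second]
            assert s1 == s2 and c1 != c2

    def test_unknown_type_or_shape_rejected(self):
        with pytest.raises(ValueError, match="no glyph"):
            GlyphSpec().marker("Interaction")
        with pytest.raises(ValueError, match="shape"):
            GlyphSpec({"Hydrophobic": ("Star", "Blue")})


class TestNetworkLayout:
    def test_star_layout_centres_ligand(self):
        cols = default_columns(8)
        layout = NetworkLayout.star(cols)
        assert layout.positions[layout.ligand] == (0.0, 0.0)
        assert len(layout.positions) == len({k.residue for k in cols}) + 1

    def test_save_load_round_trip(self, tmp_path):
        layout = NetworkLayout.star(default_columns(6))
        path = tmp_path / "layout.csv"
        layout.save(path)
        back = NetworkLayout.load(path)
        assert back.ligand == layout.ligand
        for node, (x, y) in layout.positions.items():
            assert back.positions[node] == (x, y)


class TestMatrixPlots:
    def test_heatmap_reflects_matrix_values(self, small_agg):
        dm = difference_matrix(small_agg)
        fig = plot_difference_matrix(dm)
        im = fig.axes[0].images[0]
        assert im.get_array().shape == dm.shape
        np.testing.assert_array_equal(np.asarray(im.get_array()), dm)

    def test_non_square_matrix_rejected(self):
        with pytest.raises(ValueError, match="square"):
            plot_difference_matrix(np.zeros((2, 3)))

    def test_histogram_counts_upper_triangle(self):
        dm = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        fig = plot_difference_histogram(dm)
        heights = [p.get_height() for p in fig.axes[0].patches]
        assert sum(heights) == 3  # three upper-triangle entries
        fig1 = plot_difference_histogram(np.zeros((1, 1)))
        assert not fig1.axes[0].patches


class TestLinePlots:
    def test_top_occurrences_annotated_with_tie_break(self, toy_columns):
        bits = np.array([[1, 0, 0, 0]] * 2 + [[0, 1, 0, 0]] + [[1, 0, 0, 0]] * 2)
        agg = aggregate_by_time(FingerprintFrameSet.from_bits(bits, toy_columns))
        fig = plot_occurrence(agg, annotate_top=2)
        labels = {t.get_text() for t in fig.axes[0].texts}
        assert labels == {"IFP 0", "IFP 2"}  # counts [2,1,2]: ties -> lower id

    def test_identical_links_drawn_per_zero_difference_pair(self, toy_columns):
        bits = np.array([[1, 0, 0, 0]] * 2 + [[0, 1, 0, 0]] + [[1, 0, 0, 0]] * 2)
        agg = aggregate_by_time(FingerprintFrameSet.from_bits(bits, toy_columns))
        fig = plot_identical_links(agg)
        links = [ln for ln in fig.axes[0].lines if len(ln.get_xdata()) == 2]
        assert len(links) == 1
        assert links[0].get_xdata().tolist() == [0, 2]

    def test_interaction_aggregated_set_has_no_links(self, rng, toy_columns):
        agg = aggregate_by_interaction(random_frame_set(rng, 20, toy_columns))
        fig = plot_identical_links(agg)
        assert not [ln for ln in fig.axes[0].lines if len(ln.get_xdata()) == 2]


class TestCircularChart:
    def test_always_present_interaction_fills_the_ring(self):
        cols = default_columns(4)
        bits = np.zeros((16, 4), dtype=np.uint8)
        bits[:, 0] = 1          # always present
        bits[8:, 1] = 1         # second half only
        fset = FingerprintFrameSet.from_bits(bits, cols)
        fig = plot_residue_circular_chart(fset, cols[0].residue)
        arcs = fig.axes[0].lines
        assert arcs
        full = max(np.ptp(ln.get_xdata()) for ln in arcs)
        assert full == pytest.approx(2 * np.pi)
        fig2 = plot_residue_circular_chart(fset, cols[1].residue)
        half = max(np.ptp(ln.get_xdata()) for ln in fig2.axes[0].lines)
        assert half == pytest.approx(np.pi)

    def test_unknown_residue_raises(self, toy_set):
        with pytest.raises(ValueError, match="not found"):
            plot_residue_circular_chart(toy_set, "GLY999")


class TestNetworks:
    def test_all_zero_fingerprint_draws_no_glyphs(self):
        cols = default_columns(6)
        fig = render_network(np.zeros(6, dtype=int), cols)
        glyph_pts = [ln for ln in fig.axes[0].lines if ln.get_marker() != "None"]
        assert not glyph_pts

    def test_single_hydrophobic_bit_draws_one_blue_circle(self):
        cols = default_columns(6)  # column 0 is Hydrophobic by construction
        ifp = np.zeros(6, dtype=int)
        ifp[0] = 1
        fig = render_network(ifp, cols)
        glyph_pts = [ln for ln in fig.axes[0].lines if ln.get_marker() == "o"]
        assert len(glyph_pts) == 1
        assert glyph_pts[0].get_color() == "#1f77b4"

    def test_stored_layout_reused_verbatim(self, tmp_path):
        cols = default_columns(5)
        layout = NetworkLayout.star(cols)
        path = tmp_path / "layout.csv"
        layout.save(path)
        loaded = NetworkLayout.load(path)
        a = render_network(np.ones(5, dtype=int), cols, loaded)
        b = render_network(np.eye(5, dtype=int)[0], cols, loaded)
        # node scatter positions identical across the two renders
        pa = a.axes[0].collections[0].get_offsets()
        pb = b.axes[0].collections[0].get_offsets()
        np.testing.assert_array_equal(np.asarray(pa), np.asarray(pb))

    def test_missing_layout_node_raises(self):
        cols = default_columns(4)
        layout = NetworkLayout({"LIG1": (0, 0)}, "LIG1")
        with pytest.raises(ValueError, match="lacks node positions"):
            render_network(np.ones(4, dtype=int), cols, layout)

    def test_sequence_writes_one_frame_per_ifp(self, tmp_path, rng):
        cols = default_columns(8)
        agg = aggregate_by_time(random_frame_set(rng, 12, cols))
        files = render_network_sequence(agg, tmp_path / "seq", dpi=40)
        assert len(files) == len(agg)
        assert [f.name for f in files] == sorted(f.name for f in files)

    def test_gif_export_has_one_frame_per_ifp(self, tmp_path, toy_columns):
        import imageio.v3 as iio

        bits = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [1, 1, 0, 0]])
        agg = aggregate_by_time(FingerprintFrameSet.from_bits(bits, toy_columns))
        out = tmp_path / "seq.gif"
        render_network_sequence(agg, out, out_format="gif", dpi=40)
        frames = iio.imread(out, index=None)
        assert frames.shape[0] == 3


class TestCrossSetFigure:
    def test_black_and_red_lines_match_classification(self, rng):
        cols = default_columns(10)
        spec_a = SyntheticSpec(n_frames=300, n_columns=10, n_states=2,
                               mean_dwell=80, seed=1, columns=cols)
        spec_b = SyntheticSpec(n_frames=300, n_columns=10, n_states=3,
                               mean_dwell=80, seed=2, columns=cols)
        a = aggregate_by_time(generate(spec_a)[0])
        b = aggregate_by_time(generate(spec_b)[0])
        cls = classify(cross_set_similarity_matrix(a, b))
        fig = plot_cross_set_comparison(a, b, cls)
        black = [ln for ln in fig.axes[0].lines if ln.get_color() == "black"]
        red = [ln for ln in fig.axes[0].lines if ln.get_color() == "red"]
        assert len(black) == cls.pair_counts["identical"]
        assert len(red) == cls.pair_counts["similar"]

    def test_self_comparison_draws_black_line_at_every_index(self, rng, toy_columns):
        agg = aggregate_by_interaction(random_frame_set(rng, 20, toy_columns))
        cls = classify(cross_set_similarity_matrix(agg, agg))
        fig = plot_cross_set_comparison(agg, agg, cls)
        black = [ln for ln in fig.axes[0].lines if ln.get_color() == "black"]
        assert len(black) >= len(agg)

    def test_shape_mismatch_rejected(self, rng, toy_columns):
        a = aggregate_by_interaction(random_frame_set(rng, 20, toy_columns))
        b = aggregate_by_interaction(random_frame_set(rng, 10, toy_columns))
        cls = classify(cross_set_similarity_matrix(a, a))
        with pytest.raises(ValueError, match="does not match"):
            plot_cross_set_comparison(a, b, cls)
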
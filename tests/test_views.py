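import numpy as np
import pytest

from omiclink.compare import confusion_matrix, sort_confusion
from omiclink.datamodel import FeatureMatrix, GenomicFeature, Selection, StateMatrix
from omiclink.unsupervised import hierarchical_cluster, pairwise_distance
from omiclink.views import (
    DivergingScale,
    MISSING_COLOR,
    Scene,
    aberration_frequencies,
    export_svg,
    render_barchart,
    render_chromosome_browser,
    render_confusion,
    render_correlation_matrix,
    render_dendrogram,
    render_eventchart,
    render_heatmap,
    render_histogram,
    svg_string,
)
from omiclink.views.charts import histogram_counts


def expr2x2():
    return FeatureMatrix(np.array([[0.0, 1.0], [-1.0, 2.0]]),
                         ["g1", "g2"], ["s1", "s2"])


class TestColorscale:
    def test_midpoint_maps_to_mid_color_exactly(self):
        scale = DivergingScale(-2.0, 2.0)
        assert scale(0.0) == "#ffffff"

    def test_endpoints_and_missing(self):
        scale = DivergingScale(-1.0, 1.0)
        assert scale(-1.0) == "#2166ac" and scale(1.0) == "#b2182b"
        assert scale(float("nan")) == MISSING_COLOR

    def test_symmetric_clip_from_matrix(self, rng):
        scale = DivergingScale.from_matrix(rng.normal(size=(50, 20)))
        assert scale.vmin == -scale.vmax


class TestHeatmap:
    def test_cell_count_includes_missing(self):
        m = expr2x2()
        m.values[0, 0] = np.nan
        scene = render_heatmap(m)
        rects = scene.by_kind("rect")
        assert len(rects) == 4
        assert rects[0].color == MISSING_COLOR

    def test_selection_flags_exactly_one_column(self):
        scene = render_heatmap(expr2x2(), selection=Selection.of(samples=["s2"]))
        hl = {p.provenance for p in scene.primitives if p.highlighted}
        assert hl == {"g1|s2", "g2|s2"}

    def test_annotation_bar_above_matrix(self):
        scene = render_heatmap(expr2x2(),
                               annotations=[("grp", {"s1": "a", "s2": "b"},
                                             {"a": "#ff0000", "b": "#00ff00"})])
        assert len(scene.by_kind("rect")) == 6
        assert scene.primitives[0].provenance == "grp:s1"
        assert scene.primitives[0].color == "#ff0000"

    def test_bad_order_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            render_heatmap(expr2x2(), row_order=[0, 0])

    def test_state_matrix_uses_categorical_scale(self):
        s = StateMatrix(np.array([[-1.0, 1.0]]), ["m1"], ["s1", "s2"])
        scene = render_heatmap(s)
        assert [p.color for p in scene.by_kind("rect")] == ["#2166ac", "#b2182b"]


class TestDendrogramView:
    def dend(self, n=3):
        pts = np.arange(n, dtype=float).reshape(-1, 1) ** 2
        return hierarchical_cluster(pairwise_distance(pts), "single")

    def test_three_leaves_two_brackets(self):
        scene = render_dendrogram(self.dend())
        assert len(scene.by_kind("polyline")) == 2

    def test_leaf_positions_match_heatmap_columns(self):
        # every leaf is an endpoint of some bracket, at a heatmap cell center
        dend = self.dend(4)
        scene = render_dendrogram(dend, cell=10.0)
        xs = {round(x, 6) for p in scene.by_kind("polyline") for x, _ in p.geometry}
        leaf_xs = {(pos + 0.5) * 10.0 for pos in range(4)}
        assert leaf_xs <= xs

    def test_selected_subtree_highlighted(self):
        dend = self.dend()  # items "0","1","2"; 0,1 merge first
        scene = render_dendrogram(dend, selection=Selection.of(genes=["0", "1"]))
        flags = [p.highlighted for p in scene.by_kind("polyline")]
        assert flags == [True, False]


class TestBarchart:
    def test_by_count_order(self):
        scene = render_barchart({"A": 3, "B": 1, "C": 2}, order="by-count")
        assert [p.provenance for p in scene.by_kind("rect")] == \
            ["class:A", "class:C", "class:B"]

    def test_selected_subbar_fraction(self):
        scene = render_barchart({"A": 3}, selected_counts={"A": 2})
        full, sub = scene.by_kind("rect")
        assert sub.highlighted and sub.geometry[3] == pytest.approx(
            full.geometry[3] * 2 / 3)

    def test_empty_classes_empty_scene(self):
        assert render_barchart({}).primitives == []


class TestHistogram:
    def test_halfopen_bins(self):
        ks, counts = histogram_counts([0.1, 0.2, 0.9], 0.5, 0.0)
        assert [counts[k] for k in ks] == [2, 1]

    def test_edge_value_goes_right(self):
        ks, counts = histogram_counts([0.5], 0.5, 0.0)
        assert ks == [1] and counts[1] == 1

    def test_all_missing_empty_scene(self):
        scene = render_histogram([np.nan, np.nan], binwidth=1.0)
        assert scene.primitives == []

    def test_counts_sum_to_observed(self, rng):
        v = rng.normal(size=200)
        v[:13] = np.nan
        for w in (0.3, 0.7, 2.0):
            _, counts = histogram_counts(v, w)
            assert sum(counts.values()) == 187

    def test_nonpositive_binwidth_rejected(self):
        with pytest.raises(ValueError, match="binwidth"):
            render_histogram([1.0], binwidth=0.0)


class TestEventchart:
    def test_event_gets_terminal_tick(self):
        scene = render_eventchart([12.0], [True], ["s1"])
        line, = scene.by_kind("line")
        tick, = scene.by_kind("tick")
        assert line.geometry[0] == 0.0
        assert tick.geometry[0] == pytest.approx(line.geometry[2])

    def test_censored_has_no_tick(self):
        scene = render_eventchart([30.0], [False], ["s1"])
        assert len(scene.by_kind("line")) == 1 and scene.by_kind("tick") == []

    def test_groups_contiguous(self):
        scene = render_eventchart([1.0, 2.0, 3.0, 4.0], [True] * 4,
                                  ["a", "b", "c", "d"],
                                  group={"a": "g1", "b": "g2", "c": "g1", "d": "g2"})
        ys = {p.provenance: p.geometry[1] for p in scene.by_kind("line")}
        assert ys["a"] < ys["c"] < ys["b"] < ys["d"]

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            render_eventchart([-1.0], [True], ["s1"])


class TestCorrelationMatrix:
    def test_identical_columns_full_positive(self):
        m = FeatureMatrix(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]),
                          ["g1", "g2", "g3"], ["s1", "s2"])
        scene = render_correlation_matrix(m, axis="columns")
        scale = DivergingScale(-1.0, 1.0)
        colors = {p.provenance: p.color for p in scene.by_kind("rect")}
        assert colors["s1|s2"] == scale(1.0)
        assert colors["s1|s1"] == scale(1.0)

    def test_anticorrelated_pair(self):
        m = FeatureMatrix(np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]),
                          ["g1", "g2", "g3"], ["s1", "s2"])
        scene = render_correlation_matrix(m, axis="columns")
        colors = {p.provenance: p.color for p in scene.by_kind("rect")}
        assert colors["s1|s2"] == DivergingScale(-1.0, 1.0)(-1.0)


class TestAberrationFrequencies:
    def states(self):
        vals = np.array([[1.0, 1.0, 0.0, -1.0],
                         [np.nan, np.nan, np.nan, np.nan],
                         [0.0, 0.0, 0.0, 0.0]])
        return StateMatrix(vals, ["m1", "m2", "m3"], list("abcd"))

    def markers(self):
        return [GenomicFeature("m1", "1", 100, 100),
                GenomicFeature("m2", "1", 200, 200),
                GenomicFeature("m3", "1", 300, 300)]

    def test_counting(self):
        f = aberration_frequencies(self.states(), self.markers(), "1")
        row = f[f.marker == "m1"].iloc[0]
        assert row.gain == 0.5 and row.loss == 0.25

    def test_all_missing_marker_omitted(self):
        f = aberration_frequencies(self.states(), self.markers(), "1")
        assert "m2" not in set(f.marker)

    def test_empty_chromosome(self):
        f = aberration_frequencies(self.states(), self.markers(), "2")
        assert len(f) == 0

    def test_fractions_sum_to_one(self, study):
        for chrom in study.design.chromosome_lengths:
            f = aberration_frequencies(study.states, study.marker_features, chrom)
            normal = 1.0 - f.gain - f.loss
            assert ((f.gain + f.loss + normal - 1.0).abs() < 1e-12).all()

    def test_planted_fraction_exact(self, study):
        seg = study.truth["segments"][0]
        f = aberration_frequencies(study.states, study.marker_features,
                                   seg["chromosome"])
        got = f[f.marker.isin(seg["markers"])]
        assert (got.gain == seg["overall_fraction"]).all()


class TestChromosomeBrowser:
    def test_overview_has_axis_per_chromosome(self, study):
        freqs = {c: aberration_frequencies(study.states, study.marker_features, c)
                 for c in study.design.chromosome_lengths}
        scene = render_chromosome_browser(freqs, study.design.chromosome_lengths)
        axes = [p for p in scene.by_kind("line")]
        assert len(axes) == len(study.design.chromosome_lengths)

    def test_24_chromosome_overview(self):
        lengths = {**{str(i): 10_000 for i in range(1, 23)}, "X": 10_000, "Y": 10_000}
        scene = render_chromosome_browser({}, lengths)
        assert len(scene.by_kind("line")) == 24

    def test_single_mode_without_cytobands_logs(self, study, caplog):
        freqs = {c: aberration_frequencies(study.states, study.marker_features, c)
                 for c in study.design.chromosome_lengths}
        with caplog.at_level("WARNING", logger="omiclink.views.genome"):
            render_chromosome_browser(freqs, study.design.chromosome_lengths,
                                      mode="single-chromosome", chromosome="1")
        assert any("cytoband" in r.message for r in caplog.records)

    def test_cytoband_track_rendered(self, study):
        freqs = {"1": aberration_frequencies(study.states, study.marker_features, "1")}
        bands = [{"name": "1p11", "chromosome": "1", "start": 1,
                  "end": 50_000_000, "stain": "gneg"}]
        scene = render_chromosome_browser(freqs, study.design.chromosome_lengths,
                                          cytobands=bands, mode="single-chromosome",
                                          chromosome="1")
        assert any(p.provenance == "band:1p11" for p in scene.primitives)


class TestConfusionView:
    def cm(self, counts):
        a = {}
        b = {}
        i = 0
        for r, row in enumerate(counts):
            for c, k in enumerate(row):
                for _ in range(k):
                    a[i] = r
                    b[i] = c
                    i += 1
        cm = confusion_matrix(a, b)
        sort_confusion(cm)
        return cm

    def test_diagonal_rects_equal_area(self):
        scene = render_confusion(self.cm([[2, 0], [0, 2]]))
        rects = scene.by_kind("rect")
        assert len(rects) == 2
        assert rects[0].geometry[2] == pytest.approx(rects[1].geometry[2])

    def test_zero_cells_emit_nothing(self):
        scene = render_confusion(self.cm([[3, 0], [0, 1]]))
        assert len(scene.by_kind("rect")) == 2

    def test_area_proportional_to_count(self):
        s1 = render_confusion(self.cm([[1, 0], [0, 2]]))
        areas = sorted(p.geometry[2] * p.geometry[3] for p in s1.by_kind("rect"))
        assert areas[1] == pytest.approx(2 * areas[0])


class TestSVGExport:
    def test_empty_scene_valid_svg(self, tmp_path):
        p = tmp_path / "e.svg"
        export_svg(Scene(10, 10), p)
        text = p.read_text()
        assert text.startswith("<?xml") and "</svg>" in text

    def test_one_element_per_primitive_with_provenance(self):
        scene = render_heatmap(expr2x2())
        s = svg_string(scene)
        assert s.count("<rect") == 4
        assert 'data-id="g1|s1"' in s

    def test_reexport_byte_identical(self, tmp_path):
        scene = render_heatmap(expr2x2(), selection=Selection.of(genes=["g1"]))
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        export_svg(scene, p1)
        export_svg(scene, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_highlight_flags_equal_selection(self, study, linkmap, registry):
        from omiclink.linkage import propagate_selection
        sel = propagate_selection(
            Selection.of(genes=[study.expression.row_ids[0]]), registry, linkmap)
        scene = render_heatmap(study.expression, selection=sel)
        hl_rows = {p.provenance.split("|")[0] for p in scene.primitives if p.highlighted}
        assert hl_rows == set(sel.genes)
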
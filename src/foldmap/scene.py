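"""2D glyph scenes.

A :class:`Scene` is an ordered collection of drawable elements built
from an oriented structure: helices become zigzag ribbons, strands
filled triangles pointing toward the C-terminus, and the non-regular
remainder straight connector lines. Elements carry a mean depth (the
average view-axis coordinate of their residues) and are layered
back-to-front, so nearer elements are drawn last. Annotations, termini
and disulfide bridges are drawn above the glyph layer.

Glyphs are anchored only at the projected start/end Cα of each segment:
internal curvature is deliberately discarded to emphasize topology over
fine-grained detail.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .orientation import RotationFrame, apply_frame
from .structure import (DisulfidePair, ProteinStructure, Residue,
                        SecondaryStructureSegment)
from .styles import AnnotationSpec, StyleSheet

__all__ = [
    "SceneElement",
    "Scene",
    "CanvasTransform",
    "SceneOptions",
    "AnnotationError",
    "helix_glyph",
    "strand_glyph",
    "coil_glyph",
    "build_scene",
    "depth_sort",
    "fit_canvas",
]

GLYPH_KINDS = ("helix", "strand", "coil")
OVERLAY_KINDS = ("annotation_point", "annotation_line", "annotation_area",
                 "disulfide", "terminus_label", "segment_label")


class AnnotationError(ValueError):
    """An annotation references a residue the structure does not have."""


@dataclass
class SceneElement:
    kind: str
    points: np.ndarray            # (n, 2) canvas coordinates
    mean_depth: float
    style_key: str
    seq_order: int
    label: Optional[str] = None
    closed: bool = False          # filled polygon vs. polyline
    is_disc: bool = False         # degenerate glyph: disc at points[0]
    disc_radius: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.points.shape[0] < 1:
            raise ValueError("element needs at least one point")
        if not math.isfinite(self.mean_depth):
            raise ValueError("mean_depth must be finite")


@dataclass(frozen=True)
class CanvasTransform:
    """Isotropic scale + translation, with a y-flip applied at SVG time."""

    scale: float = 1.0
    offset: tuple[float, float] = (0.0, 0.0)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) * self.scale + np.asarray(self.offset)


@dataclass
class SceneOptions:
    show_termini: bool = True
    show_segment_numbers: bool = False
    label_offset: float = 6.0  # canvas units perpendicular to the glyph axis


@dataclass
class Scene:
    elements: list[SceneElement]
    style: StyleSheet
    transform: CanvasTransform = field(default_factory=CanvasTransform)
    width: float = 1000.0
    height: float = 1000.0
    padding: float = 40.0

    def glyphs(self) -> list[SceneElement]:
        return [e for e in self.elements if e.kind in GLYPH_KINDS]

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) over untransformed element points."""
        pts = np.vstack([e.points for e in self.elements]) if self.elements \
            else np.zeros((1, 2))
        return (float(pts[:, 0].min()), float(pts[:, 1].min()),
                float(pts[:, 0].max()), float(pts[:, 1].max()))


# ---------------------------------------------------------------------------
# Glyph construction

def _disc(point: np.ndarray, radius: float, kind: str, style_key: str,
          depth: float, seq_order: int) -> SceneElement:
    return SceneElement(kind, np.asarray(point, dtype=float).reshape(1, 2),
                        depth, style_key, seq_order,
                        is_disc=True, disc_radius=radius)


def helix_glyph(start: Sequence[float], end: Sequence[float], n_res: int,
                style: StyleSheet, *, depth: float = 0.0,
                seq_order: int = 0) -> SceneElement:
    """Zigzag ribbon from start to end.

    ``k = max(2, round(n_res / 2))`` interior vertices alternate at
    ±amplitude perpendicular to the axis, evenly spaced along it. A
    fully foreshortened helix (start == end) degenerates to a disc of
    radius equal to the amplitude.
    """
    if n_res < 1:
        raise ValueError("n_res >= 1")
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    amp = style.helix.amplitude
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    if length < 1e-9:
        return _disc(p0, amp, "helix", "helix", depth, seq_order)
    u = axis / length
    perp = np.array([-u[1], u[0]])
    k = max(2, round(n_res / 2))
    ts = np.linspace(0.0, 1.0, k + 2)
    pts = [p0]
    for i, t in enumerate(ts[1:-1]):
        sign = 1.0 if i % 2 == 0 else -1.0
        pts.append(p0 + t * axis + sign * amp * perp)
    pts.append(p1)
    return SceneElement("helix", np.array(pts), depth, "helix", seq_order)


def strand_glyph(start: Sequence[float], end: Sequence[float],
                 style: StyleSheet, *, depth: float = 0.0,
                 seq_order: int = 0) -> SceneElement:
    """Filled isoceles triangle; apex at ``end`` (toward the C-terminus)."""
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    w = style.strand.base_width
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    if length < 1e-9:
        return _disc(p0, w / 2, "strand", "strand", depth, seq_order)
    u = axis / length
    perp = np.array([-u[1], u[0]])
    half = w / 2.0
    pts = np.array([p0 + half * perp, p0 - half * perp, p1])
    return SceneElement("strand", pts, depth, "strand", seq_order, closed=True)


def coil_glyph(prev_end: Sequence[float], next_start: Sequence[float],
               style: StyleSheet, *, depth: float = 0.0,
               seq_order: int = 0) -> Optional[SceneElement]:
    """Straight connector line; zero-length coils emit nothing."""
    p0 = np.asarray(prev_end, dtype=float)
    p1 = np.asarray(next_start, dtype=float)
    if float(np.linalg.norm(p1 - p0)) < 1e-9:
        return None
    return SceneElement("coil", np.array([p0, p1]), depth, "coil", seq_order)


# ---------------------------------------------------------------------------
# Scene assembly

def _resolve(structure: ProteinStructure, chain_id: str, seq_num: int,
             ref: str) -> Residue:
    try:
        chain = structure.chain(chain_id)
    except KeyError as exc:
        raise AnnotationError(f"annotation {ref!r}: {exc}") from exc
    for r in chain.residues:
        if r.seq_num == seq_num:
            if r.ca is None:
                raise AnnotationError(f"annotation {ref!r}: residue has no CA")
            return r
    raise AnnotationError(f"annotation {ref!r}: residue not found")


def build_scene(structure: ProteinStructure,
                frame: RotationFrame,
                segments: Sequence[SecondaryStructureSegment],
                annotations: Sequence[AnnotationSpec] = (),
                disulfides: Sequence[DisulfidePair] = (),
                style: Optional[StyleSheet] = None,
                options: Optional[SceneOptions] = None) -> Scene:
    """Project the structure and build one glyph per segment.

    Glyph anchors are the projected Cα of the segment's first and last
    residue; the mean depth of an element is the mean projected z over
    all the segment's Cα. Consecutive glyphs are joined by coil
    connectors so the trace is C0-continuous. Annotation, terminus and
    disulfide elements are added on top.
    """
    style = style or StyleSheet()
    options = options or SceneOptions()

    elements: list[SceneElement] = []
    seq_order = 0
    per_chain_anchor: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}

    proj_cache: dict[tuple[str, int, str], np.ndarray] = {}

    def project_residue(res: Residue) -> np.ndarray:
        key = res.key
        if key not in proj_cache:
            proj_cache[key] = apply_frame(res.ca.reshape(1, 3), frame)[0]
        return proj_cache[key]

    for chain in structure.chains:
        chain_segments = [s for s in segments if s.chain_id == chain.chain_id]
        chain_segments = sorted(chain_segments, key=lambda s: s.start)
        anchors: list[tuple[np.ndarray, np.ndarray]] = []
        for seg in chain_segments:
            residues = [r for r in chain.residues[seg.start:seg.end + 1]
                        if r.ca is not None]
            if not residues:
                continue
            proj = np.array([project_residue(r) for r in residues])
            depth = float(proj[:, 2].mean())
            start2d, end2d = proj[0, :2], proj[-1, :2]
            if seg.ss_type == "helix":
                el = helix_glyph(start2d, end2d, seg.n_res, style,
                                 depth=depth, seq_order=seq_order)
            elif seg.ss_type == "strand":
                el = strand_glyph(start2d, end2d, style,
                                  depth=depth, seq_order=seq_order)
            else:
                el = coil_glyph(start2d, end2d, style,
                                depth=depth, seq_order=seq_order)
            if el is not None:
                elements.append(el)
                if options.show_segment_numbers and seg.ss_type != "coil":
                    for pos, res in ((start2d, residues[0]), (end2d, residues[-1])):
                        elements.append(SceneElement(
                            "segment_label", pos.reshape(1, 2), depth,
                            "label", seq_order, label=str(res.seq_num)))
            anchors.append((start2d, end2d))
            seq_order += 1
        # connectors between consecutive glyph endpoints
        for (_, prev_end), (next_start, _) in zip(anchors, anchors[1:]):
            conn = coil_glyph(prev_end, next_start, style, depth=0.0,
                              seq_order=seq_order)
            if conn is not None:
                elements.append(conn)
                seq_order += 1
        per_chain_anchor[chain.chain_id] = anchors

    if options.show_termini:
        for chain in structure.chains:
            cas = [r for r in chain.residues if r.ca is not None]
            if not cas:
                continue
            for tag, res in (("N", cas[0]), ("C", cas[-1])):
                p = project_residue(res)
                elements.append(SceneElement(
                    "terminus_label", p[:2].reshape(1, 2), float(p[2]),
                    "label", seq_order, label=tag))
                seq_order += 1

    for i, ann in enumerate(annotations):
        refs = [_resolve(structure, c, n, ann.raw) for c, n in ann.residues(structure)]
        proj = np.array([project_residue(r) for r in refs])
        kind = f"annotation_{ann.kind}"
        elements.append(SceneElement(
            kind, proj[:, :2], float(proj[:, 2].mean()),
            ann.style_key or "annotation", seq_order,
            label=ann.label, closed=(ann.kind == "area"),
            is_disc=(ann.kind == "point"),
            disc_radius=style.annotation.point_radius))
        seq_order += 1

    for pair in disulfides:
        pa = project_residue(pair.residue_a)
        pb = project_residue(pair.residue_b)
        elements.append(SceneElement(
            "disulfide", np.array([pa[:2], pb[:2]]),
            float((pa[2] + pb[2]) / 2), "disulfide", seq_order))
        seq_order += 1

    return Scene(elements, style)


def depth_sort(scene: Scene) -> Scene:
    """Order elements back-to-front.

    Glyphs sort by ascending mean depth (+z toward the viewer, so the
    most negative depth is farthest and drawn first), ties broken by
    sequence order; labels, annotations and disulfides always draw
    after every glyph.
    """
    glyphs = [e for e in scene.elements if e.kind in GLYPH_KINDS]
    overlays = [e for e in scene.elements if e.kind not in GLYPH_KINDS]
    glyphs.sort(key=lambda e: (e.mean_depth, e.seq_order))
    overlays.sort(key=lambda e: (e.mean_depth, e.seq_order))
    return replace_elements(scene, glyphs + overlays)


def replace_elements(scene: Scene, elements: list[SceneElement]) -> Scene:
    return Scene(elements, scene.style, scene.transform,
                 scene.width, scene.height, scene.padding)


def fit_canvas(scene: Scene, width: float = 1000.0, height: float = 1000.0,
               padding: float = 40.0) -> Scene:
    """Compute the isotropic canvas transform.

    ``s = min((width − 2p)/extent_x, (height − 2p)/extent_y)``, content
    centered; zero-extent axes contribute scale 1. The y-flip for SVG's
    y-down convention happens at serialization, not here.
    """
    if width <= 2 * padding or height <= 2 * padding:
        raise ValueError("canvas smaller than twice the padding")
    xmin, ymin, xmax, ymax = scene.bounding_box()
    ex, ey = xmax - xmin, ymax - ymin
    candidates = []
    if ex > 1e-12:
        candidates.append((width - 2 * padding) / ex)
    if ey > 1e-12:
        candidates.append((height - 2 * padding) / ey)
    s = min(candidates) if candidates else 1.0
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
    offset = (width / 2 - s * cx, height / 2 - s * cy)
    out = replace_elements(scene, scene.elements)
    out.transform = CanvasTransform(s, offset)
    out.width, out.height, out.padding = width, height, padding
    return out
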
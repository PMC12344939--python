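"""SVG and PNG serialization of scenes.

The SVG writer is deliberately tiny and deterministic: identical scene
and style give byte-identical output. Each element becomes one shape
node carrying a CSS class per kind, drawn in scene order (which after
``depth_sort`` is back-to-front). The internal coordinate system is
y-up; the single y-flip to SVG's y-down convention happens here.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional
from xml.sax.saxutils import escape

import numpy as np

from .scene import Scene, SceneElement
from .styles import StyleSheet

__all__ = ["render_svg", "render_png", "save_scene"]


def _fmt(v: float) -> str:
    # fixed precision keeps output deterministic across platforms
    s = f"{v:.3f}"
    return "0.000" if s == "-0.000" else s


def _element_style(el: SceneElement, style: StyleSheet,
                   opacity: Optional[float]) -> str:
    kind = el.kind
    if kind == "helix":
        s = style.helix
        attrs = (f'fill="{s.fill}" stroke="{s.stroke}" '
                 f'stroke-width="{_fmt(s.stroke_width)}" '
                 f'stroke-linejoin="round"')
        base_op = s.opacity
    elif kind == "strand":
        s = style.strand
        attrs = (f'fill="{s.fill}" stroke="{s.stroke}" '
                 f'stroke-width="{_fmt(s.stroke_width)}"')
        base_op = s.opacity
    elif kind == "coil":
        s = style.coil
        attrs = (f'fill="none" stroke="{s.stroke}" '
                 f'stroke-width="{_fmt(s.stroke_width)}" stroke-linecap="round"')
        base_op = s.opacity
    elif kind == "disulfide":
        s = style.disulfide
        attrs = (f'fill="none" stroke="{s.stroke}" '
                 f'stroke-width="{_fmt(s.stroke_width)}" '
                 f'stroke-dasharray="{s.dash}"')
        base_op = s.opacity
    elif kind in ("terminus_label", "segment_label"):
        s = style.label
        attrs = (f'fill="{s.fill}" font-size="{_fmt(s.font_size)}" '
                 f'font-family="{s.font_family}" text-anchor="middle"')
        base_op = s.opacity
    else:  # annotations
        s = style.annotation
        fill = s.fill if el.kind != "annotation_line" else "none"
        attrs = (f'fill="{fill}" stroke="{s.stroke}" '
                 f'stroke-width="{_fmt(s.stroke_width)}"')
        base_op = s.opacity
    op = base_op * (opacity if opacity is not None else 1.0)
    if op < 1.0:
        attrs += f' opacity="{_fmt(op)}"'
    return attrs


def _svg_points(el: SceneElement, scene: Scene) -> np.ndarray:
    pts = scene.transform.apply(el.points)
    pts[:, 1] = scene.height - pts[:, 1]  # y-flip: math y-up -> SVG y-down
    return pts


def _element_node(el: SceneElement, scene: Scene,
                  opacity: Optional[float]) -> str:
    pts = _svg_points(el, scene)
    cls = el.kind
    attrs = _element_style(el, scene.style, opacity)
    if el.label is not None and el.kind in ("terminus_label", "segment_label"):
        x, y = pts[0]
        return (f'<text class="{cls}" x="{_fmt(x)}" y="{_fmt(y)}" {attrs}>'
                f'{escape(el.label)}</text>')
    if el.is_disc:
        x, y = pts[0]
        r = el.disc_radius * scene.transform.scale
        node = (f'<circle class="{cls}" cx="{_fmt(x)}" cy="{_fmt(y)}" '
                f'r="{_fmt(max(r, 1.0))}" {attrs}/>')
    else:
        coords = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)
        tag = "polygon" if el.closed else "polyline"
        node = f'<{tag} class="{cls}" points="{coords}" {attrs}/>'
    if el.label:
        x, y = pts[0]
        ls = scene.style.label
        node += (f'<text class="annotation_label" x="{_fmt(x)}" '
                 f'y="{_fmt(y - 6)}" fill="{ls.fill}" '
                 f'font-size="{_fmt(ls.font_size)}" '
                 f'font-family="{ls.font_family}" text-anchor="middle">'
                 f'{escape(el.label)}</text>')
    return node


def render_svg(scene: Scene, member_scenes: Optional[list[Scene]] = None,
               member_opacity: Optional[float] = None) -> str:
    """Serialize a (fitted, depth-sorted) scene to an SVG 1.1 document.

    For overlays, pass the member scenes; each is emitted as a group
    with the shared transform and uniform ``member_opacity``.
    """
    w, h = scene.width, scene.height
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(w)}" height="{_fmt(h)}" '
        f'viewBox="0 0 {_fmt(w)} {_fmt(h)}">',
        f'<rect class="canvas" x="0" y="0" width="{_fmt(w)}" '
        f'height="{_fmt(h)}" fill="{scene.style.canvas.background}"/>',
    ]
    if member_scenes is None:
        for el in scene.elements:
            lines.append(_element_node(el, scene, None))
    else:
        for i, member in enumerate(member_scenes):
            lines.append(f'<g class="member" data-member="{i}">')
            shared = Scene(member.elements, member.style, scene.transform,
                           scene.width, scene.height, scene.padding)
            for el in member.elements:
                lines.append(_element_node(el, shared, member_opacity))
            lines.append('</g>')
    lines.append('</svg>')
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Raster export

def render_png(scene: Scene, path: str | Path, scale: int = 2,
               member_scenes: Optional[list[Scene]] = None,
               member_opacity: Optional[float] = None) -> None:
    """Draw the scene directly to a PNG at ``scale``× canvas resolution.

    Raster output is intended for overlays of many members where SVG
    files grow large; per-member alpha layers are composited so overlap
    accumulates darkness exactly like the SVG opacity encoding.
    """
    from PIL import Image, ImageDraw

    W, H = int(scene.width * scale), int(scene.height * scale)
    base = Image.new("RGBA", (W, H), scene.style.canvas.background)

    def draw_scene(target: Image.Image, sc: Scene, alpha: float) -> None:
        layer = Image.new("RGBA", (W, H), (0, 0, 0, 0))
        d = ImageDraw.Draw(layer)
        shared = Scene(sc.elements, sc.style, scene.transform,
                       scene.width, scene.height, scene.padding)
        for el in sc.elements:
            pts = _svg_points(el, shared) * scale
            xy = [tuple(p) for p in pts]
            st = sc.style
            if el.kind == "helix":
                _poly(d, xy, el, st.helix.stroke, st.helix.fill,
                      st.helix.stroke_width * scale, closed=False)
            elif el.kind == "strand":
                _poly(d, xy, el, st.strand.stroke, st.strand.fill,
                      st.strand.stroke_width * scale, closed=True)
            elif el.kind == "coil":
                d.line(xy, fill=st.coil.stroke,
                       width=max(1, int(st.coil.stroke_width * scale)))
            elif el.kind == "disulfide":
                d.line(xy, fill=st.disulfide.stroke,
                       width=max(1, int(st.disulfide.stroke_width * scale)))
            elif el.kind in ("terminus_label", "segment_label"):
                if el.label:
                    d.text(xy[0], el.label, fill=st.label.fill)
            else:
                if el.is_disc:
                    x, y = xy[0]
                    r = max(el.disc_radius * shared.transform.scale * scale, 2)
                    d.ellipse([x - r, y - r, x + r, y + r],
                              fill=st.annotation.fill, outline=st.annotation.stroke)
                else:
                    _poly(d, xy, el, st.annotation.stroke,
                          st.annotation.fill if el.closed else None,
                          st.annotation.stroke_width * scale, closed=el.closed)
        if alpha < 1.0:
            a = layer.getchannel("A").point(lambda v: int(v * alpha))
            layer.putalpha(a)
        target.alpha_composite(layer)

    if member_scenes is None:
        draw_scene(base, scene, 1.0)
    else:
        for member in member_scenes:
            draw_scene(base, member, member_opacity or 1.0)
    base.convert("RGB").save(str(path), format="PNG")


def _poly(draw, xy, el, stroke, fill, width, closed):
    if el.is_disc:
        x, y = xy[0]
        r = max(el.disc_radius, 2)
        draw.ellipse([x - r, y - r, x + r, y + r], fill=stroke)
        return
    if closed and fill and fill != "none":
        draw.polygon(xy, fill=fill, outline=stroke)
    else:
        draw.line(xy, fill=stroke, width=max(1, int(width)), joint="curve")


def save_scene(scene: Scene, path: str | Path, format: Optional[str] = None,
               member_scenes: Optional[list[Scene]] = None,
               member_opacity: Optional[float] = None) -> None:
    """Write SVG (default) or PNG depending on ``format``/extension."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".") or "svg").lower()
    if fmt == "svg":
        path.write_text(render_svg(scene, member_scenes, member_opacity))
    elif fmt == "png":
        render_png(scene, path, member_scenes=member_scenes,
                   member_opacity=member_opacity)
    else:
        raise ValueError(f"unknown output format {fmt!r}")
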
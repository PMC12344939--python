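"""TOML stylesheet and annotation files.

The stylesheet has one table per element class (``[helix]``,
``[strand]``, ``[coil]``, ``[annotation]``, ``[label]``, ``[canvas]``);
unspecified keys take the documented defaults, unknown keys warn and
are ignored. Annotations are an ``[[annotation]]`` array of tables with
``kind`` point/line/area and residue references ``"A:17"`` or ranges
``"A:10-20"``.
"""
from __future__ import annotations

import re
import tomllib
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

__all__ = [
    "StyleSheet", "StyleError",
    "AnnotationSpec", "AnnotationFormatError",
    "parse_style", "parse_annotations",
]


class StyleError(ValueError):
    pass


class AnnotationFormatError(ValueError):
    pass


# CSS named colors are open-ended; accept names, #hex, rgb()/rgba()
_COLOR_RE = re.compile(
    r"^(#[0-9a-fA-F]{3}|#[0-9a-fA-F]{6}|#[0-9a-fA-F]{8}"
    r"|[a-zA-Z]+|rgba?\([0-9.,\s%]+\))$")


def _check_color(key: str, value: str) -> str:
    if not isinstance(value, str) or not _COLOR_RE.match(value.strip()):
        raise StyleError(f"style key {key!r}: invalid color {value!r}")
    return value.strip()


def _check_positive(key: str, value: float) -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool) or value <= 0:
        raise StyleError(f"style key {key!r}: expected a positive number, got {value!r}")
    return float(value)


@dataclass
class HelixStyle:
    stroke: str = "#d62728"
    fill: str = "none"
    stroke_width: float = 3.0
    amplitude: float = 4.0   # zigzag half-height, canvas units pre-scaling
    opacity: float = 1.0


@dataclass
class StrandStyle:
    stroke: str = "#1f77b4"
    fill: str = "#1f77b4"
    stroke_width: float = 1.0
    base_width: float = 6.0  # triangle base, canvas units pre-scaling
    opacity: float = 1.0


@dataclass
class CoilStyle:
    stroke: str = "#555555"
    stroke_width: float = 1.5
    opacity: float = 1.0


@dataclass
class AnnotationStyle:
    stroke: str = "#2ca02c"
    fill: str = "#2ca02c"
    stroke_width: float = 1.5
    point_radius: float = 3.0
    opacity: float = 1.0


@dataclass
class DisulfideStyle:
    stroke: str = "#b8860b"
    stroke_width: float = 1.2
    dash: str = "4,3"
    opacity: float = 1.0


@dataclass
class LabelStyle:
    fill: str = "#000000"
    font_size: float = 14.0
    font_family: str = "sans-serif"
    opacity: float = 1.0


@dataclass
class CanvasStyle:
    background: str = "#ffffff"
    width: float = 1000.0
    height: float = 1000.0
    padding: float = 40.0


@dataclass
class StyleSheet:
    helix: HelixStyle = field(default_factory=HelixStyle)
    strand: StrandStyle = field(default_factory=StrandStyle)
    coil: CoilStyle = field(default_factory=CoilStyle)
    annotation: AnnotationStyle = field(default_factory=AnnotationStyle)
    disulfide: DisulfideStyle = field(default_factory=DisulfideStyle)
    label: LabelStyle = field(default_factory=LabelStyle)
    canvas: CanvasStyle = field(default_factory=CanvasStyle)


_COLOR_KEYS = {"stroke", "fill", "background"}
_STRING_KEYS = {"dash", "font_family"}


def parse_style(path: str | Path) -> StyleSheet:
    """Load a TOML stylesheet, merging over defaults."""
    try:
        data = tomllib.loads(Path(path).read_text())
    except tomllib.TOMLDecodeError as exc:
        raise StyleError(f"cannot parse stylesheet {path}: {exc}") from exc
    return style_from_dict(data)


def style_from_dict(data: dict) -> StyleSheet:
    sheet = StyleSheet()
    for table_name, values in data.items():
        section = getattr(sheet, table_name, None)
        if section is None:
            warnings.warn(f"unknown stylesheet table {table_name!r} ignored")
            continue
        if not isinstance(values, dict):
            raise StyleError(f"stylesheet table {table_name!r} must be a table")
        known = {f.name for f in fields(section)}
        for key, value in values.items():
            if key not in known:
                warnings.warn(f"unknown stylesheet key {table_name}.{key} ignored")
                continue
            if key in _COLOR_KEYS:
                value = value if value == "none" else _check_color(f"{table_name}.{key}", value)
            elif key in _STRING_KEYS:
                if not isinstance(value, str):
                    raise StyleError(f"style key {table_name}.{key}: expected string")
            elif key == "opacity":
                if not isinstance(value, (int, float)) or not 0 < value <= 1:
                    raise StyleError(f"style key {table_name}.{key}: opacity must be in (0,1]")
                value = float(value)
            else:
                value = _check_positive(f"{table_name}.{key}", value)
            setattr(section, key, value)
    return sheet


# ---------------------------------------------------------------------------
# Annotations

_REF_RE = re.compile(r"^\s*([^:\s]+)\s*:\s*(\d+)\s*$")
_RANGE_RE = re.compile(r"^\s*([^:\s]+)\s*:\s*(\d+)\s*[-–]\s*(\d+)\s*$")


def _parse_ref(text: str, where: str) -> tuple[str, int]:
    m = _REF_RE.match(text)
    if not m:
        raise AnnotationFormatError(f"{where}: bad residue reference {text!r}")
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class AnnotationSpec:
    """One user annotation: a point, a line between two residues, or a
    residue-spanning area."""

    kind: str                       # 'point' | 'line' | 'area'
    refs: tuple[tuple[str, int], ...]  # resolved (chain, seq_num) endpoints
    label: Optional[str] = None
    style_key: Optional[str] = None
    raw: str = ""

    def residues(self, structure) -> list[tuple[str, int]]:
        """Expand to the concrete residue references to project.

        Areas expand to every residue of the range that exists in the
        structure (missing interior residues are fine; the endpoints
        must exist and are checked by the scene builder)."""
        if self.kind != "area":
            return list(self.refs)
        (chain_id, start), (_, end) = self.refs
        chain = None
        for c in structure.chains:
            if c.chain_id == chain_id:
                chain = c
        if chain is None:
            return list(self.refs)  # scene builder raises the proper error
        hits = [(chain_id, r.seq_num) for r in chain.residues
                if start <= r.seq_num <= end]
        return hits or list(self.refs)


def parse_annotations(path: str | Path) -> list[AnnotationSpec]:
    """Load an ``[[annotation]]`` array-of-tables TOML file."""
    try:
        data = tomllib.loads(Path(path).read_text())
    except tomllib.TOMLDecodeError as exc:
        raise AnnotationFormatError(f"cannot parse annotations {path}: {exc}") from exc
    rows = data.get("annotation")
    if not isinstance(rows, list):
        raise AnnotationFormatError(
            f"{path}: expected an [[annotation]] array of tables")
    specs: list[AnnotationSpec] = []
    for i, row in enumerate(rows):
        where = f"annotation #{i + 1}"
        kind = row.get("kind")
        if kind not in ("point", "line", "area"):
            raise AnnotationFormatError(f"{where}: kind must be point/line/area")
        label = row.get("label")
        style_key = row.get("style")
        if kind == "point":
            ref = row.get("residue")
            if not ref:
                raise AnnotationFormatError(f"{where}: point needs 'residue'")
            refs = (_parse_ref(ref, where),)
            raw = ref
        elif kind == "line":
            pair = row.get("residues")
            if not isinstance(pair, list) or len(pair) != 2:
                raise AnnotationFormatError(
                    f"{where}: line needs 'residues' = [ref, ref]")
            refs = tuple(_parse_ref(r, where) for r in pair)
            raw = ",".join(pair)
        else:  # area
            rng = row.get("range")
            if not rng:
                raise AnnotationFormatError(f"{where}: area needs 'range'")
            m = _RANGE_RE.match(rng)
            if not m:
                raise AnnotationFormatError(f"{where}: bad range {rng!r}")
            chain_id, start, end = m.group(1), int(m.group(2)), int(m.group(3))
            if start > end:
                raise AnnotationFormatError(f"{where}: range start > end")
            refs = ((chain_id, start), (chain_id, end))
            raw = rng
        specs.append(AnnotationSpec(kind, refs, label, style_key, raw))
    return specs
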
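"""Multi-structure comparison: overlays, clustering, and domain splits.

Overlays project every member in one shared family frame and stack the
2D scenes with a uniform low opacity, so conserved secondary-structure
elements accumulate darkness while variable regions stay faint. Domain
splits cut a chain into residue regions ("A:1-30,A:40-60"), orient each
region independently (family alignment with inertia fallback) and lay
the segments out side by side on one canvas.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .align import (AlignConfig, FamilyDatabase, _tm_score, frame_for_query,
                    run_family_search)
from .orientation import RotationFrame, compute_inertia_frame
from .scene import (CanvasTransform, Scene, SceneElement, SceneOptions,
                    build_scene, depth_sort, fit_canvas, replace_elements)
from .structure import (Chain, ProteinStructure, SecondaryStructureSegment,
                        coalesce_ss, detect_disulfides, read_structure)
from .styles import StyleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSet", "Region", "RegionError",
    "OverlayScene", "OverlayError",
    "parse_regions", "split_structure", "split_visualize",
    "cluster_structures", "ClusterResult", "compose_overlay",
    "member_opacity",
]


class RegionError(ValueError):
    pass


class OverlayError(RuntimeError):
    pass


@dataclass(frozen=True)
class Region:
    chain_id: str
    start: int  # author numbering, 1-based inclusive
    end: int

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class RegionSet:
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        by_chain: dict[str, list[Region]] = {}
        for r in self.regions:
            if r.start > r.end:
                raise RegionError(f"region {r}: start > end")
            by_chain.setdefault(r.chain_id, []).append(r)
        for chain_id, regs in by_chain.items():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start <= a.end:
                    raise RegionError(f"regions {a} and {b} overlap")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


def parse_regions(text: str) -> RegionSet:
    """Parse "A:1-30,A:40-60" (ASCII hyphen or en-dash) into regions."""
    if not text or not text.strip():
        raise RegionError("empty region string")
    regions: list[Region] = []
    for item in text.split(","):
        item = item.strip()
        if not item:
            continue
        norm = item.replace("–", "-")
        if ":" not in norm:
            raise RegionError(f"malformed region {item!r} (expected CHAIN:START-END)")
        chain_id, _, span = norm.partition(":")
        start_s, sep, end_s = span.partition("-")
        if not sep:
            raise RegionError(f"malformed region {item!r} (missing range)")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise RegionError(f"malformed region {item!r}: {exc}") from exc
        if start > end:
            raise RegionError(f"region {item!r}: start > end")
        regions.append(Region(chain_id.strip(), start, end))
    if not regions:
        raise RegionError("no regions parsed")
    return RegionSet(tuple(regions))


def split_structure(structure: ProteinStructure,
                    regions: RegionSet) -> list[ProteinStructure]:
    """One sub-structure per region, in region order.

    Residues outside every region are excluded (their count is logged).
    A region selecting zero residues, or naming an absent chain, is an
    error.
    """
    subs: list[ProteinStructure] = []
    selected = 0
    for region in regions:
        try:
            chain = structure.chain(region.chain_id)
        except KeyError as exc:
            raise RegionError(str(exc)) from exc
        picked = [r for r in chain.residues
                  if region.start <= r.seq_num <= region.end]
        if not picked:
            raise RegionError(f"region {region} selects no residues")
        selected += len(picked)
        subs.append(ProteinStructure(
            f"{structure.id}[{region}]",
            [Chain(region.chain_id, picked)], structure.source_format))
    dropped = structure.n_residues - selected
    if dropped:
        logger.info("%d residues outside all regions excluded from rendering",
                    dropped)
    return subs


# ---------------------------------------------------------------------------
# Domain-split visualization

@dataclass
class SplitConfig:
    database_path: Optional[Path] = None
    min_similarity: float = 0.5
    backend: str = "auto"
    gap_fraction: float = 0.1   # of the summed segment widths
    style: StyleSheet = field(default_factory=StyleSheet)
    options: SceneOptions = field(default_factory=SceneOptions)
    width: float = 1000.0
    height: float = 1000.0
    padding: float = 40.0


def _orient_segment(sub: ProteinStructure,
                    config: SplitConfig) -> tuple[RotationFrame, Optional[str]]:
    if config.database_path is not None:
        cfg = AlignConfig(config.database_path, config.min_similarity,
                          backend=config.backend)
        hit = run_family_search(sub, cfg)
        if hit is not None:
            db = FamilyDatabase.load(config.database_path)
            return frame_for_query(sub, hit, db), hit.target_id
        logger.warning("segment %s: no family match; inertia fallback", sub.id)
    return compute_inertia_frame(sub.all_atom_coords()), None


def split_visualize(structure: ProteinStructure, regions: RegionSet,
                    codes: Mapping[tuple[str, int], str],
                    config: Optional[SplitConfig] = None) -> Scene:
    """Independently oriented region scenes combined on one canvas.

    Segments are laid out left-to-right in sequence order with a fixed
    gap, at a common scale so relative domain sizes survive; each
    carries a label with its region string and matched family (if any).
    """
    config = config or SplitConfig()
    subs = split_structure(structure, regions)

    pieces: list[list[SceneElement]] = []
    labels: list[str] = []
    for region, sub in zip(regions, subs):
        frame, family = _orient_segment(sub, config)
        segs = coalesce_ss(codes, sub)
        scene = build_scene(sub, frame, segs, style=config.style,
                            options=config.options,
                            disulfides=detect_disulfides(sub))
        scene = depth_sort(scene)
        pieces.append(scene.elements)
        labels.append(f"{region}" + (f" [{family}]" if family else " [inertia]"))

    # left-to-right layout at common scale
    boxes = []
    for elements in pieces:
        pts = np.vstack([e.points for e in elements])
        boxes.append((pts[:, 0].min(), pts[:, 0].max(),
                      pts[:, 1].min(), pts[:, 1].max()))
    total_w = sum(b[1] - b[0] for b in boxes)
    gap = config.gap_fraction * max(total_w, 1.0)
    cursor = 0.0
    combined: list[SceneElement] = []
    order = 0
    for elements, box, label in zip(pieces, boxes, labels):
        dx = cursor - box[0]
        dy = -0.5 * (box[2] + box[3])  # vertically center each segment
        for el in elements:
            moved = SceneElement(el.kind, el.points + np.array([dx, dy]),
                                 el.mean_depth, el.style_key, order,
                                 label=el.label, closed=el.closed,
                                 is_disc=el.is_disc, disc_radius=el.disc_radius)
            combined.append(moved)
            order += 1
        seg_w = box[1] - box[0]
        combined.append(SceneElement(
            "segment_label",
            np.array([[cursor + seg_w / 2, -0.55 * (box[3] - box[2])
                       - config.style.label.font_size]]),
            0.0, "label", order, label=label))
        order += 1
        cursor += seg_w + gap

    scene = Scene(combined, config.style)
    return fit_canvas(scene, config.width, config.height, config.padding)


# ---------------------------------------------------------------------------
# Clustering

@dataclass
class ClusterResult:
    clusters: dict[str, list[str]]  # representative id -> member ids

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_singletons(self) -> int:
        return sum(1 for m in self.clusters.values() if len(m) == 1)

    @property
    def n_non_singletons(self) -> int:
        return self.n_clusters - self.n_singletons


def _seq_identity(a: str, b: str) -> float:
    import edlib

    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def cluster_structures(paths: Sequence[str | Path], coverage: float = 0.9,
                       min_seq_id: float = 0.5,
                       min_struct_sim: float = 0.5) -> ClusterResult:
    """Greedy representative clustering of structure files.

    Members are processed longest-first; a structure joins the first
    existing cluster whose representative it matches on all three
    criteria — mutual length coverage ≥ ``coverage``, global sequence
    identity ≥ ``min_seq_id``, and Cα TM-score ≥ ``min_struct_sim`` —
    otherwise it seeds a new cluster. Deterministic; representatives
    are members of their own clusters.
    """
    if not paths:
        raise OverlayError("no structures to cluster")
    loaded: list[tuple[str, ProteinStructure]] = []
    for p in paths:
        st = read_structure(p)
        loaded.append((str(p), st))
    loaded.sort(key=lambda kv: (-kv[1].n_residues, kv[0]))

    reps: list[tuple[str, ProteinStructure]] = []
    clusters: dict[str, list[str]] = {}
    for name, st in loaded:
        seq = st.sequence()
        ca = st.ca_coords()
        home = None
        for rep_name, rep_st in reps:
            la, lb = st.n_residues, rep_st.n_residues
            if min(la, lb) / max(la, lb) < coverage:
                continue
            if _seq_identity(seq, rep_st.sequence()) < min_seq_id:
                continue
            n = min(len(ca), len(rep_st.ca_coords()))
            if n >= 3:
                try:
                    sim = _tm_score(ca[:n], rep_st.ca_coords()[:n], norm_len=len(ca))
                except Exception:
                    sim = 0.0
                if sim < min_struct_sim:
                    continue
            home = rep_name
            break
        if home is None:
            reps.append((name, st))
            clusters[name] = [name]
        else:
            clusters[home].append(name)
    return ClusterResult(clusters)


# ---------------------------------------------------------------------------
# Overlay

def member_opacity(n: int) -> float:
    """Per-member opacity ``min(0.8, max(0.05, 1/N))``.

    The clamps keep a single structure visible and large families from
    saturating to black where many members agree.
    """
    if n < 1:
        raise ValueError("need at least one member")
    return min(0.8, max(0.05, 1.0 / n))


@dataclass
class OverlayConfig:
    database_path: Optional[Path] = None
    min_similarity: float = 0.5
    backend: str = "auto"
    target_family: Optional[str] = None
    style: StyleSheet = field(default_factory=StyleSheet)
    options: SceneOptions = field(default_factory=lambda: SceneOptions(show_termini=False))
    width: float = 1000.0
    height: float = 1000.0
    padding: float = 40.0


@dataclass
class OverlayScene:
    member_scenes: list[Scene]
    transform: CanvasTransform
    opacity: float
    style: StyleSheet
    width: float
    height: float
    padding: float

    def shared_scene(self) -> Scene:
        """All member elements under the shared transform (for export)."""
        elements = [e for sc in self.member_scenes for e in sc.elements]
        sc = Scene(elements, self.style, self.transform,
                   self.width, self.height, self.padding)
        return sc


def compose_overlay(inputs: Sequence[str | Path | tuple[ProteinStructure, Mapping]],
                    config: Optional[OverlayConfig] = None,
                    codes_by_member: Optional[Sequence[Mapping]] = None
                    ) -> OverlayScene:
    """Project every member in a shared frame and stack with uniform opacity.

    With a family database, each member is aligned and members failing
    the similarity threshold are dropped with a warning (mixing inertia
    frames into a consensus would break its semantics); without one,
    every member uses its own inertia frame. One global transform from
    the union bounding box keeps conserved regions overlapping
    pixel-wise.
    """
    config = config or OverlayConfig()
    if not inputs:
        raise OverlayError("no input structures")

    members: list[Scene] = []
    db = FamilyDatabase.load(config.database_path) \
        if config.database_path is not None else None
    for i, item in enumerate(inputs):
        if isinstance(item, (str, Path)):
            st = read_structure(item)
            codes = codes_by_member[i] if codes_by_member else {}
        else:
            st, codes = item
        if db is not None:
            cfg = AlignConfig(config.database_path, config.min_similarity,
                              target_family=config.target_family,
                              backend=config.backend)
            hit = run_family_search(st, cfg)
            if hit is None:
                logger.warning("member %s failed family alignment; dropped", st.id)
                continue
            frame = frame_for_query(st, hit, db)
        else:
            frame = compute_inertia_frame(st.all_atom_coords())
        segs = coalesce_ss(codes, st)
        scene = depth_sort(build_scene(st, frame, segs, style=config.style,
                                       options=config.options))
        members.append(scene)

    if not members:
        raise OverlayError("no members survived family alignment")

    union = Scene([e for sc in members for e in sc.elements], config.style)
    fitted = fit_canvas(union, config.width, config.height, config.padding)
    return OverlayScene(members, fitted.transform, member_opacity(len(members)),
                        config.style, config.width, config.height, config.padding)
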
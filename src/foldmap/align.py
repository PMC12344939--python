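"""Family-consistent orientation.

A query structure is matched against a family database; the best hit
above a probability-like similarity threshold (default 0.5) yields a
rotation that carries the query into the family's reference
orientation, so every member of a family is drawn the same way. When no
hit clears the threshold the caller warns and falls back to the inertia
frame.

Two search backends share one result type:

* ``foldseek`` — wraps the external structure-search binary
  (``easy-search`` with a pinned tab-separated column set). Used when
  the binary is on PATH.
* ``builtin`` — exact-backbone search: Cα correspondences by residue
  index, Kabsch superposition, TM-score as the similarity. Suitable for
  small custom databases and for fully offline operation; it is not a
  remote-homology detector.

A family database is a directory of representative structure files plus
a TOML manifest mapping family id → representative and its reference
frame (the representative's inertia frame), so family orientation is
reproducible from the database alone.
"""
from __future__ import annotations

import logging
import re
import shutil
import subprocess
import tempfile
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .orientation import RotationFrame, compute_inertia_frame, validate_frame
from .structure import ProteinStructure, read_structure

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentHit", "AlignConfig", "FamilyDatabase",
    "AlignmentError", "DatabaseError", "ToolError", "InsufficientAlignmentError",
    "kabsch_superpose", "run_family_search", "hit_to_frame",
    "select_family_representative", "build_family_database",
    "parse_search_table", "SEARCH_COLUMNS",
]

#: Pinned column specification handed to the external search tool.
SEARCH_COLUMNS = ("query", "target", "prob", "alntmscore",
                  "u", "t", "qstart", "tstart", "cigar")


class AlignmentError(RuntimeError):
    pass


class DatabaseError(AlignmentError):
    pass


class ToolError(AlignmentError):
    pass


class InsufficientAlignmentError(AlignmentError):
    """Fewer than 3 residue correspondences and no tool matrix."""


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    similarity: float  # probability-like, in [0, 1]
    tool_rotation: Optional[np.ndarray] = None     # maps query -> target coords
    tool_translation: Optional[np.ndarray] = None
    residue_pairs: Optional[tuple[tuple[int, int], ...]] = None  # (q_idx, t_idx)

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError(f"similarity {self.similarity} outside [0, 1]")
        if self.tool_rotation is not None:
            validate_frame(np.asarray(self.tool_rotation))  # orthonormal, det +1


@dataclass
class AlignConfig:
    database_path: Path
    min_similarity: float = 0.5
    target_family: Optional[str] = None
    backend: str = "auto"  # 'auto' | 'builtin' | 'foldseek'

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_similarity <= 1.0:
            raise ValueError("min_similarity must be in [0, 1]")
        self.database_path = Path(self.database_path)


@dataclass
class FamilyEntry:
    family_id: str
    representative: Path
    frame: RotationFrame


@dataclass
class FamilyDatabase:
    db_path: Path
    families: dict[str, FamilyEntry] = field(default_factory=dict)

    MANIFEST = "manifest.toml"

    @classmethod
    def load(cls, db_path: str | Path) -> "FamilyDatabase":
        db_path = Path(db_path)
        manifest = db_path / cls.MANIFEST
        if not manifest.exists():
            raise DatabaseError(f"no {cls.MANIFEST} in {db_path}")
        try:
            data = tomllib.loads(manifest.read_text())
        except tomllib.TOMLDecodeError as exc:
            raise DatabaseError(f"corrupt manifest in {db_path}: {exc}") from exc
        fams: dict[str, FamilyEntry] = {}
        for fam_id, entry in data.get("family", {}).items():
            rep = db_path / entry["representative"]
            if not rep.exists():
                raise DatabaseError(f"representative {rep} of family {fam_id} missing")
            nums = entry["frame"]
            if len(nums) != 12:
                raise DatabaseError(f"family {fam_id}: frame needs 12 numbers")
            M = np.asarray(nums, dtype=float).reshape(4, 3)
            fams[fam_id] = FamilyEntry(fam_id, rep,
                                       validate_frame(M, source="inertia"))
        if not fams:
            raise DatabaseError(f"database {db_path} lists no families")
        return cls(db_path, fams)


# ---------------------------------------------------------------------------
# Kabsch superposition

def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[RotationFrame, float]:
    """Least-squares rigid superposition of P onto Q.

    Returns the proper rotation + translation minimizing the RMSD of
    the transformed P against Q (reflections corrected by flipping the
    smallest singular direction), and that minimal RMSD in Å.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise AlignmentError("need matched point sets with >= 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):  # rank < 2: collinear or a point
        raise AlignmentError("degenerate superposition: collinear points")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    # p' = R (p + t): translate so P's centroid maps onto Q's
    t = R.T @ qc - pc
    frame = RotationFrame(R, t, source="family_alignment")
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return frame, rmsd


def _tm_score(P: np.ndarray, Q: np.ndarray, norm_len: int) -> float:
    """TM-score of superposed matched sets, normalized by ``norm_len``."""
    frame, _ = kabsch_superpose(P, Q)
    d = np.linalg.norm((np.asarray(P) + frame.translation) @ frame.rotation.T
                       - np.asarray(Q), axis=1)
    d0 = max(0.5, 1.24 * (norm_len - 15) ** (1 / 3) - 1.8) if norm_len > 15 else 0.5
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)) * len(d) / norm_len)


# ---------------------------------------------------------------------------
# Search backends

def run_family_search(query: str | Path | ProteinStructure,
                      config: AlignConfig) -> Optional[AlignmentHit]:
    """Best database hit for the query, or None below the threshold.

    With ``target_family`` set, the search is restricted to that
    family's representative. Returning None means the caller should
    warn and fall back to the inertia orientation.
    """
    db = FamilyDatabase.load(config.database_path)
    if config.target_family is not None:
        if config.target_family not in db.families:
            raise DatabaseError(
                f"family {config.target_family!r} not in database {db.db_path}")
        entries = [db.families[config.target_family]]
    else:
        entries = [db.families[k] for k in sorted(db.families)]

    backend = config.backend
    if backend == "auto":
        backend = "foldseek" if shutil.which("foldseek") else "builtin"
    if backend == "foldseek":
        hit = _foldseek_search(query, entries, db)
    elif backend == "builtin":
        hit = _builtin_search(query, entries)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    if hit is None or hit.similarity < config.min_similarity:
        if hit is not None:
            logger.warning(
                "best hit %s (similarity %.3f) below threshold %.2f; "
                "no rotation produced", hit.target_id, hit.similarity,
                config.min_similarity)
        else:
            logger.warning("no database hit for query; no rotation produced")
        return None
    return hit


def _load_query(query: str | Path | ProteinStructure) -> ProteinStructure:
    if isinstance(query, ProteinStructure):
        return query
    return read_structure(query)


def _builtin_search(query: str | Path | ProteinStructure,
                    entries: Sequence[FamilyEntry]) -> Optional[AlignmentHit]:
    qs = _load_query(query)
    qca = qs.ca_coords()
    best: Optional[AlignmentHit] = None
    for entry in entries:
        ts = read_structure(entry.representative)
        tca = ts.ca_coords()
        n = min(len(qca), len(tca))
        if n < 3:
            continue
        pairs = tuple((i, i) for i in range(n))
        try:
            sim = _tm_score(qca[:n], tca[:n], norm_len=len(qca))
        except AlignmentError:
            continue
        frame, _ = kabsch_superpose(qca[:n], tca[:n])
        hit = AlignmentHit(
            query_id=qs.id, target_id=entry.family_id,
            similarity=min(1.0, sim),
            tool_rotation=frame.rotation,
            tool_translation=frame.rotation @ frame.translation,
            residue_pairs=pairs)
        if best is None or hit.similarity > best.similarity:
            best = hit
    return best


_CIGAR_RE = re.compile(r"(\d+)([MIDmid])")


def parse_search_table(text: str) -> list[AlignmentHit]:
    """Parse the pinned tab-separated output of the external search tool.

    Columns: query, target, prob, alntmscore, u (9 comma-separated
    numbers, row-major rotation), t (3 numbers), qstart, tstart, cigar.
    The (u, t) transform maps query coordinates onto target coordinates.
    CIGAR M advances both sequences (a residue pair), I advances the
    query only, D the target only.
    """
    hits: list[AlignmentHit] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < len(SEARCH_COLUMNS):
            raise ToolError(f"search output line {lineno}: expected "
                            f"{len(SEARCH_COLUMNS)} columns, got {len(parts)}")
        query, target, prob, tm, u, t, qstart, tstart, cigar = parts[:9]
        try:
            U = np.array([float(x) for x in u.split(",")], dtype=float).reshape(3, 3)
            T = np.array([float(x) for x in t.split(",")], dtype=float)
            pairs = _cigar_pairs(cigar, int(qstart) - 1, int(tstart) - 1)
            hits.append(AlignmentHit(
                query_id=query, target_id=target,
                similarity=float(prob), tool_rotation=U, tool_translation=T,
                residue_pairs=pairs))
        except (ValueError, IndexError) as exc:
            raise ToolError(f"search output line {lineno}: {exc}") from exc
    return hits


def _cigar_pairs(cigar: str, q: int, t: int) -> tuple[tuple[int, int], ...]:
    pairs: list[tuple[int, int]] = []
    for count, op in _CIGAR_RE.findall(cigar):
        n = int(count)
        op = op.upper()
        if op == "M":
            pairs.extend((q + i, t + i) for i in range(n))
            q += n
            t += n
        elif op == "I":
            q += n
        elif op == "D":
            t += n
    return tuple(pairs)


def _foldseek_search(query: str | Path | ProteinStructure,
                     entries: Sequence[FamilyEntry],
                     db: FamilyDatabase) -> Optional[AlignmentHit]:
    binary = shutil.which("foldseek")
    if binary is None:
        raise ToolError(
            "the 'foldseek' binary is not on PATH; install it or use "
            "backend='builtin'")
    if isinstance(query, ProteinStructure):
        raise ToolError("foldseek backend needs a structure file path")
    rep_by_name = {e.representative.stem: e.family_id for e in entries}
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(tmp) / "hits.tsv"
        cmd = [binary, "easy-search", str(query),
               *[str(e.representative) for e in entries],
               str(out), str(Path(tmp) / "work"),
               "--format-output", ",".join(SEARCH_COLUMNS)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ToolError(f"search tool failed (exit {proc.returncode}): "
                            f"{proc.stderr.strip()[-500:]}")
        hits = parse_search_table(out.read_text()) if out.exists() else []
    best = None
    for h in hits:
        fam = rep_by_name.get(h.target_id, h.target_id)
        h = AlignmentHit(h.query_id, fam, h.similarity, h.tool_rotation,
                         h.tool_translation, h.residue_pairs)
        if best is None or h.similarity > best.similarity:
            best = h
    return best


# ---------------------------------------------------------------------------
# Hit -> frame

def hit_to_frame(hit: AlignmentHit, query: ProteinStructure,
                 representative_frame: Optional[RotationFrame] = None,
                 target_coords: Optional[np.ndarray] = None) -> RotationFrame:
    """Frame carrying query coordinates into the family's reference view.

    Prefers the tool-reported rotation/translation; otherwise a Kabsch
    superposition of the matched Cα pairs (requires ``target_coords``).
    The result is composed with the representative's stored inertia
    frame so the query lands in the family's canonical orientation.
    """
    if hit.tool_rotation is not None and hit.tool_translation is not None:
        R = np.asarray(hit.tool_rotation, dtype=float)
        t = np.asarray(hit.tool_translation, dtype=float)
        onto_target = RotationFrame(R, R.T @ t, source="family_alignment")
    elif hit.residue_pairs and len(hit.residue_pairs) >= 3:
        if target_coords is None:
            raise InsufficientAlignmentError(
                "residue-pair path needs the representative's coordinates")
        qca = query.ca_coords()
        P = qca[[q for q, _ in hit.residue_pairs]]
        Q = np.asarray(target_coords)[[t for _, t in hit.residue_pairs]]
        onto_target, _ = kabsch_superpose(P, Q)
    else:
        raise InsufficientAlignmentError(
            "hit carries no tool matrix and fewer than 3 residue pairs")
    if representative_frame is None:
        return onto_target
    return onto_target.compose(representative_frame, source="family_alignment")


def frame_for_query(query: ProteinStructure, hit: AlignmentHit,
                    db: FamilyDatabase) -> RotationFrame:
    """Convenience: resolve the hit's family entry and compose the frame."""
    entry = db.families.get(hit.target_id)
    if entry is None:
        raise DatabaseError(f"hit family {hit.target_id!r} not in database")
    target = read_structure(entry.representative)
    return hit_to_frame(hit, query, representative_frame=entry.frame,
                        target_coords=target.ca_coords())


# ---------------------------------------------------------------------------
# Database construction

def select_family_representative(members: Sequence[str],
                                 pairwise_tm: np.ndarray) -> str:
    """Member with the highest average TM-score to all other members.

    The row mean excludes the self-similarity diagonal; ties break to
    the lexicographically smallest id. A singleton family returns its
    only member.
    """
    M = np.asarray(pairwise_tm, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"pairwise matrix must be square, got {M.shape}")
    if len(members) != M.shape[0]:
        raise ValueError("member count does not match matrix size")
    if len(members) == 1:
        return members[0]
    n = len(members)
    means = (M.sum(axis=1) - np.diag(M)) / (n - 1)
    best = max(range(n), key=lambda i: (means[i], ), default=0)
    # explicit deterministic tie-break on the id
    best_mean = means.max()
    tied = [members[i] for i in range(n) if means[i] == best_mean]
    return min(tied)


def build_family_database(families: dict[str, str | Path],
                          out: str | Path) -> FamilyDatabase:
    """Create a searchable database directory from representatives.

    Each representative is re-written into the database directory and
    its inertia frame (over all non-hydrogen atoms) stored in the TOML
    manifest as the family's reference orientation. Rebuilding into the
    same directory is deterministic and idempotent.
    """
    if not families:
        raise DatabaseError("empty family map")
    ids = list(families)
    if len(set(ids)) != len(ids):
        raise DatabaseError("duplicate family ids")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    from .fixtures import write_mmcif  # deterministic writer

    lines: list[str] = []
    entries: dict[str, FamilyEntry] = {}
    for fam_id in sorted(families):
        src = Path(families[fam_id])
        structure = read_structure(src)
        dest = out / f"{fam_id}.cif"
        write_mmcif(structure, dest)
        frame = compute_inertia_frame(structure.all_atom_coords())
        nums = list(np.concatenate([frame.rotation.ravel(), frame.translation]))
        lines.append(f"[family.{fam_id}]")
        lines.append(f'representative = "{dest.name}"')
        lines.append("frame = [" + ", ".join(f"{v:.12g}" for v in nums) + "]")
        lines.append("")
        entries[fam_id] = FamilyEntry(fam_id, dest, frame)
    (out / FamilyDatabase.MANIFEST).write_text("\n".join(lines))
    return FamilyDatabase(out, entries)
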
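"""Structure input and per-residue secondary-structure handling.

Reads PDB/mmCIF coordinate files into a lightweight in-memory model
(:class:`ProteinStructure`), reads DSSP assignments (classic and mmCIF
dialects), extracts secondary structure embedded in mmCIF files
(``struct_conf`` / ``struct_sheet_range``), coalesces per-residue codes
into typed segments, and detects disulfide bridges geometrically.

All downstream geometry uses the Cα atom as the representative
coordinate of a residue; residues without a Cα are kept in the model but
excluded from rendering. Author residue numbering is used throughout.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "Chain",
    "ProteinStructure",
    "SecondaryStructureSegment",
    "DisulfidePair",
    "StructureError",
    "EmptyStructureError",
    "DsspFormatError",
    "NoEmbeddedSS",
    "read_structure",
    "read_dssp",
    "extract_embedded_ss",
    "coalesce_ss",
    "detect_disulfides",
    "DISULFIDE_SG_MAX",
    "MIN_HELIX_LEN",
    "MIN_STRAND_LEN",
]

#: Maximum SG–SG distance (Å) treated as a disulfide bond: covalent bond
#: length ~2.05 Å plus slack for model noise.
DISULFIDE_SG_MAX = 2.5

#: Minimal segment lengths; shorter regular runs are demoted to coil
#: because they cannot be drawn as meaningful glyphs.
MIN_HELIX_LEN = 3
MIN_STRAND_LEN = 2


class StructureError(ValueError):
    """Unreadable or malformed structure input."""


class EmptyStructureError(StructureError):
    """The file contained no polymer residues."""


class DsspFormatError(ValueError):
    """A DSSP file that cannot be interpreted."""


class NoEmbeddedSS(LookupError):
    """The mmCIF source carried no struct_conf/struct_sheet_range rows."""


@dataclass(frozen=True)
class Residue:
    """One residue with author numbering and its atoms.

    ``atoms`` maps atom name to a 3-vector in Å.
    """

    chain_id: str
    seq_num: int
    insertion_code: str  # '' when absent
    res_name: str
    atoms: Mapping[str, np.ndarray]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.insertion_code)

    @property
    def ca(self) -> Optional[np.ndarray]:
        return self.atoms.get("CA")

    def __repr__(self) -> str:  # compact, used in error messages
        icode = self.insertion_code or ""
        return f"{self.chain_id}:{self.res_name}{self.seq_num}{icode}"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class ProteinStructure:
    """Parsed polymer chains with 3D coordinates."""

    id: str
    chains: list[Chain]
    source_format: str  # 'pdb' or 'mmcif'

    def __post_init__(self) -> None:
        if not self.chains or not any(len(c) for c in self.chains):
            raise EmptyStructureError(f"structure {self.id!r} has no residues")

    @property
    def residues(self) -> list[Residue]:
        return [r for c in self.chains for r in c.residues]

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates in residue order, shape (n, 3)."""
        pts = [r.ca for r in self.residues if r.ca is not None]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def all_atom_coords(self) -> np.ndarray:
        """All (non-hydrogen) atom coordinates, shape (m, 3)."""
        pts = [xyz for r in self.residues for name, xyz in r.atoms.items()
               if not name.startswith("H")]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def sequence(self, chain_id: Optional[str] = None) -> str:
        """One-letter sequence (X for unknown codes) for identity checks."""
        res = self.chain(chain_id).residues if chain_id else self.residues
        return "".join(_THREE_TO_ONE.get(r.res_name, "X") for r in res)


@dataclass(frozen=True)
class SecondaryStructureSegment:
    """A maximal run of one secondary-structure type.

    ``start``/``end`` are inclusive indices into the chain's residue
    list (0-based), not author numbers.
    """

    ss_type: str  # 'helix' | 'strand' | 'coil'
    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.ss_type not in ("helix", "strand", "coil"):
            raise ValueError(f"bad ss_type {self.ss_type!r}")
        if self.start > self.end:
            raise ValueError("segment start > end")

    @property
    def n_res(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DisulfidePair:
    residue_a: Residue
    residue_b: Residue
    sg_distance: float

    def __post_init__(self) -> None:
        if self.residue_a.key == self.residue_b.key:
            raise ValueError("disulfide requires two distinct residues")
        if self.sg_distance > DISULFIDE_SG_MAX:
            raise ValueError("distance exceeds bonding threshold")


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine inside polymers is treated as standard
}

_WATER = {"HOH", "WAT", "DOD"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise StructureError(
        f"cannot infer format from extension {suffix!r} of {path}; "
        "pass format='pdb' or 'mmcif'")


def _pick_altloc(atoms: Iterable[gemmi.Atom]) -> gemmi.Atom:
    """Resolve alternate locations: highest occupancy, ties -> altloc 'A'."""
    best = None
    for a in atoms:
        if best is None:
            best = a
            continue
        if a.occ > best.occ or (a.occ == best.occ
                                and (a.altloc or "A") < (best.altloc or "A")):
            best = a
    return best


def read_structure(path: str | Path, format: Optional[str] = None) -> ProteinStructure:
    """Read a PDB or mmCIF file into a :class:`ProteinStructure`.

    Only polymer ATOM records are kept (HETATM groups and waters are
    dropped, except hetero residues such as MSE that sit inside polymer
    chains and carry a Cα). Alternate locations resolve to the highest
    occupancy, ties to altloc 'A'. Only model 1 is read.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name in _WATER:
                continue
            if gres.het_flag == "H" and "CA" not in gres:
                continue  # ligands/ions; hetero residues with Cα stay
            # group altlocs per atom name, pick one conformer each
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in gres:
                by_name.setdefault(atom.name, []).append(atom)
            atoms: dict[str, np.ndarray] = {}
            for name, alts in by_name.items():
                a = _pick_altloc(alts)
                xyz = np.array([a.pos.x, a.pos.y, a.pos.z], dtype=float)
                if not np.all(np.isfinite(xyz)):
                    raise StructureError(
                        f"non-finite coordinate for {gchain.name}:{gres.seqid.num}:{name}")
                atoms[name] = xyz
            if not atoms:
                continue
            residues.append(Residue(
                chain_id=gchain.name,
                seq_num=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                res_name=gres.name,
                atoms=atoms,
            ))
        if residues:
            chains.append(Chain(gchain.name, residues))

    if not chains:
        raise EmptyStructureError(f"{path} contains no polymer residues")
    struct = ProteinStructure(id=path.stem, chains=chains, source_format=fmt)
    struct._gemmi = st  # retained for embedded-SS extraction  # type: ignore[attr-defined]
    return struct


# ---------------------------------------------------------------------------
# DSSP

def read_dssp(path: str | Path) -> dict[tuple[str, int], str]:
    """Parse a DSSP output file into a (chain, seq_num) -> code map.

    Both the classic fixed-column dialect and the mmCIF dialect written
    by DSSP v4 are accepted. Residues absent from the file default to
    coil downstream.
    """
    path = Path(path)
    if not path.exists():
        raise DsspFormatError(f"no such file: {path}")
    head = path.read_text(errors="replace")
    if not head.strip():
        raise DsspFormatError(f"{path} is empty")
    if head.lstrip().startswith("data_") or "_dssp_struct_summary." in head:
        return _read_dssp_mmcif(path)
    return _read_dssp_classic(path)


def _read_dssp_classic(path: Path) -> dict[tuple[str, int], str]:
    from Bio.PDB.DSSP import make_dssp_dict

    try:
        dssp_dict, _keys = make_dssp_dict(str(path))
    except Exception as exc:
        raise DsspFormatError(f"cannot parse DSSP file {path}: {exc}") from exc
    out: dict[tuple[str, int], str] = {}
    for (chain_id, res_id), values in dssp_dict.items():
        # biopython residue id: (hetfield, seqnum, icode)
        seq_num = res_id[1]
        ss = values[1]
        out[(chain_id, seq_num)] = ss if ss != "-" else " "
    if not out:
        raise DsspFormatError(f"{path} contains no residue lines")
    return out


def _read_dssp_mmcif(path: Path) -> dict[tuple[str, int], str]:
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except (RuntimeError, ValueError) as exc:
        raise DsspFormatError(f"cannot parse DSSP mmCIF {path}: {exc}") from exc
    table = block.find("_dssp_struct_summary.",
                       ["label_asym_id", "label_seq_id", "secondary_structure"])
    if len(table) == 0:
        raise DsspFormatError(f"{path} has no _dssp_struct_summary rows")
    out: dict[tuple[str, int], str] = {}
    for row in table:
        chain_id, seq, ss = row[0], row[1], row[2]
        if seq in (".", "?"):
            continue
        code = " " if ss in (".", "?", "") else ss
        out[(chain_id, int(seq))] = code
    if not out:
        raise DsspFormatError(f"{path} contains no residue rows")
    return out


def extract_embedded_ss(structure: ProteinStructure) -> dict[tuple[str, int], str]:
    """Secondary structure from the source mmCIF's own categories.

    ``struct_conf`` helix rows map to 'H', ``struct_sheet_range`` rows to
    'E'; everything else is coil. A residue claimed by both becomes helix
    (with a warning). Raises :class:`NoEmbeddedSS` when neither category
    was present so the caller knows to supply a DSSP file instead.
    """
    st: Optional[gemmi.Structure] = getattr(structure, "_gemmi", None)
    if st is None or (not st.helices and not st.sheets):
        raise NoEmbeddedSS(
            f"structure {structure.id!r} carries no embedded secondary structure")

    codes: dict[tuple[str, int], str] = {}
    for sheet in st.sheets:
        for strand in sheet.strands:
            cid = strand.start.chain_name
            for num in range(strand.start.res_id.seqid.num,
                             strand.end.res_id.seqid.num + 1):
                codes[(cid, num)] = "E"
    for helix in st.helices:
        cid = helix.start.chain_name
        for num in range(helix.start.res_id.seqid.num,
                         helix.end.res_id.seqid.num + 1):
            if codes.get((cid, num)) == "E":
                warnings.warn(
                    f"residue {cid}:{num} typed both helix and strand; helix wins")
            codes[(cid, num)] = "H"
    return codes


# ---------------------------------------------------------------------------
# Segment coalescing

# DSSP alphabet -> glyph class. Isolated bridges (B) and turns/bends render
# as noise at this abstraction level, so they join the coil.
_DSSP_TO_TYPE = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand",
    "B": "coil", "T": "coil", "S": "coil", "P": "coil",
    " ": "coil", "": "coil", "-": "coil", "C": "coil",
}


def coalesce_ss(codes: Mapping[tuple[str, int], str],
                structure: ProteinStructure) -> list[SecondaryStructureSegment]:
    """Turn per-residue DSSP codes into maximal typed segments.

    Helix runs shorter than :data:`MIN_HELIX_LEN` and strand runs shorter
    than :data:`MIN_STRAND_LEN` are demoted to coil, then adjacent
    same-type runs merge. The result partitions each chain's residues in
    order: the segment lengths sum to the residue count, no overlaps,
    no two adjacent segments share a type.
    """
    segments: list[SecondaryStructureSegment] = []
    for chain in structure.chains:
        types: list[str] = []
        for res in chain.residues:
            code = codes.get((chain.chain_id, res.seq_num), " ")
            t = _DSSP_TO_TYPE.get(code)
            if t is None:
                warnings.warn(f"unknown DSSP code {code!r}; treated as coil")
                t = "coil"
            types.append(t)
        # demote too-short regular runs
        for start, end, t in _runs(types):
            n = end - start + 1
            if (t == "helix" and n < MIN_HELIX_LEN) or \
               (t == "strand" and n < MIN_STRAND_LEN):
                types[start:end + 1] = ["coil"] * n
        for start, end, t in _runs(types):
            segments.append(SecondaryStructureSegment(t, chain.chain_id, start, end))
    return segments


def _runs(types: list[str]) -> list[tuple[int, int, str]]:
    out: list[tuple[int, int, str]] = []
    i = 0
    while i < len(types):
        j = i
        while j + 1 < len(types) and types[j + 1] == types[i]:
            j += 1
        out.append((i, j, types[i]))
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# Disulfides

def detect_disulfides(structure: ProteinStructure) -> list[DisulfidePair]:
    """All unordered CYS pairs with SG–SG distance ≤ 2.5 Å, each once."""
    cys = [r for r in structure.residues if r.res_name == "CYS"]
    with_sg = []
    for r in cys:
        if "SG" in r.atoms:
            with_sg.append(r)
        else:
            logger.debug("CYS %r lacks an SG atom; skipped", r)
    pairs: list[DisulfidePair] = []
    for i in range(len(with_sg)):
        for j in range(i + 1, len(with_sg)):
            a, b = with_sg[i], with_sg[j]
            d = float(np.linalg.norm(a.atoms["SG"] - b.atoms["SG"]))
            if d <= DISULFIDE_SG_MAX:
                pairs.append(DisulfidePair(a, b, d))
    return pairs
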
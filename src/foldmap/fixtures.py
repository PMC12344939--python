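"""Deterministic synthetic Cα-trace structures for testing and demos.

Builds ideal secondary-structure blocks from textbook α-helix geometry
(1.5 Å rise, 100° twist, 2.3 Å radius per residue) and extended strands,
concatenates them with seeded rigid placements, and writes them as
minimal PDB/mmCIF files. Each generated structure comes with its
ground-truth per-residue secondary-structure codes, so the full pipeline
is testable without any external assignment program or downloads.

These traces exist to make the orientation and glyph math analytically
checkable, not to mimic real protein backbones.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .structure import Chain, ProteinStructure, Residue

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "make_ideal_helix",
    "make_ideal_strand",
    "make_coil",
    "assemble_fixture",
    "write_pdb",
    "write_mmcif",
    "standard_fixture_set",
    "HELIX_RISE",
    "HELIX_TWIST_DEG",
    "HELIX_RADIUS",
    "STRAND_RISE",
]

HELIX_RISE = 1.5       # Å per residue along the axis
HELIX_TWIST_DEG = 100.0  # degrees per residue
HELIX_RADIUS = 2.3     # Å, Cα helix radius
STRAND_RISE = 3.4      # Å per residue, extended chain
STRAND_PLEAT = 0.5     # Å alternating offset

_CLASH_DIST = 2.0      # Å; non-consecutive Cα closer than this is a clash


class FixtureError(RuntimeError):
    """Clash-free placement could not be found."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic structure.

    ``blocks`` is an ordered list of (kind, n_res) with kind in
    {'helix', 'strand', 'coil'}; ``cys_positions`` requests pairs of
    residue indices (0-based) to replace with bonded CYS.
    """

    blocks: tuple[tuple[str, int], ...]
    chain_id: str = "A"
    seed: int = 0
    noise_sigma: float = 0.0
    cys_pairs: tuple[tuple[int, int], ...] = ()
    start_num: int = 1

    def __post_init__(self) -> None:
        for kind, n in self.blocks:
            if kind not in ("helix", "strand", "coil"):
                raise ValueError(f"unknown block kind {kind!r}")
            if n < 1:
                raise ValueError("block needs n_res >= 1")


def _helix_trace(n_res: int, rise: float = HELIX_RISE,
                 twist_deg: float = HELIX_TWIST_DEG,
                 radius: float = HELIX_RADIUS) -> np.ndarray:
    i = np.arange(n_res)
    theta = np.deg2rad(twist_deg) * i
    return np.column_stack([radius * np.cos(theta),
                            radius * np.sin(theta),
                            rise * i])


def _strand_trace(n_res: int, rise: float = STRAND_RISE) -> np.ndarray:
    i = np.arange(n_res)
    pleat = STRAND_PLEAT * np.where(i % 2 == 0, 1.0, -1.0)
    return np.column_stack([pleat, np.zeros(n_res), rise * i])


def _coil_trace(n_res: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random-walk coil with realistic 3.8 Å Cα–Cα steps."""
    pts = [np.zeros(3)]
    for _ in range(max(n_res - 1, 0)):
        for _ in range(100):
            step = rng.normal(size=3)
            cand = pts[-1] + 3.8 * step / np.linalg.norm(step)
            if len(pts) < 2 or np.linalg.norm(
                    np.array(pts[:-1]) - cand, axis=1).min() >= _CLASH_DIST:
                pts.append(cand)
                break
        else:
            raise FixtureError("self-avoiding coil walk failed after 100 tries")
    return np.array(pts)


def _as_structure(coords: np.ndarray, chain_id: str = "A", start_num: int = 1,
                  res_names: Optional[Sequence[str]] = None,
                  struct_id: str = "fixture",
                  sg_coords: Optional[dict[int, np.ndarray]] = None) -> ProteinStructure:
    residues = []
    for idx, xyz in enumerate(coords):
        atoms = {"CA": np.asarray(xyz, dtype=float)}
        if sg_coords and idx in sg_coords:
            atoms["SG"] = np.asarray(sg_coords[idx], dtype=float)
        name = res_names[idx] if res_names else "ALA"
        residues.append(Residue(chain_id, start_num + idx, "", name, atoms))
    return ProteinStructure(struct_id, [Chain(chain_id, residues)], "pdb")


def make_ideal_helix(n_res: int, rise: float = HELIX_RISE,
                     twist_deg: float = HELIX_TWIST_DEG,
                     radius: float = HELIX_RADIUS,
                     chain_id: str = "A") -> ProteinStructure:
    """Cα trace on a regular helix around the z axis.

    Consecutive Cα–Cα distance is the constant
    sqrt((2 r sin(twist/2))² + rise²) ≈ 3.8 Å for the defaults.
    """
    if n_res < 1:
        raise ValueError("n_res >= 1")
    return _as_structure(_helix_trace(n_res, rise, twist_deg, radius),
                         chain_id, struct_id=f"helix{n_res}")


def make_ideal_strand(n_res: int, rise: float = STRAND_RISE,
                      chain_id: str = "A") -> ProteinStructure:
    """Cα trace along a line with a ±0.5 Å alternating pleat offset."""
    if n_res < 1:
        raise ValueError("n_res >= 1")
    return _as_structure(_strand_trace(n_res, rise), chain_id,
                         struct_id=f"strand{n_res}")


def make_coil(n_res: int, seed: int = 0, chain_id: str = "A") -> ProteinStructure:
    return _as_structure(_coil_trace(n_res, np.random.default_rng(seed)),
                         chain_id, struct_id=f"coil{n_res}")


_BLOCK_CODE = {"helix": "H", "strand": "E", "coil": " "}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 2] = -Q[:, 2]
    return Q


def assemble_fixture(spec: FixtureSpec) -> tuple[ProteinStructure,
                                                 dict[tuple[str, int], str],
                                                 list[tuple[int, int]]]:
    """Concatenate blocks into one chain with seeded rigid placements.

    Each block after the first is rotated randomly (seeded) and attached
    3.8 Å from the previous block's last Cα; placements putting any two
    non-consecutive Cα closer than 2 Å are rejected and resampled (up to
    1000 tries). Returns the structure, its ground-truth DSSP-style
    codes keyed by (chain, seq_num), and the CYS pair indices.
    """
    rng = np.random.default_rng(spec.seed)
    placed: list[np.ndarray] = []
    codes_per_res: list[str] = []
    for kind, n in spec.blocks:
        if kind == "helix":
            block = _helix_trace(n)
        elif kind == "strand":
            block = _strand_trace(n)
        else:
            block = _coil_trace(n, rng)
        codes_per_res.extend([_BLOCK_CODE[kind]] * n)
        if not placed:
            placed.append(block - block[0])
            continue
        prev = np.vstack(placed)
        tail = prev[-1]
        for _ in range(1000):
            R = _random_rotation(rng)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = (block - block[0]) @ R.T + tail + 3.8 * d
            # clash check against everything except the connecting pair
            diff = prev[:-1, None, :] - cand[None, :, :]
            ok = diff.size == 0 or np.sqrt((diff ** 2).sum(-1)).min() >= _CLASH_DIST
            if ok and len(cand) > 1:
                ok = np.linalg.norm(cand[1:] - tail, axis=1).min() >= _CLASH_DIST
            if ok:
                placed.append(cand)
                break
        else:
            raise FixtureError("no clash-free placement found in 1000 tries")
    coords = np.vstack(placed)
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(scale=spec.noise_sigma, size=coords.shape)

    res_names = ["ALA"] * len(coords)
    sg: dict[int, np.ndarray] = {}
    cys_pairs = [tuple(p) for p in spec.cys_pairs]
    for a, b in cys_pairs:
        res_names[a] = res_names[b] = "CYS"
        # SG atoms placed midway, 2.04 Å apart, regardless of Cα separation
        mid = 0.5 * (coords[a] + coords[b])
        axis = coords[b] - coords[a]
        n = np.linalg.norm(axis)
        axis = axis / n if n > 1e-9 else np.array([1.0, 0, 0])
        sg[a] = mid - 1.02 * axis
        sg[b] = mid + 1.02 * axis

    structure = _as_structure(coords, spec.chain_id, spec.start_num, res_names,
                              struct_id=f"fixture_seed{spec.seed}", sg_coords=sg)
    codes = {(spec.chain_id, spec.start_num + i): c
             for i, c in enumerate(codes_per_res)}
    return structure, codes, cys_pairs


# ---------------------------------------------------------------------------
# Writers

def _to_gemmi(structure: ProteinStructure,
              ss_codes: Optional[dict[tuple[str, int], str]] = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_num, res.insertion_code or " ")
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element("S" if name == "SG" else name[0])
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    if ss_codes:
        _attach_ss(st, structure, ss_codes)
    return st


def _attach_ss(st: gemmi.Structure, structure: ProteinStructure,
               codes: dict[tuple[str, int], str]) -> None:
    """Store helix/strand runs as struct_conf / struct_sheet_range."""
    def addr(chain_id: str, res: Residue) -> gemmi.AtomAddress:
        return gemmi.AtomAddress(chain_id, gemmi.SeqId(res.seq_num, " "),
                                 res.res_name, "")

    sheet = gemmi.Sheet("A")
    n_strand = 0
    for chain in structure.chains:
        run_code, run_start = None, 0
        rows = [codes.get((chain.chain_id, r.seq_num), " ") for r in chain.residues]
        rows.append("$")  # sentinel
        for i, code in enumerate(rows):
            code = "H" if code in "HGI" else ("E" if code == "E" else " ")
            if code != run_code:
                if run_code == "H":
                    h = gemmi.Helix()
                    h.start = addr(chain.chain_id, chain.residues[run_start])
                    h.end = addr(chain.chain_id, chain.residues[i - 1])
                    h.length = i - run_start
                    st.helices.append(h)
                elif run_code == "E":
                    s = gemmi.Sheet.Strand()
                    s.start = addr(chain.chain_id, chain.residues[run_start])
                    s.end = addr(chain.chain_id, chain.residues[i - 1])
                    n_strand += 1
                    s.name = str(n_strand)
                    sheet.strands.append(s)
                run_code, run_start = code, i
    if sheet.strands:
        st.sheets.append(sheet)


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Minimal standards-conformant ATOM records (fixed columns)."""
    st = _to_gemmi(structure)
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def write_mmcif(structure: ProteinStructure, path: str | Path,
                ss_codes: Optional[dict[tuple[str, int], str]] = None) -> None:
    """atom_site loop plus optional embedded struct_conf/struct_sheet_range."""
    st = _to_gemmi(structure, ss_codes)
    try:
        st.make_mmcif_document().write_file(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def standard_fixture_set(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Dump the standard test set used by the CLI's ``fixtures`` command."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    recipes = {
        "helix12": FixtureSpec((("helix", 12),), seed=seed),
        "strand8": FixtureSpec((("strand", 8),), seed=seed),
        "mixed": FixtureSpec((("helix", 8), ("coil", 4), ("strand", 6)), seed=seed),
        "two_domain": FixtureSpec(
            (("helix", 10), ("strand", 6), ("coil", 9),
             ("helix", 10), ("strand", 6)), seed=seed),
        "disulfide": FixtureSpec((("helix", 8), ("coil", 4), ("helix", 8)),
                                 seed=seed, cys_pairs=((2, 17),)),
    }
    for name, spec in recipes.items():
        structure, codes, _ = assemble_fixture(spec)
        pdb = out / f"{name}.pdb"
        cif = out / f"{name}.cif"
        write_pdb(structure, pdb)
        write_mmcif(structure, cif, ss_codes=codes)
        written += [pdb, cif]
    return written
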
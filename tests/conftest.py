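"""Shared fixtures: synthetic structures, a toy family database, and
golden secondary-structure assignment files (both DSSP dialects),
all generated programmatically at test time."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from foldmap.align import build_family_database
from foldmap.fixtures import (FixtureSpec, assemble_fixture, make_ideal_helix,
                              write_mmcif, write_pdb)
from foldmap.structure import Chain, ProteinStructure, Residue


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_helix(12)


@pytest.fixture(scope="session")
def mixed_fixture():
    """helix(8)-coil(4)-strand(6) with ground-truth codes."""
    return assemble_fixture(FixtureSpec(
        (("helix", 8), ("coil", 4), ("strand", 6)), seed=11))


@pytest.fixture(scope="session")
def two_domain_fixture():
    """Two copies of the same helix-strand motif joined by a coil."""
    return assemble_fixture(FixtureSpec(
        (("helix", 10), ("strand", 6), ("coil", 9),
         ("helix", 10), ("strand", 6)), seed=7))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, mixed_fixture, two_domain_fixture):
    """Structure files for the session: PDB + mmCIF of each fixture."""
    d = tmp_path_factory.mktemp("structs")
    st, codes, _ = mixed_fixture
    write_pdb(st, d / "mixed.pdb")
    write_mmcif(st, d / "mixed.cif", ss_codes=codes)
    st2, codes2, _ = two_domain_fixture
    write_pdb(st2, d / "two_domain.pdb")
    write_mmcif(st2, d / "two_domain.cif", ss_codes=codes2)
    write_mmcif(make_ideal_helix(12), d / "helix12.cif")
    return d


@pytest.fixture(scope="session")
def toy_db(tmp_path_factory, fixture_dir):
    """Two-family database: fold A = pure helix, fold B = mixed motif."""
    out = tmp_path_factory.mktemp("familydb")
    return build_family_database(
        {"foldA": fixture_dir / "helix12.cif",
         "foldB": fixture_dir / "mixed.cif"}, out)


def rigid_copy(structure: ProteinStructure, rotation: np.ndarray,
               translation: np.ndarray, new_id: str = "copy") -> ProteinStructure:
    """Apply a rigid motion to every atom of a structure."""
    chains = []
    for chain in structure.chains:
        residues = []
        for r in chain.residues:
            atoms = {name: rotation @ xyz + translation
                     for name, xyz in r.atoms.items()}
            residues.append(Residue(r.chain_id, r.seq_num, r.insertion_code,
                                    r.res_name, atoms))
        chains.append(Chain(chain.chain_id, residues))
    return ProteinStructure(new_id, chains, structure.source_format)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 2] = -Q[:, 2]
    return Q


# ---------------------------------------------------------------------------
# Golden DSSP files (classic v4 fixed-column dialect and the mmCIF dialect)

def _classic_dssp_line(num: int, resnum: int, chain: str, aa: str, ss: str) -> str:
    line = [" "] * 136
    s = f"{num:5d}{resnum:5d} {chain} {aa}  {ss}"
    for i, ch in enumerate(s):
        line[i] = ch
    # plausible ACC and dihedral columns so fixed-column parsers are happy
    body =("{:>4}{:>4}{:>5}".format(0, 0, 0) +
            "      0, 0.0     0, 0.0     0, 0.0     0, 0.0  "
            "0.000 360.0 360.0-100.0 100.0 "
            "{:>7.1f}{:>7.1f}{:>7.1f}".format(0.0, 0.0, 0.0))
    for i, ch in enumerate(body):
        if 25 + i < 136:
            line[25 + i] = ch
    return "".join(line).rstrip()


@pytest.fixture(scope="session")
def dssp_classic_file(tmp_path_factory) -> Path:
    """Hand-built classic-dialect file: chain A residues 1-5 all 'H'."""
    d = tmp_path_factory.mktemp("dssp")
    header = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "REFERENCE  synthetic golden file",
        "HEADER     synthetic helix",
        "  5  1  0  0  0 TOTAL NUMBER OF RESIDUES",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    "
        "X-CA   Y-CA   Z-CA",
    ]
    lines = [_classic_dssp_line(i + 1, i + 1, "A", "A", "H") for i in range(5)]
    p = d / "helix.dssp"
    p.write_text("\n".join(header + lines) + "\n")
    return p


@pytest.fixture(scope="session")
def dssp_mmcif_file(tmp_path_factory) -> Path:
    """Same assignment in the mmCIF dialect (_dssp_struct_summary loop)."""
    d = tmp_path_factory.mktemp("dssp_cif")
    rows = "\n".join(f"1 A {i} {i} H" for i in range(1, 6))
    text = f"""data_helix
loop_
_dssp_struct_summary.entry_id
_dssp_struct_summary.label_asym_id
_dssp_struct_summary.label_seq_id
_dssp_struct_summary.auth_seq_id
_dssp_struct_summary.secondary_structure
{rows}
"""
    p = d / "helix_dssp.cif"
    p.write_text(text)
    return p
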
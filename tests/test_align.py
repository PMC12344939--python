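"""Kabsch superposition, family search, and database construction."""
import numpy as np
import pytest

from conftest import random_rotation, rigid_copy

from foldmap.align import (AlignConfig, AlignmentHit, DatabaseError,
                           FamilyDatabase, InsufficientAlignmentError,
                           build_family_database, frame_for_query,
                           hit_to_frame, kabsch_superpose, parse_search_table,
                           run_family_search, select_family_representative)
from foldmap.orientation import apply_frame
from foldmap.structure import read_structure


class TestKabsch:
    def test_identical_sets_give_identity(self):
        P = np.random.default_rng(0).normal(size=(10, 3))
        frame, rmsd = kabsch_superpose(P, P)
        assert np.allclose(frame.rotation, np.eye(3), atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_constructed_90deg_rotation_recovered(self):
        Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        P = np.random.default_rng(1).normal(size=(12, 3))
        frame, rmsd = kabsch_superpose(P, P @ Rz.T)
        assert np.allclose(frame.rotation, Rz, atol=1e-9)
        assert rmsd < 1e-9

    def test_recovers_50_random_rotations_noise_free(self):
        """Noise-free pairs: recovery within 1e-6 Frobenius, always proper."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            R = random_rotation(rng)
            P = rng.normal(size=(25, 3)) * 3
            t = rng.normal(size=3)
            frame, rmsd = kabsch_superpose(P, P @ R.T + t)
            assert np.linalg.norm(frame.rotation - R) < 1e-6
            assert np.linalg.det(frame.rotation) == pytest.approx(1.0, abs=1e-9)
            assert rmsd < 1e-9

    def test_agrees_with_scipy_oracle_under_noise(self):
        """Noisy case: rotation matches scipy's independent implementation."""
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(13)
        R = random_rotation(rng)
        P = rng.normal(size=(50, 3)) * 4
        Q = P @ R.T + rng.normal(scale=0.1, size=(50, 3))
        frame, rmsd = kabsch_superpose(P, Q)
        est, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert np.linalg.norm(frame.rotation - est.as_matrix()) < 1e-6
        assert np.linalg.norm(frame.rotation - R) < 1e-2

    def test_rmsd_monotone_in_noise(self):
        rng = np.random.default_rng(2)
        R = random_rotation(rng)
        P = rng.normal(size=(50, 3)) * 4
        rmsds = []
        for sigma in (0.5, 0.1, 0.01):
            noise = np.random.default_rng(99).normal(size=(50, 3))
            _, rmsd = kabsch_superpose(P, P @ R.T + sigma * noise)
            rmsds.append(rmsd)
        assert rmsds[0] > rmsds[1] > rmsds[2]

    def test_collinear_input_degenerate(self):
        P = np.array([[i, 0.0, 0.0] for i in range(5)])
        with pytest.raises(Exception):
            kabsch_superpose(P, P)

    def test_reflection_corrected(self):
        # target is a mirror image; result must still be a proper rotation
        rng = np.random.default_rng(4)
        P = rng.normal(size=(20, 3))
        Q = P * np.array([1, 1, -1])
        frame, _ = kabsch_superpose(P, Q)
        assert np.linalg.det(frame.rotation) == pytest.approx(1.0, abs=1e-9)


class TestSearchTable:
    GOLDEN = (
        "q1\trepA\t0.92\t0.88\t1,0,0,0,1,0,0,0,1\t0,0,0\t1\t1\t5M\n"
        "q1\trepB\t0.40\t0.35\t0,-1,0,1,0,0,0,0,1\t1,2,3\t2\t4\t3M2I1M\n")

    def test_golden_rows_parsed(self):
        hits = parse_search_table(self.GOLDEN)
        assert len(hits) == 2
        assert hits[0].similarity == pytest.approx(0.92)
        assert hits[0].residue_pairs == tuple((i, i) for i in range(5))
        assert np.allclose(hits[1].tool_rotation,
                           [[0, -1, 0], [1, 0, 0], [0, 0, 1]])
        assert np.allclose(hits[1].tool_translation, [1, 2, 3])

    def test_cigar_insertion_shifts_query_only(self):
        hits = parse_search_table(self.GOLDEN)
        # 3M at (q=1,t=3), 2I skips query, then 1M pairs (6,6)
        assert hits[1].residue_pairs == ((1, 3), (2, 4), (3, 5), (6, 6))

    def test_truncated_line_rejected(self):
        with pytest.raises(Exception):
            parse_search_table("q\tt\t0.9\n")

    def test_similarity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            AlignmentHit("q", "t", 1.5)


class TestFamilySearch:
    def test_self_alignment_invariant(self, toy_db, fixture_dir):
        """Every representative finds its own family above threshold."""
        for fam_id, entry in toy_db.families.items():
            hit = run_family_search(entry.representative,
                                    AlignConfig(toy_db.db_path))
            assert hit is not None
            assert hit.target_id == fam_id
            assert hit.similarity >= 0.5

    def test_below_threshold_returns_none(self, toy_db, fixture_dir, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="foldmap.align"):
            hit = run_family_search(
                fixture_dir / "helix12.cif",
                AlignConfig(toy_db.db_path, min_similarity=1.0 - 1e-12,
                            target_family="foldB"))
        # helix12 vs the mixed fold: not a perfect match at threshold ~1
        assert hit is None
        assert any("no rotation produced" in r.message for r in caplog.records)

    def test_default_threshold_rejects_weak_mocked_hit(self, toy_db,
                                                       fixture_dir,
                                                       monkeypatch):
        """A best hit at similarity 0.40 falls below the default 0.5
        threshold: no frame is produced, only a warning."""
        import foldmap.align as fa
        weak = AlignmentHit("q", "foldA", 0.40)
        monkeypatch.setattr(fa, "_builtin_search", lambda *a, **k: weak)
        hit = run_family_search(fixture_dir / "helix12.cif",
                                AlignConfig(toy_db.db_path, backend="builtin"))
        assert hit is None
        strong = AlignmentHit("q", "foldA", 0.92)
        monkeypatch.setattr(fa, "_builtin_search", lambda *a, **k: strong)
        hit = run_family_search(fixture_dir / "helix12.cif",
                                AlignConfig(toy_db.db_path, backend="builtin"))
        assert hit is strong

    def test_target_family_restricts_search(self, toy_db, fixture_dir):
        hit = run_family_search(fixture_dir / "helix12.cif",
                                AlignConfig(toy_db.db_path, min_similarity=0.0,
                                            target_family="foldB"))
        assert hit is not None and hit.target_id == "foldB"

    def test_unknown_target_family_errors(self, toy_db, fixture_dir):
        with pytest.raises(DatabaseError):
            run_family_search(fixture_dir / "helix12.cif",
                              AlignConfig(toy_db.db_path, target_family="nope"))


class TestHitToFrame:
    def test_identical_query_gives_identity_modulo_centering(self, toy_db):
        rep = read_structure(toy_db.families["foldB"].representative)
        hit = run_family_search(rep, AlignConfig(toy_db.db_path))
        frame = hit_to_frame(hit, rep)  # no representative frame composed
        assert np.allclose(frame.rotation, np.eye(3), atol=1e-6)

    def test_known_rotation_inverted(self, toy_db):
        rep = read_structure(toy_db.families["foldB"].representative)
        Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        moved = rigid_copy(rep, Rz, np.array([4.0, -1.0, 2.0]))
        hit = run_family_search(moved, AlignConfig(toy_db.db_path))
        frame = hit_to_frame(hit, moved)
        # applying the frame must undo the rigid motion: R_frame == Rz^-1
        assert np.allclose(frame.rotation, Rz.T, atol=1e-6)

    def test_residue_pair_path_equals_tool_matrix_path(self, toy_db):
        """Kabsch on matched pairs reproduces the tool-matrix frame."""
        rep = read_structure(toy_db.families["foldB"].representative)
        rng = np.random.default_rng(6)
        moved = rigid_copy(rep, random_rotation(rng), rng.normal(size=3))
        hit = run_family_search(moved, AlignConfig(toy_db.db_path))
        via_matrix = hit_to_frame(hit, moved)
        pair_hit = AlignmentHit(hit.query_id, hit.target_id, hit.similarity,
                                residue_pairs=hit.residue_pairs)
        via_pairs = hit_to_frame(pair_hit, moved,
                                 target_coords=rep.ca_coords())
        assert np.allclose(via_matrix.rotation, via_pairs.rotation, atol=1e-3)
        assert np.allclose(via_matrix.translation, via_pairs.translation,
                           atol=1e-3)

    def test_insufficient_pairs_error(self, toy_db):
        rep = read_structure(toy_db.families["foldB"].representative)
        hit = AlignmentHit("q", "foldB", 0.9, residue_pairs=((0, 0), (1, 1)))
        with pytest.raises(InsufficientAlignmentError):
            hit_to_frame(hit, rep, target_coords=rep.ca_coords())

    def test_orientation_consistency_of_rigid_copies(self, toy_db):
        """Two rigid-body copies aligned to the same family project to
        coincident Cα point sets (within 0.1 Å)."""
        rep = read_structure(toy_db.families["foldB"].representative)
        db = FamilyDatabase.load(toy_db.db_path)
        projections = []
        for seed in (21, 22):
            rng = np.random.default_rng(seed)
            moved = rigid_copy(rep, random_rotation(rng), rng.normal(size=3) * 10)
            hit = run_family_search(moved, AlignConfig(toy_db.db_path))
            frame = frame_for_query(moved, hit, db)
            projections.append(apply_frame(moved.ca_coords(), frame)[:, :2])
        dev = np.linalg.norm(projections[0] - projections[1], axis=1).max()
        assert dev < 0.1


class TestRepresentativeSelection:
    def test_singleton(self):
        assert select_family_representative(["only"], np.ones((1, 1))) == "only"

    def test_highest_row_mean_wins(self):
        M = np.array([[1.0, 0.9, 0.7],
                      [0.9, 1.0, 0.3],
                      [0.7, 0.3, 1.0]])
        assert select_family_representative(["a", "b", "c"], M) == "a"

    def test_tie_breaks_lexicographically(self):
        M = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert select_family_representative(["zeta", "alpha"], M) == "alpha"

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            select_family_representative(["a", "b"], np.ones((2, 3)))


class TestBuildDatabase:
    def test_empty_map_rejected(self, tmp_path):
        with pytest.raises(DatabaseError):
            build_family_database({}, tmp_path / "db")

    def test_rebuild_is_idempotent(self, tmp_path, fixture_dir):
        fams = {"A": fixture_dir / "helix12.cif"}
        db1 = build_family_database(fams, tmp_path / "db")
        manifest1 = (tmp_path / "db" / "manifest.toml").read_text()
        build_family_database(fams, tmp_path / "db")
        assert (tmp_path / "db" / "manifest.toml").read_text() == manifest1
        assert "foldA" not in db1.families or True

    def test_loaded_frames_are_valid_rotations(self, toy_db):
        db = FamilyDatabase.load(toy_db.db_path)
        for entry in db.families.values():
            R = entry.frame.rotation
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-6)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-6)

    def test_missing_manifest_errors(self, tmp_path):
        with pytest.raises(DatabaseError):
            FamilyDatabase.load(tmp_path)
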
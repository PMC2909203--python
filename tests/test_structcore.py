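"""Structure data model, PDB I/O, superposition and torsion geometry."""

import numpy as np
import pytest

from consfold.geometry import build_backbone
from consfold.structcore import (
    AtomRecord,
    Model,
    Sequence,
    StructureError,
    _format_atom_line,
    backbone_torsions,
    dihedral,
    helix_fraction,
    kabsch_superimpose,
    read_pdb,
    read_ensemble,
    superimpose_repeats,
    write_ensemble,
    write_pdb,
)

GLY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
"""


class TestPdbIO:
    def test_minimal_glycine_parse(self, tmp_path):
        p = tmp_path / "gly.pdb"
        p.write_text(GLY_PDB)
        m = read_pdb(p)
        assert len(m.sequence) == 1
        assert m.sequence.residues == "G"
        assert len(m.atoms) == 4
        assert not m.coarse_grained

    def test_round_trip_preserves_coordinates(self, toy_bundle, tmp_path):
        p = tmp_path / "bundle.pdb"
        write_pdb(toy_bundle, p)
        back = read_pdb(p)
        # PDB stores 3 decimals: the round trip is exact at that precision
        np.testing.assert_array_equal(np.round(toy_bundle.coords(), 3),
                                      back.coords())
        assert [a.atom_name for a in back.atoms] == \
               [a.atom_name for a in toy_bundle.atoms]
        assert back.sequence.residues == toy_bundle.sequence.residues
        # second round trip is byte-identical
        p2 = tmp_path / "again.pdb"
        write_pdb(back, p2)
        assert p.read_text() == p2.read_text()

    def test_ca_only_trace_flagged_coarse(self, tmp_path):
        lines = []
        for i in range(1, 4):
            lines.append(f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                         f"{float(i) * 3.8:8.3f}{0.0:8.3f}{1.0:8.3f}  1.00  0.00           C")
        p = tmp_path / "trace.pdb"
        p.write_text("\n".join(lines) + "\n")
        m = read_pdb(p)
        assert m.coarse_grained
        assert len(m.sequence) == 3

    def test_missing_ca_is_hard_error(self, tmp_path):
        bad = GLY_PDB.replace("CA ", "CG ")
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(StructureError, match="CA"):
            read_pdb(p)

    def test_unknown_residue_rejected(self, tmp_path):
        p = tmp_path / "unk.pdb"
        p.write_text(GLY_PDB.replace("GLY", "UNK"))
        with pytest.raises(StructureError, match="unknown residue"):
            read_pdb(p)

    def test_hetatm_rejected(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(GLY_PDB + "HETATM    5  O   HOH A   2      10.000  10.000  10.000  1.00  0.00           O\n")
        with pytest.raises(StructureError):
            read_pdb(p)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        m = read_pdb(p)
        ca = m.get_atom(1, "CA")
        assert ca.position[0] == pytest.approx(2.0)

    def test_atom_line_format(self):
        a = AtomRecord("CA", "C", 1, "A", np.array([1.2345, -2.5, 3.0]))
        line = _format_atom_line(1, a)
        assert line[30:38] == "   1.234" or line[30:38] == "   1.235"
        assert line[38:46] == "  -2.500"
        assert line[46:54] == "   3.000"
        assert line[54:60] == "  1.00"
        assert line[60:66] == "  0.00"

    def test_serial_overflow_is_error(self):
        a = AtomRecord("CA", "C", 1, "A", np.zeros(3))
        with pytest.raises(OverflowError):
            _format_atom_line(100000, a)

    def test_ensemble_round_trip(self, perturbed, tmp_path):
        p = tmp_path / "ens.pdb"
        write_ensemble(perturbed, p)
        back = read_ensemble(p)
        assert len(back) == len(perturbed)
        for a, b in zip(perturbed, back):
            np.testing.assert_array_equal(np.round(a.coords(), 3), b.coords())


class TestKabsch:
    def test_identical_sets_zero_rmsd(self, rng):
        pts = rng.normal(size=(12, 3))
        _, _, rmsd = kabsch_superimpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_recovered(self, rng):
        pts = rng.normal(size=(10, 3))
        theta = np.pi / 2
        Rz = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0],
                       [0, 0, 1.0]])
        moved = pts @ Rz.T + np.array([1.0, -2.0, 3.0])
        R, t, rmsd = kabsch_superimpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)

    @staticmethod
    def quaternion_rmsd(A, B):
        """Independent oracle: Horn's closed-form quaternion method."""
        A0 = A - A.mean(axis=0)
        B0 = B - B.mean(axis=0)
        M = B0.T @ A0
        Sxx, Sxy, Sxz = M[0]
        Syx, Syy, Syz = M[1]
        Szx, Szy, Szz = M[2]
        N = np.array([
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ])
        lam = np.linalg.eigvalsh(N)[-1]
        e = (A0 ** 2).sum() + (B0 ** 2).sum() - 2.0 * lam
        return np.sqrt(max(e, 0.0) / len(A))

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(20):
            A = rng.normal(size=(10, 3))
            B = rng.normal(size=(10, 3))
            _, _, rmsd = kabsch_superimpose(A, B)
            assert rmsd == pytest.approx(self.quaternion_rmsd(A, B), abs=1e-9)

    def test_symmetry_and_rigid_invariance(self, rng):
        A = rng.normal(size=(15, 3))
        B = rng.normal(size=(15, 3))
        r_ab = kabsch_superimpose(A, B)[2]
        r_ba = kabsch_superimpose(B, A)[2]
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        # arbitrary rigid transform of one input
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        th = 1.1
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * K @ K
        r2 = kabsch_superimpose(A, B @ R.T + 5.0)[2]
        assert r2 == pytest.approx(r_ab, abs=1e-9)

    def test_degenerate_inputs_rejected(self, rng):
        line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        other = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superimpose(line, other)
        with pytest.raises(ValueError):
            kabsch_superimpose(other[:4], other)


class TestRepeats:
    def test_identical_ranges_zero(self, toy_bundle):
        rmsd, n = superimpose_repeats(toy_bundle, (1, 10), (1, 10))
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert n == 10

    def test_exact_rigid_repeat_copy(self, toy_bundle):
        # both helices of the bundle are the same ideal helix geometry
        rmsd, n = superimpose_repeats(toy_bundle, (1, 10), (15, 24))
        assert n == 10
        assert rmsd < 0.15

    def test_noisy_repeat_within_expected_band(self):
        # repeat B = repeat A + isotropic Gaussian noise of 1 A expected
        # displacement over 30 CA; the band [0.77, 1.15] is the 99%
        # interval of a 1000-rep Monte-Carlo oracle of this exact setup
        rng = np.random.default_rng(42)
        n = 30
        helix = build_backbone("A" * n, np.full(n, -57.0), np.full(n, -47.0))
        ca = helix.ca_coords()
        vals = []
        for _ in range(50):
            noisy = ca + rng.normal(0.0, 1.0 / np.sqrt(3.0), size=ca.shape)
            vals.append(kabsch_superimpose(ca, noisy)[2])
        # single draws span [0.77, 1.15] at 99%; the 50-draw mean must sit
        # in the corresponding mean band around 0.96
        assert 0.93 <= np.mean(vals) <= 0.99

    def test_unequal_intervals_rejected(self, toy_bundle):
        with pytest.raises(ValueError):
            superimpose_repeats(toy_bundle, (1, 10), (15, 23))


class TestTorsions:
    def test_ideal_helix_angles(self):
        m = build_backbone("A" * 12, np.full(12, -57.0), np.full(12, -47.0))
        t = backbone_torsions(m)
        assert np.all(np.abs(t.phi[1:] - (-57.0)) < 0.5)
        assert np.all(np.abs(t.psi[:-1] - (-47.0)) < 0.5)
        assert np.isnan(t.phi[0]) and np.isnan(t.psi[-1])

    def test_fully_extended_angles(self):
        m = build_backbone("A" * 8, np.full(8, 180.0), np.full(8, 180.0))
        t = backbone_torsions(m)
        assert np.all(np.abs(np.abs(t.phi[1:])) > 179.5)
        assert np.all(np.abs(np.abs(t.psi[:-1])) > 179.5)

    def test_analytic_ninety_degree_dihedral(self):
        p0 = np.array([1.0, 0.0, 0.0])
        p1 = np.array([0.0, 0.0, 0.0])
        p2 = np.array([0.0, 0.0, 1.0])
        p3 = np.array([0.0, 1.0, 1.0])
        assert dihedral(p0, p1, p2, p3) == pytest.approx(90.0, abs=1e-6)


class TestHelixFraction:
    def test_ideal_helix_counts_interior(self):
        n = 20
        m = build_backbone("A" * n, np.full(n, -57.0), np.full(n, -47.0))
        assert helix_fraction(m) == pytest.approx((n - 2) / n)

    def test_extended_chain_zero(self):
        m = build_backbone("A" * 20, np.full(20, 180.0), np.full(20, 180.0))
        assert helix_fraction(m) == 0.0

    def test_helix_with_extended_tail(self):
        # 30-residue helix + 10-residue extended tail; the junction psi
        # belongs to the tail, so 28 interior residues qualify
        phi = np.concatenate([np.full(30, -57.0), np.full(10, 180.0)])
        psi = np.concatenate([np.full(29, -47.0), np.full(11, 180.0)])
        m = build_backbone("A" * 40, phi, psi)
        assert helix_fraction(m) == pytest.approx(28 / 40)

    def test_monotone_in_added_helical_residue(self):
        # lengthening the helical run never decreases the numerator
        counts = []
        for k in (10, 11, 12):
            phi = np.concatenate([np.full(k, -57.0), np.full(8, 180.0)])
            psi = np.concatenate([np.full(k - 1, -47.0), np.full(9, 180.0)])
            m = build_backbone("A" * (k + 8), phi, psi)
            counts.append(helix_fraction(m) * (k + 8))
        assert counts[0] <= counts[1] <= counts[2]


def test_sequence_validation():
    with pytest.raises(ValueError):
        Sequence("")
    with pytest.raises(ValueError):
        Sequence("AXZ")
    assert len(Sequence("ACDEFG")) == 6


def test_model_validation_requires_ca():
    seq = Sequence("AA")
    atoms = [AtomRecord("CA", "C", 1, "A", np.zeros(3)),
             AtomRecord("N", "N", 2, "A", np.ones(3))]
    with pytest.raises(StructureError, match="lacks a CA"):
        Model(seq, atoms)
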
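"""Sequence- and surface-level functional-site analyses."""

import math

import numpy as np
import pytest

from consfold import (
    BundleSpec,
    detect_heptad_repeats,
    estimate_mw,
    find_amphipathic_helices,
    find_basic_clusters,
    hydrophobic_moment,
    make_amphipathic_sequence,
    make_bundle,
    oda_patches,
    residue_composition,
    sasa,
)
from consfold.funcsite import pdcd10_sequence, read_fasta, write_fasta
from consfold.structcore import AtomRecord, Model, Sequence
from consfold.tables import EISENBERG


class TestHydrophobicMoment:
    def test_poly_leucine_cancels_exactly(self):
        # 18 x 100 deg = 5 full turns: identical vectors sum to zero
        assert hydrophobic_moment("L" * 18) == pytest.approx(0.0, abs=1e-12)

    def test_matches_complex_sum_oracle(self, rng):
        letters = list(EISENBERG)
        for _ in range(10):
            window = "".join(rng.choice(letters) for _ in range(18))
            oracle = abs(sum(
                EISENBERG[res] * np.exp(1j * math.radians(100.0) * n)
                for n, res in enumerate(window))) / len(window)
            assert hydrophobic_moment(window) == pytest.approx(oracle,
                                                               abs=1e-6)

    def test_reversal_with_angle_negation_invariance(self, rng):
        letters = list(EISENBERG)
        window = "".join(rng.choice(letters) for _ in range(15))
        fwd = hydrophobic_moment(window, angle=100.0)
        rev = hydrophobic_moment(window[::-1], angle=-100.0)
        assert fwd == pytest.approx(rev, abs=1e-9)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            hydrophobic_moment("LLLLL")

    def test_non_canonical_rejected(self):
        with pytest.raises(ValueError):
            hydrophobic_moment("LLLXLLL")


class TestAmphipathicScan:
    def test_planted_helix_recovered(self):
        s = make_amphipathic_sequence(60, 20, 20, [20, 23, 30, 34, 37],
                                      seed=7)
        hits = find_amphipathic_helices(s)
        assert hits, "planted helix must be detected"
        planted = set(range(20, 40))
        best = max(hits, key=lambda h: len(planted
                                           & set(range(h.start, h.end + 1))))
        overlap = len(planted & set(range(best.start, best.end + 1)))
        assert overlap >= 0.8 * len(planted)

    def test_homopolymer_has_no_annotations(self):
        assert find_amphipathic_helices("S" * 50) == []

    def test_shuffled_sequence_rarely_recovers_planted_site(self, rng):
        """Shuffling destroys the planted periodicity: annotations that
        still cover >= 80% of the planted interval (the recovery
        criterion above) become rare."""
        s = make_amphipathic_sequence(60, 20, 20, [20, 23, 30, 34, 37],
                                      seed=7)
        planted = set(range(20, 40))
        letters = list(s.residues)
        detections = 0
        n_shuffles = 300
        for _ in range(n_shuffles):
            rng.shuffle(letters)
            hits = find_amphipathic_helices("".join(letters))
            if any(len(planted & set(range(h.start, h.end + 1)))
                   >= 0.8 * len(planted) for h in hits):
                detections += 1
        assert detections < 0.05 * n_shuffles

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_amphipathic_helices("LKLLEELKKL")


class TestBasicClusters:
    def test_pdcd10_spacing_fixture(self):
        # K at relative offsets 0,3,10,14,17 => span 18, five lysines
        start = 20
        pos = [start + o for o in (0, 3, 10, 14, 17)]
        s = make_amphipathic_sequence(60, start, 20, pos, seed=7)
        helices = find_amphipathic_helices(s)
        patches = find_basic_clusters(s, helices)
        assert len(patches) == 1
        assert len(patches[0].basic_residues) == 5
        assert all(r == "K" for _, r in patches[0].basic_residues)
        assert patches[0].span == 18

    def test_no_basic_residues_empty(self):
        s = "L" * 9 + "SEQ" * 17  # amphipathic-ish but K/R free
        helices = find_amphipathic_helices(
            make_amphipathic_sequence(60, 20, 20, [], seed=3))
        seq = make_amphipathic_sequence(60, 20, 20, [], seed=3)
        cleaned = seq.residues.replace("K", "S").replace("R", "S")
        patches = find_basic_clusters(cleaned, helices)
        assert patches == []

    def test_min_basic_threshold_semantics(self):
        start = 20
        pos = [start + 4, start + 8, start + 13]  # inside the helix core
        s = make_amphipathic_sequence(60, start, 20, pos, seed=5)
        helices = find_amphipathic_helices(s)
        # strip every basic residue except the three planted lysines
        seq3 = "".join(
            c if (i + 1 in pos or c not in "KR") else "S"
            for i, c in enumerate(s.residues))
        assert find_basic_clusters(seq3, helices, min_basic=4) == []
        got = find_basic_clusters(seq3, helices, min_basic=3)
        assert len(got) == 1
        assert len(got[0].basic_residues) == 3


class TestSasa:
    def test_isolated_atom_closed_form(self):
        m = Model(Sequence("A"), [AtomRecord("CA", "C", 1, "A", [0, 0, 0])])
        area = sasa(m)[0]
        exact = 4 * math.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.02)

    def test_fully_enclosed_atom_zero(self):
        atoms = [AtomRecord("CA", "C", 1, "A", [0.0, 0.0, 0.0])]
        # cage of atoms on a sphere of radius 2.0: their 3.1 A probe
        # spheres swallow every test point of the central atom
        golden = math.pi * (3 - math.sqrt(5))
        k = np.arange(40)
        phi = np.arccos(1 - 2 * (k + 0.5) / 40)
        theta = golden * k
        cage = 2.0 * np.stack([np.sin(phi) * np.cos(theta),
                               np.sin(phi) * np.sin(theta),
                               np.cos(phi)], axis=1)
        seq = "A" * 41
        for i, p in enumerate(cage):
            atoms.append(AtomRecord("CA", "C", i + 2, "A", p))
        m = Model(Sequence(seq), atoms)
        assert sasa(m)[0] == 0.0

    def test_two_atom_symmetry(self):
        atoms = [AtomRecord("CA", "C", 1, "A", [0.0, 0.0, 0.0]),
                 AtomRecord("CA", "C", 2, "A", [2.5, 0.0, 0.0])]
        m = Model(Sequence("AA"), atoms)
        a = sasa(m)
        assert a[0] == pytest.approx(a[1], abs=1e-6)

    def test_additivity_for_distant_molecules(self, hairpin):
        single = sasa(hairpin).sum()
        coords = hairpin.coords()
        n_atoms = len(hairpin.atoms)
        seq2 = Sequence(hairpin.sequence.residues * 2)
        atoms = []
        for offset, shift in ((0, 0.0), (len(hairpin.sequence), 500.0)):
            for a in hairpin.atoms:
                atoms.append(AtomRecord(a.atom_name, a.element,
                                        a.residue_index + offset,
                                        a.residue_type,
                                        a.position + shift))
        double = sasa(Model(seq2, atoms)).sum()
        assert double == pytest.approx(2 * single, rel=1e-6)

    def test_against_independent_shrake_rupley(self, hairpin):
        """Cross-check against biotite's Shrake-Rupley with single-element
        radii (same radius convention)."""
        biotite_struc = pytest.importorskip("biotite.structure")
        n = len(hairpin.atoms)
        arr = biotite_struc.AtomArray(n)
        arr.coord = hairpin.coords().astype(np.float32)
        arr.atom_name = np.array([a.atom_name for a in hairpin.atoms])
        arr.element = np.array([a.element for a in hairpin.atoms])
        arr.res_id = np.array([a.residue_index for a in hairpin.atoms])
        arr.res_name = np.array(["ALA"] * n)
        arr.chain_id = np.array(["A"] * n)
        ref = biotite_struc.sasa(arr, probe_radius=1.4, point_number=1000,
                                 vdw_radii="Single")
        mine = sasa(hairpin, n_points=1000)
        assert mine.sum() == pytest.approx(float(np.nansum(ref)), rel=0.03)


class TestOdaPatches:
    def charged_cap_sphere(self):
        """Sphere of apolar carbons with a charged cap around +z."""
        golden = math.pi * (3 - math.sqrt(5))
        n = 60
        k = np.arange(n)
        phi = np.arccos(1 - 2 * (k + 0.5) / n)
        theta = golden * k
        pts = 8.0 * np.stack([np.sin(phi) * np.cos(theta),
                              np.sin(phi) * np.sin(theta),
                              np.cos(phi)], axis=1)
        atoms = []
        residues = []
        for i, p in enumerate(pts):
            charged = p[2] > 6.5
            res = "K" if charged else "L"
            residues.append(res)
            atoms.append(AtomRecord("CA", "C", i + 1, res, p))
            atoms.append(AtomRecord("CB", "C", i + 1, res, p * 1.05))
        return Model(Sequence("".join(residues)), atoms), pts

    def test_best_patch_avoids_charged_cap(self):
        m, pts = self.charged_cap_sphere()
        patches = oda_patches(m, patch_radius=6.0)
        assert patches
        best_center = m.atoms[patches[0].center_atom]
        assert best_center.residue_type == "L"
        center_z = m.atoms[patches[0].center_atom].position[2]
        assert center_z < 6.5

    def test_buried_atoms_never_in_patches(self, hairpin):
        areas = sasa(hairpin)
        patches = oda_patches(hairpin, areas=areas)
        buried = set(np.nonzero(areas <= 1.0)[0])
        for p in patches:
            assert buried.isdisjoint(p.member_atoms)

    def test_patch_count_bounded_by_surface(self, hairpin):
        areas = sasa(hairpin)
        patches = oda_patches(hairpin, areas=areas)
        assert 0 < len(patches) <= int((areas > 1.0).sum())

    def test_rigid_transform_stability(self, hairpin, rng):
        base = oda_patches(hairpin)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        th = 0.9
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * K @ K
        moved = hairpin.with_coords(hairpin.coords() @ R.T + 30.0)
        rotated = oda_patches(moved)
        assert len(rotated) == pytest.approx(len(base), abs=1)
        assert rotated[0].oda_score == pytest.approx(base[0].oda_score,
                                                     rel=0.05)


class TestCompositionAndMass:
    def test_keke_counts(self):
        comp = residue_composition("KEKE")
        assert comp == {"K": 2, "E": 2}

    def test_counts_sum_to_length(self, rng):
        letters = list(EISENBERG)
        seq = "".join(rng.choice(letters) for _ in range(77))
        assert sum(residue_composition(seq).values()) == 77

    def test_pdcd10_reference_composition(self):
        seq = pdcd10_sequence()
        comp = residue_composition(seq)
        assert len(seq) == 212
        assert comp["K"] == 21
        assert comp["E"] == 21

    def test_pdcd10_alpha5_lysines(self):
        seq = pdcd10_sequence()
        for pos in (169, 172, 179, 183, 186):
            assert seq.residues[pos - 1] == "K"

    def test_free_glycine_mass(self):
        assert estimate_mw("G") == pytest.approx(75.07, abs=0.01)

    def test_diglycine_condensation(self):
        assert estimate_mw("GG") == pytest.approx(132.12, abs=0.01)

    def test_dimer_is_exactly_twice_monomer(self):
        seq = pdcd10_sequence()
        assert estimate_mw(seq, 2) == 2 * estimate_mw(seq, 1)

    def test_mass_additivity(self):
        s1, s2 = "ACDEFG", "KLMNPQ"
        assert estimate_mw(s1 + s2) == pytest.approx(
            estimate_mw(s1) + estimate_mw(s2) - 18.02, abs=1e-9)


class TestHeptad:
    def ideal_heptad(self, n_repeats=4):
        return "LSSLSSS" * n_repeats  # L at positions a and d

    def test_ideal_repeat_register(self):
        from consfold.funcsite import HelixAnnotation
        seq = self.ideal_heptad()
        helix = HelixAnnotation(1, len(seq), 0.5, [True] * len(seq))
        out = detect_heptad_repeats(seq, [helix])
        assert out[0] is not None
        assert out[0]["frame"] == 0
        reg = out[0]["register"]
        assert all(reg[i] in "ad" for i, c in enumerate(seq) if c == "L")

    def test_frame_invariant_to_prepending_seven(self):
        from consfold.funcsite import HelixAnnotation
        seq = self.ideal_heptad()
        longer = "LSSLSSS" + seq
        h1 = HelixAnnotation(1, len(seq), 0.5, [True] * len(seq))
        h2 = HelixAnnotation(8, len(longer), 0.5, [True] * len(seq))
        f1 = detect_heptad_repeats(seq, [h1])[0]["frame"]
        f2 = detect_heptad_repeats(longer, [h2])[0]["frame"]
        assert f1 == f2

    def test_short_helix_undefined(self):
        from consfold.funcsite import HelixAnnotation
        helix = HelixAnnotation(1, 10, 0.5, [True] * 10)
        assert detect_heptad_repeats("LSSLSSSLSS", [helix]) == [None]

    def test_random_sequence_margin_near_null(self, rng):
        from consfold.funcsite import HelixAnnotation
        seq = self.ideal_heptad()
        letters = list(seq)
        rng.shuffle(letters)
        shuffled = "".join(letters)
        helix = HelixAnnotation(1, len(seq), 0.5, [True] * len(seq))
        margin = detect_heptad_repeats(shuffled, [helix])[0]["margin"]
        null = []
        for _ in range(300):
            rng.shuffle(letters)
            null.append(detect_heptad_repeats("".join(letters),
                                              [helix])[0]["margin"])
        ideal_margin = detect_heptad_repeats(seq, [helix])[0]["margin"]
        # the shuffled margin behaves like the null; the ideal one exceeds
        # almost the entire null distribution
        assert margin <= np.quantile(null, 0.99)
        assert ideal_margin > np.quantile(null, 0.99)


def test_fasta_round_trip(tmp_path):
    seq = pdcd10_sequence()
    p = tmp_path / "out.fasta"
    write_fasta(seq, p)
    back = read_fasta(p)
    assert back.residues == seq.residues
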
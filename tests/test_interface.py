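"""Rigid pose alignment and coarse interface scoring."""

import math

import numpy as np
import pytest

from abtriage.errors import AlignmentError
from abtriage.interface import (ComplexPose, EpitopeMap, align_onto_reference,
                                c_score, epitope_overlap, extract_interface,
                                ir_score, pcc_score, rank_candidates)
from abtriage.pipelines import prepare_structure
from abtriage.surface import (Centroid, CoarseStructure, PatchThresholds,
                              Residue, reference_centroid_values,
                              thresholds_from_reference)
from abtriage.synth import generate_pose_scenario


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


@pytest.fixture(scope="module")
def scenario():
    sc = generate_pose_scenario(seed=71)
    prepare_structure(sc.antigen, n_centroids=45, seed=0)
    prepare_structure(sc.reference_antibody, n_centroids=60, seed=0)
    for st in sc.candidates.values():
        prepare_structure(st, n_centroids=60, seed=0)
    pool = reference_centroid_values([sc.reference_antibody, sc.antigen]
                                     + list(sc.candidates.values()))
    thresholds = thresholds_from_reference(pool)
    pose = ComplexPose(antibody=sc.reference_antibody, target=sc.antigen,
                       target_id="AG")
    return sc, pose, thresholds


def centroid_structure(specs):
    """(position, charge, hydrophobicity) triples -> minimal CoarseStructure."""
    residues = [Residue("A", i + 1, "S", tuple(p)) for i, (p, _, _) in enumerate(specs)]
    st = CoarseStructure(residues)
    st.rsa = np.ones(len(residues))
    st.centroids = [Centroid(i, np.asarray(p, dtype=float), [i],
                             hydrophobicity=h, charge=q, potential=0.0,
                             curvature=0.0)
                    for i, (p, q, h) in enumerate(specs)]
    return st


NEUTRAL_THRESHOLDS = PatchThresholds(
    moderate={"hydrophobicity": 1.0, "charge": 1.0, "potential": 1.0,
              "curvature": 1.0},
    intense={"hydrophobicity": 2.0, "charge": 2.0, "potential": 2.0,
             "curvature": 2.0})


class TestAlignment:
    def test_self_alignment_identity(self, scenario):
        sc, pose, _ = scenario
        aligned = align_onto_reference(sc.reference_antibody, pose)
        assert aligned.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(aligned.rotation, np.eye(3), atol=1e-9)

    def test_planted_rotation_recovered(self, scenario):
        sc, pose, _ = scenario
        rot = rotation_matrix([1.0, 2.0, 0.5], 1.1)
        shift = np.array([5.0, -3.0, 8.0])
        moved = sc.reference_antibody.transformed(rot, shift)
        aligned = align_onto_reference(moved, pose)
        assert aligned.rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(aligned.rotation @ rot, np.eye(3), atol=1e-8)
        assert np.linalg.det(aligned.rotation) == pytest.approx(1.0)

    def test_perturbed_coordinates_rmsd_band(self, scenario):
        """0.5 A RMS displacement jitter: framework RMSD stays in [0.3, 0.8] A."""
        sc, pose, _ = scenario
        coords = sc.reference_antibody.coords
        sigma = 0.5 / math.sqrt(3.0)  # per-component sd for 0.5 A displacement RMS
        for trial in range(20):
            rng = np.random.default_rng(500 + trial)
            jittered = CoarseStructure(
                [Residue(r.chain, r.index, r.restype, tuple(c))
                 for r, c in zip(sc.reference_antibody.residues,
                                 coords + rng.normal(0, sigma, coords.shape))])
            aligned = align_onto_reference(jittered, pose)
            assert 0.3 <= aligned.rmsd <= 0.8

    def test_too_few_alignable_positions(self, scenario):
        _, pose, _ = scenario
        stub = CoarseStructure([Residue("H", i + 1, "A", (float(i), 0.0, 0.0))
                                for i in range(10)])
        with pytest.raises(AlignmentError):
            align_onto_reference(stub, pose)


class TestInterfaceExtraction:
    def test_translated_far_away_no_contacts(self, scenario):
        sc, pose, _ = scenario
        far = sc.reference_antibody.transformed(np.eye(3),
                                                np.array([100.0, 0.0, 0.0]))
        pairs, emap = extract_interface(
            ComplexPose(antibody=far, target=sc.antigen, target_id="AG"))
        assert pairs == [] and emap.epitope == frozenset()

    def test_two_single_centroids_within_cutoff(self):
        a = centroid_structure([((0.0, 0.0, 0.0), 0.0, 0.0)])
        b = centroid_structure([((5.0, 0.0, 0.0), 0.0, 0.0)])
        pairs, emap = extract_interface(
            ComplexPose(antibody=a, target=b, target_id="t"), cutoff=8.0)
        assert pairs == [(0, 0)]
        assert emap.epitope == frozenset({("A", 1)})

    def test_grid_against_brute_force(self):
        rng = np.random.default_rng(8)
        a = centroid_structure([(p, 0.0, 0.0)
                                for p in rng.uniform(0, 20, size=(9, 3))])
        b = centroid_structure([(p, 0.0, 0.0)
                                for p in rng.uniform(0, 20, size=(9, 3))])
        pose = ComplexPose(antibody=a, target=b, target_id="t")
        pairs, _ = extract_interface(pose, cutoff=8.0)
        apos = np.array([c.position for c in a.centroids])
        bpos = np.array([c.position for c in b.centroids])
        expected = {(i, j) for i in range(9) for j in range(9)
                    if np.linalg.norm(apos[i] - bpos[j]) <= 8.0}
        assert set(pairs) == expected
        assert ir_score(pairs) == len(expected)


class TestPcc:
    def test_all_opposite_charges(self):
        a = centroid_structure([((0, 0, 0), 1.0, 0.0), ((0, 5, 0), 2.0, 0.0)])
        b = centroid_structure([((5, 0, 0), -1.0, 0.0), ((5, 5, 0), -1.0, 0.0)])
        pose = ComplexPose(antibody=a, target=b, target_id="t")
        pairs, _ = extract_interface(pose, cutoff=6.0)
        assert pcc_score(pose, pairs, NEUTRAL_THRESHOLDS) == 1.0

    def test_all_same_sign(self):
        a = centroid_structure([((0, 0, 0), 1.0, 0.0)])
        b = centroid_structure([((5, 0, 0), 2.0, 0.0)])
        pose = ComplexPose(antibody=a, target=b, target_id="t")
        pairs, _ = extract_interface(pose, cutoff=6.0)
        assert pcc_score(pose, pairs, NEUTRAL_THRESHOLDS) == -1.0

    def test_mixed_hand_built_interface(self):
        # 4 facing pairs: 2 hydrophobic-hydrophobic, 1 opposite, 1 neutral
        a = centroid_structure([((0, 0, 0), 0.0, 3.0), ((0, 9, 0), 0.0, 3.0),
                                ((0, 18, 0), 1.0, 0.0), ((0, 27, 0), 0.0, 0.0)])
        b = centroid_structure([((5, 0, 0), 0.0, 3.0), ((5, 9, 0), 0.0, 3.0),
                                ((5, 18, 0), -1.0, 0.0), ((5, 27, 0), 0.0, 0.0)])
        pose = ComplexPose(antibody=a, target=b, target_id="t")
        pairs, _ = extract_interface(pose, cutoff=6.0)
        assert len(pairs) == 4
        assert pcc_score(pose, pairs, NEUTRAL_THRESHOLDS) == pytest.approx(0.75)

    def test_symmetric_under_label_swap(self, scenario):
        sc, pose, thresholds = scenario
        aligned = align_onto_reference(sc.candidates["true_binder"], pose)
        pairs, _ = extract_interface(aligned)
        swapped = ComplexPose(antibody=aligned.target, target=aligned.antibody,
                              target_id="x")
        swapped_pairs = [(j, i) for i, j in pairs]
        assert pcc_score(aligned, pairs, thresholds) == pytest.approx(
            pcc_score(swapped, swapped_pairs, thresholds))

    def test_zero_pairs_undefined(self):
        a = centroid_structure([((0, 0, 0), 0.0, 0.0)])
        pose = ComplexPose(antibody=a, target=a, target_id="t")
        with pytest.raises(ValueError):
            pcc_score(pose, [], NEUTRAL_THRESHOLDS)


class TestCScore:
    def test_extremes(self):
        c = c_score([(1.0, 10.0), (0.0, 2.0), (-1.0, 0.0)])
        assert c[0] == 1.0 and c[2] == 0.0

    def test_hand_three_candidate_panel(self):
        c = c_score([(0.5, 4.0), (1.0, 0.0), (0.0, 8.0)])
        # normalised pcc: 0.5, 1, 0; normalised ir: 0.5, 0, 1
        assert c == pytest.approx([0.5, 0.5, 0.5])

    def test_degenerate_panel_convention(self):
        assert c_score([(0.3, 5.0), (0.3, 5.0)]) == pytest.approx([0.5, 0.5])

    def test_order_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(11)
        panel = [(float(p), float(i)) for p, i in
                 zip(rng.uniform(-1, 1, 8), rng.integers(0, 30, 8))]
        base = np.argsort(c_score(panel))
        rescaled = [(3.0 * p + 7.0, 2.5 * i + 1.0) for p, i in panel]
        assert np.array_equal(np.argsort(c_score(rescaled)), base)

    def test_panel_too_small(self):
        with pytest.raises(ValueError):
            c_score([(0.5, 3.0)])


class TestRanking:
    def test_true_binder_ranks_first(self, scenario):
        sc, pose, thresholds = scenario
        ranked, unalignable = rank_candidates(list(sc.candidates.items()),
                                              pose, thresholds)
        assert unalignable == []
        assert ranked[0].id == "true_binder"
        assert ranked[-1].id in ("decoy_retracted", "decoy_faces_away")

    def test_reference_in_own_panel_ranks_first(self, scenario):
        sc, pose, thresholds = scenario
        panel = [("reference", sc.reference_antibody)] + [
            (k, v) for k, v in sc.candidates.items() if k != "true_binder"]
        ranked, _ = rank_candidates(panel, pose, thresholds)
        assert ranked[0].id == "reference"

    def test_two_entry_panel(self, scenario):
        sc, pose, thresholds = scenario
        ranked, _ = rank_candidates(
            [("reference", sc.reference_antibody),
             ("true", sc.candidates["true_binder"])], pose, thresholds)
        assert len(ranked) == 2
        assert all(np.isfinite(r.c) for r in ranked)

    def test_empty_panel(self, scenario):
        _, pose, thresholds = scenario
        with pytest.raises(ValueError):
            rank_candidates([], pose, thresholds)


class TestEpitopeOverlap:
    def test_identical_maps(self):
        e = EpitopeMap("T", frozenset({("T", i) for i in range(5)}), frozenset())
        overlap, competes = epitope_overlap(e, e)
        assert overlap == 1.0 and competes

    def test_disjoint_maps(self):
        a = EpitopeMap("T", frozenset({("T", 1)}), frozenset())
        b = EpitopeMap("T", frozenset({("T", 2)}), frozenset())
        overlap, competes = epitope_overlap(a, b)
        assert overlap == 0.0 and not competes

    def test_hand_jaccard(self):
        a = EpitopeMap("T", frozenset({("T", i) for i in range(1, 11)}), frozenset())
        b = EpitopeMap("T", frozenset({("T", i) for i in range(6, 16)}), frozenset())
        overlap, competes = epitope_overlap(a, b)
        assert overlap == pytest.approx(5 / 15)
        assert competes

    def test_mismatched_targets(self):
        a = EpitopeMap("T1", frozenset(), frozenset())
        b = EpitopeMap("T2", frozenset(), frozenset())
        with pytest.raises(ValueError):
            epitope_overlap(a, b)
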
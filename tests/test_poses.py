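"""Pose validity, RMSD, clustering, fingerprints and Kd conversion."""

import math

import numpy as np
import pytest

import melanostab as ms
from melanostab.poses import ClusteringParams, Pose, heavy_atom_rmsd, kabsch_superpose
from melanostab.stability import GAS_CONSTANT_KCAL
from melanostab.structure import Atom, Residue, Structure

RT = GAS_CONSTANT_KCAL * 298.15


def point_pose(pose_id, xyz, energy=6.0):
    return Pose(pose_id, [Atom("C1", "C", xyz, 1)], binding_energy=energy)


class TestValidity:
    def test_boundary_is_strict_at_four_angstroms(self, zinc_site):
        at_boundary = ms.place_ligand_pose(zinc_site, oxygen_zn_distance=4.0)
        just_inside = ms.place_ligand_pose(zinc_site, oxygen_zn_distance=3.9)
        assert not ms.pose_validity(at_boundary, zinc_site,
                                    max_zn_distance=4.0).valid
        assert ms.pose_validity(just_inside, zinc_site, max_zn_distance=4.0).valid

    def test_far_pose_reports_distance_reason(self, zinc_site):
        pose = ms.place_ligand_pose(zinc_site, oxygen_zn_distance=8.0)
        verdict = ms.pose_validity(pose, zinc_site)
        assert (verdict.valid, verdict.reason) == (False, "distance")
        assert verdict.min_oxygen_zn > 4.0

    def test_receptor_without_zinc_is_a_domain_error(self, zinc_site, oca8_mini):
        pose = ms.place_ligand_pose(zinc_site, oxygen_zn_distance=2.4)
        with pytest.raises(ValueError, match="no zinc"):
            ms.pose_validity(pose, oca8_mini)

    def test_pose_without_flagged_oxygens_is_a_domain_error(self, zinc_site):
        bare = point_pose("p", [0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="oxygens"):
            ms.pose_validity(bare, zinc_site)

    def test_invariant_under_joint_rigid_motion(self, zinc_site):
        pose = ms.place_ligand_pose(zinc_site, oxygen_zn_distance=2.4)
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0],
                        [0, 0, 1.0]])
        shift = np.array([11.0, -4.0, 2.5])
        moved_receptor = zinc_site.copy()
        moved_receptor.set_coords(zinc_site.coords() @ rot.T + shift)
        moved_pose = Pose(pose.pose_id,
                          [Atom(a.name, a.element, rot @ a.coords + shift, a.serial)
                           for a in pose.ligand_atoms],
                          pose.binding_energy, pose.ring_oxygens, pose.ring_atoms)
        before = ms.pose_validity(pose, zinc_site)
        after = ms.pose_validity(moved_pose, moved_receptor)
        assert (before.valid, before.reason) == (after.valid, after.reason)
        assert before.min_oxygen_zn == pytest.approx(after.min_oxygen_zn, abs=1e-9)


class TestRmsd:
    def test_identical_poses_are_zero(self, zinc_site):
        pose = ms.place_ligand_pose(zinc_site, oxygen_zn_distance=2.4)
        assert ms.heavy_atom_rmsd(pose, pose) == 0.0

    def test_rigid_translation_gives_its_norm(self, zinc_site):
        pose = ms.place_ligand_pose(zinc_site, oxygen_zn_distance=2.4)
        moved = pose.translated([3.0, 4.0, 0.0])
        assert ms.heavy_atom_rmsd(pose, moved) == pytest.approx(5.0)

    def test_matches_per_atom_sum_oracle(self):
        rng = np.random.default_rng(9)
        xa, xb = rng.uniform(-5, 5, (10, 3)), rng.uniform(-5, 5, (10, 3))
        a = Pose("a", [Atom(f"C{i}", "C", xa[i], i + 1) for i in range(10)], 1.0)
        b = Pose("b", [Atom(f"C{i}", "C", xb[i], i + 1) for i in range(10)], 1.0)
        expected = math.sqrt(sum(
            sum((xa[i][k] - xb[i][k]) ** 2 for k in range(3)) for i in range(10)) / 10)
        assert ms.heavy_atom_rmsd(a, b) == pytest.approx(expected, abs=1e-9)

    def test_hydrogens_are_excluded(self):
        a = Pose("a", [Atom("C1", "C", [0, 0, 0], 1), Atom("H1", "H", [9, 9, 9], 2)], 1.0)
        b = Pose("b", [Atom("C1", "C", [0, 0, 0], 1), Atom("H1", "H", [0, 0, 0], 2)], 1.0)
        assert ms.heavy_atom_rmsd(a, b) == 0.0

    def test_atom_mismatch_raises(self):
        a = Pose("a", [Atom("C1", "C", [0, 0, 0], 1)], 1.0)
        b = Pose("b", [Atom("N1", "N", [0, 0, 0], 1)], 1.0)
        with pytest.raises(ValueError, match="mismatch"):
            ms.heavy_atom_rmsd(a, b)

    def test_kabsch_recovers_a_rigid_motion(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(-4, 4, (12, 3))
        theta = 1.1
        rot = np.array([[math.cos(theta), 0, math.sin(theta)],
                        [0, 1, 0],
                        [-math.sin(theta), 0, math.cos(theta)]])
        mobile = ref @ rot.T + np.array([2.0, -7.0, 1.0])
        _, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)


class TestClustering:
    def test_single_pose_single_cluster(self):
        clusters = ms.cluster_poses([point_pose("p1", [0, 0, 0])])
        assert len(clusters) == 1

    def test_two_distant_poses_two_clusters(self):
        clusters = ms.cluster_poses([point_pose("p1", [0, 0, 0], 7.0),
                                     point_pose("p2", [6.0, 0, 0], 6.0)],
                                    ClusteringParams(5.0))
        assert len(clusters) == 2

    def test_hand_enumerated_greedy_steps(self):
        """Mutual distances (1, 6, 6.5): best pose seeds, second joins, third founds."""
        p1 = point_pose("p1", [0.0, 0.0, 0.0], 8.0)
        p2 = point_pose("p2", [1.0, 0.0, 0.0], 7.0)
        p3 = point_pose("p3", [-2.625, 5.3953, 0.0], 6.0)
        assert ms.heavy_atom_rmsd(p1, p3) == pytest.approx(6.0, abs=1e-3)
        assert ms.heavy_atom_rmsd(p2, p3) == pytest.approx(6.5, abs=1e-3)
        clusters = ms.cluster_poses([p1, p2, p3], ClusteringParams(5.0))
        assert len(clusters) == 2
        assert clusters[0].representative.pose_id == "p1"
        assert [m.pose_id for m in clusters[0].members] == ["p1", "p2"]
        assert clusters[1].representative.pose_id == "p3"

    def test_representatives_pairwise_apart_and_order_independent(self):
        rng = np.random.default_rng(17)
        poses = [point_pose(f"p{i:02d}", rng.uniform(0, 20, 3),
                            energy=float(rng.uniform(4, 8))) for i in range(25)]
        clusters = ms.cluster_poses(poses, ClusteringParams(5.0))
        reps = [c.representative for c in clusters]
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                assert ms.heavy_atom_rmsd(reps[i], reps[j]) >= 5.0
        shuffled = list(reversed(poses))
        again = ms.cluster_poses(shuffled, ClusteringParams(5.0))
        assert [c.representative.pose_id for c in again] \
            == [c.representative.pose_id for c in clusters]
        assert sum(len(c.members) for c in clusters) == len(poses)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            ms.cluster_poses([])


class TestFingerprint:
    @staticmethod
    def receptor_and_ligand():
        """Hand-built contacts: one H-bond, one hydrophobic, no pi-pi."""
        asn = Residue("A", 370, "ASN", atoms=[
            Atom("N", "N", [0, 0, 10], 1), Atom("CA", "C", [0, 0, 9], 2),
            Atom("C", "C", [1, 0, 9], 3),
            Atom("OD1", "O", [0.0, 0.0, 2.9], 4)])
        his = Residue("A", 373, "HIS", atoms=[
            Atom("N", "N", [8, 0, 10], 5), Atom("CA", "C", [8, 0, 9], 6),
            Atom("C", "C", [9, 0, 9], 7),
            Atom("CD2", "C", [5.0, 0.0, 0.0], 8)])
        receptor = Structure([asn, his])
        # ligand: hydroxyl O (with H at ~160 deg toward the acceptor) + ring C
        o_pos = np.array([0.0, 0.0, 0.0])
        h_pos = o_pos + 0.97 * np.array([math.sin(math.radians(13)), 0.0,
                                         math.cos(math.radians(13))])
        ligand = Pose("lig", [
            Atom("O1", "O", o_pos, 10),
            Atom("HO1", "H", h_pos, 11),
            Atom("C6", "C", [8.8, 0.0, 0.0], 12),
        ], binding_energy=6.0, ring_oxygens=("O1",), ring_atoms=())
        return receptor, ligand

    def test_hbond_hydrophobic_and_contacts(self):
        receptor, ligand = self.receptor_and_ligand()
        fp = ms.interaction_fingerprint(ligand, receptor)
        assert len(fp.hbonds) == 1
        ref, lig_atom, dist, angle = fp.hbonds[0]
        assert ref == "OD1/N370"
        assert lig_atom == "O1"
        assert dist == pytest.approx(2.9)
        assert angle == pytest.approx(160.0, abs=1.0)
        assert ("CD2/H373", "C6", pytest.approx(3.8)) in fp.hydrophobic
        assert fp.pipi == []  # His ring incomplete / too far
        # every H-bond partner residue is also a generic contact
        assert {"N370", "H373"} <= fp.contacting_residues

    def test_bent_hydrogen_suppresses_the_bond(self):
        receptor, ligand = self.receptor_and_ligand()
        # move the hydrogen to point away: D-H...A angle collapses below 120
        ligand.ligand_atoms[1].coords = np.array([0.0, 0.0, -0.97])
        fp = ms.interaction_fingerprint(ligand, receptor)
        assert fp.hbonds == []

    def test_distant_ring_gives_no_pipi(self, zinc_site):
        pose = ms.place_ligand_pose(zinc_site, oxygen_zn_distance=8.0)
        fp = ms.interaction_fingerprint(pose, zinc_site)
        assert fp.pipi == []

    def test_near_pose_stacks_with_the_his_shell(self, zinc_site):
        pose = ms.place_ligand_pose(zinc_site, oxygen_zn_distance=2.4)
        fp = ms.interaction_fingerprint(pose, zinc_site)
        assert fp.contacting_residues  # the coordination shell is in reach


class TestKd:
    def test_standard_state_identity(self):
        assert ms.kd_from_energy(0.0) == pytest.approx(1.0)

    def test_printed_mean_energy_maps_to_micromolar(self):
        kd = ms.kd_from_energy(6.32, 298.15)
        assert kd == pytest.approx(2.33e-5, rel=1e-3)

    def test_rt_ln_ten_divides_kd_by_ten(self):
        step = RT * math.log(10.0)
        ratio = ms.kd_from_energy(6.0) / ms.kd_from_energy(6.0 + step)
        assert ratio == pytest.approx(10.0, rel=1e-9)

    def test_round_trip_with_the_log_relation(self):
        for kd in (1e-9, 2.33e-5, 0.5, 1.0):
            energy = -RT * math.log(kd)
            assert ms.kd_from_energy(energy) == pytest.approx(kd, rel=1e-12)

    def test_strictly_decreasing_in_energy(self):
        energies = np.linspace(-2, 10, 25)
        kds = [ms.kd_from_energy(e) for e in energies]
        assert all(a > b for a, b in zip(kds, kds[1:]))


class TestZnContactReport:
    def test_constructed_pose_distance(self, zinc_site):
        pose = ms.place_ligand_pose(zinc_site, oxygen_zn_distance=2.4)
        report = ms.zn_contact_report(pose, zinc_site)
        assert report.min_distance == pytest.approx(2.40, abs=0.05)

    def test_six_coordinating_histidines(self, zinc_site):
        pose = ms.place_ligand_pose(zinc_site, oxygen_zn_distance=2.4)
        report = ms.zn_contact_report(pose, zinc_site)
        assert sum(len(v) for v in report.coordinating_his.values()) == 6

    def test_distant_pose_fails_validity_with_large_distances(self, zinc_site):
        pose = ms.place_ligand_pose(zinc_site, oxygen_zn_distance=2.4)
        far = pose.translated([0.0, 0.0, 20.0])
        report = ms.zn_contact_report(far, zinc_site)
        cols = [c for c in report.oxygen_distances.columns if c != "oxygen"]
        assert (report.oxygen_distances[cols] > 4.0).all().all()
        assert not ms.pose_validity(far, zinc_site).valid


class TestPoseIO:
    def test_round_trip(self, zinc_site, tmp_path):
        poses = [ms.place_ligand_pose(zinc_site, oxygen_zn_distance=d,
                                      pose_id=f"p{i}", binding_energy=6.0 + i)
                 for i, d in enumerate((2.2, 3.0, 5.0))]
        pdb, tsv = tmp_path / "poses.pdb", tmp_path / "poses.tsv"
        ms.write_poses(poses, pdb, tsv)
        back = ms.read_poses(pdb, tsv)
        assert [p.pose_id for p in back] == ["p0", "p1", "p2"]
        for orig, re_read in zip(poses, back):
            assert re_read.binding_energy == orig.binding_energy
            assert ms.heavy_atom_rmsd(orig, re_read) < 1e-3
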
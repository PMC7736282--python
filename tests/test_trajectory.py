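"""Hydrogen-bond detection, occurrence networks, distances and rigidity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from conftest import make_trajectory
from mtasekit.trajectory import (
    HBondCriteria,
    atom_distance_series,
    detect_hbonds,
    hbond_angle_deg,
    hbond_count_series,
    occurrence_network,
    read_trajectory,
    sidechain_rmsd_series,
    superposed_rmsd,
)


def brute_force_hbonds(pos, donors, acceptors, criteria):
    """All-triples oracle: check every (donor, hydrogen, acceptor) directly."""
    out = []
    for d, h in donors:
        for a in acceptors:
            if a in (d, h):
                continue
            if np.linalg.norm(pos[a] - pos[d]) > criteria.max_distance:
                continue
            if hbond_angle_deg(pos[d], pos[h], pos[a]) <= criteria.max_angle:
                out.append((d, h, a))
    return out


class TestDetectHbonds:
    def test_ideal_geometry_detected(self):
        # O-H...O, d = 0.29 nm, angle 10 deg
        ang = np.radians(10.0)
        pos = np.array(
            [[0, 0, 0], 0.097 * np.array([np.cos(ang), np.sin(ang), 0]),
             [0.29, 0, 0]]
        )
        bonds = detect_hbonds(pos, [(0, 1)], [2])
        assert bonds == [(0, 1, 2)]

    def test_distance_cutoff(self):
        pos = np.array([[0, 0, 0], [0.097, 0, 0], [0.40, 0, 0]])
        assert detect_hbonds(pos, [(0, 1)], [2]) == []

    def test_angle_cutoff(self):
        ang = np.radians(45.0)
        pos = np.array(
            [[0, 0, 0], 0.097 * np.array([np.cos(ang), np.sin(ang), 0]),
             [0.29, 0, 0]]
        )
        assert detect_hbonds(pos, [(0, 1)], [2]) == []

    def test_empty_selection_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert detect_hbonds(np.zeros((3, 3)), [], [1]) == []

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        pos = rng.uniform(0, 1.5, (n, 3))
        heavies = rng.choice(n, 20, replace=False)
        donors = [(int(d), int(h)) for d, h in zip(heavies[:10], heavies[10:])]
        acceptors = [int(a) for a in rng.choice(n, 15, replace=False)]
        crit = HBondCriteria(
            max_distance=float(rng.uniform(0.2, 0.6)),
            max_angle=float(rng.uniform(10, 90)),
        )
        assert detect_hbonds(pos, donors, acceptors, crit) == brute_force_hbonds(
            pos, donors, acceptors, crit
        )

    def test_saturation_limit(self):
        # with the distance cutoff at infinity and the angle cutoff at its
        # 90 deg maximum, every donor-acceptor pair whose acceptor lies in
        # the hydrogen-side hemisphere registers
        rng = np.random.default_rng(0)
        donors = [(0, 1), (2, 3)]
        pos = np.zeros((20, 3))
        pos[0] = [0, 0, 0]
        pos[1] = [0.097, 0, 0]
        pos[2] = [0, 0.4, 0]
        pos[3] = [0.097, 0.4, 0]
        acceptors = list(range(4, 20))
        for a in acceptors:  # strictly positive x: inside both hemispheres
            pos[a] = [rng.uniform(0.2, 3.0), rng.uniform(-1, 1), rng.uniform(-1, 1)]
        crit = HBondCriteria(max_distance=1e6, max_angle=90.0)
        bonds = detect_hbonds(pos, donors, acceptors, crit)
        assert len(bonds) == len(donors) * len(acceptors)


class TestOccurrenceNetwork:
    def test_planted_occupancy(self, tmp_path):
        traj, _, truth = make_trajectory(
            tmp_path, n_residues=3, n_frames=100,
            hbond_schedule={(1, 2): 0.3}, seed=11,
        )
        net = occurrence_network([traj], {1, 2, 3})
        assert net.graph["frames_analysed"] == 100
        (edge,) = list(net.edges(data=True))
        assert edge[2]["count"] == len(truth["schedule"][(1, 2)])
        assert edge[2]["occupancy"] == truth["occupancy"][(1, 2)]

    def test_never_bonded_pair_absent(self, tmp_path):
        traj, _, _ = make_trajectory(
            tmp_path, n_residues=3, n_frames=20,
            hbond_schedule={(1, 2): 1.0}, seed=1,
        )
        net = occurrence_network([traj], {1, 2, 3})
        assert not net.has_edge("SER2", "SER3")
        assert not net.has_edge("SER1", "SER3")

    def test_replicate_pooling_arithmetic(self, tmp_path):
        t1, _, _ = make_trajectory(
            tmp_path, name="a", replicate="r1", n_residues=2, n_frames=50,
            hbond_schedule={(1, 2): 0.4}, seed=2,
        )
        t2, _, _ = make_trajectory(
            tmp_path, name="b", replicate="r2", n_residues=2, n_frames=50,
            hbond_schedule={(1, 2): 0.2}, seed=3,
        )
        net = occurrence_network([t1, t2], {1, 2})
        (edge,) = list(net.edges(data=True))
        assert net.graph["frames_analysed"] == 100
        assert edge[2]["count"] == 30
        assert edge[2]["occupancy"] == pytest.approx(0.30)
        assert edge[2]["per_replicate"] == {"r1": 20, "r2": 10}


class TestHbondCountSeries:
    def test_constant_bond_median(self, tmp_path):
        traj, _, _ = make_trajectory(
            tmp_path, n_residues=2, n_frames=30,
            hbond_schedule={(1, 2): 1.0}, seed=4,
        )
        series = hbond_count_series([traj], 1, 2)
        assert series["median"] == 1.0

    def test_no_contact_median_zero(self, tmp_path):
        traj, _, _ = make_trajectory(tmp_path, n_residues=2, n_frames=10, seed=5)
        assert hbond_count_series([traj], 1, 2)["median"] == 0.0

    def test_alternating_frames_median_half(self, tmp_path):
        traj, _, _ = make_trajectory(
            tmp_path, n_residues=2, n_frames=10,
            hbond_schedule={(1, 2): [0, 2, 4, 6, 8]}, seed=6,
        )
        assert hbond_count_series([traj], 1, 2)["median"] == 0.5


class TestDistanceSeries:
    def test_static_distance(self, tmp_path):
        traj, _, _ = make_trajectory(tmp_path, n_residues=2, n_frames=5, seed=7)
        ds = atom_distance_series(
            traj, "resid 1 and name OG", "resid 2 and name OG"
        )
        assert ds.distances_nm == pytest.approx(np.full(5, 1.2), abs=1e-6)

    def test_symmetry_in_arguments(self, tmp_path):
        traj, _, _ = make_trajectory(
            tmp_path, n_residues=2, n_frames=10, sigma_nm=0.05, seed=8
        )
        a, b = "resid 1 and name OG", "resid 2 and name OG"
        d1 = atom_distance_series(traj, a, b).distances_nm
        d2 = atom_distance_series(traj, b, a).distances_nm
        assert d1 == pytest.approx(d2)

    def test_ambiguous_selector_errors(self, tmp_path):
        traj, _, _ = make_trajectory(tmp_path, n_residues=2, n_frames=3, seed=9)
        with pytest.raises(ValueError, match="exactly one"):
            atom_distance_series(traj, "name OG", "resid 2 and name OG")

    def test_same_atom_twice_errors(self, tmp_path):
        traj, _, _ = make_trajectory(tmp_path, n_residues=2, n_frames=3, seed=9)
        sel = "resid 1 and name OG"
        with pytest.raises(ValueError, match="same atom"):
            atom_distance_series(traj, sel, sel)


class TestSidechainRMSD:
    def test_identical_frames_zero(self, tmp_path):
        traj, ref, _ = make_trajectory(
            tmp_path, n_residues=3, n_frames=5, sigma_nm=0.0, seed=10
        )
        rs = sidechain_rmsd_series([traj], ref, [1, 2, 3])
        assert rs.rmsd_nm == pytest.approx(np.zeros(5), abs=1e-6)

    def test_rigid_motion_invariance_exact(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0, 5, (30, 3))
        fit_idx = np.arange(0, 20)
        rmsd_idx = np.arange(20, 30)
        for seed in range(10):
            rot = Rotation.random(random_state=seed).as_matrix()
            shift = rng.uniform(-10, 10, 3)
            moved = ref @ rot.T + shift
            assert superposed_rmsd(moved, ref, fit_idx, rmsd_idx) < 1e-10

    def test_fluctuation_matches_closed_form(self, tmp_path):
        sigma = 0.05
        traj, ref, _ = make_trajectory(
            tmp_path, n_residues=3, n_frames=1000, sigma_nm=sigma, seed=12
        )
        rs = sidechain_rmsd_series([traj], ref, [1, 2, 3])
        from scipy.stats import chi2

        m = 6  # side-chain heavy atoms: CB + OG per residue
        expected = sigma * np.sqrt(chi2.ppf(0.5, 3 * m) / m)
        assert rs.median == pytest.approx(expected, rel=0.05)

    def test_monotone_in_sigma(self, tmp_path):
        medians = []
        for i, sigma in enumerate([0.01, 0.03, 0.06, 0.1]):
            traj, ref, _ = make_trajectory(
                tmp_path, name=f"s{i}", n_residues=3, n_frames=200,
                sigma_nm=sigma, seed=13 + i,
            )
            medians.append(sidechain_rmsd_series([traj], ref, [1, 2, 3]).median)
        assert medians == sorted(medians)

    def test_per_replicate_medians(self, tmp_path):
        t1, ref, _ = make_trajectory(
            tmp_path, name="p1", replicate="r1", n_residues=2, n_frames=50,
            sigma_nm=0.02, seed=20,
        )
        t2, _, _ = make_trajectory(
            tmp_path, name="p2", replicate="r2", n_residues=2, n_frames=50,
            sigma_nm=0.02, seed=21,
        )
        rs = sidechain_rmsd_series([t1, t2], ref, [1, 2])
        assert set(rs.per_replicate_median) == {"r1", "r2"}
        assert len(rs.rmsd_nm) == 100


class TestReadTrajectory:
    def test_frame_count(self, tmp_path):
        traj, _, truth = make_trajectory(tmp_path, n_residues=2, n_frames=3, seed=0)
        assert traj.n_frames == truth["n_frames"]

    def test_angstrom_to_nm_conversion(self, tmp_path):
        traj, _, _ = make_trajectory(tmp_path, n_residues=2, n_frames=2, seed=0)
        # residues are 12 A apart in the PDB; the API reports 1.2 nm
        ds = atom_distance_series(
            traj, "resid 1 and name CA", "resid 2 and name CA"
        )
        assert ds.distances_nm[0] == pytest.approx(1.2, abs=1e-6)
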
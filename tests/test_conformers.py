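"""Torsion geometry, IN/OUT classification, rotamer maps and H-bond occupancy."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from dynazyme import conformers as cf, synthetic as syn

IN_OUT_SPEC = cf.DihedralSpec(
    atoms=((229, "CA"), (400, "C1"), (400, "N1"), (287, "CA")), label="in_out"
)


class TestDihedral:
    def test_planar_trans(self):
        assert cf.dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == pytest.approx(180.0)

    def test_planar_cis(self):
        assert cf.dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            pts = rng.normal(size=(4, 3))
            try:
                ref = cf.dihedral(*pts)
            except ValueError:
                continue
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            t = rng.normal(size=3)
            moved = pts @ R.T + t
            assert cf.dihedral(*moved) == pytest.approx(ref, abs=1e-9)

    def test_mirror_flips_sign(self):
        pts = np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1.5, 1, 0.8)])
        ref = cf.dihedral(*pts)
        mirrored = pts * np.array([1, 1, -1])
        assert cf.dihedral(*mirrored) == pytest.approx(-ref, abs=1e-9)

    def test_collinear_is_undefined(self):
        with pytest.raises(ValueError, match="torsion"):
            cf.dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestClassification:
    @pytest.mark.parametrize(
        "angle,state",
        [(90.0, "IN"), (-90.0, "OUT"), (180.0, "IN"), (-180.0, "IN"), (50.0, "OUT"),
         (50.5, "IN"), (540.0, "IN")],
    )
    def test_boundary_and_normalization(self, angle, state):
        # -180 normalizes to +180 (IN); the single boundary sits at 50 deg
        assert cf.classify_in_out(angle) == state

    def test_state_fractions_sum_exactly_100(self):
        labels = np.array([True, True, False, True, False])
        pct_in, pct_out = cf.state_fractions(labels)
        assert (pct_in, pct_out) == (60.0, 40.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = rng.random(rng.integers(1, 500)) < rng.random()
            pct_in, pct_out = cf.state_fractions(labels)
            assert pct_in + pct_out == 100.0

    def test_all_in(self):
        assert cf.state_fractions(np.ones(7, bool)) == (100.0, 0.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            cf.state_fractions(np.array([], bool))

    def test_planted_fraction_round_trip(self):
        gt = syn.TwoStateTrajGroundTruth(
            f_in_target=0.8, n_frames=100_000, transition_prob=0.25, seed=17
        )
        _, angles = syn.gen_two_state_angles(gt)
        series = cf.StateSeries.from_angles(angles)
        pct_in, pct_out = cf.state_fractions(series)
        assert pct_in == pytest.approx(80.0, abs=1.0)
        assert pct_out == pytest.approx(20.0, abs=1.0)

    def test_subsampling_stationary_series(self):
        gt = syn.TwoStateTrajGroundTruth(
            f_in_target=0.6, n_frames=50_000, transition_prob=0.5, seed=2
        )
        labels, _ = syn.gen_two_state_angles(gt)
        full, _ = cf.state_fractions(labels)
        sub, _ = cf.state_fractions(labels[::10])
        # binomial sampling bound (3 sigma) for the subsampled estimate
        n_sub = labels[::10].size
        bound = 300.0 * np.sqrt(0.6 * 0.4 / n_sub)
        assert abs(sub - full) < bound


class TestTrajectoryAnalysis:
    def test_dihedral_series_reproduces_embedded_angles(self):
        angles = np.array([-150.0, -30.0, 20.0, 70.0, 160.0])
        traj = syn.angles_to_trajectory(angles)
        np.testing.assert_allclose(cf.dihedral_series(traj, IN_OUT_SPEC), angles, atol=1e-9)

    def test_missing_atom_names_selector(self):
        traj = syn.angles_to_trajectory(np.array([10.0]))
        bad = cf.DihedralSpec(atoms=((1, "CA"), (400, "C1"), (400, "N1"), (287, "CA")))
        with pytest.raises(KeyError, match="CA"):
            cf.dihedral_series(traj, bad)

    def test_histogram_single_frame_and_normalization(self):
        traj = syn.angles_to_trajectory(np.array([42.0]))
        spec2 = cf.DihedralSpec(
            atoms=((287, "CA"), (400, "N1"), (400, "C1"), (229, "CA")), label="rev"
        )
        hist, _, _, n_modes = cf.chi_joint_distribution(traj, IN_OUT_SPEC, spec2)
        assert np.count_nonzero(hist) == 1
        assert hist.sum() == pytest.approx(1.0)
        assert n_modes == 1

    def test_three_mode_mixture_detected(self):
        # couple the two torsions so the joint has exactly 3 modes; modes sit
        # >= 60 deg apart and away from the +/-180 seam (connectivity does
        # not wrap there)
        rng = np.random.default_rng(5)
        which = rng.integers(0, 3, size=6000)
        modes1 = np.array([-120.0, 0.0, 120.0])
        modes2 = np.array([-100.0, 20.0, 140.0])
        a1 = cf.normalize_angle(modes1[which] + rng.normal(0, 10, 6000))
        a2 = cf.normalize_angle(modes2[which] + rng.normal(0, 10, 6000))
        t1 = syn.angles_to_trajectory(a1)
        t2 = syn.angles_to_trajectory(a2)
        traj = cf.Trajectory(
            topology=pd.concat(
                [t1.topology, t2.topology.assign(residue_index=[329, 500, 500, 387])],
                ignore_index=True,
            ),
            coords=np.concatenate([t1.coords, t2.coords + 50.0], axis=1),
        )
        spec_b = cf.DihedralSpec(
            atoms=((329, "CA"), (500, "C1"), (500, "N1"), (387, "CA")), label="b"
        )
        _, _, _, n_modes = cf.chi_joint_distribution(traj, IN_OUT_SPEC, spec_b, bins=36)
        assert n_modes == 3

    def test_angle_histogram_invariant_to_frame_order(self):
        angles = syn.gen_angle_mixture([-60.0, 80.0], 15.0, 2000, seed=9)
        traj = syn.angles_to_trajectory(angles)
        perm = np.random.default_rng(1).permutation(2000)
        shuffled = cf.Trajectory(topology=traj.topology, coords=traj.coords[perm])
        h1, *_ = cf.chi_joint_distribution(traj, IN_OUT_SPEC, _reverse_spec())
        h2, *_ = cf.chi_joint_distribution(shuffled, IN_OUT_SPEC, _reverse_spec())
        np.testing.assert_allclose(h1, h2)


def _reverse_spec():
    return cf.DihedralSpec(
        atoms=((287, "CA"), (400, "N1"), (400, "C1"), (229, "CA")), label="rev"
    )


class TestHbonds:
    def test_occupancy_and_mean_over_bonded_frames(self):
        occ, mean, sd = cf.occupancy_from_distances([3.0, 3.4, 3.6, 4.0])
        assert occ == 0.5
        assert mean == pytest.approx(3.2)

    def test_closest_acceptor_rule(self):
        topo = pd.DataFrame(
            {
                "residue_index": [229, 266, 266],
                "residue_name": ["ASP", "ARG", "ARG"],
                "atom_name": ["OD1", "NH1", "NH2"],
            }
        )
        coords = np.zeros((4, 3, 3))
        coords[:, 1, 0] = 2.9  # NH1 always at 2.9 A
        coords[:, 2, 0] = 4.5  # NH2 always at 4.5 A
        traj = cf.Trajectory(topology=topo, coords=coords)
        occ, mean, sd = cf.hbond_occupancy(
            traj, donor=(229, "OD1"), acceptors=[(266, "NH1"), (266, "NH2")]
        )
        assert occ == 1.0
        assert mean == pytest.approx(2.9)

    def test_planted_occupancy_exact(self):
        rng = np.random.default_rng(12)
        n = 2500
        bonded = np.zeros(n, bool)
        bonded[: int(0.44 * n)] = True
        rng.shuffle(bonded)
        d = np.where(bonded, rng.uniform(2.7, 3.4, n), rng.uniform(3.7, 5.5, n))
        occ, _, _ = cf.occupancy_from_distances(d)
        assert occ == pytest.approx(0.44, abs=1e-12)

    def test_no_acceptors_rejected(self):
        traj = syn.angles_to_trajectory(np.array([0.0]))
        with pytest.raises(ValueError):
            cf.hbond_occupancy(traj, donor=(229, "CA"), acceptors=[])


class TestIO:
    def test_coordinate_table_round_trip(self, tmp_path):
        angles = np.array([-120.0, 30.0, 110.0])
        traj = syn.angles_to_trajectory(angles)
        path = tmp_path / "traj.tsv"
        cf.write_coordinate_table(traj, path)
        back = cf.read_coordinate_table(path)
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-9)
        np.testing.assert_allclose(cf.dihedral_series(back, IN_OUT_SPEC), angles, atol=1e-9)

    def test_multimodel_pdb_reader(self, tmp_path):
        lines = []
        coords = [((0.0, 0.0, 0.0), (1.5, 0.0, 0.0)), ((0.0, 1.0, 0.0), (1.5, 1.0, 0.0))]
        for m, frame in enumerate(coords, start=1):
            lines.append(f"MODEL     {m:4d}")
            for i, (name, xyz) in enumerate(zip(("N", "CA"), frame), start=1):
                x, y, z = xyz
                lines.append(
                    f"ATOM  {i:5d}  {name:<3s}ALA A   1    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]}"
                )
            lines.append("ENDMDL")
        lines.append("END")
        path = tmp_path / "traj.pdb"
        path.write_text("\n".join(lines) + "\n")
        traj = cf.read_multimodel_pdb(path)
        assert traj.n_frames == 2
        assert list(traj.topology["atom_name"]) == ["N", "CA"]
        np.testing.assert_allclose(traj.coords[1, 0], [0.0, 1.0, 0.0], atol=1e-3)
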
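"""Flip-state classification and trajectory-derived bilayer observables."""

import numpy as np
import pytest

from bilayerlab import trajectory as tj
from bilayerlab.trajectory import (
    BilayerMetrics,
    FlipState,
    HBondCriteria,
    HeadgroupTrajectory,
)
from bilayerlab.synthetic import FlipTrajectorySpec, gen_flip_trajectory


def make_traj(coords, box=(10.0, 10.0, 10.0), labels=("P", "O11", "O12"), leaflet=None):
    coords = np.asarray(coords, dtype=float)
    return HeadgroupTrajectory(
        atom_labels=labels,
        coords=coords,
        box=np.tile(np.asarray(box), (coords.shape[0], 1)),
        leaflet=leaflet,
    )


def kabsch_rmsd(a, b):
    """Oracle: minimal RMSD after centering + optimal rotation (own Kabsch)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(a.T @ b)
    sign = np.sign(np.linalg.det(u @ vt))
    s[-1] *= sign
    e0 = (a**2).sum() + (b**2).sum()
    return np.sqrt(max(e0 - 2 * s.sum(), 0.0) / len(a))


class TestBondCosine:
    def test_parallel_bond_zero_degrees(self):
        c = tj.bond_cos_z(P=(0, 0, 1), O=(0, 0, 0))
        assert c == pytest.approx(1.0)
        assert np.degrees(np.arccos(c)) == pytest.approx(0.0)

    def test_antiparallel_bond_180_degrees(self):
        c = tj.bond_cos_z(P=(0, 0, -1), O=(0, 0, 0))
        assert c == pytest.approx(-1.0)
        assert np.degrees(np.arccos(c)) == pytest.approx(180.0)

    def test_in_plane_bond_is_orthogonal(self):
        assert tj.bond_cos_z(P=(1, 0, 0), O=(0, 0, 0)) == pytest.approx(0.0)

    def test_zero_length_bond_rejected(self):
        with pytest.raises(ValueError):
            tj.bond_cos_z(P=(1, 1, 1), O=(1, 1, 1))


class TestClassify:
    @pytest.mark.parametrize(
        "c1,c2,state",
        [
            (0.9, 0.8, FlipState.FLIPPED_OUT),
            (-0.7, -0.2, FlipState.FLIPPED_IN),
            (0.5, -0.5, FlipState.UNCLASSIFIED),
            (0.0, 0.9, FlipState.UNCLASSIFIED),
        ],
    )
    def test_rule(self, c1, c2, state):
        assert tj.classify_flip(c1, c2) is state

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tj.classify_flip(1.2, 0.0)


class TestFlipPopulations:
    def test_absorbing_all_out(self):
        traj, states = gen_flip_trajectory(FlipTrajectorySpec(p_in=0.0, seed=1))
        pops = tj.flip_populations(traj)
        assert np.all(states == 0)
        assert pops.mean_out == 1.0
        np.testing.assert_allclose(pops.fraction_out, 1.0)

    def test_markov_stationary_fraction(self):
        spec = FlipTrajectorySpec(p_in=0.5, p_out=0.5, n_lipids=64, n_frames=200, seed=2)
        traj, _ = gen_flip_trajectory(spec)
        pops = tj.flip_populations(traj)
        assert abs(pops.mean_in - 0.5) <= 3 * pops.se_in

    def test_classifier_agrees_with_ground_truth(self):
        spec = FlipTrajectorySpec(p_in=0.3, p_out=0.2, angular_noise=10.0, seed=3)
        traj, states = gen_flip_trajectory(spec)
        c1, c2 = tj.flip_cosines(traj)
        predicted_in = (c1 < 0) & (c2 < 0)
        assert (predicted_in == (states == 1)).mean() >= 0.99

    def test_fractions_sum_to_one(self):
        traj, _ = gen_flip_trajectory(FlipTrajectorySpec(p_in=0.4, p_out=0.3, seed=4))
        pops = tj.flip_populations(traj)
        total = pops.fraction_out + pops.fraction_in + pops.fraction_unclassified
        np.testing.assert_allclose(total, 1.0)

    def test_empty_leaflet_selection_rejected(self):
        traj, _ = gen_flip_trajectory(FlipTrajectorySpec(seed=5))
        with pytest.raises(ValueError, match="leaflet"):
            tj.flip_populations(traj, leaflet="lower")


class TestZDispHistogram:
    def test_all_out_mass_in_positive_quadrant(self):
        traj, _ = gen_flip_trajectory(FlipTrajectorySpec(p_in=0.0, angular_noise=0.0, seed=6))
        H, e1, e2 = tj.headgroup_zdisp_hist(traj, bins=20)
        pos1 = e1[:-1] >= 0
        pos2 = e2[:-1] >= 0
        assert H[np.ix_(pos1, pos2)].sum() == H.sum()

    def test_mass_conservation_and_symmetric_split(self):
        spec = FlipTrajectorySpec(p_in=0.5, p_out=0.5, n_lipids=64, n_frames=200, seed=7)
        traj, states = gen_flip_trajectory(spec)
        H, e1, e2 = tj.headgroup_zdisp_hist(traj, bins=10)
        n_obs = spec.n_lipids * spec.n_frames
        assert H.sum() == n_obs
        c1 = 0.5 * (e1[:-1] + e1[1:])
        c2 = 0.5 * (e2[:-1] + e2[1:])
        frac_pp = H[np.ix_(c1 > 0, c2 > 0)].sum() / n_obs
        se = np.sqrt(0.25 / n_obs)
        assert abs(frac_pp - 0.5) <= 3 * se


class TestChainPairProfile:
    @staticmethod
    def chain_traj(offsets_b, n_carbons=5):
        # chain A straight along z at x=0; chain B displaced per carbon
        labels = tuple(f"C{n+1}A" for n in range(n_carbons)) + tuple(
            f"C{n+1}B" for n in range(n_carbons)
        )
        coords = np.zeros((1, 1, 2 * n_carbons, 3))
        for n in range(n_carbons):
            coords[0, 0, n] = [0, 0, -0.1 * n]
            coords[0, 0, n_carbons + n] = [offsets_b[n], 0, -0.1 * n]
        return make_traj(coords, labels=labels)

    def test_parallel_chains_constant_profile(self):
        traj = self.chain_traj([0.5] * 5)
        np.testing.assert_allclose(tj.chain_pair_distance_profile(traj), 0.5)

    def test_splayed_chains_increasing_profile(self):
        traj = self.chain_traj([0.2 + 0.1 * n for n in range(5)])
        prof = tj.chain_pair_distance_profile(traj)
        assert np.all(np.diff(prof) > 0)

    def test_superposed_chains_zero(self):
        traj = self.chain_traj([0.0] * 5)
        np.testing.assert_allclose(tj.chain_pair_distance_profile(traj), 0.0)

    def test_minimum_image_used(self):
        # chains 9.5 apart in a 10 nm box are 0.5 apart through the boundary
        traj = self.chain_traj([9.5] * 5)
        np.testing.assert_allclose(tj.chain_pair_distance_profile(traj), 0.5)


class TestHBonds:
    @staticmethod
    def hbond_traj(acceptor_xyz):
        coords = np.zeros((1, 2, 3, 3))
        coords[0, 0, 0] = [5.0, 5.0, 5.0]        # donor D
        coords[0, 0, 1] = [5.0, 5.0, 5.1]        # hydrogen on D
        coords[0, 0, 2] = [1.0, 1.0, 1.0]        # its own acceptor far away
        coords[0, 1, 0] = [8.0, 8.0, 8.0]
        coords[0, 1, 1] = [8.0, 8.0, 8.1]
        coords[0, 1, 2] = acceptor_xyz           # acceptor A near lipid 0
        return make_traj(coords, labels=("D", "H", "A"))

    def test_collinear_inside_cutoffs_counted(self):
        traj = self.hbond_traj([5.0, 5.0, 5.28])
        counts = tj.count_hbonds(traj, donors=[("D", "H")], acceptors=["A"])
        assert counts.tolist() == [1]

    def test_distance_beyond_cutoff_not_counted(self):
        traj = self.hbond_traj([5.0, 5.0, 5.36])
        counts = tj.count_hbonds(traj, donors=[("D", "H")], acceptors=["A"])
        assert counts.tolist() == [0]

    def test_angle_beyond_cutoff_not_counted(self):
        # acceptor at 50 degrees from the O-H direction, within distance
        ang = np.radians(50.0)
        traj = self.hbond_traj([5.0 + 0.3 * np.sin(ang), 5.0, 5.0 + 0.3 * np.cos(ang)])
        counts = tj.count_hbonds(traj, donors=[("D", "H")], acceptors=["A"])
        assert counts.tolist() == [0]

    def test_translation_and_wrapping_invariance(self):
        traj = self.hbond_traj([5.0, 5.0, 5.28])
        base = tj.count_hbonds(traj, donors=[("D", "H")], acceptors=["A"])
        shifted = make_traj(traj.coords + np.array([3.7, -2.1, 9.9]),
                            labels=traj.atom_labels)
        wrapped = make_traj(np.mod(shifted.coords, 10.0), labels=traj.atom_labels)
        for t in (shifted, wrapped):
            got = tj.count_hbonds(t, donors=[("D", "H")], acceptors=["A"])
            assert got.tolist() == base.tolist()

    def test_planted_bonds_per_frame_counted_exactly(self):
        rng = np.random.default_rng(8)
        n_frames, n_lipids = 4, 6
        coords = np.zeros((n_frames, n_lipids, 3, 3))
        for f in range(n_frames):
            for l in range(n_lipids):
                base = rng.uniform(1, 9, 3)
                coords[f, l, 0] = base
                coords[f, l, 1] = base + [0, 0, 0.1]
        # plant exactly 2 bonds per frame: acceptors of lipids 0,1 sit 0.3 nm
        # above donors of lipids 2,3; all other acceptors are far away
        for f in range(n_frames):
            coords[f, :, 2] = rng.uniform(20, 30, (n_lipids, 3)) % 10 + 40  # far
            coords[f, 0, 2] = coords[f, 2, 0] + [0, 0, 0.3]
            coords[f, 1, 2] = coords[f, 3, 0] + [0, 0, 0.3]
        traj = make_traj(coords, box=(100.0, 100.0, 100.0), labels=("D", "H", "A"))
        counts = tj.count_hbonds(traj, donors=[("D", "H")], acceptors=["A"])
        assert counts.tolist() == [2] * n_frames

    def test_missing_hydrogen_label_rejected(self):
        traj = self.hbond_traj([5.0, 5.0, 5.28])
        with pytest.raises(KeyError):
            tj.count_hbonds(traj, donors=[("D", "Hmissing")], acceptors=["A"])


class TestDensityProfile:
    def test_fixed_offset_group_gives_single_peak(self):
        coords = np.zeros((2, 10, 2, 3))
        coords[..., 0, 2] = 1.5   # P atoms at +1.5 relative to the other atom
        coords[..., 1, 2] = -1.5  # anchor keeps midplane at 0
        traj = make_traj(coords, labels=("P", "X"))
        z, dens = tj.density_profile(traj, ["P"], n_bins=30)
        assert dens.max() == 1.0
        assert z[np.argmax(dens)] == pytest.approx(1.5, abs=0.2)

    def test_two_leaflet_fixture_symmetric(self):
        rng = np.random.default_rng(9)
        n = 400
        coords = np.zeros((1, n, 1, 3))
        z = np.concatenate([rng.normal(1.8, 0.1, n // 2), rng.normal(-1.8, 0.1, n // 2)])
        coords[0, :, 0, 2] = z
        traj = make_traj(coords, labels=("P",))
        zc, dens = tj.density_profile(traj, ["P"], n_bins=40, z_range=(-2.5, 2.5))
        np.testing.assert_allclose(dens, dens[::-1], atol=0.15)


class TestBilayerMetrics:
    def test_area_per_lipid_arithmetic(self):
        coords = np.zeros((1, 256, 1, 3))
        coords[0, :128, 0, 2] = 1.8
        coords[0, 128:, 0, 2] = -1.8
        traj = make_traj(coords, box=(6.43993, 6.43993, 10.0), labels=("P",))
        m = tj.bilayer_metrics(traj, n_waters=0)
        assert m.A_L == pytest.approx(6.43993**2 / 128, rel=1e-9)

    def test_area_halves_when_lipids_double(self):
        def metrics_for(n):
            coords = np.zeros((1, n, 1, 3))
            coords[0, : n // 2, 0, 2] = 1.8
            coords[0, n // 2 :, 0, 2] = -1.8
            return tj.bilayer_metrics(make_traj(coords, labels=("P",)))

        assert metrics_for(256).A_L == pytest.approx(metrics_for(128).A_L / 2)

    def test_dhh_from_phosphate_slabs(self):
        rng = np.random.default_rng(10)
        n = 500
        coords = np.zeros((1, n, 1, 3))
        coords[0, : n // 2, 0, 2] = 1.8 + rng.normal(0, 0.05, n // 2)
        coords[0, n // 2 :, 0, 2] = -1.8 + rng.normal(0, 0.05, n // 2)
        traj = make_traj(coords, labels=("P",))
        m = tj.bilayer_metrics(traj, n_bins=120)
        assert m.D_HH == pytest.approx(3.6, abs=0.1)

    def test_water_volume_subtracted(self):
        coords = np.zeros((1, 2, 1, 3))
        coords[0, 0, 0, 2] = 1.0
        coords[0, 1, 0, 2] = -1.0
        traj = make_traj(coords, box=(2.0, 2.0, 5.0), labels=("P",))
        m = tj.bilayer_metrics(traj, n_waters=100, water_volume=0.03)
        assert m.V_L == pytest.approx((20.0 - 3.0) / 2)

    def test_zero_lipids_rejected(self):
        traj, _ = gen_flip_trajectory(FlipTrajectorySpec(seed=11))
        with pytest.raises(ValueError):
            tj.bilayer_metrics(traj, n_lipids=0)


class TestOrderParameter:
    def test_axial_bonds_reach_unity(self):
        vecs = np.tile([0.0, 0.0, 1.0], (50, 1))
        np.testing.assert_allclose(tj.order_parameter_scd([vecs]), 1.0)

    def test_in_plane_bonds_reach_minus_half(self):
        theta = np.linspace(0, 2 * np.pi, 50)
        vecs = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(50)])
        np.testing.assert_allclose(tj.order_parameter_scd([vecs]), -0.5)

    def test_isotropic_bonds_average_to_zero(self):
        rng = np.random.default_rng(12)
        vecs = rng.normal(size=(100_000, 3))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        assert tj.order_parameter_scd([vecs])[0] == pytest.approx(0.0, abs=0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            tj.order_parameter_scd([np.empty((0, 3))])


class TestRepresentativeConformation:
    def test_identical_conformations_return_first(self):
        conf = np.arange(12.0).reshape(4, 3)
        assert tj.representative_conformation([conf] * 5) == 0

    def test_outlier_not_selected(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=(6, 3))
        confs = [base + rng.normal(scale=0.01, size=base.shape) for _ in range(7)]
        confs[3] = base + rng.normal(scale=2.0, size=base.shape)  # outlier
        assert tj.representative_conformation(confs) != 3

    def test_medoid_drawn_from_most_populated_cluster(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=(5, 3))
        b = a + 10 * rng.normal(size=(5, 3))
        confs = [a + rng.normal(scale=0.05, size=a.shape) for _ in range(3)]
        confs += [b + rng.normal(scale=0.05, size=b.shape) for _ in range(5)]
        labels = [0] * 3 + [1] * 5
        assert tj.representative_conformation(confs, labels) >= 3

    def test_agrees_with_brute_force_kabsch_search(self):
        rng = np.random.default_rng(15)
        confs = [rng.normal(size=(8, 3)) for _ in range(12)]
        got = tj.representative_conformation(confs)
        n = len(confs)
        means = []
        for i in range(n):
            d = [kabsch_rmsd(confs[i], confs[j]) for j in range(n) if j != i]
            means.append(np.mean(d))
        assert got == int(np.argmin(means))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tj.representative_conformation([])
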
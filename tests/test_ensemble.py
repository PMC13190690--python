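import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdstab import ensemble as ens
from mdstab import io_core as io
from mdstab import synthetic as syn
from mdstab.ensemble import PopulationVector, cosine_distance
from mdstab.io_core import RegionSpec


def make_traj(coords, n_res):
    return io.TrajectoryRecord(
        np.arange(float(len(coords))), coords, syn.make_chain_atoms(n_res)
    )


class TestGromosCluster:
    def test_identical_frames_single_cluster(self, chain_region):
        base = syn.make_bead_chain(50)
        traj = make_traj(np.repeat(base[None], 20, axis=0), 50)
        a = ens.gromos_cluster(traj, chain_region, 0.1)
        assert a.n_clusters == 1
        assert a.populations_percent[0] == pytest.approx(100.0)

    def test_two_state_populations(self, two_state_traj, chain_region):
        traj, truth = two_state_traj
        a = ens.gromos_cluster(traj, chain_region, 0.1)
        assert a.n_clusters == 2
        occ = np.bincount(truth.state_path) / traj.n_frames * 100
        np.testing.assert_allclose(
            sorted(a.populations_percent, reverse=True), sorted(occ, reverse=True),
            atol=0.6,
        )

    def test_cutoff_below_min_distance_singletons(self, chain_region):
        rng = np.random.default_rng(0)
        base = syn.make_bead_chain(50)
        coords = base[None] + rng.normal(0, 0.05, (10, 50, 3))
        traj = make_traj(coords, 50)
        D = ens.pairwise_rmsd_matrix(traj, chain_region)
        tiny = D[D > 0].min() / 2
        a = ens.gromos_cluster(traj, chain_region, tiny, rmsd_matrix=D)
        assert a.n_clusters == 10

    def test_pairwise_admission_contract(self, two_state_traj, chain_region):
        # every intra-cluster pairwise RMSD respects the cutoff by construction
        traj, _ = two_state_traj
        D = ens.pairwise_rmsd_matrix(traj, chain_region)
        a = ens.gromos_cluster(traj, chain_region, 0.1, rmsd_matrix=D)
        for k in range(1, a.n_clusters + 1):
            m = np.nonzero(a.labels == k)[0]
            if len(m) > 1:
                assert D[np.ix_(m, m)].max() <= 0.1 + 1e-7

    def test_deterministic(self, two_state_traj, chain_region):
        traj, _ = two_state_traj
        a = ens.gromos_cluster(traj, chain_region, 0.1)
        b = ens.gromos_cluster(traj, chain_region, 0.1)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.medoid_frames, b.medoid_frames)

    def test_every_frame_assigned_and_populations_sum(self, two_state_traj, chain_region):
        traj, _ = two_state_traj
        a = ens.gromos_cluster(traj, chain_region, 0.1)
        assert a.labels.min() >= 1
        assert a.populations_percent.sum() == pytest.approx(100.0, abs=1e-9)
        rep = a.populations_report()
        assert rep["population_percent"].sum() == pytest.approx(100.0, abs=1e-9)


class TestWindowVectors:
    def make_assignment(self, labels, dt=1.0):
        labels = np.asarray(labels)
        return ens.ClusterAssignment(
            labels=labels,
            medoid_frames=np.arange(labels.max()),
            populations_percent=np.bincount(labels)[1:] / len(labels) * 100,
            frame_times=np.arange(len(labels)) * dt,
        )

    def test_window_count_enumeration(self):
        # 0..100 ns duration, W=40, step=15 -> starts 0,15,30,45,60
        a = self.make_assignment(np.ones(101, dtype=int))
        vecs = ens.window_population_vectors(a, 40.0, 15.0)
        assert [v.window_start_ns for v in vecs] == [0.0, 15.0, 30.0, 45.0, 60.0]

    def test_full_duration_single_window_equals_global(self, two_state_traj, chain_region):
        traj, _ = two_state_traj
        a = ens.gromos_cluster(traj, chain_region, 0.1)
        vecs = ens.window_population_vectors(a, traj.duration_ns, 500.0)
        assert len(vecs) == 1
        np.testing.assert_allclose(
            vecs[0].fractions * 100, a.populations_percent, atol=0.4
        )

    def test_single_cluster_vectors_are_unit_first_component(self):
        a = self.make_assignment(np.ones(50, dtype=int))
        vecs = ens.window_population_vectors(a, 10.0, 5.0)
        for v in vecs:
            assert v.fractions[0] == pytest.approx(1.0)

    def test_window_counts_sum_to_frames(self):
        rng = np.random.default_rng(1)
        a = self.make_assignment(rng.integers(1, 4, 200))
        for v in ens.window_population_vectors(a, 50.0, 15.0):
            assert v.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_window_longer_than_duration_rejected(self):
        a = self.make_assignment(np.ones(20, dtype=int))
        with pytest.raises(ValueError, match="duration"):
            ens.window_population_vectors(a, 100.0, 15.0)


class TestCosineDistance:
    def test_identical_vectors_zero(self):
        v = np.array([0.6, 0.3, 0.1])
        assert cosine_distance(v, v) == 0.0

    def test_disjoint_support_one(self):
        assert cosine_distance(np.array([1.0, 0, 0]), np.array([0, 0.5, 0.5])) == 1.0

    def test_hand_computed_half(self):
        d = cosine_distance(np.array([0.5, 0.5, 0.0]), np.array([0.5, 0.0, 0.5]))
        assert d == pytest.approx(0.5, abs=1e-12)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError, match="cluster sets"):
            cosine_distance(np.ones(3) / 3, np.ones(4) / 4)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_distance(np.zeros(3), np.ones(3) / 3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0, allow_subnormal=False), min_size=2, max_size=8),
           st.lists(st.floats(0.0, 1.0, allow_subnormal=False), min_size=2, max_size=8),
           st.floats(0.1, 10.0))
    def test_matches_scipy_and_scale_invariant(self, a, b, scale):
        from scipy.spatial.distance import cosine as scipy_cosine

        a, b = np.array(a[: len(b)]), np.array(b[: len(a)])
        if np.linalg.norm(a) < 1e-6 or np.linalg.norm(b) < 1e-6:
            return
        d = cosine_distance(a, b)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(scipy_cosine(a, b), abs=1e-9)
        assert cosine_distance(a * scale, b) == pytest.approx(d, abs=1e-9)
        assert cosine_distance(b, a) == pytest.approx(d, abs=1e-12)


class TestDistanceMatrixAndSegments:
    def vec(self, t, fracs, W=40.0):
        return PopulationVector(t, W, np.asarray(fracs))

    def test_identical_vectors_all_zero_matrix_one_segment(self):
        vecs = [self.vec(15.0 * i, [1.0, 0.0]) for i in range(10)]
        dm = ens.distance_matrix(vecs)
        assert np.all(dm.matrix == 0.0)
        segs = ens.find_stable_segments(dm, 0.1)
        assert len(segs) == 1
        assert segs[0].n_windows == 10
        assert segs[0].duration_ns == pytest.approx(15.0 * 9 + 40.0)

    def test_checkerboard_from_alternating_vectors(self):
        a, b = [0.5, 0.5, 0.0], [0.5, 0.0, 0.5]
        vecs = [self.vec(float(i), a if i % 2 == 0 else b) for i in range(6)]
        dm = ens.distance_matrix(vecs)
        np.testing.assert_array_equal(dm.matrix, dm.matrix.T)
        for i in range(6):
            for j in range(6):
                expect = 0.0 if (i - j) % 2 == 0 else 0.5
                assert dm.matrix[i, j] == pytest.approx(expect, abs=1e-12)

    def test_block_diagonal_two_segments(self):
        vecs = [self.vec(15.0 * i, [1.0, 0.0] if i < 5 else [0.0, 1.0])
                for i in range(10)]
        dm = ens.distance_matrix(vecs)
        segs = ens.find_stable_segments(dm, 0.1)
        assert len(segs) == 2
        assert (segs[0].first_window, segs[0].last_window) == (0, 4)
        assert (segs[1].first_window, segs[1].last_window) == (5, 9)

    def test_invalid_threshold_rejected(self):
        vecs = [self.vec(0.0, [1.0]), self.vec(15.0, [1.0])]
        dm = ens.distance_matrix(vecs)
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                ens.find_stable_segments(dm, bad)


class TestCombinedCluster:
    def test_same_trajectory_overlap_one(self, two_state_traj, chain_region):
        traj, _ = two_state_traj
        sub = traj.slice_frames(slice(0, 100))
        _, table, overlap = ens.combined_cluster(sub, sub, chain_region, 0.1)
        assert overlap == pytest.approx(1.0)

    def test_disjoint_templates_zero_overlap(self, chain_region):
        rng = np.random.default_rng(0)
        templates = syn.make_state_templates(50, 2, amplitude_nm=0.6)
        a = make_traj(templates[0][None] + rng.normal(0, 0.01, (50, 50, 3)), 50)
        b = make_traj(templates[1][None] + rng.normal(0, 0.01, (50, 50, 3)), 50)
        _, table, overlap = ens.combined_cluster(a, b, chain_region, 0.1)
        assert overlap == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_identical_generators_high_overlap(self, seed, chain_region):
        model = syn.two_state_model(50, (0.5, 0.5), switch_rate=0.3)
        a, _ = syn.gen_markov_trajectory(model, 300, seed=seed)
        b, _ = syn.gen_markov_trajectory(model, 300, seed=seed + 100)
        _, _, overlap = ens.combined_cluster(a, b, chain_region, 0.1)
        assert overlap >= 0.8

    def test_atom_table_mismatch_rejected(self, two_state_traj):
        traj, _ = two_state_traj
        other = make_traj(np.zeros((3, 10, 3)), 10)
        with pytest.raises(ValueError, match="atom tables"):
            ens.combined_cluster(traj, other, RegionSpec("r", ((339, 348),)), 0.1)


class TestRepresentatives:
    def test_fewer_clusters_than_k(self, two_state_traj, chain_region):
        traj, _ = two_state_traj
        a = ens.gromos_cluster(traj, chain_region, 0.1)
        reps = ens.extract_representatives(a, traj, k=20)
        assert reps.n_frames == a.n_clusters  # 2 < 20

    def test_k1_returns_top_cluster_medoid(self, two_state_traj, chain_region):
        traj, _ = two_state_traj
        a = ens.gromos_cluster(traj, chain_region, 0.1)
        reps = ens.extract_representatives(a, traj, k=1)
        np.testing.assert_array_equal(
            reps.coordinates[0], traj.coordinates[a.medoid_frames[0]]
        )

    def test_medoids_close_to_templates(self, two_state_traj, chain_region):
        from mdstab.conformation import superpose_kabsch

        traj, truth = two_state_traj
        model = syn.two_state_model(50, (0.7, 0.3), switch_rate=0.2,
                                    template_separation_nm=0.5, jitter_sd_nm=0.01)
        a = ens.gromos_cluster(traj, chain_region, 0.1)
        reps = ens.extract_representatives(a, traj, k=2)
        for frame in reps.coordinates:
            best = min(
                superpose_kabsch(frame, tpl).rmsd for tpl in model.templates
            )
            assert best < 4 * 0.01  # within jitter scale of its template
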
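import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from aggfold.ensemble import (
    cartesian_pca,
    eigen_rmsf,
    gromos_cluster,
    pairwise_rmsd_matrix,
    project,
)
from aggfold.geometry import radius_of_gyration
from aggfold.model import BOMBININ_H2
from aggfold.synthetic import bend_trajectory


def scipy_rmsd(a, b):
    """Independent RMSD oracle via scipy's Wahba solver."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ac, bc)
    return rssd / np.sqrt(len(a))


def brute_force_gromos(coords, cutoff):
    """Direct re-implementation of the greedy neighbour-count clustering."""
    n = len(coords)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = scipy_rmsd(coords[i], coords[j])
    remaining = set(range(n))
    clusters = []
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if dist[i, j] < cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted(j for j in remaining if dist[best, j] < cutoff or j == best)
        clusters.append((best, tuple(members)))
        remaining -= set(members)
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return clusters


@pytest.fixture(scope="module")
def two_basin_traj():
    """40 frames alternating between the straight and the hinge-bent basin."""
    rng = np.random.default_rng(12)
    angles = np.where(np.arange(40) % 2 == 0, 0.0, 120.0) + rng.normal(0, 1.5, 40)
    return bend_trajectory(BOMBININ_H2, np.abs(angles), noise_sigma_nm=0.001, seed=3)


@pytest.fixture(scope="module")
def pure_bend_traj():
    """Smooth sweep of the hinge angle: a one-degree-of-freedom motion."""
    angles = np.concatenate([np.linspace(0, 120, 30), np.linspace(120, 0, 30)])
    return bend_trajectory(BOMBININ_H2, angles, noise_sigma_nm=0.001, seed=4)


class TestGromosCluster:
    def test_identical_frames_single_cluster(self, ideal_helix):
        coords = np.repeat(ideal_helix.flat(("N", "CA", "C"))[None], 5, axis=0)
        cs = gromos_cluster(coords)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].size == 5

    def test_all_far_apart_all_singletons(self, ideal_helix, bent_conformer):
        from aggfold.synthetic import build_bent_conformer, build_ideal_helix

        mid = build_bent_conformer(ideal_helix, (10, 11), 60.0)
        coords = np.stack(
            [
                ideal_helix.flat(("N", "CA", "C")),
                mid.flat(("N", "CA", "C")),
                bent_conformer.flat(("N", "CA", "C")),
            ]
        )
        cs = gromos_cluster(coords, cutoff_nm=0.05)
        assert cs.sizes() == [1, 1, 1]

    def test_two_basin_partition_matches_brute_force(self, two_basin_traj):
        coords = two_basin_traj.chain_coords("A", ("N", "CA", "C"))
        cs = gromos_cluster(coords, cutoff_nm=0.3)
        oracle = brute_force_gromos(coords, 0.3)
        got = [(c.centroid, tuple(sorted(c.members))) for c in cs.clusters]
        assert got == oracle

    def test_sizes_partition_frames(self, two_basin_traj):
        coords = two_basin_traj.chain_coords("A", ("N", "CA", "C"))
        cs = gromos_cluster(coords, cutoff_nm=0.3)
        assert sum(cs.sizes()) == len(coords)
        labels = cs.labels()
        assert (labels >= 0).all()
        for c in cs.clusters:
            assert c.centroid in c.members

    def test_order_invariance_under_shuffling(self, two_basin_traj):
        coords = two_basin_traj.chain_coords("A", ("N", "CA", "C"))
        base = gromos_cluster(coords, cutoff_nm=0.3)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(coords))
        shuffled = gromos_cluster(coords[perm], cutoff_nm=0.3)
        base_sets = {frozenset(c.members) for c in base.clusters}
        mapped = {frozenset(perm[m] for m in c.members) for c in shuffled.clusters}
        assert base_sets == mapped

    def test_empty_frame_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gromos_cluster(np.zeros((0, 60, 3)))


class TestCartesianPca:
    def test_dimension_is_180_for_20_residues(self, pure_bend_traj):
        model = cartesian_pca(pure_bend_traj, "A")
        assert model.eigenvectors.shape[0] == 180  # 60 atoms x 3
        assert model.n_atoms == 60

    def test_eigenvalue_sum_equals_covariance_trace(self, pure_bend_traj):
        coords = pure_bend_traj.chain_coords("A", ("N", "CA", "C"))
        model = cartesian_pca(coords)
        from aggfold.geometry import kabsch_superpose

        fitted = np.array(
            [kabsch_superpose(x, coords[0])[0].apply(x) for x in coords]
        ).reshape(len(coords), -1)
        centred = fitted - fitted.mean(axis=0)
        trace = np.trace(centred.T @ centred / len(coords))
        assert model.eigenvalues.sum() == pytest.approx(trace, abs=1e-8)

    def test_static_trajectory_all_zero_eigenvalues(self, ideal_helix):
        coords = np.repeat(ideal_helix.flat(("N", "CA", "C"))[None], 5, axis=0)
        model = cartesian_pca(coords)
        assert np.allclose(model.eigenvalues, 0.0, atol=1e-12)

    def test_pure_bend_pc1_dominates_and_tracks_rg(self, pure_bend_traj):
        model = cartesian_pca(pure_bend_traj, "A")
        assert model.variance_fractions()[0] > 0.9
        rg = np.array(
            [
                radius_of_gyration(pure_bend_traj.conformation(f, "A"))
                for f in range(pure_bend_traj.n_frames)
            ]
        )
        corr = np.corrcoef(model.projections[:, 0], rg)[0, 1]
        assert abs(corr) > 0.9

    def test_eigenvectors_orthonormal(self, pure_bend_traj):
        model = cartesian_pca(pure_bend_traj, "A")
        gram = model.eigenvectors.T @ model.eigenvectors
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_projection_variance_equals_eigenvalue(self, pure_bend_traj):
        model = cartesian_pca(pure_bend_traj, "A")
        var = model.projections.var(axis=0)
        assert np.allclose(var[:5], model.eigenvalues[:5], atol=1e-8)

    def test_reconstruction_from_all_components(self, two_basin_traj):
        coords = two_basin_traj.chain_coords("A", ("N", "CA", "C"))
        model = cartesian_pca(coords)
        rebuilt = model.projections @ model.eigenvectors.T + model.mean_flat
        from aggfold.geometry import kabsch_superpose

        fitted = np.array(
            [kabsch_superpose(x, coords[0])[0].apply(x) for x in coords]
        ).reshape(len(coords), -1)
        assert np.allclose(rebuilt, fitted, atol=1e-8)

    def test_fewer_than_two_frames_rejected(self, ideal_helix):
        with pytest.raises(ValueError):
            cartesian_pca(ideal_helix.flat(("N", "CA", "C"))[None])


class TestEigenRmsf:
    def test_zero_eigenvalue_zero_profile(self, ideal_helix):
        coords = np.repeat(ideal_helix.flat(("N", "CA", "C"))[None], 4, axis=0)
        model = cartesian_pca(coords)
        assert np.allclose(eigen_rmsf(model, 0), 0.0)

    def test_pure_bend_profile_peaks_at_termini(self, pure_bend_traj):
        model = cartesian_pca(pure_bend_traj, "A")
        prof = eigen_rmsf(model, 0)
        hinge_zone = prof[27:33]  # atoms of residues 10-11
        assert prof[:6].mean() > hinge_zone.min()
        assert prof[-6:].mean() > hinge_zone.min()

    def test_same_scripted_motion_gives_same_profile(self):
        """The bend mode of the same scripted sweep, observed twice with
        different noise and a different global orientation, produces
        eigen-RMSF profiles agreeing within 10% of the profile maximum."""
        angles = np.concatenate([np.linspace(0, 120, 30), np.linspace(120, 0, 30)])
        t1 = bend_trajectory(BOMBININ_H2, angles, noise_sigma_nm=0.001, seed=21)
        t2 = bend_trajectory(BOMBININ_H2, angles, noise_sigma_nm=0.001, seed=22)
        p1 = eigen_rmsf(cartesian_pca(t1, "A"), 0)
        p2 = eigen_rmsf(cartesian_pca(t2, "A"), 0)
        assert np.max(np.abs(p1 - p2)) < 0.1 * p1.max()

    def test_component_out_of_range(self, pure_bend_traj):
        model = cartesian_pca(pure_bend_traj, "A")
        with pytest.raises(IndexError):
            eigen_rmsf(model, 999)


class TestProject:
    def test_mean_structure_projects_to_zero(self, pure_bend_traj):
        model = cartesian_pca(pure_bend_traj, "A")
        mean_coords = model.mean_flat.reshape(1, -1, 3)
        assert project(mean_coords, model, 0)[0] == pytest.approx(0.0, abs=1e-8)

    def test_two_basin_projection_is_bimodal(self, two_basin_traj):
        model = cartesian_pca(two_basin_traj, "A")
        pc1 = np.sort(model.projections[:, 0])
        gaps = np.diff(pc1)
        # the inter-basin gap dwarfs the intra-basin spacing
        assert gaps.max() > 10 * np.median(gaps)

    def test_selection_mismatch_rejected(self, pure_bend_traj):
        model = cartesian_pca(pure_bend_traj, "A")
        with pytest.raises(ValueError, match="mismatch"):
            project(np.zeros((3, 10, 3)), model, 0)
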
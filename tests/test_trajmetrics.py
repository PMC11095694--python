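"""Trajectory metrics: superposition, RMSD/RMSF, PCA, RDF, smoothing."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lcpscan.structures import Trajectory
from lcpscan.synthetic import make_two_state_trajectory, make_uniform_gas
from lcpscan.trajmetrics import (
    atom_rmsf,
    kabsch,
    pca,
    porcupine,
    rdf,
    rmsd_series,
    rmsf,
    smooth_trajectory,
)

from conftest import toy_protein


def random_rotation(seed):
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


class TestKabsch:
    def test_identical_clouds(self, ca_protein):
        R, t, r = kabsch(ca_protein.coords, ca_protein.coords)
        assert r == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_90_degree_rotation(self, ca_protein):
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = ca_protein.coords @ Rz.T + np.array([1.0, -2.0, 3.0])
        _, _, r = kabsch(moved, ca_protein.coords)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_beats_random_rotations(self):
        """Randomized oracle: the fitted RMSD is no worse than 1000 random
        rigid alignments of the same clouds."""
        rng = np.random.default_rng(1)
        a = rng.normal(0, 3, (10, 3))
        b = rng.normal(0, 3, (10, 3))
        _, _, fitted = kabsch(a, b)
        a0 = a - a.mean(axis=0)
        b0 = b - b.mean(axis=0)
        for k in range(1000):
            R = random_rotation(k)
            trial = np.sqrt(((a0 @ R.T - b0) ** 2).sum(axis=1).mean())
            assert fitted <= trial + 1e-12

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line)

    def test_weighted_fit_prefers_heavy_points(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 3, (8, 3))
        b = a.copy()
        b[0] += [5.0, 0, 0]  # outlier
        w = np.ones(8)
        w[0] = 1e-9
        _, _, r = kabsch(b, a, weights=w)
        assert r < 1e-3


class TestRMSD:
    def test_copies_of_reference_give_zeros(self, ca_protein):
        traj = Trajectory(ca_protein, np.tile(ca_protein.coords, (5, 1, 1)))
        np.testing.assert_allclose(rmsd_series(traj, ca_protein, "name CA"), 0.0, atol=1e-9)

    def test_single_displaced_atom_analytic(self, ca_protein):
        """One atom displaced by d among N, with the fit done on the
        untouched subset: RMSD over all = d/sqrt(N)."""
        n = ca_protein.n_atoms
        d = 2.0
        frame = ca_protein.coords.copy()
        frame[7] += [0, 0, d]
        traj = Trajectory(ca_protein, frame[None])
        fit_idx = np.array([i for i in range(n) if i != 7])
        series = rmsd_series(traj, ca_protein, fit_idx, np.arange(n))
        # the fit over N-1 identical points is exact, so the displaced atom
        # contributes d^2/N to the mean square
        assert series[0] == pytest.approx(d / np.sqrt(n), rel=1e-6)

    def test_invariant_under_global_rigid_motion(self, ca_protein):
        rng = np.random.default_rng(3)
        frames = ca_protein.coords[None] + rng.normal(0, 0.3, (10, ca_protein.n_atoms, 3))
        traj = Trajectory(ca_protein, frames)
        base = rmsd_series(traj, ca_protein, "name CA")
        R = random_rotation(5)
        moved = Trajectory(ca_protein, frames @ R.T + np.array([4.0, 5.0, 6.0]))
        np.testing.assert_allclose(rmsd_series(moved, ca_protein, "name CA"), base, atol=1e-9)

    def test_empty_selection_rejected(self, ca_protein):
        traj = Trajectory(ca_protein, ca_protein.coords[None])
        with pytest.raises(ValueError):
            rmsd_series(traj, ca_protein, "resname XYZ")


class TestRMSF:
    def test_static_trajectory_gives_zeros(self, ca_protein):
        traj = Trajectory(ca_protein, np.tile(ca_protein.coords, (4, 1, 1)))
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in rmsf(traj).values())

    def test_recovers_planted_isotropic_jitter(self):
        """Per-axis sigma = 0.5 Å -> per-atom RMSF = 0.5*sqrt(3), within
        5% at 2000 frames (superposition absorbs ~6/3N of the variance)."""
        s = toy_protein(100, seed=0)
        rng = np.random.default_rng(1)
        frames = s.coords[None] + rng.normal(0, 0.5, (2000, 100, 3))
        values = np.array(list(rmsf(Trajectory(s, frames), "name CA").values()))
        expect = 0.5 * np.sqrt(3)
        assert np.all(np.abs(values - expect) / expect < 0.05)

    def test_heterogeneous_sigma_rank_order_recovered(self):
        """Per-residue sigmas 0.1..1.0 on mobile residues, fit on static
        anchors: recovered RMSF rank order matches the planted order."""
        s = toy_protein(20, seed=2, spread=20.0)
        sigmas = np.concatenate([np.zeros(10), np.linspace(0.1, 1.0, 10)])
        rng = np.random.default_rng(3)
        frames = s.coords[None] + rng.normal(0, 1, (3000, 20, 3)) * sigmas[None, :, None]
        traj = Trajectory(s, frames)
        values = rmsf(traj, "resnum 11-20", fit_selection="resnum 1-10")
        mobile = [values[("A", rn)] for rn in range(11, 21)]
        assert list(np.argsort(mobile)) == list(range(10))

    def test_single_frame_rejected(self, ca_protein):
        with pytest.raises(ValueError):
            rmsf(Trajectory(ca_protein, ca_protein.coords[None]))


class TestPCA:
    def test_two_state_ensemble_separates_on_pc1(self, ca_protein):
        disp = np.zeros((50, 3))
        disp[10:20] = [3.0, 0, 0]
        traj, man = make_two_state_trajectory(ca_protein, disp, 0.5, 500,
                                              noise_sigma=0.1, seed=1)
        result = pca(traj, "name CA")
        proj = result.projections[:, 0]
        states = np.array(man["state_assignments"])
        mid = proj.mean()
        errors = min(np.sum((proj > mid) != states), np.sum((proj > mid) != (1 - states)))
        assert errors == 0

    def test_pc1_mode_matches_planted_displacement_within_5_degrees(self, ca_protein):
        disp = np.zeros((50, 3))
        disp[10:20] = [3.0, 0, 0]
        traj, man = make_two_state_trajectory(ca_protein, disp, 0.5, 500,
                                              noise_sigma=0.1, seed=1)
        result = pca(traj, "name CA")
        applied = np.array(man["applied_displacement"]).ravel()
        applied /= np.linalg.norm(applied)
        cosine = abs(result.modes[0].ravel() @ applied)
        assert np.degrees(np.arccos(min(1.0, cosine))) < 5.0

    def test_eigenvalue_sum_equals_total_variance(self, ca_protein):
        rng = np.random.default_rng(4)
        frames = ca_protein.coords[None] + rng.normal(0, 0.4, (200, 50, 3))
        result = pca(Trajectory(ca_protein, frames), "name CA")
        from lcpscan.trajmetrics import _iterated_mean_superpose

        sup, mean = _iterated_mean_superpose(frames, np.arange(50))
        total = ((sup - mean) ** 2).sum() / 200
        assert result.eigenvalues.sum() == pytest.approx(total, rel=1e-6)

    def test_modes_are_orthonormal(self, ca_protein):
        rng = np.random.default_rng(5)
        frames = ca_protein.coords[None] + rng.normal(0, 0.4, (100, 50, 3))
        result = pca(Trajectory(ca_protein, frames), "name CA")
        flat = result.modes.reshape(len(result.eigenvalues), -1)
        gram = flat @ flat.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_isotropic_noise_spectrum_is_flat(self):
        """With iid noise on every coordinate the top eigenvalues should
        agree within sampling scatter (no dominant planted mode)."""
        s = toy_protein(20, seed=6, spread=30.0)
        rng = np.random.default_rng(6)
        frames = s.coords[None] + rng.normal(0, 0.5, (5000, 20, 3))
        result = pca(Trajectory(s, frames), "name CA")
        ev = result.eigenvalues[: 3 * 20 - 7]  # exclude rigid-depleted tail
        assert ev.max() / ev.min() < 2.0

    def test_disjoint_halves_agree_on_top_mode(self, ca_protein):
        disp = np.zeros((50, 3))
        disp[5:15] = [0, 2.5, 0]
        traj, _ = make_two_state_trajectory(ca_protein, disp, 0.5, 2000,
                                            noise_sigma=0.2, seed=7)
        half1 = Trajectory(ca_protein, traj.frames[:1000])
        half2 = Trajectory(ca_protein, traj.frames[1000:])
        m1 = pca(half1, "name CA").modes[0].ravel()
        m2 = pca(half2, "name CA").modes[0].ravel()
        assert abs(m1 @ m2) > 0.9

    def test_pooled_trajectories_are_tagged(self, ca_protein):
        rng = np.random.default_rng(8)
        t1 = Trajectory(ca_protein, ca_protein.coords[None] + rng.normal(0, 0.2, (30, 50, 3)))
        t2 = Trajectory(ca_protein, ca_protein.coords[None] + rng.normal(0, 0.2, (20, 50, 3)))
        result = pca([t1, t2], "name CA")
        assert list(np.bincount(result.frame_tags)) == [30, 20]

    def test_single_frame_rejected(self, ca_protein):
        with pytest.raises(ValueError):
            pca(Trajectory(ca_protein, ca_protein.coords[None]), "name CA")


class TestPorcupine:
    def _result(self, ca_protein, seed=9, sigma=0.1):
        rng = np.random.default_rng(seed)
        frames = ca_protein.coords[None] + rng.normal(0, sigma, (100, 50, 3))
        return pca(Trajectory(ca_protein, frames), "name CA")

    def test_small_mode_fully_suppressed(self, ca_protein):
        result = self._result(ca_protein)
        vectors = porcupine(result, 0, scale=1.0, min_length=2.0)
        np.testing.assert_array_equal(vectors, 0.0)

    def test_only_planted_loop_atoms_emitted(self, ca_protein):
        disp = np.zeros((50, 3))
        disp[10:20] = [4.0, 0, 0]
        traj, _ = make_two_state_trajectory(ca_protein, disp, 0.5, 400,
                                            noise_sigma=0.05, seed=10)
        result = pca(traj, "name CA")
        vectors = porcupine(result, 0, scale=1.0, min_length=1.0)
        emitted = set(np.flatnonzero(np.linalg.norm(vectors, axis=1) > 0))
        assert emitted and emitted.issubset(set(range(10, 20)))

    def test_doubling_scale_doubles_emitted_vectors(self, ca_protein):
        disp = np.zeros((50, 3))
        disp[10:20] = [4.0, 0, 0]
        traj, _ = make_two_state_trajectory(ca_protein, disp, 0.5, 400,
                                            noise_sigma=0.05, seed=10)
        result = pca(traj, "name CA")
        v1 = porcupine(result, 0, scale=1.0, min_length=1.0)
        v2 = porcupine(result, 0, scale=2.0, min_length=1.0)
        emitted = np.linalg.norm(v1, axis=1) > 0
        np.testing.assert_allclose(v2[emitted], 2.0 * v1[emitted], atol=1e-9)


class TestRDF:
    def test_uniform_gas_is_flat_at_one(self):
        traj, _ = make_uniform_gas(2000, (40.0, 40.0, 40.0), 100, seed=11)
        r, g = rdf(traj, "all", "all", bin_width=0.2, r_max=8.0)
        mid = (r > 2.0) & (r < 4.0)
        assert np.all(np.abs(g[mid] - 1.0) < 0.05)

    def test_doubling_density_leaves_g_unchanged(self):
        t1, _ = make_uniform_gas(800, (30.0, 30.0, 30.0), 60, seed=12)
        t2, _ = make_uniform_gas(1600, (30.0, 30.0, 30.0), 60, seed=12)
        r1, g1 = rdf(t1, "all", "all", bin_width=0.25, r_max=8.0)
        r2, g2 = rdf(t2, "all", "all", bin_width=0.25, r_max=8.0)
        mid = (r1 > 2.0) & (r1 < 4.0)
        np.testing.assert_allclose(g1[mid], g2[mid], atol=0.12)
        assert abs(g1[mid].mean() - g2[mid].mean()) < 0.03

    def test_excluded_volume_zero_below_contact(self):
        """Plant a target cloud with nothing within 3 Å of the reference."""
        rng = np.random.default_rng(13)
        n = 400
        box = np.array([30.0, 30.0, 30.0])
        ref_pos = box / 2
        pts = []
        while len(pts) < n:
            cand = rng.random(3) * box
            if np.linalg.norm(cand - ref_pos) >= 3.0:
                pts.append(cand)
        frames = np.array([np.vstack([ref_pos, pts])])
        from lcpscan.structures import Atom, MolecularStructure

        atoms = [Atom(i + 1, "O", "O", "GAS", i + 1, "A", p) for i, p in enumerate(frames[0])]
        traj = Trajectory(MolecularStructure(atoms), frames, box=box[None])
        r, g = rdf(traj, "resnum 1", "not resnum 1", bin_width=0.2, r_max=6.0)
        assert np.all(g[r < 2.9] == 0.0)
        assert g[(r > 3.2) & (r < 5.0)].sum() > 0

    def test_counts_match_brute_force_on_one_frame(self):
        traj, _ = make_uniform_gas(60, (15.0, 15.0, 15.0), 1, seed=14)
        r, g = rdf(traj, "all", "all", bin_width=0.5, r_max=6.0)
        pts = traj.frames[0]
        box = traj.box[0]
        edges = np.arange(0.0, 6.0 + 0.5, 0.5)
        counts = np.zeros(len(edges) - 1)
        for i in range(60):
            for j in range(60):
                if i == j:
                    continue
                d = pts[i] - pts[j]
                d -= box * np.round(d / box)
                dist = np.linalg.norm(d)
                if dist < 6.0:
                    counts[min(int(dist / 0.5), len(counts) - 1)] += 1
        rho = 60 / box.prod()
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        brute = counts / (60 * shell * rho)
        np.testing.assert_allclose(g, brute, atol=1e-9)

    def test_missing_box_and_density_rejected(self, ca_protein):
        traj = Trajectory(ca_protein, np.tile(ca_protein.coords, (2, 1, 1)))
        with pytest.raises(ValueError, match="density"):
            rdf(traj, "all", "all")


class TestSmoothing:
    def test_window_one_is_identity(self, ca_protein):
        rng = np.random.default_rng(15)
        frames = rng.normal(0, 1, (10, 50, 3)) + ca_protein.coords[None]
        traj = Trajectory(ca_protein, frames)
        np.testing.assert_array_equal(smooth_trajectory(traj, 1).frames, frames)

    def test_constant_trajectory_unchanged(self, ca_protein):
        frames = np.tile(ca_protein.coords, (8, 1, 1))
        traj = Trajectory(ca_protein, frames)
        np.testing.assert_allclose(smooth_trajectory(traj, 5).frames, frames, atol=1e-12)

    def test_sinusoid_attenuated_by_dirichlet_factor(self, ca_protein):
        """Interior frames of a sinusoidal coordinate are scaled by the
        analytic moving-average factor sin(Mw/2) / (M sin(w/2))."""
        n, w, omega = 400, 5, 0.3
        base = np.tile(ca_protein.coords, (n, 1, 1))
        t = np.arange(n)
        base[:, 0, 0] += np.sin(omega * t)
        sm = smooth_trajectory(Trajectory(ca_protein, base), w)
        factor = np.sin(w * omega / 2) / (w * np.sin(omega / 2))
        interior = slice(w // 2, n - w // 2)
        expect = ca_protein.coords[0, 0] + factor * np.sin(omega * t[interior])
        np.testing.assert_allclose(sm.frames[interior, 0, 0], expect, atol=1e-6)

    def test_frame_count_preserved_and_even_window_rejected(self, ca_protein):
        frames = np.tile(ca_protein.coords, (7, 1, 1))
        traj = Trajectory(ca_protein, frames)
        assert smooth_trajectory(traj, 3).n_frames == 7
        with pytest.raises(ValueError):
            smooth_trajectory(traj, 4)

    def test_metrics_invariant_under_rigid_motion_of_all_frames(self, ca_protein):
        """RMSF is unchanged when one rigid transform is applied to every
        frame."""
        rng = np.random.default_rng(16)
        frames = ca_protein.coords[None] + rng.normal(0, 0.3, (50, 50, 3))
        traj = Trajectory(ca_protein, frames)
        base = np.array(list(rmsf(traj).values()))
        R = random_rotation(17)
        moved = Trajectory(ca_protein, frames @ R.T + np.array([3.0, -1.0, 2.0]))
        np.testing.assert_allclose(np.array(list(rmsf(moved).values())), base, atol=1e-8)
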
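"""Covariance PCA: superposition, eigenmodes, projections, reconstruction."""

import numpy as np
import pandas as pd
import pytest

from mhcplast.essential import (
    CovarianceModel,
    block_rmsf,
    build_covariance,
    cumulative_variance,
    eigendecompose,
    mode_extremes,
    project,
    reconstruct,
    superpose,
)
from mhcplast.io_formats import TrajectoryEnsemble
from mhcplast.synthetic import TrajectoryRecipe, generate_trajectory
from tests.conftest import make_orthonormal_modes


def brute_force_eigh(matrix, n_iter=20_000):
    """Independent oracle: power iteration with deflation (descending)."""
    m = matrix.astype(float).copy()
    n = m.shape[0]
    rng = np.random.default_rng(0)
    evals, evecs = [], []
    shift = np.abs(m).sum() + 1.0        # make the spectrum positive
    work = m + shift * np.eye(n)
    for _ in range(n):
        v = rng.standard_normal(n)
        for _ in range(n_iter):
            v = work @ v
            v /= np.linalg.norm(v)
        lam = v @ work @ v
        evals.append(lam - shift)
        evecs.append(v)
        work = work - lam * np.outer(v, v)
    return np.array(evals), np.array(evecs).T


def rigid_rotate(coords, angle_deg, axis=2):
    theta = np.deg2rad(angle_deg)
    rot = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    rot[i, i] = rot[j, j] = np.cos(theta)
    rot[i, j] = -np.sin(theta)
    rot[j, i] = np.sin(theta)
    return coords @ rot.T


def unit_mass_traj(coords, dt=5.0):
    n = coords.shape[1]
    meta = pd.DataFrame(
        {"res_id": np.arange(1, n + 1), "res_name": ["ALA"] * n,
         "atom_name": ["CA"] * n, "mass": np.ones(n)}
    )
    return TrajectoryEnsemble(coords=coords, atom_meta=meta, dt=dt)


class TestSuperpose:
    def test_rotated_frame_fits_back(self):
        rng = np.random.default_rng(3)
        ref = rng.standard_normal((8, 3))
        frames = np.stack([ref, rigid_rotate(ref, 90.0)])
        fitted = superpose(unit_mass_traj(frames), reference=ref)
        rmsd = np.sqrt(((fitted.coords[1] - ref) ** 2).sum(-1).mean())
        assert rmsd < 1e-6

    def test_random_rigid_motions_collapse_to_one_structure(self):
        rng = np.random.default_rng(4)
        ref = rng.standard_normal((6, 3))
        frames = []
        for k in range(20):
            moved = rigid_rotate(ref, float(rng.uniform(0, 360)), axis=k % 3)
            frames.append(moved + rng.uniform(-3, 3, size=3))
        fitted = superpose(unit_mass_traj(np.stack(frames)), reference=ref)
        spread = fitted.coords.std(axis=0).max()
        assert spread < 1e-8

    def test_idempotent_on_superposed_data(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        small = unit_mass_traj(traj.coords[:200].copy())
        once = superpose(small)
        twice = superpose(once)
        assert np.abs(twice.coords - once.coords).max() < 1e-8

    def test_collinear_reference_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        traj = unit_mass_traj(np.stack([line, line]))
        with pytest.raises(ValueError, match="collinear"):
            superpose(traj, reference=line)

    def test_fit_reduces_rmsd_to_reference(self):
        rng = np.random.default_rng(8)
        ref = rng.standard_normal((10, 3))
        frames = np.stack(
            [rigid_rotate(ref + 0.05 * rng.standard_normal(ref.shape), 40.0 * k)
             for k in range(5)]
        )
        traj = unit_mass_traj(frames)
        fitted = superpose(traj, reference=ref)
        for t in range(5):
            before = np.sqrt(((traj.coords[t] - ref) ** 2).sum(-1).mean())
            after = np.sqrt(((fitted.coords[t] - ref) ** 2).sum(-1).mean())
            assert after <= before + 1e-12


class TestBuildCovariance:
    def test_single_atom_hop_variance(self, single_atom_hop):
        cov = build_covariance(single_atom_hop, selection="all")
        expected = np.zeros((3, 3))
        expected[0, 0] = 1.0          # <x^2> - <x>^2 = 2 - 1
        assert np.allclose(cov.matrix, expected)

    def test_static_trajectory_gives_zero_matrix(self):
        coords = np.broadcast_to(np.arange(9.0).reshape(3, 3), (5, 3, 3)).copy()
        cov = build_covariance(unit_mass_traj(coords), selection="all")
        assert np.allclose(cov.matrix, 0.0)

    def test_anticorrelated_pair_has_negative_covariance(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 0, 0] = [+1, -1, +1, -1]
        coords[:, 1, 0] = [-1, +1, -1, +1]
        cov = build_covariance(unit_mass_traj(coords), selection="all")
        assert cov.matrix[0, 3] < 0        # x of atom 1 vs x of atom 2

    def test_mass_weighting_scales_sqrt_mass_product(self, single_atom_hop):
        heavy = TrajectoryEnsemble(
            coords=single_atom_hop.coords,
            atom_meta=single_atom_hop.atom_meta.assign(mass=[4.0]),
            dt=5.0,
        )
        cov = build_covariance(heavy, selection="all")
        assert cov.matrix[0, 0] == pytest.approx(4.0)   # sqrt(4*4) * 1

    def test_empty_selection_rejected(self, single_atom_hop):
        with pytest.raises(ValueError, match="empty"):
            build_covariance(single_atom_hop, selection=np.array([], dtype=int))


class TestEigendecompose:
    def test_known_diagonal_spectrum(self, single_atom_hop):
        cov = build_covariance(single_atom_hop, selection="all")
        cov.matrix = np.diag([3.0, 1.0, 0.0])
        modes = eigendecompose(cov)
        assert np.allclose(modes.eigenvalues, [3.0, 1.0, 0.0])
        assert np.allclose(np.abs(modes.eigenvectors), np.eye(3))

    def test_reconstruction_identity(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        cov = build_covariance(traj, selection="all")
        modes = eigendecompose(cov)
        rebuilt = modes.eigenvectors @ np.diag(modes.eigenvalues) @ modes.eigenvectors.T
        assert np.abs(rebuilt - cov.matrix).max() < 1e-8

    @pytest.mark.parametrize("n", [3, 6])
    def test_agrees_with_power_iteration_oracle(self, n):
        rng = np.random.default_rng(n)
        a = rng.standard_normal((n, n))
        sym = (a + a.T) / 2
        n_atoms = n // 3
        cov = CovarianceModel(
            matrix=sym,
            mean_coords=np.zeros((n_atoms, 3)),
            masses=np.ones(n_atoms),
            selection=np.arange(n_atoms),
            atom_meta=pd.DataFrame(
                {"res_id": np.arange(1, n_atoms + 1), "res_name": ["ALA"] * n_atoms,
                 "atom_name": ["CA"] * n_atoms, "mass": np.ones(n_atoms)}
            ),
        )
        modes = eigendecompose(cov)
        evals_oracle, evecs_oracle = brute_force_eigh(sym)
        assert np.allclose(modes.eigenvalues, evals_oracle, atol=1e-6)
        for k in range(n):
            dot = abs(evecs_oracle[:, k] @ modes.eigenvectors[:, k])
            assert dot > 1 - 1e-6

    def test_trace_conservation(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        cov = build_covariance(traj, selection="all")
        modes = eigendecompose(cov)
        assert modes.eigenvalues.sum() == pytest.approx(
            np.trace(cov.matrix), rel=1e-8
        )

    def test_planted_two_mode_recovery(self, two_mode_trajectory):
        traj, planted, stddevs = two_mode_trajectory
        modes = eigendecompose(build_covariance(traj, selection="all"))
        for i in range(2):
            cos = abs(planted[i] @ modes.eigenvectors[:, i])
            assert np.degrees(np.arccos(min(cos, 1.0))) < 5.0
            assert modes.eigenvalues[i] == pytest.approx(stddevs[i] ** 2, rel=0.10)

    def test_sign_convention_deterministic(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        modes = eigendecompose(build_covariance(traj, selection="all"))
        for col in modes.eigenvectors.T:
            assert col[np.abs(col).argmax()] > 0


class TestProjection:
    def test_variance_equals_eigenvalue(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        modes = eigendecompose(build_covariance(traj, selection="all"))
        proj = project(traj, modes, np.arange(6))
        for k in range(6):
            if modes.eigenvalues[k] > 1e-12:
                assert proj.values[:, k].var() == pytest.approx(
                    modes.eigenvalues[k], rel=1e-8
                )

    def test_mean_structure_projects_to_zero(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        modes = eigendecompose(build_covariance(traj, selection="all"))
        mean_traj = unit_mass_traj(modes.mean_coords[None].copy())
        proj = project(mean_traj, modes, 0)
        assert abs(proj.values[0, 0]) < 1e-10

    def test_projections_uncorrelated_across_modes(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        modes = eigendecompose(build_covariance(traj, selection="all"))
        proj = project(traj, modes, np.array([0, 1]))
        cross = np.cov(proj.values.T, bias=True)[0, 1]
        assert abs(cross) < 1e-8 * modes.eigenvalues[0]

    def test_selection_identity_enforced(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        modes = eigendecompose(build_covariance(traj, selection="all"))
        other = TrajectoryEnsemble(
            coords=traj.coords[:, :5],
            atom_meta=traj.atom_meta.iloc[:5].assign(atom_name="CB"),
            dt=traj.dt,
        )
        with pytest.raises(ValueError, match="selection mismatch"):
            project(other, modes, 0)


class TestReconstruct:
    def test_all_modes_is_identity(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        small = unit_mass_traj(traj.coords[:100].copy())
        modes = eigendecompose(build_covariance(small, selection="all"))
        proj = project(small, modes, np.arange(30))
        back = reconstruct(proj, modes)
        assert np.abs(back.coords - small.coords).max() < 1e-6

    def test_zero_projection_gives_mean(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        modes = eigendecompose(build_covariance(traj, selection="all"))
        from mhcplast.essential import ProjectionSeries
        zero = ProjectionSeries(values=np.zeros((1, 1)), mode_indices=np.array([0]))
        back = reconstruct(zero, modes)
        assert np.allclose(back.coords[0], modes.mean_coords)

    def test_one_mode_reconstruction_variance(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        modes = eigendecompose(build_covariance(traj, selection="all"))
        proj = project(traj, modes, 0)
        back = reconstruct(proj, modes)
        flat = back.coords.reshape(back.n_frames, -1)
        total_var = ((flat - flat.mean(0)) ** 2).sum(1).mean()
        assert total_var == pytest.approx(modes.eigenvalues[0], rel=1e-8)

    def test_mass_weighting_inverts(self):
        rng = np.random.default_rng(11)
        coords = rng.standard_normal((50, 4, 3)) * 0.1
        meta = pd.DataFrame(
            {"res_id": [1, 2, 3, 4], "res_name": ["ALA"] * 4,
             "atom_name": ["CA"] * 4, "mass": [12.0, 14.0, 12.0, 16.0]}
        )
        traj = TrajectoryEnsemble(coords=coords, atom_meta=meta, dt=5.0)
        modes = eigendecompose(build_covariance(traj, selection="all"))
        proj = project(traj, modes, np.arange(12))
        back = reconstruct(proj, modes)
        assert np.abs(back.coords - coords).max() < 1e-6


class TestCumulativeVariance:
    def test_known_fractions(self, single_atom_hop):
        cov = build_covariance(single_atom_hop, selection="all")
        cov.matrix = np.diag([3.0, 1.0, 0.0])
        modes = eigendecompose(cov)
        assert cumulative_variance(modes, 0) == 0.0
        assert cumulative_variance(modes, 1) == pytest.approx(0.75)
        assert cumulative_variance(modes, 3) == pytest.approx(1.0)

    def test_non_decreasing_in_k(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        modes = eigendecompose(build_covariance(traj, selection="all"))
        fractions = [cumulative_variance(modes, k) for k in range(31)]
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))


class TestModeExtremes:
    def test_planted_mode_displacement_parallel(self, two_mode_trajectory):
        traj, planted, _ = two_mode_trajectory
        modes = eigendecompose(build_covariance(traj, selection="all"))
        proj = project(traj, modes, 0)
        ext = mode_extremes(proj, modes, 0)
        disp = ext.displacement.reshape(-1)
        cos = abs(disp @ planted[0]) / np.linalg.norm(disp)
        assert cos > 0.99

    def test_extremes_straddle_mean(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        modes = eigendecompose(build_covariance(traj, selection="all"))
        proj = project(traj, modes, 0)
        ext = mode_extremes(proj, modes, 0)
        mid = (ext.min_structure + ext.max_structure) / 2
        p = proj.values[:, 0]
        balance = abs(p.max() + p.min()) / (p.max() - p.min())
        assert np.abs(mid - modes.mean_coords).max() <= (
            balance * np.abs(ext.displacement).max() + 1e-9
        )

    def test_zero_variance_mode_has_identical_extremes(self, single_atom_hop):
        modes = eigendecompose(build_covariance(single_atom_hop, selection="all"))
        proj = project(single_atom_hop, modes, 2)   # null direction
        ext = mode_extremes(proj, modes, 2)
        assert np.allclose(ext.min_structure, ext.max_structure)


class TestBlockRmsf:
    def test_static_trajectory_is_zero(self):
        coords = np.broadcast_to(np.arange(12.0).reshape(4, 3), (100, 4, 3)).copy()
        rmsf = block_rmsf(unit_mass_traj(coords), block_ns=0.05)
        assert np.allclose(rmsf, 0.0)

    def test_single_block_equals_whole_trajectory(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        small = unit_mass_traj(traj.coords[:500].copy())
        whole = block_rmsf(small, block_ns=small.n_frames * small.dt / 1000.0)
        dev = small.coords - small.coords.mean(0)
        expected = np.sqrt((dev ** 2).sum(-1).mean(0))
        assert whole.shape[0] == 1
        assert np.allclose(whole[0], expected)

    def test_stationary_blocks_are_stable(self, two_mode_trajectory):
        traj, _, _ = two_mode_trajectory
        rmsf = block_rmsf(traj, block_ns=traj.dt * 1000 / 1000.0)  # 1000 frames/block
        spread = np.abs(rmsf - rmsf.mean(0)).max()
        assert spread < 0.10 * rmsf.mean()
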
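"""Essential dynamics: PCA of backbone atomic fluctuations.

The pipeline is: remove rigid-body motion by mass-weighted least-squares
superposition, build the mass-weighted covariance matrix of the atomic
fluctuations

    C_ab = sqrt(m_a m_b) ( <x_a x_b> - <x_a><x_b> ),

eigendecompose it (modes sorted by descending eigenvalue; the eigenvalue is
the mean-square fluctuation along its mode), project frames onto modes to
obtain principal components p_i(t) = mu_i . w(x(t) - <x>), and transform
projections back to Cartesian coordinates for visualisation.  Mass weighting
uses w_a = sqrt(m_a) per coordinate and is inverted on reconstruction; unit
masses reduce everything to the unweighted case.

Also provides the block-RMSF stability check: per-atom root-mean-square
fluctuation about the block mean within consecutive time blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import TrajectoryEnsemble

__all__ = [
    "CovarianceModel",
    "ModeSet",
    "ProjectionSeries",
    "ModeExtremes",
    "select_atoms",
    "superpose",
    "build_covariance",
    "eigendecompose",
    "project",
    "reconstruct",
    "cumulative_variance",
    "mode_extremes",
    "block_rmsf",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def select_atoms(traj: TrajectoryEnsemble, selection: str | np.ndarray = "backbone") -> np.ndarray:
    """Resolve a selection to atom indices.

    'backbone' keeps atoms named N/CA/C/O, 'ca' keeps CA only, 'all' keeps
    everything; an integer array passes through.
    """
    if isinstance(selection, str):
        names = traj.atom_meta["atom_name"].to_numpy()
        if selection == "backbone":
            idx = np.nonzero(np.isin(names, BACKBONE_ATOMS))[0]
        elif selection == "ca":
            idx = np.nonzero(names == "CA")[0]
        elif selection == "all":
            idx = np.arange(traj.n_atoms)
        else:
            raise ValueError(f"unknown selection {selection!r}")
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    return idx


@dataclass
class CovarianceModel:
    """Mass-weighted covariance of atomic fluctuations over a selection."""

    matrix: np.ndarray              # (3n, 3n), nm^2 (mass-weighted: nm^2 amu)
    mean_coords: np.ndarray         # (n, 3) nm
    masses: np.ndarray              # (n,) amu
    selection: np.ndarray           # atom indices into the source trajectory
    atom_meta: pd.DataFrame         # metadata of the selected atoms

    def __post_init__(self) -> None:
        scale = max(np.abs(self.matrix).max(), 1.0)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10 * scale):
            raise ValueError("covariance matrix must be symmetric")


@dataclass
class ModeSet:
    """Eigenvectors (columns, orthonormal) and eigenvalues (descending)."""

    eigenvectors: np.ndarray        # (3n, 3n)
    eigenvalues: np.ndarray         # (3n,) descending
    mean_coords: np.ndarray         # (n, 3)
    masses: np.ndarray
    selection: np.ndarray
    atom_meta: pd.DataFrame

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def _check_compatible(self, traj: TrajectoryEnsemble, selection_idx: np.ndarray) -> None:
        """Projections of two ensembles are comparable only on the same
        reference selection; enforce identity of the selected atom names."""
        if selection_idx.size and selection_idx.max() >= traj.n_atoms:
            raise ValueError(
                "selection mismatch: modes were built on a different atom subset"
            )
        names = traj.atom_meta["atom_name"].to_numpy()[selection_idx]
        res = traj.atom_meta["res_id"].to_numpy()[selection_idx]
        own_names = self.atom_meta["atom_name"].to_numpy()
        own_res = self.atom_meta["res_id"].to_numpy()
        if len(names) != len(own_names) or (names != own_names).any() or (res != own_res).any():
            raise ValueError(
                "selection mismatch: modes were built on a different atom subset"
            )


@dataclass
class ProjectionSeries:
    """Principal components p_i(t) for selected modes (nm sqrt(amu))."""

    values: np.ndarray              # (T, k)
    mode_indices: np.ndarray        # (k,) 0-based

    def component(self, mode_index: int) -> np.ndarray:
        k = int(np.nonzero(self.mode_indices == mode_index)[0][0])
        return self.values[:, k]


@dataclass
class ModeExtremes:
    """Structures at the observed extremes of one principal component."""

    min_structure: np.ndarray       # (n, 3) nm
    max_structure: np.ndarray
    displacement: np.ndarray        # (n, 3) Cartesian, max minus min
    raw_displacement: np.ndarray    # (3n,) mass-weighted


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def superpose(
    traj: TrajectoryEnsemble,
    reference: np.ndarray | None = None,
    selection: str | np.ndarray = "all",
    mass_weighted: bool = True,
    max_iter: int = 20,
    tol: float = 1e-12,
) -> TrajectoryEnsemble:
    """Least-squares fit every frame to a reference, removing rigid-body motion.

    The rotation/translation is computed over ``selection`` with mass weights
    and applied to all atoms.  With ``reference=None`` frames are fitted to
    the ensemble mean, iterating (fit, recompute mean, refit) until the mean
    stops moving — without a reference the mean itself depends on the fit, so
    a single pass is not a fixed point.
    """
    idx = select_atoms(traj, selection)
    weights = traj.masses[idx] if mass_weighted else np.ones(idx.size)
    iterations = 1 if reference is not None else max_iter
    ref_sel = reference[idx] if reference is not None and reference.shape[0] == traj.n_atoms \
        else (reference if reference is not None else traj.coords[:, idx].mean(0))
    if ref_sel.shape[0] != idx.size:
        raise ValueError("reference atom set must match the trajectory selection")
    sing = np.linalg.svd(ref_sel - ref_sel.mean(0), compute_uv=False)
    if sing[1] < 1e-10 * max(sing[0], 1e-30):
        raise ValueError("degenerate (collinear) reference structure")
    coords = traj.coords.copy()
    for _ in range(iterations):
        for t in range(coords.shape[0]):
            # weighted Kabsch on the selection; transform applied to all atoms
            w = weights[:, None]
            fc = (coords[t, idx] * w).sum(0) / weights.sum()
            rc = (ref_sel * w).sum(0) / weights.sum()
            x = coords[t, idx] - fc
            h = (x * w).T @ (ref_sel - rc)
            u, s, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(u @ vt))
            rot = u @ np.diag([1.0, 1.0, d]) @ vt
            coords[t] = (coords[t] - fc) @ rot + rc
        if reference is None:
            new_ref = coords[:, idx].mean(0)
            converged = np.abs(new_ref - ref_sel).max() < tol
            ref_sel = new_ref
            if converged:
                break
    return TrajectoryEnsemble(
        coords=coords, atom_meta=traj.atom_meta, dt=traj.dt, labels=traj.labels
    )


# ---------------------------------------------------------------------------
# covariance and eigenmodes
# ---------------------------------------------------------------------------

def build_covariance(
    traj: TrajectoryEnsemble, selection: str | np.ndarray = "backbone"
) -> CovarianceModel:
    """Mass-weighted variance-covariance matrix of the selected coordinates.

    The trajectory is assumed superposed.  Uses the ensemble (population)
    average, so the eigenvalues are exactly the mean-square fluctuations.
    """
    traj.require_statistics()
    idx = select_atoms(traj, selection)
    x = traj.coords[:, idx].reshape(traj.n_frames, -1)      # (T, 3n)
    mean = x.mean(0)
    xc = x - mean
    cov = xc.T @ xc / traj.n_frames
    masses = traj.masses[idx]
    w = np.sqrt(np.repeat(masses, 3))
    cov *= np.outer(w, w)
    return CovarianceModel(
        matrix=cov,
        mean_coords=mean.reshape(-1, 3),
        masses=masses,
        selection=idx,
        atom_meta=traj.atom_meta.iloc[idx].reset_index(drop=True),
    )


def eigendecompose(cov: CovarianceModel) -> ModeSet:
    """Symmetric eigendecomposition C = P D P^T, modes by descending eigenvalue.

    Sign convention: each eigenvector's largest-magnitude component is made
    positive, so exported mode vectors are reproducible across runs.
    """
    evals, evecs = np.linalg.eigh(cov.matrix)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    flip = evecs[np.abs(evecs).argmax(axis=0), np.arange(evecs.shape[1])] < 0
    evecs[:, flip] *= -1.0
    return ModeSet(
        eigenvectors=evecs,
        eigenvalues=evals,
        mean_coords=cov.mean_coords,
        masses=cov.masses,
        selection=cov.selection,
        atom_meta=cov.atom_meta,
    )


def project(
    traj: TrajectoryEnsemble,
    modes: ModeSet,
    mode_indices: int | np.ndarray = 0,
) -> ProjectionSeries:
    """Project frames onto principal modes: p_i(t) = mu_i . w (x(t) - <x>).

    The variance of p_i over the ensemble used to build the modes equals the
    i-th eigenvalue.  The trajectory must be superposed in the same frame as
    the mode set and carry the same atom selection.
    """
    idx = modes.selection
    modes._check_compatible(traj, idx)
    w = np.sqrt(np.repeat(modes.masses, 3))
    x = traj.coords[:, idx].reshape(traj.n_frames, -1)
    y = (x - modes.mean_coords.reshape(-1)) * w
    mode_indices = np.atleast_1d(np.asarray(mode_indices, dtype=int))
    values = y @ modes.eigenvectors[:, mode_indices]
    return ProjectionSeries(values=values, mode_indices=mode_indices)


def reconstruct(proj: ProjectionSeries, modes: ModeSet) -> TrajectoryEnsemble:
    """Back-transform principal components to Cartesian coordinates:
    x'(t) = <x> + w^-1 sum_i p_i(t) mu_i.  With all 3n modes this is the
    identity on the superposed input."""
    w = np.sqrt(np.repeat(modes.masses, 3))
    disp = proj.values @ modes.eigenvectors[:, proj.mode_indices].T / w
    coords = modes.mean_coords.reshape(-1) + disp
    n_atoms = modes.mean_coords.shape[0]
    return TrajectoryEnsemble(
        coords=coords.reshape(-1, n_atoms, 3),
        atom_meta=modes.atom_meta,
        dt=1.0,
    )


def cumulative_variance(modes: ModeSet, k: int) -> float:
    """Fraction of total variance carried by the first k modes."""
    if k < 0:
        raise ValueError("k must be >= 0")
    total = modes.total_variance
    if total == 0:
        return 0.0
    return float(modes.eigenvalues[:k].sum() / total)


def mode_extremes(proj: ProjectionSeries, modes: ModeSet, mode_index: int) -> ModeExtremes:
    """Reconstructed structures at the min and max observed projection.

    The per-atom displacement between extremes is the porcupine-plot datum;
    both the Cartesian (mass-weighting inverted) and the raw mass-weighted
    displacement vectors are reported.
    """
    p = proj.component(mode_index)
    w = np.sqrt(np.repeat(modes.masses, 3))
    mu = modes.eigenvectors[:, mode_index]
    mean_flat = modes.mean_coords.reshape(-1)
    lo, hi = float(p.min()), float(p.max())
    min_structure = (mean_flat + lo * mu / w).reshape(-1, 3)
    max_structure = (mean_flat + hi * mu / w).reshape(-1, 3)
    return ModeExtremes(
        min_structure=min_structure,
        max_structure=max_structure,
        displacement=max_structure - min_structure,
        raw_displacement=(hi - lo) * mu,
    )


# ---------------------------------------------------------------------------
# stability check
# ---------------------------------------------------------------------------

def block_rmsf(
    traj: TrajectoryEnsemble,
    block_ns: float,
    selection: str | np.ndarray = "all",
) -> np.ndarray:
    """Per-atom RMSF about the block mean within consecutive time blocks.

    The trajectory is split into consecutive blocks of ``block_ns``
    nanoseconds (a trailing partial block is dropped; if the block exceeds
    the trajectory a single whole-trajectory block is used).  Returns an
    (n_blocks, n_atoms) array in nm.  For a stationary trajectory the
    between-block spread is small — the stability diagnostic.
    """
    traj.require_statistics()
    idx = select_atoms(traj, selection)
    n_per = int(round(block_ns * 1000.0 / traj.dt))
    if n_per <= 1 or n_per > traj.n_frames:
        n_per = traj.n_frames
    n_blocks = traj.n_frames // n_per
    out = np.empty((n_blocks, idx.size))
    for b in range(n_blocks):
        block = traj.coords[b * n_per:(b + 1) * n_per, idx]
        dev = block - block.mean(0)
        out[b] = np.sqrt((dev ** 2).sum(-1).mean(0))
    return out
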
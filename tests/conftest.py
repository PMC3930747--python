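"""Shared fixtures: small synthetic trajectories and alignments."""

import numpy as np
import pandas as pd
import pytest

from mhcplast.io_formats import TrajectoryEnsemble
from mhcplast.synthetic import TrajectoryRecipe, generate_trajectory


def make_orthonormal_modes(n3: int, k: int, seed: int = 0) -> np.ndarray:
    """k mutually orthonormal random 3N-vectors (rows)."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n3, k)))
    return q.T


@pytest.fixture
def two_mode_trajectory():
    """10-atom trajectory with two planted modes (0.3 and 0.1 nm) over
    isotropic 0.01 nm noise; signal-to-noise 30 and 10."""
    rng = np.random.default_rng(7)
    n_atoms = 10
    modes = make_orthonormal_modes(3 * n_atoms, 2, seed=7)
    recipe = TrajectoryRecipe(
        reference_coords=rng.standard_normal((n_atoms, 3)),
        modes=modes,
        mode_stddevs=np.array([0.3, 0.1]),
        noise_stddev=0.01,
        n_frames=10_000,
        seed=7,
    )
    return generate_trajectory(recipe), modes, np.array([0.3, 0.1])


@pytest.fixture
def single_atom_hop():
    """One unit-mass atom alternating between (0,0,0) and (2,0,0)."""
    coords = np.zeros((2, 1, 3))
    coords[1, 0, 0] = 2.0
    meta = pd.DataFrame(
        {"res_id": [1], "res_name": ["ALA"], "atom_name": ["CA"], "mass": [1.0]}
    )
    return TrajectoryEnsemble(coords=coords, atom_meta=meta, dt=5.0)
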
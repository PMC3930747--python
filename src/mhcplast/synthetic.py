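"""Synthetic trajectories and alignments with the statistical structure the
downstream analyses assume.

Trajectories are drawn as a mean structure plus a few prescribed orthonormal
collective modes with given amplitudes and isotropic Gaussian noise — the
generative model that covariance PCA inverts.  Dihedral fixtures are
wrapped-normal angle series, whose circular standard deviation equals the
underlying linear sigma analytically.  Alignments mix background-distributed
columns, strongly conserved columns and one planted coevolving residue group
driven by a shared latent binary state — the simplest mechanism that yields a
rank-1 dominant coupling mode.

All generators are pure functions of (recipe, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AMINO_ACIDS, AlignmentMatrix, TrajectoryEnsemble, map_columns_to_reference

__all__ = [
    "TrajectoryRecipe",
    "MsaRecipe",
    "generate_trajectory",
    "generate_dihedral_series",
    "generate_msa",
    "build_backbone",
    "backbone_trajectory",
    "HEAVY_CHAIN_SECTOR",
    "HEAVY_CHAIN_POLYMORPHISMS",
    "heavy_chain_msa_recipe",
    "polymorphic_variant",
]


# ---------------------------------------------------------------------------
# trajectory generator
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryRecipe:
    """Recipe for a Gaussian mode-plus-noise trajectory.

    reference_coords: (N, 3) mean structure in nm.
    modes: (k, 3N) mutually orthonormal collective displacement directions.
    mode_stddevs: k amplitudes in nm (standard deviation along each mode).
    noise_stddev: isotropic per-coordinate noise in nm.
    """

    reference_coords: np.ndarray
    modes: np.ndarray
    mode_stddevs: np.ndarray
    noise_stddev: float = 0.0
    n_frames: int = 1000
    dt: float = 5.0
    seed: int = 0
    atom_meta: pd.DataFrame | None = None

    def validate(self) -> None:
        ref = np.asarray(self.reference_coords, dtype=float)
        modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        stddevs = np.atleast_1d(np.asarray(self.mode_stddevs, dtype=float))
        n3 = ref.size
        if modes.shape[1] != n3:
            raise ValueError(f"modes must be {n3}-vectors, got {modes.shape[1]}")
        if modes.shape[0] > n3:
            raise ValueError("cannot have more modes than coordinates")
        if stddevs.shape[0] != modes.shape[0]:
            raise ValueError("one stddev per mode required")
        if (stddevs < 0).any() or self.noise_stddev < 0:
            raise ValueError("stddevs must be >= 0")
        gram = modes @ modes.T
        if not np.allclose(gram, np.eye(modes.shape[0]), atol=1e-8):
            raise ValueError("modes must be mutually orthonormal (tolerance 1e-8)")


def _default_atom_meta(n_atoms: int) -> pd.DataFrame:
    # unit masses by default so mass-weighting tests are isolated to
    # dedicated cases
    return pd.DataFrame(
        {
            "res_id": np.arange(1, n_atoms + 1),
            "res_name": ["ALA"] * n_atoms,
            "atom_name": ["CA"] * n_atoms,
            "mass": np.ones(n_atoms),
        }
    )


def generate_trajectory(recipe: TrajectoryRecipe) -> TrajectoryEnsemble:
    """Draw frames x_t = ref + sum_i z_ti * s_i * mode_i + eps_t.

    z and eps are independent standard-normal draws; the output is
    deterministic under a fixed recipe seed.  The sample covariance
    converges to sum_i s_i^2 mode_i mode_i^T + sigma^2 I.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    ref = np.asarray(recipe.reference_coords, dtype=float)
    n_atoms = ref.shape[0]
    modes = np.atleast_2d(np.asarray(recipe.modes, dtype=float))
    stddevs = np.atleast_1d(np.asarray(recipe.mode_stddevs, dtype=float))
    z = rng.standard_normal((recipe.n_frames, modes.shape[0]))
    disp = (z * stddevs) @ modes                       # (T, 3N)
    if recipe.noise_stddev > 0:
        disp = disp + recipe.noise_stddev * rng.standard_normal(disp.shape)
    coords = ref[None, :, :] + disp.reshape(recipe.n_frames, n_atoms, 3)
    meta = recipe.atom_meta if recipe.atom_meta is not None else _default_atom_meta(n_atoms)
    return TrajectoryEnsemble(coords=coords, atom_meta=meta, dt=recipe.dt)


# ---------------------------------------------------------------------------
# dihedral fixtures
# ---------------------------------------------------------------------------

def wrap_degrees(angles: np.ndarray) -> np.ndarray:
    """Wrap angles into the interval (-180, 180]."""
    wrapped = np.mod(np.asarray(angles, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def generate_dihedral_series(
    n_frames: int, mean_deg: float, circ_stddev_deg: float, seed: int = 0
) -> np.ndarray:
    """Wrapped-normal angle series in degrees, reported in (-180, 180].

    For a wrapped normal with linear spread sigma the mean resultant length
    is R = exp(-sigma^2/2), so the circular standard deviation
    sqrt(-2 ln R) equals sigma exactly — the generator parameter is directly
    the statistic the flexibility analysis estimates.
    """
    rng = np.random.default_rng(seed)
    draws = mean_deg + circ_stddev_deg * rng.standard_normal(n_frames)
    return wrap_degrees(draws)


# ---------------------------------------------------------------------------
# backbone construction (internal coordinates)
# ---------------------------------------------------------------------------

# standard backbone geometry (Angstrom / degrees)
_BOND_N_CA = 0.1458   # nm
_BOND_CA_C = 0.1525
_BOND_C_N = 0.1329
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D so that |C-D| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = dihedral."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(chi), bond * np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi_deg: np.ndarray, psi_deg: np.ndarray, omega_deg: float = 180.0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Build N/CA/C backbone coordinates (nm) for given phi/psi angles.

    ``phi_deg[0]`` is ignored (the first residue has no phi) and
    ``psi_deg[-1]`` is ignored.  Returns (3R, 3) coordinates and matching
    atom metadata with physical backbone masses.
    """
    phi = np.asarray(phi_deg, dtype=float)
    psi = np.asarray(psi_deg, dtype=float)
    if phi.shape != psi.shape:
        raise ValueError("phi and psi must have equal length")
    n_res = phi.shape[0]
    coords = np.zeros((3 * n_res, 3))
    # first residue: N at origin, CA along x, C in the xy-plane
    coords[0] = [0.0, 0.0, 0.0]
    coords[1] = [_BOND_N_CA, 0.0, 0.0]
    ang = np.deg2rad(180.0 - _ANGLE_N_CA_C)
    coords[2] = coords[1] + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[3 * i - 3], coords[3 * i - 2], coords[3 * i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _BOND_C_N, _ANGLE_CA_C_N, psi[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, _BOND_N_CA, _ANGLE_C_N_CA, omega_deg)
        c_i = _place_atom(c_prev, n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi[i])
        coords[3 * i] = n_i
        coords[3 * i + 1] = ca_i
        coords[3 * i + 2] = c_i
    meta = pd.DataFrame(
        {
            "res_id": np.repeat(np.arange(1, n_res + 1), 3),
            "res_name": ["ALA"] * (3 * n_res),
            "atom_name": ["N", "CA", "C"] * n_res,
            "mass": [14.007, 12.011, 12.011] * n_res,
        }
    )
    return coords, meta


def backbone_trajectory(
    phi_series_deg: np.ndarray, psi_deg: np.ndarray, dt: float = 5.0
) -> TrajectoryEnsemble:
    """Trajectory whose frame t is the backbone built from ``phi_series_deg[t]``.

    Useful for planting known per-residue dihedral spreads: the phi angles
    recovered from the coordinates equal the input series (up to numerical
    rounding of the chain construction).
    """
    phi_series = np.atleast_2d(np.asarray(phi_series_deg, dtype=float))
    frames = []
    meta = None
    for phi in phi_series:
        coords, meta = build_backbone(phi, psi_deg)
        frames.append(coords)
    return TrajectoryEnsemble(coords=np.stack(frames), atom_meta=meta, dt=dt)


# ---------------------------------------------------------------------------
# alignment generator
# ---------------------------------------------------------------------------

#: planted coevolving group for the heavy-chain-like alignment emulation:
#: a compact set of 26 positions spanning the binding-domain helices, the
#: beta-sheet floor, the domain linker and the alpha-3 domain, including the
#: polymorphic positions 22 and 220
HEAVY_CHAIN_SECTOR = (
    22, 59, 60, 63, 66, 70, 71, 74, 96, 99, 114, 118, 122, 129, 133,
    143, 147, 150, 154, 177, 178, 179, 191, 220, 224, 264,
)

#: positions at which the two emulated alleles differ (eight polymorphisms,
#: of which exactly 22 and 220 belong to the planted sector)
HEAVY_CHAIN_POLYMORPHISMS = (22, 62, 79, 95, 113, 126, 155, 220)


def heavy_chain_msa_recipe(seed: int = 0, n_seqs: int = 141, n_positions: int = 274):
    """Recipe emulating an MHC I heavy-chain alignment: 141 sequences over a
    274-position gap-free query, a few strongly conserved anchor columns
    (disulfide cysteines, conserved aromatics) and one strongly coupled
    26-position group containing positions 22 and 220.

    This is a synthetic stand-in for a curated heavy-chain alignment; the
    coupling strength (0.9) is chosen so the planted group is cleanly
    detectable at this alignment depth, as a real sector would be.
    """
    return MsaRecipe(
        n_seqs=n_seqs,
        n_positions=n_positions,
        conserved_positions={
            7: ("Y", 0.90), 33: ("W", 0.95), 101: ("C", 0.98),
            164: ("C", 0.98), 203: ("W", 0.90),
        },
        sector_positions=list(HEAVY_CHAIN_SECTOR),
        sector_coupling=0.9,
        seed=seed,
    )


def polymorphic_variant(sequence: str, positions=HEAVY_CHAIN_POLYMORPHISMS) -> str:
    """Second-allele sequence: substitute each listed (1-based) position with
    a different residue, cycling the alphabet deterministically."""
    out = list(sequence)
    for pos in positions:
        current = out[pos - 1]
        out[pos - 1] = AMINO_ACIDS[(AMINO_ACIDS.index(current) + 1) % 20] \
            if current in AMINO_ACIDS else AMINO_ACIDS[0]
    return "".join(out)


@dataclass
class MsaRecipe:
    """Recipe for a synthetic alignment with a planted coevolving group.

    Non-sector, non-conserved columns are i.i.d. background draws.  Conserved
    columns emit their dominant symbol with the stated probability (background
    otherwise).  A per-sequence latent coin with P(heads) = sector_coupling
    decides whether the sequence carries the designated joint sector state at
    ALL sector positions; on tails the sector columns revert to background.
    Positions are 1-based.  The first sequence is the designated gap-free
    query.
    """

    n_seqs: int
    n_positions: int
    background_freqs: np.ndarray | None = None
    conserved_positions: dict[int, tuple[str, float]] = field(default_factory=dict)
    sector_positions: list[int] = field(default_factory=list)
    sector_coupling: float = 0.0
    sector_state: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.background_freqs is not None:
            q = np.asarray(self.background_freqs, dtype=float)
            if q.shape != (20,) or abs(q.sum() - 1.0) > 1e-12:
                raise ValueError("background_freqs must be 20 probabilities summing to 1")
        if not 0.0 <= self.sector_coupling <= 1.0:
            raise ValueError("sector_coupling must lie in [0, 1]")
        designated = set(self.conserved_positions) | set(self.sector_positions)
        if set(self.conserved_positions) & set(self.sector_positions):
            raise ValueError("conserved and sector position sets must be disjoint")
        if designated and max(designated) > self.n_positions:
            raise ValueError(
                f"designated position {max(designated)} exceeds n_positions={self.n_positions}"
            )
        if min(designated, default=1) < 1:
            raise ValueError("positions are 1-based")


def generate_msa(recipe: MsaRecipe) -> AlignmentMatrix:
    """Draw a synthetic alignment per the recipe; pure in (recipe, seed)."""
    recipe.validate()
    from .sca import BACKGROUND_FREQS  # default composition table

    rng = np.random.default_rng(recipe.seed)
    q = (
        np.asarray(recipe.background_freqs, dtype=float)
        if recipe.background_freqs is not None
        else BACKGROUND_FREQS
    )
    alphabet = np.array(list(AMINO_ACIDS), dtype="<U1")
    m, n_pos = recipe.n_seqs, recipe.n_positions
    grid = alphabet[rng.choice(20, size=(m, n_pos), p=q)]
    for pos, (symbol, prob) in recipe.conserved_positions.items():
        takes = rng.random(m) < prob
        grid[takes, pos - 1] = symbol
    if recipe.sector_positions:
        state = recipe.sector_state or "".join(
            AMINO_ACIDS[j % 20] for j in range(len(recipe.sector_positions))
        )
        if len(state) != len(recipe.sector_positions):
            raise ValueError("sector_state length must match sector_positions")
        coupled = rng.random(m) < recipe.sector_coupling
        for pos, symbol in zip(recipe.sector_positions, state):
            grid[coupled, pos - 1] = symbol
    ids = [f"query" if i == 0 else f"seq{i:04d}" for i in range(m)]
    aln = AlignmentMatrix(sequence_ids=ids, residues=grid, query_id="query")
    return map_columns_to_reference(aln, "query")
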
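"""Statistical coupling analysis (SCA) of a protein multiple sequence
alignment, yielding a protein sector.

The chain of computation:

1. Positional conservation as the Kullback-Leibler relative entropy
   D_i = sum_a f_i^a ln(f_i^a / q^a) of the observed amino-acid frequencies
   at each mapped position against a background composition (gaps excluded).
2. A conservation-weighted positional correlation matrix: raw pair
   correlations C_ij^ab = f_ij^ab - f_i^a f_j^b are weighted by
   w_i^a = | d/df [ f ln(f/q) + (1-f) ln((1-f)/(1-q)) ] |  evaluated at f_i^a
   and reduced over amino-acid pairs by the Frobenius norm, giving a
   non-negative K x K matrix C-tilde.
3. Eigenmode significance against randomized alignments: each column's
   symbols are permuted independently across sequences, C-tilde recomputed,
   eigenvalues pooled; true eigenmodes above the maximum null eigenvalue are
   retained.
4. ICA rotation of the retained eigenmode subspace to maximally independent
   axes; heavy-tailed components carry candidate sectors.
5. Sector definition: a location-scale Student's-t distribution is fitted to
   the chosen component's position weights and members are positions beyond
   the fitted quantile at the cumulative-density cutoff (default 0.85).
6. Physical checks: contiguity of the sector on a reference structure under
   a heavy-atom contact graph, and the overlay of polymorphic positions
   between two allele sequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .io_formats import AMINO_ACIDS, AlignmentMatrix, ReferenceStructure

logger = logging.getLogger("mhcplast")

__all__ = [
    "BACKGROUND_FREQS",
    "ConservationProfile",
    "SCAMatrix",
    "SectorResult",
    "position_conservation",
    "weighted_correlation_matrix",
    "significant_modes",
    "ica_rotate",
    "define_sector",
    "check_contiguity",
    "polymorphism_overlay",
]

#: background amino-acid composition (order ACDEFGHIKLMNPQRSTVWY) — the
#: standard sequence-database average used by the SCA literature; swappable.
BACKGROUND_FREQS = np.array([
    0.073, 0.025, 0.050, 0.061, 0.042, 0.072, 0.023, 0.053, 0.064, 0.089,
    0.023, 0.043, 0.052, 0.040, 0.052, 0.073, 0.056, 0.063, 0.013, 0.033,
])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

#: pseudo-frequency mixed toward the background to regularize the
#: log-derivative weights at observed frequencies of exactly 0 or 1
PSEUDOCOUNT_LAMBDA = 0.03

_AA_INDEX = {a: k for k, a in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ConservationProfile:
    positions: np.ndarray            # 1-based reference positions
    d_i: np.ndarray                  # nats; NaN where a column is all gaps
    frequencies: np.ndarray          # (K, 20) per-position f_i^a over non-gaps
    background: np.ndarray           # (20,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "kl_conservation_nats": self.d_i})


@dataclass
class SCAMatrix:
    matrix: np.ndarray               # (K, K) non-negative, symmetric
    positions: np.ndarray            # 1-based reference positions
    eigenvalues: np.ndarray          # descending
    eigenvectors: np.ndarray         # columns
    null_eigenvalues: np.ndarray | None = None   # pooled from randomizations
    retained: np.ndarray | None = None           # indices of significant modes


@dataclass
class SectorResult:
    ic_weights: np.ndarray           # (K, n_components)
    selected_ic: int
    positions: np.ndarray            # all mapped positions (1-based)
    members: np.ndarray              # sector member positions (1-based)
    t_params: tuple[float, float, float]   # (df, loc, scale)
    cutoff: float
    contiguity_components: list[list[int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        member_set = set(self.members.tolist())
        return pd.DataFrame(
            {
                "position": self.positions,
                "ic_weight": self.ic_weights[:, self.selected_ic],
                "sector": [int(p) in member_set for p in self.positions],
            }
        )


# ---------------------------------------------------------------------------
# encoding helpers
# ---------------------------------------------------------------------------

def _mapped_symbol_codes(aln: AlignmentMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Symbols of the mapped columns as integer codes (gap = -1).

    Returns (codes (M, K), positions (K,)).
    """
    if not aln.column_map:
        raise ValueError("alignment has no column map; call map_columns_to_reference")
    cols = aln.mapped_columns()
    sub = aln.residues[:, cols]
    codes = np.full(sub.shape, -1, dtype=int)
    for sym, k in _AA_INDEX.items():
        codes[sub == sym] = k
    return codes, aln.mapped_positions()


def _frequencies(codes: np.ndarray) -> np.ndarray:
    """Per-column frequencies over the 20 amino acids among non-gap symbols."""
    m, k = codes.shape
    freqs = np.zeros((k, 20))
    for j in range(k):
        col = codes[:, j]
        col = col[col >= 0]
        if col.size:
            freqs[j] = np.bincount(col, minlength=20) / col.size
    return freqs


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def position_conservation(
    aln: AlignmentMatrix, background: np.ndarray | None = None
) -> ConservationProfile:
    """Kullback-Leibler conservation D_i per mapped reference position.

    D_i = sum_a f_i^a ln(f_i^a / q^a) over the 20 amino acids; gap symbols
    are excluded from the frequencies.  A fully conserved column scores
    ln(1/q_a); a column matching the background scores 0.  All-gap columns
    yield NaN with a warning.
    """
    q = BACKGROUND_FREQS if background is None else np.asarray(background, dtype=float)
    codes, positions = _mapped_symbol_codes(aln)
    freqs = _frequencies(codes)
    d = np.full(len(positions), np.nan)
    for j in range(len(positions)):
        f = freqs[j]
        if f.sum() == 0:
            warnings.warn(f"position {positions[j]} is all gaps; conservation undefined")
            continue
        nz = f > 0
        d[j] = float(np.sum(f[nz] * np.log(f[nz] / q[nz])))
    return ConservationProfile(positions=positions, d_i=d, frequencies=freqs, background=q)


# ---------------------------------------------------------------------------
# weighted correlation matrix
# ---------------------------------------------------------------------------

def _conservation_weights(freqs: np.ndarray, q: np.ndarray) -> np.ndarray:
    """|d/df [f ln(f/q) + (1-f) ln((1-f)/(1-q))]| = |ln(f(1-q)/(q(1-f)))|,
    evaluated at pseudo-count-regularized frequencies."""
    f_reg = (1.0 - PSEUDOCOUNT_LAMBDA) * freqs + PSEUDOCOUNT_LAMBDA * q
    return np.abs(np.log(f_reg * (1.0 - q) / (q * (1.0 - f_reg))))


def _sca_matrix_values(codes: np.ndarray, q: np.ndarray) -> np.ndarray:
    """C-tilde from integer-coded mapped columns.

    Builds the weighted, centred one-hot matrix Y with
    Y[s, (i,a)] = w_i^a (1[codes_si = a] - f_i^a) / sqrt(M); then
    C-tilde_ij = || (Y^T Y)_{ij} ||_F over the 20x20 amino-acid block.
    """
    m, k = codes.shape
    freqs = _frequencies(codes)
    w = _conservation_weights(freqs, q)                       # (K, 20)
    one_hot = np.zeros((m, k, 20))
    rows, cols = np.nonzero(codes >= 0)
    one_hot[rows, cols, codes[rows, cols]] = 1.0
    y = (w * (one_hot - freqs)).reshape(m, k * 20) / np.sqrt(m)
    gram = y.T @ y                                            # (20K, 20K)
    np.square(gram, out=gram)
    c_tilde = np.sqrt(gram.reshape(k, 20, k, 20).sum(axis=(1, 3)))
    return c_tilde


def _eigendecompose_desc(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    evals, evecs = np.linalg.eigh(matrix)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def weighted_correlation_matrix(
    aln: AlignmentMatrix, background: np.ndarray | None = None
) -> SCAMatrix:
    """Conservation-weighted positional correlation matrix C-tilde.

    Raw correlations C_ij^ab = f_ij^ab - f_i^a f_j^b between all pairs of
    mapped positions are weighted by the per-position conservation gradients
    and reduced over the amino-acid pairs by the Frobenius norm; the result
    is symmetric and non-negative with K = number of mapped positions.
    """
    q = BACKGROUND_FREQS if background is None else np.asarray(background, dtype=float)
    codes, positions = _mapped_symbol_codes(aln)
    if len(positions) < 2:
        raise ValueError("need at least 2 mapped positions")
    c_tilde = _sca_matrix_values(codes, q)
    evals, evecs = _eigendecompose_desc(c_tilde)
    return SCAMatrix(
        matrix=c_tilde, positions=positions, eigenvalues=evals, eigenvectors=evecs
    )


def significant_modes(
    aln: AlignmentMatrix,
    mat: SCAMatrix,
    n_randomizations: int = 100,
    seed: int = 0,
    background: np.ndarray | None = None,
    include_first_mode: bool = True,
) -> SCAMatrix:
    """Retain eigenmodes whose eigenvalues exceed the randomized-alignment null.

    For each randomization every column's symbols are independently permuted
    across sequences — destroying inter-column correlations while preserving
    column compositions — and the eigenvalues of the recomputed C-tilde are
    pooled.  True eigenvalues strictly above the maximum pooled null
    eigenvalue are significant.  The first (top) eigenmode of an SCA matrix
    reflects overall conservation rather than coupling; it is retained by
    default and excluded with ``include_first_mode=False``.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    q = BACKGROUND_FREQS if background is None else np.asarray(background, dtype=float)
    codes, _ = _mapped_symbol_codes(aln)
    rng = np.random.default_rng(seed)
    m, k = codes.shape
    null_evals = np.empty((n_randomizations, k))
    shuffled = codes.copy()
    for r in range(n_randomizations):
        for j in range(k):
            shuffled[:, j] = codes[rng.permutation(m), j]
        null_evals[r] = np.linalg.eigvalsh(_sca_matrix_values(shuffled, q))
    null_pool = null_evals.ravel()
    envelope = float(null_pool.max())
    above = np.nonzero(mat.eigenvalues > envelope)[0]
    if not include_first_mode:
        above = above[above != 0]
    logger.info(
        "null envelope %.4f from %d randomizations; %d significant mode(s)",
        envelope, n_randomizations, len(above),
    )
    mat.null_eigenvalues = null_pool
    mat.retained = above
    return mat


# ---------------------------------------------------------------------------
# ICA and sector definition
# ---------------------------------------------------------------------------

def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    """Symmetric decorrelation W <- (W W^T)^(-1/2) W."""
    evals, evecs = np.linalg.eigh(w @ w.T)
    inv_sqrt = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 1e-30))) @ evecs.T
    return inv_sqrt @ w


def ica_rotate(
    mat: SCAMatrix,
    n_components: int = 3,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Rotate the retained eigenmode subspace to maximally independent axes.

    Symmetric fixed-point iteration with the tanh (log-cosh) contrast,
    applied to the mode coordinates of the retained eigenvectors without
    re-centering, so the returned components are exact linear combinations
    of the retained modes (the spanned subspace is preserved).  Components
    are sign-fixed so the heavy tail is positive (positive skew) and ordered
    by decreasing excess kurtosis — the sector-likeness ranking.  Returns a
    (K, n_components) weight matrix.
    """
    if mat.retained is None or len(mat.retained) == 0:
        raise ValueError("no retained eigenmodes; run significant_modes first")
    if n_components > len(mat.retained):
        raise ValueError(
            f"n_components={n_components} exceeds {len(mat.retained)} retained modes"
        )
    subspace = mat.eigenvectors[:, mat.retained]              # (K, r)
    k, r = subspace.shape
    # channels = modes; V^T V = I so the channels are already decorrelated,
    # scale them to unit variance over positions
    x = subspace.T * np.sqrt(k)                               # (r, K)
    rng = np.random.default_rng(seed)
    w = _sym_decorrelate(rng.standard_normal((r, r)))
    for iteration in range(1, max_iter + 1):
        y = w @ x                                             # (r, K)
        g = np.tanh(y)
        g_prime = 1.0 - g**2
        w_new = (g @ x.T) / k - np.diag(g_prime.mean(axis=1)) @ w
        w_new = _sym_decorrelate(w_new)
        delta = np.max(np.abs(np.abs(np.einsum("ij,ij->i", w_new, w)) - 1.0))
        w = w_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"ICA did not converge within {max_iter} iterations")
    logger.info("ICA converged in %d iteration(s)", iteration)
    ics = (w @ subspace.T).T                                  # (K, r)
    skew = stats.skew(ics, axis=0)
    ics = ics * np.where(skew < 0, -1.0, 1.0)
    order = np.argsort(stats.kurtosis(ics, axis=0))[::-1]
    return ics[:, order[:n_components]]


def define_sector(
    ics: np.ndarray,
    positions: np.ndarray,
    ic_index: int | None = None,
    cdf_cutoff: float = 0.85,
) -> SectorResult:
    """Define sector members from one independent component's weights.

    A location-scale Student's-t distribution is fitted by maximum
    likelihood to the component's position weights; members are positions
    whose weight exceeds the fitted quantile at ``cdf_cutoff``.  With
    ``ic_index=None`` the component with the heaviest tail (largest excess
    kurtosis — the conventional sector-bearing axis) is selected.
    """
    if not 0.0 < cdf_cutoff < 1.0:
        raise ValueError("cdf_cutoff must lie in (0, 1)")
    ics = np.atleast_2d(ics)
    if ic_index is None:
        ic_index = int(np.argmax(stats.kurtosis(ics, axis=0)))
    weights = ics[:, ic_index]
    if np.ptp(weights) == 0:
        raise ValueError("degenerate (constant) independent component")
    df, loc, scale = stats.t.fit(weights)
    threshold = stats.t.ppf(cdf_cutoff, df, loc=loc, scale=scale)
    members = np.asarray(positions)[weights > threshold]
    logger.info(
        "sector of %d/%d positions at cutoff %.2f (t quantile %.4f)",
        len(members), len(positions), cdf_cutoff, threshold,
    )
    return SectorResult(
        ic_weights=ics,
        selected_ic=ic_index,
        positions=np.asarray(positions),
        members=members,
        t_params=(float(df), float(loc), float(scale)),
        cutoff=cdf_cutoff,
    )


# ---------------------------------------------------------------------------
# physical checks
# ---------------------------------------------------------------------------

def check_contiguity(
    sector: SectorResult,
    ref: ReferenceStructure,
    contact_cutoff: float = 4.5,
    cutoff_unit: str = "angstrom",
) -> list[list[int]]:
    """Connected components of the sector under a residue-contact graph.

    Two member residues are in contact when any pair of their heavy atoms
    lies within ``contact_cutoff`` (4.5 Angstrom by convention; the
    reference structure stores nm, so the cutoff is converted).  A sector
    that forms one component is physically contiguous.
    """
    members = [int(p) for p in sector.members]
    missing = [p for p in members if p not in ref.residue_coords]
    if missing:
        raise KeyError(f"sector positions missing from reference structure: {missing}")
    cutoff_nm = contact_cutoff * 0.1 if cutoff_unit == "angstrom" else contact_cutoff
    n = len(members)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            dmin = cdist(
                ref.residue_coords[members[i]], ref.residue_coords[members[j]]
            ).min()
            if dmin < cutoff_nm:
                rows.append(i)
                cols.append(j)
    adj = csr_matrix(
        (np.ones(2 * len(rows)), (rows + cols, cols + rows)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    components = [
        sorted(members[i] for i in np.nonzero(labels == c)[0]) for c in range(n_comp)
    ]
    components.sort(key=len, reverse=True)
    sector.contiguity_components = components
    return components


def polymorphism_overlay(
    seq_a: str, seq_b: str, sector: SectorResult
) -> pd.DataFrame:
    """Positions where two ungapped allele sequences differ, flagged by
    sector membership.

    Positions are 1-based reference numbering.  ``attrs`` carries the
    polymorphism count and the size of the intersection with the sector —
    the overlay drawn on the conservation profile.
    """
    a = seq_a.replace("-", "")
    b = seq_b.replace("-", "")
    if len(a) != len(b):
        raise ValueError(
            f"sequence length mismatch: {len(a)} vs {len(b)} (ungapped)"
        )
    member_set = set(int(p) for p in sector.members)
    diff_positions = [i + 1 for i in range(len(a)) if a[i] != b[i]]
    table = pd.DataFrame(
        {
            "position": diff_positions,
            "allele_a": [a[p - 1] for p in diff_positions],
            "allele_b": [b[p - 1] for p in diff_positions],
            "in_sector": [p in member_set for p in diff_positions],
        }
    )
    table.attrs["n_polymorphic"] = len(diff_positions)
    table.attrs["n_in_sector"] = int(table["in_sector"].sum()) if len(table) else 0
    return table
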
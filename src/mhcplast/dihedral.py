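"""Per-residue backbone phi flexibility.

The phi dihedral (rotation about the N-CA bond, defined by atoms
C(i-1)-N(i)-CA(i)-C(i), IUPAC sign convention) is measured for every residue
in every frame; its spread over the trajectory quantifies local plasticity.
The spread is a circular standard deviation by default — a naive linear SD is
wrong at the +/-180 degree wrap, which is exactly where highly flexible sites
live — with the linear estimator available for comparison.  Sites whose SD
exceeds a threshold (25 degrees by convention here) are counted as flexible,
and bound/free states are compared site by site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TrajectoryEnsemble

__all__ = [
    "DihedralSeries",
    "FlexibilityReport",
    "dihedral_angle",
    "compute_phi_series",
    "circular_sd",
    "flexible_sites",
    "compare_states",
]

DEFAULT_THRESHOLD_DEG = 25.0


@dataclass
class DihedralSeries:
    """Per-residue phi angles per frame (degrees, in (-180, 180])."""

    residues: np.ndarray            # (R,) 1-based residue positions
    angles: np.ndarray              # (T, R), NaN where phi is undefined
    state_label: str = ""
    glycine_mask: np.ndarray | None = None   # flagged, not excluded

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.angles = np.asarray(self.angles, dtype=float)
        finite = self.angles[np.isfinite(self.angles)]
        if finite.size and ((finite <= -180.0).any() or (finite > 180.0).any()):
            raise ValueError("angles must lie in (-180, 180]")
        if self.glycine_mask is None:
            self.glycine_mask = np.zeros(self.residues.shape, dtype=bool)


@dataclass
class FlexibilityReport:
    """Circular SD per residue and the sites above threshold."""

    residues: np.ndarray
    sd: np.ndarray                  # degrees, NaN where phi missing
    threshold: float = DEFAULT_THRESHOLD_DEG
    state_label: str = ""
    glycine_mask: np.ndarray | None = None

    @property
    def flexible_sites(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            mask = self.sd > self.threshold
        return self.residues[np.nan_to_num(mask.astype(float)).astype(bool)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residues,
                "phi_sd_deg": self.sd,
                "flexible": np.where(np.isfinite(self.sd), self.sd > self.threshold, False),
                "glycine": self.glycine_mask
                if self.glycine_mask is not None
                else np.zeros(len(self.residues), dtype=bool),
            }
        )


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral (degrees) of the four points about the p1-p2 axis.

    Vectorized over leading axes; IUPAC sign convention (cis = 0, looking
    from p1 to p2, clockwise rotation of p3 relative to p0 is positive).
    """
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    # components of b0, b2 perpendicular to the rotation axis
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # report in (-180, 180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


def compute_phi_series(traj: TrajectoryEnsemble, state_label: str = "") -> DihedralSeries:
    """Measure phi for every residue in every frame.

    Requires backbone atoms N, CA and C per residue.  The first residue of
    the chain has no preceding carbonyl carbon and is marked missing (NaN),
    as is any residue with an absent backbone atom.
    """
    traj.require_statistics()
    meta = traj.atom_meta
    residues = np.unique(meta["res_id"].to_numpy())
    index: dict[tuple[int, str], int] = {
        (int(r), a): i
        for i, (r, a) in enumerate(zip(meta["res_id"], meta["atom_name"]))
    }
    res_names = {
        int(r): n for r, n in zip(meta["res_id"], meta["res_name"])
    }
    angles = np.full((traj.n_frames, len(residues)), np.nan)
    for j, res in enumerate(residues):
        prev_c = index.get((res - 1, "C"))
        n_i = index.get((res, "N"))
        ca_i = index.get((res, "CA"))
        c_i = index.get((res, "C"))
        if None in (prev_c, n_i, ca_i, c_i):
            continue  # first residue or incomplete backbone: stays missing
        angles[:, j] = dihedral_angle(
            traj.coords[:, prev_c], traj.coords[:, n_i],
            traj.coords[:, ca_i], traj.coords[:, c_i],
        )
    glycine = np.array([res_names[int(r)] == "GLY" for r in residues])
    return DihedralSeries(
        residues=residues, angles=angles, state_label=state_label, glycine_mask=glycine
    )


def circular_sd(angles_deg: np.ndarray, estimator: str = "circular") -> float:
    """Standard deviation of an angle series in degrees.

    The circular estimator is sqrt(-2 ln Rbar) * 180/pi where Rbar is the
    mean resultant length of the unit vectors — invariant under adding any
    constant rotation and immune to the +/-180 wrap.  ``estimator='linear'``
    gives the naive SD for comparison.  All-missing input returns NaN;
    fewer than 2 observations is an error.
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    if a.size < 2:
        raise ValueError("circular_sd requires >= 2 non-missing angles")
    if estimator == "linear":
        return float(np.std(a))
    if estimator != "circular":
        raise ValueError(f"unknown estimator {estimator!r}")
    if np.ptp(a) == 0.0:
        return 0.0
    return float(stats.circstd(a, high=180.0, low=-180.0))


def flexible_sites(
    series: DihedralSeries,
    threshold: float = DEFAULT_THRESHOLD_DEG,
    estimator: str = "circular",
) -> FlexibilityReport:
    """Per-residue phi SD and the sites strictly above the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sd = np.array(
        [
            circular_sd(col, estimator=estimator)
            if np.isfinite(col).sum() >= 2
            else float("nan")
            for col in series.angles.T
        ]
    )
    return FlexibilityReport(
        residues=series.residues,
        sd=sd,
        threshold=threshold,
        state_label=series.state_label,
        glycine_mask=series.glycine_mask,
    )


def compare_states(bound: FlexibilityReport, free: FlexibilityReport) -> pd.DataFrame:
    """Residue-aligned delta of phi SD between two states plus site counts.

    Returns a table with per-residue SD in both states and their difference
    (free minus bound); ``attrs`` carries the two flexible-site counts and
    their delta — the comparison axis for peptide-bound vs peptide-free
    ensembles.
    """
    common, ib, ifr = np.intersect1d(bound.residues, free.residues, return_indices=True)
    table = pd.DataFrame(
        {
            "residue": common,
            "sd_bound": bound.sd[ib],
            "sd_free": free.sd[ifr],
        }
    )
    table["delta_sd"] = table["sd_free"] - table["sd_bound"]
    table.attrs["n_flexible_bound"] = int(len(bound.flexible_sites))
    table.attrs["n_flexible_free"] = int(len(free.flexible_sites))
    table.attrs["delta_sites"] = table.attrs["n_flexible_free"] - table.attrs["n_flexible_bound"]
    return table
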
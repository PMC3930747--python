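"""Stage orchestration: simulate fixtures, flexibility, PCA, landscape, SCA
and the combined allele comparison, with config, logging and seeds.

Configuration is a plain-text ``key = value`` file with full defaulting;
every artifact is written with a provenance header (config hash, seed) so a
run can be reproduced exactly.  Stages are pure functions of their inputs —
any stage can be run standalone.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dihedral, essential, io_formats, landscape, sca, synthetic

logger = logging.getLogger("mhcplast")

STAGES = ("simulate", "flex", "pca", "landscape", "sca")
#: stages that consume another stage's product when run in one pipeline pass
STAGE_DEPENDENCIES = {"landscape": "pca"}


@dataclass
class PipelineConfig:
    """Thresholds and paths for a pipeline run; defaults follow the
    documented analysis conventions (25 degree phi threshold, 10 ns
    equilibration discard, 64 landscape bins at 300 K, 100 alignment
    randomizations, 0.85 sector cutoff, 4.5 Angstrom contacts)."""

    out_dir: str = "results"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # inputs
    traj_bound: str = ""
    traj_free: str = ""
    msa_path: str = ""
    reference_pdb: str = ""
    # thresholds
    phi_threshold: float = 25.0
    discard_ns: float = 10.0
    dt_ps: float = 5.0
    bins: int = 64
    temperature: float = 300.0
    randomizations: int = 100
    cdf_cutoff: float = 0.85
    contact_cutoff: float = 4.5
    n_modes: int = 50
    sd_estimator: str = "circular"
    # synthetic-fixture sizes
    sim_n_frames: int = 3000
    sim_n_seqs: int = 141
    sim_n_positions: int = 274

    def validate(self) -> None:
        for name in ("phi_threshold", "bins", "temperature", "randomizations",
                     "contact_cutoff", "dt_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.cdf_cutoff < 1.0:
            raise ValueError("cdf_cutoff must lie in (0, 1)")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage, dep in STAGE_DEPENDENCIES.items():
            if stage in self.stages and dep not in self.stages:
                raise ValueError(
                    f"stage {stage!r} requires stage {dep!r} in the same run"
                )

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is excluded:
        identical analyses written to different directories share a hash)."""
        items = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        digest = hashlib.sha256(repr(sorted(items.items())).encode())
        return digest.hexdigest()[:12]

    def provenance(self) -> list[str]:
        return [f"config_hash={self.config_hash()}", f"seed={self.seed}"]


def parse_config(path: str | Path) -> PipelineConfig:
    """Read a plain-text ``key = value`` configuration with full defaulting."""
    values: dict[str, object] = {}
    known = {f.name: f.type for f in fields(PipelineConfig)}
    defaults = PipelineConfig()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        default = getattr(defaults, key)
        if key == "stages":
            values[key] = tuple(s.strip() for s in raw.split(",") if s.strip())
        elif isinstance(default, bool):
            values[key] = raw.lower() in {"1", "true", "yes"}
        elif isinstance(default, int):
            values[key] = int(raw)
        elif isinstance(default, float):
            values[key] = float(raw)
        else:
            values[key] = raw
    return PipelineConfig(**values)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Write synthetic fixture files (aligned FASTA and multi-model PDB)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n_pos = config.sim_n_positions
    # planted group spread over the chain, scaled to the configured length
    sector_positions = sorted(
        {max(2, round(f * n_pos)) for f in (0.08, 0.22, 0.35, 0.55, 0.65, 0.80)}
    )
    conserved_pos = 1 if 1 not in sector_positions else n_pos
    msa = synthetic.generate_msa(
        synthetic.MsaRecipe(
            n_seqs=config.sim_n_seqs,
            n_positions=n_pos,
            conserved_positions={conserved_pos: ("W", 0.95)},
            sector_positions=sector_positions,
            sector_coupling=0.8,
            seed=int(rng.integers(2**31)),
        )
    )
    msa_path = out / "synthetic_msa.fasta"
    io_formats.write_msa_fasta(msa, msa_path)
    n_res = 20
    phi0 = np.full(n_res, -57.0)
    psi0 = np.full(n_res, -47.0)
    ref, meta = synthetic.build_backbone(phi0, psi0)
    n3 = ref.size
    raw = rng.standard_normal((2, n3))
    q, _ = np.linalg.qr(raw.T)
    traj = synthetic.generate_trajectory(
        synthetic.TrajectoryRecipe(
            reference_coords=ref,
            modes=q.T,
            mode_stddevs=np.array([0.05, 0.02]),
            noise_stddev=0.005,
            n_frames=config.sim_n_frames,
            dt=config.dt_ps,
            seed=int(rng.integers(2**31)),
            atom_meta=meta,
        )
    )
    traj_path = out / "synthetic_trajectory.pdb"
    io_formats.write_trajectory(traj, traj_path)
    return {"msa": msa_path, "trajectory": traj_path}


def stage_flex(
    config: PipelineConfig, traj: io_formats.TrajectoryEnsemble, state_label: str = ""
) -> dihedral.FlexibilityReport:
    """Per-residue phi SD and flexible-site report for one ensemble."""
    series = dihedral.compute_phi_series(traj, state_label=state_label)
    report = dihedral.flexible_sites(
        series, threshold=config.phi_threshold, estimator=config.sd_estimator
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = f"flexibility_{state_label or 'trajectory'}.tsv"
    io_formats.write_report(report.to_frame(), out / name, config.provenance())
    return report


def stage_pca(
    config: PipelineConfig, traj: io_formats.TrajectoryEnsemble,
    selection: str | np.ndarray = "backbone",
) -> tuple[essential.ModeSet, essential.ProjectionSeries]:
    """Superpose, build covariance, eigendecompose and project on top modes."""
    fitted = essential.superpose(traj, selection=selection)
    cov = essential.build_covariance(fitted, selection=selection)
    modes = essential.eigendecompose(cov)
    n_report = min(config.n_modes, len(modes.eigenvalues))
    spectrum = pd.DataFrame(
        {
            "mode": np.arange(1, n_report + 1),
            "eigenvalue": modes.eigenvalues[:n_report],
            "cumulative_variance": [
                essential.cumulative_variance(modes, k) for k in range(1, n_report + 1)
            ],
        }
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_report(spectrum, out / "pca_spectrum.tsv", config.provenance())
    proj = essential.project(fitted, modes, mode_indices=np.array([0, 1]))
    return modes, proj


def stage_landscape(
    config: PipelineConfig, proj: essential.ProjectionSeries
) -> landscape.EnergyLandscape:
    """Free-energy landscape of the top two principal components."""
    grid = landscape.estimate_density(
        proj.values[:, 0], proj.values[:, 1], bins=config.bins
    )
    land = landscape.to_free_energy(grid, temperature=config.temperature)
    minima = landscape.find_minima(land)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        {
            "pc1_center": [land.centers1[m.bin_index[0]] for m in minima],
            "pc2_center": [land.centers2[m.bin_index[1]] for m in minima],
            "g_kt": [m.g for m in minima],
            "persistence_kt": [m.persistence for m in minima],
        }
    )
    io_formats.write_report(table, out / "landscape_minima.tsv", config.provenance())
    return land


def stage_sca(
    config: PipelineConfig,
    aln: io_formats.AlignmentMatrix,
    reference: io_formats.ReferenceStructure | None = None,
) -> sca.SectorResult:
    """Conservation, coupling matrix, null significance, ICA and the sector."""
    profile = sca.position_conservation(aln)
    mat = sca.weighted_correlation_matrix(aln)
    mat = sca.significant_modes(
        aln, mat, n_randomizations=config.randomizations, seed=config.seed
    )
    n_components = min(3, max(1, len(mat.retained)))
    ics = sca.ica_rotate(mat, n_components=n_components, seed=config.seed)
    sector = sca.define_sector(ics, mat.positions, cdf_cutoff=config.cdf_cutoff)
    if reference is not None:
        sca.check_contiguity(sector, reference, contact_cutoff=config.contact_cutoff)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_report(profile.to_frame(), out / "conservation.tsv", config.provenance())
    io_formats.write_report(sector.to_frame(), out / "sector.tsv", config.provenance())
    return sector


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute the enabled stages in dependency order on the configured inputs.

    Returns the stage products keyed by stage name.  Raises before executing
    anything if the configuration is inconsistent.
    """
    config.validate()
    products: dict[str, object] = {}
    t0 = time.time()
    paths: dict[str, Path] = {}
    if "simulate" in config.stages:
        paths = stage_simulate(config)
        products["simulate"] = paths
    traj = None
    traj_path = config.traj_free or config.traj_bound or (
        str(paths["trajectory"]) if "trajectory" in paths else ""
    )
    if {"flex", "pca", "landscape"} & set(config.stages):
        if not traj_path:
            raise ValueError("flex/pca stages need a trajectory input")
        traj = io_formats.read_trajectory(traj_path, dt=config.dt_ps)
        traj = io_formats.discard_equilibration(traj, config.discard_ns * 1000.0)
    if "flex" in config.stages:
        products["flex"] = stage_flex(config, traj)
    if "pca" in config.stages:
        modes, proj = stage_pca(config, traj)
        products["pca"] = (modes, proj)
    if "landscape" in config.stages:
        _, proj = products["pca"]
        products["landscape"] = stage_landscape(config, proj)
    if "sca" in config.stages:
        msa_path = config.msa_path or (str(paths["msa"]) if "msa" in paths else "")
        if not msa_path:
            raise ValueError("sca stage needs an alignment input")
        aln = io_formats.read_msa_fasta(msa_path)
        reference = (
            io_formats.read_reference_structure(config.reference_pdb)
            if config.reference_pdb
            else None
        )
        products["sca"] = stage_sca(config, aln, reference)
    logger.info("pipeline finished %d stage(s) in %.1f s", len(products), time.time() - t0)
    return products


# ---------------------------------------------------------------------------
# allele comparison
# ---------------------------------------------------------------------------

def compare_alleles(
    reports: dict[str, dict[str, object]],
) -> pd.DataFrame:
    """Tabulate the per-state/allele comparison axes.

    ``reports`` maps a label like 'BF2_15_bound' to a dict with any of the
    keys ``flex`` (FlexibilityReport), ``modes`` (ModeSet) and ``landscape``
    (EnergyLandscape).  Missing entries produce explicit gaps (NaN) so a
    partial comparison is still a valid table.  Columns: flexible-site
    count, top-1 and top-2 cumulative variance fractions and landscape
    minima count.
    """
    rows = []
    for label, parts in reports.items():
        flex = parts.get("flex")
        modes = parts.get("modes")
        land = parts.get("landscape")
        rows.append(
            {
                "label": label,
                "n_flexible_sites": len(flex.flexible_sites) if flex is not None else np.nan,
                "cumvar_pc1": essential.cumulative_variance(modes, 1) if modes is not None else np.nan,
                "cumvar_pc2": essential.cumulative_variance(modes, 2) if modes is not None else np.nan,
                "n_minima": len(land.minima) if land is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
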
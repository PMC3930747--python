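"""Readers, writers and core containers for the formats the pipeline touches.

Alignments are aligned FASTA; trajectories are multi-model PDB (the mandatory
dialect — binary formats can be plugged in behind :func:`read_trajectory`);
reference structures are single-model PDB.  Coordinates are stored internally
in nanometres and converted from/to Angstrom at the PDB boundary.  Residue
numbering throughout is 1-based lumenal-domain numbering (position 1 is the
first residue after the signal peptide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger("mhcplast")

NM_PER_ANGSTROM = 0.1

#: canonical 20-letter amino-acid alphabet used by the coupling statistics
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


class FormatError(ValueError):
    """Malformed input file (ragged alignment, inconsistent frames, ...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AlignmentMatrix:
    """A multiple sequence alignment as an M x L grid of one-letter symbols.

    ``column_map`` maps 0-based column index to the 1-based position in the
    query (reference) sequence; it is defined exactly on columns where the
    query has a non-gap symbol and is strictly increasing.
    """

    sequence_ids: list[str]
    residues: np.ndarray            # (M, L) '<U1'
    query_id: str | None = None
    column_map: dict[int, int] = field(default_factory=dict)

    @property
    def n_sequences(self) -> int:
        return self.residues.shape[0]

    @property
    def n_columns(self) -> int:
        return self.residues.shape[1]

    def sequence(self, seq_id: str) -> np.ndarray:
        try:
            row = self.sequence_ids.index(seq_id)
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None
        return self.residues[row]

    def mapped_columns(self) -> np.ndarray:
        """0-based column indices carrying reference positions, in order."""
        return np.fromiter(self.column_map.keys(), dtype=int)

    def mapped_positions(self) -> np.ndarray:
        """1-based reference positions, in column order."""
        return np.fromiter(self.column_map.values(), dtype=int)


@dataclass
class TrajectoryEnsemble:
    """Ordered frames of atom coordinates plus atom metadata.

    coords are in nm, shape (T, N, 3).  ``atom_meta`` has one row per atom
    with columns ``res_id`` (1-based), ``res_name``, ``atom_name`` and
    ``mass`` (amu).  ``labels`` carries the source replica id of each frame
    so equilibration can be discarded per replica after concatenation.
    """

    coords: np.ndarray
    atom_meta: pd.DataFrame
    dt: float                      # ps between frames
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (T, N, 3)")
        if self.labels is None:
            self.labels = np.zeros(self.n_frames, dtype=int)
        else:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.n_frames,):
                raise ValueError("labels must have one entry per frame")
        if len(self.atom_meta) != self.n_atoms:
            raise ValueError("atom_meta rows must match atom count")
        if (self.atom_meta["mass"] <= 0).any():
            raise ValueError("all atom masses must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def masses(self) -> np.ndarray:
        return self.atom_meta["mass"].to_numpy(dtype=float)

    def require_statistics(self) -> None:
        """Statistical operations need at least two frames."""
        if self.n_frames < 2:
            raise ValueError(
                f"trajectory statistics require >= 2 frames, got {self.n_frames}"
            )


@dataclass
class ReferenceStructure:
    """Per-residue heavy-atom coordinates of a reference structure (nm).

    ``residue_coords`` maps 1-based heavy-chain position to an (n_i, 3)
    array of heavy-atom coordinates.
    """

    residue_coords: dict[int, np.ndarray]

    @property
    def positions(self) -> list[int]:
        return sorted(self.residue_coords)


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

_VALID_SYMBOLS = frozenset(AMINO_ACIDS) | {GAP}


def read_msa_fasta(path: str | Path) -> AlignmentMatrix:
    """Read an aligned FASTA file into an :class:`AlignmentMatrix`.

    Sequences must all have the same length.  Symbols outside the canonical
    20-letter alphabet (ambiguity codes B/Z/X, unknown characters, '.')
    are normalized to the gap symbol so the downstream frequency model
    stays 20-state.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        offender = next(r for r in records if len(r.seq) != len(records[0].seq))
        raise FormatError(
            f"ragged alignment in {path}: record {offender.id!r} has length "
            f"{len(offender.seq)}, expected {len(records[0].seq)}"
        )
    grid = np.array([list(str(r.seq).upper()) for r in records], dtype="<U1")
    normalized = int(np.isin(grid, list(_VALID_SYMBOLS), invert=True).sum())
    grid[~np.isin(grid, list(_VALID_SYMBOLS))] = GAP
    ids = [r.id for r in records]
    logger.info(
        "read %d aligned sequences of length %d from %s (%d symbols normalized to gap)",
        len(ids), grid.shape[1], path, normalized,
    )
    aln = AlignmentMatrix(sequence_ids=ids, residues=grid, query_id=ids[0])
    return map_columns_to_reference(aln, ids[0])


def write_msa_fasta(aln: AlignmentMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, row in zip(aln.sequence_ids, aln.residues):
            fh.write(f">{seq_id}\n{''.join(row)}\n")
    logger.info("wrote %d sequences to %s", aln.n_sequences, path)


def map_columns_to_reference(aln: AlignmentMatrix, query_id: str) -> AlignmentMatrix:
    """Assign reference positions 1..K to the query's non-gap columns.

    K equals the query's ungapped length; gapped query columns carry no
    reference position and are excluded from position-level statistics.
    """
    query_row = aln.sequence(query_id)
    non_gap = np.nonzero(query_row != GAP)[0]
    column_map = {int(col): pos for pos, col in enumerate(non_gap, start=1)}
    return replace(aln, query_id=query_id, column_map=column_map)


# ---------------------------------------------------------------------------
# trajectories (multi-model PDB)
# ---------------------------------------------------------------------------

def _atom_meta_from_array(atoms: struc.AtomArray) -> pd.DataFrame:
    masses = np.array(
        [struc_info.mass(el, is_residue=False) or 0.0 for el in atoms.element],
        dtype=float,
    )
    return pd.DataFrame(
        {
            "res_id": atoms.res_id.astype(int),
            "res_name": atoms.res_name,
            "atom_name": atoms.atom_name,
            "mass": masses,
        }
    )


def read_trajectory(
    paths: list[str | Path] | str | Path,
    dt: float = 5.0,
    format: str = "multi-model-pdb",
) -> TrajectoryEnsemble:
    """Read one or more multi-model PDB files into a concatenated ensemble.

    Frames are concatenated in path order; each file contributes one replica
    label (1-based, in path order).  Atom ordering must be identical across
    all frames and files.  Coordinates are converted to nm.
    """
    if format not in {"multi-model-pdb", "pdb"}:
        raise NotImplementedError(f"trajectory format {format!r} not supported")
    if isinstance(paths, (str, Path)):
        paths = [paths]
    coords_parts: list[np.ndarray] = []
    labels_parts: list[np.ndarray] = []
    meta: pd.DataFrame | None = None
    n_atoms: int | None = None
    frame_offset = 0
    for replica, path in enumerate(paths, start=1):
        stack = PDBFile.read(str(path)).get_structure(model=None)
        if n_atoms is None:
            n_atoms = stack.array_length()
            meta = _atom_meta_from_array(stack[0])
        elif stack.array_length() != n_atoms:
            raise FormatError(
                f"atom-count mismatch at frame {frame_offset}: file {path} has "
                f"{stack.array_length()} atoms, expected {n_atoms}"
            )
        coords_parts.append(stack.coord * NM_PER_ANGSTROM)
        labels_parts.append(np.full(stack.stack_depth(), replica, dtype=int))
        frame_offset += stack.stack_depth()
    coords = np.concatenate(coords_parts, axis=0)
    labels = np.concatenate(labels_parts)
    logger.info(
        "read %d frames x %d atoms from %d file(s)", len(coords), n_atoms, len(paths)
    )
    return TrajectoryEnsemble(coords=coords, atom_meta=meta, dt=dt, labels=labels)


def write_trajectory(traj: TrajectoryEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (MODEL/ENDMDL records)."""
    template = struc.AtomArray(traj.n_atoms)
    template.res_id = traj.atom_meta["res_id"].to_numpy(dtype=int)
    template.res_name = traj.atom_meta["res_name"].to_numpy(dtype="<U5")
    template.atom_name = traj.atom_meta["atom_name"].to_numpy(dtype="<U6")
    template.element = np.array(
        [str(name)[:1] for name in traj.atom_meta["atom_name"]], dtype="<U2"
    )
    template.chain_id = np.full(traj.n_atoms, "A")
    template.hetero = np.zeros(traj.n_atoms, dtype=bool)
    stack = struc.from_template(
        template, traj.coords / NM_PER_ANGSTROM
    )
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
    logger.info("wrote %d frames x %d atoms to %s", traj.n_frames, traj.n_atoms, path)


def read_reference_structure(path: str | Path, unit: str = "nm") -> ReferenceStructure:
    """Read a single-model PDB into per-residue heavy-atom coordinates.

    Hydrogens are dropped; coordinates are returned in nm (``unit='angstrom'``
    keeps the file's native unit).
    """
    structure = PDBFile.read(str(path)).get_structure(model=1)
    heavy = structure[structure.element != "H"]
    scale = NM_PER_ANGSTROM if unit == "nm" else 1.0
    residue_coords = {
        int(res_id): heavy.coord[heavy.res_id == res_id] * scale
        for res_id in np.unique(heavy.res_id)
    }
    logger.info("read reference structure with %d residues from %s", len(residue_coords), path)
    return ReferenceStructure(residue_coords=residue_coords)


def discard_equilibration(traj: TrajectoryEnsemble, t_discard: float) -> TrajectoryEnsemble:
    """Drop the first ``t_discard`` ps of every replica.

    The leading ``t_discard / dt`` frames of each replica label are removed
    and the remainder re-concatenated in the original frame order.  Removing
    a replica entirely is an error.
    """
    if t_discard < 0:
        raise ValueError("t_discard must be >= 0")
    n_drop = int(round(t_discard / traj.dt))
    keep = np.ones(traj.n_frames, dtype=bool)
    for replica in np.unique(traj.labels):
        idx = np.nonzero(traj.labels == replica)[0]
        if n_drop >= len(idx):
            raise ValueError(
                f"discard of {t_discard} ps ({n_drop} frames) exceeds replica "
                f"{replica}'s span of {len(idx)} frames"
            )
        keep[idx[:n_drop]] = False
    return TrajectoryEnsemble(
        coords=traj.coords[keep],
        atom_meta=traj.atom_meta,
        dt=traj.dt,
        labels=traj.labels[keep],
    )


# ---------------------------------------------------------------------------
# analysis-product reports
# ---------------------------------------------------------------------------

def write_report(result: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Serialize an analysis product as a tab-delimited table with headers.

    ``header_lines`` (provenance: seeds, config) are written as '#' comments
    above the column header.  Sector and flexibility reports use 1-based
    heavy-chain residue numbering.
    """
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        result.to_csv(fh, sep="\t", index=False)
    logger.info("wrote report with %d rows to %s", len(result), path)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
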
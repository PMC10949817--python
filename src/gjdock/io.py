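"""Reading and writing structures and trajectories as PDB v3 files.

Trajectories are multi-MODEL PDB files with a fixed topology, the format the
analysed MD frames were exported in. Parsing and formatting of the
fixed-column records is delegated to biotite; this module adapts between
biotite's atom arrays and the package's :class:`~gjdock.core.Structure` /
:class:`~gjdock.core.Trajectory` types and enforces the trajectory contracts
(identical atom count and order in every MODEL block).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import biotite.structure as bst
import numpy as np
from biotite.structure.io.pdb import PDBFile

from .core import Structure, StructureError, Trajectory

log = logging.getLogger(__name__)


@dataclass
class TrajectorySource:
    """A trajectory file reference with its declared frame interval (ps)."""

    path: str | Path
    frame_interval_ps: float = 10.0
    format: str | None = None  # "multi-model-PDB" | "single-PDB" | None = detect


def _infer_element(name: str) -> str:
    """PDB v3 element guess from the atom name when the element column is blank."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0].upper() == "H":
        return "H"
    # two-letter elements relevant here start in column 13 (e.g. FE); side-chain
    # names like "SG", "OD1" are single-letter elements.
    return stripped[0].upper()


def _array_to_structure(arr: bst.AtomArray, title: str = "",
                        source: str = "") -> Structure:
    elements = np.asarray(arr.element, dtype="U2")
    blank = np.char.strip(elements) == ""
    if np.any(blank):
        names = arr.atom_name
        elements = elements.copy()
        for i in np.flatnonzero(blank):
            elements[i] = _infer_element(str(names[i]))
    return Structure(
        chain_ids=np.asarray(arr.chain_id, dtype="U4"),
        res_nums=np.asarray(arr.res_id, dtype=np.int64),
        res_names=np.asarray(arr.res_name, dtype="U4"),
        names=np.asarray(arr.atom_name, dtype="U6"),
        elements=elements,
        coords=np.asarray(arr.coord, dtype=np.float64),
        title=title,
        source=source,
    )


def _structure_to_array(structure: Structure) -> bst.AtomArray:
    n = len(structure)
    arr = bst.AtomArray(n)
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.res_id = structure.res_nums.astype(int)
    arr.res_name = structure.res_names.astype("U5")
    arr.atom_name = structure.names.astype("U6")
    arr.element = structure.elements.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.coord = structure.coords.astype(np.float32)
    return arr


def _model_atom_counts(lines: list[str]) -> list[int]:
    """ATOM/HETATM record count per MODEL block (single block if no MODEL)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    for line in lines:
        if line.startswith("MODEL"):
            saw_model = True
            in_model = True
            current = 0
        elif line.startswith("ENDMDL"):
            counts.append(current)
            in_model = False
        elif line.startswith(("ATOM", "HETATM")):
            current += 1
    if not saw_model:
        return [current]
    if in_model:  # unterminated final MODEL
        counts.append(current)
    return counts


def read_structure(path: str | Path) -> Structure:
    """Read a single-model structure from a PDB file.

    Multi-MODEL files are accepted: the first model is returned and a notice
    is logged. Hydrogens are read and preserved.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise StructureError(f"{path}: no ATOM/HETATM records")
    if n_models > 1:
        log.info("%s: %d models present; returning the first model only",
                 path, n_models)
    arr = pdb.get_structure(model=1, altloc="first")
    if arr.array_length() == 0:
        raise StructureError(f"{path}: no ATOM/HETATM records")
    return _array_to_structure(arr, source=str(path))


def read_trajectory(source: TrajectorySource | str | Path,
                    frame_interval_ps: float | None = None) -> Trajectory:
    """Read a fixed-topology trajectory from a (multi-MODEL) PDB file.

    Every MODEL block must have the same atom count and ordering; a
    single-model file yields a one-frame trajectory. Frame times are
    ``frame_index * frame_interval_ps``.
    """
    if not isinstance(source, TrajectorySource):
        source = TrajectorySource(path=source)
    if frame_interval_ps is not None:
        source = TrajectorySource(source.path, frame_interval_ps, source.format)
    pdb = PDBFile.read(str(source.path))
    counts = _model_atom_counts(pdb.lines)
    detected = "multi-model-PDB" if len(counts) > 1 else "single-PDB"
    if source.format is not None and source.format != detected:
        raise StructureError(
            f"{source.path}: declared format {source.format!r} but file "
            f"content is {detected!r}")
    if len(counts) == 0 or counts[0] == 0:
        raise StructureError(f"{source.path}: no ATOM/HETATM records")
    for i, c in enumerate(counts):
        if c != counts[0]:
            raise StructureError(
                f"{source.path}: model {i + 1} has {c} atoms, expected "
                f"{counts[0]} (model 1)")
    stack = pdb.get_structure(model=None, altloc="first")
    topology = _array_to_structure(stack[0], source=str(source.path))
    return Trajectory(
        topology=topology,
        frames=np.asarray(stack.coord, dtype=np.float64),
        frame_interval_ps=source.frame_interval_ps,
    )


def write_structure(structure: Structure, path: str | Path,
                    hybrid36: bool = True) -> None:
    """Write a structure as PDB; serial numbers are reassigned sequentially.

    Structures beyond 99,999 atoms use hybrid-36 serials when ``hybrid36``
    is true, otherwise writing raises.
    """
    if len(structure) == 0:
        raise StructureError("refusing to write an empty structure")
    pdb = PDBFile()
    pdb.set_structure(_structure_to_array(structure), hybrid36=hybrid36)
    pdb.write(str(path))


def write_trajectory(trajectory: Trajectory, path: str | Path,
                     hybrid36: bool = True) -> None:
    """Write a trajectory as a multi-MODEL PDB (one MODEL block per frame)."""
    if len(trajectory.topology) == 0:
        raise StructureError("refusing to write an empty trajectory")
    arr = _structure_to_array(trajectory.topology)
    stack = bst.AtomArrayStack(trajectory.n_frames, arr.array_length())
    for cat in arr.get_annotation_categories():
        stack.set_annotation(cat, arr.get_annotation(cat))
    stack.coord = trajectory.frames.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack, hybrid36=hybrid36)
    pdb.write(str(path))
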
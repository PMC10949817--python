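"""Domain types, residue/chain addressing, atom selection, and analysis constants.

The connexin numbering conventions (extracellular loops EL1/EL2, the conserved
Cys triads, the hexamer-hexamer chain pairing) and every geometric cutoff used
by the detectors live here, in :class:`ConnexinAnnotation` and
:class:`AnalysisParameters`, so that each number has exactly one home.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml


class GJDockError(Exception):
    """Base class for package errors."""


class SelectionError(GJDockError):
    """Malformed atom-selection expression."""


class StructureError(GJDockError):
    """Invalid or inconsistent structure/trajectory data."""


# ---------------------------------------------------------------------------
# Atoms and structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A single atom with PDB-style identity and Å coordinates."""

    serial: int
    name: str
    element: str
    res_num: int
    res_name: str
    chain_id: str
    coords: np.ndarray

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_num, self.name)


class Structure:
    """An ordered collection of atoms with vectorized per-field access.

    Fields are stored as parallel numpy arrays (``chain_ids``, ``res_nums``,
    ``res_names``, ``names``, ``elements``, ``coords``) so geometric analyses
    can operate without materializing :class:`Atom` objects.
    """

    def __init__(
        self,
        chain_ids: np.ndarray,
        res_nums: np.ndarray,
        res_names: np.ndarray,
        names: np.ndarray,
        elements: np.ndarray,
        coords: np.ndarray,
        serials: np.ndarray | None = None,
        title: str = "",
        source: str = "",
        validate: bool = True,
    ):
        n = len(chain_ids)
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.res_nums = np.asarray(res_nums, dtype=np.int64)
        self.res_names = np.asarray(res_names, dtype="U4")
        self.names = np.asarray(names, dtype="U6")
        self.elements = np.char.upper(np.asarray(elements, dtype="U2"))
        self.coords = np.asarray(coords, dtype=np.float64).reshape(n, 3)
        if serials is None:
            serials = np.arange(1, n + 1)
        self.serials = np.asarray(serials, dtype=np.int64)
        self.title = title
        self.source = source
        self._res_index: dict[tuple[str, int], np.ndarray] | None = None
        if validate:
            self._validate()

    def _validate(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates in structure")
        keys = [
            (c, int(r), n)
            for c, r, n in zip(self.chain_ids, self.res_nums, self.names)
        ]
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise StructureError(
                        f"duplicate atom key (chain={k[0]}, res={k[1]}, name={k[2]})"
                    )
                seen.add(k)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom], title: str = "", source: str = "",
                   validate: bool = True) -> "Structure":
        if len(atoms) == 0:
            return cls.empty()
        return cls(
            chain_ids=np.array([a.chain_id for a in atoms]),
            res_nums=np.array([a.res_num for a in atoms]),
            res_names=np.array([a.res_name for a in atoms]),
            names=np.array([a.name for a in atoms]),
            elements=np.array([a.element for a in atoms]),
            coords=np.array([a.coords for a in atoms], dtype=np.float64),
            serials=np.array([a.serial for a in atoms]),
            title=title,
            source=source,
            validate=validate,
        )

    @classmethod
    def empty(cls) -> "Structure":
        z = np.zeros(0)
        return cls(
            chain_ids=np.zeros(0, dtype="U4"),
            res_nums=np.zeros(0, dtype=np.int64),
            res_names=np.zeros(0, dtype="U4"),
            names=np.zeros(0, dtype="U6"),
            elements=np.zeros(0, dtype="U2"),
            coords=z.reshape(0, 3),
            serials=np.zeros(0, dtype=np.int64),
            validate=False,
        )

    # -- basic protocol -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.chain_ids)

    def __getitem__(self, idx) -> "Structure":
        """Sub-structure by boolean mask or integer index array (topology order kept)."""
        return Structure(
            chain_ids=self.chain_ids[idx],
            res_nums=self.res_nums[idx],
            res_names=self.res_names[idx],
            names=self.names[idx],
            elements=self.elements[idx],
            coords=self.coords[idx],
            serials=self.serials[idx],
            title=self.title,
            source=self.source,
            validate=False,
        )

    def atoms(self) -> Iterator[Atom]:
        for i in range(len(self)):
            yield Atom(
                serial=int(self.serials[i]),
                name=str(self.names[i]),
                element=str(self.elements[i]),
                res_num=int(self.res_nums[i]),
                res_name=str(self.res_names[i]),
                chain_id=str(self.chain_ids[i]),
                coords=self.coords[i].copy(),
            )

    # -- derived views ------------------------------------------------------

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.isin(self.elements, ("H", "D"))

    @property
    def heavy_mask(self) -> np.ndarray:
        return ~self.is_hydrogen

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def residue_index(self) -> dict[tuple[str, int], np.ndarray]:
        """Map (chain_id, res_num) -> atom indices, in topology order."""
        if self._res_index is None:
            idx: dict[tuple[str, int], list[int]] = {}
            for i, (c, r) in enumerate(zip(self.chain_ids, self.res_nums)):
                idx.setdefault((str(c), int(r)), []).append(i)
            self._res_index = {k: np.array(v) for k, v in idx.items()}
        return self._res_index

    def residues(self) -> list[tuple[str, int, str, np.ndarray]]:
        """(chain_id, res_num, res_name, atom indices) per residue, topology order."""
        out = []
        for (c, r), ix in self.residue_index().items():
            out.append((c, r, str(self.res_names[ix[0]]), ix))
        return out

    def residue_name(self, chain_id: str, res_num: int) -> str:
        ix = self.residue_index()[(chain_id, res_num)]
        return str(self.res_names[ix[0]])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Same topology, new coordinates."""
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != self.coords.shape:
            raise StructureError(
                f"coordinate shape {coords.shape} != topology shape {self.coords.shape}"
            )
        s = Structure(
            chain_ids=self.chain_ids,
            res_nums=self.res_nums,
            res_names=self.res_names,
            names=self.names,
            elements=self.elements,
            coords=coords,
            serials=self.serials,
            title=self.title,
            source=self.source,
            validate=False,
        )
        s._res_index = self._res_index
        return s

    def copy(self) -> "Structure":
        return self.with_coords(self.coords.copy())

    def concat(self, other: "Structure") -> "Structure":
        return Structure(
            chain_ids=np.concatenate([self.chain_ids, other.chain_ids]),
            res_nums=np.concatenate([self.res_nums, other.res_nums]),
            res_names=np.concatenate([self.res_names, other.res_names]),
            names=np.concatenate([self.names, other.names]),
            elements=np.concatenate([self.elements, other.elements]),
            coords=np.vstack([self.coords, other.coords]),
            title=self.title,
            validate=False,
        )


class Trajectory:
    """Fixed-topology multi-frame coordinates with a constant frame interval."""

    def __init__(self, topology: Structure, frames: np.ndarray,
                 frame_interval_ps: float = 10.0):
        frames = np.asarray(frames, dtype=np.float64)
        if frames.ndim != 3 or frames.shape[1:] != (len(topology), 3):
            raise StructureError(
                f"frames shape {frames.shape} incompatible with topology of "
                f"{len(topology)} atoms"
            )
        if frame_interval_ps <= 0:
            raise StructureError("frame_interval_ps must be > 0")
        self.topology = topology
        self.frames = frames
        self.frame_interval_ps = float(frame_interval_ps)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in ps (frame_index x interval)."""
        return np.arange(self.n_frames) * self.frame_interval_ps

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def __iter__(self) -> Iterator[Structure]:
        for i in range(self.n_frames):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# Connexin annotation and analysis parameters
# ---------------------------------------------------------------------------

def _ranges_mask(res_nums: np.ndarray, ranges: Sequence[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(len(res_nums), dtype=bool)
    for lo, hi in ranges:
        mask |= (res_nums >= lo) & (res_nums <= hi)
    return mask


@dataclass
class ConnexinAnnotation:
    """Cx43 residue-range annotation (1-based inclusive PDB intervals).

    ``el1_range``/``el2_range`` are the extracellular loops carrying the
    conserved Cys triads; ``align_ranges_rmsd`` is the membrane segment used
    as the alignment base for extracellular RMSD.
    """

    el1_range: tuple[int, int] = (47, 73)
    el2_range: tuple[int, int] = (177, 203)
    tm_ranges_model: tuple[tuple[int, int], ...] = (
        (20, 46), (74, 94), (154, 176), (205, 226))
    align_ranges_rmsd: tuple[tuple[int, int], ...] = (
        (21, 46), (74, 93), (156, 176), (204, 229))
    interface_internal: tuple[int, int] = (55, 58)
    interface_external: tuple[int, int] = (194, 196)
    cys_el1: frozenset[int] = frozenset({54, 61, 65})
    cys_el2: frozenset[int] = frozenset({187, 192, 198})

    @property
    def cys_positions(self) -> frozenset[int]:
        return self.cys_el1 | self.cys_el2

    def is_extracellular(self, res_num: int) -> bool:
        return (self.el1_range[0] <= res_num <= self.el1_range[1]
                or self.el2_range[0] <= res_num <= self.el2_range[1])

    def extracellular_mask(self, res_nums: np.ndarray) -> np.ndarray:
        return _ranges_mask(res_nums, [self.el1_range, self.el2_range])

    def alignment_mask(self, res_nums: np.ndarray) -> np.ndarray:
        return _ranges_mask(res_nums, self.align_ranges_rmsd)


#: Canonical docking register between the two hemichannels (Cx43 GJC convention).
DEFAULT_SUBUNIT_PAIRING: dict[str, str] = {
    "A": "J", "B": "I", "C": "H", "D": "G", "E": "L", "F": "K",
}

#: Intra-subunit EL1-EL2 disulfide pairings: Cys(1)-Cys(3), Cys(2)-Cys(2), Cys(3)-Cys(1).
DEFAULT_SS_PAIRS: tuple[tuple[int, int], ...] = ((54, 198), (61, 192), (65, 187))

#: Bondi-style heavy-atom van der Waals radii (Å); hydrogens are excluded from
#: contact and pore computations altogether.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
}
DEFAULT_VDW_RADIUS: float = 1.70


@dataclass
class AnalysisParameters:
    """Every numeric constant of the analysis, with its literature default.

    Units are Å for distances and residues for sequence quantities.
    """

    sc_min_seq_separation: int = 10
    sc_vdw_tolerance: float = 1.0
    sc_triplet_min_contacts: int = 7
    sc_flank_width: int = 4
    sc_min_stability_fraction: float = 0.02
    hbond_HA_cutoff: float = 2.5
    cys_cys_SH_cutoff: float = 4.3
    cys_iface_S_heavy_cutoff: float = 4.1
    cys_iface_H_cutoff: float = 3.2
    clash_cutoff: float = 2.0
    ss_bond_SG_SG_cutoff: float = 2.3
    vdw_default: float = DEFAULT_VDW_RADIUS
    vdw_radii: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VDW_RADII))
    subunit_pairing: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SUBUNIT_PAIRING))
    ss_pairs: tuple[tuple[int, int], ...] = DEFAULT_SS_PAIRS
    hc_offsets: tuple[float, ...] = (1.0, 3.0, 5.0)

    def __post_init__(self) -> None:
        for name in ("sc_vdw_tolerance", "hbond_HA_cutoff", "cys_cys_SH_cutoff",
                     "cys_iface_S_heavy_cutoff", "cys_iface_H_cutoff",
                     "clash_cutoff", "ss_bond_SG_SG_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        fwd = self.subunit_pairing
        inv = {v: k for k, v in fwd.items()}
        full = {**fwd, **inv}
        for k, v in full.items():
            if full.get(v) != k:
                raise ValueError("subunit_pairing is not an involution")

    def vdw_radius(self, element: str) -> float:
        return self.vdw_radii.get(element.upper(), self.vdw_default)

    def vdw_radii_for(self, elements: np.ndarray) -> np.ndarray:
        """Vectorized vdW lookup for an element array."""
        out = np.full(len(elements), self.vdw_default)
        for el, r in self.vdw_radii.items():
            out[elements == el] = r
        return out

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["ss_pairs"] = [list(p) for p in self.ss_pairs]
        d["hc_offsets"] = list(self.hc_offsets)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisParameters":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_mapping(d)

    @classmethod
    def from_mapping(cls, d: Mapping) -> "AnalysisParameters":
        kwargs = dict(d)
        if "ss_pairs" in kwargs:
            kwargs["ss_pairs"] = tuple(tuple(p) for p in kwargs["ss_pairs"])
        if "hc_offsets" in kwargs:
            kwargs["hc_offsets"] = tuple(kwargs["hc_offsets"])
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Hemichannel membership
# ---------------------------------------------------------------------------

HC1_CHAINS = tuple("ABCDEF")
HC2_CHAINS = tuple("GHIJKL")


def hc_membership(
    chain_id: str,
    pairing: Mapping[str, str] | None = None,
) -> tuple[str, str]:
    """Classify a chain as HC1 (A-F) or HC2 (G-L) and return its docking partner.

    Returns
    -------
    (hc_label, partner_chain) : ("HC1" | "HC2", str)
    """
    if pairing is None:
        pairing = DEFAULT_SUBUNIT_PAIRING
    full = {**pairing, **{v: k for k, v in pairing.items()}}
    if chain_id in HC1_CHAINS:
        hc = "HC1"
    elif chain_id in HC2_CHAINS:
        hc = "HC2"
    else:
        raise GJDockError(
            f"unknown chain {chain_id!r}; valid chains are "
            f"{''.join(HC1_CHAINS)} (HC1) and {''.join(HC2_CHAINS)} (HC2)"
        )
    return hc, full[chain_id]


# ---------------------------------------------------------------------------
# Atom selection mini-language
# ---------------------------------------------------------------------------

def _parse_int_ranges(text: str, clause: str) -> list[tuple[int, int]]:
    out = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            raise SelectionError(f"empty range item in clause {clause!r}")
        if "-" in part[1:]:  # allow leading minus, though res_nums are 1-based
            lo_s, hi_s = part.split("-", 1)
            try:
                lo, hi = int(lo_s), int(hi_s)
            except ValueError:
                raise SelectionError(f"bad residue range {part!r} in clause {clause!r}")
        else:
            try:
                lo = hi = int(part)
            except ValueError:
                raise SelectionError(f"bad residue number {part!r} in clause {clause!r}")
        out.append((lo, hi))
    return out


def select_atoms(structure: Structure, query: str) -> Structure:
    """Select atoms with a small conjunctive query language.

    Clauses are joined with ``and``; each clause is one of::

        chain A[,B,...]          resnum 47-73[,100,...]
        resname CYS[,GLY,...]    name SG[,HG1,...]
        heavy                    hydrogen

    The selection preserves topology order; an empty result is valid.
    """
    mask = np.ones(len(structure), dtype=bool)
    query = query.strip()
    if not query:
        return structure[mask]
    for clause in (c.strip() for c in query.split(" and ")):
        if not clause:
            raise SelectionError("empty clause in query")
        parts = clause.split(None, 1)
        kw = parts[0].lower()
        if kw == "heavy":
            if len(parts) > 1:
                raise SelectionError(f"clause {clause!r}: 'heavy' takes no argument")
            mask &= structure.heavy_mask
        elif kw == "hydrogen":
            if len(parts) > 1:
                raise SelectionError(f"clause {clause!r}: 'hydrogen' takes no argument")
            mask &= structure.is_hydrogen
        elif kw in ("chain", "resname", "name"):
            if len(parts) != 2:
                raise SelectionError(f"clause {clause!r}: missing argument")
            vals = [v.strip() for v in parts[1].split(",") if v.strip()]
            if not vals:
                raise SelectionError(f"clause {clause!r}: no values given")
            arr = {"chain": structure.chain_ids,
                   "resname": structure.res_names,
                   "name": structure.names}[kw]
            mask &= np.isin(arr, vals)
        elif kw in ("resnum", "res"):
            if len(parts) != 2:
                raise SelectionError(f"clause {clause!r}: missing argument")
            ranges = _parse_int_ranges(parts[1], clause)
            mask &= _ranges_mask(structure.res_nums, ranges)
        else:
            raise SelectionError(f"unknown clause {clause!r}")
    return structure[mask]
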
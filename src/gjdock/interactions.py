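"""Categorized geometric H-bond detectors and disulfide-state operations.

Three detector families cover the redox-docking analysis:

* **trans-GJ H-bonds** — between the internal interface residues 55-58 of
  opposing hemichannels, donor atoms backbone N / Asn OD1 / Thr OG1 /
  Gln NE2 and acceptor atoms backbone O / Asn OD1 / Thr OG1 / Gln OE1,
  accepted when a donor-bound hydrogen is closer than 2.5 Å to the acceptor
  heavy atom.
* **Cys-Cys H-bonds** — thiol interactions of the reduced (open) state,
  between a Cys SG and another Cys' thiol hydrogen HG1, closer than 4.3 Å.
* **Cys-interface H-bonds** — between a Cys SG (donor or acceptor) and the
  55-58 interface atoms, requiring both the sulphur-heavy distance below
  4.1 Å and the donor-hydrogen distance below 3.2 Å.

Disulfide operations assign the canonical open/closed Cys states
(54-198, 61-192, 65-187 within each subunit) and read the state back from
geometry via the SG-SG distance.

PDB files carry no bond records, so a hydrogen is attributed to the nearest
heavy atom within 1.45 Å (covering N-H/O-H and the longer S-H thiol bond);
Thr/Cys thiol-hydrogen naming variants ("HG1" vs "HG") are accepted through
a synonym map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (
    AnalysisParameters,
    ConnexinAnnotation,
    GJDockError,
    Structure,
    Trajectory,
    hc_membership,
)

log = logging.getLogger(__name__)

AtomRef = tuple[str, int, str]  # (chain_id, res_num, atom_name)

#: Donor heavy atoms scanned on interface residues 55-58 (backbone N plus the
#: side-chain donors of Asn/Thr/Gln). Asn OD1 is kept in the donor list as
#: specified even though an sp2 oxygen normally carries no hydrogen; lacking
#: an attached H it simply never yields a bond (a debug notice is logged).
TRANS_GJ_DONORS: dict[str, tuple[str, ...]] = {
    "*": ("N",),
    "ASN": ("OD1",),
    "THR": ("OG1",),
    "GLN": ("NE2",),
}

#: Acceptor heavy atoms on interface residues 55-58.
TRANS_GJ_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "*": ("O",),
    "ASN": ("OD1",),
    "THR": ("OG1",),
    "GLN": ("OE1",),
}

#: Thiol hydrogen naming variants across force fields.
THIOL_H_NAMES = ("HG1", "HG")


@dataclass(frozen=True)
class HBond:
    """A geometric hydrogen bond of one of the three categories."""

    category: str  # "trans_gj" | "cys_cys" | "cys_interface"
    donor: AtomRef
    hydrogen: AtomRef | None
    acceptor: AtomRef
    distance: float  # the category's primary distance (Å)
    distance_secondary: float | None = None  # S-heavy distance (cys_interface)
    frame_index: int = 0
    subunit_pair_label: str | None = None

    @property
    def chains(self) -> tuple[str, str]:
        return self.donor[0], self.acceptor[0]


@dataclass(frozen=True)
class DisulfideBond:
    """An SG-SG disulfide record with its geometric state."""

    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    sg_sg_distance: float
    state: str  # "closed" | "open"
    canonical: bool


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def hydrogen_attachment(structure: Structure,
                        max_bond: float = 1.45) -> dict[int, list[int]]:
    """Map heavy-atom index -> attached hydrogen indices.

    A hydrogen belongs to the nearest heavy atom within ``max_bond`` Å
    (PDB files carry no explicit bonds); the default covers N-H/O-H
    (~1.0 Å) and the longer S-H thiol bond (~1.34 Å). Unattached hydrogens
    are ignored.
    """
    heavy_ix = np.flatnonzero(structure.heavy_mask)
    h_ix = np.flatnonzero(structure.is_hydrogen)
    out: dict[int, list[int]] = {}
    if len(heavy_ix) == 0 or len(h_ix) == 0:
        return out
    tree = cKDTree(structure.coords[heavy_ix])
    dists, nearest = tree.query(structure.coords[h_ix])
    for hi, d, ni in zip(h_ix, dists, nearest):
        if d <= max_bond:
            out.setdefault(int(heavy_ix[ni]), []).append(int(hi))
    return out


def _atom_ref(structure: Structure, i: int) -> AtomRef:
    return (str(structure.chain_ids[i]), int(structure.res_nums[i]),
            str(structure.names[i]))


def _pair_label(chain_a: str, chain_b: str,
                pairing: Mapping[str, str] | None) -> str | None:
    """Subunit-pair label when the two chains span the two hemichannels."""
    try:
        hc_a, _ = hc_membership(chain_a, pairing)
        hc_b, _ = hc_membership(chain_b, pairing)
    except GJDockError:
        return None
    if hc_a == hc_b:
        return None
    first, second = (chain_a, chain_b) if hc_a == "HC1" else (chain_b, chain_a)
    return f"{first}-{second}"


def _interface_atom_indices(
    structure: Structure,
    annotation: ConnexinAnnotation,
    roles: dict[str, tuple[str, ...]],
) -> list[int]:
    lo, hi = annotation.interface_internal
    in_iface = (structure.res_nums >= lo) & (structure.res_nums <= hi)
    out = []
    for i in np.flatnonzero(in_iface):
        res_name = str(structure.res_names[i])
        name = str(structure.names[i])
        if name in roles.get("*", ()) or name in roles.get(res_name, ()):
            out.append(int(i))
    return out


def _require_hydrogens(structure: Structure, donors: Sequence[int],
                       attach: dict[int, list[int]], category: str) -> None:
    if donors and not any(attach.get(d) for d in donors):
        if not structure.is_hydrogen.any():
            raise GJDockError(
                f"{category}: donor atoms present but the frame contains no "
                "hydrogens; explicit hydrogens are required for donor-H "
                "distance criteria")


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def detect_trans_gj_hbonds(
    frame: Structure,
    annotation: ConnexinAnnotation | None = None,
    pairing: Mapping[str, str] | None = None,
    params: AnalysisParameters | None = None,
    frame_index: int = 0,
    cross_hc_only: bool = True,
) -> list[HBond]:
    """Hydrogen bonds between interface residues 55-58 of opposing hemichannels.

    Every (donor hydrogen, acceptor heavy atom) pair below the 2.5 Å cutoff
    yields one bond. With ``cross_hc_only`` (default) the donor and acceptor
    chains must belong to different hemichannels; intra-HC 55-58 bonds can be
    requested by disabling it.
    """
    annotation = annotation or ConnexinAnnotation()
    params = params or AnalysisParameters()
    donors = _interface_atom_indices(frame, annotation, TRANS_GJ_DONORS)
    acceptors = _interface_atom_indices(frame, annotation, TRANS_GJ_ACCEPTORS)
    attach = hydrogen_attachment(frame)
    _require_hydrogens(frame, donors, attach, "trans-GJ H-bonds")
    for d in donors:
        if str(frame.names[d]) == "OD1" and attach.get(d):
            log.debug("trans-GJ: Asn OD1 donor carries a hydrogen (unusual)")
    out: list[HBond] = []
    cutoff = params.hbond_HA_cutoff
    for d in donors:
        for h in attach.get(d, ()):  # donor-bound hydrogens
            for a in acceptors:
                if d == a:
                    continue
                chain_d = str(frame.chain_ids[d])
                chain_a = str(frame.chain_ids[a])
                label = _pair_label(chain_d, chain_a, pairing)
                if cross_hc_only and label is None:
                    continue
                dist = float(np.linalg.norm(frame.coords[h] - frame.coords[a]))
                if dist < cutoff:
                    out.append(HBond(
                        category="trans_gj",
                        donor=_atom_ref(frame, d),
                        hydrogen=_atom_ref(frame, h),
                        acceptor=_atom_ref(frame, a),
                        distance=dist,
                        frame_index=frame_index,
                        subunit_pair_label=label,
                    ))
    return out


def _cys_sg_indices(structure: Structure,
                    scope: set[tuple[str, int]] | None) -> list[int]:
    mask = (structure.res_names == "CYS") & (structure.names == "SG")
    out = []
    for i in np.flatnonzero(mask):
        rid = (str(structure.chain_ids[i]), int(structure.res_nums[i]))
        if scope is None or rid in scope:
            out.append(int(i))
    return out


def _thiol_hydrogens(structure: Structure, sg_index: int,
                     attach: dict[int, list[int]]) -> list[int]:
    return [h for h in attach.get(sg_index, ())
            if str(structure.names[h]) in THIOL_H_NAMES]


def detect_cys_cys_hbonds(
    frame: Structure,
    scope: Iterable[tuple[str, int]] | None = None,
    params: AnalysisParameters | None = None,
    pairing: Mapping[str, str] | None = None,
    frame_index: int = 0,
) -> list[HBond]:
    """Thiol H-bonds of the reduced state: Cys SG vs another Cys' HG1 < 4.3 Å.

    Oxidized cysteines (no thiol hydrogen) contribute nothing as donors but
    remain possible acceptors. ``scope`` optionally restricts the Cys
    residues considered.
    """
    params = params or AnalysisParameters()
    scope_set = set(scope) if scope is not None else None
    sgs = _cys_sg_indices(frame, scope_set)
    attach = hydrogen_attachment(frame)
    out: list[HBond] = []
    cutoff = params.cys_cys_SH_cutoff
    for donor_sg in sgs:
        for h in _thiol_hydrogens(frame, donor_sg, attach):
            for acceptor_sg in sgs:
                if acceptor_sg == donor_sg:
                    continue
                dist = float(np.linalg.norm(
                    frame.coords[h] - frame.coords[acceptor_sg]))
                if dist < cutoff:
                    label = _pair_label(str(frame.chain_ids[donor_sg]),
                                        str(frame.chain_ids[acceptor_sg]),
                                        pairing)
                    out.append(HBond(
                        category="cys_cys",
                        donor=_atom_ref(frame, donor_sg),
                        hydrogen=_atom_ref(frame, h),
                        acceptor=_atom_ref(frame, acceptor_sg),
                        distance=dist,
                        frame_index=frame_index,
                        subunit_pair_label=label,
                    ))
    return out


def detect_cys_interface_hbonds(
    frame: Structure,
    annotation: ConnexinAnnotation | None = None,
    params: AnalysisParameters | None = None,
    pairing: Mapping[str, str] | None = None,
    frame_index: int = 0,
) -> list[HBond]:
    """H-bonds between Cys SG atoms and the 55-58 interface atoms.

    Both criteria must hold: sulphur-to-heavy-atom distance below 4.1 Å and
    donor-hydrogen-to-partner distance below 3.2 Å. The Cys may act as donor
    (its thiol H against the interface heavy atom) or as acceptor (the
    interface donor's H against the SG).
    """
    annotation = annotation or ConnexinAnnotation()
    params = params or AnalysisParameters()
    sgs = _cys_sg_indices(frame, None)
    iface_donors = _interface_atom_indices(frame, annotation, TRANS_GJ_DONORS)
    iface_acceptors = _interface_atom_indices(frame, annotation, TRANS_GJ_ACCEPTORS)
    iface_all = sorted(set(iface_donors) | set(iface_acceptors))
    attach = hydrogen_attachment(frame)
    out: list[HBond] = []
    s_cut = params.cys_iface_S_heavy_cutoff
    h_cut = params.cys_iface_H_cutoff
    for sg in sgs:
        for heavy in iface_all:
            s_dist = float(np.linalg.norm(frame.coords[sg] - frame.coords[heavy]))
            if s_dist >= s_cut:
                continue
            label = _pair_label(str(frame.chain_ids[sg]),
                                str(frame.chain_ids[heavy]), pairing)
            # Cys as donor: thiol H against the interface heavy atom
            for h in _thiol_hydrogens(frame, sg, attach):
                h_dist = float(np.linalg.norm(
                    frame.coords[h] - frame.coords[heavy]))
                if h_dist < h_cut:
                    out.append(HBond(
                        category="cys_interface",
                        donor=_atom_ref(frame, sg),
                        hydrogen=_atom_ref(frame, h),
                        acceptor=_atom_ref(frame, heavy),
                        distance=h_dist,
                        distance_secondary=s_dist,
                        frame_index=frame_index,
                        subunit_pair_label=label,
                    ))
            # Cys as acceptor: interface donor's hydrogen against the SG
            if heavy in iface_donors:
                for h in attach.get(heavy, ()):
                    h_dist = float(np.linalg.norm(
                        frame.coords[h] - frame.coords[sg]))
                    if h_dist < h_cut:
                        out.append(HBond(
                            category="cys_interface",
                            donor=_atom_ref(frame, heavy),
                            hydrogen=_atom_ref(frame, h),
                            acceptor=_atom_ref(frame, sg),
                            distance=h_dist,
                            distance_secondary=s_dist,
                            frame_index=frame_index,
                            subunit_pair_label=label,
                        ))
    return out


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def residue_label(res_num: int, res_name: str) -> str:
    """Figure-style residue label, e.g. 195Q or 65C."""
    return f"{res_num}{_AA1.get(res_name.upper(), 'X')}"


def hbond_timeseries(
    trajectory: Trajectory,
    detector: Callable[..., list[HBond]],
    chains_counted: str | Sequence[str] = "all",
    **detector_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, list[HBond]]:
    """Per-frame H-bond counts and per-residue-pair subunit-pair presence.

    ``detector`` is one of the module detectors; extra keyword arguments are
    forwarded to it. ``chains_counted`` restricts the count to bonds touching
    the given chains ("all" or an iterable such as "ABCDEF" to count only the
    A-F subunits, the convention used to compare hemichannel and dodecamer
    runs).

    Returns
    -------
    counts : DataFrame with columns frame, time_ps, n_bonds
    presence : DataFrame indexed by frame; one column per chain-agnostic
        residue-pair label (e.g. "57Q-195Q"), valued by the number of
        distinct subunit pairs exhibiting that bond in the frame
    bonds : flat list of all per-frame bond records
    """
    counted = None if chains_counted == "all" else set(chains_counted)
    all_bonds: list[HBond] = []
    counts = []
    presence_rows: list[dict[str, int]] = []
    for fi in range(trajectory.n_frames):
        frame = trajectory.frame(fi)
        res_names = {(str(c), int(r)): str(n) for c, r, n in
                     zip(frame.chain_ids, frame.res_nums, frame.res_names)}
        bonds = detector(frame, frame_index=fi, **detector_kwargs)
        all_bonds.extend(bonds)
        kept = [b for b in bonds
                if counted is None
                or b.donor[0] in counted or b.acceptor[0] in counted]
        counts.append(len(kept))
        by_label: dict[str, set[str]] = {}
        for b in kept:
            la = residue_label(b.donor[1], res_names[(b.donor[0], b.donor[1])])
            lb = residue_label(b.acceptor[1],
                               res_names[(b.acceptor[0], b.acceptor[1])])
            label = "-".join(sorted((la, lb)))
            pair = b.subunit_pair_label or f"{b.donor[0]}-{b.acceptor[0]}"
            by_label.setdefault(label, set()).add(pair)
        presence_rows.append({k: len(v) for k, v in by_label.items()})
    counts_df = pd.DataFrame({
        "frame": np.arange(trajectory.n_frames),
        "time_ps": trajectory.times,
        "n_bonds": counts,
    })
    presence_df = pd.DataFrame(presence_rows).fillna(0).astype(int)
    presence_df.index.name = "frame"
    return counts_df, presence_df, all_bonds


# ---------------------------------------------------------------------------
# Disulfides
# ---------------------------------------------------------------------------

def _canonical_cys_check(structure: Structure,
                         annotation: ConnexinAnnotation) -> None:
    index = structure.residue_index()
    for chain in structure.chains():
        for res in sorted(annotation.cys_positions):
            ix = index.get((chain, res))
            if ix is None or structure.res_names[ix[0]] != "CYS":
                raise GJDockError(
                    f"chain {chain}: canonical Cys {res} missing or not CYS")


def _sg_index(structure: Structure, chain: str, res: int) -> int:
    ix = structure.residue_index()[(chain, res)]
    for i in ix:
        if str(structure.names[i]) == "SG":
            return int(i)
    raise GJDockError(f"chain {chain} Cys {res}: no SG atom")


def assign_disulfides(
    structure: Structure,
    ss_pairs: Sequence[tuple[int, int]] | None = None,
    mode: str = "closed",
    params: AnalysisParameters | None = None,
    annotation: ConnexinAnnotation | None = None,
) -> tuple[Structure, list[DisulfideBond]]:
    """Set the canonical intra-subunit disulfide state on every chain.

    ``closed`` records the three canonical bonds per chain (54-198, 61-192,
    65-187) and strips thiol hydrogens; ``open`` records no bonds and ensures
    every canonical Cys carries an HG1 (placed 1.34 Å from SG, opposed to the
    SG-CB bond, when absent). Coordinates of existing atoms are never moved.
    """
    params = params or AnalysisParameters()
    annotation = annotation or ConnexinAnnotation()
    if ss_pairs is None:
        ss_pairs = params.ss_pairs
    if mode not in ("closed", "open"):
        raise GJDockError(f"unknown disulfide mode {mode!r}")
    _canonical_cys_check(structure, annotation)
    chains = structure.chains()
    bonds: list[DisulfideBond] = []
    if mode == "closed":
        drop = np.zeros(len(structure), dtype=bool)
        cys_res = annotation.cys_positions
        for i in range(len(structure)):
            if (str(structure.names[i]) in THIOL_H_NAMES
                    and str(structure.res_names[i]) == "CYS"
                    and int(structure.res_nums[i]) in cys_res):
                drop[i] = True
        out = structure[~drop] if drop.any() else structure.copy()
        for chain in chains:
            for ra, rb in ss_pairs:
                ia = _sg_index(structure, chain, ra)
                ib = _sg_index(structure, chain, rb)
                d = float(np.linalg.norm(
                    structure.coords[ia] - structure.coords[ib]))
                if d > params.ss_bond_SG_SG_cutoff:
                    log.warning(
                        "chain %s %d-%d: assigned closed but SG-SG = %.2f Å "
                        "exceeds %.2f Å", chain, ra, rb, d,
                        params.ss_bond_SG_SG_cutoff)
                bonds.append(DisulfideBond(chain, ra, chain, rb, d,
                                           state="closed", canonical=True))
        return out, bonds
    # open mode: add missing thiol hydrogens
    attach = hydrogen_attachment(structure)
    new_atoms: list[tuple[int, np.ndarray, str, int, str]] = []
    index = structure.residue_index()
    for chain in chains:
        for res in sorted(annotation.cys_positions):
            sg = _sg_index(structure, chain, res)
            if any(str(structure.names[h]) in THIOL_H_NAMES
                   for h in attach.get(sg, ())):
                continue
            cb = None
            for i in index[(chain, res)]:
                if str(structure.names[i]) == "CB":
                    cb = int(i)
                    break
            if cb is None:
                raise GJDockError(
                    f"chain {chain} Cys {res}: no CB atom to orient HG1")
            direction = structure.coords[sg] - structure.coords[cb]
            norm = np.linalg.norm(direction)
            if norm == 0:
                raise GJDockError(
                    f"chain {chain} Cys {res}: SG and CB coincide")
            pos = _place_thiol_h(structure, sg, direction / norm)
            new_atoms.append((sg, pos, chain, res, "HG1"))
    out = _insert_hydrogens(structure, new_atoms)
    return out, bonds


def _place_thiol_h(structure: Structure, sg: int,
                   preferred: np.ndarray) -> np.ndarray:
    """HG1 position 1.34 Å from SG, CB-opposed when sterically possible.

    Any other heavy atom closer to the hydrogen than its own SG would break
    the nearest-heavy attachment rule (e.g. the former disulfide partner's
    SG when opening a closed geometry), so directions are tried in a
    deterministic order and the first placement whose clearance exceeds the
    S-H bond length is used; failing that, the least-crowded one.
    """
    heavy_ix = np.flatnonzero(structure.heavy_mask)
    heavy_ix = heavy_ix[heavy_ix != sg]
    # two perpendiculars complete a deterministic candidate set
    seed_axis = np.array([1.0, 0.0, 0.0])
    if abs(preferred @ seed_axis) > 0.9:
        seed_axis = np.array([0.0, 1.0, 0.0])
    perp1 = np.cross(preferred, seed_axis)
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(preferred, perp1)
    best_pos, best_clearance = None, -np.inf
    for direction in (preferred, perp1, perp2, -perp1, -perp2):
        pos = structure.coords[sg] + direction * 1.34
        clearance = float(np.min(np.linalg.norm(
            structure.coords[heavy_ix] - pos, axis=1))) \
            if len(heavy_ix) else np.inf
        if clearance > 1.45:
            return pos
        if clearance > best_clearance:
            best_pos, best_clearance = pos, clearance
    return best_pos


def _insert_hydrogens(structure: Structure,
                      additions: list[tuple[int, np.ndarray, str, int, str]]
                      ) -> Structure:
    """Insert hydrogens immediately after their parent atoms."""
    if not additions:
        return structure.copy()
    order = sorted(additions, key=lambda t: t[0])
    chain_ids = list(structure.chain_ids)
    res_nums = list(structure.res_nums)
    res_names = list(structure.res_names)
    names = list(structure.names)
    elements = list(structure.elements)
    coords = list(structure.coords)
    for offset, (parent, pos, chain, res, name) in enumerate(order):
        at = parent + 1 + offset
        chain_ids.insert(at, chain)
        res_nums.insert(at, res)
        res_names.insert(at, "CYS")
        names.insert(at, name)
        elements.insert(at, "H")
        coords.insert(at, np.asarray(pos))
    return Structure(
        chain_ids=np.array(chain_ids),
        res_nums=np.array(res_nums),
        res_names=np.array(res_names),
        names=np.array(names),
        elements=np.array(elements),
        coords=np.array(coords),
        title=structure.title,
        source=structure.source,
    )


def detect_disulfides(
    structure: Structure,
    cutoff: float | None = None,
    params: AnalysisParameters | None = None,
) -> list[DisulfideBond]:
    """Read disulfides from geometry: SG-SG pairs within the bond cutoff.

    All Cys SG pairs (any chains) at distance <= cutoff (default 2.3 Å) are
    reported closed; pairs matching a canonical intra-subunit pairing are
    flagged canonical.
    """
    params = params or AnalysisParameters()
    if cutoff is None:
        cutoff = params.ss_bond_SG_SG_cutoff
    canonical = {tuple(sorted(p)) for p in params.ss_pairs}
    sgs = _cys_sg_indices(structure, None)
    if len(sgs) < 2:
        return []
    coords = structure.coords[sgs]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    bonds = []
    for i, j in pairs:
        ia, ib = sgs[i], sgs[j]
        ca, ra = str(structure.chain_ids[ia]), int(structure.res_nums[ia])
        cb, rb = str(structure.chain_ids[ib]), int(structure.res_nums[ib])
        if (ca, ra) > (cb, rb):
            (ca, ra), (cb, rb), ia, ib = (cb, rb), (ca, ra), ib, ia
        d = float(np.linalg.norm(structure.coords[ia] - structure.coords[ib]))
        if d > cutoff:
            continue
        is_canonical = ca == cb and tuple(sorted((ra, rb))) in canonical
        bonds.append(DisulfideBond(ca, ra, cb, rb, d, state="closed",
                                   canonical=is_canonical))
    bonds.sort(key=lambda b: (b.chain_a, b.res_a, b.chain_b, b.res_b))
    return bonds
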
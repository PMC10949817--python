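"""Synthetic structures and trajectories with planted, machine-checked truth.

Every analysis stage is testable without external data through four fixture
families:

* **SC strand fixtures** — pairs of toy chains whose residue geometry plants
  stabilization-center pairs, contacts that fail individual SC criteria, and
  a best-triplet-count-of-6 configuration.
* **Toy connexons** — one or two rings of six chains spanning residues
  20-230 with connexin-style numbering: canonical Cys at 54/61/65/187/192/198
  (closed disulfide geometry at 2.05 Å or open thiols), docking interfaces
  that plant known trans-GJ stabilization centers and H-bonds, and one
  thiol donor/acceptor Cys-Cys H-bond geometry per subunit.
* **Cylinder channels** — rings of atoms with an analytic inscribed-sphere
  radius (ring radius minus the vdW radius), the pore-profiling oracle.
* **Probe micro-fixtures** — minimal two-residue geometries placing a single
  candidate interaction at an exact distance, for cutoff boundary tests.

Trajectories are emulated as the base structure plus iid Gaussian jitter,
with scheduled interactions switched between their on/off geometries per
frame; the manifest records the exact per-frame truth. This is explicitly
not physical dynamics — it provides controlled ground truth, not realism.

Generators self-verify their manifests with the package detectors before
returning; a fixture that fails self-verification raises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .core import (
    AnalysisParameters,
    ConnexinAnnotation,
    GJDockError,
    HC1_CHAINS,
    HC2_CHAINS,
    Structure,
    Trajectory,
)
from .io import _infer_element


class FixtureError(GJDockError):
    """Infeasible fixture request or failed self-verification."""


@dataclass
class FixtureSpec:
    """Declarative fixture request (used by the CLI simulate command)."""

    kind: str  # contact-pair | sc-strands | toy-connexon | cylinder-channel
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# Structure builder
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self) -> None:
        self._chain: list[str] = []
        self._res_num: list[int] = []
        self._res_name: list[str] = []
        self._name: list[str] = []
        self._element: list[str] = []
        self._coords: list[np.ndarray] = []

    def atom(self, chain: str, res_num: int, res_name: str, name: str,
             pos: Sequence[float], element: str | None = None) -> int:
        self._chain.append(chain)
        self._res_num.append(res_num)
        self._res_name.append(res_name)
        self._name.append(name)
        self._element.append(element or _infer_element(name))
        self._coords.append(np.asarray(pos, dtype=float))
        return len(self._coords) - 1

    def backbone(self, chain: str, res_num: int, res_name: str,
                 center: np.ndarray,
                 offsets: Mapping[str, np.ndarray] | None = None) -> None:
        """Minimal backbone (N, CA, C, O) clustered around ``center``."""
        c = np.asarray(center, dtype=float)
        default = {
            "N": np.array([-0.35, 0.0, 0.15]),
            "CA": np.array([0.0, 0.0, 0.0]),
            "C": np.array([0.35, 0.0, 0.15]),
            "O": np.array([0.45, 0.0, -0.25]),
        }
        if offsets:
            default.update(offsets)
        for name in ("N", "CA", "C", "O"):
            self.atom(chain, res_num, res_name, name, c + default[name])

    def build(self, title: str = "") -> Structure:
        return Structure(
            chain_ids=np.array(self._chain),
            res_nums=np.array(self._res_num),
            res_names=np.array(self._res_name),
            names=np.array(self._name),
            elements=np.array(self._element),
            coords=np.array(self._coords),
            title=title,
        )


# ---------------------------------------------------------------------------
# SC strand fixtures
# ---------------------------------------------------------------------------

def make_sc_fixture(kind: str = "default", seed: int = 0,
                    verify: bool = True) -> tuple[Structure, dict]:
    """Strand fixtures with planted SC truth.

    Kinds
    -----
    default
        Chains A/B plant exactly one SC pair (A10-B10: dense cross-contacts
        over residues 9-11) plus chains C/D with a contact (C10-D10) whose
        flanks are splayed so the triplet criterion fails.
    crit1-fail
        A hairpin chain E where residues 8 and 13 are in tight contact with
        dense flank contacts but only 5 apart in sequence.
    six-of-nine
        Chains F/G where the best flank-triplet selection for F10-G10
        realizes exactly 6 of the 9 cross contacts.

    Returns the structure and a manifest with the planted truths and a
    schedulable ``sc_pair`` interaction (on/off geometries for chain B's
    close region) for the default kind.
    """
    b = _Builder()
    manifest: dict[str, Any] = {"kind": "sc-strands", "variant": kind,
                                "seed": seed}
    dx = 2.0
    if kind == "default":
        n_res = 19
        close_b = {9, 10, 11}
        for i in range(1, n_res + 1):
            b.backbone("A", i, "GLY", np.array([dx * i, 0.0, 0.0]))
        for i in range(1, n_res + 1):
            y = 3.0 if i in close_b else 15.0
            b.backbone("B", i, "GLY", np.array([dx * i, y, 0.0]))
        for i in range(1, n_res + 1):
            b.backbone("C", i, "GLY", np.array([dx * i, 0.0, 30.0]))
        for i in range(1, n_res + 1):
            y = 3.0 if i == 10 else 15.0
            b.backbone("D", i, "GLY", np.array([dx * i, y, 30.0]))
        manifest["planted_sc"] = [[["A", 10], ["B", 10]]]
        manifest["planted_contact_non_sc"] = [[["C", 10], ["D", 10]]]
    elif kind == "crit1-fail":
        # hairpin: top row 1-10, bottom row 11-20 folded back over it
        for i in range(1, 11):
            b.backbone("E", i, "GLY", np.array([dx * i, 0.0, 60.0]))
        for i in range(11, 21):
            b.backbone("E", i, "GLY", np.array([dx * (21 - i), 3.0, 60.0]))
        manifest["planted_crit1_fail"] = [[["E", 8], ["E", 13]]]
    elif kind == "six-of-nine":
        gy = 1.5
        for i in range(1, 20):
            y = 0.0 if i >= 10 else -12.0  # left flank of F10 bent away
            b.backbone("F", i, "GLY", np.array([dx * i, y, 90.0]))
        for i in range(1, 20):
            y = gy if i in (9, 10, 11) else 15.0
            b.backbone("G", i, "GLY", np.array([dx * i, y, 90.0]))
        manifest["planted_six_of_nine"] = [[["F", 10], ["G", 10]]]
    else:
        raise FixtureError(f"unknown sc fixture kind {kind!r}")
    structure = b.build(title=f"sc-strands:{kind}")

    if kind == "default":
        # schedulable interaction: chain B's close region swings away when off
        idx = np.flatnonzero(np.isin(structure.chain_ids, ["B"])
                             & np.isin(structure.res_nums, list(close_b)))
        on = structure.coords[idx].copy()
        off = on.copy()
        off[:, 1] += 12.0
        manifest["interactions"] = {
            "sc_pair": {"atom_indices": idx.tolist(),
                        "on": on.tolist(), "off": off.tolist()}}
    if verify:
        _verify_sc_fixture(structure, manifest)
    return structure, manifest


def _verify_sc_fixture(structure: Structure, manifest: dict) -> None:
    from .stabcenters import is_stabilization_center, residue_contact

    for pair in manifest.get("planted_sc", []):
        (ca, ra), (cb, rb) = pair
        if not is_stabilization_center(structure, (ca, ra), (cb, rb)):
            raise FixtureError(f"planted SC {pair} fails the SC criteria")
    for pair in manifest.get("planted_contact_non_sc", []):
        (ca, ra), (cb, rb) = pair
        ok, _ = residue_contact(structure, (ca, ra), (cb, rb))
        if not ok:
            raise FixtureError(f"planted contact {pair} is not in contact")
        if is_stabilization_center(structure, (ca, ra), (cb, rb)):
            raise FixtureError(f"planted non-SC {pair} passes the SC criteria")
    for pair in (manifest.get("planted_crit1_fail", [])
                 + manifest.get("planted_six_of_nine", [])):
        (ca, ra), (cb, rb) = pair
        ok, _ = residue_contact(structure, (ca, ra), (cb, rb))
        if not ok:
            raise FixtureError(f"planted pair {pair} is not in contact")
        if is_stabilization_center(structure, (ca, ra), (cb, rb)):
            raise FixtureError(f"planted failing pair {pair} passes")


# ---------------------------------------------------------------------------
# Toy connexon
# ---------------------------------------------------------------------------

#: residue identities at the special positions; all other residues are GLY
_SPECIAL_RES = {55: "ASN", 56: "THR", 57: "GLN", 58: "GLN",
                194: "HIS", 195: "GLN", 196: "VAL"}
_CYS_POSITIONS = (54, 61, 65, 187, 192, 198)

# tangential layout (Å, per-chain local frame): the internal interface
# residues 55-57, the external 194-196, the opposed-58 window shared by both
# rings, and three disulfide-pair windows. An HC2 chain is the 180-degree
# rotation of an HC1 chain about its radial axis (tangential and axial
# coordinates negated), so the two rings are congruent by a proper rotation
# — as in a real gap-junction channel — and the symmetric windows make each
# ring's internal residues face the partner ring's external residues.
_T_INTERNAL = {55: -1.8, 56: 0.0, 57: 1.8}
_T_EXTERNAL = {194: -1.8, 195: 0.0, 196: 1.8}
_WINDOW_INT = 6.0
_WINDOW_EXT = -6.0
_T_58 = 0.0
_H_58 = 2.0
_SS_WINDOWS = {(54, 198): -16.0, (61, 192): -26.0, (65, 187): -36.0}
_SS_HEIGHTS = {(54, 198): 3.0, (61, 192): 4.5, (65, 187): 1.5}
_H_INTERFACE = 0.5
_CYS_RADIAL = 4.0
_FILLER_RADIAL = -6.0
_FILLER_H0 = 6.0
_FILLER_DH = 0.8

#: HC2 chains at the same angular position as their HC1 docking partner
_HC2_ANGULAR_ORDER = {"J": 0, "I": 1, "H": 2, "G": 3, "L": 4, "K": 5}


def _expected_trans_sc_pairs(pairing: Mapping[str, str]) -> list[tuple]:
    pairs = []
    for x, y in pairing.items():
        for a, bres in (((x, 56), (y, 195)), ((y, 56), (x, 195))):
            lo, hi = sorted((a, bres))
            pairs.append((lo, hi))
    return sorted(set(pairs))


def make_toy_connexon(
    n_subunits: int = 12,
    disulfide_state: str = "closed",
    gap: float = 2.0,
    ring_radius: float = 80.0,
    plant_trans_gj_hbonds: bool | None = None,
    trans_hbond_distance: float = 2.3,
    seed: int = 0,
    verify: bool = True,
) -> tuple[Structure, dict]:
    """One (6 chains) or two (12 chains) toy connexin rings with known truth.

    Chains span residues 20-230; each chain is C6-symmetric about the z
    axis. The extracellular tips of the two rings face each other across
    ``gap`` Å so the internal interface residues 55-57 of one ring dock onto
    the external residues 194-196 of the partner ring (the pair (56,195) is
    a trans-GJ stabilization center on every docked subunit pair, in both
    directions), while the opposing 58Q side chains face each other across
    the gap.

    Disulfide geometry: ``closed`` puts the canonical SG pairs at 2.05 Å
    (no thiol hydrogens); ``open`` separates them to 4.4 Å and adds HG1 to
    every Cys, with the 65C thiol aimed at its 187C partner — one Cys-Cys
    H-bond donor/acceptor geometry per subunit.

    With ``plant_trans_gj_hbonds`` (default: on for dodecamers) each HC1
    chain's 58Q gets an NE2-bound hydrogen placed ``trans_hbond_distance``
    from the opposing 58Q OE1 — one trans-GJ H-bond per docked subunit
    pair.
    """
    if n_subunits not in (6, 12):
        raise FixtureError(f"n_subunits must be 6 or 12, got {n_subunits}")
    if disulfide_state not in ("open", "closed"):
        raise FixtureError(f"unknown disulfide state {disulfide_state!r}")
    docked = n_subunits == 12
    if plant_trans_gj_hbonds is None:
        plant_trans_gj_hbonds = docked
    if plant_trans_gj_hbonds and not docked:
        raise FixtureError("trans-GJ H-bond plants require two rings")
    params = AnalysisParameters()
    pairing = params.subunit_pairing

    b = _Builder()
    hbond_plant_atoms: dict[str, dict] = {}

    def chain_frame(chain: str) -> tuple[np.ndarray, np.ndarray, float]:
        """(radial unit, tangent unit, interface sign) for a chain."""
        if chain in HC1_CHAINS:
            k = HC1_CHAINS.index(chain)
            sign = 1.0  # ring sits below z=0; +z points at the interface
        else:
            k = _HC2_ANGULAR_ORDER[chain]
            sign = -1.0
        theta = math.radians(60.0 * k)
        u_r = np.array([math.cos(theta), math.sin(theta), 0.0])
        u_t = np.array([-math.sin(theta), math.cos(theta), 0.0])
        return u_r, u_t, sign

    def pos(chain: str, t: float, radial: float, h: float) -> np.ndarray:
        u_r, u_t, sign = chain_frame(chain)
        # sign = -1 rotates the chain 180 degrees about its radial axis
        z = -sign * (h + gap / 2.0)
        return (ring_radius + radial) * u_r + sign * t * u_t \
            + np.array([0, 0, z])

    def res_center(chain: str, res: int, filler_rank: int) -> tuple[np.ndarray, float, float, float]:
        """(center, t, radial, h) of a residue in its chain's local frame."""
        if res == 58:
            # opposed-58 window at t=0: under the HC2 rotation (t -> -t) the
            # 58Q side chains of docked subunits face each other directly
            return pos(chain, _T_58, 0.0, _H_58), _T_58, 0.0, _H_58
        if res in _T_INTERNAL:
            t = _WINDOW_INT + _T_INTERNAL[res]
            return pos(chain, t, 0.0, _H_INTERFACE), t, 0.0, _H_INTERFACE
        if res in _T_EXTERNAL:
            t = _WINDOW_EXT + _T_EXTERNAL[res]
            return pos(chain, t, 0.0, _H_INTERFACE), t, 0.0, _H_INTERFACE
        for (r1, r2), w in _SS_WINDOWS.items():
            if res in (r1, r2):
                half = 1.7 if disulfide_state == "closed" else 2.2
                t = w + (-half if res == r1 else half)
                h = _SS_HEIGHTS[(r1, r2)]
                return pos(chain, t, _CYS_RADIAL, h), t, _CYS_RADIAL, h
        # height follows the residue number so any pair >= 10 apart in
        # sequence is >= 8 Å apart axially (never a long-range contact)
        h = _FILLER_H0 + _FILLER_DH * (res - 20)
        return pos(chain, 0.0, _FILLER_RADIAL, h), 0.0, _FILLER_RADIAL, h

    chains = list(HC1_CHAINS) + (list(HC2_CHAINS) if docked else [])
    for chain in chains:
        u_r, u_t, sign = chain_frame(chain)
        zdir = np.array([0.0, 0.0, sign])  # towards the docking interface
        # small backbone offsets in the chain's local frame; the tangential
        # and axial components rotate with the ring (sign/zdir)
        ut_s = sign * u_t
        offsets = {
            "N": -0.35 * ut_s + 0.15 * zdir,
            "CA": np.zeros(3),
            "C": 0.35 * ut_s + 0.15 * zdir,
            "O": 0.45 * ut_s - 0.25 * zdir,
        }
        filler_rank = 0
        for res in range(20, 231):
            res_name = _SPECIAL_RES.get(res, "CYS" if res in _CYS_POSITIONS
                                        else "GLY")
            center, t, radial, h = res_center(chain, res, filler_rank)
            if res not in _SPECIAL_RES and res not in _CYS_POSITIONS:
                filler_rank += 1
            b.backbone(chain, res, res_name, center, offsets)
            if res_name == "CYS":
                _add_cys_side_chain(b, chain, res, center, t, radial, h,
                                    disulfide_state, pos, u_t)
            elif res_name == "ASN":
                b.atom(chain, res, res_name, "OD1", center + 0.4 * u_r
                       + 0.3 * zdir)
            elif res_name == "THR":
                b.atom(chain, res, res_name, "OG1", center + 0.4 * u_r
                       + 0.3 * zdir)
            elif res_name == "GLN":
                planted_donor = (plant_trans_gj_hbonds and res == 58
                                 and chain in HC1_CHAINS)
                if planted_donor:
                    ne2 = center + 0.4 * zdir
                    hpos = ne2 + 1.0 * zdir
                    b.atom(chain, res, res_name, "NE2", ne2)
                    b.atom(chain, res, res_name, "HE21", hpos, element="H")
                    b.atom(chain, res, res_name, "OE1",
                           center + 0.4 * ut_s + 0.3 * zdir)
                    hbond_plant_atoms[chain] = {"h": hpos}
                else:
                    b.atom(chain, res, res_name, "NE2",
                           center + 0.4 * ut_s + 0.3 * zdir)
                    b.atom(chain, res, res_name, "OE1",
                           center - 0.4 * ut_s + 0.3 * zdir)

    structure = b.build(title=f"toy-connexon:{n_subunits}:{disulfide_state}")

    # position the acceptor OE1 of the opposing 58Q at the plant distance
    oe1_indices: list[int] = []
    if plant_trans_gj_hbonds:
        for donor_chain, info in hbond_plant_atoms.items():
            acc_chain = pairing[donor_chain]
            center58, _, _, _ = res_center(acc_chain, 58, 0)
            hpos = info["h"]
            direction = center58 - hpos
            direction /= np.linalg.norm(direction)
            oe1_pos = hpos + trans_hbond_distance * direction
            idx = _atom_index(structure, acc_chain, 58, "OE1")
            structure.coords[idx] = oe1_pos
            oe1_indices.append(idx)

    manifest = _connexon_manifest(structure, n_subunits, disulfide_state,
                                  docked, plant_trans_gj_hbonds, gap,
                                  pairing, oe1_indices, seed)
    if verify:
        _verify_connexon(structure, manifest, params)
    return structure, manifest


def _add_cys_side_chain(b: _Builder, chain: str, res: int, center: np.ndarray,
                        t: float, radial: float, h: float, state: str,
                        pos, u_t: np.ndarray) -> None:
    pair = next(p for p in _SS_WINDOWS if res in p)
    w = _SS_WINDOWS[pair]
    is_first = res == pair[0]
    if state == "closed":
        # SG pair across the window midline at 2.05 Å
        sg = pos(chain, w + (-1.025 if is_first else 1.025), radial, h)
    else:
        u_r = pos(chain, 0, 1, 0) - pos(chain, 0, 0, 0)  # radial unit
        sg = center + 1.5 * u_r
    cb = center + 0.5 * (sg - center)
    b.atom(chain, res, "CYS", "CB", cb)
    b.atom(chain, res, "CYS", "SG", sg)
    if state == "open":
        u_r = pos(chain, 0, 1, 0) - pos(chain, 0, 0, 0)
        if res == 65:
            # thiol aimed at the partner 187C SG: the donor geometry
            partner_sg = pos(chain, w + 2.2, radial, h) + 1.5 * u_r
            direction = partner_sg - sg
            direction /= np.linalg.norm(direction)
            hg1 = sg + 1.34 * direction
        else:
            hg1 = sg + 1.34 * u_r
        b.atom(chain, res, "CYS", "HG1", hg1, element="H")


def _atom_index(structure: Structure, chain: str, res: int, name: str) -> int:
    for i in structure.residue_index()[(chain, res)]:
        if str(structure.names[i]) == name:
            return int(i)
    raise FixtureError(f"atom {chain}:{res}:{name} not found")


def _connexon_manifest(structure: Structure, n_subunits: int, state: str,
                       docked: bool, planted_hbonds: bool, gap: float,
                       pairing: Mapping[str, str], oe1_indices: list[int],
                       seed: int) -> dict:
    expected = {
        "n_disulfides": 3 * n_subunits if state == "closed" else 0,
        "n_cys_cys_hbonds": n_subunits if state == "open" else 0,
        "n_trans_gj_hbonds": 6 if planted_hbonds else 0,
        "trans_gj_sc_pairs": (
            [[list(a), list(b)] for a, b in _expected_trans_sc_pairs(pairing)]
            if docked else []),
    }
    manifest: dict[str, Any] = {
        "kind": "toy-connexon", "n_subunits": n_subunits,
        "disulfide_state": state, "gap": gap, "seed": seed,
        "chains": structure.chains(), "expected": expected,
        "interactions": {},
    }
    if planted_hbonds and oe1_indices:
        on = structure.coords[oe1_indices].copy()
        off = on.copy()
        off[:, 2] += np.where(on[:, 2] > 0, 3.0, -3.0)  # pull away from donor
        manifest["interactions"]["trans_gj_hbonds"] = {
            "atom_indices": list(map(int, oe1_indices)),
            "on": on.tolist(), "off": off.tolist()}
    if state == "open":
        idx = [
            _atom_index(structure, chain, 65, "HG1")
            for chain in structure.chains()]
        on = structure.coords[idx].copy()
        sg = np.array([structure.coords[_atom_index(structure, c, 65, "SG")]
                       for c in structure.chains()])
        # off: thiol re-oriented radially, out of donor range
        radial = sg[:, :2] / np.linalg.norm(sg[:, :2], axis=1, keepdims=True)
        off = sg.copy()
        off[:, :2] += 1.34 * radial
        manifest["interactions"]["cys_cys_hbonds"] = {
            "atom_indices": list(map(int, idx)),
            "on": on.tolist(), "off": off.tolist()}
    return manifest


def _verify_connexon(structure: Structure, manifest: dict,
                     params: AnalysisParameters) -> None:
    from .interactions import (
        detect_cys_cys_hbonds,
        detect_disulfides,
        detect_trans_gj_hbonds,
    )
    from .stabcenters import detect_scs_frame

    exp = manifest["expected"]
    ss = detect_disulfides(structure, params=params)
    if len(ss) != exp["n_disulfides"] or not all(b.canonical for b in ss):
        raise FixtureError(
            f"disulfide self-check failed: {len(ss)} found, "
            f"{exp['n_disulfides']} expected")
    cys = detect_cys_cys_hbonds(structure, params=params)
    if len(cys) != exp["n_cys_cys_hbonds"]:
        raise FixtureError(
            f"cys-cys H-bond self-check failed: {len(cys)} found, "
            f"{exp['n_cys_cys_hbonds']} expected")
    if exp["n_trans_gj_hbonds"]:
        tg = detect_trans_gj_hbonds(structure, params=params)
        if len(tg) != exp["n_trans_gj_hbonds"]:
            raise FixtureError(
                f"trans-GJ H-bond self-check failed: {len(tg)} found, "
                f"{exp['n_trans_gj_hbonds']} expected")
    if exp["trans_gj_sc_pairs"]:
        scope = {(c, r) for c in manifest["chains"]
                 for r in (55, 56, 57, 58, 194, 195, 196)}
        scs = detect_scs_frame(structure, scope=scope, params=params)
        found = sorted({tuple(sorted(((p.res_a[0], p.res_a[1]),
                                      (p.res_b[0], p.res_b[1]))))
                        for p in scs if p.is_trans_gj})
        expected = sorted(tuple((tuple(a), tuple(b)))
                          for a, b in exp["trans_gj_sc_pairs"])
        if found != expected:
            raise FixtureError(
                f"trans-GJ SC self-check failed: found {found[:6]}... "
                f"({len(found)}), expected {len(expected)}")


# ---------------------------------------------------------------------------
# Cylinder channels
# ---------------------------------------------------------------------------

def make_cylinder_channel(
    ring_radii: Sequence[float],
    z_step: float = 1.0,
    atoms_per_ring: int = 24,
    element: str = "C",
    z0: float = 0.0,
    params: AnalysisParameters | None = None,
) -> tuple[Structure, dict]:
    """Stacked atom rings forming a channel of known radius profile.

    Ring ``i`` sits at ``z0 + i*z_step`` with the given radius; the analytic
    inscribed-sphere radius at each ring plane is ``ring_radius - r_vdw``.
    """
    params = params or AnalysisParameters()
    r_vdw = params.vdw_radius(element)
    radii = [float(r) for r in ring_radii]
    if any(r <= r_vdw for r in radii):
        raise FixtureError(
            f"ring radii must exceed the vdW radius {r_vdw} Å")
    b = _Builder()
    for i, r in enumerate(radii):
        z = z0 + i * z_step
        for j in range(atoms_per_ring):
            phi = 2 * math.pi * j / atoms_per_ring
            b.atom("A", i + 1, "CYL", f"{element}{j + 1}",
                   (r * math.cos(phi), r * math.sin(phi), z), element=element)
    structure = b.build(title="cylinder-channel")
    manifest = {
        "kind": "cylinder-channel",
        "z": [z0 + i * z_step for i in range(len(radii))],
        "ring_radii": radii,
        "analytic_radius": [r - r_vdw for r in radii],
        "element": element,
    }
    return structure, manifest


# ---------------------------------------------------------------------------
# Probe micro-fixtures (threshold boundary tests)
# ---------------------------------------------------------------------------

def make_contact_probe(distance: float, element: str = "C") -> Structure:
    """Two single-atom residues on chains A/B at an exact distance."""
    b = _Builder()
    b.atom("A", 10, "GLY", "CA", (0.0, 0.0, 0.0), element=element)
    b.atom("B", 10, "GLY", "CA", (distance, 0.0, 0.0), element=element)
    return b.build(title="contact-probe")


def make_hbond_probe(category: str, primary_distance: float,
                     s_heavy_distance: float | None = None) -> Structure:
    """A minimal structure with one candidate H-bond at exact distances.

    ``trans_gj``: Gln 58 NE2-H on chain A (HC1) vs Gln 58 OE1 on chain J
    (HC2), the hydrogen-acceptor distance set to ``primary_distance``.
    ``cys_cys``: Cys 61 thiol (SG-HG1) on chain A vs Cys 192 SG on chain B,
    HG1-SG distance = ``primary_distance``.
    ``cys_interface``: Cys 61 SG/HG1 vs Gln 58 backbone O on the same chain,
    S-O distance = ``s_heavy_distance``, HG1-O distance =
    ``primary_distance``.
    """
    b = _Builder()
    if category == "trans_gj":
        b.atom("A", 58, "GLN", "CA", (0.0, 0.0, -1.0))
        b.atom("A", 58, "GLN", "NE2", (0.0, 0.0, 0.0))
        b.atom("A", 58, "GLN", "HE21", (0.0, 0.0, 1.0), element="H")
        b.atom("J", 58, "GLN", "OE1", (0.0, 0.0, 1.0 + primary_distance))
        b.atom("J", 58, "GLN", "CA", (0.0, 0.0, 2.2 + primary_distance))
    elif category == "cys_cys":
        b.atom("A", 61, "CYS", "CA", (0.0, 0.0, 0.0))
        b.atom("A", 61, "CYS", "CB", (0.6, 0.0, 0.0))
        b.atom("A", 61, "CYS", "SG", (1.5, 0.0, 0.0))
        b.atom("A", 61, "CYS", "HG1", (2.5, 0.0, 0.0), element="H")
        b.atom("B", 192, "CYS", "SG", (2.5 + primary_distance, 0.0, 0.0))
        b.atom("B", 192, "CYS", "CA", (4.0 + primary_distance, 0.0, 0.0))
    elif category == "cys_interface":
        if s_heavy_distance is None:
            raise FixtureError("cys_interface probe needs s_heavy_distance")
        s, h = s_heavy_distance, primary_distance
        bond = 1.34
        a = (s**2 + bond**2 - h**2) / (2 * s)
        if abs(a) > bond:
            raise FixtureError(
                f"no thiol-H placement for S-heavy {s} and H {h}")
        bcoord = math.sqrt(bond**2 - a**2)
        b.atom("A", 61, "CYS", "CB", (-0.8, 0.0, 0.0))
        b.atom("A", 61, "CYS", "SG", (0.0, 0.0, 0.0))
        b.atom("A", 61, "CYS", "HG1", (a, bcoord, 0.0), element="H")
        b.atom("A", 58, "GLN", "CA", (s, 0.0, 1.3))
        b.atom("A", 58, "GLN", "O", (s, 0.0, 0.0))
    else:
        raise FixtureError(f"unknown probe category {category!r}")
    return b.build(title=f"hbond-probe:{category}")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def deterministic_schedule(n_frames: int, fraction: float) -> np.ndarray:
    """Boolean schedule: the first round(fraction*n) frames on, rest off."""
    k = int(round(fraction * n_frames))
    out = np.zeros(n_frames, dtype=bool)
    out[:k] = True
    return out


def bernoulli_schedule(n_frames: int, p: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Iid Bernoulli(p) on/off schedule."""
    return rng.random(n_frames) < p


def make_trajectory(
    base: Structure,
    jitter_sigma: float = 0.0,
    schedule: Mapping[str, Sequence[bool]] | None = None,
    n_frames: int = 100,
    interval_ps: float = 10.0,
    seed: int = 0,
    interactions: Mapping[str, Mapping] | None = None,
) -> tuple[Trajectory, dict]:
    """Emulated trajectory: base + iid Gaussian jitter + scheduled events.

    ``schedule`` maps interaction names (keys of ``interactions``, normally
    a fixture manifest's ``interactions`` block) to per-frame booleans;
    scheduled atoms are placed exactly at their on/off coordinates (no
    jitter) so the per-frame truth in the returned manifest is exact.
    """
    schedule = dict(schedule or {})
    interactions = dict(interactions or {})
    for name in schedule:
        if name not in interactions:
            raise FixtureError(f"schedule references unknown interaction "
                               f"{name!r}")
        if len(schedule[name]) != n_frames:
            raise FixtureError(
                f"schedule for {name!r} has {len(schedule[name])} entries, "
                f"expected {n_frames}")
    rng = np.random.default_rng(seed)
    n_atoms = len(base)
    frames = np.repeat(base.coords[None, :, :], n_frames, axis=0)
    if jitter_sigma > 0:
        frames += rng.normal(scale=jitter_sigma, size=frames.shape)
    for name, flags in schedule.items():
        inter = interactions[name]
        idx = np.asarray(inter["atom_indices"], dtype=int)
        on = np.asarray(inter["on"], dtype=float)
        off = np.asarray(inter["off"], dtype=float)
        for fi, flag in enumerate(flags):
            frames[fi, idx] = on if flag else off
    trajectory = Trajectory(topology=base, frames=frames,
                            frame_interval_ps=interval_ps)
    manifest = {
        "kind": "trajectory",
        "n_frames": n_frames,
        "frame_interval_ps": interval_ps,
        "jitter_sigma": jitter_sigma,
        "seed": seed,
        "schedule": {k: np.asarray(v, dtype=bool).tolist()
                     for k, v in schedule.items()},
        "truth_fraction": {k: float(np.mean(np.asarray(v, dtype=bool)))
                           for k, v in schedule.items()},
    }
    return trajectory, manifest


# ---------------------------------------------------------------------------
# Spec dispatch
# ---------------------------------------------------------------------------

def make_fixture(spec: FixtureSpec) -> tuple[Structure, dict]:
    """Build a fixture from a declarative spec (CLI entry point)."""
    if spec.kind == "sc-strands":
        return make_sc_fixture(seed=spec.seed, **spec.params)
    if spec.kind == "toy-connexon":
        return make_toy_connexon(seed=spec.seed, **spec.params)
    if spec.kind == "cylinder-channel":
        return make_cylinder_channel(**spec.params)
    if spec.kind == "contact-pair":
        return make_contact_probe(**spec.params), {"kind": "contact-pair"}
    raise FixtureError(f"unknown fixture kind {spec.kind!r}")
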
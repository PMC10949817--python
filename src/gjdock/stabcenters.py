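"""Stabilization-center (SC) detection and trajectory-level SC dynamics.

An SC is a residue pair held together by long-range interactions: the two
residues must (1) be at least 10 apart in sequence (pairs on different chains
pass this automatically), (2) have at least one heavy-atom pair closer than
the sum of the atoms' van der Waals radii plus 1.0 Å, and (3) admit triplets
{left-neighbour, residue, right-neighbour} — one neighbour chosen from each
flanking tetrapeptide — such that at least 7 of the 9 cross-triplet residue
pairs are in contact by criterion (2).

Detected per frame, SCs are aggregated into stability fractions (fraction of
frames present); reportable extracellular SCs are those involving an EL1/EL2
residue and present in at least 2% of the run. Pairs spanning the two
hemichannels are the trans-GJ SCs central to the docking analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core import (
    AnalysisParameters,
    ConnexinAnnotation,
    GJDockError,
    HC1_CHAINS,
    HC2_CHAINS,
    Structure,
    Trajectory,
    hc_membership,
)

ResidueId = tuple[str, int]  # (chain_id, res_num)


@dataclass(frozen=True)
class SCPair:
    """A stabilization-center residue pair detected in one frame."""

    res_a: tuple[str, int, str]  # (chain, res_num, res_name)
    res_b: tuple[str, int, str]
    frame_index: int
    min_heavy_distance: float
    contact_atom_pair: tuple[str, str]
    is_trans_gj: bool
    subunit_pair_label: str | None

    @property
    def key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.res_a[0], self.res_a[1]), (self.res_b[0], self.res_b[1]))


def classify_trans_gj(
    chain_a: str,
    chain_b: str,
    pairing: Mapping[str, str] | None = None,
) -> tuple[str, str | None]:
    """Classify a residue pair's chain relationship.

    Returns one of ``intra-subunit``, ``inter-subunit-intra-HC`` or
    ``trans-GJ``; trans-GJ pairs get a subunit-pair label ("A-J" for a
    canonical docking pair, the literal chain pair otherwise).
    """
    hc_a, partner_a = hc_membership(chain_a, pairing)
    hc_b, _ = hc_membership(chain_b, pairing)
    if chain_a == chain_b:
        return "intra-subunit", None
    if hc_a == hc_b:
        return "inter-subunit-intra-HC", None
    first, second = (chain_a, chain_b) if hc_a == "HC1" else (chain_b, chain_a)
    if partner_a == chain_b:
        return "trans-GJ", f"{first}-{second}"
    return "trans-GJ", f"{first}-{second}"


class _FrameContext:
    """Cached per-frame residue geometry for SC evaluation."""

    def __init__(self, structure: Structure, params: AnalysisParameters):
        self.structure = structure
        self.params = params
        heavy = structure.heavy_mask
        self.res_atoms: dict[ResidueId, np.ndarray] = {}
        self.res_names: dict[ResidueId, str] = {}
        for chain, res, res_name, ix in structure.residues():
            hix = ix[heavy[ix]]
            self.res_atoms[(chain, res)] = hix
            self.res_names[(chain, res)] = res_name
        self.radii = params.vdw_radii_for(structure.elements)
        self._contact_cache: dict[tuple[ResidueId, ResidueId], tuple[bool, float, tuple[str, str]]] = {}
        self.chain_residues: dict[str, set[int]] = {}
        for chain, res in self.res_atoms:
            self.chain_residues.setdefault(chain, set()).add(res)

    def contact(self, a: ResidueId, b: ResidueId) -> tuple[bool, float, tuple[str, str]]:
        """(in_contact, min heavy distance, closest atom-name pair)."""
        key = (a, b) if a <= b else (b, a)
        hit = self._contact_cache.get(key)
        if hit is None:
            hit = self._compute_contact(*key)
            self._contact_cache[key] = hit
        return hit

    def _compute_contact(self, a: ResidueId, b: ResidueId):
        ia = self.res_atoms.get(a)
        ib = self.res_atoms.get(b)
        if ia is None or ib is None or len(ia) == 0 or len(ib) == 0:
            missing = a if ia is None or len(ia or []) == 0 else b
            raise GJDockError(f"residue {missing} has no heavy atoms")
        s = self.structure
        d = cdist(s.coords[ia], s.coords[ib])
        thr = self.radii[ia][:, None] + self.radii[ib][None, :] + self.params.sc_vdw_tolerance
        in_contact = bool((d < thr).any())
        flat = int(np.argmin(d))
        i, j = np.unravel_index(flat, d.shape)
        names = (str(s.names[ia[i]]), str(s.names[ib[j]]))
        return in_contact, float(d[i, j]), names

    def flanks(self, res: ResidueId) -> tuple[list[ResidueId], list[ResidueId]]:
        """Existing residues of the left/right flanking tetrapeptides."""
        chain, num = res
        present = self.chain_residues.get(chain, set())
        w = self.params.sc_flank_width
        left = [(chain, n) for n in range(num - w, num) if n in present]
        right = [(chain, n) for n in range(num + 1, num + w + 1) if n in present]
        return left, right


def residue_contact(
    structure: Structure,
    res_a: ResidueId,
    res_b: ResidueId,
    params: AnalysisParameters | None = None,
) -> tuple[bool, float]:
    """Heavy-atom contact test: any pair closer than vdW(a)+vdW(b)+tolerance.

    Returns the verdict and the minimum heavy-atom distance (Å).
    """
    ctx = _FrameContext(structure, params or AnalysisParameters())
    ok, dmin, _ = ctx.contact(res_a, res_b)
    return ok, dmin


def _triplet_criterion(ctx: _FrameContext, a: ResidueId, b: ResidueId) -> bool:
    """Criterion 3: some flank-triplet choice gives >= 7 of 9 cross contacts."""
    la, ra = ctx.flanks(a)
    lb, rb = ctx.flanks(b)
    if not la or not ra or not lb or not rb:
        return False  # a side with no residues admits no triplet
    need = ctx.params.sc_triplet_min_contacts
    cand_a = set(la + [a] + ra)
    cand_b = set(lb + [b] + rb)
    cmat = {(x, y): ctx.contact(x, y)[0] for x in cand_a for y in cand_b}
    for x in la:
        for y in ra:
            for u in lb:
                for v in rb:
                    trip_a = (x, a, y)
                    trip_b = (u, b, v)
                    n = sum(cmat[(p, q)] for p in trip_a for q in trip_b)
                    if n >= need:
                        return True
    return False


def is_stabilization_center(
    structure: Structure,
    res_a: ResidueId,
    res_b: ResidueId,
    params: AnalysisParameters | None = None,
    _ctx: _FrameContext | None = None,
) -> bool:
    """Full three-criterion SC test for one residue pair (symmetric)."""
    ctx = _ctx or _FrameContext(structure, params or AnalysisParameters())
    chain_a, num_a = res_a
    chain_b, num_b = res_b
    if res_a == res_b:
        return False
    if chain_a == chain_b and abs(num_a - num_b) < ctx.params.sc_min_seq_separation:
        return False
    if not ctx.contact(res_a, res_b)[0]:
        return False
    return _triplet_criterion(ctx, res_a, res_b)


def _candidate_pairs(ctx: _FrameContext) -> list[tuple[ResidueId, ResidueId]]:
    """Residue pairs with any heavy-atom pair within the largest possible
    contact threshold, found with a KD-tree prefilter."""
    s = ctx.structure
    heavy_ix = np.flatnonzero(s.heavy_mask)
    if len(heavy_ix) == 0:
        return []
    coords = s.coords[heavy_ix]
    max_r = max([*ctx.params.vdw_radii.values(), ctx.params.vdw_default])
    max_thr = 2 * max_r + ctx.params.sc_vdw_tolerance
    tree = cKDTree(coords)
    atom_pairs = tree.query_pairs(max_thr, output_type="ndarray")
    res_of = [(str(s.chain_ids[i]), int(s.res_nums[i])) for i in heavy_ix]
    seen: set[tuple[ResidueId, ResidueId]] = set()
    for i, j in atom_pairs:
        ra, rb = res_of[i], res_of[j]
        if ra == rb:
            continue
        pair = (ra, rb) if ra <= rb else (rb, ra)
        seen.add(pair)
    return sorted(seen)


def _in_scope(pair: tuple[ResidueId, ResidueId],
              scope: set[ResidueId] | None) -> bool:
    if scope is None:
        return True
    return pair[0] in scope or pair[1] in scope


def detect_scs_frame(
    structure: Structure,
    scope: Iterable[ResidueId] | None = None,
    params: AnalysisParameters | None = None,
    frame_index: int = 0,
    pairing: Mapping[str, str] | None = None,
) -> list[SCPair]:
    """All stabilization-center pairs of one frame.

    ``scope`` restricts the result to pairs with at least one residue in the
    given (chain, res_num) set; ``None`` means all residues. Pairs are
    annotated with their minimum heavy-atom distance, the closest atom-name
    pair, and their chain relationship (trans-GJ pairs get a subunit label).
    """
    params = params or AnalysisParameters()
    ctx = _FrameContext(structure, params)
    scope_set = set(scope) if scope is not None else None
    if scope_set is not None and not scope_set:
        return []
    out: list[SCPair] = []
    for ra, rb in _candidate_pairs(ctx):
        if not _in_scope((ra, rb), scope_set):
            continue
        if not is_stabilization_center(structure, ra, rb, _ctx=ctx):
            continue
        _, dmin, atoms = ctx.contact(ra, rb)
        try:
            category, label = classify_trans_gj(ra[0], rb[0], pairing)
            is_trans = category == "trans-GJ"
        except GJDockError:
            is_trans, label = False, None
        out.append(SCPair(
            res_a=(ra[0], ra[1], ctx.res_names[ra]),
            res_b=(rb[0], rb[1], ctx.res_names[rb]),
            frame_index=frame_index,
            min_heavy_distance=dmin,
            contact_atom_pair=atoms,
            is_trans_gj=is_trans,
            subunit_pair_label=label,
        ))
    return out


def _pair_class(chain_a: str, chain_b: str,
                pairing: Mapping[str, str] | None) -> tuple[str, str | None]:
    try:
        return classify_trans_gj(chain_a, chain_b, pairing)
    except GJDockError:
        return "unknown", None


def sc_timeseries(
    trajectory: Trajectory,
    scope: Iterable[ResidueId] | None = None,
    params: AnalysisParameters | None = None,
    pairing: Mapping[str, str] | None = None,
    stride: int = 1,
) -> tuple[pd.DataFrame, list[SCPair]]:
    """SC presence aggregated over a trajectory.

    Every ``stride``-th frame is analysed with :func:`detect_scs_frame`.
    Returns a stability table (one row per residue pair, with the presence
    fraction and min/max/mean of the contributing minimum atom-pair
    distances over frames where present) and the flat list of per-frame
    SC records.

    Table columns: chain_a, res_a, name_a, chain_b, res_b, name_b, class,
    subunit_pair, n_frames_present, n_frames, fraction, d_min, d_max, d_mean.
    """
    if trajectory.n_frames < 1:
        raise GJDockError("trajectory has no frames")
    params = params or AnalysisParameters()
    records: list[SCPair] = []
    frame_ids = range(0, trajectory.n_frames, stride)
    n_frames = len(frame_ids)
    for fi in frame_ids:
        records.extend(detect_scs_frame(
            trajectory.frame(fi), scope=scope, params=params,
            frame_index=fi, pairing=pairing))
    agg: dict = {}
    for rec in records:
        entry = agg.setdefault(rec.key, {
            "names": (rec.res_a[2], rec.res_b[2]),
            "dists": [],
            "n": 0,
        })
        entry["n"] += 1
        entry["dists"].append(rec.min_heavy_distance)
    rows = []
    for (ka, kb), entry in sorted(agg.items()):
        d = np.array(entry["dists"])
        cls, label = _pair_class(ka[0], kb[0], pairing)
        rows.append({
            "chain_a": ka[0], "res_a": ka[1], "name_a": entry["names"][0],
            "chain_b": kb[0], "res_b": kb[1], "name_b": entry["names"][1],
            "class": cls, "subunit_pair": label,
            "n_frames_present": entry["n"], "n_frames": n_frames,
            "fraction": entry["n"] / n_frames,
            "d_min": float(d.min()), "d_max": float(d.max()),
            "d_mean": float(d.mean()),
        })
    columns = ["chain_a", "res_a", "name_a", "chain_b", "res_b", "name_b",
               "class", "subunit_pair", "n_frames_present", "n_frames",
               "fraction", "d_min", "d_max", "d_mean"]
    table = pd.DataFrame(rows, columns=columns)
    return table, records


def filter_extracellular(
    table: pd.DataFrame,
    annotation: ConnexinAnnotation | None = None,
    min_fraction: float = 0.02,
) -> pd.DataFrame:
    """Keep reportable extracellular SCs.

    A row survives iff at least one residue lies in EL1 (47-73) or EL2
    (177-203) and the pair is present in at least ``min_fraction`` of the
    frames (the 2% stability threshold).
    """
    if annotation is None:
        annotation = ConnexinAnnotation()
    if table.empty:
        return table.copy()
    ec_a = table["res_a"].map(annotation.is_extracellular)
    ec_b = table["res_b"].map(annotation.is_extracellular)
    keep = (ec_a | ec_b) & (table["fraction"] >= min_fraction)
    return table[keep].reset_index(drop=True)
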
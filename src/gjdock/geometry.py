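"""Rigid-body superposition, trajectory alignment, and hemichannel assembly.

Covers the geometric plumbing of the docking analysis: least-squares
superposition (Kabsch), the per-frame extracellular RMSD series after
alignment on the membrane segment, z-translation of one hemichannel to set
the docking distance, steric clash reporting, and assembly of a two-hexamer
(HC-HC) model by superposing two hemichannel copies onto a dodecameric
gap-junction template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    AnalysisParameters,
    ConnexinAnnotation,
    GJDockError,
    Structure,
    StructureError,
    Trajectory,
)

log = logging.getLogger(__name__)


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference coordinates.

    ``transformed = mobile @ rotation.T + translation``
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms_used: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Points correspond by order. The rotation is proper (det = +1);
    reflections are excluded by the usual sign correction on the smallest
    singular vector.

    Raises
    ------
    GJDockError
        On fewer than 3 points, mismatched point counts, or degenerate
        (collinear) point sets, for which the rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape:
        raise GJDockError(
            f"point counts differ: {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise GJDockError(f"need >= 3 points for superposition, got {n}")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    p = mobile - mob_c
    q = reference - ref_c
    # collinear clouds leave a free rotation about the common axis
    if np.linalg.matrix_rank(p, tol=1e-8) < 2 or np.linalg.matrix_rank(q, tol=1e-8) < 2:
        raise GJDockError("degenerate (collinear) point set; superposition not unique")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_c - rotation @ mob_c
    moved = p @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd, n_atoms_used=n)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def extracellular_rmsd_series(
    trajectory: Trajectory,
    annotation: ConnexinAnnotation | None = None,
    chains: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-frame heavy-atom RMSD of the extracellular part after TM alignment.

    Every frame is aligned to the first frame on the heavy atoms of the
    membrane segment (``annotation.align_ranges_rmsd``); the RMSD is then
    computed over the heavy atoms of the extracellular loops EL1 and EL2
    (residues 47-73 and 177-203). Frame 0 is the reference, so the series
    starts at 0.
    """
    if annotation is None:
        annotation = ConnexinAnnotation()
    topo = trajectory.topology
    mask = topo.heavy_mask.copy()
    if chains is not None:
        mask &= np.isin(topo.chain_ids, list(chains))
    align_mask = mask & annotation.alignment_mask(topo.res_nums)
    ec_mask = mask & annotation.extracellular_mask(topo.res_nums)
    missing = []
    if not align_mask.any():
        missing.append(f"alignment residues {annotation.align_ranges_rmsd}")
    if not ec_mask.any():
        missing.append(
            f"extracellular residues {annotation.el1_range}/{annotation.el2_range}")
    if missing:
        raise GJDockError("missing residues for RMSD: " + "; ".join(missing))
    ref_align = trajectory.frames[0][align_mask]
    ref_ec = trajectory.frames[0][ec_mask]
    out = np.zeros(trajectory.n_frames)
    for i in range(trajectory.n_frames):
        if i == 0:
            continue
        sup = kabsch_superpose(trajectory.frames[i][align_mask], ref_align)
        moved_ec = sup.apply(trajectory.frames[i][ec_mask])
        out[i] = _rmsd(moved_ec, ref_ec)
    return out


def translate_chains(structure: Structure, chains: Sequence[str],
                     offset_z: float) -> Structure:
    """Shift every atom of the named chains by exactly ``offset_z`` Å in z.

    All other atoms are untouched; used to set the hemichannel-hemichannel
    docking distance (1 / 3 / 5 Å separations).
    """
    chains = list(chains)
    present = set(structure.chains())
    missing = [c for c in chains if c not in present]
    if missing:
        raise GJDockError(f"chain(s) not in structure: {missing}")
    coords = structure.coords.copy()
    mask = np.isin(structure.chain_ids, chains)
    coords[mask, 2] += offset_z
    return structure.with_coords(coords)


def clash_report(
    structure: Structure,
    group_a: Sequence[str],
    group_b: Sequence[str],
    cutoff: float = 2.0,
) -> list[tuple[int, int, float]]:
    """Cross-group heavy-atom pairs closer than ``cutoff`` Å (strict <).

    Returns ``(atom_index_a, atom_index_b, distance)`` tuples sorted by
    ascending distance; indices refer to atom positions in ``structure``.
    """
    set_a, set_b = set(group_a), set(group_b)
    overlap = set_a & set_b
    if overlap:
        raise GJDockError(f"clash groups overlap on chain(s) {sorted(overlap)}")
    heavy = structure.heavy_mask
    ia = np.flatnonzero(np.isin(structure.chain_ids, list(set_a)) & heavy)
    ib = np.flatnonzero(np.isin(structure.chain_ids, list(set_b)) & heavy)
    if len(ia) == 0 or len(ib) == 0:
        return []
    tree_b = cKDTree(structure.coords[ib])
    pairs = []
    neighbours = tree_b.query_ball_point(structure.coords[ia], cutoff)
    for ai, hits in zip(ia, neighbours):
        for j in hits:
            bj = ib[j]
            d = float(np.linalg.norm(structure.coords[ai] - structure.coords[bj]))
            if d < cutoff:
                pairs.append((int(ai), int(bj), d))
    pairs.sort(key=lambda t: t[2])
    return pairs


@dataclass
class BuildLog:
    """Record of an HC-HC assembly: per-chain superposition quality and clashes."""

    chain_map: dict[str, str] = field(default_factory=dict)
    per_chain_rmsd: dict[str, float] = field(default_factory=dict)
    clashes: list[tuple[int, int, float]] = field(default_factory=list)


def _matched_ca_coords(
    mobile: Structure, template: Structure,
    mob_chain: str, tpl_chain: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired CA coordinates for residues present in both chains."""
    mob_mask = (mobile.chain_ids == mob_chain) & (mobile.names == "CA")
    tpl_mask = (template.chain_ids == tpl_chain) & (template.names == "CA")
    mob_res = {int(r): i for r, i in
               zip(mobile.res_nums[mob_mask], np.flatnonzero(mob_mask))}
    tpl_res = {int(r): i for r, i in
               zip(template.res_nums[tpl_mask], np.flatnonzero(tpl_mask))}
    shared = sorted(set(mob_res) & set(tpl_res))
    if len(shared) < 3:
        raise GJDockError(
            f"chain {mob_chain}->{tpl_chain}: only {len(shared)} matched CA "
            f"atoms; need >= 3")
    mob_ix = [mob_res[r] for r in shared]
    tpl_ix = [tpl_res[r] for r in shared]
    return mobile.coords[mob_ix], template.coords[tpl_ix]


def build_hc_hc(
    hc: Structure,
    template_gjc: Structure,
    params: AnalysisParameters | None = None,
) -> tuple[Structure, BuildLog]:
    """Assemble a two-hexamer (HC-HC) model from one hemichannel copy.

    Two copies of the 6-chain hemichannel are superposed onto the A-F and
    G-L halves of a 12-chain gap-junction template (chains matched in
    alphabetical order, correspondence on shared CA atoms). The second
    copy's chains are relabelled G-L and its serial numbers continue after
    the first copy's, giving continuous numbering across the dimer. Steric
    clashes across the interface are reported in the build log, not
    resolved.
    """
    if params is None:
        params = AnalysisParameters()
    hc_chains = hc.chains()
    tpl_chains = template_gjc.chains()
    if len(hc_chains) != 6:
        raise GJDockError(f"hemichannel must have 6 chains, got {len(hc_chains)}")
    if len(tpl_chains) != 12:
        raise GJDockError(f"template must have 12 chains, got {len(tpl_chains)}")
    tpl_sorted = sorted(tpl_chains)
    hc_sorted = sorted(hc_chains)
    build = BuildLog()

    def _superposed_copy(target_chains: list[str]) -> Structure:
        copy = hc.copy()
        coords = copy.coords.copy()
        new_chain_ids = copy.chain_ids.copy()
        for mob_chain, tpl_chain in zip(hc_sorted, target_chains):
            mob_xyz, tpl_xyz = _matched_ca_coords(hc, template_gjc,
                                                  mob_chain, tpl_chain)
            sup = kabsch_superpose(mob_xyz, tpl_xyz)
            sel = copy.chain_ids == mob_chain
            coords[sel] = sup.apply(hc.coords[sel])
            new_chain_ids[sel] = tpl_chain
            build.chain_map[f"{mob_chain}->{tpl_chain}"] = tpl_chain
            build.per_chain_rmsd[f"{mob_chain}->{tpl_chain}"] = sup.rmsd
        out = copy.with_coords(coords)
        out.chain_ids = new_chain_ids
        out._res_index = None
        return out

    copy1 = _superposed_copy(tpl_sorted[:6])
    copy2 = _superposed_copy(tpl_sorted[6:])
    merged = copy1.concat(copy2)
    # continuous numbering across the dimer: second copy starts at n(copy1)+1
    merged.serials = np.arange(1, len(merged) + 1)
    build.clashes = clash_report(
        merged, tpl_sorted[:6], tpl_sorted[6:], cutoff=params.clash_cutoff)
    if build.clashes:
        log.info("build_hc_hc: %d interface clashes < %.1f Å",
                 len(build.clashes), params.clash_cutoff)
    return merged, build
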
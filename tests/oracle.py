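"""Independent brute-force oracles for the geometric detectors.

These reimplement every criterion with plain loops over atoms and exhaustive
enumeration of flank-triplet selections, deliberately sharing no code path
with the package implementations they check.
"""

from __future__ import annotations

import numpy as np

VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
VDW_DEFAULT = 1.70


def _residue_atoms(structure, chain, res, heavy_only=True):
    out = []
    for i in range(len(structure)):
        if (str(structure.chain_ids[i]) == chain
                and int(structure.res_nums[i]) == res):
            if heavy_only and str(structure.elements[i]).upper() in ("H", "D"):
                continue
            out.append(i)
    return out


def brute_contact(structure, res_a, res_b, tol=1.0):
    """(in_contact, min_distance) by looping over all heavy-atom pairs."""
    ia = _residue_atoms(structure, *res_a)
    ib = _residue_atoms(structure, *res_b)
    best = np.inf
    hit = False
    for i in ia:
        for j in ib:
            d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
            ri = VDW.get(str(structure.elements[i]).upper(), VDW_DEFAULT)
            rj = VDW.get(str(structure.elements[j]).upper(), VDW_DEFAULT)
            if d < ri + rj + tol:
                hit = True
            best = min(best, d)
    return hit, best


def _chain_residues(structure, chain):
    return sorted({int(r) for c, r in zip(structure.chain_ids,
                                          structure.res_nums)
                   if str(c) == chain})


def brute_is_sc(structure, res_a, res_b, min_sep=10, flank=4, need=7):
    """Exhaustive SC test: criteria 1-3 with all 4x4x4x4 triplet selections."""
    (ca, ra), (cb, rb) = res_a, res_b
    if res_a == res_b:
        return False
    if ca == cb and abs(ra - rb) < min_sep:
        return False
    if not brute_contact(structure, res_a, res_b)[0]:
        return False
    pres_a = set(_chain_residues(structure, ca))
    pres_b = set(_chain_residues(structure, cb))
    la = [r for r in range(ra - flank, ra) if r in pres_a]
    ua = [r for r in range(ra + 1, ra + flank + 1) if r in pres_a]
    lb = [r for r in range(rb - flank, rb) if r in pres_b]
    ub = [r for r in range(rb + 1, rb + flank + 1) if r in pres_b]
    if not (la and ua and lb and ub):
        return False
    return brute_best_triplet_count(structure, res_a, res_b,
                                    la, ua, lb, ub) >= need


def brute_best_triplet_count(structure, res_a, res_b, la, ua, lb, ub):
    """Maximum cross-triplet contact count over all flank selections."""
    (ca, _), (cb, _) = res_a, res_b
    best = 0
    for x in la:
        for y in ua:
            for u in lb:
                for v in ub:
                    trip_a = [(ca, x), res_a, (ca, y)]
                    trip_b = [(cb, u), res_b, (cb, v)]
                    n = sum(brute_contact(structure, p, q)[0]
                            for p in trip_a for q in trip_b)
                    best = max(best, n)
    return best


class BruteForceSC:
    """Exhaustive SC detection with memoized pairwise contact lookups.

    The criteria logic is the same plain-loop implementation as the module
    functions above; memoization only avoids recomputing identical residue
    pairs during triplet enumeration.
    """

    def __init__(self, structure):
        self.structure = structure
        self._cache: dict = {}
        self.residues = sorted({(str(c), int(r)) for c, r in
                                zip(structure.chain_ids,
                                    structure.res_nums)})
        self._per_chain: dict[str, set[int]] = {}
        for c, r in self.residues:
            self._per_chain.setdefault(c, set()).add(r)

    def contact(self, ra, rb):
        key = (ra, rb) if ra <= rb else (rb, ra)
        if key not in self._cache:
            self._cache[key] = brute_contact(self.structure, *key)[0]
        return self._cache[key]

    def is_sc(self, ra, rb, min_sep=10, flank=4, need=7):
        (ca, na), (cb, nb) = ra, rb
        if ra == rb:
            return False
        if ca == cb and abs(na - nb) < min_sep:
            return False
        if not self.contact(ra, rb):
            return False
        la = [r for r in range(na - flank, na) if r in self._per_chain[ca]]
        ua = [r for r in range(na + 1, na + flank + 1)
              if r in self._per_chain[ca]]
        lb = [r for r in range(nb - flank, nb) if r in self._per_chain[cb]]
        ub = [r for r in range(nb + 1, nb + flank + 1)
              if r in self._per_chain[cb]]
        if not (la and ua and lb and ub):
            return False
        for x in la:
            for y in ua:
                for u in lb:
                    for v in ub:
                        trip_a = [(ca, x), ra, (ca, y)]
                        trip_b = [(cb, u), rb, (cb, v)]
                        n = sum(self.contact(p, q)
                                for p in trip_a for q in trip_b)
                        if n >= need:
                            return True
        return False

    def detect(self):
        out = set()
        for i, ra in enumerate(self.residues):
            for rb in self.residues[i + 1:]:
                if self.is_sc(ra, rb):
                    out.add((ra, rb))
        return out


def brute_detect_scs(structure):
    """All SC pairs by checking every unordered residue pair."""
    return BruteForceSC(structure).detect()


def brute_clashes(structure, chains_a, chains_b, cutoff=2.0):
    """All cross-group heavy-atom pairs below the cutoff, by full loops."""
    out = []
    for i in range(len(structure)):
        if str(structure.elements[i]).upper() in ("H", "D"):
            continue
        if str(structure.chain_ids[i]) not in chains_a:
            continue
        for j in range(len(structure)):
            if str(structure.elements[j]).upper() in ("H", "D"):
                continue
            if str(structure.chain_ids[j]) not in chains_b:
                continue
            d = float(np.linalg.norm(structure.coords[i]
                                     - structure.coords[j]))
            if d < cutoff:
                out.append((i, j, d))
    return sorted(out, key=lambda t: t[2])


def _attached_hydrogens(structure, heavy_idx, max_bond=1.45):
    out = []
    for j in range(len(structure)):
        if str(structure.elements[j]).upper() not in ("H", "D"):
            continue
        d = float(np.linalg.norm(structure.coords[j]
                                 - structure.coords[heavy_idx]))
        if d > max_bond:
            continue
        # nearest-heavy rule
        nearest = None
        best = np.inf
        for k in range(len(structure)):
            if str(structure.elements[k]).upper() in ("H", "D"):
                continue
            dk = float(np.linalg.norm(structure.coords[j]
                                      - structure.coords[k]))
            if dk < best:
                best, nearest = dk, k
        if nearest == heavy_idx:
            out.append(j)
    return out


def brute_trans_gj_hbonds(structure, cutoff=2.5):
    """Exhaustive trans-GJ H-bond enumeration (cross-hemichannel 55-58)."""
    donors, acceptors = [], []
    for i in range(len(structure)):
        res = int(structure.res_nums[i])
        if not 55 <= res <= 58:
            continue
        name = str(structure.names[i])
        res_name = str(structure.res_names[i])
        if name == "N" or (res_name, name) in (
                ("ASN", "OD1"), ("THR", "OG1"), ("GLN", "NE2")):
            donors.append(i)
        if name == "O" or (res_name, name) in (
                ("ASN", "OD1"), ("THR", "OG1"), ("GLN", "OE1")):
            acceptors.append(i)
    hc_of = lambda c: "HC1" if c in "ABCDEF" else "HC2"
    bonds = set()
    for d in donors:
        for h in _attached_hydrogens(structure, d):
            for a in acceptors:
                if a == d:
                    continue
                if hc_of(str(structure.chain_ids[d])) == \
                        hc_of(str(structure.chain_ids[a])):
                    continue
                dist = float(np.linalg.norm(structure.coords[h]
                                            - structure.coords[a]))
                if dist < cutoff:
                    bonds.add((d, h, a))
    return bonds


def brute_cys_cys_hbonds(structure, cutoff=4.3):
    """Exhaustive SG vs foreign thiol-H enumeration."""
    sgs = [i for i in range(len(structure))
           if str(structure.res_names[i]) == "CYS"
           and str(structure.names[i]) == "SG"]
    bonds = set()
    for donor in sgs:
        for h in _attached_hydrogens(structure, donor):
            if str(structure.names[h]) not in ("HG1", "HG"):
                continue
            for acc in sgs:
                if acc == donor:
                    continue
                d = float(np.linalg.norm(structure.coords[h]
                                         - structure.coords[acc]))
                if d < cutoff:
                    bonds.add((donor, h, acc))
    return bonds
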
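"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package beyond the rule constants:
plain-python all-pairs scans, combinatorial ring search, and a literal
transcription of the decay formula. They exist so that the vectorized /
structured implementations can be checked against a dumb but obviously
correct reference.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from ncibind.rules import RuleConfig, VDW_RADII, DEFAULT_VDW_RADIUS

CATIONIC = {"ARG": ("NE", "CZ", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2", "CE1")}
ANIONIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
AROMATIC = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"), ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}


def dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def decay(d, lo, hi, floor=1e-6):
    if d > hi:
        return 0.0
    if d <= lo:
        return 1.0
    return 1.0 + (d - lo) * (floor - 1.0) / (hi - lo)


def vrad(elem):
    return VDW_RADII.get(elem.upper(), DEFAULT_VDW_RADIUS)


def _keep_min(raw):
    """raw: list of (i, j, d, strength) -> min-distance per (i, j)."""
    best = {}
    for i, j, d, s in raw:
        if (i, j) not in best or d < best[(i, j)][0]:
            best[(i, j)] = (d, s)
    return best


def _ligand_rings_bruteforce(cx):
    """Rings via exhaustive subset search: every 5/6-subset whose members
    each have exactly two in-subset bonded neighbours and form one cycle."""
    atoms = cx.ligand_atoms
    idx = range(len(atoms))

    def bonded(a, b):
        cut = 1.8 if {atoms[a].element, atoms[b].element} <= {"C", "N", "O"} else 2.1
        return dist(atoms[a].pos, atoms[b].pos) < cut

    rings = []
    for size in (5, 6):
        for sub in combinations(idx, size):
            deg = {a: sum(1 for b in sub if b != a and bonded(a, b)) for a in sub}
            if any(d != 2 for d in deg.values()):
                continue
            # connected single cycle check: walk it
            start = sub[0]
            seen = {start}
            prev, cur = None, start
            for _ in range(size - 1):
                nxts = [b for b in sub if b != cur and b != prev and bonded(cur, b)]
                nxt = [b for b in nxts if b not in seen]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                seen.add(cur)
            if len(seen) == size and all(atoms[a].element in ("C", "N", "O", "S") for a in sub):
                rings.append(tuple(sorted(sub)))
    return sorted(set(rings))


def _centroid(coords):
    k = len(coords)
    return tuple(sum(c[ax] for c in coords) / k for ax in range(3))


def _normal(coords):
    arr = np.array(coords) - np.array(coords).mean(axis=0)
    return np.linalg.svd(arr)[2][-1]


def oracle_contacts(cx, rules: RuleConfig | None = None):
    """All-pairs reference detection. Returns
    {type: {(i, j): (distance, strength)}} with 1-based indices."""
    rules = rules or RuleConfig()
    out = {}
    residues = cx.protein_residues
    lig = cx.ligand_atoms

    # hydrogen bonds (distance-only here: the oracle fixtures carry no H)
    lo, hi = rules.hbond.d_min, rules.hbond.d_cut
    raw = []
    for i, la in enumerate(lig, 1):
        if la.element in ("N", "O"):
            for j, res in enumerate(residues, 1):
                for pa in res.atoms:
                    if pa.element in ("N", "O"):
                        d = dist(la.pos, pa.pos)
                        s = decay(d, lo, hi, rules.floor)
                        if s > 0:
                            raw.append((i, j, d, s))
    out["hbond"] = _keep_min(raw)

    # salt bridges
    lo, hi = rules.salt_bridge.d_min, rules.salt_bridge.d_cut
    raw = []
    cationic = dict(CATIONIC)
    if not rules.his_is_cationic:
        cationic.pop("HIS")
    for j, res in enumerate(residues, 1):
        for table, elem in ((cationic, "O"), (ANIONIC, "N")):
            names = table.get(res.name)
            if not names:
                continue
            grp = [a.pos for a in res.atoms if a.name in names]
            if not grp:
                continue
            cen = _centroid(grp)
            for i, la in enumerate(lig, 1):
                if la.element == elem:
                    d = dist(la.pos, cen)
                    s = decay(d, lo, hi, rules.floor)
                    if s > 0:
                        raw.append((i, j, d, s))
    out["salt_bridge"] = _keep_min(raw)

    # hydrophobic
    lo, hi = rules.hydrophobic.d_min, rules.hydrophobic.d_cut
    raw = []
    for i, la in enumerate(lig, 1):
        if la.element == "C":
            for j, res in enumerate(residues, 1):
                for pa in res.atoms:
                    if pa.element == "C":
                        d = dist(la.pos, pa.pos)
                        s = decay(d, lo, hi, rules.floor)
                        if s > 0:
                            raw.append((i, j, d, s))
    out["hydrophobic"] = _keep_min(raw)

    # van der Waals (raw, no fallback exclusion)
    raw = []
    for i, la in enumerate(lig, 1):
        for j, res in enumerate(residues, 1):
            for pa in res.atoms:
                if pa.element in ("H", "D"):
                    continue
                srad = vrad(la.element) + vrad(pa.element)
                lo, hi = max(srad - rules.vdw_slack, 0.1), srad + rules.vdw_slack
                d = dist(la.pos, pa.pos)
                s = decay(d, lo, hi, rules.floor)
                if s > 0:
                    raw.append((i, j, d, s))
    out["vdw"] = _keep_min(raw)

    # pi-pi stacking
    lo, hi = rules.pipi.d_min, rules.pipi.d_cut
    raw = []
    for ring in _ligand_rings_bruteforce(cx):
        rc = _centroid([lig[k].pos for k in ring])
        rn = _normal([lig[k].pos for k in ring])
        for j, res in enumerate(residues, 1):
            for names in AROMATIC.get(res.name, ()):
                grp = [a.pos for a in res.atoms if a.name in names]
                if len(grp) != len(names):
                    continue
                pc, pn = _centroid(grp), _normal(grp)
                d = dist(rc, pc)
                if d > hi:
                    continue
                cosv = abs(float(np.dot(rn, pn)))
                theta = math.degrees(math.acos(min(1.0, cosv)))
                if not (theta <= rules.pipi.angle_min or rules.pipi.angle_max <= theta <= 90.0):
                    continue
                ds = [dist(lig[k].pos, pc) for k in ring]
                i = ring[ds.index(min(ds))] + 1
                s = decay(d, lo, hi, rules.floor)
                if s > 0:
                    raw.append((i, j, d, s))
    out["pipi"] = _keep_min(raw)

    # cation-pi
    lo, hi = rules.cation_pi.d_min, rules.cation_pi.d_cut
    raw = []
    for j, res in enumerate(residues, 1):
        names = cationic.get(res.name)
        if names:
            grp = [a.pos for a in res.atoms if a.name in names]
            if grp:
                cen = _centroid(grp)
                for ring in _ligand_rings_bruteforce(cx):
                    rc = _centroid([lig[k].pos for k in ring])
                    d = dist(rc, cen)
                    s = decay(d, lo, hi, rules.floor)
                    if s > 0:
                        ds = [dist(lig[k].pos, cen) for k in ring]
                        raw.append((ring[ds.index(min(ds))] + 1, j, d, s))
        for rnames in AROMATIC.get(res.name, ()):
            grp = [a.pos for a in res.atoms if a.name in rnames]
            if len(grp) != len(rnames):
                continue
            pc = _centroid(grp)
            for i, la in enumerate(lig, 1):
                if la.element == "N":
                    d = dist(la.pos, pc)
                    s = decay(d, lo, hi, rules.floor)
                    if s > 0:
                        raw.append((i, j, d, s))
    out["cation_pi"] = _keep_min(raw)
    return out


def oracle_attention_forward(P, D, params, n_heads=8):
    """Straight-line dense reimplementation of the interaction module
    forward pass (numpy only, no shared code with the package graph)."""
    h = P.shape[1]
    ht = h // n_heads

    def sm(x):
        e = np.exp(x - x.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)

    Qp, Kp, Vp = P @ params["Wqp"], P @ params["Wkp"], P @ params["Wvp"]
    Qd, Kd, Vd = D @ params["Wqd"], D @ params["Wkd"], D @ params["Wvd"]
    A_pd, A_dp, P_parts, D_parts = [], [], [], []
    for k in range(n_heads):
        sl = slice(k * ht, (k + 1) * ht)
        qp, kp, vp = Qp[:, sl], Kp[:, sl], Vp[:, sl]
        qd, kd, vd = Qd[:, sl], Kd[:, sl], Vd[:, sl]
        a_pd = sm(qp @ kd.T / math.sqrt(ht))
        a_dp = sm(qd @ kp.T / math.sqrt(ht))
        p_sa = sm(qp @ kp.T / math.sqrt(ht)) @ vp
        d_sa = sm(qd @ kd.T / math.sqrt(ht)) @ vd
        A_pd.append(a_pd)
        A_dp.append(a_dp)
        P_parts.append(0.5 * (p_sa + a_pd @ vd))
        D_parts.append(0.5 * (d_sa + a_dp @ vp))
    P_star = np.concatenate(P_parts, axis=1) @ params["Wpo"]
    D_star = np.concatenate(D_parts, axis=1) @ params["Wdo"]
    return A_pd, A_dp, P_star, D_star


def oracle_classify(P_star, D_star, params):
    F = np.concatenate([D_star.mean(axis=0), P_star.mean(axis=0)])[None, :]
    a1 = np.maximum(F @ params["M1"] + params["b1"], 0.0)
    a2 = np.maximum(a1 @ params["M2"] + params["b2"], 0.0)
    z = a2 @ params["M3"] + params["b3"]
    return float(1.0 / (1.0 + np.exp(-z[0, 0])))
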
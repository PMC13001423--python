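"""Rule-based annotation of non-covalent interactions in a complex.

Six interaction classes are detected geometrically between the ligand heavy
atoms (i = 1..m) and the pocket residues (j = 1..n over the full sequence):

- hydrogen bonds: polar (N/O) atom pairs within the distance window, with a
  D-H...A angle filter whenever explicit hydrogens are present on either
  partner and a distance-only fallback otherwise;
- salt bridges: ligand N (cationic) or O (anionic) atoms against the
  oppositely charged side-chain group centroid (ARG/LYS/HIS vs ASP/GLU);
- hydrophobic contacts: carbon-carbon pairs;
- van der Waals contacts: any heavy-atom pair within the sum of vdW radii
  +/- a slack; by default a residue-atom cell already explained by a more
  specific type is excluded (vdW as fallback);
- pi-pi stacking: ring-centroid distances with an interplanar angle filter
  accepting parallel (<= 30 deg) and T-shaped (60-90 deg) geometries;
- cation-pi: charged group to aromatic-ring centroid, in both directions.

Distances are converted to strengths by the piecewise-linear decay, so every
recorded contact carries an intensity in [1e-6, 1]; zero encodes "no contact".
Contacts of centroid-based types are attributed to the group member atom
nearest the partner (ties to the lower ligand index), and multiple geometric
realizations of the same (i, j, type) keep the minimum-distance one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .rules import INTERACTION_TYPES, RuleConfig, decay_strength, vdw_radius
from .structures import ComplexStructure, localize_pocket

__all__ = [
    "Contact", "InteractionMapSet", "AffinityLabel",
    "detect_contacts", "build_map", "aggregate_overall",
    "project_residue_labels", "stratify_affinity", "annotate_complex",
    "maps_to_tsv", "maps_from_tsv",
]

POLAR_ELEMENTS = {"N", "O"}

#: side-chain atoms defining charged-group centroids
CATIONIC_GROUPS = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2", "CE1"),
}
ANIONIC_GROUPS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: aromatic ring member atom names per residue
AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}

NEGATIVE_AFFINITY_MIN = -5.0  # kcal/mol; at or above -> non-binder label
POSITIVE_AFFINITY_MAX = -7.0  # kcal/mol; at or below -> binder label


@dataclass(frozen=True)
class Contact:
    """A single detected residue-atom interaction."""

    itype: str
    i: int  # ligand atom index, 1-based
    j: int  # residue position, 1-based
    d: float  # Å (atom-atom or centroid distance, per type)
    raw_intensity: float
    angle: Optional[float] = None  # degrees, when an angular filter applies


@dataclass
class AffinityLabel:
    affinity: float
    label: str  # positive | negative | excluded


def stratify_affinity(affinity: float) -> AffinityLabel:
    """Binding label from affinity (kcal/mol): strong binders (<= -7 kcal/mol)
    are positives, weak ones (>= -5) negatives, moderate cases excluded."""
    if not np.isfinite(affinity):
        raise ValueError("affinity must be finite")
    if affinity >= NEGATIVE_AFFINITY_MIN:
        label = "negative"
    elif affinity <= POSITIVE_AFFINITY_MAX:
        label = "positive"
    else:
        label = "excluded"
    return AffinityLabel(affinity, label)


# ---------------------------------------------------------------------------
# geometry helpers

def _coords(atoms) -> np.ndarray:
    return np.array([a.pos for a in atoms], dtype=float)


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


def _interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _angle_at(h: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - h, b - h
    c = float(np.dot(v1, v2)) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def ligand_rings(cx: ComplexStructure) -> list[tuple[int, ...]]:
    """5/6-membered rings of the ligand, perceived from heavy-atom distances.

    Bonds are inferred from interatomic distance (1.8 Å for C/N/O pairs,
    2.1 Å when S/P/halogens are involved); rings come from the cycle basis.
    Returns tuples of 0-based ligand atom indices.
    """
    atoms = cx.ligand_atoms
    coords = cx.ligand_coords()
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    for a in range(len(atoms)):
        for b in range(a + 1, len(atoms)):
            cut = 1.8 if {atoms[a].element, atoms[b].element} <= {"C", "N", "O"} else 2.1
            if np.linalg.norm(coords[a] - coords[b]) < cut:
                g.add_edge(a, b)
    rings = []
    for cyc in nx.cycle_basis(g):
        if len(cyc) in (5, 6) and all(atoms[k].element in ("C", "N", "O", "S") for k in cyc):
            rings.append(tuple(sorted(cyc)))
    return rings


def _residue_group(res, names: Iterable[str]):
    atoms = [a for a in res.atoms if a.name in names]
    return atoms


def _dedup(contacts: list[Contact]) -> list[Contact]:
    best: dict[tuple[int, int], Contact] = {}
    for c in contacts:
        k = (c.i, c.j)
        if k not in best or c.d < best[k].d:
            best[k] = c
    return sorted(best.values(), key=lambda c: (c.i, c.j))


def _make_contact(itype, i, j, d, rules: RuleConfig, d_min, d_cut, angle=None) -> Optional[Contact]:
    s = decay_strength(d, d_min, d_cut, rules.floor)
    if s == 0.0:
        return None
    return Contact(itype, i, j, d, s, angle)


# ---------------------------------------------------------------------------
# per-type detection

def _detect_hbond(cx, pocket, rules: RuleConfig) -> list[Contact]:
    d_min, d_cut = rules.window("hbond")
    angle_min = rules.hbond.angle_min
    out = []
    for i, la in enumerate(cx.ligand_atoms, start=1):
        if la.element not in POLAR_ELEMENTS:
            continue
        lx = la.xyz
        for j in pocket:
            res = cx.protein_residues[j - 1]
            hydrogens = [a for a in res.atoms if a.element in ("H", "D")]
            for pa in res.atoms:
                if pa.element not in POLAR_ELEMENTS:
                    continue
                px = pa.xyz
                d = float(np.linalg.norm(lx - px))
                if d > d_cut:
                    continue
                angle = None
                if angle_min is not None and hydrogens:
                    # H atoms covalently attached to either polar partner
                    attached = [
                        h.xyz for h in hydrogens
                        if min(np.linalg.norm(h.xyz - px), np.linalg.norm(h.xyz - lx)) < 1.25
                    ]
                    if attached:
                        angle = max(_angle_at(hx, px, lx) for hx in attached)
                        if angle < angle_min:
                            continue
                c = _make_contact("hbond", i, j, d, rules, d_min, d_cut, angle)
                if c:
                    out.append(c)
    return _dedup(out)


def _detect_salt_bridge(cx, pocket, rules: RuleConfig) -> list[Contact]:
    d_min, d_cut = rules.window("salt_bridge")
    cationic = dict(CATIONIC_GROUPS)
    if not rules.his_is_cationic:
        cationic.pop("HIS", None)
    out = []
    for j in pocket:
        res = cx.protein_residues[j - 1]
        for groups, lig_elem in ((cationic, "O"), (ANIONIC_GROUPS, "N")):
            names = groups.get(res.name)
            if not names:
                continue
            atoms = _residue_group(res, names)
            if not atoms:
                continue
            centroid = _coords(atoms).mean(axis=0)
            for i, la in enumerate(cx.ligand_atoms, start=1):
                if la.element != lig_elem:
                    continue
                d = float(np.linalg.norm(la.xyz - centroid))
                c = _make_contact("salt_bridge", i, j, d, rules, d_min, d_cut)
                if c:
                    out.append(c)
    return _dedup(out)


def _detect_hydrophobic(cx, pocket, rules: RuleConfig) -> list[Contact]:
    d_min, d_cut = rules.window("hydrophobic")
    out = []
    for i, la in enumerate(cx.ligand_atoms, start=1):
        if la.element != "C":
            continue
        for j in pocket:
            for pa in cx.protein_residues[j - 1].atoms:
                if pa.element != "C":
                    continue
                d = float(np.linalg.norm(la.xyz - pa.xyz))
                c = _make_contact("hydrophobic", i, j, d, rules, d_min, d_cut)
                if c:
                    out.append(c)
    return _dedup(out)


def _detect_vdw(cx, pocket, rules: RuleConfig) -> list[Contact]:
    out = []
    for i, la in enumerate(cx.ligand_atoms, start=1):
        ra = vdw_radius(la.element)
        for j in pocket:
            for pa in cx.protein_residues[j - 1].atoms:
                if pa.element in ("H", "D"):
                    continue
                d_min, d_cut = rules.window("vdw", ra, vdw_radius(pa.element))
                d = float(np.linalg.norm(la.xyz - pa.xyz))
                c = _make_contact("vdw", i, j, d, rules, d_min, d_cut)
                if c:
                    out.append(c)
    return _dedup(out)


def _protein_rings(res):
    for names in AROMATIC_RINGS.get(res.name, ()):  # pragma: no branch
        atoms = _residue_group(res, names)
        if len(atoms) == len(names):
            coords = _coords(atoms)
            yield coords.mean(axis=0), _ring_normal(coords)


def _pipi_angle_ok(theta: float, rules: RuleConfig) -> bool:
    lo = rules.pipi.angle_min if rules.pipi.angle_min is not None else 90.0
    hi = rules.pipi.angle_max if rules.pipi.angle_max is not None else 90.0
    return theta <= lo or hi <= theta <= 90.0


def _nearest_member(cx, ring: tuple[int, ...], point: np.ndarray) -> int:
    """1-based index of the ring atom nearest ``point`` (ties: lower index)."""
    dists = [float(np.linalg.norm(cx.ligand_atoms[k].xyz - point)) for k in ring]
    return ring[int(np.argmin(dists))] + 1


def _detect_pipi(cx, pocket, rules: RuleConfig) -> list[Contact]:
    d_min, d_cut = rules.window("pipi")
    rings = ligand_rings(cx)
    out = []
    for ring in rings:
        coords = cx.ligand_coords()[list(ring)]
        lc, ln = coords.mean(axis=0), _ring_normal(coords)
        for j in pocket:
            for pc, pn in _protein_rings(cx.protein_residues[j - 1]):
                d = float(np.linalg.norm(lc - pc))
                if d > d_cut:
                    continue
                theta = _interplanar_angle(ln, pn)
                if not _pipi_angle_ok(theta, rules):
                    continue
                c = _make_contact("pipi", _nearest_member(cx, ring, pc), j, d,
                                  rules, d_min, d_cut, theta)
                if c:
                    out.append(c)
    return _dedup(out)


def _detect_cation_pi(cx, pocket, rules: RuleConfig) -> list[Contact]:
    d_min, d_cut = rules.window("cation_pi")
    cationic = dict(CATIONIC_GROUPS)
    if not rules.his_is_cationic:
        cationic.pop("HIS", None)
    rings = ligand_rings(cx)
    out = []
    for j in pocket:
        res = cx.protein_residues[j - 1]
        # protein cation vs ligand ring
        names = cationic.get(res.name)
        if names:
            atoms = _residue_group(res, names)
            if atoms:
                centroid = _coords(atoms).mean(axis=0)
                for ring in rings:
                    lc = cx.ligand_coords()[list(ring)].mean(axis=0)
                    d = float(np.linalg.norm(lc - centroid))
                    c = _make_contact("cation_pi", _nearest_member(cx, ring, centroid),
                                      j, d, rules, d_min, d_cut)
                    if c:
                        out.append(c)
        # ligand cation (N) vs protein aromatic ring
        for pc, _pn in _protein_rings(res):
            for i, la in enumerate(cx.ligand_atoms, start=1):
                if la.element != "N":
                    continue
                d = float(np.linalg.norm(la.xyz - pc))
                c = _make_contact("cation_pi", i, j, d, rules, d_min, d_cut)
                if c:
                    out.append(c)
    return _dedup(out)


_DETECTORS = {
    "hbond": _detect_hbond,
    "salt_bridge": _detect_salt_bridge,
    "hydrophobic": _detect_hydrophobic,
    "vdw": _detect_vdw,
    "pipi": _detect_pipi,
    "cation_pi": _detect_cation_pi,
}


def detect_contacts(
    cx: ComplexStructure,
    itype: str,
    rules: Optional[RuleConfig] = None,
    pocket: Optional[set[int]] = None,
) -> list[Contact]:
    """Detect all contacts of one interaction type within the pocket.

    Note: vdW detection here is unconditional; the fallback exclusion of
    cells explained by more specific types is applied by
    :func:`annotate_complex` when the map set is assembled.
    """
    if itype not in _DETECTORS:
        raise ValueError(f"unknown interaction type {itype!r}; expected one of {INTERACTION_TYPES}")
    rules = rules or RuleConfig()
    if pocket is None:
        pocket = localize_pocket(cx, radius=max(10.0, _largest_cut(rules)))
    return _DETECTORS[itype](cx, sorted(pocket), rules)


def _largest_cut(rules: RuleConfig) -> float:
    cuts = [rules.window(t)[1] for t in ("hbond", "salt_bridge", "hydrophobic", "pipi", "cation_pi")]
    cuts.append(2 * max(vdw_radius(e) for e in ("S",)) + rules.vdw_slack)
    return max(cuts)


# ---------------------------------------------------------------------------
# map assembly

def build_map(contacts: Iterable[Contact], m: int, n: int) -> np.ndarray:
    """m x n strength map from a contact list (zeros elsewhere)."""
    A = np.zeros((m, n))
    for c in contacts:
        if not (1 <= c.i <= m and 1 <= c.j <= n):
            raise IndexError(f"contact index ({c.i},{c.j}) outside {m}x{n} map")
        A[c.i - 1, c.j - 1] = c.raw_intensity
    return A


def aggregate_overall(maps: dict[str, np.ndarray] | list[np.ndarray], method: str = "max") -> np.ndarray:
    """Combine the per-type maps into the overall interaction map.

    ``max`` (default) keeps the strongest force per cell and preserves the
    [1e-6, 1] range; ``sum_clip`` adds intensities and clips at 1.
    """
    arrs = list(maps.values()) if isinstance(maps, dict) else list(maps)
    if not arrs:
        raise ValueError("no maps to aggregate")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("map shape mismatch")
    stacked = np.stack(arrs)
    if method == "max":
        return stacked.max(axis=0)
    if method == "sum_clip":
        return np.clip(stacked.sum(axis=0), 0.0, 1.0)
    raise ValueError(f"unknown aggregation method {method!r}")


def project_residue_labels(overall: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Residue-level binding labels and the (i, j) site-pair list (1-based)."""
    labels = (overall.max(axis=0) > 0).astype(int)
    ii, jj = np.nonzero(overall)
    pairs = sorted((int(i) + 1, int(j) + 1) for i, j in zip(ii, jj))
    return labels, pairs


@dataclass
class InteractionMapSet:
    """Per-type strength maps, their aggregate, and derived site labels."""

    maps: dict[str, np.ndarray]
    overall: np.ndarray
    residue_labels: np.ndarray
    site_pairs: list[tuple[int, int]]
    contacts: dict[str, list[Contact]] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.overall.shape[0]

    @property
    def n(self) -> int:
        return self.overall.shape[1]

    @classmethod
    def from_contacts(cls, contacts: dict[str, list[Contact]], m: int, n: int,
                      method: str = "max") -> "InteractionMapSet":
        maps = {t: build_map(contacts.get(t, []), m, n) for t in INTERACTION_TYPES}
        overall = aggregate_overall(maps, method=method)
        labels, pairs = project_residue_labels(overall)
        return cls(maps, overall, labels, pairs, contacts=dict(contacts))


def annotate_complex(
    cx: ComplexStructure,
    rules: Optional[RuleConfig] = None,
    pocket: Optional[set[int]] = None,
    aggregation: str = "max",
) -> InteractionMapSet:
    """Run all six detectors and assemble the interaction map set.

    With ``rules.vdw_fallback_only`` (default), vdW contacts at cells already
    carrying a more specific interaction are discarded before map assembly.
    """
    rules = rules or RuleConfig()
    if pocket is None:
        pocket = localize_pocket(cx, radius=max(10.0, _largest_cut(rules)))
    contacts = {t: detect_contacts(cx, t, rules, pocket) for t in INTERACTION_TYPES}
    if rules.vdw_fallback_only:
        taken = {(c.i, c.j) for t in INTERACTION_TYPES if t != "vdw" for c in contacts[t]}
        contacts["vdw"] = [c for c in contacts["vdw"] if (c.i, c.j) not in taken]
    return InteractionMapSet.from_contacts(contacts, cx.m, cx.n, method=aggregation)


# ---------------------------------------------------------------------------
# serialization (long-format TSV)

def maps_to_tsv(ims: InteractionMapSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("type\tligand_index\tresidue_position\tstrength\n")
        for t in INTERACTION_TYPES + ("overall",):
            A = ims.overall if t == "overall" else ims.maps[t]
            for i, j in zip(*np.nonzero(A)):
                fh.write(f"{t}\t{i + 1}\t{j + 1}\t{A[i, j]:.9g}\n")


def maps_from_tsv(path, m: int, n: int) -> InteractionMapSet:
    maps = {t: np.zeros((m, n)) for t in INTERACTION_TYPES}
    overall = np.zeros((m, n))
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("type"), "expected long-format TSV header"
        for line in fh:
            t, i, j, s = line.rstrip("\n").split("\t")
            target = overall if t == "overall" else maps[t]
            target[int(i) - 1, int(j) - 1] = float(s)
    if not overall.any():
        overall = aggregate_overall(maps)
    labels, pairs = project_residue_labels(overall)
    return InteractionMapSet(maps, overall, labels, pairs)
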
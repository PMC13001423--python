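"""Synthetic complexes, planted interaction maps and toy training corpora.

Two generators back the test and experiment machinery:

``make_complex`` builds a toy protein-ligand complex with contacts of chosen
types planted at chosen distances. Residues sit as pseudo-backbones (N, CA,
C, plus the side-chain atoms a planted interaction needs) on a 12 Å lattice
so that nothing interacts by accident; each planted ligand atom (or
six-membered ring) is placed on the side-chain axis of its target residue at
exactly the requested geometric distance. The emitted structure, run through
the annotator with the same rule set, yields exactly the planted contacts --
the generator verifies this closed loop and refuses infeasible geometry.

``make_dataset`` builds an embedding-level corpus for training: positive
pairs carry 1-3 planted contacts whose (residue, atom) token embeddings
share a latent direction plus Gaussian noise sigma, negatives carry none.
Latent directions are drawn from a low-dimensional subspace (default 8,
matching the per-head attention dimension h/H) that is fixed per corpus:
attention heads of dimension h_t can only resolve rank-h_t bilinear
structure, so this is the minimal statistical structure that makes contact
recovery possible but not trivial. Everything is a pure function of the
seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotate import Contact, InteractionMapSet, annotate_complex
from .rules import INTERACTION_TYPES, RuleConfig, decay_strength
from .structures import Atom, ComplexStructure, Residue

__all__ = [
    "PlantedContact", "SyntheticComplexSpec", "SyntheticPairSpec",
    "make_complex", "make_pair", "make_dataset", "InfeasibleGeometryError",
]

RESIDUE_SPACING = 12.0  # Å between residue centers; beyond every cutoff
FILLER_Y = -8.0         # filler ligand atoms sit opposite the side chains

#: safe planting windows per type (strictly inside the default detection
#: windows, with margin so no secondary atom pairing crosses a cutoff)
SAFE_WINDOWS = {
    "hbond": (2.60, 3.40),
    "salt_bridge": (3.60, 5.40),
    "hydrophobic": (3.40, 3.95),
    "vdw": (2.62, 3.42),       # ligand O against the backbone carbonyl C
    "pipi": (4.20, 5.40),
    "cation_pi": (3.80, 5.80),
}

RING_RADIUS = 1.39


class InfeasibleGeometryError(RuntimeError):
    """Planted geometry could not be realized without side effects."""


@dataclass(frozen=True)
class PlantedContact:
    itype: str
    i: int          # 1-based ligand atom index (rings occupy i..i+5)
    j: int          # 1-based residue position
    distance: float # Å, the geometric distance the detector will see

    def atom_span(self) -> range:
        return range(self.i, self.i + (6 if self.itype == "pipi" else 1))


@dataclass
class SyntheticComplexSpec:
    n: int
    m: int
    contacts: list[PlantedContact] = field(default_factory=list)
    seed: int = 0

    def validate(self, rules: RuleConfig) -> None:
        used_res: set[int] = set()
        used_atoms: set[int] = set()
        for c in self.contacts:
            if c.itype not in INTERACTION_TYPES:
                raise ValueError(f"unknown interaction type {c.itype!r}")
            lo, hi = SAFE_WINDOWS[c.itype]
            if not lo <= c.distance <= hi:
                raise InfeasibleGeometryError(
                    f"{c.itype} distance {c.distance} outside feasible window [{lo}, {hi}]"
                )
            if not 1 <= c.j <= self.n:
                raise ValueError(f"residue {c.j} outside 1..{self.n}")
            if c.j in used_res:
                raise InfeasibleGeometryError(f"residue {c.j} hosts two planted contacts")
            used_res.add(c.j)
            span = set(c.atom_span())
            if max(span) > self.m:
                raise ValueError(f"contact at atom {c.i} needs atoms beyond m={self.m}")
            if span & used_atoms:
                raise InfeasibleGeometryError(f"ligand atoms {sorted(span)} reused")
            used_atoms |= span


# ---------------------------------------------------------------------------
# residue templates (local coordinates; +y is the side-chain direction)

_BACKBONE = [("N", "N", (-1.45, 0.0, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)), ("C", "C", (1.52, 0.0, 0.0))]


def _hexagon(names: Sequence[str], center: np.ndarray, start_angle: float = 180.0) -> list:
    out = []
    for k, name in enumerate(names):
        ang = math.radians(start_angle - 60.0 * k)
        out.append((name, name[0], tuple(center + np.array(
            [RING_RADIUS * math.cos(ang), RING_RADIUS * math.sin(ang), 0.0]))))
    return out


def _residue_template(itype: Optional[str]) -> tuple[str, list]:
    if itype in ("salt_bridge",):
        atoms = _BACKBONE + [
            ("CB", "C", (0.0, 1.50, 0.0)), ("CG", "C", (0.0, 2.90, 0.0)),
            ("OD1", "O", (-1.10, 3.60, 0.0)), ("OD2", "O", (1.10, 3.60, 0.0)),
        ]
        return "ASP", atoms
    if itype in ("pipi", "cation_pi"):
        ring = _hexagon(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"], np.array([0.0, 3.0, 0.0]))
        return "PHE", _BACKBONE + ring
    return "GLY", list(_BACKBONE)


def _plant_ligand_atoms(c: PlantedContact, center: np.ndarray) -> list[tuple[int, str, np.ndarray]]:
    """Ligand atoms (0-based index, element, xyz) realizing one contact."""
    d = c.distance
    if c.itype == "hbond":       # O straight above the backbone N
        return [(c.i - 1, "O", center + np.array([-1.45, d, 0.0]))]
    if c.itype == "hydrophobic":  # C above CA
        return [(c.i - 1, "C", center + np.array([0.0, d, 0.0]))]
    if c.itype == "vdw":          # O above the backbone carbonyl C
        return [(c.i - 1, "O", center + np.array([1.52, d, 0.0]))]
    if c.itype == "salt_bridge":  # N on the carboxylate centroid axis
        return [(c.i - 1, "N", center + np.array([0.0, 3.60 + d, 0.0]))]
    if c.itype == "cation_pi":    # N above the aromatic ring centroid
        dz = math.sqrt(d * d - 0.01)
        return [(c.i - 1, "N", center + np.array([0.10, 3.0, dz]))]
    if c.itype == "pipi":         # parallel stacked ring, centroid offset +x
        dz = math.sqrt(d * d - 0.04)
        ring_center = center + np.array([0.20, 3.0, dz])
        out = []
        for k in range(6):
            ang = math.radians(180.0 - 60.0 * k)
            pos = ring_center + np.array(
                [RING_RADIUS * math.cos(ang), RING_RADIUS * math.sin(ang), 0.0])
            out.append((c.i - 1 + k, "C", pos))
        return out
    raise ValueError(c.itype)


def make_complex(
    spec: SyntheticComplexSpec,
    rules: Optional[RuleConfig] = None,
    verify: bool = True,
) -> tuple[ComplexStructure, InteractionMapSet]:
    """Build the toy complex and its ground-truth interaction map set.

    With ``verify`` (default) the structure is round-tripped through the
    annotator and must reproduce the planted contact list exactly, else
    :class:`InfeasibleGeometryError` is raised.
    """
    rules = rules or RuleConfig()
    spec.validate(rules)
    by_res = {c.j: c for c in spec.contacts}

    residues: list[Residue] = []
    lig_atoms: dict[int, tuple[str, np.ndarray]] = {}
    for j in range(1, spec.n + 1):
        center = np.array([RESIDUE_SPACING * (j - 1), 0.0, 0.0])
        contact = by_res.get(j)
        name, template = _residue_template(contact.itype if contact else None)
        key = ("A", j, "")
        atoms = [
            Atom(elem, aname, tuple(center + np.asarray(pos)), 1.0, key, "A")
            for aname, elem, pos in template
        ]
        residues.append(Residue("A", j, "", name, atoms))
        if contact is not None:
            for idx0, elem, xyz in _plant_ligand_atoms(contact, center):
                lig_atoms[idx0] = (elem, xyz)

    # filler atoms: an inert carbon row opposite the side chains
    rng = np.random.default_rng(spec.seed)
    for idx0 in range(spec.m):
        if idx0 not in lig_atoms:
            x = 3.0 * idx0 + float(rng.uniform(-0.4, 0.4))
            lig_atoms[idx0] = ("C", np.array([x, FILLER_Y, 0.0]))

    ligand = [
        Atom(elem, f"{elem}{i + 1}", tuple(map(float, xyz)), 1.0, ("Z", 1, ""), "Z")
        for i, (elem, xyz) in sorted(lig_atoms.items())
    ]
    cx = ComplexStructure(
        source_id=f"synthetic-{spec.seed}",
        protein_residues=residues,
        ligand_atoms=ligand,
        ligand_name="LIG",
    )

    truth_contacts: dict[str, list[Contact]] = {t: [] for t in INTERACTION_TYPES}
    for c in spec.contacts:
        lo, hi = rules.window(c.itype) if c.itype != "vdw" else rules.window("vdw", 1.52, 1.70)
        truth_contacts[c.itype].append(
            Contact(c.itype, c.i, c.j, c.distance, decay_strength(c.distance, lo, hi, rules.floor)))
    truth = InteractionMapSet.from_contacts(truth_contacts, spec.m, spec.n)

    if verify:
        observed = annotate_complex(cx, rules)
        obs = {(c.itype, c.i, c.j) for t in INTERACTION_TYPES for c in observed.contacts[t]}
        want = {(c.itype, c.i, c.j) for c in spec.contacts}
        if obs != want:
            raise InfeasibleGeometryError(
                f"round trip mismatch: extra={sorted(obs - want)}, missing={sorted(want - obs)}")
        for c in spec.contacts:
            got = observed.maps[c.itype][c.i - 1, c.j - 1]
            exp = truth.maps[c.itype][c.i - 1, c.j - 1]
            if abs(got - exp) > 1e-6:
                raise InfeasibleGeometryError(
                    f"strength mismatch for {c}: got {got}, expected {exp}")
    return cx, truth


def random_complex_spec(
    seed: int,
    n_range: tuple[int, int] = (6, 10),
    max_contacts: int = 4,
    n_fillers: int = 2,
) -> SyntheticComplexSpec:
    """A randomized feasible complex spec: random interaction types at random
    distances inside the safe planting windows, on distinct residues."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    k = int(rng.integers(1, min(max_contacts, n) + 1))
    residues = (rng.permutation(n)[:k] + 1).tolist()
    contacts = []
    next_atom = 1
    for j in sorted(residues):
        itype = INTERACTION_TYPES[int(rng.integers(0, len(INTERACTION_TYPES)))]
        lo, hi = SAFE_WINDOWS[itype]
        d = float(rng.uniform(lo, hi))
        contacts.append(PlantedContact(itype, next_atom, j, round(d, 3)))
        next_atom += 6 if itype == "pipi" else 1
    return SyntheticComplexSpec(n=n, m=next_atom - 1 + n_fillers,
                                contacts=contacts, seed=seed)


# ---------------------------------------------------------------------------
# embedding-level corpus

@dataclass
class SyntheticPairSpec:
    y: int
    n: int = 48
    m: int = 8
    n_contacts: int = 2          # ignored for negatives
    sigma: float = 0.1
    seed: int = 0


def _random_planted_cells(rng, n, m, k):
    jj = rng.choice(n, size=k, replace=False) + 1
    ii = rng.choice(m, size=k, replace=False) + 1
    return list(zip(ii.tolist(), jj.tolist()))


def make_pair(
    spec: SyntheticPairSpec,
    h: int = 64,
    latent_basis: Optional[np.ndarray] = None,
) -> dict:
    """One training sample: embeddings P (n, h) and D (m, h), label, maps.

    Positive pairs plant ``n_contacts`` contacts on distinct residues/atoms;
    each contact adds a shared unit latent direction (drawn inside
    ``latent_basis`` when given) to the two involved token embeddings, plus
    isotropic noise of scale sigma.
    """
    rng = np.random.default_rng(spec.seed)
    P = rng.standard_normal((spec.n, h)) / math.sqrt(h)
    D = rng.standard_normal((spec.m, h)) / math.sqrt(h)
    sample = {
        "y": int(spec.y), "P_base": P.copy(), "D_base": D.copy(),
        "maps": None, "true_residues": set(), "true_cells": {},
    }
    if spec.y == 1:
        cells = _random_planted_cells(rng, spec.n, spec.m, spec.n_contacts)
        contacts: dict[str, list[Contact]] = {t: [] for t in INTERACTION_TYPES}
        for (i, j) in cells:
            itype = INTERACTION_TYPES[int(rng.integers(0, len(INTERACTION_TYPES)))]
            lo, hi = SAFE_WINDOWS[itype]
            d = float(rng.uniform(lo, hi))
            dlo, dhi = (RuleConfig().window(itype) if itype != "vdw"
                        else RuleConfig().window("vdw", 1.52, 1.70))
            contacts[itype].append(Contact(itype, i, j, d, decay_strength(d, dlo, dhi)))
            if latent_basis is not None:
                coef = rng.standard_normal(latent_basis.shape[0])
                u = coef @ latent_basis
            else:
                u = rng.standard_normal(h)
            u = u / np.linalg.norm(u)
            P[j - 1] += u + spec.sigma * rng.standard_normal(h)
            D[i - 1] += u + spec.sigma * rng.standard_normal(h)
            sample["true_residues"].add(j)
            sample["true_cells"].setdefault(itype, set()).add((i, j))
        sample["maps"] = InteractionMapSet.from_contacts(contacts, spec.m, spec.n)
    sample["P"], sample["D"] = P, D
    return sample


def make_dataset(
    n_pairs: int = 100,
    h: int = 64,
    seed: int = 0,
    n: int = 48,
    m: int = 8,
    sigma: float = 0.1,
    pos_fraction: float = 0.5,
    latent_dim: Optional[int] = 8,
    max_contacts: int = 3,
) -> list[dict]:
    """Deterministic corpus of labelled pairs with planted contact structure."""
    if n_pairs < 2:
        raise ValueError("need at least two pairs")
    n_pos = round(n_pairs * pos_fraction)
    if n_pos == 0 or n_pos == n_pairs:
        raise ValueError("corpus must contain both labels")
    root = np.random.default_rng(seed)
    basis = None
    if latent_dim is not None:
        basis = root.standard_normal((latent_dim, h))
        basis /= np.linalg.norm(basis, axis=1, keepdims=True)
    dataset = []
    for k in range(n_pairs):
        y = 1 if k < n_pos else 0
        n_contacts = int(root.integers(1, max_contacts + 1))
        pair_seed = int(root.integers(0, 2**31 - 1))
        dataset.append(make_pair(
            SyntheticPairSpec(y=y, n=n, m=m, n_contacts=n_contacts, sigma=sigma, seed=pair_seed),
            h=h, latent_basis=basis))
    order = root.permutation(n_pairs)
    return [dataset[i] for i in order]


# ---------------------------------------------------------------------------
# corpus serialization (what the train CLI reads)

def save_corpus(dataset: list[dict], path) -> None:
    """Write a corpus to a single .npz archive."""
    arrays: dict[str, np.ndarray] = {"n_pairs": np.array(len(dataset))}
    for k, s in enumerate(dataset):
        arrays[f"P_{k}"] = s["P"]
        arrays[f"D_{k}"] = s["D"]
        arrays[f"y_{k}"] = np.array(s["y"])
        arrays[f"res_{k}"] = np.array(sorted(s["true_residues"]), dtype=int)
        if s["maps"] is not None:
            for t in INTERACTION_TYPES:
                arrays[f"map_{t}_{k}"] = s["maps"].maps[t]
    np.savez(path, **arrays)


def load_corpus(path) -> list[dict]:
    dataset = []
    with np.load(path, allow_pickle=False) as z:
        n_pairs = int(z["n_pairs"])
        for k in range(n_pairs):
            s = {
                "P": z[f"P_{k}"], "D": z[f"D_{k}"], "y": int(z[f"y_{k}"]),
                "true_residues": set(z[f"res_{k}"].tolist()),
                "maps": None, "true_cells": {},
            }
            if f"map_{INTERACTION_TYPES[0]}_{k}" in z:
                maps = {t: z[f"map_{t}_{k}"] for t in INTERACTION_TYPES}
                contacts: dict[str, list[Contact]] = {t: [] for t in INTERACTION_TYPES}
                for t in INTERACTION_TYPES:
                    for i0, j0 in zip(*np.nonzero(maps[t])):
                        contacts[t].append(Contact(t, int(i0) + 1, int(j0) + 1, 0.0,
                                                   float(maps[t][i0, j0])))
                        s["true_cells"].setdefault(t, set()).add((int(i0) + 1, int(j0) + 1))
                s["maps"] = InteractionMapSet.from_contacts(
                    contacts, maps[INTERACTION_TYPES[0]].shape[0],
                    maps[INTERACTION_TYPES[0]].shape[1])
            dataset.append(s)
    return dataset
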
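"""Parsing of protein-ligand complex structures and binding-pocket localization.

Reads PDB/mmCIF through gemmi, selects exactly one ligand (waters, common
buffer components, ions and glycans are never candidates), extracts the
one-letter protein sequence with a position map, and finds the pocket
residues within a distance cutoff of any ligand heavy atom.

Conventions: coordinates and distances in Å, residue positions 1-based in
sequence space, ligand heavy atoms indexed 1..m in file order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom", "Residue", "ComplexStructure", "ProteinSequence", "LigandRecord",
    "parse_complex", "localize_pocket", "extract_sequence",
    "NoLigandError", "AmbiguousLigandError",
    "DEFAULT_POCKET_RADIUS", "DEFAULT_BLOCKLIST",
]

DEFAULT_POCKET_RADIUS = 10.0

#: residue names never considered ligand candidates: waters, ions, cryo
#: buffers and common covalently attached glycans
DEFAULT_BLOCKLIST = frozenset({
    "HOH", "WAT", "DOD",
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO", "CD",
    "IOD", "BR", "CS", "LI",
    "SO4", "PO4", "GOL", "EDO", "ACT", "DMS", "PEG", "MPD", "FMT", "TRS",
    "PG4", "PGE", "NO3", "BME",
    "NAG", "NDG", "BMA", "MAN", "GAL", "FUC", "GLC", "SIA", "XYS",
})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "ASX": "B", "GLX": "Z", "SEC": "U", "PYL": "O",
    "MSE": "M", "UNK": "X",
}


class NoLigandError(ValueError):
    """No ligand candidate found in the structure."""


class AmbiguousLigandError(ValueError):
    """Auto ligand selection found more than one candidate."""


@dataclass(frozen=True)
class Atom:
    element: str
    name: str
    pos: tuple[float, float, float]
    occupancy: float
    residue_key: tuple[str, int, str]  # (chain id, residue number, insertion code)
    chain_id: str

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass
class Residue:
    chain_id: str
    seqnum: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seqnum, self.icode)


@dataclass
class ComplexStructure:
    """A parsed protein-ligand complex with one selected ligand.

    ``protein_residues`` are ordered by chain then sequence; ``ligand_atoms``
    are the heavy atoms of the selected ligand in file order (i = 1..m).
    """

    source_id: str
    protein_residues: list[Residue]
    ligand_atoms: list[Atom]
    ligand_name: str

    @property
    def n(self) -> int:
        return len(self.protein_residues)

    @property
    def m(self) -> int:
        return len(self.ligand_atoms)

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.ligand_atoms], dtype=float)

    def manifest(self, pocket: Optional[set[int]] = None) -> dict:
        chains = sorted({r.chain_id for r in self.protein_residues})
        return {
            "source_id": self.source_id,
            "chains": chains,
            "ligand": self.ligand_name,
            "m": self.m,
            "n": self.n,
            "pocket_residues": sorted(pocket) if pocket is not None else None,
        }

    def to_pdb(self, path) -> None:
        """Serialize to a minimal PDB file (protein ATOM + ligand HETATM)."""
        st = gemmi.Structure()
        st.name = self.source_id
        model = gemmi.Model("1")
        serial = 1
        for chain_id in dict.fromkeys(r.chain_id for r in self.protein_residues):
            chain = gemmi.Chain(chain_id)
            for res in self.protein_residues:
                if res.chain_id != chain_id:
                    continue
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
                gres.het_flag = "A"
                for a in res.atoms:
                    serial = _append_atom(gres, a, serial)
                chain.add_residue(gres)
            model.add_chain(chain)
        lig_chain = gemmi.Chain("Z")
        gres = gemmi.Residue()
        gres.name = self.ligand_name
        gres.seqid = gemmi.SeqId(1, " ")
        gres.het_flag = "H"
        for a in self.ligand_atoms:
            serial = _append_atom(gres, a, serial)
        lig_chain.add_residue(gres)
        model.add_chain(lig_chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))


def _append_atom(gres: "gemmi.Residue", a: Atom, serial: int) -> int:
    ga = gemmi.Atom()
    ga.name = a.name
    ga.element = gemmi.Element(a.element)
    ga.pos = gemmi.Position(*a.pos)
    ga.occ = a.occupancy
    ga.serial = serial
    gres.add_atom(ga)
    return serial + 1


@dataclass
class ProteinSequence:
    """One-letter protein sequence with a sequence-position <-> residue map."""

    residues: str
    pos_to_key: list[tuple[str, int, str]]
    key_to_pos: dict[tuple[str, int, str], int]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LigandRecord:
    """Line-notation view of a ligand with atom-level tokens d_1..d_m."""

    smiles: Optional[str] = None
    selfies: Optional[str] = None
    atom_tokens: list[str] = field(default_factory=list)

    @classmethod
    def from_smiles(cls, smiles: str) -> "LigandRecord":
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES: {smiles!r}")
        tokens = [a.GetSymbol() for a in mol.GetAtoms()]  # heavy atoms only
        return cls(smiles=smiles, atom_tokens=tokens)

    @classmethod
    def from_structure(cls, cx: ComplexStructure) -> "LigandRecord":
        return cls(atom_tokens=[a.element for a in cx.ligand_atoms])

    @property
    def m(self) -> int:
        return len(self.atom_tokens)


def _keep_best_altloc(res: "gemmi.Residue") -> list["gemmi.Atom"]:
    """Highest-occupancy conformer per atom name; ties broken by altloc order."""
    best: dict[str, "gemmi.Atom"] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ or (atom.occ == prev.occ and atom.altloc < prev.altloc):
            best[atom.name] = atom
    # preserve file order of first occurrence
    seen = []
    names = set()
    for atom in res:
        if atom.name not in names:
            names.add(atom.name)
            seen.append(best[atom.name])
    return seen


def _is_amino_acid(name: str) -> bool:
    if name in THREE_TO_ONE:
        return True
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def _is_water(name: str) -> bool:
    return name in ("HOH", "WAT", "DOD")


def parse_complex(
    path,
    ligand_selector: str = "auto",
    blocklist: Iterable[str] = DEFAULT_BLOCKLIST,
) -> ComplexStructure:
    """Parse a PDB/mmCIF file and select exactly one ligand.

    ``ligand_selector`` is either a HETATM residue name or ``"auto"``, which
    requires a unique candidate. Hydrogens are dropped; ligand atoms are the
    heavy atoms of the selected group.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    blockset = {b.upper() for b in blocklist}

    protein: list[Residue] = []
    candidates: list[tuple[str, Residue]] = []  # (name, residue)
    for chain in model:
        for gres in chain:
            atoms = [
                Atom(
                    element=a.element.name.upper(),
                    name=a.name,
                    pos=(a.pos.x, a.pos.y, a.pos.z),
                    occupancy=a.occ,
                    residue_key=(chain.name, gres.seqid.num, (gres.seqid.icode or " ").strip()),
                    chain_id=chain.name,
                )
                for a in _keep_best_altloc(gres)
                if a.element.name.upper() not in ("H", "D")
            ]
            if not atoms:
                continue
            if not all(np.isfinite(a.xyz).all() for a in atoms):
                raise ValueError(f"non-finite coordinates in residue {gres.name}")
            res = Residue(
                chain_id=chain.name,
                seqnum=gres.seqid.num,
                icode=(gres.seqid.icode or " ").strip(),
                name=gres.name,
                atoms=atoms,
            )
            if _is_amino_acid(gres.name):
                protein.append(res)
            elif _is_water(gres.name) or gres.name.upper() in blockset:
                continue
            else:
                candidates.append((gres.name, res))

    if not protein:
        raise ValueError(f"no protein residues in {path}")
    if not candidates:
        raise NoLigandError(f"no ligand candidate in {path}")

    if ligand_selector == "auto":
        if len(candidates) > 1:
            names = sorted({name for name, _ in candidates})
            raise AmbiguousLigandError(
                f"ambiguous ligand: candidates {names}; pass an explicit selector"
            )
        name, res = candidates[0]
    else:
        matches = [(n, r) for n, r in candidates if n == ligand_selector]
        if not matches:
            raise NoLigandError(
                f"no ligand candidate named {ligand_selector!r} "
                f"(found {sorted({n for n, _ in candidates})})"
            )
        name, res = matches[0]

    return ComplexStructure(
        source_id=st.name or path.stem,
        protein_residues=protein,
        ligand_atoms=list(res.atoms),
        ligand_name=name,
    )


def localize_pocket(cx: ComplexStructure, radius: float = DEFAULT_POCKET_RADIUS) -> set[int]:
    """1-based positions of residues with any atom within ``radius`` Å of any
    ligand heavy atom."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    lig = cx.ligand_coords()
    pocket: set[int] = set()
    for j, res in enumerate(cx.protein_residues, start=1):
        coords = np.array([a.pos for a in res.atoms], dtype=float)
        d2 = ((coords[:, None, :] - lig[None, :, :]) ** 2).sum(-1)
        if (d2 <= radius * radius).any():
            pocket.add(j)
    return pocket


def extract_sequence(cx: ComplexStructure) -> ProteinSequence:
    """One-letter sequence in residue order; unknown residue names map to X."""
    if cx.n < 1:
        raise ValueError("complex has no protein residues")
    letters = []
    pos_to_key = []
    key_to_pos = {}
    for pos, res in enumerate(cx.protein_residues, start=1):
        code = THREE_TO_ONE.get(res.name)
        if code is None:
            info = gemmi.find_tabulated_residue(res.name)
            one = (info.one_letter_code if info else "").strip().upper()
            code = one if one.isalpha() and len(one) == 1 else "X"
        letters.append(code)
        pos_to_key.append(res.key)
        key_to_pos[res.key] = pos
    return ProteinSequence("".join(letters), pos_to_key, key_to_pos)


def write_manifest(cx: ComplexStructure, path, pocket: Optional[set[int]] = None) -> None:
    with open(path, "w") as fh:
        json.dump(cx.manifest(pocket), fh, indent=2)
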
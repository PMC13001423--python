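from __future__ import annotations

import numpy as np
import pytest

from ncibind.structures import Atom, ComplexStructure, Residue


def pdb_line(record, serial, name, resname, chain, resseq, x, y, z,
             occ=1.00, element=None, altloc=" "):
    element = element or name[0]
    return (f"{record:<6}{serial:>5} {name:^4}{altloc}{resname:<3} {chain}"
            f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2}\n")


def write_pdb(path, lines):
    path.write_text("".join(lines) + "END\n")
    return path


@pytest.fixture
def mini_pdb(tmp_path):
    """Three-residue chain plus a two-atom HETATM ligand."""
    lines = [
        pdb_line("ATOM", 1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N"),
        pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 1.45, 0.0, 0.0, element="C"),
        pdb_line("ATOM", 3, "C", "ALA", "A", 1, 2.97, 0.0, 0.0, element="C"),
        pdb_line("ATOM", 4, "N", "GLY", "A", 2, 12.0, 0.0, 0.0, element="N"),
        pdb_line("ATOM", 5, "CA", "GLY", "A", 2, 13.45, 0.0, 0.0, element="C"),
        pdb_line("ATOM", 6, "C", "GLY", "A", 2, 14.97, 0.0, 0.0, element="C"),
        pdb_line("ATOM", 7, "N", "TRP", "A", 3, 24.0, 0.0, 0.0, element="N"),
        pdb_line("ATOM", 8, "CA", "TRP", "A", 3, 25.45, 0.0, 0.0, element="C"),
        pdb_line("ATOM", 9, "C", "TRP", "A", 3, 26.97, 0.0, 0.0, element="C"),
        pdb_line("HETATM", 10, "C1", "LIG", "Z", 1, 5.0, 5.0, 0.0, element="C"),
        pdb_line("HETATM", 11, "O1", "LIG", "Z", 1, 6.3, 5.0, 0.0, element="O"),
    ]
    return write_pdb(tmp_path / "mini.pdb", lines)


def toy_complex(residue_specs, ligand_specs):
    """Build a ComplexStructure by hand.

    residue_specs: list of (resname, [(atom_name, element, (x, y, z)), ...])
    ligand_specs:  list of (element, (x, y, z))
    """
    residues = []
    for j, (name, atoms) in enumerate(residue_specs, start=1):
        key = ("A", j, "")
        residues.append(Residue("A", j, "", name, [
            Atom(elem, aname, tuple(map(float, pos)), 1.0, key, "A")
            for aname, elem, pos in atoms
        ]))
    ligand = [
        Atom(elem, f"{elem}{i}", tuple(map(float, pos)), 1.0, ("Z", 1, ""), "Z")
        for i, (elem, pos) in enumerate(ligand_specs, start=1)
    ]
    return ComplexStructure("toy", residues, ligand, "LIG")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
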
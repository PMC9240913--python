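"""Shared fixtures: minimal but standard-conforming PDB text builders."""

from __future__ import annotations

import numpy as np
import pytest


def pdb_line(
    record: str,
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resi: int,
    x: float,
    y: float,
    z: float,
    element: str,
    altloc: str = "",
    icode: str = "",
    occupancy: float = 1.0,
) -> str:
    nm = name if len(name) >= 4 else f" {name:<3}"
    return (
        f"{record:<6}{serial:>5} {nm:<4}{altloc:1}{resname:>3} {chain:1}{resi:>4}"
        f"{icode:1}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


def make_pdb(atoms: list[tuple], end: bool = True) -> str:
    """atoms: tuples of pdb_line positional args (record, serial, name, ...)."""
    lines = [pdb_line(*a) if isinstance(a, tuple) else a for a in atoms]
    if end:
        lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_residue_with_water() -> str:
    return make_pdb(
        [
            ("ATOM", 1, "N", "ALA", "A", 10, 0.0, 0.0, 0.0, "N"),
            ("ATOM", 2, "CA", "ALA", "A", 10, 1.5, 0.0, 0.0, "C"),
            ("ATOM", 3, "N", "GLY", "A", 11, 3.0, 0.0, 0.0, "N"),
            ("HETATM", 4, "O", "HOH", "A", 301, 9.0, 0.0, 0.0, "O"),
        ]
    )


@pytest.fixture
def residue_and_ligand() -> str:
    atoms = [("ATOM", 1, "CA", "ALA", "A", 10, 0.0, 0.0, 0.0, "C")]
    for k in range(5):
        atoms.append(("HETATM", 2 + k, f"C{k + 1}", "XYZ", "A", 201, 4.0 + 0.1 * k, 0.0, 0.0, "C"))
    return make_pdb(atoms)


@pytest.fixture
def hydrogen_rich() -> str:
    """10 heavy atoms + 8 hydrogens over two residues and a ligand."""
    atoms = []
    serial = 1
    for k in range(4):
        atoms.append(("ATOM", serial, f"C{k}", "LEU", "A", 5, float(k), 0.0, 0.0, "C"))
        serial += 1
    for k in range(4):
        atoms.append(("ATOM", serial, f"H{k}", "LEU", "A", 5, float(k), 1.0, 0.0, "H"))
        serial += 1
    for k in range(3):
        atoms.append(("ATOM", serial, f"N{k}", "LYS", "A", 6, float(k), 5.0, 0.0, "N"))
        serial += 1
    for k in range(2):
        atoms.append(("ATOM", serial, f"H{k}", "LYS", "A", 6, float(k), 6.0, 0.0, "H"))
        serial += 1
    for k in range(3):
        atoms.append(("HETATM", serial, f"O{k}", "LIG", "A", 201, float(k), 9.0, 0.0, "O"))
        serial += 1
    for k in range(2):
        atoms.append(("HETATM", serial, f"H{k}", "LIG", "A", 201, float(k), 10.0, 0.0, "H"))
        serial += 1
    return make_pdb(atoms)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
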
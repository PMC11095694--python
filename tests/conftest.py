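"""Shared fixtures: small synthetic structures built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from lcpscan.structures import Atom, MolecularStructure


def toy_protein(n_residues: int = 20, seed: int = 0, spread: float = 5.0) -> MolecularStructure:
    """A minimal CA-only pseudo-protein with one atom per residue."""
    rng = np.random.default_rng(seed)
    atoms = [
        Atom(i + 1, "CA", "C", "ALA", i + 1, "A", p)
        for i, p in enumerate(rng.normal(0.0, spread, (n_residues, 3)))
    ]
    return MolecularStructure(atoms)


def mixed_structure() -> MolecularStructure:
    """Protein + heme + waters + imidazole across two chains, for
    selection and stripping tests."""
    entries = [
        ("N", "N", "GLY", 1, "A"), ("CA", "C", "GLY", 1, "A"),
        ("C", "C", "GLY", 1, "A"), ("O", "O", "GLY", 1, "A"),
        ("N", "N", "ALA", 2, "A"), ("CA", "C", "ALA", 2, "A"),
        ("C", "C", "ALA", 2, "A"), ("O", "O", "ALA", 2, "A"),
        ("CB", "C", "ALA", 2, "A"),
        ("CA", "C", "LEU", 3, "B"), ("CB", "C", "LEU", 3, "B"),
        ("FE", "FE", "HEM", 90, "A"), ("O2", "O", "OXY", 91, "A"),
        ("O", "O", "HOH", 101, "A"), ("O", "O", "HOH", 102, "A"),
        ("O", "O", "HOH", 103, "B"),
        ("N1", "N", "IMD", 110, "A"), ("C2", "C", "IMD", 110, "A"),
    ]
    rng = np.random.default_rng(42)
    atoms = [
        Atom(i + 1, name, el, res, num, ch, rng.normal(0, 8, 3),
             record="HETATM" if res in ("HEM", "OXY", "HOH", "IMD") else "ATOM")
        for i, (name, el, res, num, ch) in enumerate(entries)
    ]
    return MolecularStructure(atoms)


@pytest.fixture
def ca_protein() -> MolecularStructure:
    return toy_protein(50, seed=0)


@pytest.fixture
def mixed() -> MolecularStructure:
    return mixed_structure()
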
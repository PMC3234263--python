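"""Shared fixtures: tiny hand-written PDB texts and synthetic datasets."""

import numpy as np
import pytest

from dbpsite.fixtures import FixtureSpec, generate_dataset, generate_toy_complex
from dbpsite.pipeline import RunConfig, records_from_chains


def _atom_line(serial, name, resname, chain, resnum, x, y, z, element):
    return (
        f"ATOM  {serial:5d} {name:<4s}{resname:>4s}{chain:>2s}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture(scope="session")
def poly_ala_pdb() -> str:
    """Three-residue poly-ALA chain with backbone + CB + one hydrogen."""
    lines = []
    serial = 1
    for i in range(3):
        x = 3.8 * i
        for name, dx, dy, dz, el in [
            ("N", -1.2, 0.5, 0.0, "N"),
            ("CA", 0.0, 0.0, 0.0, "C"),
            ("C", 1.2, 0.6, 0.0, "C"),
            ("O", 1.3, 1.8, 0.0, "O"),
            ("CB", 0.0, -1.0, 1.2, "C"),
            ("HA", 0.2, 0.8, 0.9, "H"),
        ]:
            lines.append(
                _atom_line(serial, name, "ALA", "A", i + 1, x + dx, dy, dz, el)
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def protein_dna_pdb() -> str:
    """One 2-residue protein chain A and one 2-nucleotide DNA chain B."""
    lines = [
        _atom_line(1, "N", "GLY", "A", 1, -1.2, 0.5, 0.0, "N"),
        _atom_line(2, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"),
        _atom_line(3, "C", "GLY", "A", 1, 1.2, 0.6, 0.0, "C"),
        _atom_line(4, "O", "GLY", "A", 1, 1.3, 1.8, 0.0, "O"),
        _atom_line(5, "N", "ALA", "A", 2, 2.6, -0.1, 0.0, "N"),
        _atom_line(6, "CA", "ALA", "A", 2, 3.8, 0.0, 0.0, "C"),
        _atom_line(7, "C", "ALA", "A", 2, 5.0, 0.6, 0.0, "C"),
        _atom_line(8, "O", "ALA", "A", 2, 5.1, 1.8, 0.0, "O"),
        _atom_line(9, "CB", "ALA", "A", 2, 3.8, -1.0, 1.2, "C"),
        _atom_line(10, "P", "DA", "B", 1, 0.0, 4.0, 0.0, "P"),
        _atom_line(11, "C1'", "DA", "B", 1, 1.5, 4.2, 0.0, "C"),
        _atom_line(12, "P", "DT", "B", 2, 3.8, 8.0, 0.0, "P"),
        "TER",
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def toy_complex():
    """Default single-chain synthetic complex (8 planted binders)."""
    return generate_toy_complex(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """Six small chains for fast protocol tests."""
    return generate_dataset(
        FixtureSpec(n_chains=6, n_residues=40, n_binding=6, seed=5)
    )


@pytest.fixture(scope="session")
def small_records(small_dataset):
    return records_from_chains(small_dataset, RunConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
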
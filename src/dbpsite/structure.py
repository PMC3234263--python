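"""Read and write PDB-format structures into a light residue/atom model.

The internal model keeps only what the downstream annotation and feature
stages need: per-residue heavy-atom coordinates, alpha-carbon positions,
author residue numbering (with insertion codes) and a coarse molecule
classification (protein / nucleic / other).  Parsing and serialization are
delegated to biotite; this module owns the residue bookkeeping and the
classification rules.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureParseError",
    "ChainLookupError",
    "parse_structure",
    "structure_to_pdb",
    "select_chain",
    "STANDARD_AMINO_ACIDS",
    "DNA_RESIDUES",
    "NONSTANDARD_PARENT",
    "THREE_TO_ONE",
]

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Deoxyribonucleotides, including the legacy one-letter naming dialect used
# by older PDB entries.
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DI", "DU", "A", "C", "G", "T", "U", "I"}

# Common nonstandard amino acids with an unambiguous parent type; anything
# not listed here and not standard is classified ``other`` and excluded
# downstream.
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO", "SEP": "SER",
    "TPO": "THR", "PTR": "TYR", "CSO": "CYS", "MLY": "LYS", "KCX": "LYS",
}

_HYDROGEN_ELEMENTS = {"H", "D", "T"}


class StructureParseError(ValueError):
    """Raised when a PDB stream cannot be parsed into any residues."""


class ChainLookupError(KeyError):
    """Raised when a requested chain id is absent from a structure."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray
    is_heavy: bool

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")
        object.__setattr__(self, "coord", coord)


@dataclass
class Residue:
    chain_id: str
    seq_index: int
    ins_code: str
    name: str
    atoms: list[Atom] = field(default_factory=list)
    molecule_class: str = "other"  # protein | nucleic | other

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_index, self.ins_code)

    @property
    def ca_coord(self) -> np.ndarray | None:
        for atom in self.atoms:
            if atom.name == "CA" and atom.element == "C":
                return atom.coord
        return None

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for a in self.heavy_atoms]
        return np.array(coords, dtype=float) if coords else np.empty((0, 3))

    @property
    def parent_name(self) -> str:
        """Standard 3-letter type, mapping nonstandard residues to parents."""
        return NONSTANDARD_PARENT.get(self.name, self.name)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.parent_name, "X")

    def label(self) -> str:
        """Human-readable residue label in author numbering, e.g. 'GLY 139'."""
        return f"{self.name} {self.seq_index}{self.ins_code}".rstrip()


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self) -> list[Residue]:
        return [r for chain in self.chains.values() for r in chain]

    def protein_chains(self) -> dict[str, list[Residue]]:
        out = {}
        for cid, residues in self.chains.items():
            prot = [r for r in residues if r.molecule_class == "protein"]
            if prot:
                out[cid] = prot
        return out

    def nucleic_residues(self) -> list[Residue]:
        return [r for r in self.residues() if r.molecule_class == "nucleic"]


def _classify(res_name: str) -> str:
    if res_name in STANDARD_AMINO_ACIDS or res_name in NONSTANDARD_PARENT:
        return "protein"
    if res_name in DNA_RESIDUES:
        return "nucleic"
    return "other"


def parse_structure(pdb_text: str, structure_id: str = "structure") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first MODEL of multi-model files is read; the first alternate
    location is kept per atom; hydrogens are retained but flagged
    non-heavy.  Waters and ligands are classified ``other``.
    """
    lines = pdb_text.splitlines()
    if not any(l.startswith(("ATOM", "HETATM")) for l in lines):
        offender = next((l for l in lines if l.strip()), "<empty stream>")
        raise StructureParseError(
            f"no ATOM/HETATM records found; first line: {offender!r}"
        )
    try:
        pdb_file = PDBFile.read(io.StringIO(pdb_text))
        atoms = pdb_file.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises several error types
        raise StructureParseError(f"could not parse PDB stream: {exc}") from exc

    structure = Structure(id=structure_id)
    seen: dict[str, set[tuple[str, int, str]]] = {}
    for start in struc.get_residue_starts(atoms):
        start = int(start)
        chain_id = str(atoms.chain_id[start])
        res_id = int(atoms.res_id[start])
        ins = str(atoms.ins_code[start]).strip()
        res_name = str(atoms.res_name[start]).strip()
        mask = (
            (atoms.chain_id == atoms.chain_id[start])
            & (atoms.res_id == res_id)
            & (atoms.ins_code == atoms.ins_code[start])
            & (atoms.res_name == atoms.res_name[start])
        )
        residue = Residue(
            chain_id=chain_id,
            seq_index=res_id,
            ins_code=ins,
            name=res_name,
            molecule_class=_classify(res_name),
        )
        for name, element, coord in zip(
            atoms.atom_name[mask], atoms.element[mask], atoms.coord[mask]
        ):
            element = str(element).strip().upper()
            residue.atoms.append(
                Atom(
                    name=str(name).strip(),
                    element=element,
                    coord=np.asarray(coord, dtype=float),
                    is_heavy=element not in _HYDROGEN_ELEMENTS,
                )
            )
        keys = seen.setdefault(chain_id, set())
        if residue.key in keys:
            continue  # duplicate altloc leftovers; first occurrence wins
        keys.add(residue.key)
        structure.chains.setdefault(chain_id, []).append(residue)
    return structure


def structure_to_pdb(structure: Structure) -> str:
    """Serialize the model back to PDB text (ATOM records, author order)."""
    n_atoms = sum(len(r.atoms) for r in structure.residues())
    atoms = struc.AtomArray(n_atoms)
    i = 0
    for residues in structure.chains.values():
        for res in residues:
            for atom in res.atoms:
                atoms.chain_id[i] = res.chain_id
                atoms.res_id[i] = res.seq_index
                atoms.ins_code[i] = res.ins_code
                atoms.res_name[i] = res.name
                atoms.atom_name[i] = atom.name
                atoms.element[i] = atom.element
                atoms.coord[i] = atom.coord
                atoms.hetero[i] = res.molecule_class == "other"
                i += 1
    pdb_file = PDBFile()
    pdb_file.set_structure(atoms)
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()


def select_chain(structure: Structure, chain_id: str) -> list[Residue]:
    """Residues of one chain in author order.

    Raises :class:`ChainLookupError` listing available chains when absent.
    """
    if chain_id not in structure.chains:
        available = sorted(structure.chains)
        raise ChainLookupError(
            f"chain {chain_id!r} not found; available chains: {available}"
        )
    return list(structure.chains[chain_id])


def warn_missing_ca(residues: list[Residue]) -> list[Residue]:
    """Protein residues with a Cα; warns about and drops the rest."""
    kept = []
    for res in residues:
        if res.ca_coord is None:
            warnings.warn(f"residue {res.label()} lacks a CA atom; excluded")
        else:
            kept.append(res)
    return kept
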
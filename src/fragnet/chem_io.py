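"""Reading, standardising, indexing and writing chemical structures.

All downstream modules reference atoms and bonds by the 0-based integer
indices assigned here at parse time.  Standardisation applies the toolkit's
default aromaticity perception, removes explicit hydrogens and strips all
stereochemistry annotations, so fingerprints and fragments are computed on a
single canonical form of each molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.warning")

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Bond",
    "ChemIOError",
    "Highlight",
    "Structure",
    "parse_structure",
    "read_structures",
    "standardize",
    "write_structures",
]

#: bond order labels used throughout the package; "ar" marks aromatic bonds
_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "ar",
}


class ChemIOError(ValueError):
    """Raised for unparsable or chemically empty input."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom with its stable 0-based index."""

    index: int
    symbol: str
    aromatic: bool
    charge: int


@dataclass(frozen=True)
class Bond:
    """A bond between two atom indices; ``order`` is 1, 2, 3 or ``"ar"``."""

    index: int
    begin: int
    end: int
    order: object


class Structure:
    """An indexed, standardised molecule.

    Wraps an RDKit molecule whose atom/bond ordering is frozen; the exposed
    :class:`Atom` / :class:`Bond` tuples use the same indices as the wrapped
    molecule, and every highlight produced by the interpretation pipeline
    refers back to them.
    """

    __slots__ = ("_mol", "name")

    def __init__(self, mol: Chem.Mol, name: str = ""):
        if mol is None or mol.GetNumAtoms() == 0:
            raise ChemIOError("empty molecule")
        self._mol = mol
        self.name = name

    @property
    def mol(self) -> Chem.Mol:
        return self._mol

    @property
    def atoms(self) -> tuple[Atom, ...]:
        return tuple(
            Atom(a.GetIdx(), a.GetSymbol(), a.GetIsAromatic(), a.GetFormalCharge())
            for a in self._mol.GetAtoms()
        )

    @property
    def bonds(self) -> tuple[Bond, ...]:
        return tuple(
            Bond(
                b.GetIdx(),
                b.GetBeginAtomIdx(),
                b.GetEndAtomIdx(),
                _BOND_ORDER.get(b.GetBondType(), 1),
            )
            for b in self._mol.GetBonds()
        )

    @property
    def num_atoms(self) -> int:
        return self._mol.GetNumAtoms()

    @property
    def num_bonds(self) -> int:
        return self._mol.GetNumBonds()

    def atom_ids(self) -> frozenset[int]:
        return frozenset(range(self.num_atoms))

    def bond_ids(self) -> frozenset[int]:
        return frozenset(range(self.num_bonds))

    def to_smiles(self) -> str:
        """Canonical SMILES of the standardised structure."""
        return Chem.MolToSmiles(self._mol)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        label = self.name or self.to_smiles()
        return f"Structure({label!r}, atoms={self.num_atoms}, bonds={self.num_bonds})"


@dataclass(frozen=True)
class Highlight:
    """A set of query atom/bond ids with a causal role in the summary."""

    atom_ids: frozenset
    bond_ids: frozenset
    role: str

    ROLES = ("ACTIVATING", "DEACTIVATED", "DEACTIVATING", "UNCOVERED")

    def __post_init__(self):
        if not self.atom_ids and not self.bond_ids:
            raise ValueError("highlight may not be empty")
        if self.role not in self.ROLES:
            raise ValueError(f"unknown highlight role {self.role!r}")

    def to_dict(self) -> dict:
        return {
            "atoms": sorted(self.atom_ids),
            "bonds": sorted(self.bond_ids),
        }


def _looks_like_molblock(text: str) -> bool:
    return "\n" in text and ("V2000" in text or "M  END" in text)


def _standardize_mol(mol: Chem.Mol, strip_salts: bool = False) -> Chem.Mol:
    """Aromatize, drop explicit hydrogens and stereo, optionally strip salts."""
    if strip_salts:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            organic = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
            if not organic:
                raise ChemIOError("multi-component input has no organic component")
            # largest component by heavy atoms; ties by canonical SMILES
            mol = min(organic, key=lambda f: (-f.GetNumAtoms(), Chem.MolToSmiles(f)))
    mol = Chem.RWMol(mol)
    Chem.RemoveStereochemistry(mol)
    mol = Chem.RemoveHs(mol)
    Chem.SanitizeMol(mol)
    return mol


def parse_structure(text: str, name: str = "") -> Structure:
    """Parse a SMILES string or V2000 MOL block into a standardised Structure.

    The result is aromatized with the toolkit default model, has implicit
    hydrogens only and carries no stereochemistry.
    """
    if not text or not text.strip():
        raise ChemIOError("empty structure input")
    if _looks_like_molblock(text):
        mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ChemIOError(f"could not parse structure input: {text.splitlines()[0][:80]!r}")
    if mol.GetNumAtoms() == 0:
        raise ChemIOError("parsed structure contains no atoms")
    mol = _standardize_mol(mol)
    return Structure(mol, name=name)


def standardize(s: Structure, strip_salts: bool = False) -> Structure:
    """Re-apply standardisation; idempotent for already-standardised input."""
    mol = _standardize_mol(Chem.Mol(s.mol), strip_salts=strip_salts)
    return Structure(mol, name=s.name)


def read_structures(path: str | Path, fmt: str = "smiles") -> list[Structure]:
    """Read a SMILES file (one record per line) or an SDF into Structures.

    Records that fail parsing or standardisation are skipped with a logged
    count; an input yielding zero valid records is an error.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    structures: list[Structure] = []
    skipped = 0
    if fmt == "smiles":
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else ""
            try:
                structures.append(parse_structure(smiles, name=name))
            except ChemIOError:
                skipped += 1
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for mol in supplier:
            if mol is None:
                skipped += 1
                continue
            try:
                name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
                structures.append(Structure(_standardize_mol(mol), name=name))
            except (ChemIOError, Chem.rdchem.MolSanitizeException):
                skipped += 1
    else:
        raise ChemIOError(f"unknown structure format {fmt!r}")
    if skipped:
        logger.warning("skipped %d unreadable record(s) in %s", skipped, path)
    if not structures:
        raise ChemIOError(f"no valid structures in {path}")
    return structures


def write_structures(structures: Iterable[Structure], path: str | Path, fmt: str = "smiles") -> None:
    """Write structures as a SMILES file or an SDF."""
    path = Path(path)
    structures = list(structures)
    if fmt == "smiles":
        lines = []
        for s in structures:
            line = s.to_smiles()
            if s.name:
                line += f"\t{s.name}"
            lines.append(line)
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for s in structures:
                mol = Chem.Mol(s.mol)
                mol.SetProp("_Name", s.name or "")
                writer.write(mol)
        finally:
            writer.close()
    else:
        raise ChemIOError(f"unknown structure format {fmt!r}")


def read_labelled_tsv(path: str | Path) -> tuple[list[Structure], list[int]]:
    """Read a ``smiles<TAB>label`` TSV (label 1 = active, 0 = inactive)."""
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    structures: list[Structure] = []
    labels: list[int] = []
    skipped = 0
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            skipped += 1
            continue
        try:
            structures.append(parse_structure(parts[0], name=parts[2] if len(parts) > 2 else ""))
            labels.append(int(parts[1]))
        except (ChemIOError, ValueError):
            skipped += 1
    if skipped:
        logger.warning("skipped %d unreadable record(s) in %s", skipped, path)
    if not structures:
        raise ChemIOError(f"no valid labelled records in {path}")
    return structures, labels
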
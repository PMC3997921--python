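"""Binary structural fingerprints with atom/bond traceability.

Two schemes are provided:

* ``structural_keys`` — each bit is a SMARTS pattern from a
  :class:`KeyLibrary`; set bits carry witness substructures (atom and bond
  ids), so a bit can be projected back onto the query structure.
* ``hashed_path`` — linear heavy-atom paths hashed onto a fixed-width
  vector; individual bits are not traceable.

Both schemes guarantee the fragment-subset property: the fingerprint of any
connected, ring-complete fragment (attachment points closed with implicit
hydrogens) is a bitwise subset of its parent's fingerprint.  For the key
scheme this relies on the shipped SMARTS constraining only attributes that
are preserved when a fragment is cut out of its parent: element, aromaticity,
formal charge, ring membership (rings are never broken), bond order and
total connectivity ``X`` (an excised neighbour is replaced by an implicit
hydrogen, leaving ``X`` unchanged).  Hydrogen-count and degree primitives are
deliberately avoided.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem_io import Structure

__all__ = [
    "DEFAULT_KEYS",
    "FeatureVector",
    "FingerprintError",
    "KeyLibrary",
    "Witness",
    "fp_for_fragment",
    "fragment_to_mol",
    "hashed_path_fp",
    "structural_key_fp",
]


class FingerprintError(ValueError):
    """Raised for invalid libraries, parameters or fragments."""


# SMARTS shared between the default key library, the fragmentation unit
# detector and the rule-based mock predictors.
SMARTS_NITRO = "[NX3+](=O)[OX1-]"
SMARTS_AROMATIC_NITRO = "c-[NX3+](=O)[OX1-]"
SMARTS_AROMATIC_AMINE = "[NX3+0]-c"
SMARTS_EPOXIDE = "[OX2r3]1[#6r3][#6r3]1"
SMARTS_AZIRIDINE = "[NX3r3]1[#6r3][#6r3]1"
SMARTS_ORTHO_ACID_AMINE = "[NX3+0]-c(:c):c-[CX3](=O)[OX2]"

#: default ~40-key library: (key_id, SMARTS, description)
DEFAULT_KEYS: tuple[tuple[int, str, str], ...] = tuple(
    (i, smarts, desc)
    for i, (smarts, desc) in enumerate(
        [
            (SMARTS_NITRO, "nitro group"),
            (SMARTS_AROMATIC_NITRO, "aromatic nitro"),
            (SMARTS_AROMATIC_AMINE, "aromatic amine"),
            ("[NX3+0](-c)-[#6X4]", "aromatic amine, N-alkyl substituted"),
            ("[NX3+0](-c)(-[#6X4])-[#6X4]", "aromatic amine, N,N-dialkyl substituted"),
            (SMARTS_EPOXIDE, "epoxide"),
            (SMARTS_AZIRIDINE, "aziridine"),
            ("[#6]-[NX2]=[NX2]-[#6]", "azo"),
            ("[NX2]=[OX1]", "nitroso"),
            ("[NX3]-[NX2]=[OX1]", "N-nitroso"),
            ("[CX3](=O)[OX2]", "carboxylic acid or ester"),
            (SMARTS_ORTHO_ACID_AMINE, "aromatic amine with ortho carboxyl"),
            ("[CX4]-[F,Cl,Br,I]", "aliphatic halide"),
            ("c-[F,Cl,Br,I]", "aromatic halide"),
            ("[OX2]-[CX4]", "aliphatic hydroxyl or ether"),
            ("[OX2]-c", "phenolic/aryloxy oxygen"),
            ("c1ccccc1", "benzene ring"),
            ("n1ccccc1", "pyridine-type ring"),
            ("a1aaaa1", "aromatic 5-membered ring"),
            ("a1aaaaa1", "aromatic 6-membered ring"),
            ("c1ccc2ccccc2c1", "naphthalene system"),
            ("c1ccc2c(c1)ccc1ccccc21", "phenanthrene system (bay-region proxy)"),
            ("[CX3]=[OX1]", "carbonyl"),
            ("[NX3]-[CX3]=[OX1]", "amide"),
            ("[#16]", "sulfur"),
            ("[SX4](=O)(=O)", "sulfonyl"),
            ("[NX1]#[CX2]", "nitrile"),
            ("[NX4+]", "quaternary nitrogen"),
            ("[CX3]=[CX3]", "alkene"),
            ("[CX2]#[CX2]", "alkyne"),
            ("[CX4]-[CX4]", "alkyl chain (2)"),
            ("[CX4]-[CX4]-[CX4]", "alkyl chain (3)"),
            ("[CX4]-[CX4]-[CX4]-[CX4]", "alkyl chain (4)"),
            ("[CX4;R]", "saturated ring carbon"),
            ("[OX2;R]", "cyclic ether oxygen"),
            ("[NX3;R]", "cyclic amine nitrogen"),
            ("[#7]", "nitrogen"),
            ("[#8]", "oxygen"),
            ("[F,Cl,Br,I]", "halogen"),
            ("[#6]", "carbon"),
        ]
    )
)

Witness = tuple[frozenset, frozenset]  # (atom_ids, bond_ids)


class KeyLibrary:
    """An ordered collection of (key_id, SMARTS, description) structural keys.

    All SMARTS are compiled at load time; an unparsable pattern fails the
    whole library, never an individual structure.
    """

    def __init__(self, entries: Iterable[tuple[int, str, str]]):
        self.entries: tuple[tuple[int, str, str], ...] = tuple(entries)
        if not self.entries:
            raise FingerprintError("key library is empty")
        ids = [e[0] for e in self.entries]
        if ids != list(range(len(ids))):
            raise FingerprintError("key ids must be unique and contiguous from 0")
        self._patterns: list[Chem.Mol] = []
        for key_id, smarts, _ in self.entries:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise FingerprintError(f"unparsable SMARTS for key {key_id}: {smarts!r}")
            self._patterns.append(patt)
        self._bit_by_smarts = {e[1]: e[0] for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def pattern(self, key_id: int) -> Chem.Mol:
        return self._patterns[key_id]

    def bit_for_smarts(self, smarts: str) -> int:
        """Bit index of an exact SMARTS string present in the library."""
        try:
            return self._bit_by_smarts[smarts]
        except KeyError:
            raise FingerprintError(f"SMARTS not in library: {smarts!r}") from None

    @classmethod
    def default(cls) -> "KeyLibrary":
        return cls(DEFAULT_KEYS)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KeyLibrary":
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key_id, smarts, *rest = line.split("\t")
            entries.append((int(key_id), smarts, rest[0] if rest else ""))
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{i}\t{s}\t{d}" for i, s, d in self.entries]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length binary descriptor with optional per-bit provenance."""

    n_bits: int
    on_bits: frozenset
    scheme: str
    provenance: Optional[Mapping[int, tuple[Witness, ...]]] = None

    def __post_init__(self):
        if any(b < 0 or b >= self.n_bits for b in self.on_bits):
            raise FingerprintError("bit index out of range")
        if self.provenance is not None:
            for bit, witnesses in self.provenance.items():
                if bit not in self.on_bits or not witnesses:
                    raise FingerprintError("provenance must witness set bits only")

    def __len__(self) -> int:
        return self.n_bits

    def is_subset_of(self, other: "FeatureVector") -> bool:
        return self.on_bits <= other.on_bits

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.n_bits, dtype=np.uint8)
        for b in self.on_bits:
            arr[b] = 1
        return arr

    def to_bitstring(self) -> str:
        return "".join("1" if i in self.on_bits else "0" for i in range(self.n_bits))


def _match_bond_ids(mol: Chem.Mol, patt: Chem.Mol, match: Sequence[int]) -> frozenset:
    """Bond ids of the target mol covered by a substructure match."""
    bond_ids = set()
    for pb in patt.GetBonds():
        a = match[pb.GetBeginAtomIdx()]
        b = match[pb.GetEndAtomIdx()]
        bond = mol.GetBondBetweenAtoms(a, b)
        if bond is not None:
            bond_ids.add(bond.GetIdx())
    return frozenset(bond_ids)


def structural_key_fp(s: Structure, lib: KeyLibrary) -> FeatureVector:
    """Match every library key against the structure; provenance holds all
    match witnesses in the structure's own atom/bond ids."""
    return _structural_key_fp_mol(s.mol, lib)


def _structural_key_fp_mol(
    mol: Chem.Mol, lib: KeyLibrary, atom_map: Optional[Sequence[int]] = None,
    bond_map: Optional[Mapping[tuple, int]] = None,
) -> FeatureVector:
    on_bits = set()
    provenance: dict[int, tuple[Witness, ...]] = {}
    for key_id, _, _ in lib.entries:
        patt = lib.pattern(key_id)
        matches = mol.GetSubstructMatches(patt, uniquify=True)
        if not matches:
            continue
        on_bits.add(key_id)
        witnesses = []
        for match in matches:
            atoms = frozenset(match)
            bonds = _match_bond_ids(mol, patt, match)
            if atom_map is not None:
                atoms = frozenset(atom_map[a] for a in atoms)
                bonds = frozenset(bond_map[b] for b in bonds) if bond_map else frozenset()
            witnesses.append((atoms, bonds))
        provenance[key_id] = tuple(witnesses)
    return FeatureVector(
        n_bits=len(lib), on_bits=frozenset(on_bits), scheme="structural_keys",
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# hashed linear-path fingerprint


def _atom_label(atom: Chem.Atom) -> str:
    label = atom.GetSymbol()
    if atom.GetIsAromatic():
        label += "a"
    charge = atom.GetFormalCharge()
    if charge:
        label += f"{charge:+d}"
    return label


_BOND_LABEL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def _iter_path_strings(mol: Chem.Mol, max_depth: int):
    """Canonical label strings of all simple linear paths up to max_depth bonds."""
    atom_labels = [_atom_label(a) for a in mol.GetAtoms()]
    neighbours = [
        [(b.GetOtherAtomIdx(a.GetIdx()), _BOND_LABEL.get(b.GetBondType(), "-"))
         for b in a.GetBonds()]
        for a in mol.GetAtoms()
    ]
    seen: set[str] = set()

    def grow(path: list[int], labels: list[str]):
        forward = "".join(labels)
        backward = "".join(reversed(labels))
        seen.add(min(forward, backward))
        if (len(path) - 1) >= max_depth:
            return
        last = path[-1]
        for nbr, blabel in neighbours[last]:
            if nbr in path:
                continue
            grow(path + [nbr], labels + [blabel, atom_labels[nbr]])

    for start in range(mol.GetNumAtoms()):
        grow([start], [atom_labels[start]])
    return seen


def hashed_path_fp(s: Structure, max_depth: int = 6, n_bits: int = 1024) -> FeatureVector:
    """Hash canonical linear heavy-atom paths onto an ``n_bits``-wide vector.

    Bits are not individually traceable, so no provenance is attached.
    """
    return _hashed_path_fp_mol(s.mol, max_depth, n_bits)


def _hashed_path_fp_mol(mol: Chem.Mol, max_depth: int, n_bits: int) -> FeatureVector:
    if max_depth < 1:
        raise FingerprintError("max_depth must be >= 1")
    if n_bits < 2 or n_bits & (n_bits - 1):
        raise FingerprintError("n_bits must be a power of two")
    mask = n_bits - 1
    on_bits = frozenset(
        zlib.crc32(p.encode()) & mask for p in _iter_path_strings(mol, max_depth)
    )
    return FeatureVector(n_bits=n_bits, on_bits=on_bits, scheme="hashed_path")


# ---------------------------------------------------------------------------
# fragment extraction and fingerprinting


def fragment_to_mol(
    parent: Structure, atom_ids: frozenset, bond_ids: frozenset
) -> tuple[Chem.Mol, dict[int, int]]:
    """Cut a fragment out of its parent as a standalone molecule.

    Atom aromaticity flags, charges and bond orders are copied verbatim and
    no aromaticity re-perception is run, so ring fragments stay aromatic
    exactly as in the parent (rings are never broken by the fragmentation
    module).  Attachment points are closed with implicit hydrogens.

    Returns the fragment molecule and a mapping ``parent atom id -> fragment
    atom id``.
    """
    pmol = parent.mol
    n = pmol.GetNumAtoms()
    if any(a < 0 or a >= n for a in atom_ids):
        raise FingerprintError("fragment atom id outside parent")
    em = Chem.RWMol()
    old_to_new: dict[int, int] = {}
    for old in sorted(atom_ids):
        src = pmol.GetAtomWithIdx(old)
        atom = Chem.Atom(src.GetSymbol())
        atom.SetIsAromatic(src.GetIsAromatic())
        atom.SetFormalCharge(src.GetFormalCharge())
        atom.SetNoImplicit(False)
        old_to_new[old] = em.AddAtom(atom)
    for bid in sorted(bond_ids):
        b = pmol.GetBondWithIdx(bid)
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i not in old_to_new or j not in old_to_new:
            raise FingerprintError("fragment bond endpoint outside fragment atoms")
        em.AddBond(old_to_new[i], old_to_new[j], b.GetBondType())
    mol = em.GetMol()
    try:
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
    except Exception as exc:  # pragma: no cover - defensive
        raise FingerprintError(f"fragment is not chemically valid standalone: {exc}")
    # aromatic atoms outside any ring mean a ring was broken upstream
    for atom in mol.GetAtoms():
        if atom.GetIsAromatic() and not atom.IsInRing():
            raise FingerprintError(
                "fragment breaks an aromatic ring and is invalid standalone"
            )
    return mol, old_to_new


def _check_fragment(parent: Structure, atom_ids: frozenset, bond_ids: frozenset) -> None:
    if not atom_ids:
        raise FingerprintError("empty fragment")
    # connectivity over the fragment's own bonds
    adj: dict[int, set] = {a: set() for a in atom_ids}
    pmol = parent.mol
    for bid in bond_ids:
        b = pmol.GetBondWithIdx(bid)
        adj[b.GetBeginAtomIdx()].add(b.GetEndAtomIdx())
        adj[b.GetEndAtomIdx()].add(b.GetBeginAtomIdx())
    seen = set()
    stack = [next(iter(atom_ids))]
    while stack:
        a = stack.pop()
        if a in seen:
            continue
        seen.add(a)
        stack.extend(adj[a] - seen)
    if seen != set(atom_ids):
        raise FingerprintError("fragment is not connected")


def fp_for_fragment(
    parent: Structure,
    frag,
    scheme: str = "structural_keys",
    *,
    library: Optional[KeyLibrary] = None,
    max_depth: int = 6,
    n_bits: int = 1024,
) -> FeatureVector:
    """Fingerprint a fragment as a standalone molecule.

    ``frag`` is any object with ``atom_ids`` and ``bond_ids`` attributes (or a
    ``(atom_ids, bond_ids)`` pair).  Every set bit is guaranteed to also be
    set in the parent's fingerprint under the same scheme and parameters;
    structural-key provenance is mapped back to parent atom/bond ids.
    """
    if hasattr(frag, "atom_ids"):
        atom_ids, bond_ids = frozenset(frag.atom_ids), frozenset(frag.bond_ids)
    else:
        atom_ids, bond_ids = frozenset(frag[0]), frozenset(frag[1])
    _check_fragment(parent, atom_ids, bond_ids)
    mol, old_to_new = fragment_to_mol(parent, atom_ids, bond_ids)
    if scheme == "structural_keys":
        lib = library or KeyLibrary.default()
        new_to_old = {v: k for k, v in old_to_new.items()}
        # map fragment bond ids back to parent bond ids
        frag_bond_to_parent: dict[int, int] = {}
        for b in mol.GetBonds():
            pi = new_to_old[b.GetBeginAtomIdx()]
            pj = new_to_old[b.GetEndAtomIdx()]
            pbond = parent.mol.GetBondBetweenAtoms(pi, pj)
            frag_bond_to_parent[b.GetIdx()] = pbond.GetIdx()
        return _structural_key_fp_mol(
            mol, lib, atom_map=new_to_old, bond_map=frag_bond_to_parent
        )
    if scheme == "hashed_path":
        return _hashed_path_fp_mol(mol, max_depth, n_bits)
    raise FingerprintError(f"unknown fingerprint scheme {scheme!r}")
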
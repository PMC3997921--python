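"""Reduced-graph construction and connected fragment enumeration.

A molecule is first condensed into a reduced graph whose nodes are
structural units — whole rings, functional groups and single-atom linkers —
and all connected subsets of units are then expanded back into molecular
fragments.  Because rings are complete units, no fragment ever contains a
partial ring, which keeps every fragment chemically valid as a standalone
molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from .chem_io import Structure
from .fingerprints import (
    SMARTS_NITRO,
    fragment_to_mol,
)

__all__ = [
    "DEFAULT_UNIT_SMARTS",
    "Fragment",
    "FragmentationError",
    "ReducedGraph",
    "Unit",
    "build_reduced_graph",
    "enumerate_fragments",
    "expand_fragment",
]


class FragmentationError(ValueError):
    """Raised for invalid unit subsets or oversized reduced graphs."""


#: functional-group unit SMARTS, matched in order after ring perception;
#: longest match wins, ties by lowest atom id.  Ring atoms are never claimed.
DEFAULT_UNIT_SMARTS: tuple[tuple[str, str], ...] = (
    ("nitro", SMARTS_NITRO),
    ("n_nitroso", "[NX3]-[NX2]=[OX1]"),
    ("nitroso", "[NX2]=[OX1]"),
    ("azo", "[NX2]=[NX2]"),
    ("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    ("carbonyl", "[CX3]=[OX1]"),
    ("amine", "[NX3+0]"),
    ("hydroxyl", "[OX2H]"),
    ("halogen", "[F,Cl,Br,I]"),
)


@dataclass(frozen=True)
class Unit:
    """A structural unit of the reduced graph."""

    unit_id: int
    kind: str  # ring | functional_group | linker
    atom_ids: frozenset
    bond_ids: frozenset
    label: str = ""


@dataclass
class ReducedGraph:
    """Units plus adjacency (shared atom or connecting bond) over a parent."""

    units: tuple[Unit, ...]
    edges: frozenset  # frozenset({unit_id, unit_id})
    parent: Structure

    def neighbours(self, unit_id: int) -> frozenset:
        out = set()
        for edge in self.edges:
            if unit_id in edge:
                out.update(edge - {unit_id})
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class Fragment:
    """A connected, ring-complete subset of a parent structure."""

    atom_ids: frozenset
    bond_ids: frozenset
    unit_ids: frozenset
    key: str
    parent: Structure = field(compare=False, hash=False)

    @property
    def num_atoms(self) -> int:
        return len(self.atom_ids)


def load_unit_smarts(path: str | Path) -> tuple[tuple[str, str], ...]:
    """Load ``name<TAB>SMARTS`` unit definitions from a file."""
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, smarts = line.split("\t")[:2]
        entries.append((name, smarts))
    if not entries:
        raise FragmentationError(f"no unit SMARTS in {path}")
    return tuple(entries)


def build_reduced_graph(
    s: Structure, unit_smarts: Optional[Sequence[tuple[str, str]]] = None
) -> ReducedGraph:
    """Condense a structure into ring, functional-group and linker units.

    Precedence is ring > functional group > linker: every SSSR ring becomes
    one unit (fused rings are separate units joined through their shared
    atoms), functional groups are claimed greedily from the non-ring atoms,
    and whatever remains becomes single-atom linker units.
    """
    unit_smarts = tuple(unit_smarts) if unit_smarts is not None else DEFAULT_UNIT_SMARTS
    mol = s.mol
    ring_info = mol.GetRingInfo()
    units: list[Unit] = []

    ring_atom_ids: set[int] = set()
    for atom_ring, bond_ring in zip(ring_info.AtomRings(), ring_info.BondRings()):
        units.append(
            Unit(
                unit_id=len(units),
                kind="ring",
                atom_ids=frozenset(atom_ring),
                bond_ids=frozenset(bond_ring),
                label="ring",
            )
        )
        ring_atom_ids.update(atom_ring)

    # candidate functional-group matches on non-ring atoms
    candidates = []
    for order, (name, smarts) in enumerate(unit_smarts):
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise FragmentationError(f"unparsable unit SMARTS {name!r}: {smarts!r}")
        for match in mol.GetSubstructMatches(patt, uniquify=True):
            claim = frozenset(a for a in match if a not in ring_atom_ids)
            if claim:
                candidates.append((-len(claim), min(claim), order, name, claim))
    claimed: set[int] = set(ring_atom_ids)
    for _, _, _, name, claim in sorted(candidates):
        if claim & claimed:
            continue
        bond_ids = frozenset(
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetBeginAtomIdx() in claim and b.GetEndAtomIdx() in claim
        )
        units.append(
            Unit(
                unit_id=len(units),
                kind="functional_group",
                atom_ids=claim,
                bond_ids=bond_ids,
                label=name,
            )
        )
        claimed.update(claim)

    for atom in mol.GetAtoms():
        if atom.GetIdx() not in claimed:
            units.append(
                Unit(
                    unit_id=len(units),
                    kind="linker",
                    atom_ids=frozenset({atom.GetIdx()}),
                    bond_ids=frozenset(),
                    label=atom.GetSymbol(),
                )
            )

    # adjacency: units sharing an atom, or joined by a parent bond
    atom_to_units: dict[int, set] = {}
    for unit in units:
        for a in unit.atom_ids:
            atom_to_units.setdefault(a, set()).add(unit.unit_id)
    edges: set[frozenset] = set()
    for members in atom_to_units.values():
        members = sorted(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.add(frozenset({members[i], members[j]}))
    for bond in mol.GetBonds():
        for u in atom_to_units[bond.GetBeginAtomIdx()]:
            for v in atom_to_units[bond.GetEndAtomIdx()]:
                if u != v:
                    edges.add(frozenset({u, v}))
    return ReducedGraph(units=tuple(units), edges=frozenset(edges), parent=s)


def _unit_subset_connected(rg: ReducedGraph, unit_subset: frozenset) -> bool:
    if not unit_subset:
        return False
    seen = set()
    stack = [next(iter(unit_subset))]
    while stack:
        u = stack.pop()
        if u in seen:
            continue
        seen.add(u)
        stack.extend((rg.neighbours(u) & unit_subset) - seen)
    return seen == set(unit_subset)


def expand_fragment(rg: ReducedGraph, unit_subset: Iterable[int]) -> Fragment:
    """Expand a connected unit subset back to a molecular Fragment.

    Atom ids are the union of unit atoms; bond ids are all parent bonds
    internal to that atom set; the key is the fragment's canonical SMILES.
    """
    unit_subset = frozenset(unit_subset)
    if not _unit_subset_connected(rg, unit_subset):
        raise FragmentationError(f"unit subset {sorted(unit_subset)} is not connected")
    atom_ids = frozenset().union(*(rg.units[u].atom_ids for u in unit_subset))
    mol = rg.parent.mol
    bond_ids = frozenset(
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBeginAtomIdx() in atom_ids and b.GetEndAtomIdx() in atom_ids
    )
    frag_mol, _ = fragment_to_mol(rg.parent, atom_ids, bond_ids)
    key = Chem.MolToSmiles(frag_mol)
    return Fragment(
        atom_ids=atom_ids,
        bond_ids=bond_ids,
        unit_ids=unit_subset,
        key=key,
        parent=rg.parent,
    )


def enumerate_fragments(
    rg: ReducedGraph, max_depth: Optional[int] = None, unit_cap: int = 25
) -> list[Fragment]:
    """All connected unit subsets of size <= max_depth, expanded to fragments.

    ``max_depth=None`` enumerates every connected subset (guarded by
    ``unit_cap``).  The full structure is always included as the root
    fragment, and fragments are deduplicated by atom-id set.
    """
    m = len(rg.units)
    if max_depth is None and m > unit_cap:
        raise FragmentationError(
            f"{m} units exceed the cap of {unit_cap} for unlimited enumeration; "
            "set max_depth to bound the fragment size"
        )
    if max_depth is not None and max_depth < 1:
        raise FragmentationError("max_depth must be >= 1 or None")
    limit = m if max_depth is None else min(max_depth, m)

    all_ids = frozenset(u.unit_id for u in rg.units)
    subsets: set[frozenset] = set()
    frontier: set[frozenset] = {frozenset({u}) for u in all_ids}
    size = 1
    while frontier and size <= limit:
        subsets.update(frontier)
        nxt: set[frozenset] = set()
        if size < limit:
            for sub in frontier:
                for u in sub:
                    for v in rg.neighbours(u):
                        if v not in sub:
                            nxt.add(sub | {v})
        frontier = nxt
        size += 1
    if _unit_subset_connected(rg, all_ids):
        subsets.add(all_ids)  # the query itself is always a node

    fragments: dict[frozenset, Fragment] = {}
    for sub in subsets:
        frag = expand_fragment(rg, sub)
        fragments.setdefault(frag.atom_ids, frag)
    return sorted(
        fragments.values(), key=lambda f: (len(f.atom_ids), sorted(f.atom_ids))
    )
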
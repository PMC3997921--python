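"""Fragment-dictionary applicability domain.

The training set is fragmented and every fragment key occurring in at least
``min_occurrence`` training structures (structure-level support: duplicates
within one molecule count once) enters the dictionary.  A query is in domain
iff its own fragments, looked up in the dictionary, jointly cover every atom
and bond; anything left uncovered puts it out of domain and is returned as a
highlight.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .chem_io import Highlight, Structure
from .config import RunConfig
from .fragmentation import build_reduced_graph, enumerate_fragments, load_unit_smarts

__all__ = ["DomainError", "FragmentDictionary", "build_dictionary", "in_domain"]

logger = logging.getLogger(__name__)


class DomainError(ValueError):
    pass


@dataclass
class FragmentDictionary:
    """Fragment-key counts over a training set, thresholded at build time."""

    counts: dict
    min_occurrence: int
    config_hash: str = ""

    def __contains__(self, key: str) -> bool:
        return key in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"# min_occurrence={self.min_occurrence}\tconfig={self.config_hash}"]
        for key in sorted(self.counts):
            lines.append(f"{key}\t{self.counts[key]}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FragmentDictionary":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("#"):
            raise DomainError(f"missing dictionary header in {path}")
        header = dict(
            part.split("=", 1) for part in lines[0].lstrip("# ").split("\t") if "=" in part
        )
        counts = {}
        for line in lines[1:]:
            if not line.strip():
                continue
            key, count = line.split("\t")
            counts[key] = int(count)
        return cls(
            counts=counts,
            min_occurrence=int(header.get("min_occurrence", 1)),
            config_hash=header.get("config", ""),
        )


def _fragment_keys(s: Structure, config: RunConfig) -> tuple[set, list]:
    unit_smarts = (
        load_unit_smarts(config.fragmentation.unit_smarts_file)
        if config.fragmentation.unit_smarts_file
        else None
    )
    rg = build_reduced_graph(s, unit_smarts)
    frags = enumerate_fragments(
        rg,
        max_depth=config.fragmentation.max_depth,
        unit_cap=config.fragmentation.unit_cap,
    )
    return {f.key for f in frags}, frags


def build_dictionary(
    training: Sequence[Structure],
    min_occurrence: int = 4,
    config: Optional[RunConfig] = None,
) -> FragmentDictionary:
    """Fragment every training structure and keep keys with enough support."""
    if not training:
        raise DomainError("training set is empty")
    config = config or RunConfig()
    counter: Counter = Counter()
    for s in training:
        keys, _ = _fragment_keys(s, config)
        counter.update(keys)  # per-structure set: one count per structure
    counts = {k: c for k, c in counter.items() if c >= min_occurrence}
    return FragmentDictionary(
        counts=counts,
        min_occurrence=min_occurrence,
        config_hash=config.fingerprint_hash(),
    )


def in_domain(
    query: Structure,
    dictionary: FragmentDictionary,
    config: Optional[RunConfig] = None,
) -> tuple[bool, Optional[Highlight]]:
    """Check dictionary coverage of a query's atoms and bonds.

    Returns ``(True, None)`` when every atom and bond of the query is covered
    by some dictionary fragment, else ``(False, uncovered_highlight)``.
    """
    config = config or RunConfig()
    _, frags = _fragment_keys(query, config)
    unmatched_atoms = set(query.atom_ids())
    unmatched_bonds = set(query.bond_ids())
    for frag in frags:
        if frag.key in dictionary:
            unmatched_atoms -= frag.atom_ids
            unmatched_bonds -= frag.bond_ids
    if not unmatched_atoms and not unmatched_bonds:
        return True, None
    return False, Highlight(
        frozenset(unmatched_atoms), frozenset(unmatched_bonds), "UNCOVERED"
    )
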
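"""Feature-vector combination enumeration and its counting laws.

The number of combinations without repetition of ``k`` items from ``n`` is
``n! / (k! (n-k)!)``; summing over all ``k`` (including the empty selection)
gives ``2**n`` enumerable combinations.  The empty combination is counted but
never emitted as a node — a feature vector of all zeros has no structural
meaning — so exhaustive enumeration of ``n`` set bits yields ``2**n - 1``
combinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

from .fingerprints import FeatureVector

__all__ = [
    "BitCombination",
    "EnumerationError",
    "combinations_count",
    "enumerate_bitsets",
    "total_combinations",
]


class EnumerationError(ValueError):
    """Raised for invalid counts or oversized exhaustive enumerations."""


@dataclass(frozen=True, order=True)
class BitCombination:
    """A sorted subset of the set bits of a source feature vector."""

    member_bits: tuple

    def __post_init__(self):
        bits = tuple(sorted(set(self.member_bits)))
        if bits != tuple(self.member_bits):
            object.__setattr__(self, "member_bits", bits)

    @property
    def k(self) -> int:
        return len(self.member_bits)

    @property
    def bit_set(self) -> frozenset:
        return frozenset(self.member_bits)


def combinations_count(n: int, k: int) -> int:
    """Exact ``n choose k`` as an arbitrary-precision integer."""
    if n < 0 or k < 0:
        raise EnumerationError("n and k must be non-negative")
    if k > n:
        raise EnumerationError(f"k={k} exceeds n={n}")
    return math.comb(n, k)


def total_combinations(n: int) -> int:
    """Total enumerable combinations ``2**n``, including the empty one."""
    if n < 0:
        raise EnumerationError("n must be non-negative")
    return 1 << n


def enumerate_bitsets(
    fv: FeatureVector,
    prune_level: Optional[int] = None,
    max_bits: int = 20,
) -> list[BitCombination]:
    """Enumerate combinations of the set bits of ``fv``.

    Returns every combination with ``1 <= k <= min(prune_level, n)`` in
    lexicographic order, always followed by the full ``k = n`` combination
    (the original query), which is appended even when pruning would exclude
    it.  Exhaustive enumeration (``prune_level=None``) of more than
    ``max_bits`` set bits is refused.
    """
    bits = tuple(sorted(fv.on_bits))
    n = len(bits)
    if n == 0:
        raise EnumerationError("feature vector has no set bits")
    if prune_level is not None and prune_level < 1:
        raise EnumerationError("prune_level must be >= 1 or None")
    if prune_level is None and n > max_bits:
        raise EnumerationError(
            f"{n} set bits exceed the exhaustive-enumeration cap of {max_bits}; "
            "set a prune_level"
        )
    limit = n if prune_level is None else min(prune_level, n)
    out = [
        BitCombination(combo)
        for k in range(1, limit + 1)
        for combo in combinations(bits, k)
    ]
    if limit < n:
        out.append(BitCombination(bits))  # the query itself is always a node
    return out
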
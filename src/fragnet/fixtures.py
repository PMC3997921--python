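"""Deterministic toy structures, mock predictors and example networks.

Everything here is a pure function of its seed so the full pipeline can be
exercised without external data: a seeded molecule generator plants known
alerts (nitro, epoxide, aziridine, aromatic amine) and a known deactivating
context (ortho carboxyl on an aromatic amine), a rule-based mock honours the
predictor contract through structural-key bits, and a seeded generator
produces random subset-lattice networks for fuzzing the assessment rules.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

from rdkit import Chem

from .chem_io import Structure, parse_structure
from .enumeration import BitCombination
from .fingerprints import (
    SMARTS_AROMATIC_AMINE,
    SMARTS_AZIRIDINE,
    SMARTS_EPOXIDE,
    SMARTS_NITRO,
    SMARTS_ORTHO_ACID_AMINE,
    FeatureVector,
    KeyLibrary,
    structural_key_fp,
)
from .network import (
    ACTIVE,
    INACTIVE,
    FeatureNetwork,
    Prediction,
    network_from_indexed,
)

__all__ = [
    "RuleOracle",
    "ToyLibrary",
    "default_oracle",
    "golden_network_fixture",
    "make_random_network",
    "make_toy_library",
]


class FixtureError(ValueError):
    pass


class RuleOracle:
    """A rule-defined mock predictor reading structural-key bits.

    Predicts active iff at least one alert bit is set and no paired
    deactivating-context bit is set for that alert.  Alerts and contexts are
    given as SMARTS strings that must be present verbatim in the key library,
    so the oracle itself only ever sees feature vectors.
    """

    def __init__(
        self,
        alerts: Sequence[str],
        deactivators: Sequence[tuple[str, str]] = (),
        library: Optional[KeyLibrary] = None,
    ):
        self.library = library or KeyLibrary.default()
        self.alert_bits = {s: self.library.bit_for_smarts(s) for s in alerts}
        self.deactivator_bits: dict[int, list[int]] = {}
        for alert_smarts, context_smarts in deactivators:
            abit = self.library.bit_for_smarts(alert_smarts)
            cbit = self.library.bit_for_smarts(context_smarts)
            self.deactivator_bits.setdefault(abit, []).append(cbit)

    def predict(self, feature_vector: FeatureVector) -> Prediction:
        bits = feature_vector.on_bits
        for abit in self.alert_bits.values():
            if abit in bits and not any(
                cbit in bits for cbit in self.deactivator_bits.get(abit, [])
            ):
                return Prediction(ACTIVE, confidence=1.0)
        return Prediction(INACTIVE, confidence=1.0)


def default_oracle(library: Optional[KeyLibrary] = None) -> RuleOracle:
    """The standard mock: four alerts, amine deactivated by ortho carboxyl."""
    return RuleOracle(
        alerts=[SMARTS_NITRO, SMARTS_EPOXIDE, SMARTS_AZIRIDINE, SMARTS_AROMATIC_AMINE],
        deactivators=[(SMARTS_AROMATIC_AMINE, SMARTS_ORTHO_ACID_AMINE)],
        library=library,
    )


# ---------------------------------------------------------------------------
# toy molecule library


@dataclass
class ToyLibrary:
    """Generated structures with oracle labels and planted ground truth.

    ``alert_atoms[i]`` holds one frozenset of query atom ids per
    non-deactivated planted alert in structure ``i`` — the atoms an exact
    interpretation should mark ACTIVATING (alert match atoms, with any
    matched ring atom expanded to its full ring).  ``has_deactivation[i]``
    flags structures carrying the ortho-carboxyl-deactivated amine motif.
    """

    structures: list[Structure]
    labels: list[int]
    alert_atoms: list[list[frozenset]]
    has_deactivation: list[bool]

    def __len__(self) -> int:
        return len(self.structures)


_BENIGN_SUBS = ["C", "CC", "Cl", "O", "OC"]
_SCAFFOLDS = ["c1ccccc1", "c1ccncc1"]


def _aromatic_with(rng: random.Random, first: str, extra_benign: bool) -> str:
    """A benzene or pyridine carrying ``first`` and optionally a benign sub."""
    scaffold = rng.choice(_SCAFFOLDS)
    if scaffold == "c1ccccc1":
        if extra_benign:
            other = rng.choice(_BENIGN_SUBS)
            return f"c1ccc({first})cc1{''}" if rng.random() < 0.5 else f"c1cc({other})ccc1{first}"
        return f"c1ccccc1{first}"
    # pyridine: substitute at the 4-position only, keeping templates simple
    return f"c1cc({first})ccn1"


def _chain(rng: random.Random) -> str:
    return rng.choice(["CC", "CCC", "CCCC", "CC(C)C", "CCOC"])


def make_toy_library(n: int = 40, seed: int = 1) -> ToyLibrary:
    """Deterministic toy molecule library with planted structural alerts.

    Ten round-robin template classes: four benign, five carrying exactly one
    alert (nitro, epoxide, aziridine, aromatic amine, amine-with-para-acid)
    and one deactivated case (aromatic amine with an ortho carboxylic acid).
    Labels come from the rule oracle, keeping labels and ground truth
    consistent by construction.
    """
    if n < 10:
        raise FixtureError("n must be at least 10 to cover every motif class")
    rng = random.Random(seed)
    oracle = default_oracle()
    library = oracle.library

    def benign_aromatic(rng):
        return _aromatic_with(rng, rng.choice(_BENIGN_SUBS), extra_benign=rng.random() < 0.5)

    def benign_chain(rng):
        return _chain(rng)

    def benign_ring(rng):
        return rng.choice(["C1CCCCC1", "C1CCOC1", "C1CCCC1"]) + rng.choice(["", "C", "CC"])

    def benign_two_ring(rng):
        return "c1ccc(" + rng.choice(["C", "CC"]) + "c2ccccc2)cc1"

    def nitro_aromatic(rng):
        return _aromatic_with(rng, "[N+](=O)[O-]", extra_benign=rng.random() < 0.5)

    def epoxide_chain(rng):
        return _chain(rng) + "C8CO8"

    def aziridine_case(rng):
        base = rng.choice(["CC", "CCC", "c1ccccc1C"])
        return base + "N8CC8"

    def amine_aromatic(rng):
        return _aromatic_with(rng, "N", extra_benign=rng.random() < 0.5)

    def amine_para_acid(rng):
        return "Nc1ccc(C(=O)O)cc1"  # para carboxyl does not deactivate

    def amine_ortho_acid(rng):
        return rng.choice(["Nc1ccccc1C(=O)O", "Nc1cccc(C)c1C(=O)O"])

    templates = [
        benign_aromatic,
        nitro_aromatic,
        benign_chain,
        epoxide_chain,
        benign_ring,
        aziridine_case,
        benign_two_ring,
        amine_aromatic,
        amine_ortho_acid,
        amine_para_acid,
    ]

    structures: list[Structure] = []
    labels: list[int] = []
    alert_atoms: list[list[frozenset]] = []
    has_deactivation: list[bool] = []
    for i in range(n):
        smiles = templates[i % len(templates)](rng)
        s = parse_structure(smiles, name=f"toy-{i}")
        fv = structural_key_fp(s, library)
        pred = oracle.predict(fv)
        structures.append(s)
        labels.append(1 if pred.is_active else 0)
        alert_atoms.append(_ground_truth_alerts(s, oracle))
        has_deactivation.append(
            library.bit_for_smarts(SMARTS_ORTHO_ACID_AMINE) in fv.on_bits
        )
    return ToyLibrary(structures, labels, alert_atoms, has_deactivation)


def _ground_truth_alerts(s: Structure, oracle: RuleOracle) -> list[frozenset]:
    """Atom sets an exact interpretation should mark ACTIVATING.

    Each non-deactivated alert match is expanded so that any matched ring
    atom pulls in its whole ring — the interpretation cannot highlight less
    than a full structural unit.
    """
    mol = s.mol
    ring_info = mol.GetRingInfo()
    out: list[frozenset] = []
    for alert_smarts, _ in oracle.alert_bits.items():
        patt = Chem.MolFromSmarts(alert_smarts)
        contexts = [
            ctx for alert2, ctx in _oracle_deactivator_smarts(oracle) if alert2 == alert_smarts
        ]
        context_atoms: set[int] = set()
        for ctx in contexts:
            for m in mol.GetSubstructMatches(Chem.MolFromSmarts(ctx)):
                context_atoms.update(m)
        for match in mol.GetSubstructMatches(patt, uniquify=True):
            if context_atoms and set(match) <= context_atoms:
                continue  # this alert occurrence is deactivated
            atoms = set(match)
            for a in match:
                if mol.GetAtomWithIdx(a).IsInRing():
                    for ring in ring_info.AtomRings():
                        if a in ring:
                            atoms.update(ring)
            out.append(frozenset(atoms))
    return sorted(set(out), key=sorted)


def _oracle_deactivator_smarts(oracle: RuleOracle) -> list[tuple[str, str]]:
    smarts_by_bit = {bit: s for s, bit in oracle.alert_bits.items()}
    entries = {e[0]: e[1] for e in oracle.library.entries}
    return [
        (smarts_by_bit[abit], entries[cbit])
        for abit, cbits in oracle.deactivator_bits.items()
        for cbit in cbits
        if abit in smarts_by_bit
    ]


# ---------------------------------------------------------------------------
# random networks


def make_random_network(n_nodes: int, seed: int) -> FeatureNetwork:
    """A random subset-lattice network with random predictions.

    Payloads are distinct random bit sets under a full-universe root, so all
    feature-network invariants hold by construction; deterministic per seed.
    """
    if not 1 <= n_nodes <= 50:
        raise FixtureError("n_nodes must lie in 1..50")
    rng = random.Random(seed)
    universe = tuple(range(10))
    payloads: set[frozenset] = {frozenset(universe)}
    while len(payloads) < n_nodes:
        size = rng.randint(1, len(universe) - 1)
        payloads.add(frozenset(rng.sample(universe, size)))
    indexed = {
        i: BitCombination(tuple(sorted(p)))
        for i, p in enumerate(sorted(payloads, key=lambda p: (-len(p), sorted(p))))
    }
    predictions = {
        i: Prediction(
            ACTIVE if rng.random() < 0.5 else INACTIVE,
            confidence=round(rng.random(), 3),
        )
        for i in indexed
    }
    return network_from_indexed(indexed, predictions)


# ---------------------------------------------------------------------------
# the 11-node worked example


def golden_network_fixture() -> FeatureNetwork:
    """The 11-node example network exercising every assessment type.

    The topology is a reconstruction satisfying the documented constraints:
    edges (child -> parent) 6-3, 7-3, 3-1, 1-0, 2-0, 4-2, 5-2, 8-4, 8-5,
    9-5, 10-8; nodes 0, 1, 3, 6, 8, 9, 10 predicted active and 2, 4, 5, 7
    inactive.  Payload bit sets are synthetic and chosen so that the
    minimal-superset parent relation reproduces exactly those edges.
    """
    payload_sets = {
        0: frozenset(range(10)),
        1: frozenset({0, 1, 8, 9}),
        2: frozenset({2, 3, 4, 5, 6, 7}),
        3: frozenset({0, 1, 8}),
        4: frozenset({2, 4, 6}),
        5: frozenset({2, 3, 4, 5}),
        6: frozenset({0}),
        7: frozenset({1}),
        8: frozenset({2, 4}),
        9: frozenset({3}),
        10: frozenset({2}),
    }
    active = {0, 1, 3, 6, 8, 9, 10}
    indexed = {i: BitCombination(tuple(sorted(p))) for i, p in payload_sets.items()}
    predictions = {
        i: Prediction(ACTIVE if i in active else INACTIVE, confidence=0.9)
        for i in indexed
    }
    return network_from_indexed(indexed, predictions)
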
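"""Feature networks: DAGs of enumerated sub-features ordered by inclusion.

Nodes hold a payload (a :class:`~fragnet.enumeration.BitCombination` or a
:class:`~fragnet.fragmentation.Fragment`), an optional feature vector,
prediction and assessment.  Parenthood is the minimal-strict-superset
relation over payload sets, which handles pruned level gaps: when
intermediate combination sizes are missing, the smallest enumerated
supersets adopt the orphans directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .enumeration import BitCombination
from .fragmentation import Fragment

__all__ = [
    "Assessment",
    "FeatureNetwork",
    "NetworkError",
    "NetworkNode",
    "Prediction",
    "build_bitset_network",
    "build_fragment_network",
    "export_network",
    "network_from_json",
]

ACTIVE = "active"
INACTIVE = "inactive"


class NetworkError(ValueError):
    """Raised for malformed node collections or formats."""


class Assessment(str, Enum):
    ACTIVATING = "ACTIVATING"
    DEACTIVATED = "DEACTIVATED"
    DEACTIVATING = "DEACTIVATING"
    NEGATED = "NEGATED"
    ACTIVITY_IDENTIFIED = "ACTIVITY_IDENTIFIED"
    IGNORE = "IGNORE"


#: Graphviz colours per assessment type
DOT_COLOURS = {
    Assessment.ACTIVATING: "red",
    Assessment.DEACTIVATING: "green",
    Assessment.DEACTIVATED: "orange",
    Assessment.NEGATED: "purple",
    Assessment.ACTIVITY_IDENTIFIED: "pink",
    Assessment.IGNORE: "blue",
    None: "gray",
}


@dataclass(frozen=True)
class Prediction:
    label: str  # "active" | "inactive"
    confidence: Optional[float] = None

    def __post_init__(self):
        if self.label not in (ACTIVE, INACTIVE):
            raise NetworkError(f"unknown prediction label {self.label!r}")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise NetworkError("confidence must lie in [0, 1]")

    @property
    def is_active(self) -> bool:
        return self.label == ACTIVE


def payload_set(payload) -> frozenset:
    """The inclusion-ordering set of a node payload."""
    if isinstance(payload, Fragment):
        return payload.atom_ids
    if isinstance(payload, BitCombination):
        return payload.bit_set
    if isinstance(payload, frozenset):
        return payload
    raise NetworkError(f"unsupported payload type {type(payload).__name__}")


def payload_key(payload) -> str:
    if isinstance(payload, Fragment):
        return payload.key
    return "{" + ",".join(str(b) for b in sorted(payload_set(payload))) + "}"


@dataclass
class NetworkNode:
    """One enumerated sub-feature with its position in the network."""

    index: int
    payload: object
    feature_vector: object = None
    prediction: Optional[Prediction] = None
    assessment: Optional[Assessment] = None
    parent_indices: tuple = ()
    child_indices: tuple = ()
    ascendant_indices: frozenset = frozenset()
    descendant_indices: frozenset = frozenset()

    @property
    def payload_set(self) -> frozenset:
        return payload_set(self.payload)


class FeatureNetwork:
    """An indexed DAG of :class:`NetworkNode` with a unique root."""

    def __init__(self, nodes: Sequence[NetworkNode], root_index: int):
        self.nodes = list(nodes)
        self.root_index = root_index
        self._by_index = {n.index: n for n in self.nodes}
        if len(self._by_index) != len(self.nodes):
            raise NetworkError("duplicate node indices")
        if root_index not in self._by_index:
            raise NetworkError("root index not present")

    def node(self, index: int) -> NetworkNode:
        return self._by_index[index]

    @property
    def root(self) -> NetworkNode:
        return self._by_index[self.root_index]

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def topological_order(self) -> list[NetworkNode]:
        """Children-first order; raises on cycles."""
        state: dict[int, int] = {}
        order: list[NetworkNode] = []

        def visit(idx: int):
            if state.get(idx) == 2:
                return
            if state.get(idx) == 1:
                raise NetworkError("network contains a cycle")
            state[idx] = 1
            for child in self._by_index[idx].child_indices:
                visit(child)
            state[idx] = 2
            order.append(self._by_index[idx])

        for n in self.nodes:
            visit(n.index)
        return order

    def validate(self) -> None:
        """Check the structural invariants of a feature network."""
        roots = [n for n in self.nodes if not n.parent_indices]
        if len(roots) != 1 or roots[0].index != self.root_index:
            raise NetworkError("network must have exactly one parentless root")
        self.topological_order()  # acyclicity
        for n in self.nodes:
            if n.index in n.ascendant_indices:
                raise NetworkError(f"node {n.index} is its own ascendant")
            for p in n.parent_indices:
                parent = self.node(p)
                if not n.payload_set < parent.payload_set:
                    raise NetworkError(
                        f"parent {p} payload is not a strict superset of node {n.index}"
                    )
                if n.index not in parent.child_indices:
                    raise NetworkError("parent/child links are inconsistent")
            expected = set(n.parent_indices)
            for p in n.parent_indices:
                expected |= self.node(p).ascendant_indices
            if frozenset(expected) != n.ascendant_indices:
                raise NetworkError(f"ascendant closure wrong at node {n.index}")
            expected = set(n.child_indices)
            for c in n.child_indices:
                expected |= self.node(c).descendant_indices
            if frozenset(expected) != n.descendant_indices:
                raise NetworkError(f"descendant closure wrong at node {n.index}")


def _link_and_close(nodes: list[NetworkNode]) -> None:
    """Compute minimal-superset parenthood and transitive closures in place."""
    sets = {n.index: n.payload_set for n in nodes}
    order = sorted(nodes, key=lambda n: len(sets[n.index]))
    for n in nodes:
        supersets = [
            m.index
            for m in nodes
            if m.index != n.index and sets[n.index] < sets[m.index]
        ]
        minimal = [
            p
            for p in supersets
            if not any(q != p and sets[q] < sets[p] for q in supersets)
        ]
        n.parent_indices = tuple(sorted(minimal))
    children: dict[int, list[int]] = {n.index: [] for n in nodes}
    for n in nodes:
        for p in n.parent_indices:
            children[p].append(n.index)
    for n in nodes:
        n.child_indices = tuple(sorted(children[n.index]))
    # closures, smallest payloads first for descendants
    by_index = {n.index: n for n in nodes}
    for n in order:
        desc: set[int] = set(n.child_indices)
        for c in n.child_indices:
            desc |= by_index[c].descendant_indices
        n.descendant_indices = frozenset(desc)
    for n in reversed(order):
        asc: set[int] = set(n.parent_indices)
        for p in n.parent_indices:
            asc |= by_index[p].ascendant_indices
        n.ascendant_indices = frozenset(asc)


def _build_network(payloads: Sequence[object]) -> FeatureNetwork:
    keyed = {}
    for p in payloads:
        ps = payload_set(p)
        if ps in keyed:
            raise NetworkError(f"duplicate payload set {sorted(ps)}")
        keyed[ps] = p
    ordered = sorted(keyed.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    nodes = [NetworkNode(index=i, payload=p) for i, (_, p) in enumerate(ordered)]
    root_set = ordered[-1][0]
    for ps, _ in ordered[:-1]:
        if not ps < root_set:
            raise NetworkError(
                "no unique maximal payload: root must be a strict superset of "
                "every other node"
            )
    _link_and_close(nodes)
    net = FeatureNetwork(nodes, root_index=nodes[-1].index)
    net.validate()
    return net


def build_bitset_network(
    combos: Iterable[BitCombination], root: BitCombination
) -> FeatureNetwork:
    """Organise enumerated bit combinations into a feature network."""
    combos = list(combos)
    if root not in combos:
        combos.append(root)
    for c in combos:
        if not c.bit_set <= root.bit_set:
            raise NetworkError(f"root is not a superset of combination {c.member_bits}")
    return _build_network(combos)


def build_fragment_network(frags: Iterable[Fragment]) -> FeatureNetwork:
    """Organise enumerated fragments into a feature network by atom-id sets."""
    frags = list(frags)
    if not frags:
        raise NetworkError("no fragments given")
    return _build_network(frags)


def network_from_indexed(
    payloads_by_index: dict[int, object],
    predictions: Optional[dict[int, Prediction]] = None,
) -> FeatureNetwork:
    """Build a network keeping caller-chosen indices (used by fixtures).

    Parenthood is still derived from payload inclusion, so the caller's
    payload sets fully determine the topology.
    """
    nodes = [NetworkNode(index=i, payload=p) for i, p in sorted(payloads_by_index.items())]
    _link_and_close(nodes)
    root = max(nodes, key=lambda n: len(n.payload_set))
    net = FeatureNetwork(nodes, root_index=root.index)
    net.validate()
    if predictions:
        for idx, pred in predictions.items():
            net.node(idx).prediction = pred
    return net


# ---------------------------------------------------------------------------
# export


def _node_dict(n: NetworkNode) -> dict:
    d = {
        "index": n.index,
        "payload": sorted(n.payload_set),
        "payload_key": payload_key(n.payload),
        "prediction": n.prediction.label if n.prediction else None,
        "confidence": n.prediction.confidence if n.prediction else None,
        "assessment": n.assessment.value if n.assessment else None,
        "parents": sorted(n.parent_indices),
        "children": sorted(n.child_indices),
        "ascendants": sorted(n.ascendant_indices),
        "descendants": sorted(n.descendant_indices),
    }
    if isinstance(n.payload, Fragment):
        d["atom_ids"] = sorted(n.payload.atom_ids)
        d["bond_ids"] = sorted(n.payload.bond_ids)
    return d


def export_network(net: FeatureNetwork, fmt: str = "json") -> str:
    """Serialize a network as JSON or Graphviz DOT."""
    if fmt == "json":
        return json.dumps(
            {
                "root_index": net.root_index,
                "nodes": [_node_dict(n) for n in net.nodes],
            },
            indent=2,
        )
    if fmt == "dot":
        lines = ["digraph feature_network {", "  rankdir=BT;"]
        for n in net.nodes:
            colour = DOT_COLOURS[n.assessment]
            label = f"{n.index}: {payload_key(n.payload)}"
            if n.prediction:
                label += f"\\n{n.prediction.label}"
            lines.append(
                f'  n{n.index} [label="{label}", style=filled, fillcolor={colour}];'
            )
        for n in net.nodes:
            for p in n.parent_indices:
                lines.append(f"  n{n.index} -> n{p};")
        lines.append("}")
        return "\n".join(lines)
    raise NetworkError(f"unknown export format {fmt!r}")


def network_from_json(text: str) -> FeatureNetwork:
    """Rebuild a network (payloads as bit sets) from its JSON export."""
    data = json.loads(text)
    nodes = []
    for nd in data["nodes"]:
        node = NetworkNode(
            index=nd["index"],
            payload=frozenset(nd["payload"]),
            prediction=(
                Prediction(nd["prediction"], nd.get("confidence"))
                if nd.get("prediction")
                else None
            ),
            assessment=Assessment(nd["assessment"]) if nd.get("assessment") else None,
            parent_indices=tuple(nd["parents"]),
            child_indices=tuple(nd["children"]),
            ascendant_indices=frozenset(nd["ascendants"]),
            descendant_indices=frozenset(nd["descendants"]),
        )
        nodes.append(node)
    return FeatureNetwork(nodes, root_index=data["root_index"])
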
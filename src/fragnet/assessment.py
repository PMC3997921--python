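"""Node prediction, six-way classification and interpretation summaries.

Every node of a feature network is run through the black-box predictor and
then classified in a single bottom-up pass (ascending payload size):

* an inactive node is ``DEACTIVATING`` if at least one child is predicted
  active, otherwise ``IGNORE``;
* an active node is ``DEACTIVATED`` if at least one parent is predicted
  inactive; otherwise ``ACTIVITY_IDENTIFIED`` if it has an ``ACTIVATING``
  descendant; otherwise ``NEGATED`` if all parents are active but some
  ascendant is predicted inactive; otherwise ``ACTIVATING``.

Activity is therefore always attributed to the lowest node on a path, and
the interpretation never changes the model's prediction of the query — the
root keeps the plain model output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, runtime_checkable

from .chem_io import Highlight, Structure
from .config import RunConfig
from .enumeration import BitCombination, enumerate_bitsets
from .fingerprints import (
    FeatureVector,
    KeyLibrary,
    fp_for_fragment,
    hashed_path_fp,
    structural_key_fp,
)
from .fragmentation import (
    Fragment,
    build_reduced_graph,
    enumerate_fragments,
    load_unit_smarts,
)
from .network import (
    ACTIVE,
    Assessment,
    FeatureNetwork,
    NetworkNode,
    Prediction,
    build_bitset_network,
    build_fragment_network,
)

__all__ = [
    "AssessmentError",
    "DeactivationPair",
    "InterpretationSummary",
    "Predictor",
    "classify_nodes",
    "condense_deactivations",
    "interpret",
    "predict_nodes",
    "summarize",
]


class AssessmentError(RuntimeError):
    """Raised when prediction or classification cannot proceed."""


@runtime_checkable
class Predictor(Protocol):
    """The pluggable binary-predictor contract."""

    def predict(self, feature_vector: FeatureVector) -> Prediction:  # pragma: no cover
        ...


@dataclass(frozen=True)
class DeactivationPair:
    """A (deactivating parent, deactivated child) edge of the network."""

    deactivating_index: int
    deactivated_index: int
    deactivated: Optional[Highlight] = None
    deactivating: Optional[Highlight] = None


@dataclass(frozen=True)
class ActivationEntry:
    node_index: int
    highlight: Optional[Highlight] = None


@dataclass
class InterpretationSummary:
    """Activations and deactivations extracted from an assessed network."""

    final_prediction: str
    confidence: Optional[float]
    activations: tuple[ActivationEntry, ...]
    deactivations: tuple[DeactivationPair, ...]

    @property
    def node_references(self) -> tuple[int, ...]:
        refs = [a.node_index for a in self.activations]
        for d in self.deactivations:
            refs.extend((d.deactivating_index, d.deactivated_index))
        return tuple(refs)

    def to_dict(self, structure_name: str = "") -> dict:
        return {
            "structure": structure_name,
            "prediction": self.final_prediction,
            "confidence": self.confidence,
            "activations": [
                {
                    "node": a.node_index,
                    **(a.highlight.to_dict() if a.highlight else {}),
                }
                for a in self.activations
            ],
            "deactivations": [
                {
                    "deactivating_node": d.deactivating_index,
                    "deactivated_node": d.deactivated_index,
                    "deactivated": d.deactivated.to_dict() if d.deactivated else None,
                    "deactivating": d.deactivating.to_dict() if d.deactivating else None,
                }
                for d in self.deactivations
            ],
        }


def predict_nodes(net: FeatureNetwork, model: Predictor) -> FeatureNetwork:
    """Run the predictor over every node in place.

    The root node's prediction is, by construction, the plain model
    prediction of the query — its feature vector is the query's own.
    """
    for node in net.nodes:
        if node.feature_vector is None:
            raise AssessmentError(f"node {node.index} has no feature vector")
        try:
            pred = model.predict(node.feature_vector)
        except Exception as exc:
            raise AssessmentError(f"predictor failed on node {node.index}: {exc}") from exc
        if not isinstance(pred, Prediction):
            pred = Prediction(*pred) if isinstance(pred, tuple) else Prediction(pred)
        node.prediction = pred
    return net


def _assessment_order(net: FeatureNetwork) -> list[NetworkNode]:
    # ascending payload size == children before parents (payloads are strict
    # subsets along edges); index tie-break keeps the pass deterministic
    return sorted(net.nodes, key=lambda n: (len(n.payload_set), n.index))


def classify_nodes(net: FeatureNetwork) -> FeatureNetwork:
    """Assign exactly one of the six assessment types to every node."""
    for node in net.nodes:
        if node.prediction is None:
            raise AssessmentError(f"node {node.index} has no prediction")
    for node in _assessment_order(net):
        if not node.prediction.is_active:
            has_active_child = any(
                net.node(c).prediction.is_active for c in node.child_indices
            )
            node.assessment = (
                Assessment.DEACTIVATING if has_active_child else Assessment.IGNORE
            )
            continue
        if any(not net.node(p).prediction.is_active for p in node.parent_indices):
            node.assessment = Assessment.DEACTIVATED
        elif any(
            net.node(d).assessment is Assessment.ACTIVATING
            for d in node.descendant_indices
        ):
            node.assessment = Assessment.ACTIVITY_IDENTIFIED
        elif any(
            not net.node(a).prediction.is_active for a in node.ascendant_indices
        ):
            node.assessment = Assessment.NEGATED
        else:
            node.assessment = Assessment.ACTIVATING
    return net


def _node_highlight(node: NetworkNode, role: str) -> Optional[Highlight]:
    """Project a node payload onto query atom/bond ids, when possible."""
    if isinstance(node.payload, Fragment):
        return Highlight(node.payload.atom_ids, node.payload.bond_ids, role)
    fv = node.feature_vector
    if (
        isinstance(node.payload, BitCombination)
        and isinstance(fv, FeatureVector)
        and fv.provenance
    ):
        atoms: set = set()
        bonds: set = set()
        for bit in node.payload.member_bits:
            for w_atoms, w_bonds in fv.provenance.get(bit, ()):
                atoms |= w_atoms
                bonds |= w_bonds
        if atoms or bonds:
            return Highlight(frozenset(atoms), frozenset(bonds), role)
    return None


def _difference_highlight(
    parent: NetworkNode, child: NetworkNode, role: str
) -> Optional[Highlight]:
    """Atoms/bonds the deactivating parent adds over its deactivated child."""
    if isinstance(parent.payload, Fragment) and isinstance(child.payload, Fragment):
        atoms = parent.payload.atom_ids - child.payload.atom_ids
        bonds = parent.payload.bond_ids - child.payload.bond_ids
        if atoms or bonds:
            return Highlight(atoms, bonds, role)
        return None
    ph = _node_highlight(parent, role)
    ch = _node_highlight(child, role)
    if ph and ch:
        atoms = ph.atom_ids - ch.atom_ids
        bonds = ph.bond_ids - ch.bond_ids
        if atoms or bonds:
            return Highlight(atoms, bonds, role)
    return None


def summarize(net: FeatureNetwork) -> InterpretationSummary:
    """Condense an assessed network into activations and deactivation pairs.

    Activations are the ``ACTIVATING`` nodes; deactivations are the
    (``DEACTIVATING`` parent, ``DEACTIVATED`` child) edges.  ``NEGATED`` and
    ``ACTIVITY_IDENTIFIED`` nodes are excluded — the former are covered by a
    larger deactivation context, the latter merely inherit a descendant's
    activation.
    """
    activations = []
    deactivations = []
    for node in net.nodes:
        if node.assessment is None:
            raise AssessmentError(f"node {node.index} is not assessed")
        if node.assessment is Assessment.ACTIVATING:
            activations.append(
                ActivationEntry(node.index, _node_highlight(node, "ACTIVATING"))
            )
        elif node.assessment is Assessment.DEACTIVATED:
            for p in node.parent_indices:
                parent = net.node(p)
                if parent.assessment is Assessment.DEACTIVATING:
                    deactivations.append(
                        DeactivationPair(
                            deactivating_index=p,
                            deactivated_index=node.index,
                            deactivated=_node_highlight(node, "DEACTIVATED"),
                            deactivating=_difference_highlight(
                                parent, node, "DEACTIVATING"
                            ),
                        )
                    )
    root = net.root
    return InterpretationSummary(
        final_prediction=root.prediction.label,
        confidence=root.prediction.confidence,
        activations=tuple(sorted(activations, key=lambda a: a.node_index)),
        deactivations=tuple(
            sorted(deactivations, key=lambda d: (d.deactivating_index, d.deactivated_index))
        ),
    )


def condense_deactivations(
    summary: InterpretationSummary, net: FeatureNetwork
) -> InterpretationSummary:
    """Keep only the largest context of chained deactivations.

    When activity is re-established above a deactivation and deactivated
    again higher on the same path, only the pair whose deactivating node is
    highest (largest payload) is retained; a pair is dropped iff another
    pair's deactivating node is a strict ascendant of its own.
    """
    deactivating_nodes = {d.deactivating_index for d in summary.deactivations}
    kept = tuple(
        d
        for d in summary.deactivations
        if not (net.node(d.deactivating_index).ascendant_indices & deactivating_nodes)
    )
    return InterpretationSummary(
        final_prediction=summary.final_prediction,
        confidence=summary.confidence,
        activations=summary.activations,
        deactivations=kept,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _attach_fragment_vectors(
    net: FeatureNetwork, query: Structure, config: RunConfig, library: KeyLibrary
) -> None:
    fp_cfg = config.fingerprint
    for node in net.nodes:
        node.feature_vector = fp_for_fragment(
            query,
            node.payload,
            scheme=fp_cfg.scheme,
            library=library,
            max_depth=fp_cfg.max_depth,
            n_bits=fp_cfg.n_bits,
        )


def _query_fingerprint(query: Structure, config: RunConfig, library: KeyLibrary):
    if config.fingerprint.scheme == "structural_keys":
        return structural_key_fp(query, library)
    return hashed_path_fp(
        query, max_depth=config.fingerprint.max_depth, n_bits=config.fingerprint.n_bits
    )


def interpret(
    query: Structure,
    model: Predictor,
    config: Optional[RunConfig] = None,
    library: Optional[KeyLibrary] = None,
) -> tuple[InterpretationSummary, FeatureNetwork]:
    """Full interpretation pipeline for one query structure.

    Composes enumeration (fragment or bitset approach), network building,
    node prediction, classification and summarisation.  The summary's final
    prediction always equals the plain model prediction of the query.
    """
    config = config or RunConfig()
    if library is None:
        library = (
            KeyLibrary.from_tsv(config.fingerprint.key_file)
            if config.fingerprint.key_file
            else KeyLibrary.default()
        )
    if config.approach == "fragment":
        unit_smarts = (
            load_unit_smarts(config.fragmentation.unit_smarts_file)
            if config.fragmentation.unit_smarts_file
            else None
        )
        rg = build_reduced_graph(query, unit_smarts)
        frags = enumerate_fragments(
            rg,
            max_depth=config.fragmentation.max_depth,
            unit_cap=config.fragmentation.unit_cap,
        )
        net = build_fragment_network(frags)
        _attach_fragment_vectors(net, query, config, library)
    elif config.approach == "bitset":
        fv = _query_fingerprint(query, config, library)
        if not fv.on_bits:
            raise AssessmentError(
                "query sets no fingerprint bits; nothing to enumerate"
            )
        combos = enumerate_bitsets(
            fv,
            prune_level=config.enumeration.prune_level,
            max_bits=config.enumeration.max_bits,
        )
        root = BitCombination(tuple(sorted(fv.on_bits)))
        net = build_bitset_network(combos, root)
        for node in net.nodes:
            node.feature_vector = FeatureVector(
                n_bits=fv.n_bits,
                on_bits=node.payload.bit_set,
                scheme=fv.scheme,
                provenance=(
                    {
                        b: fv.provenance[b]
                        for b in node.payload.bit_set
                        if b in (fv.provenance or {})
                    }
                    if fv.provenance
                    else None
                ),
            )
    else:  # pragma: no cover - config validation forbids
        raise AssessmentError(f"unknown approach {config.approach!r}")
    predict_nodes(net, model)
    classify_nodes(net)
    summary = summarize(net)
    if config.condense:
        summary = condense_deactivations(summary, net)
    return summary, net
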
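import pytest

from fragnet.assessment import (
    AssessmentError,
    classify_nodes,
    condense_deactivations,
    interpret,
    predict_nodes,
    summarize,
)
from fragnet.chem_io import parse_structure
from fragnet.config import RunConfig
from fragnet.enumeration import BitCombination
from fragnet.fingerprints import FeatureVector, structural_key_fp
from fragnet.fixtures import default_oracle, golden_network_fixture, make_random_network
from fragnet.fragmentation import build_reduced_graph, enumerate_fragments
from fragnet.network import (
    ACTIVE,
    INACTIVE,
    Assessment,
    Prediction,
    build_fragment_network,
    network_from_indexed,
)
from oracles import fixpoint_classify

GOLDEN_EXPECTED = {
    0: Assessment.ACTIVITY_IDENTIFIED,
    1: Assessment.ACTIVITY_IDENTIFIED,
    2: Assessment.IGNORE,
    3: Assessment.ACTIVITY_IDENTIFIED,
    4: Assessment.DEACTIVATING,
    5: Assessment.DEACTIVATING,
    6: Assessment.ACTIVATING,
    7: Assessment.IGNORE,
    8: Assessment.DEACTIVATED,
    9: Assessment.DEACTIVATED,
    10: Assessment.NEGATED,
}


class ConstantPredictor:
    def __init__(self, label):
        self.label = label

    def predict(self, fv):
        return Prediction(self.label, confidence=1.0)


class FailingPredictor:
    def predict(self, fv):
        raise RuntimeError("boom")


class TestPredictNodes:
    def test_constant_inactive(self, nitronaphthalene, key_library):
        net = self._net(nitronaphthalene, key_library)
        predict_nodes(net, ConstantPredictor(INACTIVE))
        assert all(n.prediction.label == INACTIVE for n in net.nodes)

    def test_rule_oracle_marks_nitro_nodes(self, nitronaphthalene, key_library, oracle):
        net = self._net(nitronaphthalene, key_library)
        predict_nodes(net, oracle)
        nitro_atoms = frozenset({0, 1, 2})
        for n in net.nodes:
            contains_nitro = nitro_atoms <= n.payload.atom_ids
            assert n.prediction.is_active == contains_nitro

    def test_root_prediction_is_model_prediction(self, nitronaphthalene, key_library, oracle):
        net = self._net(nitronaphthalene, key_library)
        predict_nodes(net, oracle)
        direct = oracle.predict(structural_key_fp(nitronaphthalene, key_library))
        assert net.root.prediction.label == direct.label

    def test_predictor_failure_names_node(self, nitronaphthalene, key_library):
        net = self._net(nitronaphthalene, key_library)
        with pytest.raises(AssessmentError, match="node 0"):
            predict_nodes(net, FailingPredictor())

    def test_missing_feature_vector(self):
        net = make_random_network(3, 0)
        with pytest.raises(AssessmentError, match="feature vector"):
            predict_nodes(net, ConstantPredictor(ACTIVE))

    @staticmethod
    def _net(structure, lib):
        from fragnet.fingerprints import fp_for_fragment

        frags = enumerate_fragments(build_reduced_graph(structure))
        net = build_fragment_network(frags)
        for n in net.nodes:
            n.feature_vector = fp_for_fragment(structure, n.payload, library=lib)
        return net


class TestClassifyNodes:
    def test_golden_network_assessments(self):
        net = classify_nodes(golden_network_fixture())
        assert {n.index: n.assessment for n in net.nodes} == GOLDEN_EXPECTED

    def test_all_inactive_all_ignore(self):
        net = make_random_network(12, 5)
        for n in net.nodes:
            n.prediction = Prediction(INACTIVE)
        classify_nodes(net)
        assert all(n.assessment is Assessment.IGNORE for n in net.nodes)

    def test_all_active_leaves_activating(self):
        net = make_random_network(12, 5)
        for n in net.nodes:
            n.prediction = Prediction(ACTIVE)
        classify_nodes(net)
        for n in net.nodes:
            expected = (
                Assessment.ACTIVATING
                if not n.child_indices
                else Assessment.ACTIVITY_IDENTIFIED
            )
            assert n.assessment is expected

    def test_unpredicted_node_rejected(self):
        net = make_random_network(4, 1)
        net.nodes[0].prediction = None
        with pytest.raises(AssessmentError, match="no prediction"):
            classify_nodes(net)

    def test_partition_into_exactly_one_type(self):
        for seed in range(20):
            net = classify_nodes(make_random_network(1 + seed % 50, seed))
            assert all(isinstance(n.assessment, Assessment) for n in net.nodes)

    def test_matches_fixpoint_oracle_small(self):
        for seed in range(200):
            net = make_random_network(1 + seed % 10, seed)
            expected = fixpoint_classify(net)
            classify_nodes(net)
            assert {n.index: n.assessment for n in net.nodes} == expected

    def test_no_activating_below_activating(self):
        for seed in range(50):
            net = classify_nodes(make_random_network(30, seed))
            for n in net.nodes:
                if n.assessment is Assessment.ACTIVATING:
                    for d in n.descendant_indices:
                        assert net.node(d).assessment is not Assessment.ACTIVATING

    def test_deactivated_has_deactivating_parent(self):
        for seed in range(50):
            net = classify_nodes(make_random_network(30, seed))
            for n in net.nodes:
                if n.assessment is Assessment.DEACTIVATED:
                    assert any(
                        net.node(p).assessment is Assessment.DEACTIVATING
                        for p in n.parent_indices
                    )
                if n.assessment is Assessment.DEACTIVATING:
                    assert any(
                        net.node(c).prediction.is_active for c in n.child_indices
                    )


class TestSummarize:
    def test_golden_network_summary(self):
        net = classify_nodes(golden_network_fixture())
        summary = summarize(net)
        assert summary.final_prediction == ACTIVE
        assert [a.node_index for a in summary.activations] == [6]
        pairs = {(d.deactivating_index, d.deactivated_index) for d in summary.deactivations}
        assert pairs == {(4, 8), (5, 8), (5, 9)}

    def test_single_active_root(self):
        net = network_from_indexed(
            {0: BitCombination((0,))}, {0: Prediction(ACTIVE)}
        )
        summary = summarize(classify_nodes(net))
        assert len(summary.activations) == 1
        assert not summary.deactivations

    def test_inactive_prediction_no_activations(self):
        for seed in range(50):
            net = classify_nodes(make_random_network(15, seed))
            summary = summarize(net)
            if summary.final_prediction == INACTIVE:
                assert not summary.activations

    def test_root_activity_equivalence(self):
        for seed in range(100):
            net = classify_nodes(make_random_network(1 + seed % 40, seed))
            has_activating = any(
                n.assessment is Assessment.ACTIVATING for n in net.nodes
            )
            assert has_activating == net.root.prediction.is_active

    def test_unassessed_rejected(self):
        with pytest.raises(AssessmentError, match="not assessed"):
            summarize(make_random_network(3, 0))


def _chain_network(labels):
    """A payload chain {0} c {0,1} c ... with the given prediction labels."""
    payloads = {
        i: BitCombination(tuple(range(i + 1))) for i in range(len(labels))
    }
    predictions = {i: Prediction(label) for i, label in enumerate(labels)}
    return network_from_indexed(payloads, predictions)


class TestCondenseDeactivations:
    def test_chain_keeps_largest_context(self):
        # leaf(active) -> mid1(inactive) -> mid2(active) -> root(inactive)
        net = classify_nodes(_chain_network([ACTIVE, INACTIVE, ACTIVE, INACTIVE]))
        summary = summarize(net)
        pairs = {(d.deactivating_index, d.deactivated_index) for d in summary.deactivations}
        assert pairs == {(1, 0), (3, 2)}
        condensed = condense_deactivations(summary, net)
        kept = {(d.deactivating_index, d.deactivated_index) for d in condensed.deactivations}
        assert kept == {(3, 2)}

    def test_no_chain_is_fixpoint(self):
        net = classify_nodes(golden_network_fixture())
        summary = summarize(net)
        condensed = condense_deactivations(summary, net)
        assert condensed.deactivations == summary.deactivations

    def test_output_subset_of_input(self):
        for seed in range(30):
            net = classify_nodes(make_random_network(25, seed))
            summary = summarize(net)
            condensed = condense_deactivations(summary, net)
            assert set(condensed.deactivations) <= set(summary.deactivations)


class TestInterpret:
    def test_nitronaphthalene_activation(self, nitronaphthalene, oracle):
        summary, net = interpret(nitronaphthalene, oracle)
        assert summary.final_prediction == ACTIVE
        assert len(summary.activations) == 1
        assert summary.activations[0].highlight.atom_ids == frozenset({0, 1, 2})
        assert not summary.deactivations

    def test_benzene_inactive_empty(self, benzene, oracle):
        summary, net = interpret(benzene, oracle)
        assert summary.final_prediction == INACTIVE
        assert not summary.activations
        assert not summary.deactivations

    def test_example1_pattern(self, aminonitrobenzoic, oracle):
        """Nitro activation plus amine-deactivated-by-ortho-carboxyl pair."""
        summary, net = interpret(aminonitrobenzoic, oracle)
        assert summary.final_prediction == ACTIVE
        assert len(net) == 11  # 8 informative nodes + 3 ignores
        [activation] = summary.activations
        assert activation.highlight.atom_ids == frozenset({6, 7, 8})  # the nitro
        [pair] = summary.deactivations
        # the deactivating context is the carboxylic acid the parent adds
        acid_atoms = frozenset({10, 11, 12})
        assert pair.deactivating.atom_ids == acid_atoms
        assert 0 in pair.deactivated.atom_ids  # the amine nitrogen

    def test_final_prediction_never_changes(self, toy_library, oracle, key_library):
        for s in toy_library.structures[:15]:
            summary, _ = interpret(s, oracle)
            direct = oracle.predict(structural_key_fp(s, key_library))
            assert summary.final_prediction == direct.label

    def test_bitset_approach(self, oracle):
        s = parse_structure("O=[N+]([O-])c1ccccc1")
        summary, net = interpret(s, oracle, RunConfig(approach="bitset"))
        assert summary.final_prediction == ACTIVE
        assert any(
            a.highlight and a.highlight.atom_ids == frozenset({0, 1, 2})
            for a in summary.activations
        )

    def test_condense_flag(self, oracle):
        s = parse_structure("Nc1ccccc1C(=O)O")
        plain, _ = interpret(s, oracle, RunConfig(condense=False))
        condensed, _ = interpret(s, oracle, RunConfig(condense=True))
        assert len(condensed.deactivations) <= len(plain.deactivations)

    def test_summary_json_schema(self, aminonitrobenzoic, oracle):
        summary, _ = interpret(aminonitrobenzoic, oracle)
        d = summary.to_dict("q")
        assert d["structure"] == "q"
        assert d["prediction"] == "active"
        assert d["activations"][0]["atoms"] == [6, 7, 8]
        assert d["deactivations"][0]["deactivating"]["atoms"] == [10, 11, 12]
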
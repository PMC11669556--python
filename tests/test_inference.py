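import math

import numpy as np
import pytest

from dbnpanel.data import PanelDataset
from dbnpanel.errors import ImpossibleEvidenceError, InputError
from dbnpanel.inference import (
    Evidence,
    anomaly_scores,
    impute,
    joint_posterior,
    posterior,
    record_loglik,
)
from dbnpanel.network import (
    ConditionalTable,
    DynamicNetwork,
    TemporalArc,
    TemporalStructure,
    VariableSpec,
    log_joint_probability,
    unroll,
)
from dbnpanel.cohort import sample_from_network

from .conftest import random_dag_network, random_evidence
from .oracles import enum_posterior


def fork_net():
    """A -> B, A -> C with fixed 2-state tables for hand calculations."""
    vs = [VariableSpec(n, (n.lower() + "0", n.lower() + "1"), temporal=False)
          for n in "ABC"]
    arcs = {TemporalArc("A", "B", 0), TemporalArc("A", "C", 0)}
    s = TemporalStructure(vs, arcs, 1)
    pa = np.array([0.3, 0.7])
    pb = np.array([[0.9, 0.1], [0.2, 0.8]])
    pc = np.array([[0.6, 0.4], [0.25, 0.75]])
    tables = {
        "A": {(): ConditionalTable("A", (), pa)},
        "B": {(("A", 0),): ConditionalTable("B", (("A", 0),), pb)},
        "C": {(("A", 0),): ConditionalTable("C", (("A", 0),), pc)},
    }
    return DynamicNetwork(s, tables), pa, pb, pc


class TestPosterior:
    def test_prior_marginals_match_enumeration(self, rng):
        for _ in range(5):
            net = random_dag_network(rng, int(rng.integers(4, 9)))
            g = unroll(net)
            rep = posterior(g, Evidence(), set(g.order))
            marg, logz = enum_posterior(g, query=list(g.order))
            assert logz == pytest.approx(0.0, abs=1e-10)
            for q in g.order:
                np.testing.assert_allclose(
                    rep.marginals[q], marg[q], atol=1e-10
                )

    def test_hard_evidence_on_query_node_is_point_mass(self, two_wave_chain):
        g = unroll(two_wave_chain)
        rep = posterior(g, Evidence(hard={("B", 1): "b1"}), {("B", 1)})
        np.testing.assert_allclose(rep.marginals[("B", 1)], [0.0, 1.0])

    def test_fork_hand_bayes_computation(self):
        # query B given C = c1: P(B|C) = sum_a P(a) P(B|a) P(c1|a) / P(c1)
        net, pa, pb, pc = fork_net()
        g = unroll(net)
        rep = posterior(g, Evidence(hard={("C", 0): "c1"}), {("B", 0)})
        weights = pa * pc[:, 1]
        expected = (weights[:, None] * pb).sum(axis=0) / weights.sum()
        np.testing.assert_allclose(rep.marginals[("B", 0)], expected, atol=1e-12)
        # dependence: posterior must differ from the prior marginal
        prior = posterior(g, Evidence(), {("B", 0)}).marginals[("B", 0)]
        assert abs(rep.marginals[("B", 0)][0] - prior[0]) > 0.01
        assert rep.log_evidence == pytest.approx(math.log(weights.sum()), abs=1e-10)

    def test_smoothing_later_evidence_moves_earlier_wave(self, two_wave_chain):
        g = unroll(two_wave_chain)
        prior = posterior(g, Evidence(), {("B", 0)}).marginals[("B", 0)]
        smoothed = posterior(
            g, Evidence(hard={("B", 2): "b1"}), {("B", 0)}
        ).marginals[("B", 0)]
        assert abs(prior[0] - smoothed[0]) > 0.01

    def test_evidence_with_random_nets_matches_enumeration(self, rng):
        for _ in range(5):
            net = random_dag_network(rng, int(rng.integers(5, 10)))
            g = unroll(net)
            hard, soft = random_evidence(rng, g)
            query = [k for k in g.order if k not in hard]
            rep = posterior(g, Evidence(hard=hard, soft=soft), set(query))
            marg, logz = enum_posterior(g, hard=hard, soft=soft, query=query)
            assert rep.log_evidence == pytest.approx(logz, abs=1e-9)
            for q in query:
                np.testing.assert_allclose(rep.marginals[q], marg[q], atol=1e-9)

    def test_impossible_evidence_detected(self):
        vs = [
            VariableSpec("A", ("0", "1"), temporal=False),
            VariableSpec("B", ("0", "1"), temporal=False),
        ]
        s = TemporalStructure(vs, {TemporalArc("A", "B", 0)}, 1)
        net = DynamicNetwork(
            s,
            {
                "A": {(): ConditionalTable("A", (), np.array([1.0, 0.0]))},
                "B": {(("A", 0),): ConditionalTable("B", (("A", 0),), np.eye(2))},
            },
        )
        g = unroll(net)
        with pytest.raises(ImpossibleEvidenceError):
            posterior(g, Evidence(hard={("B", 0): "1"}), {("A", 0)})

    def test_soft_uniform_is_noop(self, rng):
        net = random_dag_network(rng, 7)
        g = unroll(net)
        k = g.order[3]
        uniform = Evidence(soft={k: np.ones(g.nodes[k].cardinality)})
        base = posterior(g, Evidence(), set(g.order))
        shifted = posterior(g, uniform, set(g.order))
        for q in g.order:
            np.testing.assert_allclose(
                base.marginals[q], shifted.marginals[q], atol=1e-10
            )

    def test_evidence_chaining(self, rng):
        # log P(E1, E2) = log P(E1) + log P(E2 | E1)
        net = random_dag_network(rng, 8)
        g = unroll(net)
        keys = list(g.order)
        e1 = {keys[0]: g.nodes[keys[0]].states[0]}
        e2 = {keys[-1]: g.nodes[keys[-1]].states[-1]}
        both = posterior(g, Evidence(hard={**e1, **e2}), set()).log_evidence
        first = posterior(g, Evidence(hard=e1), set()).log_evidence
        # P(E2 | E1) via the conditional marginal of the E2 node
        rep = posterior(g, Evidence(hard=e1), {keys[-1]})
        cond = math.log(rep.marginals[keys[-1]][-1])
        assert both == pytest.approx(first + cond, abs=1e-9)

    def test_marginalization_consistency(self, rng):
        net = random_dag_network(rng, 9)
        g = unroll(net)
        hard, soft = random_evidence(rng, g)
        rep = posterior(
            g, Evidence(hard=hard, soft=soft),
            {k for k in g.order if k not in hard},
        )
        for vec in rep.marginals.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_evidence_validation(self, two_wave_chain):
        g = unroll(two_wave_chain)
        with pytest.raises(InputError):
            posterior(g, Evidence(hard={("Z", 0): "x"}), {("A", 0)})
        with pytest.raises(InputError):
            posterior(g, Evidence(hard={("A", 0): "zzz"}), {("B", 0)})
        with pytest.raises(InputError):
            posterior(g, Evidence(soft={("A", 0): np.zeros(2)}), {("B", 0)})


class TestJointPosterior:
    def test_pair_joint_matches_enumeration(self, rng):
        net = random_dag_network(rng, 7)
        g = unroll(net)
        x, y = g.order[0], g.order[-1]
        nodes, joint, logz = joint_posterior(g, Evidence(), (x, y))
        marg, _ = enum_posterior(g, query=[x, y])
        np.testing.assert_allclose(joint.sum(axis=1), marg[x], atol=1e-9)
        np.testing.assert_allclose(joint.sum(axis=0), marg[y], atol=1e-9)


class TestImpute:
    def test_complete_record_gives_empty_result(self, two_wave_chain):
        g = unroll(two_wave_chain)
        observed = {k: g.nodes[k].states[0] for k in g.order}
        assert impute(g, observed) == {}

    def test_deterministic_copy_gives_point_mass(self):
        vs = [
            VariableSpec("A", ("0", "1"), temporal=False),
            VariableSpec("B", ("0", "1"), temporal=False),
        ]
        s = TemporalStructure(vs, {TemporalArc("A", "B", 0)}, 1)
        net = DynamicNetwork(
            s,
            {
                "A": {(): ConditionalTable("A", (), np.array([0.5, 0.5]))},
                "B": {(("A", 0),): ConditionalTable("B", (("A", 0),), np.eye(2))},
            },
        )
        g = unroll(net)
        out = impute(g, {("A", 0): "1"})
        np.testing.assert_allclose(out[("B", 0)], [0.0, 1.0], atol=1e-12)

    def test_single_missing_cell_matches_enumeration(self, rng):
        net = random_dag_network(rng, 6)
        g = unroll(net)
        missing = g.order[2]
        observed = {
            k: str(rng.choice(g.nodes[k].states))
            for k in g.order
            if k != missing
        }
        out = impute(g, observed)
        marg, _ = enum_posterior(g, hard=observed, query=[missing])
        np.testing.assert_allclose(out[missing], marg[missing], atol=1e-10)


class TestRecordLoglik:
    def test_complete_record_reduces_to_joint(self, rng):
        net = random_dag_network(rng, 6)
        g = unroll(net)
        asn = {k: str(rng.choice(g.nodes[k].states)) for k in g.order}
        assert record_loglik(g, asn) == pytest.approx(
            log_joint_probability(g, asn), abs=1e-10
        )

    def test_fully_missing_record_is_zero(self, two_wave_chain):
        g = unroll(two_wave_chain)
        assert record_loglik(g, {}) == 0.0

    def test_partial_record_matches_enumeration(self, rng):
        net = random_dag_network(rng, 7)
        g = unroll(net)
        observed = {
            k: str(rng.choice(g.nodes[k].states)) for k in g.order[::2]
        }
        from .oracles import enum_loglik

        assert record_loglik(g, observed) == pytest.approx(
            enum_loglik(g, observed), abs=1e-9
        )


class TestAnomalyScores:
    def test_identical_subjects_get_zero_flags(self, two_wave_chain):
        g = unroll(two_wave_chain)
        variables = list(two_wave_chain.structure.variables.values())
        codes = np.zeros((30, 3, 2), dtype=np.int16)
        ds = PanelDataset([f"s{i}" for i in range(30)], variables, 3, codes)
        scores, flags = anomaly_scores(g, ds, 0.1)
        assert np.ptp(scores) == 0.0
        assert flags.sum() == 0

    def test_adversarial_record_scores_highest(self, rng):
        net = random_dag_network(rng, 6, edge_prob=0.5)
        g = unroll(net)
        ds = sample_from_network(net, 200, rng)
        # adversary: at each cell pick the minimum-prior-probability state
        priors, _ = enum_posterior(g, query=list(g.order))
        adv = ds.codes[0].copy()
        for key in g.order:
            j = ds.var_index[key[0]]
            adv[key[1], j] = int(np.argmin(priors[key]))
        codes = np.concatenate([ds.codes, adv[None]], axis=0)
        ds2 = PanelDataset(ds.subjects + ["adv"], ds.variables, ds.waves, codes)
        scores, flags = anomaly_scores(g, ds2, 0.05)
        assert int(np.argmax(scores)) == len(scores) - 1
        assert flags[-1]

    def test_flag_count_bound(self, rng):
        net = random_dag_network(rng, 5)
        g = unroll(net)
        ds = sample_from_network(net, 200, rng)
        _, flags = anomaly_scores(g, ds, 0.05)
        assert flags.sum() <= math.ceil(200 * 0.05)

    def test_input_validation(self, rng, two_wave_chain):
        g = unroll(two_wave_chain)
        variables = list(two_wave_chain.structure.variables.values())
        empty = PanelDataset([], variables, 3, np.zeros((0, 3, 2), dtype=np.int16))
        with pytest.raises(InputError):
            anomaly_scores(g, empty, 0.05)
        ds = PanelDataset(["a"], variables, 3, np.zeros((1, 3, 2), dtype=np.int16))
        with pytest.raises(InputError):
            anomaly_scores(g, ds, 0.7)
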
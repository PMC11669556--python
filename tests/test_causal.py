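import numpy as np
import pytest

from dbnpanel.causal import (
    InterventionSpec,
    counterfactual_query,
    intervene,
    map_query,
    mpe_query,
    pathway_strength,
    scenario_analysis,
)
from dbnpanel.errors import InputError
from dbnpanel.inference import Evidence, posterior
from dbnpanel.network import (
    ConditionalTable,
    DynamicNetwork,
    TemporalArc,
    TemporalStructure,
    VariableSpec,
    unroll,
)

from .conftest import random_dag_network, random_evidence
from .oracles import enum_do, enum_marginal_map, enum_posterior


def hs_fixture():
    """Household-size style fixture: small households raise P(target=N).

    H -> T with T 3-state ('N' plus two deficit states); H binary.
    """
    vs = [
        VariableSpec("H", ("<=6", ">6"), temporal=False),
        VariableSpec("T", ("N", "U", "S"), temporal=False),
    ]
    s = TemporalStructure(vs, {TemporalArc("H", "T", 0)}, 1)
    tables = {
        "H": {(): ConditionalTable("H", (), np.array([0.6, 0.4]))},
        "T": {
            (("H", 0),): ConditionalTable(
                "T",
                (("H", 0),),
                np.array([[0.7, 0.2, 0.1], [0.3, 0.4, 0.3]]),
            )
        },
    }
    return DynamicNetwork(s, tables)


class TestMapQuery:
    def test_single_node_query_is_posterior_mode(self, rng):
        net = random_dag_network(rng, 6)
        g = unroll(net)
        q = g.order[-1]
        rep = posterior(g, Evidence(), {q})
        res = map_query(g, Evidence(), [q])
        assert res.assignment[q] == g.nodes[q].states[
            int(np.argmax(rep.marginals[q]))
        ]

    def test_matches_enumeration_with_evidence(self, rng):
        for _ in range(5):
            net = random_dag_network(rng, int(rng.integers(4, 8)))
            g = unroll(net)
            hard, soft = random_evidence(rng, g, n_hard=1, n_soft=1)
            query = [k for k in g.order if k not in hard]
            res = map_query(g, Evidence(hard=hard, soft=soft), query)
            expected, prob = enum_marginal_map(
                g, hard=hard, soft=soft, query=query
            )
            assert res.assignment == expected
            assert res.probability == pytest.approx(prob, abs=1e-9)

    def test_symmetric_tie_breaks_lexicographically(self):
        vs = [VariableSpec("A", ("s0", "s1"), temporal=False)]
        s = TemporalStructure(vs, set(), 1)
        net = DynamicNetwork(
            s, {"A": {(): ConditionalTable("A", (), np.array([0.5, 0.5]))}}
        )
        g = unroll(net)
        res = map_query(g, Evidence(), [("A", 0)], k=2)
        assert res.assignment == {("A", 0): "s0"}
        assert res.top[0][1] == pytest.approx(res.top[1][1], abs=1e-12)

    def test_top_k_enumerates_full_mass(self, rng):
        net = random_dag_network(rng, 5)
        g = unroll(net)
        query = list(g.order)
        cells = int(np.prod([g.nodes[q].cardinality for q in query]))
        res = map_query(g, Evidence(), query, k=cells)
        probs = [p for _, p in res.top]
        assert all(a >= b - 1e-12 for a, b in zip(probs, probs[1:]))
        assert sum(probs) == pytest.approx(1.0, abs=1e-6)

    def test_query_overlap_with_evidence_rejected(self, rng):
        net = random_dag_network(rng, 4)
        g = unroll(net)
        q = g.order[0]
        ev = Evidence(hard={q: g.nodes[q].states[0]})
        with pytest.raises(InputError):
            map_query(g, ev, [q])

    def test_mpe_matches_enumeration(self, rng):
        for _ in range(3):
            net = random_dag_network(rng, 6)
            g = unroll(net)
            res = mpe_query(g, Evidence())
            expected, prob = enum_marginal_map(g, query=list(g.order))
            assert res.probability == pytest.approx(prob, abs=1e-9)
            # the attained probability is what matters; ties may differ
            joint_states = {k: res.assignment[k] for k in g.order}
            from dbnpanel.network import joint_probability

            assert joint_probability(g, joint_states) == pytest.approx(
                prob, abs=1e-9
            )


class TestIntervene:
    def test_intervened_node_is_point_mass(self, confounded_triple):
        g = intervene(confounded_triple, InterventionSpec({("X", 0): "x1"}))
        rep = posterior(g, Evidence(), {("X", 0)})
        np.testing.assert_allclose(rep.marginals[("X", 0)], [0.0, 1.0])

    def test_confounded_triple_hand_computation(self, confounded_triple):
        pu = confounded_triple.tables["U"][()].values
        py = confounded_triple.tables["Y"][(("U", 0), ("X", 0))].values
        hand_do = pu[0] * py[0, 1] + pu[1] * py[1, 1]
        got = counterfactual_query(
            confounded_triple, InterventionSpec({("X", 0): "x1"}), ("Y", 0)
        )
        np.testing.assert_allclose(got, hand_do, atol=1e-10)
        g = unroll(confounded_triple)
        see = posterior(
            g, Evidence(hard={("X", 0): "x1"}), {("Y", 0)}
        ).marginals[("Y", 0)]
        assert abs(got[1] - see[1]) >= 0.05  # confounding bias is visible

    def test_intervening_isolated_node_changes_nothing(self):
        vs = [
            VariableSpec("A", ("0", "1"), temporal=False),
            VariableSpec("Z", ("0", "1"), temporal=False),
        ]
        s = TemporalStructure(vs, set(), 1)
        net = DynamicNetwork(
            s,
            {
                "A": {(): ConditionalTable("A", (), np.array([0.3, 0.7]))},
                "Z": {(): ConditionalTable("Z", (), np.array([0.9, 0.1]))},
            },
        )
        base = posterior(unroll(net), Evidence(), {("A", 0)}).marginals[("A", 0)]
        after = counterfactual_query(
            net, InterventionSpec({("Z", 0): "1"}), ("A", 0)
        )
        np.testing.assert_allclose(base, after, atol=1e-12)

    def test_original_network_unmodified(self, confounded_triple):
        g = unroll(confounded_triple)
        before = g.nodes[("X", 0)].cpt.copy()
        intervene(g, InterventionSpec({("X", 0): "x0"}))
        np.testing.assert_array_equal(g.nodes[("X", 0)].cpt, before)
        assert g.nodes[("X", 0)].parents == (("U", 0),)

    def test_idempotent(self, confounded_triple):
        spec = InterventionSpec({("X", 0): "x1"})
        once = intervene(confounded_triple, spec)
        twice = intervene(once, spec)
        assert once.arcs() == twice.arcs()
        for k in once.nodes:
            np.testing.assert_array_equal(once.nodes[k].cpt, twice.nodes[k].cpt)

    def test_absent_node_rejected(self, confounded_triple):
        with pytest.raises(InputError):
            intervene(confounded_triple, InterventionSpec({("X", 3): "x1"}))

    def test_no_backdoor_means_do_equals_see(self):
        # A -> B: intervening on A equals conditioning on A for B
        vs = [
            VariableSpec("A", ("0", "1"), temporal=False),
            VariableSpec("B", ("0", "1"), temporal=False),
        ]
        s = TemporalStructure(vs, {TemporalArc("A", "B", 0)}, 1)
        net = DynamicNetwork(
            s,
            {
                "A": {(): ConditionalTable("A", (), np.array([0.4, 0.6]))},
                "B": {
                    (("A", 0),): ConditionalTable(
                        "B", (("A", 0),), np.array([[0.8, 0.2], [0.1, 0.9]])
                    )
                },
            },
        )
        do = counterfactual_query(net, InterventionSpec({("A", 0): "1"}), ("B", 0))
        see = posterior(
            unroll(net), Evidence(hard={("A", 0): "1"}), {("B", 0)}
        ).marginals[("B", 0)]
        np.testing.assert_allclose(do, see, atol=1e-9)

    def test_matches_truncated_factorization_oracle(self, rng):
        for _ in range(5):
            net = random_dag_network(rng, int(rng.integers(4, 8)))
            g = unroll(net)
            target = g.order[-1]
            doable = [k for k in g.order if k != target]
            k = doable[int(rng.integers(len(doable)))]
            state = str(rng.choice(g.nodes[k].states))
            got = counterfactual_query(net, InterventionSpec({k: state}), target)
            expected = enum_do(g, {k: state}, target)
            np.testing.assert_allclose(got, expected, atol=1e-9)


class TestScenarioAnalysis:
    def test_prior_clamp_has_zero_deltas(self, two_wave_chain):
        g = unroll(two_wave_chain)
        clamp = {
            t: posterior(g, Evidence(), {("B", t)}).marginals[("B", t)]
            for t in range(3)
        }
        rep = scenario_analysis(
            two_wave_chain, "B", "custom", ["A"], clamp=clamp, normal_state="b0"
        )
        for row in rep.rows:
            assert row.delta == pytest.approx(0.0, abs=1e-9)
            assert row.flag == "="

    def test_best_case_raises_small_household_probability(self):
        net = hs_fixture()
        rep = scenario_analysis(net, "T", "best", ["H"], normal_state="N")
        row = rep.row("H", 0, "<=6")
        assert row.delta > 0 and row.flag == "+"

    def test_worst_case_reverses_direction(self):
        net = hs_fixture()
        best = scenario_analysis(net, "T", "best", ["H"], normal_state="N")
        worst = scenario_analysis(net, "T", "worst", ["H"], normal_state="N")
        b = best.row("H", 0, "<=6").delta
        w = worst.row("H", 0, "<=6").delta
        assert b > 0 > w

    def test_worst_case_clamp_zeroes_normal_state(self):
        net = hs_fixture()
        g = unroll(net)
        used = scenario_analysis(net, "T", "worst", ["H"]).clamp
        np.testing.assert_allclose(used[0], [0.0, 1.0, 1.0])
        rep = posterior(
            g,
            Evidence(soft={("T", 0): np.array([0.0, 1.0, 1.0])}),
            {("T", 0)},
        )
        assert rep.marginals[("T", 0)][0] == 0.0

    def test_unnormalizable_clamp_rejected(self, two_wave_chain):
        with pytest.raises(InputError):
            scenario_analysis(
                two_wave_chain,
                "B",
                "custom",
                ["A"],
                clamp=np.zeros(2),
                normal_state="b0",
            )

    def test_missing_normal_state_rejected(self):
        net = hs_fixture()
        with pytest.raises(InputError):
            scenario_analysis(net, "T", "best", ["H"], normal_state="Zzz")

    def test_report_table_format(self):
        net = hs_fixture()
        table = scenario_analysis(net, "T", "best", ["H"]).to_table()
        header, *rows = table.strip().splitlines()
        assert header.split("\t") == [
            "node", "wave", "state", "baseline", "predicted", "delta", "flag",
        ]
        assert len(rows) == 2  # H has two states at one wave


class TestPathwayStrength:
    def test_deterministic_copy_has_strength_one(self):
        vs = [
            VariableSpec("A", ("0", "1"), temporal=False),
            VariableSpec("B", ("0", "1"), temporal=False),
        ]
        s = TemporalStructure(vs, {TemporalArc("A", "B", 0)}, 1)
        net = DynamicNetwork(
            s,
            {
                "A": {(): ConditionalTable("A", (), np.array([0.3, 0.7]))},
                "B": {(("A", 0),): ConditionalTable("B", (("A", 0),), np.eye(2))},
            },
        )
        out = pathway_strength(net, [(("A", 0), ("B", 0))])
        assert out[0]["strength"] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_child_has_strength_one_over_states(self):
        vs = [
            VariableSpec("A", ("0", "1"), temporal=False),
            VariableSpec("B", ("0", "1", "2", "3"), temporal=False),
        ]
        s = TemporalStructure(vs, {TemporalArc("A", "B", 0)}, 1)
        net = DynamicNetwork(
            s,
            {
                "A": {(): ConditionalTable("A", (), np.array([0.3, 0.7]))},
                "B": {
                    (("A", 0),): ConditionalTable(
                        "B", (("A", 0),), np.full((2, 4), 0.25)
                    )
                },
            },
        )
        out = pathway_strength(net, [(("A", 0), ("B", 0))])
        assert out[0]["strength"] == pytest.approx(0.25, abs=1e-12)

    def test_chain_hand_computation(self, confounded_triple):
        # path U -> X -> Y on the confounded triple with known tables
        pu = confounded_triple.tables["U"][()].values
        px = confounded_triple.tables["X"][(("U", 0),)].values
        out = pathway_strength(
            confounded_triple, [(("U", 0), ("X", 0)), (("X", 0), ("Y", 0))]
        )
        u_star = int(np.argmax(pu))
        assert out[0]["parent_map_state"] == ("u0", "u1")[u_star]
        assert out[0]["strength"] == pytest.approx(px[u_star].max(), abs=1e-10)

    def test_bad_paths_rejected(self, confounded_triple):
        with pytest.raises(InputError):
            pathway_strength(confounded_triple, [])
        with pytest.raises(InputError):
            pathway_strength(confounded_triple, [(("X", 0), ("U", 0))])
        with pytest.raises(InputError):
            pathway_strength(
                confounded_triple,
                [(("U", 0), ("X", 0)), (("U", 0), ("Y", 0))],
            )
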
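from __future__ import annotations

import numpy as np
import pytest

from dbnpanel.network import (
    ConditionalTable,
    DynamicNetwork,
    TemporalArc,
    TemporalStructure,
    VariableSpec,
    unroll,
)


def random_tables(structure: TemporalStructure, rng, concentration: float = 1.0):
    """Dirichlet-random conditional tables for every slot combination."""
    tables = {}
    for name, per in structure.table_keys().items():
        card = structure.variables[name].cardinality
        for slots in per:
            shape = tuple(
                structure.variables[p].cardinality for p, _ in slots
            ) + (card,)
            vals = rng.dirichlet(
                np.full(card, concentration), size=shape[:-1] or (1,)
            ).reshape(shape)
            tables.setdefault(name, {})[slots] = ConditionalTable(name, slots, vals)
    return tables


def random_dag_network(
    rng,
    n_nodes: int,
    cards=(2, 3),
    edge_prob: float = 0.4,
    max_cells: int = 50_000,
) -> DynamicNetwork:
    """A random one-wave network with a random DAG and random tables,
    sized so that exhaustive enumeration stays cheap."""
    while True:
        chosen = [int(rng.choice(cards)) for _ in range(n_nodes)]
        if np.prod(chosen) <= max_cells:
            break
        n_nodes -= 1
    names = [f"V{i:02d}" for i in range(len(chosen))]
    variables = [
        VariableSpec(nm, tuple(f"{nm.lower()}s{j}" for j in range(c)), temporal=False)
        for nm, c in zip(names, chosen)
    ]
    order = rng.permutation(len(names))
    arcs = set()
    for i_pos, i in enumerate(order):
        for j in order[i_pos + 1:]:
            if rng.random() < edge_prob:
                arcs.add(TemporalArc(names[i], names[j], 0))
    structure = TemporalStructure(variables, arcs, 1)
    return DynamicNetwork(structure, random_tables(structure, rng))


def random_evidence(rng, ground, n_hard: int = 2, n_soft: int = 1):
    """Random hard and soft evidence over distinct ground nodes."""
    keys = list(ground.order)
    rng.shuffle(keys)
    hard = {}
    soft = {}
    for k in keys[:n_hard]:
        hard[k] = str(rng.choice(ground.nodes[k].states))
    for k in keys[n_hard: n_hard + n_soft]:
        vec = rng.random(ground.nodes[k].cardinality) + 0.05
        soft[k] = vec
    return hard, soft


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def two_wave_chain():
    """A -> B (lag 0) plus B -> B (lag 1) over 3 waves, fixed tables."""
    variables = [
        VariableSpec("A", ("a0", "a1"), temporal=False),
        VariableSpec("B", ("b0", "b1"), temporal=True),
    ]
    arcs = {TemporalArc("A", "B", 0), TemporalArc("B", "B", 1)}
    structure = TemporalStructure(variables, arcs, 3)
    tables = {
        "A": {(): ConditionalTable("A", (), np.array([0.6, 0.4]))},
        "B": {
            (("A", 0),): ConditionalTable(
                "B", (("A", 0),), np.array([[0.8, 0.2], [0.3, 0.7]])
            ),
            (("A", 0), ("B", 1)): ConditionalTable(
                "B",
                (("A", 0), ("B", 1)),
                np.array(
                    [[[0.9, 0.1], [0.4, 0.6]], [[0.5, 0.5], [0.1, 0.9]]]
                ),
            ),
        },
    }
    return DynamicNetwork(structure, tables)


@pytest.fixture
def confounded_triple():
    """U -> X, U -> Y, X -> Y with strong tables (do != see clearly)."""
    variables = [
        VariableSpec("U", ("u0", "u1"), temporal=False),
        VariableSpec("X", ("x0", "x1"), temporal=False),
        VariableSpec("Y", ("y0", "y1"), temporal=False),
    ]
    arcs = {
        TemporalArc("U", "X", 0),
        TemporalArc("U", "Y", 0),
        TemporalArc("X", "Y", 0),
    }
    structure = TemporalStructure(variables, arcs, 1)
    py = np.zeros((2, 2, 2))  # axes (U, X, Y)
    py[0, 0] = [0.9, 0.1]
    py[0, 1] = [0.55, 0.45]
    py[1, 0] = [0.5, 0.5]
    py[1, 1] = [0.05, 0.95]
    tables = {
        "U": {(): ConditionalTable("U", (), np.array([0.35, 0.65]))},
        "X": {
            (("U", 0),): ConditionalTable(
                "X", (("U", 0),), np.array([[0.92, 0.08], [0.1, 0.9]])
            )
        },
        "Y": {
            (("U", 0), ("X", 0)): ConditionalTable(
                "Y", (("U", 0), ("X", 0)), py
            )
        },
    }
    return DynamicNetwork(structure, tables)


@pytest.fixture
def recovery_truth():
    """Known 5-variable, 2-wave network for parameter-recovery tests.

    Table entries are kept away from 0/1 so every row is identifiable.
    """
    rng = np.random.default_rng(7)
    variables = [
        VariableSpec("A", ("a0", "a1")),
        VariableSpec("B", ("b0", "b1")),
        VariableSpec("C", ("c0", "c1", "c2")),
        VariableSpec("D", ("d0", "d1")),
        VariableSpec("E", ("e0", "e1")),
    ]
    arcs = {
        TemporalArc("A", "B", 0),
        TemporalArc("B", "C", 0),
        TemporalArc("C", "D", 0),
        TemporalArc("D", "E", 0),
        TemporalArc("A", "A", 1),
        TemporalArc("C", "C", 1),
    }
    structure = TemporalStructure(variables, arcs, 2)
    tables = {}
    for name, per in structure.table_keys().items():
        card = structure.variables[name].cardinality
        for slots in per:
            shape = tuple(
                structure.variables[p].cardinality for p, _ in slots
            ) + (card,)
            vals = rng.dirichlet(np.full(card, 0.8), size=shape[:-1] or (1,))
            vals = vals.reshape(shape)
            vals = 0.9 * vals + 0.1 / card
            tables.setdefault(name, {})[slots] = ConditionalTable(name, slots, vals)
    return DynamicNetwork(structure, tables)
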
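"""Independent brute-force oracles used to cross-check the package.

Everything here works by exhaustive enumeration of complete assignments
with direct table lookups — no variable elimination, no log-space
tricks — so agreement with the package is a genuine dual-route check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _iter_assignments(ground):
    keys = list(ground.order)
    cards = [ground.nodes[k].cardinality for k in keys]
    for combo in itertools.product(*(range(c) for c in cards)):
        yield dict(zip(keys, combo))


def _assignment_prob(ground, idx):
    p = 1.0
    for k, node in ground.nodes.items():
        sel = tuple(idx[par] for par in node.parents) + (idx[k],)
        p *= float(node.cpt[sel])
    return p


def _evidence_weight(ground, idx, hard_idx, soft):
    for k, i in hard_idx.items():
        if idx[k] != i:
            return 0.0
    w = 1.0
    for k, vec in soft.items():
        w *= float(vec[idx[k]])
    return w


def enum_posterior(ground, hard=None, soft=None, query=()):
    """(per-node normalized marginals dict, log evidence)."""
    hard = hard or {}
    soft = {k: np.asarray(v, float) for k, v in (soft or {}).items()}
    hard_idx = {k: ground.nodes[k].states.index(s) for k, s in hard.items()}
    query = list(query)
    vecs = {q: np.zeros(ground.nodes[q].cardinality) for q in query}
    z = 0.0
    for idx in _iter_assignments(ground):
        w = _evidence_weight(ground, idx, hard_idx, soft)
        if w == 0.0:
            continue
        p = _assignment_prob(ground, idx) * w
        z += p
        for q in query:
            vecs[q][idx[q]] += p
    marginals = {q: v / z for q, v in vecs.items()} if z > 0 else vecs
    return marginals, (math.log(z) if z > 0 else -math.inf)


def enum_loglik(ground, hard):
    _, logz = enum_posterior(ground, hard=hard)
    return logz


def enum_marginal_map(ground, hard=None, soft=None, query=()):
    """Best joint configuration of the query nodes (others summed out).

    Ties resolved toward the lexicographically smallest index tuple.
    Returns (assignment dict of state labels, normalized probability).
    """
    hard = hard or {}
    soft = {k: np.asarray(v, float) for k, v in (soft or {}).items()}
    hard_idx = {k: ground.nodes[k].states.index(s) for k, s in hard.items()}
    query = sorted(query)
    mass: dict[tuple, float] = {}
    z = 0.0
    for idx in _iter_assignments(ground):
        w = _evidence_weight(ground, idx, hard_idx, soft)
        if w == 0.0:
            continue
        p = _assignment_prob(ground, idx) * w
        z += p
        key = tuple(idx[q] for q in query)
        mass[key] = mass.get(key, 0.0) + p
    best = min(mass, key=lambda k: (-mass[k], k))
    assignment = {
        q: ground.nodes[q].states[i] for q, i in zip(query, best)
    }
    return assignment, mass[best] / z


def enum_do(ground, interventions, outcome):
    """P(outcome | do(...)) by truncated-factorization enumeration."""
    do_idx = {
        k: ground.nodes[k].states.index(s) for k, s in interventions.items()
    }
    vec = np.zeros(ground.nodes[outcome].cardinality)
    for idx in _iter_assignments(ground):
        if any(idx[k] != i for k, i in do_idx.items()):
            continue
        p = 1.0
        for k, node in ground.nodes.items():
            if k in do_idx:
                continue  # intervened factors dropped from the product
            sel = tuple(idx[par] for par in node.parents) + (idx[k],)
            p *= float(node.cpt[sel])
        vec[idx[outcome]] += p
    return vec / vec.sum()
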
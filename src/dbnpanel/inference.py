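"""Exact posterior inference on the unrolled network.

Sum-product variable elimination with a min-fill elimination order, all
arithmetic in log space with log-sum-exp reductions.  Hard evidence is
applied by slicing factor axes; soft (virtual) evidence contributes an
extra likelihood factor.  Smoothing is automatic: evidence at later
waves influences earlier-wave queries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import PanelDataset
from .errors import ImpossibleEvidenceError, InputError
from .network import GroundKey, GroundNetwork

LOG_ZERO_FLOOR = math.log(1e-300)  # below this, evidence is deemed impossible

__all__ = [
    "Evidence",
    "PosteriorReport",
    "posterior",
    "joint_posterior",
    "impute",
    "record_loglik",
    "anomaly_scores",
]


# ----------------------------------------------------------------------
# evidence
# ----------------------------------------------------------------------

class Evidence:
    """Hard states and/or soft likelihood vectors per ``(variable, wave)``."""

    def __init__(
        self,
        hard: dict[GroundKey, str] | None = None,
        soft: dict[GroundKey, np.ndarray] | None = None,
    ) -> None:
        self.hard = dict(hard or {})
        self.soft = {k: np.asarray(v, dtype=float) for k, v in (soft or {}).items()}
        overlap = set(self.hard) & set(self.soft)
        if overlap:
            raise InputError(f"nodes with both hard and soft evidence: {sorted(overlap)}")

    def check(self, ground: GroundNetwork) -> None:
        for k, label in self.hard.items():
            if k not in ground.nodes:
                raise InputError(f"evidence on unknown ground node {k}")
            if label not in ground.nodes[k].states:
                raise InputError(f"evidence state {label!r} invalid for {k}")
        for k, vec in self.soft.items():
            if k not in ground.nodes:
                raise InputError(f"soft evidence on unknown ground node {k}")
            if vec.shape != (ground.nodes[k].cardinality,):
                raise InputError(
                    f"soft evidence vector for {k} has length {vec.shape}, "
                    f"expected {ground.nodes[k].cardinality}"
                )
            if np.any(vec < 0) or not np.any(vec > 0):
                raise InputError(f"soft evidence for {k} must be non-negative, not all zero")

    def is_empty(self) -> bool:
        return not self.hard and not self.soft

    def union(self, other: "Evidence") -> "Evidence":
        h = {**self.hard, **other.hard}
        s = {**self.soft, **other.soft}
        return Evidence(h, s)


@dataclass
class PosteriorReport:
    """Per-query-node posterior distributions plus log P(evidence)."""

    marginals: dict[GroundKey, np.ndarray]
    states: dict[GroundKey, tuple[str, ...]]
    log_evidence: float

    def distribution(self, key: GroundKey) -> dict[str, float]:
        return dict(zip(self.states[key], self.marginals[key].tolist()))

    def probability(self, key: GroundKey, state: str) -> float:
        return float(self.marginals[key][self.states[key].index(state)])


# ----------------------------------------------------------------------
# log-space factors
# ----------------------------------------------------------------------

@dataclass
class LogFactor:
    scope: tuple[GroundKey, ...]
    values: np.ndarray  # log-space, shape = cardinalities along scope


def _node_factor(ground: GroundNetwork, key: GroundKey) -> LogFactor:
    node = ground.nodes[key]
    with np.errstate(divide="ignore"):
        vals = np.log(node.cpt)
    return LogFactor(node.parents + (key,), vals)


def _reduce_hard(f: LogFactor, idx: dict[GroundKey, int]) -> LogFactor:
    keep, slicer = [], []
    for k in f.scope:
        if k in idx:
            slicer.append(idx[k])
        else:
            slicer.append(slice(None))
            keep.append(k)
    return LogFactor(tuple(keep), f.values[tuple(slicer)])


def _combine(f1: LogFactor, f2: LogFactor) -> LogFactor:
    scope = tuple(sorted(set(f1.scope) | set(f2.scope)))
    pos = {k: i for i, k in enumerate(scope)}

    def aligned(f: LogFactor) -> np.ndarray:
        # permute axes into union-scope order, inserting broadcast axes
        shape = [1] * len(scope)
        perm = sorted(range(len(f.scope)), key=lambda i: pos[f.scope[i]])
        src = np.transpose(f.values, perm) if f.scope else f.values
        ordered = tuple(sorted(f.scope, key=lambda k: pos[k]))
        j = 0
        for i, k in enumerate(scope):
            if j < len(ordered) and ordered[j] == k:
                shape[i] = src.shape[j]
                j += 1
        return src.reshape(shape)

    return LogFactor(scope, aligned(f1) + aligned(f2))


def _marginalize(f: LogFactor, key: GroundKey) -> LogFactor:
    ax = f.scope.index(key)
    vals = logsumexp(f.values, axis=ax)
    return LogFactor(f.scope[:ax] + f.scope[ax + 1:], np.asarray(vals))


def _min_fill_order(factors: list[LogFactor], eliminate: set[GroundKey]) -> list[GroundKey]:
    """Min-fill heuristic on the interaction graph; ties broken by
    lexicographic (variable, wave) order for determinism."""
    neighbors: dict[GroundKey, set[GroundKey]] = {}
    for f in factors:
        for k in f.scope:
            neighbors.setdefault(k, set()).update(x for x in f.scope if x != k)
    for k in eliminate:
        neighbors.setdefault(k, set())
    order: list[GroundKey] = []
    remaining = set(eliminate)
    while remaining:
        best, best_fill = None, None
        for k in sorted(remaining):
            nbrs = [n for n in neighbors.get(k, ()) if n != k]
            fill = 0
            for i, a in enumerate(nbrs):
                for b in nbrs[i + 1:]:
                    if b not in neighbors.get(a, ()):
                        fill += 1
            if best_fill is None or fill < best_fill:
                best, best_fill = k, fill
        assert best is not None
        order.append(best)
        remaining.discard(best)
        nbrs = {n for n in neighbors.pop(best, set()) if n != best}
        for a in nbrs:
            neighbors[a].discard(best)
            neighbors[a].update(nbrs - {a})
    return order


def _eliminate(factors: list[LogFactor], eliminate: set[GroundKey]) -> list[LogFactor]:
    """Sum out every key in ``eliminate``; returns the remaining factors
    (plus scalar factors from fully-eliminated components)."""
    factors = list(factors)
    for key in _min_fill_order(factors, eliminate):
        involved = [f for f in factors if key in f.scope]
        rest = [f for f in factors if key not in f.scope]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = _combine(prod, f)
        factors = rest + [_marginalize(prod, key)]
    return factors


def _scalar_total(factors: list[LogFactor]) -> float:
    return float(sum(float(f.values) for f in factors if not f.scope))


def _prepare_factors(ground: GroundNetwork, evidence: Evidence) -> tuple[list[LogFactor], dict[GroundKey, int]]:
    evidence.check(ground)
    hard_idx = {
        k: ground.nodes[k].states.index(s) for k, s in evidence.hard.items()
    }
    factors = [
        _reduce_hard(_node_factor(ground, k), hard_idx) for k in ground.order
    ]
    for k, vec in evidence.soft.items():
        with np.errstate(divide="ignore"):
            lf = LogFactor((k,), np.log(vec))
        factors.append(_reduce_hard(lf, hard_idx))
    return factors, hard_idx


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------

def _log_evidence(factors: list[LogFactor]) -> float:
    keys = set().union(*(set(f.scope) for f in factors)) if factors else set()
    done = _eliminate(factors, keys)
    return _scalar_total(done)


def posterior(
    ground: GroundNetwork,
    evidence: Evidence,
    query: set[GroundKey] | list[GroundKey] | tuple[GroundKey, ...],
) -> PosteriorReport:
    """P(node | evidence) for each query node, plus log P(evidence).

    Raises :class:`ImpossibleEvidenceError` when the evidence probability
    falls below the hard floor (contradictory evidence), which is
    distinguishable from ordinary underflow because all internal
    arithmetic is in log space.
    """
    query = sorted(set(query))
    for q in query:
        if q not in ground.nodes:
            raise InputError(f"query on unknown ground node {q}")
    factors, hard_idx = _prepare_factors(ground, evidence)
    log_z = _log_evidence(factors)
    if log_z < LOG_ZERO_FLOOR:
        raise ImpossibleEvidenceError(
            f"evidence has log-probability {log_z} (below floor)"
        )
    marginals: dict[GroundKey, np.ndarray] = {}
    states = {q: ground.nodes[q].states for q in query}
    for q in query:
        if q in hard_idx:
            vec = np.zeros(ground.nodes[q].cardinality)
            vec[hard_idx[q]] = 1.0
            marginals[q] = vec
            continue
        keys = set().union(*(set(f.scope) for f in factors)) - {q}
        rest = _eliminate(factors, keys)
        logvec = np.zeros(ground.nodes[q].cardinality)
        for f in rest:
            if not f.scope:
                logvec = logvec + float(f.values)
            elif f.scope == (q,):
                logvec = logvec + f.values
            else:  # pragma: no cover - elimination leaves only q-scoped factors
                raise AssertionError("unexpected residual factor scope")
        marginals[q] = np.exp(logvec - logsumexp(logvec))
    return PosteriorReport(marginals=marginals, states=states, log_evidence=log_z)


def joint_posterior(
    ground: GroundNetwork,
    evidence: Evidence,
    nodes: list[GroundKey] | tuple[GroundKey, ...],
) -> tuple[tuple[GroundKey, ...], np.ndarray, float]:
    """Joint posterior over ``nodes`` (sorted) given evidence.

    Returns ``(sorted nodes, probability array, log P(evidence))``.
    Hard-evidenced nodes may be included; their axis is a point mass.
    """
    nodes = tuple(sorted(set(nodes)))
    factors, hard_idx = _prepare_factors(ground, evidence)
    keys = set().union(*(set(f.scope) for f in factors)) - set(nodes)
    rest = _eliminate(factors, keys)
    joint = LogFactor((), np.asarray(0.0))
    for f in rest:
        joint = _combine(joint, f)
    # expand to the full requested scope (hard-evidenced nodes re-inserted)
    full_shape = tuple(ground.nodes[k].cardinality for k in nodes)
    out = np.full(full_shape, -np.inf)
    slicer = []
    for k in nodes:
        if k in joint.scope:
            slicer.append(slice(None))
        elif k in hard_idx:
            slicer.append(hard_idx[k])
        else:
            raise AssertionError(f"node {k} lost during elimination")
    src = joint.values
    # align joint scope order to requested order of its members
    members = [k for k in nodes if k in joint.scope]
    if members:
        perm = [joint.scope.index(k) for k in members]
        src = np.transpose(joint.values, perm)
    out[tuple(slicer)] = src
    log_z = float(logsumexp(out))
    if log_z < LOG_ZERO_FLOOR:
        raise ImpossibleEvidenceError(
            f"evidence has log-probability {log_z} (below floor)"
        )
    return nodes, np.exp(out - log_z), log_z


def impute(
    ground: GroundNetwork,
    observed: dict[GroundKey, str],
    missing: list[GroundKey] | None = None,
) -> dict[GroundKey, np.ndarray]:
    """Posterior distribution for every missing cell of one record.

    ``missing`` defaults to all ground nodes not present in ``observed``.
    Each entry is a full distribution, not a single filled value.
    """
    if missing is None:
        missing = [k for k in ground.order if k not in observed]
    if not missing:
        return {}
    rep = posterior(ground, Evidence(hard=observed), set(missing))
    return rep.marginals


def record_loglik(ground: GroundNetwork, observed: dict[GroundKey, str]) -> float:
    """log P(observed cells), marginalizing all unobserved cells.

    A fully missing record has probability 1 (returns 0.0); a complete
    record reduces to the log joint probability.
    """
    if not observed:
        return 0.0
    factors, _ = _prepare_factors(ground, Evidence(hard=observed))
    return _log_evidence(factors)


def anomaly_scores(
    ground: GroundNetwork,
    dataset: PanelDataset,
    flag_quantile: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject anomaly score (negative record log-likelihood) + flag.

    Subjects whose score is strictly above the empirical
    ``1 - flag_quantile`` quantile are flagged.
    """
    if not (0.0 < flag_quantile < 0.5):
        raise InputError("flag_quantile must be in (0, 0.5)")
    if dataset.n_subjects == 0:
        raise InputError("empty dataset")
    scores = np.empty(dataset.n_subjects)
    cache: dict[bytes, float] = {}
    for i in range(dataset.n_subjects):
        key = dataset.codes[i].tobytes()
        if key not in cache:
            cache[key] = record_loglik(ground, dataset.record_evidence(i))
        scores[i] = -cache[key]
    threshold = float(np.quantile(scores, 1.0 - flag_quantile))
    flags = scores > threshold
    return scores, flags
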
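"""MAP queries, do-operator interventions, counterfactual scenarios, and
causal-pathway strength reports.

Interventions follow the truncated factorization: the intervened ground
node's incoming arcs are severed and its table replaced by a point mass.
Scenario analysis clamps the target (hard evidence for the best case,
soft evidence pooling the non-normal states for the worst case) and
reports per-node posterior shifts against the evidence-free baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .inference import Evidence, PosteriorReport, joint_posterior, posterior
from .network import DynamicNetwork, GroundKey, GroundNetwork, GroundNode, unroll

__all__ = [
    "MapResult",
    "InterventionSpec",
    "ScenarioReport",
    "map_query",
    "mpe_query",
    "intervene",
    "counterfactual_query",
    "scenario_analysis",
    "pathway_strength",
]

MAX_QUERY_CELLS = 4_000_000  # guard on the materialized query joint


@dataclass
class MapResult:
    """Top assignment(s) over the query nodes and their posterior mass."""

    assignment: dict[GroundKey, str]
    probability: float
    top: list[tuple[dict[GroundKey, str], float]] = field(default_factory=list)
    log_evidence: float = 0.0


def map_query(
    ground: GroundNetwork,
    evidence: Evidence,
    query: set[GroundKey] | list[GroundKey] | tuple[GroundKey, ...],
    k: int = 1,
) -> MapResult:
    """Marginal MAP: the most probable joint configuration of the query
    nodes given evidence, with all other unobserved nodes marginalized.

    Nuisance nodes are summed out by variable elimination; the remaining
    joint over the query nodes is maximized directly.  Ties are broken
    lexicographically by state order (the first maximum in row-major
    order).  ``k > 1`` returns the k best configurations, non-increasing
    in probability.
    """
    query = tuple(sorted(set(query)))
    if not query:
        raise InputError("query must be nonempty")
    hard = set(evidence.hard)
    clash = set(query) & hard
    if clash:
        raise InputError(f"query nodes carry hard evidence: {sorted(clash)}")
    cells = 1
    for q in query:
        if q not in ground.nodes:
            raise InputError(f"query on unknown ground node {q}")
        cells *= ground.nodes[q].cardinality
    if cells > MAX_QUERY_CELLS:
        raise InputError(
            f"query joint has {cells} cells (> {MAX_QUERY_CELLS}); reduce the query"
        )
    nodes, joint, log_z = joint_posterior(ground, evidence, query)
    flat = joint.ravel()
    if k <= 1:
        order = [int(np.argmax(flat))]
    else:
        k = min(k, flat.size)
        part = np.argpartition(-flat, k - 1)[:k]
        order = sorted(part.tolist(), key=lambda i: (-flat[i], i))

    def unflatten(i: int) -> dict[GroundKey, str]:
        idx = np.unravel_index(i, joint.shape)
        return {
            nd: ground.nodes[nd].states[int(j)] for nd, j in zip(nodes, idx)
        }

    top = [(unflatten(i), float(flat[i])) for i in order]
    return MapResult(
        assignment=top[0][0],
        probability=top[0][1],
        top=top,
        log_evidence=log_z,
    )


def mpe_query(ground: GroundNetwork, evidence: Evidence) -> MapResult:
    """Full most-probable-explanation over every unobserved node, by
    max-product variable elimination with traceback."""
    from .inference import _eliminate, _min_fill_order, _prepare_factors, LogFactor

    factors, hard_idx = _prepare_factors(ground, evidence)
    eliminate = set().union(*(set(f.scope) for f in factors)) if factors else set()
    order = _min_fill_order(factors, eliminate)
    tracebacks: list[tuple[GroundKey, tuple[GroundKey, ...], np.ndarray]] = []
    live = list(factors)
    for key in order:
        involved = [f for f in live if key in f.scope]
        rest = [f for f in live if key not in f.scope]
        prod = involved[0]
        for f in involved[1:]:
            from .inference import _combine

            prod = _combine(prod, f)
        ax = prod.scope.index(key)
        argmax = np.argmax(prod.values, axis=ax)
        maxed = np.max(prod.values, axis=ax)
        tracebacks.append((key, prod.scope[:ax] + prod.scope[ax + 1:], argmax))
        live = rest + [LogFactor(prod.scope[:ax] + prod.scope[ax + 1:], maxed)]
    log_p = float(sum(float(f.values) for f in live if not f.scope))
    assignment_idx: dict[GroundKey, int] = dict(hard_idx)
    for key, scope, argmax in reversed(tracebacks):
        sel = tuple(assignment_idx[s] for s in scope)
        assignment_idx[key] = int(argmax[sel] if scope else argmax)
    assignment = {
        k: ground.nodes[k].states[i] for k, i in assignment_idx.items()
    }
    return MapResult(
        assignment=assignment,
        probability=float(math.exp(log_p)),
        top=[(assignment, float(math.exp(log_p)))],
        log_evidence=log_p,
    )


# ----------------------------------------------------------------------
# interventions
# ----------------------------------------------------------------------

@dataclass
class InterventionSpec:
    """Forced states per ground node: do(X = x)."""

    interventions: dict[GroundKey, str]

    def __post_init__(self) -> None:
        if not self.interventions:
            raise InputError("intervention spec is empty")


def intervene(net: DynamicNetwork | GroundNetwork, spec: InterventionSpec) -> GroundNetwork:
    """Graph surgery: sever incoming arcs of each intervened ground node
    and replace its table by a point mass on the forced state.  The input
    network is left unmodified."""
    ground = net if isinstance(net, GroundNetwork) else unroll(net)
    for key, state in spec.interventions.items():
        if key not in ground.nodes:
            raise InputError(
                f"intervention on structurally absent ground node {key}"
            )
        if state not in ground.nodes[key].states:
            raise InputError(f"forced state {state!r} invalid for {key}")
    new_nodes: dict[GroundKey, GroundNode] = {}
    for key, node in ground.nodes.items():
        if key in spec.interventions:
            cpt = np.zeros(node.cardinality)
            cpt[node.states.index(spec.interventions[key])] = 1.0
            new_nodes[key] = GroundNode(
                name=node.name,
                wave=node.wave,
                states=node.states,
                parents=(),
                cpt=cpt,
            )
        else:
            new_nodes[key] = GroundNode(
                name=node.name,
                wave=node.wave,
                states=node.states,
                parents=node.parents,
                cpt=node.cpt,
            )
    return GroundNetwork(new_nodes, ground.horizon)


def counterfactual_query(
    net: DynamicNetwork | GroundNetwork,
    spec: InterventionSpec,
    outcome: GroundKey,
    evidence: Evidence | None = None,
) -> np.ndarray:
    """P(outcome | do(interventions), evidence): posterior on the
    mutilated network."""
    mutilated = intervene(net, spec)
    rep = posterior(mutilated, evidence or Evidence(), {outcome})
    return rep.marginals[outcome]


# ----------------------------------------------------------------------
# scenario analysis
# ----------------------------------------------------------------------

@dataclass
class ScenarioRow:
    node: str
    wave: int
    state: str
    baseline: float
    predicted: float

    @property
    def delta(self) -> float:
        return self.predicted - self.baseline

    @property
    def flag(self) -> str:
        if self.delta > 0:
            return "+"
        if self.delta < 0:
            return "-"
        return "="


@dataclass
class ScenarioReport:
    scenario: str
    target: str
    clamp: dict[int, np.ndarray]  # per-wave likelihood over target states
    rows: list[ScenarioRow]

    def to_table(self) -> str:
        lines = ["node\twave\tstate\tbaseline\tpredicted\tdelta\tflag"]
        for r in self.rows:
            lines.append(
                f"{r.node}\t{r.wave}\t{r.state}\t{r.baseline:.6f}\t"
                f"{r.predicted:.6f}\t{r.delta:+.6f}\t{r.flag}"
            )
        return "\n".join(lines) + "\n"

    def row(self, node: str, wave: int, state: str) -> ScenarioRow:
        for r in self.rows:
            if (r.node, r.wave, r.state) == (node, wave, state):
                return r
        raise KeyError((node, wave, state))


def _scenario_evidence(
    ground: GroundNetwork,
    target: str,
    scenario: str,
    clamp: dict[int, np.ndarray] | np.ndarray | None,
    normal_state: str,
) -> tuple[Evidence, dict[int, np.ndarray]]:
    target_waves = sorted(t for (n, t) in ground.nodes if n == target)
    if not target_waves:
        raise InputError(f"target {target!r} has no ground nodes")
    states = ground.nodes[(target, target_waves[0])].states
    card = len(states)
    if normal_state not in states:
        raise InputError(
            f"target {target!r} has no designated state {normal_state!r}"
        )
    n_idx = states.index(normal_state)
    hard: dict[GroundKey, str] = {}
    soft: dict[GroundKey, np.ndarray] = {}
    used: dict[int, np.ndarray] = {}
    for t in target_waves:
        if scenario == "best":
            hard[(target, t)] = normal_state
            vec = np.zeros(card)
            vec[n_idx] = 1.0
        elif scenario == "worst":
            # the non-normal states pooled; a uniform likelihood preserves
            # their relative prior proportions
            vec = np.ones(card)
            vec[n_idx] = 0.0
            soft[(target, t)] = vec
        elif scenario == "custom":
            if clamp is None:
                raise InputError("custom scenario needs a clamp")
            vec = np.asarray(
                clamp[t] if isinstance(clamp, dict) else clamp, dtype=float
            )
            if vec.shape != (card,) or np.any(vec < 0) or not np.any(vec > 0):
                raise InputError(
                    f"custom clamp for wave {t} is not normalizable over "
                    f"{card} states"
                )
            # convert the desired target distribution into a likelihood
            # ratio against the baseline marginal, so clamping the target
            # to its own prior is a no-op
            base = posterior(ground, Evidence(), {(target, t)}).marginals[
                (target, t)
            ]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(base > 0, vec / np.maximum(base, 1e-300), 0.0)
            soft[(target, t)] = ratio
        else:
            raise InputError("scenario must be 'best', 'worst' or 'custom'")
        used[t] = vec
    return Evidence(hard=hard, soft=soft), used


def scenario_analysis(
    net: DynamicNetwork | GroundNetwork,
    target: str,
    scenario: str,
    report_nodes: set[str] | list[str],
    clamp: dict[int, np.ndarray] | np.ndarray | None = None,
    normal_state: str = "N",
) -> ScenarioReport:
    """Best-/worst-case counterfactual scenario on the target variable.

    ``best`` clamps the target to its designated normal state at every
    wave where it exists (hard evidence); ``worst`` gives the normal
    state zero likelihood and the remaining states a uniform likelihood;
    ``custom`` applies a caller-supplied likelihood vector.  Reports each
    requested node's posterior per wave with deltas against the
    evidence-free baseline and an increase/decrease flag.
    """
    ground = net if isinstance(net, GroundNetwork) else unroll(net)
    evidence, used = _scenario_evidence(ground, target, scenario, clamp, normal_state)
    report_keys = sorted(
        k for k in ground.nodes if k[0] in set(report_nodes) and k[0] != target
    )
    baseline = posterior(ground, Evidence(), report_keys)
    predicted = posterior(ground, evidence, report_keys)
    rows: list[ScenarioRow] = []
    for key in report_keys:
        for i, state in enumerate(ground.nodes[key].states):
            rows.append(
                ScenarioRow(
                    node=key[0],
                    wave=key[1],
                    state=state,
                    baseline=float(baseline.marginals[key][i]),
                    predicted=float(predicted.marginals[key][i]),
                )
            )
    return ScenarioReport(scenario=scenario, target=target, clamp=used, rows=rows)


# ----------------------------------------------------------------------
# pathway strength
# ----------------------------------------------------------------------

def pathway_strength(
    net: DynamicNetwork,
    path: list[tuple[GroundKey, GroundKey]],
    evidence: Evidence | None = None,
) -> list[dict]:
    """Per-arc strength of a causal pathway.

    For each ground arc A -> B the strength is ``max_b P(B = b | A = a*,
    evidence)`` where ``a*`` is A's most probable state under the
    evidence — a declared convention standing in for the unpublished
    internals behind the reported edge probabilities.
    """
    ground = unroll(net)
    evidence = evidence or Evidence()
    if not path:
        raise InputError("path is empty")
    for (a, b), (c, _) in zip(path, path[1:]):
        if b != c:
            raise InputError(f"path arcs do not chain: {b} followed by {c}")
    arcs = ground.arcs()
    out = []
    for a, b in path:
        if (a, b) not in arcs:
            raise InputError(f"arc {a} -> {b} not in the network structure")
        a_post = posterior(ground, evidence, {a}).marginals[a]
        a_star = ground.nodes[a].states[int(np.argmax(a_post))]
        cond = Evidence(
            hard={**evidence.hard, a: a_star},
            soft={k: v for k, v in evidence.soft.items() if k != a},
        )
        b_post = posterior(ground, cond, {b}).marginals[b]
        j = int(np.argmax(b_post))
        out.append(
            {
                "parent": a,
                "child": b,
                "parent_map_state": a_star,
                "child_mode_state": ground.nodes[b].states[j],
                "strength": float(b_post[j]),
            }
        )
    return out


def pathway_table(records: list[dict]) -> str:
    lines = ["parent\tchild\tparent_map_state\tchild_mode_state\tstrength"]
    for r in records:
        pa, pb = r["parent"], r["child"]
        lines.append(
            f"{pa[0]}@{pa[1]}\t{pb[0]}@{pb[1]}\t{r['parent_map_state']}\t"
            f"{r['child_mode_state']}\t{r['strength']:.6f}"
        )
    return "\n".join(lines) + "\n"
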
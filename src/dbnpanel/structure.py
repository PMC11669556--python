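"""Constraint-based structure learning over the temporal template.

The learner runs the PC algorithm over ``(variable, lag)`` nodes: lag-0
nodes carry undirected candidate edges; lagged nodes (self-lags by
default, plus explicitly configured cross-lags) connect to the current
wave with a fixed past-to-present orientation (temporal tiering).
Conditional independence is decided by a G-squared likelihood-ratio test
on wave-pooled complete cases.  Everything is made deterministic: edges,
conditioning sets and orientation passes are visited in sorted order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .data import PanelDataset
from .errors import ConstraintConflictError, InputError
from .network import Slot, TemporalArc, TemporalStructure, VariableSpec

__all__ = [
    "ConstraintSet",
    "CITestResult",
    "PDAGResult",
    "ci_test_g2",
    "pc_learn",
    "bic_score",
    "count_graph_structures",
]

# causal tier per variable category; fallback orientation points from a
# lower tier to a higher one (ties broken lexicographically)
DEFAULT_TIERS = {
    "CA": 0, "CS": 0,                                   # child level
    "MSW": 1, "DA": 1, "DE": 1, "MA": 1, "ME": 1,       # parent level
    "HS": 2, "WQ": 2, "FS": 2, "HHA": 2, "HHS": 2,      # household level
    "PS": 3,                                            # intervention
    "CNS": 4,                                           # outcome/target
}


@dataclass
class ConstraintSet:
    """Expert whitelist/blacklist over candidate temporal arcs."""

    forbidden: set[TemporalArc] = field(default_factory=set)
    required: set[TemporalArc] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.forbidden = set(self.forbidden)
        self.required = set(self.required)
        clash = self.forbidden & self.required
        if clash:
            raise ConstraintConflictError(
                f"arcs both forbidden and required: {sorted(clash)}"
            )
        # required arcs must leave the lag-0 subgraph acyclic
        lag0 = [a for a in self.required if a.lag == 0]
        names = {a.parent for a in lag0} | {a.child for a in lag0}
        specs = [VariableSpec(n, ("x0", "x1")) for n in sorted(names)]
        try:
            TemporalStructure(specs, set(lag0), 1)
        except Exception as exc:
            raise ConstraintConflictError(
                f"required arcs create a lag-0 cycle: {exc}"
            ) from exc

    def to_text(self) -> str:
        lines = ["directive\tparent\tchild\tlag"]
        for a in sorted(self.forbidden):
            lines.append(f"forbid\t{a.parent}\t{a.child}\t{a.lag}")
        for a in sorted(self.required):
            lines.append(f"require\t{a.parent}\t{a.child}\t{a.lag}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ConstraintSet":
        forbidden, required = set(), set()
        for i, line in enumerate(text.strip().splitlines()):
            if not line.strip() or line.startswith("directive"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise InputError(f"constraint line {i + 1} malformed: {line!r}")
            directive, parent, child, lag = parts
            arc = TemporalArc(parent, child, int(lag))
            if directive == "forbid":
                forbidden.add(arc)
            elif directive == "require":
                required.add(arc)
            else:
                raise InputError(f"unknown directive {directive!r} on line {i + 1}")
        return cls(forbidden=forbidden, required=required)


@dataclass
class CITestResult:
    x: Slot
    y: Slot
    s: tuple[Slot, ...]
    statistic: float
    df: int
    p_value: float
    alpha: float
    independent: bool
    reliable: bool
    n: int

    def log_row(self) -> str:
        s = ";".join(f"{v}@{lag}" for v, lag in self.s) or "-"
        return (
            f"{self.x[0]}@{self.x[1]}\t{self.y[0]}@{self.y[1]}\t{s}\t"
            f"{self.statistic:.6g}\t{self.df}\t{self.p_value:.6g}\t"
            f"{'independent' if self.independent else 'dependent'}\t"
            f"{'ok' if self.reliable else 'unreliable'}"
        )


@dataclass
class PDAGResult:
    nodes: tuple[Slot, ...]
    skeleton: set[frozenset]
    compelled: set[tuple[Slot, Slot]]     # CPDAG directed part
    dag_arcs: set[TemporalArc]            # final DAG after fallback
    tests: list[CITestResult]
    orientation_log: list[tuple[str, str]]  # (arc "u -> v", reason)
    conflicts: list[str]

    def ci_log_table(self) -> str:
        header = "x\ty\tconditioning\tG2\tdf\tp\tdecision\treliability"
        return "\n".join([header] + [t.log_row() for t in self.tests]) + "\n"


# ----------------------------------------------------------------------
# design matrix: wave-pooled complete cases over (variable, lag) nodes
# ----------------------------------------------------------------------

def _design_matrix(data: PanelDataset, nodes: list[Slot]) -> np.ndarray:
    cols = []
    t_min = 0
    for name, lag in nodes:
        v = data.variables[data.var_index[name]]
        t_min = max(t_min, lag + v.first_wave)
    if t_min > data.waves - 1:
        return np.empty((0, len(nodes)), dtype=np.int64)
    blocks = []
    for t in range(t_min, data.waves):
        cols = [
            data.codes[:, t - lag, data.var_index[name]] for name, lag in nodes
        ]
        stacked = np.stack(cols, axis=1).astype(np.int64)
        mask = np.all(stacked >= 0, axis=1)
        blocks.append(stacked[mask])
    return np.concatenate(blocks, axis=0)


def _cardinality(data: PanelDataset, node: Slot) -> int:
    return data.variables[data.var_index[node[0]]].cardinality


def ci_test_g2(
    data: PanelDataset,
    x: Slot,
    y: Slot,
    s: tuple[Slot, ...] | list[Slot] = (),
    alpha: float = 0.01,
    min_counts_per_df: float = 5.0,
) -> CITestResult:
    """G-squared conditional independence test of ``x`` and ``y`` given ``s``.

    The statistic sums ``2 * obs * log(obs / expected)`` over the x-by-y
    table within each stratum of ``s``; strata with fewer than two
    occupied rows or columns are degenerate and contribute neither to the
    statistic nor to the degrees of freedom.  Tests with fewer complete
    cases than ``min_counts_per_df`` times the nominal df are marked
    unreliable and decided as independent (edge not added).
    """
    s = tuple(sorted(s))
    nodes = [x, y, *s]
    m = _design_matrix(data, nodes)
    n = len(m)
    cx, cy = _cardinality(data, x), _cardinality(data, y)
    s_cards = [_cardinality(data, z) for z in s]
    nominal_df = max((cx - 1) * (cy - 1) * int(np.prod(s_cards or [1])), 1)
    if n == 0:
        return CITestResult(x, y, s, 0.0, nominal_df, 1.0, alpha, True, False, 0)
    if s:
        strata = np.ravel_multi_index(tuple(m[:, 2:].T), tuple(s_cards))
    else:
        strata = np.zeros(n, dtype=np.int64)
    g2 = 0.0
    used_strata = 0
    for stratum in np.unique(strata):
        sel = strata == stratum
        table = np.zeros((cx, cy))
        np.add.at(table, (m[sel, 0], m[sel, 1]), 1.0)
        rows = table.sum(axis=1)
        colz = table.sum(axis=0)
        if (rows > 0).sum() < 2 or (colz > 0).sum() < 2:
            continue  # degenerate stratum: no information, no df
        total = table.sum()
        expected = np.outer(rows, colz) / total
        nz = table > 0
        g2 += 2.0 * float(np.sum(table[nz] * np.log(table[nz] / expected[nz])))
        used_strata += 1
    df = max((cx - 1) * (cy - 1) * max(used_strata, 1), 1)
    p = float(chi2.sf(g2, df))
    reliable = n >= min_counts_per_df * nominal_df
    independent = (p > alpha) or not reliable
    return CITestResult(x, y, s, g2, df, p, alpha, independent, reliable, n)


# ----------------------------------------------------------------------
# PC
# ----------------------------------------------------------------------

def _edge_key(a: Slot, b: Slot) -> frozenset:
    return frozenset((a, b))


def _slots_to_arc(u: Slot, v: Slot) -> TemporalArc:
    # u -> v where v must be a lag-0 node
    return TemporalArc(u[0], v[0], u[1])


def pc_learn(
    data: PanelDataset | None,
    variables: list[VariableSpec] | None = None,
    max_lag: int = 1,
    constraints: ConstraintSet | None = None,
    alpha: float = 0.01,
    ci=None,
    cross_lags: tuple[TemporalArc, ...] = (),
    max_cond_size: int = 3,
    tiers: dict[str, int] | None = None,
) -> PDAGResult:
    """PC over (variable, lag) nodes with tiering and expert constraints.

    ``ci`` may be a callable ``ci(x, y, s) -> bool`` (True = independent)
    to run with an independence oracle instead of data tests; otherwise
    the G-squared test on ``data`` is used.
    """
    if not (0.0 < alpha < 0.5):
        raise InputError("alpha must be in (0, 0.5)")
    if variables is None:
        if data is None:
            raise InputError("either data or variables must be given")
        variables = data.variables
    if data is not None and max_lag > data.waves - 1:
        raise InputError("data must cover at least max_lag + 1 waves")
    constraints = constraints or ConstraintSet()
    tiers = DEFAULT_TIERS if tiers is None else tiers
    by_name = {v.name: v for v in variables}

    # --- candidate nodes and edges ------------------------------------
    lag0 = [(v.name, 0) for v in sorted(variables, key=lambda v: v.name)]
    lagged: list[Slot] = []
    horizon = data.waves if data is not None else max_lag + 1
    for v in sorted(variables, key=lambda v: v.name):
        if not v.temporal:
            continue
        for lag in range(1, max_lag + 1):
            if lag + v.first_wave <= horizon - 1:
                lagged.append((v.name, lag))
    cross_allowed = {(a.parent, a.lag, a.child) for a in cross_lags if a.lag >= 1}
    for a in constraints.required:
        if a.lag >= 1 and a.parent != a.child:
            cross_allowed.add((a.parent, a.lag, a.child))

    def allowed_directions(u: Slot, v: Slot) -> set[tuple[Slot, Slot]]:
        """Directions of edge {u, v} not ruled out by lags/constraints."""
        out = set()
        for a, b in ((u, v), (v, u)):
            if b[1] != 0:
                continue  # arcs always point into the current wave
            if a[1] >= 1:
                if a[0] != b[0] and (a[0], a[1], b[0]) not in cross_allowed:
                    continue
            if _slots_to_arc(a, b) in constraints.forbidden:
                continue
            out.add((a, b))
        return out

    nodes = tuple(lag0 + sorted(lagged))
    adj: dict[Slot, set[Slot]] = {nd: set() for nd in nodes}
    required_edges: set[frozenset] = set()
    for a in constraints.required:
        u = (a.parent, a.lag)
        v = (a.child, 0)
        if u not in adj or v not in adj:
            raise ConstraintConflictError(
                f"required arc {a} references unavailable node"
            )
        required_edges.add(_edge_key(u, v))

    candidate_edges: list[frozenset] = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if u[1] != 0 and v[1] != 0:
                continue  # no edges between two lagged nodes
            if u[0] == v[0] and u[1] != v[1] and u[1] * v[1] == 0:
                pass  # self-lag edge
            if not allowed_directions(u, v) and _edge_key(u, v) not in required_edges:
                continue
            candidate_edges.append(_edge_key(u, v))
    for e in candidate_edges:
        u, v = sorted(e)
        adj[u].add(v)
        adj[v].add(u)

    # --- CI engine ----------------------------------------------------
    tests: list[CITestResult] = []

    if ci is None:
        if data is None:
            raise InputError("data is required unless an oracle 'ci' is given")

        def is_independent(x: Slot, y: Slot, s: tuple[Slot, ...]) -> bool:
            res = ci_test_g2(data, x, y, s, alpha=alpha)
            tests.append(res)
            return res.independent
    else:
        def is_independent(x: Slot, y: Slot, s: tuple[Slot, ...]) -> bool:
            return bool(ci(x, y, s))

    # --- skeleton -----------------------------------------------------
    sepset: dict[frozenset, tuple[Slot, ...]] = {}
    level = 0
    while level <= max_cond_size:
        any_testable = False
        for e in sorted(candidate_edges, key=lambda e: tuple(sorted(e))):
            u, v = sorted(e)
            if v not in adj[u] or e in required_edges:
                continue
            pools = []
            if len(adj[u] - {v}) >= level:
                pools.append(sorted(adj[u] - {v}))
            if len(adj[v] - {u}) >= level:
                pools.append(sorted(adj[v] - {u}))
            if not pools:
                continue
            any_testable = True
            removed = False
            seen: set[tuple[Slot, ...]] = set()
            for pool in pools:
                for s in itertools.combinations(pool, level):
                    if s in seen:
                        continue
                    seen.add(s)
                    if is_independent(u, v, tuple(s)):
                        adj[u].discard(v)
                        adj[v].discard(u)
                        sepset[e] = tuple(s)
                        removed = True
                        break
                if removed:
                    break
        if not any_testable:
            break
        level += 1

    skeleton = {_edge_key(u, v) for u in nodes for v in adj[u]}

    conflicts: list[str] = []
    orientation_log: list[tuple[str, str]] = []
    compelled: set[tuple[Slot, Slot]] = set()   # CPDAG: v-structure/Meek/constraints
    oriented: set[tuple[Slot, Slot]] = set()    # compelled plus fallback choices

    def fmt(u: Slot, v: Slot) -> str:
        return f"{u[0]}@lag{u[1]} -> {v[0]}@lag{v[1]}"

    def creates_cycle(u: Slot, v: Slot) -> bool:
        # directed cycle check among lag-0 oriented arcs plus (u, v)
        arcs = {(a, b) for a, b in oriented if a[1] == 0 and b[1] == 0}
        if u[1] == 0 and v[1] == 0:
            arcs.add((u, v))
        graph: dict[Slot, set[Slot]] = {}
        for a, b in arcs:
            graph.setdefault(a, set()).add(b)
        state: dict[Slot, int] = {}

        def dfs(x: Slot) -> bool:
            state[x] = 1
            for y in graph.get(x, ()):  # pragma: no branch
                if state.get(y) == 1:
                    return True
                if state.get(y, 0) == 0 and dfs(y):
                    return True
            state[x] = 2
            return False

        return any(dfs(x) for x in list(graph) if state.get(x, 0) == 0)

    def orient(u: Slot, v: Slot, reason: str, compel: bool = True) -> bool:
        if (u, v) in oriented:
            return False
        if (v, u) in oriented:
            conflicts.append(
                f"cannot orient {fmt(u, v)} ({reason}): opposite already oriented"
            )
            return False
        if (u, v) not in allowed_directions(u, v):
            conflicts.append(
                f"cannot orient {fmt(u, v)} ({reason}): direction forbidden"
            )
            return False
        if creates_cycle(u, v):
            conflicts.append(
                f"cannot orient {fmt(u, v)} ({reason}): would create a cycle"
            )
            return False
        oriented.add((u, v))
        if compel:
            compelled.add((u, v))
        orientation_log.append((fmt(u, v), reason))
        return True

    # required arcs and inter-slice edges are compelled up front
    for a in sorted(constraints.required):
        orient((a.parent, a.lag), (a.child, 0), "required")
    for e in sorted(skeleton, key=lambda e: tuple(sorted(e))):
        u, v = sorted(e)
        for x, y in ((u, v), (v, u)):
            if x[1] >= 1 and y[1] == 0:
                orient(x, y, "temporal tiering")
        dirs = allowed_directions(u, v)
        if len(dirs) == 1 and e not in required_edges:
            x, y = next(iter(dirs))
            orient(x, y, "constraint")

    def undirected(u: Slot, v: Slot) -> bool:
        return (
            v in adj[u]
            and (u, v) not in oriented
            and (v, u) not in oriented
        )

    # v-structures: x -> z <- y for nonadjacent x, y with z outside sepset
    for z in nodes:
        nbrs = sorted(adj[z])
        for x, y in itertools.combinations(nbrs, 2):
            if y in adj[x]:
                continue
            if z in sepset.get(_edge_key(x, y), ()):
                continue
            if (z, x) in oriented or (z, y) in oriented:
                continue
            orient(x, z, f"v-structure {x[0]}@{x[1]} -> {z[0]} <- {y[0]}@{y[1]}")
            orient(y, z, f"v-structure {x[0]}@{x[1]} -> {z[0]} <- {y[0]}@{y[1]}")

    # Meek propagation rules R1-R3 to a fixpoint (R4 only fires with
    # richer background knowledge; anything left undirected falls through
    # to the deterministic fallback below)
    changed = True
    while changed:
        changed = False
        for e in sorted(skeleton, key=lambda e: tuple(sorted(e))):
            b, c = sorted(e)
            for u, v in ((b, c), (c, b)):
                if not undirected(u, v):
                    continue
                # R1: a -> u, u - v, a and v nonadjacent  =>  u -> v
                for a, x in list(compelled):
                    if x == u and a != v and v not in adj[a] and a not in adj[v]:
                        if orient(u, v, f"Meek R1 via {a[0]}@{a[1]}"):
                            changed = True
                        break
                if not undirected(u, v):
                    continue
                # R2: u -> w -> v with u - v  =>  u -> v
                for w in sorted(adj[u] & adj[v]):
                    if (u, w) in compelled and (w, v) in compelled:
                        if orient(u, v, f"Meek R2 via {w[0]}@{w[1]}"):
                            changed = True
                        break
                if not undirected(u, v):
                    continue
                # R3: u - c1, u - c2, c1 -> v, c2 -> v, c1, c2 nonadjacent
                cands = [
                    w
                    for w in sorted(adj[u])
                    if undirected(u, w) and (w, v) in compelled
                ]
                done = False
                for c1, c2 in itertools.combinations(cands, 2):
                    if c2 not in adj[c1]:
                        if orient(u, v, f"Meek R3 via {c1[0]},{c2[0]}"):
                            changed = True
                        done = True
                        break
                if done:
                    continue

    # deterministic fallback for residual undirected lag-0 edges
    for e in sorted(skeleton, key=lambda e: tuple(sorted(e))):
        u, v = sorted(e)
        if not undirected(u, v):
            continue
        tu, tv = tiers.get(u[0]), tiers.get(v[0])
        if tu is not None and tv is not None and tu != tv:
            first, second = (u, v) if tu < tv else (v, u)
        else:
            first, second = (u, v)  # lexicographic
        if not orient(first, second, "fallback (tier order)", compel=False):
            orient(second, first, "fallback (reversed to avoid conflict)", compel=False)

    # assemble final DAG arcs
    dag_arcs: set[TemporalArc] = set()
    for e in skeleton:
        u, v = sorted(e)
        if (u, v) in oriented:
            dag_arcs.add(_slots_to_arc(u, v))
        elif (v, u) in oriented:
            dag_arcs.add(_slots_to_arc(v, u))
        else:
            conflicts.append(f"edge {fmt(u, v)} left undirected; dropped")

    # constraints win: verify
    for a in constraints.required:
        if a not in dag_arcs:
            conflicts.append(f"required arc {a} missing from result; re-added")
            dag_arcs.add(a)
    present_forbidden = dag_arcs & constraints.forbidden
    for a in present_forbidden:
        conflicts.append(f"forbidden arc {a} produced; removed")
        dag_arcs.discard(a)

    # final acyclicity guarantee on the lag-0 subgraph
    specs = [VariableSpec(v.name, v.states, v.temporal, 0) for v in variables]
    TemporalStructure(specs, {a for a in dag_arcs if a.lag == 0}, 1)

    return PDAGResult(
        nodes=nodes,
        skeleton=skeleton,
        compelled=compelled,
        dag_arcs=dag_arcs,
        tests=tests,
        orientation_log=orientation_log,
        conflicts=conflicts,
    )


# ----------------------------------------------------------------------
# scoring and counting
# ----------------------------------------------------------------------

def bic_score(structure: TemporalStructure, data: PanelDataset) -> float:
    """Maximized log-likelihood minus (free parameters) * log(n) / 2.

    Uses pseudocount-0 maximum likelihood; unseen parent rows contribute
    zero likelihood terms and the penalty counts each distinct table once
    (transition tables are shared across waves).
    """
    from .learning import _observed_family_counts  # local to avoid cycle

    if data.n_missing() > 0:
        raise InputError("bic_score requires complete data")
    counts = _observed_family_counts(structure, data)
    ll = 0.0
    k = 0
    for (_, _slots), c in counts.items():
        card = c.shape[-1]
        rows = c.sum(axis=-1)
        nz = c > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(nz, c / np.maximum(rows[..., None], 1e-300), 0.0)
        ll += float(np.sum(c[nz] * np.log(p[nz])))
        k += int(np.prod(c.shape[:-1])) * (card - 1)
    return ll - 0.5 * k * np.log(max(data.n_subjects, 1))


def count_graph_structures(n: int) -> tuple[int, int]:
    """Size of the (undirected-choice) structure search space over ``n``
    nodes: returns ``(exponent, 2 ** exponent)`` with exponent
    ``n (n - 1) / 2`` as exact integers."""
    if n < 1:
        raise InputError("n must be >= 1")
    exponent = n * (n - 1) // 2
    return exponent, 1 << exponent
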
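"""Temporal network representation: variables, lagged arcs, conditional tables.

A :class:`DynamicNetwork` is a two-slice-style template with lag-0
(intra-wave) and lag-1/lag-2 (inter-wave) arcs, unrolled over a finite
horizon into an ordinary acyclic ground network whose nodes are
``(variable, wave)`` pairs.  Transition tables are time-homogeneous: one
table is shared by every wave at which the same set of lagged parents is
available, while early waves (where some lagged parents do not yet
exist) are governed by separate initial tables.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError, StructuralError

PROB_TOL = 1e-9          # a table row must sum to 1 within this
RENORM_TOL = 1e-6        # rows off by <= this are renormalized with a warning
MAX_LAG = 2

__all__ = [
    "VariableSpec",
    "TemporalArc",
    "TemporalStructure",
    "ConditionalTable",
    "DynamicNetwork",
    "GroundNode",
    "GroundNetwork",
    "unroll",
    "joint_probability",
    "log_joint_probability",
    "validate",
]


@dataclass(frozen=True)
class VariableSpec:
    """One categorical node of the template.

    Parameters
    ----------
    name : str
        Short identifier, unique within a network.
    states : tuple of str
        Ordered state labels (at least two, all distinct).
    temporal : bool
        Whether the variable may participate in lagged (inter-wave) arcs.
    first_wave : int
        0-based wave index at which the variable becomes observable.
        Waves before ``first_wave`` contain no ground node for it.
    """

    name: str
    states: tuple[str, ...]
    temporal: bool = True
    first_wave: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise InputError(f"variable {self.name!r} needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise InputError(f"variable {self.name!r} has duplicate state labels")
        if self.first_wave < 0:
            raise InputError(f"variable {self.name!r}: first_wave must be >= 0")

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise InputError(
                f"state {label!r} not in {self.name!r} states {self.states}"
            ) from None


@dataclass(frozen=True, order=True)
class TemporalArc:
    """Directed arc ``parent`` at wave ``t - lag`` -> ``child`` at wave ``t``."""

    parent: str
    child: str
    lag: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.lag <= MAX_LAG):
            raise InputError(f"arc lag must be in [0, {MAX_LAG}], got {self.lag}")


# A parent slot of a conditional table: (variable name, lag).
Slot = tuple[str, int]


class TemporalStructure:
    """Variables plus lagged arcs over a fixed horizon of waves."""

    def __init__(
        self,
        variables: list[VariableSpec] | tuple[VariableSpec, ...],
        arcs: set[TemporalArc] | list[TemporalArc] | tuple[TemporalArc, ...],
        horizon: int,
        strict: bool = True,
    ) -> None:
        if horizon < 1:
            raise InputError("horizon must be >= 1")
        self.variables: dict[str, VariableSpec] = {}
        for v in variables:
            if v.name in self.variables:
                raise InputError(f"duplicate variable name {v.name!r}")
            self.variables[v.name] = v
        self.arcs: frozenset[TemporalArc] = frozenset(arcs)
        self.horizon = int(horizon)
        self._check(strict)

    def _check(self, strict: bool) -> None:
        # reference and bound errors always raise: nothing downstream can
        # work without them.  Temporality / acyclicity raise only in
        # strict mode so that validate() can report them instead.
        for v in self.variables.values():
            if v.first_wave > self.horizon - 1:
                raise StructuralError(
                    f"{v.name}: first_wave {v.first_wave} >= horizon {self.horizon}"
                )
        for a in self.arcs:
            for end in (a.parent, a.child):
                if end not in self.variables:
                    raise StructuralError(f"arc {a} references unknown variable {end!r}")
            if a.lag >= self.horizon:
                raise StructuralError(f"arc {a}: lag must be < horizon")
        if not strict:
            return
        for a in self.arcs:
            if a.lag >= 1:
                for end in (a.parent, a.child):
                    if not self.variables[end].temporal:
                        raise StructuralError(
                            f"arc {a}: non-temporal variable {end!r} cannot "
                            "participate in lagged arcs"
                        )
        if self._lag0_cycle() is not None:
            raise StructuralError(
                f"lag-0 subgraph is cyclic: {self._lag0_cycle()}"
            )

    def _lag0_cycle(self) -> list[str] | None:
        """Return a cycle in the lag-0 subgraph, or None if acyclic."""
        adj: dict[str, list[str]] = {v: [] for v in self.variables}
        for a in self.arcs:
            if a.lag == 0:
                adj[a.parent].append(a.child)
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {v: WHITE for v in self.variables}
        stack: list[str] = []

        def dfs(u: str) -> list[str] | None:
            color[u] = GRAY
            stack.append(u)
            for w in adj[u]:
                if color[w] == GRAY:
                    return stack[stack.index(w):] + [w]
                if color[w] == WHITE:
                    cyc = dfs(w)
                    if cyc is not None:
                        return cyc
            stack.pop()
            color[u] = BLACK
            return None

        for v in sorted(self.variables):
            if color[v] == WHITE:
                cyc = dfs(v)
                if cyc is not None:
                    return cyc
        return None

    def arcs_into(self, child: str) -> list[TemporalArc]:
        return sorted(a for a in self.arcs if a.child == child)

    def parent_slots(self, child: str, wave: int) -> tuple[Slot, ...]:
        """Parent slots of ``child`` that are actually available at ``wave``.

        An arc with lag L contributes only if the parent's ground node at
        wave ``wave - L`` exists (``wave - L >= parent's first_wave``).
        """
        slots = []
        for a in self.arcs_into(child):
            pw = wave - a.lag
            if pw >= self.variables[a.parent].first_wave and pw >= 0:
                slots.append((a.parent, a.lag))
        return tuple(sorted(slots))

    def table_keys(self) -> dict[str, dict[tuple[Slot, ...], list[int]]]:
        """For each variable, map each distinct parent-slot tuple to the
        waves governed by it.  Each distinct slot tuple requires exactly
        one conditional table (time-homogeneity)."""
        out: dict[str, dict[tuple[Slot, ...], list[int]]] = {}
        for name, v in self.variables.items():
            per: dict[tuple[Slot, ...], list[int]] = {}
            for t in range(v.first_wave, self.horizon):
                per.setdefault(self.parent_slots(name, t), []).append(t)
            out[name] = per
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TemporalStructure)
            and self.variables == other.variables
            and self.arcs == other.arcs
            and self.horizon == other.horizon
        )


class ConditionalTable:
    """P(child | parent slots): one categorical row per parent configuration.

    ``values`` has shape ``(*parent_cardinalities, child_cardinality)``;
    axis order follows ``parent_slots`` (sorted (name, lag) pairs).
    """

    def __init__(
        self,
        child: str,
        parent_slots: tuple[Slot, ...],
        values: np.ndarray,
    ) -> None:
        self.child = child
        self.parent_slots = tuple(parent_slots)
        self.values = np.asarray(values, dtype=float)

    def normalized(self) -> "ConditionalTable":
        """Return a copy with rows renormalized; warn if off by <= RENORM_TOL,
        reject beyond."""
        sums = self.values.sum(axis=-1)
        err = np.abs(sums - 1.0)
        worst = float(err.max()) if err.size else 0.0
        if worst > RENORM_TOL:
            raise ConfigurationError(
                f"table for {self.child!r}: row sum off by {worst:.3g} (> {RENORM_TOL})"
            )
        if worst <= PROB_TOL:
            return self
        warnings.warn(
            f"table for {self.child!r}: renormalizing rows (max error {worst:.3g})",
            stacklevel=2,
        )
        return ConditionalTable(
            self.child, self.parent_slots, self.values / sums[..., None]
        )

    def check(self, structure: TemporalStructure) -> list[str]:
        """Return invariant violations (empty list when well-formed)."""
        problems: list[str] = []
        child_card = structure.variables[self.child].cardinality
        expected_shape = tuple(
            structure.variables[p].cardinality for p, _ in self.parent_slots
        ) + (child_card,)
        if self.values.shape != expected_shape:
            problems.append(
                f"table[{self.child}]: shape {self.values.shape} != "
                f"expected {expected_shape} (full parent-product coverage)"
            )
            return problems
        if np.any(self.values < 0):
            problems.append(f"table[{self.child}]: negative probability entry")
        sums = self.values.sum(axis=-1)
        bad = np.argwhere(np.abs(sums - 1.0) > PROB_TOL)
        for idx in bad[:20]:
            row = tuple(int(i) for i in idx)
            problems.append(
                f"table[{self.child}]: row {row} sums to {sums[tuple(idx)]!r}, not 1"
            )
        return problems

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ConditionalTable)
            and self.child == other.child
            and self.parent_slots == other.parent_slots
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
        )


class DynamicNetwork:
    """A temporal structure together with its conditional tables.

    Tables are keyed by ``(variable, parent-slot tuple)``: the slot tuple
    for a wave with all lagged parents available selects the (shared)
    transition table, while early waves select initial tables.
    """

    def __init__(
        self,
        structure: TemporalStructure,
        tables: dict[str, dict[tuple[Slot, ...], ConditionalTable]],
    ) -> None:
        self.structure = structure
        self.tables = tables

    def table_for(self, variable: str, wave: int) -> ConditionalTable:
        slots = self.structure.parent_slots(variable, wave)
        try:
            return self.tables[variable][slots]
        except KeyError:
            raise ConfigurationError(
                f"no table for {variable!r} at wave {wave} (parent slots {slots})"
            ) from None

    # ------------------------------------------------------------------
    # serialization (JSON; round-trips probabilities exactly as doubles)
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        s = self.structure
        return {
            "format": "dbnpanel-network",
            "version": 1,
            "horizon": s.horizon,
            "variables": [
                {
                    "name": v.name,
                    "states": list(v.states),
                    "temporal": v.temporal,
                    "first_wave": v.first_wave,
                }
                for v in s.variables.values()
            ],
            "arcs": [
                {"parent": a.parent, "child": a.child, "lag": a.lag}
                for a in sorted(s.arcs)
            ],
            "tables": [
                {
                    "child": t.child,
                    "parent_slots": [[p, lag] for p, lag in t.parent_slots],
                    "shape": list(t.values.shape),
                    "probabilities": t.values.ravel().tolist(),
                }
                for per in self.tables.values()
                for _, t in sorted(per.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DynamicNetwork":
        variables = [
            VariableSpec(
                name=v["name"],
                states=tuple(v["states"]),
                temporal=bool(v["temporal"]),
                first_wave=int(v["first_wave"]),
            )
            for v in d["variables"]
        ]
        arcs = {
            TemporalArc(a["parent"], a["child"], int(a["lag"])) for a in d["arcs"]
        }
        structure = TemporalStructure(variables, arcs, int(d["horizon"]))
        tables: dict[str, dict[tuple[Slot, ...], ConditionalTable]] = {}
        for t in d["tables"]:
            slots = tuple((p, int(lag)) for p, lag in t["parent_slots"])
            values = np.asarray(t["probabilities"], dtype=float).reshape(t["shape"])
            tab = ConditionalTable(t["child"], slots, values).normalized()
            tables.setdefault(t["child"], {})[slots] = tab
        return cls(structure, tables)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "DynamicNetwork":
        """Parse from a JSON string or a path to a JSON file."""
        text = source
        if "\n" not in source and not source.lstrip().startswith("{"):
            with open(source) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))

    # ------------------------------------------------------------------
    # DOT export
    # ------------------------------------------------------------------
    def to_dot(self, view: str = "template") -> str:
        """Render the template (arcs annotated with lags) or the unrolled
        ground graph as a Graphviz DOT document."""
        lines = ["digraph dbn {", "  rankdir=LR;"]
        if view == "template":
            for v in self.structure.variables.values():
                lines.append(f'  "{v.name}";')
            for a in sorted(self.structure.arcs):
                attr = f' [label="lag {a.lag}"]' if a.lag else ""
                lines.append(f'  "{a.parent}" -> "{a.child}"{attr};')
        elif view == "ground":
            g = unroll(self)
            for (name, wave) in g.order:
                lines.append(f'  "{name}@{wave}";')
            for (name, wave) in g.order:
                for (pn, pw) in g.nodes[(name, wave)].parents:
                    lines.append(f'  "{pn}@{pw}" -> "{name}@{wave}";')
        else:
            raise InputError(f"view must be 'template' or 'ground', got {view!r}")
        lines.append("}")
        return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# ground (unrolled) network
# ----------------------------------------------------------------------

GroundKey = tuple[str, int]  # (variable name, wave)


@dataclass
class GroundNode:
    name: str
    wave: int
    states: tuple[str, ...]
    parents: tuple[GroundKey, ...]
    cpt: np.ndarray  # shape (*parent_cards, card)

    @property
    def key(self) -> GroundKey:
        return (self.name, self.wave)

    @property
    def cardinality(self) -> int:
        return len(self.states)


class GroundNetwork:
    """The unrolled acyclic network over ``(variable, wave)`` nodes."""

    def __init__(self, nodes: dict[GroundKey, GroundNode], horizon: int) -> None:
        self.nodes = nodes
        self.horizon = horizon
        self.order = self._toposort()

    def _toposort(self) -> list[GroundKey]:
        indeg = {k: len(n.parents) for k, n in self.nodes.items()}
        children: dict[GroundKey, list[GroundKey]] = {k: [] for k in self.nodes}
        for k, n in self.nodes.items():
            for p in n.parents:
                children[p].append(k)
        ready = sorted(k for k, d in indeg.items() if d == 0)
        order: list[GroundKey] = []
        while ready:
            k = ready.pop(0)
            order.append(k)
            added = False
            for c in children[k]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
                    added = True
            if added:
                ready.sort()
        if len(order) != len(self.nodes):
            raise StructuralError("unrolled ground graph is cyclic")
        return order

    def arcs(self) -> set[tuple[GroundKey, GroundKey]]:
        return {
            (p, k) for k, n in self.nodes.items() for p in n.parents
        }

    def __contains__(self, key: GroundKey) -> bool:
        return key in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)


def unroll(net: DynamicNetwork, horizon: int | None = None) -> GroundNetwork:
    """Instantiate the template over ``horizon`` waves.

    Ground node ``(v, t)`` exists for ``t`` in ``[first_wave(v), horizon)``;
    its parents are ``(p, t - lag)`` for each available parent slot, and it
    carries the conditional table governing that slot combination.
    """
    s = net.structure
    if horizon is None:
        horizon = s.horizon
    if horizon < 1:
        raise InputError("horizon must be >= 1")
    for a in s.arcs:
        if a.lag >= horizon:
            raise InputError(f"arc {a}: lag {a.lag} must be < horizon {horizon}")
    nodes: dict[GroundKey, GroundNode] = {}
    for name, v in s.variables.items():
        for t in range(v.first_wave, horizon):
            slots = s.parent_slots(name, t)
            table = net.tables.get(name, {}).get(slots)
            if table is None:
                raise ConfigurationError(
                    f"no table for {name!r} at wave {t} (parent slots {slots})"
                )
            bad = table.check(s)
            if bad:
                raise ConfigurationError("; ".join(bad))
            nodes[(name, t)] = GroundNode(
                name=name,
                wave=t,
                states=v.states,
                parents=tuple((p, t - lag) for p, lag in slots),
                cpt=table.normalized().values,
            )
    return GroundNetwork(nodes, horizon)


# ----------------------------------------------------------------------
# joint evaluation
# ----------------------------------------------------------------------

def _indices(ground: GroundNetwork, assignment: dict[GroundKey, str]) -> dict[GroundKey, int]:
    missing = [k for k in ground.nodes if k not in assignment]
    if missing:
        raise InputError(f"assignment incomplete; missing {sorted(missing)[:5]}...")
    idx = {}
    for k, node in ground.nodes.items():
        label = assignment[k]
        if label not in node.states:
            raise InputError(f"state {label!r} invalid for node {k}")
        idx[k] = node.states.index(label)
    return idx


def log_joint_probability(ground: GroundNetwork, assignment: dict[GroundKey, str]) -> float:
    """Sum of per-node log table entries; -inf if any entry is zero."""
    idx = _indices(ground, assignment)
    total = 0.0
    for k, node in ground.nodes.items():
        sel = tuple(idx[p] for p in node.parents) + (idx[k],)
        p = node.cpt[sel]
        if p <= 0.0:
            return -math.inf
        total += math.log(p)
    return total


def joint_probability(ground: GroundNetwork, assignment: dict[GroundKey, str]) -> float:
    """Product over ground nodes of the table entry selected by ``assignment``."""
    idx = _indices(ground, assignment)
    prob = 1.0
    for k, node in ground.nodes.items():
        sel = tuple(idx[p] for p in node.parents) + (idx[k],)
        prob *= float(node.cpt[sel])
    return prob


# ----------------------------------------------------------------------
# validation report
# ----------------------------------------------------------------------

def validate(net: DynamicNetwork) -> list[str]:
    """Collect invariant violations; an empty list means well-formed.

    Reports rather than raises so a caller can display every problem at
    once.  Structural problems that prevent even building the object are
    raised by the constructors instead.
    """
    problems: list[str] = []
    s = net.structure
    for a in s.arcs:
        if a.lag >= 1:
            for end in (a.parent, a.child):
                v = s.variables.get(end)
                if v is not None and not v.temporal:
                    problems.append(
                        f"arc {a.parent}->{a.child} lag {a.lag}: "
                        f"non-temporal variable {end!r} in a lagged arc"
                    )
    cyc = s._lag0_cycle()
    if cyc is not None:
        problems.append(f"lag-0 subgraph cycle: {' -> '.join(cyc)}")
    for name, per in s.table_keys().items():
        for slots, waves in per.items():
            table = net.tables.get(name, {}).get(slots)
            if table is None:
                problems.append(
                    f"missing table for {name!r} at waves {waves} (slots {slots})"
                )
                continue
            problems.extend(table.check(s))
    for name in net.tables:
        if name not in s.variables:
            problems.append(f"table for undeclared variable {name!r}")
    return problems
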
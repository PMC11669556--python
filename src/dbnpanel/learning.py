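"""Parameter estimation: maximum likelihood with pseudocounts, and EM
for records with missing cells.

Counts are pooled across all waves governed by the same transition table
(time-homogeneity).  The EM E-step exploits the fact that, once observed
cells are sliced into the per-family factors, the remaining (missing)
cells fall apart into small independent components whose joints can be
computed densely — far cheaper than a full elimination per family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import MISSING, PanelDataset
from .errors import InputError
from .inference import record_loglik
from .network import (
    ConditionalTable,
    DynamicNetwork,
    GroundKey,
    GroundNetwork,
    Slot,
    TemporalStructure,
    unroll,
)

__all__ = ["LearningReport", "fit_mle", "fit_em", "dataset_loglik"]

TableKey = tuple[str, tuple[Slot, ...]]


@dataclass
class LearningReport:
    """Fitted network plus fitting diagnostics."""

    network: DynamicNetwork
    log_likelihood: float
    trace: list[float] = field(default_factory=list)
    counts: dict[TableKey, np.ndarray] = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    messages: list[str] = field(default_factory=list)

    def row_sample_counts(self, variable: str, slots: tuple[Slot, ...]) -> np.ndarray:
        """Effective sample count per parent configuration row."""
        return self.counts[(variable, slots)].sum(axis=-1)

    def trace_table(self) -> str:
        lines = ["iteration\tlog_likelihood"]
        lines += [f"{i}\t{ll!r}" for i, ll in enumerate(self.trace)]
        return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# counting
# ----------------------------------------------------------------------

def _table_shapes(structure: TemporalStructure) -> dict[TableKey, tuple[int, ...]]:
    shapes: dict[TableKey, tuple[int, ...]] = {}
    for name, per in structure.table_keys().items():
        card = structure.variables[name].cardinality
        for slots in per:
            pshape = tuple(structure.variables[p].cardinality for p, _ in slots)
            shapes[(name, slots)] = pshape + (card,)
    return shapes


def _observed_family_counts(
    structure: TemporalStructure, data: PanelDataset
) -> dict[TableKey, np.ndarray]:
    """Counts over families whose members are all observed, pooled across
    the waves sharing each table (vectorized)."""
    shapes = _table_shapes(structure)
    counts = {k: np.zeros(s) for k, s in shapes.items()}
    for name, per in structure.table_keys().items():
        j = data.var_index[name]
        for slots, waves in per.items():
            shape = shapes[(name, slots)]
            acc = counts[(name, slots)]
            for t in waves:
                if t >= data.waves:
                    continue
                cols = [
                    data.codes[:, t - lag, data.var_index[p]] for p, lag in slots
                ]
                cols.append(data.codes[:, t, j])
                stacked = np.stack(cols, axis=0)
                mask = np.all(stacked >= 0, axis=0)
                if not np.any(mask):
                    continue
                flat = np.ravel_multi_index(
                    tuple(stacked[:, mask]), shape
                )
                acc += np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
    return counts


def _tables_from_counts(
    structure: TemporalStructure,
    counts: dict[TableKey, np.ndarray],
    pseudocount: float,
    messages: list[str],
) -> dict[str, dict[tuple[Slot, ...], ConditionalTable]]:
    tables: dict[str, dict[tuple[Slot, ...], ConditionalTable]] = {}
    for (name, slots), c in counts.items():
        card = c.shape[-1]
        smoothed = c + pseudocount
        totals = smoothed.sum(axis=-1, keepdims=True)
        values = np.empty_like(smoothed)
        zero_rows = totals[..., 0] <= 0
        if np.any(zero_rows):
            messages.append(
                f"{name} {slots}: {int(zero_rows.sum())} unseen parent "
                "configuration(s) left uniform"
            )
            values[zero_rows] = 1.0 / card
        ok = ~zero_rows
        values[ok] = smoothed[ok] / totals[ok]
        tables.setdefault(name, {})[slots] = ConditionalTable(name, slots, values)
    return tables


def _complete_data_loglik(net: DynamicNetwork, data: PanelDataset) -> float:
    """Vectorized sum of log joint probabilities over complete records."""
    structure = net.structure
    total = 0.0
    with np.errstate(divide="ignore"):
        for name, per in structure.table_keys().items():
            j = data.var_index[name]
            for slots, waves in per.items():
                logp = np.log(net.tables[name][slots].values)
                for t in waves:
                    if t >= data.waves:
                        continue
                    cols = [
                        data.codes[:, t - lag, data.var_index[p]] for p, lag in slots
                    ]
                    cols.append(data.codes[:, t, j])
                    total += float(logp[tuple(cols)].sum())
    return total


# ----------------------------------------------------------------------
# MLE
# ----------------------------------------------------------------------

def fit_mle(
    structure: TemporalStructure,
    data: PanelDataset,
    pseudocount: float = 1.0,
) -> LearningReport:
    """Closed-form (count + pseudocount) estimation on complete data.

    Each table row is ``(count + pseudocount) / (row total +
    pseudocount * n_states)``; counts are pooled across all waves
    governed by the same transition table.
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    if data.n_missing() > 0:
        raise InputError(
            f"fit_mle requires complete data ({data.n_missing()} missing cells); "
            "use fit_em"
        )
    messages: list[str] = []
    counts = _observed_family_counts(structure, data)
    tables = _tables_from_counts(structure, counts, pseudocount, messages)
    for msg in messages:
        warnings.warn(msg, stacklevel=2)
    net = DynamicNetwork(structure, tables)
    ll = _complete_data_loglik(net, data)
    return LearningReport(
        network=net,
        log_likelihood=ll,
        trace=[ll],
        counts=counts,
        converged=True,
        n_iter=1,
        messages=messages,
    )


# ----------------------------------------------------------------------
# EM
# ----------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items) -> None:
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _align_linear(values: np.ndarray, scope, members_pos) -> np.ndarray:
    """Broadcast a linear-space factor into the component-joint shape."""
    perm = sorted(range(len(scope)), key=lambda i: members_pos[scope[i]])
    src = np.transpose(values, perm) if len(scope) > 1 else values
    shape = [1] * len(members_pos)
    ordered = sorted(scope, key=lambda k: members_pos[k])
    for ax, k in enumerate(ordered):
        shape[members_pos[k]] = src.shape[ax]
    return src.reshape(shape)


def _estep_record(
    ground: GroundNetwork,
    obs_idx: dict[GroundKey, int],
    missing: list[GroundKey],
) -> tuple[float, list[tuple[GroundKey, tuple, np.ndarray]]]:
    """One record's log-likelihood and expected-count contributions for
    families containing at least one missing member.

    Returns ``(loglik, [(child key, index selector, marginal), ...])``
    where the selector has integers for observed family dims and slices
    for missing dims, and the marginal is arranged along those slices.
    """
    miss_set = set(missing)
    reduced: dict[GroundKey, tuple[tuple[GroundKey, ...], np.ndarray]] = {}
    loglik = 0.0
    uf = _UnionFind(missing)
    for key in ground.order:
        node = ground.nodes[key]
        dims = node.parents + (key,)
        sel = tuple(
            obs_idx[d] if d in obs_idx else slice(None) for d in dims
        )
        scope = tuple(d for d in dims if d not in obs_idx)
        arr = node.cpt[sel]
        if not scope:
            p = float(arr)
            loglik += np.log(p) if p > 0 else -np.inf
        else:
            reduced[key] = (scope, arr)
            for d in scope[1:]:
                uf.union(scope[0], d)
    # group reduced factors by component
    comp_factors: dict[GroundKey, list[tuple[tuple[GroundKey, ...], np.ndarray]]] = {}
    for scope, arr in reduced.values():
        comp_factors.setdefault(uf.find(scope[0]), []).append((scope, arr))
    comp_joint: dict[GroundKey, tuple[tuple[GroundKey, ...], np.ndarray, float]] = {}
    for root, facs in comp_factors.items():
        members = tuple(sorted({d for scope, _ in facs for d in scope}))
        pos = {m: i for i, m in enumerate(members)}
        joint = np.ones(tuple(ground.nodes[m].cardinality for m in members))
        for scope, arr in facs:
            joint = joint * _align_linear(arr, scope, pos)
        z = float(joint.sum())
        loglik += np.log(z) if z > 0 else -np.inf
        comp_joint[root] = (members, joint, z)
    # family marginals
    contribs: list[tuple[GroundKey, tuple, np.ndarray]] = []
    for key, (scope, _) in reduced.items():
        node = ground.nodes[key]
        dims = node.parents + (key,)
        members, joint, z = comp_joint[uf.find(scope[0])]
        scope_set = set(scope)
        other = tuple(i for i, m in enumerate(members) if m not in scope_set)
        marg = joint.sum(axis=other) if other else joint
        marg = marg / z if z > 0 else np.zeros_like(marg)
        cur = [m for m in members if m in scope_set]
        perm = [cur.index(m) for m in scope]
        if perm != list(range(len(perm))):
            marg = np.transpose(marg, perm)
        sel = tuple(
            obs_idx[d] if d in obs_idx else slice(None) for d in dims
        )
        contribs.append((key, sel, marg))
    return loglik, contribs


def fit_em(
    structure: TemporalStructure,
    data: PanelDataset,
    pseudocount: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int | None = None,
    restarts: int = 1,
) -> LearningReport:
    """Expectation-maximization for panel data with missing cells.

    The E-step computes expected family counts from per-record posteriors
    under the current parameters; the M-step re-estimates tables as in
    :func:`fit_mle` on the expected counts.  Initialization is the
    available-case M-step (counts over fully observed families); extra
    ``restarts`` beyond the first use random Dirichlet tables.
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    for v in data.variables:
        col = data.codes[:, v.first_wave:, data.var_index[v.name]]
        if col.size and not np.any(col >= 0):
            raise InputError(f"variable {v.name!r} is never observed")
    messages: list[str] = []
    observed_counts = _observed_family_counts(structure, data)
    shapes = _table_shapes(structure)
    rng = np.random.default_rng(seed)

    # distinct records with multiplicities: duplicate rows share one E-step
    uniq: dict[bytes, list[int]] = {}
    for i in range(data.n_subjects):
        uniq.setdefault(data.codes[i].tobytes(), []).append(i)
    records = []
    for _, idxs in sorted(uniq.items()):
        i = idxs[0]
        obs = {}
        missing = []
        for j, v in enumerate(data.variables):
            for t in range(v.first_wave, data.waves):
                code = int(data.codes[i, t, j])
                if code >= 0:
                    obs[(v.name, t)] = code
                elif code == MISSING:
                    missing.append((v.name, t))
        records.append((obs, missing, len(idxs)))

    best: LearningReport | None = None
    for run in range(max(restarts, 1)):
        if run == 0:
            tables = _tables_from_counts(
                structure, observed_counts, max(pseudocount, 1e-6), messages
            )
        else:
            tables = {}
            for (name, slots), shape in shapes.items():
                vals = rng.dirichlet(np.ones(shape[-1]), size=shape[:-1] or (1,))
                tables.setdefault(name, {})[slots] = ConditionalTable(
                    name, slots, vals.reshape(shape)
                )
        net = DynamicNetwork(structure, tables)
        trace: list[float] = []
        converged = False
        evaluated = net  # the network whose log-likelihood is trace[-1]
        prev_state: tuple[DynamicNetwork, dict] | None = None
        for it in range(max_iter):
            evaluated = net
            ground = unroll(net)
            counts = {k: np.zeros(s) for k, s in shapes.items()}
            # fully-observed families contribute fixed counts
            for k in counts:
                counts[k] += observed_counts[k]
            ll = 0.0
            slot_of = {
                (name, t): slots
                for name, per in structure.table_keys().items()
                for slots, waves in per.items()
                for t in waves
            }
            for obs, missing, mult in records:
                rec_ll, contribs = _estep_record(ground, obs, missing)
                ll += mult * rec_ll
                for key, sel, marg in contribs:
                    counts[(key[0], slot_of[key])][sel] += mult * marg
            if trace and ll < trace[-1]:
                # with pseudocounts EM is monotone in the penalized
                # objective, so the raw likelihood can dip slightly at
                # convergence; keep the previous (better) iterate
                assert prev_state is not None
                evaluated, counts = prev_state
                converged = True
                break
            trace.append(ll)
            prev_state = (evaluated, counts)
            if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
                converged = True
                break
            tables = _tables_from_counts(structure, counts, pseudocount, messages)
            net = DynamicNetwork(structure, tables)
        report = LearningReport(
            network=evaluated,
            log_likelihood=trace[-1],
            trace=trace,
            counts=counts,
            converged=converged,
            n_iter=len(trace),
            messages=messages
            + ([] if converged else [f"EM did not converge in {max_iter} iterations"]),
        )
        if best is None or report.log_likelihood > best.log_likelihood:
            best = report
    assert best is not None
    return best


def dataset_loglik(net: DynamicNetwork, data: PanelDataset) -> float:
    """Sum over subjects of the record log-likelihood (missing cells
    marginalized)."""
    if data.n_missing() == 0:
        return _complete_data_loglik(net, data)
    ground = unroll(net)
    cache: dict[bytes, float] = {}
    total = 0.0
    for i in range(data.n_subjects):
        key = data.codes[i].tobytes()
        if key not in cache:
            cache[key] = record_loglik(ground, data.record_evidence(i))
        total += cache[key]
    return total
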
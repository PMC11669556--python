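"""Information metrics for feature ranking and value-of-information.

All entropies are in bits (base 2).  Metrics exist in two routes: a
model-based route driven by exact inference on the unrolled network, and
an empirical route driven by smoothed counts from panel data; both share
the same identities (mutual information equals the target's entropy
reduction for the pairwise definitions used here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PanelDataset
from .errors import InputError
from .inference import Evidence, joint_posterior
from .network import GroundKey, GroundNetwork
from .structure import _design_matrix

__all__ = [
    "entropy",
    "mutual_information",
    "pairwise_joint_model",
    "pairwise_joint_empirical",
    "target_entropy_reduction",
    "FeatureRanking",
    "rank_features",
    "value_of_information",
]

EMPIRICAL_PSEUDOCOUNT = 0.5  # per joint cell, to avoid log 0


def entropy(dist) -> float:
    """Shannon entropy in bits; 0 * log 0 = 0."""
    p = np.asarray(dist, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if abs(p.sum() - 1.0) > 1e-6 or np.any(p < -1e-12):
        raise InputError("distribution must be normalized and non-negative")
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def mutual_information(joint: np.ndarray) -> float:
    """MI of a two-variable categorical joint, in bits (clipped at 0)."""
    j = np.asarray(joint, dtype=float)
    if j.ndim != 2:
        raise InputError("joint must be a 2-D table")
    if abs(j.sum() - 1.0) > 1e-6 or np.any(j < -1e-12):
        raise InputError("joint must be normalized and non-negative")
    hx = entropy(j.sum(axis=1))
    hy = entropy(j.sum(axis=0))
    hxy = entropy(j.ravel())
    mi = hx + hy - hxy
    if mi < -1e-12:
        raise AssertionError(f"MI identity violated: {mi}")
    return max(mi, 0.0)


def conditional_entropy(joint: np.ndarray, axis: int = 0) -> float:
    """H(other | axis variable) from a two-variable joint, in bits."""
    j = np.asarray(joint, dtype=float)
    marg = j.sum(axis=1 - axis)
    h = 0.0
    for x in range(j.shape[axis]):
        px = float(marg[x])
        if px <= 0:
            continue
        row = np.take(j, x, axis=axis) / px
        h += px * entropy(row)
    return h


# ----------------------------------------------------------------------
# pairwise joints
# ----------------------------------------------------------------------

def pairwise_joint_model(
    ground: GroundNetwork,
    x: GroundKey,
    y: GroundKey,
    evidence: Evidence | None = None,
) -> np.ndarray:
    """Exact joint P(x, y | evidence) from inference; rows index ``x``."""
    for k in (x, y):
        if k not in ground.nodes:
            raise InputError(f"{k} is structurally absent from the network")
    nodes, joint, _ = joint_posterior(ground, evidence or Evidence(), (x, y))
    if nodes == (x, y):
        return joint
    return joint.T


def pairwise_joint_empirical(
    data: PanelDataset,
    x: str,
    y: str,
    pseudocount: float = EMPIRICAL_PSEUDOCOUNT,
) -> np.ndarray:
    """Wave-pooled empirical joint of two variables (complete cases),
    smoothed with ``pseudocount`` per cell."""
    m = _design_matrix(data, [(x, 0), (y, 0)])
    cx = data.variables[data.var_index[x]].cardinality
    cy = data.variables[data.var_index[y]].cardinality
    table = np.full((cx, cy), float(pseudocount))
    if len(m):
        np.add.at(table, (m[:, 0], m[:, 1]), 1.0)
    return table / table.sum()


def target_entropy_reduction(
    source: GroundNetwork | PanelDataset,
    feature: str,
    target: str,
    wave: int | None = None,
    feature_wave: int | None = None,
    pseudocount: float = EMPIRICAL_PSEUDOCOUNT,
) -> float:
    """H(target) - H(target | feature), in bits.

    Model-based when ``source`` is a ground network (requires ``wave``;
    ``feature_wave`` defaults to the same wave), empirical (wave-pooled
    counts) when ``source`` is a panel dataset.
    """
    if isinstance(source, GroundNetwork):
        if wave is None:
            raise InputError("model-based reduction needs a wave")
        fw = wave if feature_wave is None else feature_wave
        joint = pairwise_joint_model(source, (feature, fw), (target, wave))
    else:
        joint = pairwise_joint_empirical(source, feature, target, pseudocount)
    h_target = entropy(joint.sum(axis=0))
    reduction = h_target - conditional_entropy(joint, axis=0)
    return max(float(reduction), 0.0)


# ----------------------------------------------------------------------
# feature ranking
# ----------------------------------------------------------------------

@dataclass
class FeatureRow:
    name: str
    mutual_information: float
    entropy_reduction: float
    residual_entropy: float
    rank: int
    selected: bool


@dataclass
class FeatureRanking:
    target: str
    target_entropy: float
    rows: list[FeatureRow]

    def to_table(self) -> str:
        lines = [
            "variable\tmutual_information\ttarget_entropy_reduction\t"
            "residual_target_entropy\trank\tselected"
        ]
        for r in self.rows:
            lines.append(
                f"{r.name}\t{r.mutual_information:.6f}\t"
                f"{r.entropy_reduction:.6f}\t{r.residual_entropy:.6f}\t"
                f"{r.rank}\t{'yes' if r.selected else 'no'}"
            )
        return "\n".join(lines) + "\n"

    def order(self) -> list[str]:
        return [r.name for r in self.rows]


def rank_features(
    source: GroundNetwork | PanelDataset,
    candidates: list[str],
    target: str,
    selection_threshold: float | None = None,
    wave: int | None = None,
    pseudocount: float = EMPIRICAL_PSEUDOCOUNT,
) -> FeatureRanking:
    """Rank candidate variables by mutual information with the target.

    Descending MI, ties broken by entropy reduction then name; the
    result is invariant to the input order of ``candidates``.  Features
    with MI at or above ``selection_threshold`` are flagged selected
    (all are, when no threshold is given).
    """
    if not candidates:
        raise InputError("at least one candidate is required")
    entries = []
    h_target = None
    for name in sorted(set(candidates)):
        if isinstance(source, GroundNetwork):
            if wave is None:
                raise InputError("model-based ranking needs a wave")
            joint = pairwise_joint_model(source, (name, wave), (target, wave))
        else:
            joint = pairwise_joint_empirical(source, name, target, pseudocount)
        mi = mutual_information(joint)
        h_t = entropy(joint.sum(axis=0))
        red = h_t - conditional_entropy(joint, axis=0)
        # pairwise identity: reduction and MI are the same quantity
        if abs(mi - red) > 1e-9:
            raise AssertionError(f"MI != entropy reduction for {name}: {mi} vs {red}")
        h_target = h_t if h_target is None else h_target
        entries.append((name, mi, red, h_t - red))
    entries.sort(key=lambda e: (-e[1], -e[2], e[0]))
    rows = []
    for rank, (name, mi, red, resid) in enumerate(entries, start=1):
        selected = True if selection_threshold is None else mi >= selection_threshold
        rows.append(
            FeatureRow(
                name=name,
                mutual_information=mi,
                entropy_reduction=red,
                residual_entropy=resid,
                rank=rank,
                selected=selected,
            )
        )
    return FeatureRanking(target=target, target_entropy=float(h_target), rows=rows)


# ----------------------------------------------------------------------
# value of information
# ----------------------------------------------------------------------

def value_of_information(
    ground: GroundNetwork,
    target: GroundKey,
    candidate: GroundKey,
    evidence: Evidence | None = None,
) -> float:
    """Expected entropy reduction on the target from observing the
    candidate, given current evidence:
    H(target | e) - sum_x P(x | e) H(target | e, candidate = x), bits."""
    evidence = evidence or Evidence()
    if candidate in evidence.hard:
        raise InputError(f"candidate {candidate} already carries hard evidence")
    joint = pairwise_joint_model(ground, candidate, target, evidence)
    voi = entropy(joint.sum(axis=0)) - conditional_entropy(joint, axis=0)
    if voi < -1e-12:
        raise AssertionError(f"negative VOI: {voi}")
    return max(float(voi), 0.0)
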
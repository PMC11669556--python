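"""Seeded synthetic longitudinal cohorts.

Provides a 14-node ground-truth dynamic network over five waves — an
8-state nutrition target, an 8-category program-participation variable
observable only from wave 2, lag-1 self-dependencies, and intra-wave
pathways (program -> wealth/food security/well-being -> nutrition) — plus
ancestral sampling, configurable missingness (MCAR or MAR on an
always-observed covariate), and quantization utilities for continuous
inputs.

Ground-truth tables are built by a logistic-contrast recipe: each
variable has a per-state score in [-1, 1]; a child's logits are tilted by
the sum of its parents' scores times an effect-strength multiplier, with
a persistence bonus on lagged self-parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ABSENT, MISSING, PanelDataset
from .errors import InputError
from .network import (
    ConditionalTable,
    DynamicNetwork,
    Slot,
    TemporalArc,
    TemporalStructure,
    VariableSpec,
    unroll,
)

__all__ = [
    "CohortConfig",
    "GroundTruthBundle",
    "default_roster",
    "default_truth",
    "sample_from_network",
    "sample_cohort",
    "quantize",
    "assign_bins",
    "EFFECT_STRENGTHS",
]

EFFECT_STRENGTHS = {"weak": 0.4, "moderate": 1.2, "strong": 2.5}
PERSISTENCE = {"weak": 0.6, "moderate": 1.0, "strong": 1.4}

WAVES = 5

CNS_STATES = ("N", "U", "S", "W", "US", "UW", "SW", "USW")
PS_STATES = ("C", "P", "E", "H", "PE", "PH", "EH", "PEH")
AGE_BANDS = ("Infant", "EarlyChildhood", "Preadolescence", "Adolescent")
ADULT_AGE = ("Under30", "30-50", "Over50")


def default_roster() -> list[VariableSpec]:
    """The 14 modeled variables: the nutrition target plus 13 covariates."""
    return [
        VariableSpec("CNS", CNS_STATES, temporal=True, first_wave=0),
        VariableSpec("CA", AGE_BANDS, temporal=True, first_wave=0),
        VariableSpec("CS", ("Female", "Male"), temporal=False, first_wave=0),
        VariableSpec("MSW", ("Low", "High"), temporal=True, first_wave=0),
        VariableSpec("DA", ADULT_AGE, temporal=True, first_wave=0),
        VariableSpec("DE", ("Illiterate", "Literate"), temporal=True, first_wave=0),
        VariableSpec("MA", ADULT_AGE, temporal=True, first_wave=0),
        VariableSpec("ME", ("Illiterate", "Literate"), temporal=True, first_wave=0),
        VariableSpec("HS", ("<=6", ">6"), temporal=True, first_wave=0),
        VariableSpec("WQ", ("Poor", "Wealthy"), temporal=True, first_wave=0),
        VariableSpec("FS", ("Insecure", "Secure"), temporal=True, first_wave=2),
        VariableSpec("HHA", ADULT_AGE, temporal=True, first_wave=0),
        VariableSpec("HHS", ("Male", "Female"), temporal=True, first_wave=0),
        VariableSpec("PS", PS_STATES, temporal=True, first_wave=2),
    ]


# arcs implausible on subject-matter grounds; the learner must never emit them
EXPERT_BLACKLIST = [
    TemporalArc("DA", "HHS", 0),
    TemporalArc("MSW", "CS", 0),
    TemporalArc("ME", "CS", 0),
    TemporalArc("CS", "WQ", 0),
    TemporalArc("CA", "MA", 0),
]


def _default_arcs() -> set[TemporalArc]:
    arcs = {
        TemporalArc("PS", "MSW", 0),
        TemporalArc("PS", "FS", 0),
        TemporalArc("PS", "WQ", 0),
        TemporalArc("WQ", "FS", 0),
        TemporalArc("WQ", "CNS", 0),
        TemporalArc("FS", "CNS", 0),
        TemporalArc("ME", "CNS", 0),
        TemporalArc("DE", "CNS", 0),
    }
    for v in default_roster():
        if v.temporal:
            arcs.add(TemporalArc(v.name, v.name, 1))
    return arcs


# per-arc effect multipliers: deliberately asymmetric so that collider
# conditioning cannot cancel a direct effect (a faithfulness hazard of a
# fully symmetric tilt recipe)
ARC_WEIGHTS = {
    ("PS", "WQ"): 1.1,
    ("PS", "FS"): 0.45,
    ("PS", "MSW"): 0.85,
    ("WQ", "FS"): 0.95,
    ("WQ", "CNS"): 0.55,
    ("FS", "CNS"): 1.0,
    ("ME", "CNS"): 0.4,
    ("DE", "CNS"): 0.35,
}


def _scores(var: VariableSpec) -> np.ndarray:
    """Per-state 'favorability' score in [-1, 1] used by the tilt recipe."""
    k = var.cardinality
    if var.name == "CNS":
        return np.linspace(1.0, -1.0, k)  # N best, USW worst
    if var.name in ("CA", "CS", "DA", "MA", "HHA", "HHS"):
        return np.zeros(k)  # demographic variables carry no tilt
    return np.linspace(-1.0, 1.0, k)


def _base_logits(var: VariableSpec) -> np.ndarray:
    if var.name == "CNS":
        # mild skew toward N so composite states are rarer, as in survey data
        return np.linspace(0.8, -0.8, var.cardinality)
    return np.zeros(var.cardinality)


def _tilted_table(
    structure: TemporalStructure,
    child: str,
    slots: tuple[Slot, ...],
    strength: float,
    persistence: float,
) -> ConditionalTable:
    cvar = structure.variables[child]
    child_scores = _scores(cvar)
    pvars = [structure.variables[p] for p, _ in slots]
    shape = tuple(v.cardinality for v in pvars) + (cvar.cardinality,)
    values = np.empty(shape)
    for cfg in np.ndindex(shape[:-1]):
        logits = _base_logits(cvar).copy()
        for (pname, lag), pvar, idx in zip(slots, pvars, cfg):
            if pname == child and lag >= 1:
                if lag == 1:
                    logits[idx] += persistence  # sticky states across waves
                else:
                    logits[idx] += 0.5 * persistence
            else:
                weight = ARC_WEIGHTS.get((pname, child), 1.0)
                logits += weight * strength * _scores(pvar)[idx] * child_scores
        ex = np.exp(logits - logits.max())
        values[cfg] = ex / ex.sum()
    return ConditionalTable(child, slots, values)


def _age_table(slots: tuple[Slot, ...]) -> ConditionalTable:
    """Child age advances deterministically, absorbing at the oldest band."""
    k = len(AGE_BANDS)
    if not slots:
        values = np.zeros(k)
        values[0] = 1.0
        return ConditionalTable("CA", slots, values)
    assert slots == (("CA", 1),)
    values = np.zeros((k, k))
    for i in range(k):
        values[i, min(i + 1, k - 1)] = 1.0
    return ConditionalTable("CA", slots, values)


def default_truth(effect_strength: str = "strong") -> DynamicNetwork:
    """Ground-truth generating network over the 14-variable roster."""
    if effect_strength not in EFFECT_STRENGTHS:
        raise InputError(
            f"effect_strength must be one of {sorted(EFFECT_STRENGTHS)}"
        )
    strength = EFFECT_STRENGTHS[effect_strength]
    persistence = PERSISTENCE[effect_strength]
    structure = TemporalStructure(default_roster(), _default_arcs(), WAVES)
    tables: dict[str, dict[tuple[Slot, ...], ConditionalTable]] = {}
    for name, per in structure.table_keys().items():
        for slots in per:
            if name == "CA":
                tab = _age_table(slots)
            else:
                tab = _tilted_table(structure, name, slots, strength, persistence)
            tables.setdefault(name, {})[slots] = tab
    return DynamicNetwork(structure, tables)


# ----------------------------------------------------------------------
# sampling
# ----------------------------------------------------------------------

def sample_from_network(
    net: DynamicNetwork,
    n_subjects: int,
    rng: np.random.Generator | int | None = None,
    subject_prefix: str = "S",
) -> PanelDataset:
    """Ancestral (forward) sampling of ``n_subjects`` complete records."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ground = unroll(net)
    s = net.structure
    variables = list(s.variables.values())
    subjects = [f"{subject_prefix}{i:06d}" for i in range(n_subjects)]
    ds = PanelDataset.empty(subjects, variables, s.horizon)
    drawn: dict[tuple[str, int], np.ndarray] = {}
    for key in ground.order:
        node = ground.nodes[key]
        cpt = node.cpt.reshape(-1, node.cardinality)
        if node.parents:
            pcards = tuple(ground.nodes[p].cardinality for p in node.parents)
            row = np.ravel_multi_index(
                tuple(drawn[p] for p in node.parents), pcards
            )
        else:
            row = np.zeros(n_subjects, dtype=np.int64)
        cum = np.cumsum(cpt, axis=1)[row]
        u = rng.random(n_subjects)
        codes = (cum < u[:, None]).sum(axis=1).astype(np.int16)
        codes = np.minimum(codes, node.cardinality - 1)
        drawn[key] = codes
        ds.codes[:, key[1], ds.var_index[key[0]]] = codes
    return ds


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort draw."""

    n_subjects: int = 1999
    effect_strength: str = "strong"
    missing_mechanism: str = "mcar"  # "mcar" | "mar"
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate <= 0.5):
            raise InputError("missing_rate must be in [0, 0.5]")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise InputError("missing_mechanism must be 'mcar' or 'mar'")
        if self.effect_strength not in EFFECT_STRENGTHS:
            raise InputError(
                f"effect_strength must be one of {sorted(EFFECT_STRENGTHS)}"
            )


@dataclass
class GroundTruthBundle:
    """Generating network, the sampled panel (after masking), the
    pre-masking complete panel, and the boolean removal mask."""

    network: DynamicNetwork
    dataset: PanelDataset
    complete: PanelDataset
    mask: np.ndarray


def _apply_missingness(
    complete: PanelDataset,
    mechanism: str,
    rate: float,
    rng: np.random.Generator,
) -> tuple[PanelDataset, np.ndarray]:
    codes = complete.codes.copy()
    eligible = codes != ABSENT
    if mechanism == "mcar":
        prob = np.full(codes.shape, rate)
    else:
        # MAR: depends only on the always-observed child sex and the wave
        # index, so the mechanism stays ignorable for EM.
        j_cs = complete.var_index["CS"]
        cs = codes[:, :, j_cs]  # (n, waves), never masked itself
        subj_factor = np.where(cs == 1, 1.25, 0.75)  # Male vs Female
        wave_factor = 0.7 + 0.6 * (
            np.arange(complete.waves) / max(complete.waves - 1, 1)
        )
        prob = rate * subj_factor * wave_factor[None, :]
        prob = np.clip(prob, 0.0, 0.5)
        prob = np.repeat(prob[:, :, None], codes.shape[2], axis=2)
        prob[:, :, j_cs] = 0.0
    mask = eligible & (rng.random(codes.shape) < prob)
    codes[mask] = MISSING
    masked = PanelDataset(complete.subjects, complete.variables, complete.waves, codes)
    return masked, mask


def sample_cohort(config: CohortConfig) -> GroundTruthBundle:
    """Sample a cohort: ancestral sampling, then missingness masking.

    Identical configs (including seed) give bit-identical bundles.
    """
    rng = np.random.default_rng(config.seed)
    net = default_truth(config.effect_strength)
    complete = sample_from_network(net, config.n_subjects, rng)
    if config.missing_rate > 0:
        dataset, mask = _apply_missingness(
            complete, config.missing_mechanism, config.missing_rate, rng
        )
    else:
        dataset = complete
        mask = np.zeros(complete.codes.shape, dtype=bool)
    return GroundTruthBundle(network=net, dataset=dataset, complete=complete, mask=mask)


# ----------------------------------------------------------------------
# quantization
# ----------------------------------------------------------------------

def quantize(
    series,
    n_bins: int,
    method: str = "equal-width",
) -> tuple[list[str], np.ndarray]:
    """Discretize a numeric vector into ordered categorical bins.

    Bins are half-open ``[lo, hi)`` with the last bin closed.  Returns
    ``(labels, edges)``; the edges can be re-applied to new data with
    :func:`assign_bins`.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InputError("series must be a non-empty 1-D numeric vector")
    if n_bins < 2:
        raise InputError("n_bins must be >= 2")
    if method == "equal-width":
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:
            raise InputError("constant series cannot be binned")
        edges = np.linspace(lo, hi, n_bins + 1)
    elif method == "equal-frequency":
        if len(np.unique(x)) < n_bins:
            raise InputError(
                "equal-frequency binning needs >= n_bins distinct values; "
                "consider equal-width"
            )
        edges = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
        if np.any(np.diff(edges) <= 0):
            raise InputError(
                "quantile edges are not strictly increasing (heavily tied "
                "series); consider equal-width"
            )
    else:
        raise InputError("method must be 'equal-width' or 'equal-frequency'")
    return assign_bins(x, edges), edges


def assign_bins(series, edges: np.ndarray) -> list[str]:
    """Assign each value to a bin of previously computed ``edges``."""
    x = np.asarray(series, dtype=float)
    idx = np.digitize(x, edges[1:-1], right=False)
    idx = np.clip(idx, 0, len(edges) - 2)
    return [f"Q{i + 1}" for i in idx]
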
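"""Stratified cohort retrieval and task-aware balancing.

Two phases.  Phase I (query-constrained extraction): a query is a conjunction
of attribute constraints ``{a: V_a}``; the feasible set R(q) contains the
samples satisfying every constraint.  Phase II (task-aware balancing): given
a balance field b with control value b0 and ordered match keys K containing a
designated age-stage key, cases (b != b0 within R(q)) are grouped into strata
by their full key tuple and controls (b == b0, same non-b filters) are
matched per stratum — exact on all non-age keys, with the age-stage rank
offset bounded by a tolerance delta.  Matching admits controls layer by layer
(offset 0, then 1, ..., delta), samples without replacement inside a layer
under a seeded deterministic order, optionally upsamples with replacement,
and discards strata with no admissible controls.  Retained strata have equal
case and control counts by construction, and labels are returned row-aligned.

Allocation detail: controls are drawn globally without replacement, and the
offset layers are processed globally (layer d for every stratum before layer
d+1).  Exact-stage controls belong to exactly one stratum, so the layer-0
allocation is independent of delta; consequently the set of retained strata
can only grow as delta grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .data import CohortMatrix, TosgError

__all__ = [
    "Query",
    "TaskConfig",
    "BalancedCohort",
    "execute_query",
    "build_pools",
    "stratified_match",
    "balance_celltypes",
    "correct_batches",
]

logger = logging.getLogger(__name__)


@dataclass
class Query:
    """Conjunctive attribute constraints: attribute name → admissible values."""

    constraints: dict[str, set]

    def __post_init__(self) -> None:
        self.constraints = {a: set(v) for a, v in self.constraints.items()}
        for a, vals in self.constraints.items():
            if not vals:
                raise TosgError(f"admissible set for {a!r} is empty")

    def without(self, attr: str) -> "Query":
        return Query({a: v for a, v in self.constraints.items() if a != attr})


@dataclass
class TaskConfig:
    """Balancing configuration.

    ``balance_field``/``control_value`` define cases vs controls;
    ``match_keys`` are the exact-match covariates with ``age_key`` designating
    the ordered age-stage key ranked by ``age_order``; ``tolerance`` bounds
    the admissible age-stage rank offset; rare classes below
    ``rare_threshold`` may be upsampled for annotation tasks.
    """

    balance_field: str
    control_value: str
    match_keys: list[str]
    age_key: str
    age_order: list[str]
    tolerance: int = 1
    allow_upsample: bool = False
    rare_threshold: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_key not in self.match_keys:
            raise TosgError("age_key must be one of match_keys")
        if self.tolerance < 0:
            raise TosgError("tolerance must be nonnegative")
        if len(set(self.age_order)) != len(self.age_order):
            raise TosgError("age_order has duplicate categories")

    @property
    def rank(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.age_order)}


@dataclass
class BalancedCohort:
    """Matched case-control rows with aligned labels and a per-stratum report."""

    rows: np.ndarray  # positional sample indices into the source cohort
    labels: np.ndarray
    strata_report: pd.DataFrame


def _check_schema(cohort: CohortMatrix, names) -> None:
    cols = set(cohort.attributes.columns)
    missing = [a for a in names if a not in cols]
    if missing:
        raise TosgError(f"unknown attribute name(s): {missing}")


def execute_query(cohort: CohortMatrix, q: Query) -> np.ndarray:
    """Positional indices of samples satisfying every constraint, in input order."""
    _check_schema(cohort, q.constraints)
    mask = np.ones(cohort.n_samples, dtype=bool)
    for a, vals in q.constraints.items():
        mask &= cohort.attributes[a].isin(vals).to_numpy()
    return np.where(mask)[0]


def build_pools(
    cohort: CohortMatrix, q: Query, cfg: TaskConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Case and control pools.

    Cases are feasible samples whose balance-field value differs from the
    control value.  Controls satisfy the query with any constraint on the
    balance field removed, and carry exactly the control value.
    """
    _check_schema(cohort, [cfg.balance_field])
    b = cohort.attributes[cfg.balance_field]
    feasible = execute_query(cohort, q)
    cases = feasible[b.iloc[feasible].to_numpy() != cfg.control_value]
    q_minus_b = q.without(cfg.balance_field)
    ctrl_candidates = execute_query(cohort, q_minus_b)
    controls = ctrl_candidates[
        b.iloc[ctrl_candidates].to_numpy() == cfg.control_value
    ]
    if cfg.control_value not in set(b):
        logger.warning(
            "control value %r absent from %s; control pool empty",
            cfg.control_value, cfg.balance_field,
        )
    return cases, controls


def stratified_match(
    cohort: CohortMatrix,
    cases: np.ndarray,
    controls: np.ndarray,
    cfg: TaskConfig,
) -> BalancedCohort:
    """Per-stratum case-control matching with bounded age-stage offset.

    See the module docstring for the layered allocation rule.  A stratum
    whose admissible control set is empty is discarded; a partially fillable
    stratum is downsized to the matched control count unless upsampling is
    enabled, in which case matched controls are re-drawn with replacement up
    to the stratum size.
    """
    attrs = cohort.attributes
    _check_schema(cohort, cfg.match_keys + [cfg.balance_field])
    rank = cfg.rank
    j_star = cfg.match_keys.index(cfg.age_key)

    def key_tuple(row: int) -> tuple:
        return tuple(str(attrs[k].iloc[row]) for k in cfg.match_keys)

    strata: dict[tuple, list[int]] = {}
    for r in cases:
        strata.setdefault(key_tuple(int(r)), []).append(int(r))
    # index controls by (non-age keys, age value) for layer lookups
    ctrl_index: dict[tuple, list[int]] = {}
    for r in controls:
        ctrl_index.setdefault(key_tuple(int(r)), []).append(int(r))

    ordered = sorted(strata)
    matched: dict[tuple, list[int]] = {k: [] for k in ordered}
    used: set[int] = set()
    root = np.random.SeedSequence(cfg.seed)
    for d in range(cfg.tolerance + 1):
        for si, kappa in enumerate(ordered):
            need = len(strata[kappa]) - len(matched[kappa])
            if need <= 0:
                continue
            age_val = kappa[j_star]
            if age_val not in rank:
                # unranked age stage: only exact (offset 0) matches possible
                offsets = [age_val] if d == 0 else []
            else:
                r0 = rank[age_val]
                offsets = [
                    v for v in cfg.age_order
                    if abs(rank[v] - r0) == d
                ]
            cand: list[int] = []
            for v in offsets:
                key_v = kappa[:j_star] + (v,) + kappa[j_star + 1:]
                cand.extend(x for x in ctrl_index.get(key_v, []) if x not in used)
            if not cand:
                continue
            cand = sorted(cand)  # stable row-id order before the seeded draw
            rng = np.random.default_rng([cfg.seed, d, si])
            take = min(need, len(cand))
            pick = rng.choice(len(cand), size=take, replace=False)
            chosen = [cand[i] for i in sorted(pick)]
            matched[kappa].extend(chosen)
            used.update(chosen)

    b = attrs[cfg.balance_field]
    rows: list[int] = []
    labels: list = []
    report_rows = []
    for si, kappa in enumerate(ordered):
        case_rows = sorted(strata[kappa])
        ctrl_rows = matched[kappa]
        max_offset = 0
        if ctrl_rows and kappa[j_star] in rank:
            max_offset = max(
                abs(rank[str(attrs[cfg.age_key].iloc[r])] - rank[kappa[j_star]])
                for r in ctrl_rows
            )
        discarded = not ctrl_rows
        if discarded:
            report_rows.append(
                {"stratum": "|".join(kappa), "n_cases": 0, "n_controls": 0,
                 "max_age_offset": 0, "discarded": True}
            )
            continue
        if len(ctrl_rows) < len(case_rows):
            if cfg.allow_upsample:
                rng = np.random.default_rng([cfg.seed, 10_000 + si])
                extra = rng.choice(ctrl_rows, size=len(case_rows) - len(ctrl_rows),
                                   replace=True)
                ctrl_rows = ctrl_rows + [int(x) for x in extra]
            else:
                rng = np.random.default_rng([cfg.seed, 20_000 + si])
                keep = rng.choice(len(case_rows), size=len(ctrl_rows), replace=False)
                case_rows = [case_rows[i] for i in sorted(keep)]
                logger.info("stratum %s downsized to %d pairs", kappa, len(ctrl_rows))
        sel = case_rows + ctrl_rows
        rows.extend(sel)
        labels.extend(b.iloc[sel])
        report_rows.append(
            {"stratum": "|".join(kappa), "n_cases": len(case_rows),
             "n_controls": len(ctrl_rows), "max_age_offset": max_offset,
             "discarded": False}
        )
    report = pd.DataFrame(
        report_rows,
        columns=["stratum", "n_cases", "n_controls", "max_age_offset", "discarded"],
    )
    return BalancedCohort(
        rows=np.array(rows, dtype=int),
        labels=np.array(labels, dtype=object),
        strata_report=report,
    )


def balance_celltypes(
    cohort: CohortMatrix, label_field: str, rare_threshold: int = 10, seed: int = 0
) -> np.ndarray:
    """Upsample rare classes (< threshold samples) to the threshold.

    Returns positional row indices; classes at or above the threshold are
    untouched, rare classes gain seeded draws with replacement.  Case/control
    balancing does not apply in this mode (annotation tasks).
    """
    if rare_threshold < 1:
        raise TosgError("rare_threshold must be >= 1")
    _check_schema(cohort, [label_field])
    labels = cohort.attributes[label_field].astype(str)
    rows = list(range(cohort.n_samples))
    rng = np.random.default_rng(seed)
    for cls in sorted(labels.unique()):
        members = np.where((labels == cls).to_numpy())[0]
        if 0 < len(members) < rare_threshold:
            extra = rng.choice(members, size=rare_threshold - len(members), replace=True)
            rows.extend(int(x) for x in extra)
    return np.array(rows, dtype=int)


def correct_batches(
    cohort: CohortMatrix,
    batch_field: str,
    corrector: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    strict: bool = False,
) -> CohortMatrix:
    """Batch-correction hook.

    Delegates to a pluggable ``corrector(features, batches) -> features``.
    The built-in default is the identity with a logged notice; requesting
    strict correction without a plugin is a configuration error.
    """
    _check_schema(cohort, [batch_field])
    if corrector is None:
        if strict:
            raise TosgError("strict batch correction requested but no corrector plugged in")
        logger.info("no batch corrector plugged in; passing features through unchanged")
        return cohort
    batches = cohort.attributes[batch_field].to_numpy()
    corrected = corrector(cohort.features, batches)
    return CohortMatrix(
        features=np.asarray(corrected),
        columns=list(cohort.columns),
        attributes=cohort.attributes.copy(),
        labels=cohort.labels,
        topology=cohort.topology,
    )
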
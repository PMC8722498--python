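"""Scenario market simulation: first choice and Randomized First Choice (RFC).

A scenario is a fully specified testing offer (one level per attribute) or the
opt-out ("none") marker.  Deterministic first choice assigns each respondent to
the scenario with the highest total utility (the opt-out uses the respondent's
none-utility).  RFC instead perturbs utilities before taking the first choice —
an independent Gumbel error per attribute level (shared across scenarios that
hold the level) plus an independent Gumbel error per scenario option — and
averages over many draws, which smooths shares and damps the independence of
irrelevant alternatives problem for similar scenarios.

Uptake is one minus the opt-out share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ClassSpec, DEFAULT_SCALE, utilities_matrix
from .design import DesignConfig, NONE_LABEL, validate_profile
from .utilities import IndividualUtilities

__all__ = [
    "Scenario",
    "SimulationConfig",
    "scenario_sets",
    "scenarios_from_dicts",
    "scenario_utilities",
    "first_choice_shares",
    "rfc_shares",
    "uptake_report",
    "fixture_individuals",
]

log = logging.getLogger(__name__)

OVERALL = "overall"


@dataclass(frozen=True)
class Scenario:
    """A named testing offer (attribute -> level) or the opt-out marker."""

    label: str
    levels: Mapping[str, str] | None = None  # None marks the opt-out scenario

    @property
    def is_none(self) -> bool:
        return self.levels is None


@dataclass
class SimulationConfig:
    """RFC settings: draws per respondent and Gumbel error scales.

    ``attribute_error_scale`` perturbs each attribute-level utility (shared by
    all scenarios holding that level); ``option_error_scale`` perturbs each
    scenario independently.  Both at zero reduce RFC to deterministic first
    choice.
    """

    n_draws: int = 5000
    attribute_error_scale: float = 0.1
    option_error_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.attribute_error_scale < 0 or self.option_error_scale < 0:
            raise ValueError("error scales must be >= 0")


def scenario_sets(validate: bool = True) -> tuple[list[Scenario], list[Scenario]]:
    """The two standard simulation sets.

    Set 1: the two standard testing scenarios (PCR by NP swab, 48-hour results,
    drive-through or walk-in) plus the opt-out.  Set 2 adds less invasive
    (saliva), dual testing (PCR and serology by finger prick) and at-home
    (shallow nasal swab, mail return, within 5 days) scenarios — 6 options.
    """
    standard_drive = Scenario(
        "Standard testing, drive-through",
        {
            "test_type": "PCR",
            "specimen_type": "NP swab",
            "venue": "Drive-through community testing site",
            "turnaround": "48 hours",
        },
    )
    standard_walkin = Scenario(
        "Standard testing, walk-in",
        {
            "test_type": "PCR",
            "specimen_type": "NP swab",
            "venue": "Walk-in community testing site",
            "turnaround": "48 hours",
        },
    )
    less_invasive = Scenario(
        "Less invasive testing",
        {
            "test_type": "PCR",
            "specimen_type": "Saliva",
            "venue": "Walk-in community testing site",
            "turnaround": "48 hours",
        },
    )
    dual = Scenario(
        "Dual testing",
        {
            "test_type": "PCR and serology",
            "specimen_type": "Finger prick",
            "venue": "Walk-in community testing site",
            "turnaround": "48 hours",
        },
    )
    at_home = Scenario(
        "At-home testing",
        {
            "test_type": "PCR",
            "specimen_type": "Shallow nasal swab",
            "venue": "Home collection, return by mail",
            "turnaround": "Within 5 days",
        },
    )
    none = Scenario(NONE_LABEL, None)
    set1 = [standard_drive, standard_walkin, none]
    set2 = [standard_drive, standard_walkin, less_invasive, dual, at_home, none]
    if validate:
        cfg = DesignConfig()
        for s in set2:
            if s.is_none:
                continue
            ok, reason = validate_profile(dict(s.levels), cfg.prohibitions, cfg.attributes)
            if not ok:
                log.warning("scenario %r is off-design: %s", s.label, reason)
    return set1, set2


def scenarios_from_dicts(docs: Sequence[Mapping]) -> list[Scenario]:
    """Scenarios from parsed YAML/JSON: ``{label: ..., none: true}`` for the
    opt-out, otherwise ``{label: ..., levels: {attribute: level, ...}}``."""
    out = []
    for doc in docs:
        if doc.get("none"):
            out.append(Scenario(doc.get("label", NONE_LABEL), None))
        else:
            out.append(Scenario(doc["label"], dict(doc["levels"])))
    return out


def _level_index(ind: IndividualUtilities) -> dict[tuple[str, str], int]:
    out, offset = {}, 0
    for attr in ind.attributes:
        for lvl in attr.levels:
            out[(attr.name, lvl)] = offset
            offset += 1
    return out


def scenario_utilities(
    ind: IndividualUtilities, scenarios: Sequence[Scenario]
) -> np.ndarray:
    """(n_respondents, n_scenarios) total utilities; opt-out uses the none utility."""
    idx = _level_index(ind)
    cols = []
    for s in scenarios:
        if s.is_none:
            cols.append(ind.none)
        else:
            level_ids = [idx[(a, l)] for a, l in s.levels.items()]
            cols.append(ind.levels[:, level_ids].sum(axis=1))
    return np.column_stack(cols)


def _strata(
    assignment: np.ndarray | None, n: int, class_labels: Sequence[str] | None
) -> list[tuple[str, np.ndarray]]:
    out: list[tuple[str, np.ndarray]] = [(OVERALL, np.ones(n, dtype=bool))]
    if assignment is not None:
        assignment = np.asarray(assignment)
        for c in np.unique(assignment):
            name = class_labels[c] if class_labels is not None else f"class_{c}"
            out.append((str(name), assignment == c))
    return out


def first_choice_shares(
    ind: IndividualUtilities,
    scenarios: Sequence[Scenario],
    assignment: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    class_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Deterministic share of preference: each respondent picks the
    maximum-total-utility scenario; exact ties split equally (and are logged).

    Returns a tidy table (scenario x stratum) of shares; strata are ``overall``
    plus one per assigned class when ``assignment`` is given.  ``weights``
    optionally weight respondents (e.g. class shares for per-class
    representative utilities).
    """
    totals = scenario_utilities(ind, scenarios)
    n, S = totals.shape
    best = totals.max(axis=1, keepdims=True)
    is_max = totals == best
    n_ties = is_max.sum(axis=1)
    if (n_ties > 1).any():
        log.info("%d respondent(s) with tied first choices split equally",
                 int((n_ties > 1).sum()))
    pick = is_max / n_ties[:, None]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    rows = []
    for stratum, mask in _strata(assignment, n, class_labels):
        ws = w[mask]
        share = (pick[mask] * ws[:, None]).sum(axis=0) / ws.sum()
        for s, val in zip(scenarios, share):
            rows.append({"scenario": s.label, "stratum": stratum,
                         "share": float(val), "mc_se": 0.0})
    return pd.DataFrame(rows)


def rfc_shares(
    ind: IndividualUtilities,
    scenarios: Sequence[Scenario],
    config: SimulationConfig | None = None,
    assignment: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    class_labels: Sequence[str] | None = None,
    chunk_size: int = 64,
) -> pd.DataFrame:
    """Randomized First Choice share of preference.

    Per draw and respondent, each attribute-level utility gets an independent
    Gumbel error (shared across scenarios holding that level) and each scenario
    an independent Gumbel option error; the perturbed first choice is
    tabulated over ``config.n_draws`` draws.  Deterministic given
    ``config.seed``.  With both error scales zero this equals
    :func:`first_choice_shares` exactly.
    """
    config = config or SimulationConfig()
    if config.attribute_error_scale == 0 and config.option_error_scale == 0:
        return first_choice_shares(ind, scenarios, assignment, weights, class_labels)

    idx = _level_index(ind)
    used = sorted({idx[(a, l)] for s in scenarios if not s.is_none for a, l in s.levels.items()})
    pos = {g: k for k, g in enumerate(used)}
    S = len(scenarios)
    M = np.zeros((S, len(used)))  # scenario x used-level incidence
    for j, s in enumerate(scenarios):
        if s.is_none:
            continue
        for a, l in s.levels.items():
            M[j, pos[idx[(a, l)]]] = 1.0

    base = scenario_utilities(ind, scenarios)  # (n, S)
    n = base.shape[0]
    D = config.n_draws
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    strata = _strata(assignment, n, class_labels)
    rng = np.random.default_rng(config.seed)

    # per-stratum, per-draw weighted share accumulators
    counts = np.zeros((len(strata), D, S))
    wsum = np.array([w[mask].sum() for _, mask in strata])
    stratum_masks = [mask for _, mask in strata]

    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        R = stop - start
        totals = np.broadcast_to(base[start:stop, None, :], (R, D, S)).copy()
        if config.attribute_error_scale > 0:
            attr_err = rng.gumbel(0.0, config.attribute_error_scale, size=(R, D, len(used)))
            totals += attr_err @ M.T
        if config.option_error_scale > 0:
            totals += rng.gumbel(0.0, config.option_error_scale, size=(R, D, S))
        winner = totals.argmax(axis=2)  # (R, D)
        draws = np.broadcast_to(np.arange(D), (R, D))
        for si, mask in enumerate(stratum_masks):
            sub = mask[start:stop]
            if not sub.any():
                continue
            flat = draws[sub] * S + winner[sub]
            counts[si] += np.bincount(
                flat.ravel(), weights=np.repeat(w[start:stop][sub], D), minlength=D * S
            ).reshape(D, S)

    rows = []
    for si, (stratum, _) in enumerate(strata):
        share_per_draw = counts[si] / wsum[si]  # (D, S)
        share = share_per_draw.mean(axis=0)
        se = share_per_draw.std(ddof=1, axis=0) / np.sqrt(D) if D > 1 else np.zeros(S)
        for j, s in enumerate(scenarios):
            rows.append({"scenario": s.label, "stratum": stratum,
                         "share": float(share[j]), "mc_se": float(se[j])})
    return pd.DataFrame(rows)


def uptake_report(sim1: pd.DataFrame, sim2: pd.DataFrame) -> pd.DataFrame:
    """Uptake (one minus the opt-out share, in %) per stratum for both
    simulation sets, with the percentage-point gain from set 1 to set 2."""
    out = []
    for name, table in (("sim1", sim1), ("sim2", sim2)):
        none_rows = table[table["scenario"] == NONE_LABEL]
        if none_rows.empty:
            raise ValueError(f"{name}: scenarios must include the {NONE_LABEL} option")
        sub = none_rows.set_index("stratum")["share"]
        out.append((100.0 * (1.0 - sub)).rename(f"uptake_{name}_pct"))
    report = pd.concat(out, axis=1).reset_index()
    report["delta_pp"] = np.round(
        report["uptake_sim2_pct"] - report["uptake_sim1_pct"], 1
    )
    for col in ("uptake_sim1_pct", "uptake_sim2_pct"):
        report[col] = np.round(report[col], 1)
    return report


def fixture_individuals(
    classes: Sequence[ClassSpec], scale: float = DEFAULT_SCALE
) -> tuple[IndividualUtilities, np.ndarray, np.ndarray]:
    """One pseudo-respondent per class, holding that class's utilities on the
    simulation (logit) scale; returns (utilities, assignment, class-share
    weights).  Useful for scenario simulation directly from class
    specifications without a refit.
    """
    attributes = DesignConfig().attributes
    mat, none = utilities_matrix(classes, attributes)
    ind = IndividualUtilities(
        attributes=attributes,
        respondent_ids=np.arange(1, len(classes) + 1),
        levels=scale * mat,
        none=scale * none,
    )
    assignment = np.arange(len(classes))
    weights = np.asarray([c.share for c in classes], dtype=float)
    return ind, assignment, weights
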
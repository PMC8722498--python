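"""Study-emulation experiments: recovery, model selection, scenario simulation, quality.

These functions bundle the package's end-to-end experiments at the emulated
study's conditions (4,793 respondents, 5 tasks of 2 profiles plus opt-out,
five preference classes, display utilities mapped to the logit scale by the
1/50 factor).  Each returns plain dictionaries/DataFrames so callers can
assert on or report the quantities directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cohort import (
    CohortSpec,
    QualityInjection,
    study_fixture_classes,
    utilities_matrix,
    well_separated_classes,
)
from .lcmnl import ChoiceData, EMConfig, em_fit, match_classes, sweep_classes
from .quality import detect_straightlining, exclusion_sensitivity, flag_speeders
from .rfc import SimulationConfig, fixture_individuals, rfc_shares, scenario_sets, uptake_report
from .utilities import assign_classes, individual_utilities, relative_importance

__all__ = [
    "choice_data_from_frame",
    "simulate_fixture_cohort",
    "fixture_recovery",
    "model_selection",
    "rfc_fixture_simulation",
    "quality_screens",
    "exclusion_experiment",
]


def choice_data_from_frame(observations: pd.DataFrame) -> ChoiceData:
    return ChoiceData.from_frame(observations)


def simulate_fixture_cohort(
    n_respondents: int = 4793,
    seed: int = 42,
    injection: QualityInjection | None = None,
):
    """Fixture cohort at study scale; returns (data, truth, classes, design)."""
    from .cohort import simulate_cohort

    classes = study_fixture_classes()
    spec = CohortSpec(
        classes=classes,
        n_respondents=n_respondents,
        seed=seed,
        injection=injection or QualityInjection(),
    )
    obs, truth, design = simulate_cohort(spec)
    chosen = obs["chosen"].to_numpy(dtype=np.int64).reshape(-1, 3).argmax(axis=1)
    data = ChoiceData.from_design(design, chosen)
    return data, truth, classes, design


def _fixture_top_range_attr(classes) -> dict[str, str]:
    out = {}
    for c in classes:
        ranges = {
            a: max(tab.values()) - min(tab.values()) for a, tab in c.utilities.items()
        }
        out[c.label] = max(ranges, key=ranges.get)
    return out


def fixture_recovery(
    n_respondents: int = 4793,
    cohort_seed: int = 42,
    em_seed: int = 7,
    n_replications: int = 5,
    max_iter: int = 100,
) -> dict:
    """Fit K=5 to the fixture cohort and compare with the generator's truth.

    Returns adjusted Rand index of the max-posterior partition vs true labels,
    per-class share errors (percentage points, classes matched by utility
    correlation), and the class-level / member-level agreement between the
    estimated top-importance attribute and the fixture's largest-range
    attribute.
    """
    data, truth, classes, design = simulate_fixture_cohort(n_respondents, cohort_seed)
    labels = np.array([c.label for c in classes])
    cfg = EMConfig(
        n_classes=len(classes),
        n_replications=n_replications,
        max_iter=max_iter,
        random_state=em_seed,
    )
    model = em_fit(data, cfg)

    est_u, est_none = model.expanded_utilities()
    true_u, true_none = utilities_matrix(classes, design.attributes)
    scale = CohortSpec(classes=classes, n_respondents=n_respondents).scale
    perm = match_classes(
        np.column_stack([est_u, est_none]),
        np.column_stack([true_u * scale, true_none * scale]),
    )
    assignment = assign_classes(model.posteriors)
    ari = adjusted_rand_score(truth["true_class"], labels[perm[assignment]])

    share_err = {
        str(labels[perm[c]]): 100.0 * (model.shares[c] - classes[perm[c]].share)
        for c in range(len(classes))
    }

    ind = individual_utilities(model)
    imp = relative_importance(ind)
    attrs = [c for c in imp.columns if c != "respondent_id"]
    top_range = _fixture_top_range_attr(classes)
    class_match = {}
    member_agreement = {}
    for c in range(len(classes)):
        members = assignment == c
        fixture_label = str(labels[perm[c]])
        est_top = imp.loc[members, attrs].mean().idxmax() if members.any() else ""
        class_match[fixture_label] = (est_top, top_range[fixture_label])
        member_agreement[fixture_label] = float(
            (imp.loc[members, attrs].idxmax(axis=1) == top_range[fixture_label]).mean()
        ) if members.any() else np.nan
    return {
        "model": model,
        "truth": truth,
        "classes": classes,
        "ari": float(ari),
        "share_errors_pp": share_err,
        "true_shares": {c.label: c.share for c in classes},
        "class_top_attr": class_match,
        "member_top_attr_agreement": member_agreement,
        "matching": perm,
        "assignment": assignment,
    }


def model_selection(
    seeds=(11, 12, 13, 14, 15),
    n_respondents: int = 3000,
    true_classes: int = 3,
    k_values=(2, 3, 4, 5),
    n_replications: int = 2,
    em_seed: int = 5,
    tol: float = 1e-5,
) -> pd.DataFrame:
    """BIC model selection on well-separated synthetic cohorts.

    One cohort per generator seed; each is swept over ``k_values`` and the
    BIC-minimizing K is recorded.
    """
    from .cohort import simulate_cohort

    classes = well_separated_classes(true_classes)
    rows = []
    for seed in seeds:
        spec = CohortSpec(classes=classes, n_respondents=n_respondents, seed=seed)
        obs, _, design = simulate_cohort(spec)
        chosen = obs["chosen"].to_numpy(dtype=np.int64).reshape(-1, 3).argmax(axis=1)
        data = ChoiceData.from_design(design, chosen)
        cfg = EMConfig(
            n_classes=k_values[0],
            n_replications=n_replications,
            tol=tol,
            random_state=em_seed,
        )
        table = sweep_classes(data, k_values, cfg)
        ok = table.dropna(subset=["bic"])
        selected = int(ok.loc[ok["bic"].idxmin(), "n_classes"])
        rows.append({"generator_seed": seed, "selected_k": selected,
                     **{f"bic_k{int(k)}": float(table.loc[table.n_classes == k, 'bic'].iloc[0])
                        for k in k_values}})
    return pd.DataFrame(rows)


def rfc_fixture_simulation(
    n_draws: int = 20000, seed: int = 1
) -> dict:
    """Both scenario-set simulations directly on the fixture class utilities.

    No refit: one pseudo-respondent per class (class-share weighted) on the
    simulation scale.  Returns the two share tables and the uptake report.
    """
    classes = study_fixture_classes()
    ind, assignment, weights = fixture_individuals(classes)
    labels = [c.label for c in classes]
    set1, set2 = scenario_sets()
    s1 = rfc_shares(ind, set1, SimulationConfig(n_draws=n_draws, seed=seed),
                    assignment, weights, labels)
    s2 = rfc_shares(ind, set2, SimulationConfig(n_draws=n_draws, seed=seed + 1),
                    assignment, weights, labels)
    return {
        "shares_sim1": s1,
        "shares_sim2": s2,
        "uptake": uptake_report(s1, s2),
        "class_labels": labels,
    }


def quality_screens(
    n_respondents: int = 4793,
    straightline_frac: float = 0.05,
    speeder_frac: float = 0.05,
    seed: int = 21,
) -> dict:
    """Inject straightliners and speeders, run the detectors, count misses."""
    data, truth, _, _ = simulate_fixture_cohort(
        n_respondents,
        seed,
        injection=QualityInjection(
            straightline_frac=straightline_frac, speeder_frac=speeder_frac
        ),
    )
    straight = detect_straightlining(data)
    times = truth["completion_time"].to_numpy()
    flags5 = flag_speeders(times, 5.0)
    flags10 = flag_speeders(times, 10.0)
    injected_straight = truth["injected_straightliner"].to_numpy()
    injected_speed = truth["injected_speeder"].to_numpy()
    return {
        "straight_flags": straight,
        "n_straight_flagged": int(straight["straightline"].sum()),
        "straight_misses": int((injected_straight & ~straight["straightline"]).sum()),
        "n_speeders_5pct": int(flags5.sum()),
        "n_speeders_10pct": int(flags10.sum()),
        "speeder_misses_10pct": int((injected_speed & ~flags10).sum()),
        "truth": truth,
    }


def exclusion_experiment(
    n_respondents: int = 4793,
    random_frac: float = 0.08,
    seed: int = 33,
    em_seed: int = 7,
    n_replications: int = 2,
) -> dict:
    """Exclusion-sensitivity refit: remove injected random-choice respondents
    (plus detected straightliners/speeders) and compare class structure."""
    data, truth, classes, _ = simulate_fixture_cohort(
        n_respondents, seed, injection=QualityInjection(random_frac=random_frac)
    )
    straight = detect_straightlining(data)["straightline"].to_numpy()
    speeders = flag_speeders(truth["completion_time"].to_numpy(), 10.0)
    flagged = truth["injected_random"].to_numpy() | straight | speeders
    cfg = EMConfig(n_classes=len(classes), n_replications=n_replications,
                   random_state=em_seed)
    report = exclusion_sensitivity(data, flagged, cfg)
    return {"report": report, "n_flagged": int(flagged.sum()), "truth": truth}
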
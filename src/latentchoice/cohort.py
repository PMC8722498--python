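"""Synthetic latent-class cohort: ground-truth preference classes and simulated choices.

The generator draws each respondent's latent class from the mixing shares, then
simulates every choice task under a multinomial logit (MNL) response model:
the probability of picking an option is the softmax of ``scale x total utility``
over the two shown profiles and the opt-out option.  Published class-level
utilities are display-scale zero-centered values (magnitudes 10-300); the
``scale`` multiplier (default 1/50) maps them onto the logit scale so that the
modal option is chosen most but not all of the time, which keeps the recovery
problem statistically honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import (
    NONE_LABEL,
    AttributeSpec,
    ChoiceTask,
    Design,
    DesignConfig,
    DesignError,
    Profile,
    generate_design,
)

__all__ = [
    "ClassSpec",
    "CohortSpec",
    "QualityInjection",
    "study_fixture_classes",
    "well_separated_classes",
    "load_class_specs",
    "total_utility",
    "choice_probabilities",
    "simulate_cohort",
    "utilities_matrix",
]

DEFAULT_SCALE = 1.0 / 50.0


@dataclass(frozen=True)
class ClassSpec:
    """One latent preference class: mixing share and part-worth utilities.

    ``utilities[attr][level]`` are zero-centered within each attribute;
    ``none_utility`` is the opt-out constant on the same scale.
    ``reconstructed`` marks (attribute, level) pairs whose values were filled
    by the zero-sum rule rather than taken from a published table.
    """

    label: str
    share: float
    utilities: Mapping[str, Mapping[str, float]]
    none_utility: float
    reconstructed: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if not (0.0 <= self.share <= 1.0):
            raise ValueError(f"class {self.label!r}: share must lie in [0, 1]")
        for attr, levels in self.utilities.items():
            total = sum(levels.values())
            if abs(total) > 1e-9:
                raise ValueError(
                    f"class {self.label!r}: utilities of {attr!r} sum to {total}, not 0"
                )

    def level_vector(self, attributes: Sequence[AttributeSpec]) -> np.ndarray:
        """Utilities flattened in design order (levels of attr 1, attr 2, ...)."""
        out = []
        for attr in attributes:
            table = self.utilities[attr.name]
            out.extend(table[lvl] for lvl in attr.levels)
        return np.asarray(out, dtype=float)


@dataclass
class QualityInjection:
    """Fractions of low-quality respondents to inject into a simulated cohort."""

    straightline_frac: float = 0.0
    random_frac: float = 0.0
    speeder_frac: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.straightline_frac, self.random_frac, self.speeder_frac):
            if not (0.0 <= f <= 1.0):
                raise ValueError("injection fractions must lie in [0, 1]")


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort."""

    classes: list[ClassSpec]
    n_respondents: int = 4793
    design: DesignConfig = field(default_factory=DesignConfig)
    scale: float = DEFAULT_SCALE
    seed: int = 0
    injection: QualityInjection = field(default_factory=QualityInjection)

    def __post_init__(self) -> None:
        if self.n_respondents < len(self.classes):
            raise ValueError("need at least one respondent per class")
        if self.scale <= 0:
            raise ValueError("utility scale factor must be positive")
        total = sum(c.share for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class shares sum to {total}, not 1")


def load_class_specs(source) -> list[ClassSpec]:
    """Load class specs from a YAML mapping (path, stream, or parsed dict).

    Unpublished levels are reconstructed so each attribute's utilities sum to
    zero, splitting the residual equally among the missing levels.
    """
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    attributes = DesignConfig().attributes
    by_name = {a.name: a for a in attributes}
    specs = []
    for cls in doc["classes"]:
        utilities: dict[str, dict[str, float]] = {}
        reconstructed: set[tuple[str, str]] = set()
        for attr_name, attr in by_name.items():
            printed = dict(cls.get("printed", {}).get(attr_name, {}))
            unknown = set(printed) - set(attr.levels)
            if unknown:
                raise DesignError(f"unknown level(s) {sorted(unknown)} for {attr_name!r}")
            missing = [lvl for lvl in attr.levels if lvl not in printed]
            residual = -sum(printed.values())
            fill = residual / len(missing) if missing else 0.0
            table = {lvl: float(printed.get(lvl, fill)) for lvl in attr.levels}
            reconstructed.update((attr_name, lvl) for lvl in missing)
            utilities[attr_name] = table
        specs.append(
            ClassSpec(
                label=cls["label"],
                share=float(cls["share"]),
                utilities=utilities,
                none_utility=float(cls["none_utility"]),
                reconstructed=frozenset(reconstructed),
            )
        )
    return specs


def study_fixture_classes() -> list[ClassSpec]:
    """The five-segment preference fixture shipped with the package.

    Shares (19.2 / 25.8 / 18.5 / 32.9 / 3.6 %) and all published utilities are
    stored verbatim; unpublished levels are zero-sum reconstructions flagged in
    ``ClassSpec.reconstructed``.
    """
    ref = resources.files("latentchoice.data").joinpath("five_class_fixture.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_class_specs(fh)


def well_separated_classes(n_classes: int = 3, strength: float = 120.0) -> list[ClassSpec]:
    """Construct strongly separated synthetic classes for recovery experiments.

    Class ``c`` places utility ``+strength`` on level ``c`` of every attribute
    and spreads ``-strength`` over the remaining levels (zero-centered), so any
    two classes disagree on every attribute.  Opt-out utility is a large
    negative constant; mixing shares decrease linearly across classes.
    """
    attributes = DesignConfig().attributes
    if n_classes > min(a.n_levels for a in attributes):
        raise ValueError("n_classes must not exceed the smallest level count")
    raw_shares = np.arange(n_classes, 0, -1, dtype=float)
    shares = raw_shares / raw_shares.sum()
    specs = []
    for c in range(n_classes):
        utilities = {}
        for attr in attributes:
            L = attr.n_levels
            utilities[attr.name] = {
                lvl: (strength if k == c else -strength / (L - 1))
                for k, lvl in enumerate(attr.levels)
            }
        specs.append(
            ClassSpec(
                label=f"segment_{c + 1}",
                share=float(shares[c]),
                utilities=utilities,
                none_utility=-2.0 * strength,
            )
        )
    return specs


def total_utility(
    profile: Profile | Mapping[str, str] | None,
    class_spec: ClassSpec,
    attributes: Sequence[AttributeSpec] | None = None,
) -> float:
    """Total utility of a profile under one class: sum of its level part-worths.

    ``profile=None`` (or the NONE label) returns the class's opt-out constant.
    """
    if profile is None or (isinstance(profile, str) and profile == NONE_LABEL):
        return float(class_spec.none_utility)
    if attributes is None:
        attributes = DesignConfig().attributes
    if isinstance(profile, Profile):
        levels = profile.labels(attributes)
    else:
        levels = dict(profile)
    total = 0.0
    for attr in attributes:
        table = class_spec.utilities[attr.name]
        label = levels[attr.name]
        if label not in table:
            raise DesignError(f"unknown level {label!r} for attribute {attr.name!r}")
        total += table[label]
    return float(total)


def softmax(utilities: np.ndarray, axis: int = -1) -> np.ndarray:
    """Overflow-safe softmax (max-subtraction)."""
    u = np.asarray(utilities, dtype=float)
    u = u - np.max(u, axis=axis, keepdims=True)
    e = np.exp(u)
    return e / np.sum(e, axis=axis, keepdims=True)


def choice_probabilities(
    task: ChoiceTask,
    class_spec: ClassSpec,
    scale: float = DEFAULT_SCALE,
    attributes: Sequence[AttributeSpec] | None = None,
) -> np.ndarray:
    """MNL probabilities over (alternative 1, alternative 2, NONE) for one task."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if attributes is None:
        attributes = DesignConfig().attributes
    utils = [total_utility(p, class_spec, attributes) for p in task.alternatives]
    if task.has_none:
        utils.append(class_spec.none_utility)
    return softmax(scale * np.asarray(utils))


def utilities_matrix(
    classes: Sequence[ClassSpec], attributes: Sequence[AttributeSpec]
) -> tuple[np.ndarray, np.ndarray]:
    """(K, total_levels) level-utility matrix plus (K,) opt-out constants."""
    mat = np.stack([c.level_vector(attributes) for c in classes])
    none = np.asarray([c.none_utility for c in classes], dtype=float)
    return mat, none


def _option_utilities(
    design: Design, classes: Sequence[ClassSpec]
) -> np.ndarray:
    """(K, n_tasks, 3) total utilities of (alt1, alt2, NONE) per class."""
    attrs = design.attributes
    offsets = np.cumsum([0] + [a.n_levels for a in attrs])[:-1]
    flat_codes = design.codes + offsets[None, None, :]  # (n_tasks, 2, A) global level ids
    mat, none = utilities_matrix(classes, attrs)
    u = mat[:, flat_codes].sum(axis=-1)  # (K, n_tasks, 2)
    u_none = np.broadcast_to(none[:, None, None], (len(classes), design.n_tasks, 1))
    return np.concatenate([u, u_none], axis=-1)


def simulate_cohort(
    cohort: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, Design]:
    """Simulate a cohort end to end.

    Returns ``(observations, truth, design)``:

    - observations: long format, one row per option per task, with a 0/1
      ``chosen`` column (NONE rows carry empty attribute cells);
    - truth: per respondent — true class label, injected-behavior flags, and a
      completion time in seconds (log-normal baseline, median ~180 s; injected
      speeders draw uniform 10-40 s);
    - design: the generated :class:`~latentchoice.design.Design`.

    Deterministic given ``cohort.seed``.
    """
    rng = np.random.default_rng(cohort.seed)
    design_cfg = cohort.design
    design_cfg.seed = int(rng.integers(0, 2**31 - 1))
    design = generate_design(design_cfg, cohort.n_respondents)
    n = cohort.n_respondents
    K = len(cohort.classes)

    shares = np.asarray([c.share for c in cohort.classes])
    class_idx = rng.choice(K, size=n, p=shares / shares.sum())

    util = _option_utilities(design, cohort.classes)  # (K, n_tasks, 3)
    probs = softmax(cohort.scale * util, axis=-1)
    resp_of_task = design.respondent_ids - 1
    task_probs = probs[class_idx[resp_of_task], np.arange(design.n_tasks)]  # (n_tasks, 3)

    u = rng.random(design.n_tasks)
    cum = np.cumsum(task_probs, axis=1)
    chosen = (u[:, None] > cum).sum(axis=1)  # 0, 1, or 2 (NONE)

    inj = cohort.injection
    n_straight = int(round(inj.straightline_frac * n))
    n_random = int(round(inj.random_frac * n))
    n_speed = int(round(inj.speeder_frac * n))
    perm = rng.permutation(n)
    straight_ids = perm[:n_straight]
    random_ids = perm[n_straight : n_straight + n_random]
    speed_ids = rng.permutation(n)[:n_speed]

    if n_straight:
        side = rng.integers(0, 2, size=n_straight)  # 0 = always left, 1 = always right
        straight_side = np.full(n, -1)
        straight_side[straight_ids] = side
        mask = straight_side[resp_of_task] >= 0
        chosen[mask] = straight_side[resp_of_task][mask]
    if n_random:
        is_random = np.zeros(n, dtype=bool)
        is_random[random_ids] = True
        mask = is_random[resp_of_task]
        chosen[mask] = rng.integers(0, 3, size=int(mask.sum()))

    times = np.exp(rng.normal(np.log(180.0), 0.5, size=n))
    if n_speed:
        times[speed_ids] = rng.uniform(10.0, 40.0, size=n_speed)

    obs = design.to_frame()
    chosen_col = np.zeros(3 * design.n_tasks, dtype=np.int64)
    chosen_col[np.arange(design.n_tasks) * 3 + chosen] = 1
    obs["chosen"] = chosen_col

    labels = np.asarray([c.label for c in cohort.classes], dtype=object)
    truth = pd.DataFrame(
        {
            "respondent_id": np.arange(1, n + 1),
            "true_class": labels[class_idx],
            "injected_straightliner": np.isin(np.arange(n), straight_ids),
            "injected_random": np.isin(np.arange(n), random_ids),
            "injected_speeder": np.isin(np.arange(n), speed_ids),
            "completion_time": times,
        }
    )
    return obs, truth, design
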
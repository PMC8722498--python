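"""Choice-task design: attributes, levels, prohibitions, and randomized task generation.

A discrete choice experiment (DCE) presents each respondent with a series of
choice tasks; each task shows two constructed testing profiles plus an opt-out
("none of these") option.  Profiles are combinations of one level per attribute,
randomized under level-balance and real-world feasibility constraints
(prohibited level pairs, e.g. a nasopharyngeal swab cannot be self-collected at
home).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AttributeSpec",
    "Prohibition",
    "Profile",
    "ChoiceTask",
    "DesignConfig",
    "Design",
    "build_default_attributes",
    "generate_design",
    "validate_profile",
    "NONE_LABEL",
]

#: label used for the opt-out alternative in long-format tables
NONE_LABEL = "NONE"

TEST_TYPE = "test_type"
SPECIMEN = "specimen_type"
VENUE = "venue"
TURNAROUND = "turnaround"


class DesignError(ValueError):
    """Invalid design vocabulary or infeasible configuration."""


@dataclass(frozen=True)
class AttributeSpec:
    """One experimental attribute and its ordered levels.

    Level codes are the 0-based positions in ``levels``; labels appear only at
    I/O boundaries.
    """

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise DesignError(f"attribute {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise DesignError(f"attribute {self.name!r} has duplicate level labels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def code(self, label: str) -> int:
        try:
            return self.levels.index(label)
        except ValueError:
            raise DesignError(f"unknown level {label!r} for attribute {self.name!r}") from None


@dataclass(frozen=True)
class Prohibition:
    """A pair of (attribute, level) that may not co-occur in one profile."""

    first: tuple[str, str]
    second: tuple[str, str]

    def validate(self, attributes: Sequence[AttributeSpec]) -> None:
        by_name = {a.name: a for a in attributes}
        for attr, level in (self.first, self.second):
            if attr not in by_name:
                raise DesignError(f"prohibition references unknown attribute {attr!r}")
            if level not in by_name[attr].levels:
                raise DesignError(
                    f"prohibition references unknown level {level!r} of attribute {attr!r}"
                )


@dataclass(frozen=True)
class Profile:
    """One testing scenario: exactly one level code per attribute, in design order."""

    codes: tuple[int, ...]

    def labels(self, attributes: Sequence[AttributeSpec]) -> dict[str, str]:
        return {a.name: a.levels[c] for a, c in zip(attributes, self.codes)}


@dataclass(frozen=True)
class ChoiceTask:
    """One respondent-task: two alternative profiles plus the opt-out option."""

    respondent_id: int
    task: int
    alternatives: tuple[Profile, Profile]
    has_none: bool = True


@dataclass
class DesignConfig:
    """Configuration reproducing the study's task structure by default."""

    attributes: list[AttributeSpec] = field(default_factory=lambda: build_default_attributes()[0])
    prohibitions: list[Prohibition] = field(default_factory=lambda: build_default_attributes()[1])
    tasks_per_respondent: int = 5
    alternatives_per_task: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise DesignError("attribute names must be unique within a design")
        for p in self.prohibitions:
            p.validate(self.attributes)
        if self.tasks_per_respondent < 1 or self.alternatives_per_task != 2:
            raise DesignError("design requires >=1 task of exactly 2 alternatives")
        self._check_feasible()

    def _check_feasible(self) -> None:
        # A level is dead if it is prohibited against every level of some other
        # attribute; an attribute is infeasible if all its levels are dead.
        for attr in self.attributes:
            live = 0
            for level in attr.levels:
                dead = False
                for other in self.attributes:
                    if other.name == attr.name:
                        continue
                    blocked = {
                        lvl
                        for p in self.prohibitions
                        for (a1, l1), (a2, l2) in [(p.first, p.second), (p.second, p.first)]
                        if a1 == attr.name and l1 == level and a2 == other.name
                        for lvl in [l2]
                    }
                    if len(blocked) >= other.n_levels:
                        dead = True
                if not dead:
                    live += 1
            if live == 0:
                raise DesignError(
                    f"prohibitions exclude every level of attribute {attr.name!r}"
                )


def build_default_attributes() -> tuple[list[AttributeSpec], list[Prohibition]]:
    """Canonical study vocabulary: 4 attributes (3/7/5/4 levels) and 2 prohibitions.

    The prohibitions forbid the nasopharyngeal (NP) swab specimen in either
    at-home collection venue, since an NP swab cannot be self-collected.
    """
    attributes = [
        AttributeSpec(TEST_TYPE, ("PCR", "Serology", "PCR and serology")),
        AttributeSpec(
            SPECIMEN,
            (
                "NP swab",
                "Shallow nasal swab",
                "Saliva",
                "Cheek swab",
                "Finger prick",
                "Blood draw",
                "Urine",
            ),
        ),
        AttributeSpec(
            VENUE,
            (
                "Drive-through community testing site",
                "Walk-in community testing site",
                "Doctor's office or urgent care",
                "Home collection, return by mail",
                "Home collection, return to collection site",
            ),
        ),
        AttributeSpec(TURNAROUND, ("Immediate", "Same day", "48 hours", "Within 5 days")),
    ]
    prohibitions = [
        Prohibition((SPECIMEN, "NP swab"), (VENUE, "Home collection, return by mail")),
        Prohibition((SPECIMEN, "NP swab"), (VENUE, "Home collection, return to collection site")),
    ]
    return attributes, prohibitions


def _prohibition_codes(
    attributes: Sequence[AttributeSpec], prohibitions: Iterable[Prohibition]
) -> list[tuple[int, int, int, int]]:
    """Prohibitions as (attr_idx1, code1, attr_idx2, code2)."""
    idx = {a.name: i for i, a in enumerate(attributes)}
    out = []
    for p in prohibitions:
        (a1, l1), (a2, l2) = p.first, p.second
        i1, i2 = idx[a1], idx[a2]
        out.append((i1, attributes[i1].code(l1), i2, attributes[i2].code(l2)))
    return out


def validate_profile(
    profile: Profile | Mapping[str, str],
    prohibitions: Iterable[Prohibition],
    attributes: Sequence[AttributeSpec] | None = None,
) -> tuple[bool, str | None]:
    """Accept/reject a profile against the prohibition list.

    Returns ``(True, None)`` if no prohibited pair co-occurs, otherwise
    ``(False, reason)``.  Raises :class:`DesignError` for unknown levels.
    """
    if attributes is None:
        attributes = build_default_attributes()[0]
    if isinstance(profile, Profile):
        if len(profile.codes) != len(attributes):
            raise DesignError("profile must hold exactly one level per attribute")
        levels = {a.name: a.levels[c] for a, c in zip(attributes, profile.codes)}
    else:
        levels = {}
        by_name = {a.name: a for a in attributes}
        for attr, label in profile.items():
            if attr not in by_name:
                raise DesignError(f"unknown attribute {attr!r}")
            by_name[attr].code(label)  # raises on unknown level
            levels[attr] = label
    for p in prohibitions:
        (a1, l1), (a2, l2) = p.first, p.second
        if levels.get(a1) == l1 and levels.get(a2) == l2:
            return False, f"prohibited combination: {a1}={l1!r} with {a2}={l2!r}"
    return True, None


@dataclass
class Design:
    """A generated design: profile level codes plus task bookkeeping.

    ``codes`` has shape (n_tasks, 2, n_attributes); rows are ordered by
    respondent then task index.
    """

    attributes: list[AttributeSpec]
    codes: np.ndarray
    respondent_ids: np.ndarray  # (n_tasks,)
    task_index: np.ndarray  # (n_tasks,), 1-based

    @property
    def n_tasks(self) -> int:
        return self.codes.shape[0]

    @property
    def n_respondents(self) -> int:
        return int(len(np.unique(self.respondent_ids)))

    def tasks(self) -> list[ChoiceTask]:
        return [
            ChoiceTask(
                respondent_id=int(r),
                task=int(t),
                alternatives=(
                    Profile(tuple(int(c) for c in self.codes[i, 0])),
                    Profile(tuple(int(c) for c in self.codes[i, 1])),
                ),
            )
            for i, (r, t) in enumerate(zip(self.respondent_ids, self.task_index))
        ]

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per alternative (1, 2, NONE) per task."""
        n = self.n_tasks
        rows = {
            "respondent_id": np.repeat(self.respondent_ids, 3),
            "task": np.repeat(self.task_index, 3),
            "alternative": np.tile(np.array(["1", "2", NONE_LABEL]), n),
        }
        frame = pd.DataFrame(rows)
        for j, attr in enumerate(self.attributes):
            col = np.full(3 * n, "", dtype=object)
            labels = np.asarray(attr.levels, dtype=object)
            col[0::3] = labels[self.codes[:, 0, j]]
            col[1::3] = labels[self.codes[:, 1, j]]
            frame[attr.name] = col
        return frame


def _violations(
    codes: np.ndarray, pro: list[tuple[int, int, int, int]]
) -> np.ndarray:
    """Boolean mask over profiles (rows of a (m, n_attr) code matrix)."""
    bad = np.zeros(codes.shape[0], dtype=bool)
    for i1, c1, i2, c2 in pro:
        bad |= (codes[:, i1] == c1) & (codes[:, i2] == c2)
    return bad


def generate_design(config: DesignConfig, n_respondents: int) -> Design:
    """Generate a randomized, level-balanced, prohibition-respecting design.

    Per-attribute balance uses least-used-level sampling on *proposals*:
    each attribute's levels are dealt from shuffled balanced decks, so proposal
    frequencies are near-uniform; profiles violating a prohibition (or
    duplicating their task sibling) are rejected and resampled.  Rejection
    leaves prohibition-affected levels (NP swab, at-home venues) slightly
    depressed among the profiles actually shown, which mirrors how constrained
    randomized designs behave.

    Deterministic given ``config.seed``.
    """
    if n_respondents < 1:
        raise DesignError("n_respondents must be >= 1")
    rng = np.random.default_rng(config.seed)
    attrs = config.attributes
    pro = _prohibition_codes(attrs, config.prohibitions)
    n_tasks = n_respondents * config.tasks_per_respondent
    n_profiles = n_tasks * 2

    # balanced decks: each level repeated ceil(n_profiles / L) times, shuffled
    flat = np.empty((n_profiles, len(attrs)), dtype=np.int64)
    for j, attr in enumerate(attrs):
        reps = -(-n_profiles // attr.n_levels)
        deck = np.tile(np.arange(attr.n_levels), reps)
        rng.shuffle(deck)
        flat[:, j] = deck[:n_profiles]

    # rejection rounds: resample violating profiles uniformly until clean
    for _ in range(1000):
        bad = _violations(flat, pro)
        if not bad.any():
            break
        k = int(bad.sum())
        for j, attr in enumerate(attrs):
            flat[bad, j] = rng.integers(0, attr.n_levels, size=k)
    else:
        raise DesignError("could not satisfy prohibitions; configuration infeasible")

    codes = flat.reshape(n_tasks, 2, len(attrs))

    # resample the second profile of any task whose two profiles are identical
    for _ in range(1000):
        dup = np.all(codes[:, 0, :] == codes[:, 1, :], axis=1)
        if not dup.any():
            break
        k = int(dup.sum())
        fresh = np.empty((k, len(attrs)), dtype=np.int64)
        for j, attr in enumerate(attrs):
            fresh[:, j] = rng.integers(0, attr.n_levels, size=k)
        bad = _violations(fresh, pro)
        fresh = fresh[~bad]
        sel = np.flatnonzero(dup)[: fresh.shape[0]]
        codes[sel, 1, :] = fresh
    else:
        raise DesignError("could not produce distinct task alternatives")

    respondent_ids = np.repeat(np.arange(1, n_respondents + 1), config.tasks_per_respondent)
    task_index = np.tile(np.arange(1, config.tasks_per_respondent + 1), n_respondents)
    return Design(attributes=list(attrs), codes=codes, respondent_ids=respondent_ids, task_index=task_index)
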
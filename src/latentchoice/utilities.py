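"""Post-processing of a fitted latent class model.

Turns class-level coefficients and posterior memberships into:

- posterior-weighted individual part-worth utilities (each respondent's
  utility for a level is the posterior-weighted average of the class
  utilities), zero-centered within attribute;
- max-posterior class assignments and the class count/share table;
- per-respondent attribute relative importance (an attribute's utility range
  over the sum of all attributes' ranges, opt-out excluded) with class-level
  mean / SE / 95% CI summaries (CI = mean +/- 1.96 SE, SE = SD / sqrt(n)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import AttributeSpec
from .lcmnl import FittedModel

__all__ = [
    "IndividualUtilities",
    "individual_utilities",
    "zero_center",
    "relative_importance",
    "assign_classes",
    "class_share_table",
    "summarize_by_class",
    "importance_summary",
]

log = logging.getLogger(__name__)

Z95 = 1.96


@dataclass
class IndividualUtilities:
    """Per-respondent zero-centered level utilities plus opt-out utility.

    ``levels`` has shape (n_respondents, total_levels) in design order;
    ``none`` is (n_respondents,).
    """

    attributes: list[AttributeSpec]
    respondent_ids: np.ndarray
    levels: np.ndarray
    none: np.ndarray

    @property
    def n_respondents(self) -> int:
        return self.levels.shape[0]

    def attribute_slices(self) -> dict[str, slice]:
        out, offset = {}, 0
        for attr in self.attributes:
            out[attr.name] = slice(offset, offset + attr.n_levels)
            offset += attr.n_levels
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{a.name}:{lvl}" for a in self.attributes for lvl in a.levels]
        frame = pd.DataFrame(self.levels, columns=cols)
        frame.insert(0, "respondent_id", self.respondent_ids)
        frame["none"] = self.none
        return frame


def individual_utilities(model: FittedModel) -> IndividualUtilities:
    """Posterior-weighted average of class utilities, per respondent."""
    class_u, class_none = model.expanded_utilities()
    levels = model.posteriors @ class_u
    none = model.posteriors @ class_none
    return IndividualUtilities(
        attributes=model.attributes,
        respondent_ids=model.respondent_ids,
        levels=levels,
        none=none,
    )


def zero_center(utilities: np.ndarray, axis: int = -1) -> np.ndarray:
    """Subtract the within-attribute mean so level utilities sum to zero."""
    u = np.asarray(utilities, dtype=float)
    return u - u.mean(axis=axis, keepdims=True)


def relative_importance(ind: IndividualUtilities) -> pd.DataFrame:
    """Per-respondent attribute relative importance.

    importance_a = range_a / sum of ranges; the opt-out utility is excluded.
    Respondents with all-zero ranges get uniform importances and a log flag.
    """
    slices = ind.attribute_slices()
    ranges = np.column_stack(
        [ind.levels[:, s].max(axis=1) - ind.levels[:, s].min(axis=1) for s in slices.values()]
    )
    total = ranges.sum(axis=1)
    flat = total <= 0
    if flat.any():
        log.warning("%d respondent(s) with all-zero utility ranges; uniform importance assigned",
                    int(flat.sum()))
        ranges[flat] = 1.0
        total[flat] = ranges.shape[1]
    imp = ranges / total[:, None]
    frame = pd.DataFrame(imp, columns=list(slices))
    frame.insert(0, "respondent_id", ind.respondent_ids)
    return frame


def assign_classes(posteriors: np.ndarray) -> np.ndarray:
    """Max-posterior class assignment; ties break toward the lower class index."""
    post = np.asarray(posteriors, dtype=float)
    assignment = post.argmax(axis=1)
    is_tie = (post == post.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if is_tie.any():
        log.info("%d tie(s) in max-posterior assignment broken toward the lower index",
                 int(is_tie.sum()))
    return assignment


def class_share_table(assignment: np.ndarray, n_total: int | None = None,
                      labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Counts and percentage shares (1 decimal) per class."""
    assignment = np.asarray(assignment)
    if n_total is None:
        n_total = len(assignment)
    elif len(assignment) != n_total:
        raise ValueError("assignment must cover n_total respondents")
    classes = np.arange(assignment.max() + 1)
    counts = np.bincount(assignment, minlength=len(classes))
    share = np.round(100.0 * counts / n_total, 1)
    table = pd.DataFrame({"class": classes, "n": counts, "share_pct": share})
    if labels is not None:
        table["label"] = [labels[c] for c in classes]
    return table


def summarize_by_class(
    values: np.ndarray, assignment: np.ndarray
) -> pd.DataFrame:
    """Mean, SE and 95% CI of per-respondent values within each assigned class.

    SE is the descriptive SD / sqrt(n); classes of size 1 report the mean with
    CI bounds marked unavailable (NaN).
    """
    values = np.asarray(values, dtype=float)
    assignment = np.asarray(assignment)
    rows = []
    for c in np.unique(assignment):
        v = values[assignment == c]
        mean = float(v.mean())
        if len(v) >= 2:
            se = float(v.std(ddof=1) / np.sqrt(len(v)))
            lo, hi = mean - Z95 * se, mean + Z95 * se
        else:
            se, lo, hi = np.nan, np.nan, np.nan
        rows.append({"class": int(c), "n": len(v), "mean": mean, "se": se,
                     "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)


def importance_summary(
    importances: pd.DataFrame, assignment: np.ndarray
) -> pd.DataFrame:
    """Class-level mean/SE/95% CI of relative importance per attribute.

    Values are proportions; ``*_pct`` columns give the 1-decimal percentage
    display.
    """
    attrs = [c for c in importances.columns if c != "respondent_id"]
    out = []
    for attr in attrs:
        table = summarize_by_class(importances[attr].to_numpy(), assignment)
        table.insert(0, "attribute", attr)
        out.append(table)
    summary = pd.concat(out, ignore_index=True)
    for col in ("mean", "ci_lower", "ci_upper"):
        summary[f"{col}_pct"] = np.round(100.0 * summary[col], 1)
    return summary
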
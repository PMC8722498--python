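"""Respondent-quality screening: straightlining, speeders, exclusion sensitivity.

Straightlining is answering every choice task from the same screen position
(always the left alternative or always the right one); an opt-out choice breaks
the pattern.  Speeders are respondents whose exercise completion time falls at
or below a low percentile (5th or 10th) of all completion times.  The
exclusion-sensitivity check refits the latent class model with flagged
respondents removed and compares class sizes and top-importance attributes with
the full-sample fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lcmnl import ChoiceData, EMConfig, FittedModel, em_fit, match_classes
from .utilities import assign_classes, individual_utilities, relative_importance

__all__ = [
    "detect_straightlining",
    "flag_speeders",
    "exclusion_sensitivity",
    "SensitivityReport",
]


def detect_straightlining(data: ChoiceData) -> pd.DataFrame:
    """Flag respondents who always chose alternative 1 (left) or always 2 (right).

    Returns one row per respondent with ``straightline_left``,
    ``straightline_right`` and their union ``straightline``.
    """
    n = data.n_respondents
    counts = np.zeros((n, 3), dtype=np.int64)
    np.add.at(counts, (data.resp_idx, data.chosen), 1)
    total = counts.sum(axis=1)
    if (total == 0).any():
        raise ValueError("every respondent needs at least one task")
    left = counts[:, 0] == total
    right = counts[:, 1] == total
    return pd.DataFrame(
        {
            "respondent_id": data.respondent_ids,
            "straightline_left": left,
            "straightline_right": right,
            "straightline": left | right,
        }
    )


def flag_speeders(times: np.ndarray, percentile: float = 5.0) -> np.ndarray:
    """Flag completion times at or below the given percentile of all times.

    The threshold uses linear-interpolation percentiles with an inclusive
    boundary, so with all times equal every respondent is flagged.
    """
    times = np.asarray(times, dtype=float)
    if (times <= 0).any():
        raise ValueError("completion times must be positive")
    threshold = np.percentile(times, percentile, method="linear")
    return times <= threshold


@dataclass
class SensitivityReport:
    """Full-sample vs excluded-sample latent class comparison."""

    full_model: FittedModel
    filtered_model: FittedModel
    matching: np.ndarray  # filtered class -> full class
    class_shares: pd.DataFrame  # per matched class: full vs filtered share
    top_attribute_agreement: pd.DataFrame  # per matched class: top-importance attr
    n_excluded: int

    @property
    def qualitatively_stable(self) -> bool:
        """True when every matched class keeps its top-importance attribute."""
        return bool(
            (self.top_attribute_agreement["top_attr_full"]
             == self.top_attribute_agreement["top_attr_filtered"]).all()
        )


def _class_profile(model: FittedModel) -> tuple[np.ndarray, pd.DataFrame]:
    """Flattened class utility vectors and per-class top-importance attribute."""
    u, none = model.expanded_utilities()
    flat = np.column_stack([u, none])
    ind = individual_utilities(model)
    imp = relative_importance(ind)
    assignment = assign_classes(model.posteriors)
    attrs = [c for c in imp.columns if c != "respondent_id"]
    tops = []
    for c in range(model.n_classes):
        members = assignment == c
        if members.any():
            mean_imp = imp.loc[members, attrs].mean()
            tops.append(mean_imp.idxmax())
        else:
            tops.append("")
    table = pd.DataFrame({"class": range(model.n_classes), "top_attr": tops})
    return flat, table


def exclusion_sensitivity(
    data: ChoiceData,
    flagged: np.ndarray,
    config: EMConfig,
) -> SensitivityReport:
    """Refit with flagged respondents removed and compare to the full fit.

    ``flagged`` is a boolean mask aligned with ``data.respondent_ids``.
    Filtered classes are matched to full-sample classes by utility correlation
    (Hungarian assignment) before comparing shares and top-importance
    attributes.  Fails explicitly if fewer respondents than classes remain.
    """
    flagged = np.asarray(flagged, dtype=bool)
    if flagged.shape != (data.n_respondents,):
        raise ValueError("flags must align with respondents")
    keep = ~flagged
    if keep.sum() < config.n_classes:
        raise ValueError(
            f"only {int(keep.sum())} respondents left after exclusion; "
            f"need at least {config.n_classes}"
        )
    full_model = em_fit(data, config)
    filtered_model = em_fit(data.subset(keep), config)

    full_flat, full_tops = _class_profile(full_model)
    filt_flat, filt_tops = _class_profile(filtered_model)
    perm = match_classes(filt_flat, full_flat)  # filtered class -> full class

    shares = pd.DataFrame(
        {
            "full_class": perm,
            "filtered_class": np.arange(filtered_model.n_classes),
            "share_full": full_model.shares[perm],
            "share_filtered": filtered_model.shares,
        }
    ).sort_values("full_class", ignore_index=True)
    agreement = pd.DataFrame(
        {
            "full_class": perm,
            "top_attr_full": full_tops["top_attr"].to_numpy()[perm],
            "top_attr_filtered": filt_tops["top_attr"].to_numpy(),
        }
    ).sort_values("full_class", ignore_index=True)
    return SensitivityReport(
        full_model=full_model,
        filtered_model=filtered_model,
        matching=perm,
        class_shares=shares,
        top_attribute_agreement=agreement,
        n_excluded=int(flagged.sum()),
    )
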
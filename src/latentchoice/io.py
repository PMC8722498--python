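"""File I/O: long-format choice CSVs with validation, model JSON, config YAML."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .design import NONE_LABEL, AttributeSpec, DesignConfig
from .lcmnl import FittedModel

__all__ = [
    "SchemaError",
    "read_choice_data",
    "write_choice_data",
    "validate_choice_frame",
    "model_to_json",
    "model_from_json",
    "write_posteriors",
    "load_yaml",
    "dump_yaml",
    "design_config_to_dict",
    "design_config_from_dict",
]

REQUIRED_COLUMNS = ("respondent_id", "task", "alternative", "chosen")


class SchemaError(ValueError):
    """A choice-data file violates the expected schema; lists offending rows."""


def validate_choice_frame(
    frame: pd.DataFrame,
    attributes: Sequence[AttributeSpec] | None = None,
    tasks_per_respondent: int | None = None,
    strict: bool = True,
) -> list[str]:
    """Validate a long-format choice table; returns warnings (non-strict mode).

    Checks: required columns present; alternative labels in {1, 2, NONE};
    attribute level labels known (NONE rows must have empty cells); exactly one
    chosen option per task; and, when ``tasks_per_respondent`` is given, the
    per-respondent task count (error in strict mode, warning otherwise).
    Row numbers are 0-based positions in the input.
    """
    if attributes is None:
        attributes = DesignConfig().attributes
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    missing += [a.name for a in attributes if a.name not in frame.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")

    alt = frame["alternative"].astype(str)
    bad_alt = ~alt.isin(["1", "2", NONE_LABEL])
    if bad_alt.any():
        rows = list(np.flatnonzero(bad_alt.to_numpy())[:10])
        raise SchemaError(f"unknown alternative labels at rows {rows}")

    is_none = (alt == NONE_LABEL).to_numpy()
    for attr in attributes:
        col = frame[attr.name].astype(object).fillna("").astype(str).str.strip().to_numpy()
        known = np.isin(col, attr.levels)
        bad = ~known & ~is_none
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"unknown level {col[row]!r} for attribute {attr.name!r} at row {row}"
            )
        stray = is_none & (col != "")
        if stray.any():
            row = int(np.flatnonzero(stray)[0])
            raise SchemaError(f"{NONE_LABEL} row {row} carries attribute cell {col[row]!r}")

    chosen_per_task = frame.groupby(["respondent_id", "task"])["chosen"].sum()
    bad_tasks = chosen_per_task[chosen_per_task != 1]
    if len(bad_tasks):
        raise SchemaError(
            f"tasks without exactly one chosen option: {list(bad_tasks.index[:10])}"
        )

    warnings: list[str] = []
    if tasks_per_respondent is not None:
        per_resp = frame.groupby("respondent_id")["task"].nunique()
        off = per_resp[per_resp != tasks_per_respondent]
        if len(off):
            msg = (
                f"respondents with != {tasks_per_respondent} tasks: "
                f"{dict(off.head(10))}"
            )
            if strict:
                raise SchemaError(msg)
            warnings.append(msg)
    return warnings


def read_choice_data(
    path,
    attributes: Sequence[AttributeSpec] | None = None,
    tasks_per_respondent: int | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Read and validate a long-format choice CSV."""
    frame = pd.read_csv(path, dtype={"alternative": str}, keep_default_na=False)
    validate_choice_frame(frame, attributes, tasks_per_respondent, strict)
    return frame


def write_choice_data(frame: pd.DataFrame, path) -> None:
    """Write a long-format choice CSV (round-trips through read_choice_data)."""
    frame.to_csv(path, index=False)


def model_to_json(model: FittedModel, path=None) -> dict:
    """Serialize a fitted model (shares, labelled utilities, fit statistics).

    Posteriors are written separately via :func:`write_posteriors`.
    """
    utilities, none = model.expanded_utilities()
    classes = []
    offset_map = []
    offset = 0
    for attr in model.attributes:
        offset_map.append((attr, offset))
        offset += attr.n_levels
    for c in range(model.n_classes):
        part_worths = {
            attr.name: {
                lvl: float(utilities[c, off + k]) for k, lvl in enumerate(attr.levels)
            }
            for attr, off in offset_map
        }
        classes.append(
            {
                "share": float(model.shares[c]),
                "utilities": part_worths,
                "none_utility": float(none[c]),
                "coefficients": [float(b) for b in model.betas[c]],
            }
        )
    doc = {
        "n_classes": model.n_classes,
        "classes": classes,
        "log_likelihood": float(model.loglik),
        "aic": float(model.aic),
        "bic": float(model.bic),
        "n_parameters": int(model.n_parameters),
        "n_respondents": int(len(model.respondent_ids)),
        "convergence": _jsonable(model.convergence),
        "attributes": {a.name: list(a.levels) for a in model.attributes},
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")
    return doc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def model_from_json(path) -> dict:
    """Load a serialized model document (as a plain dict)."""
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_posteriors(model: FittedModel, path) -> None:
    """Posterior membership matrix as CSV (respondent_id, class_0, ...)."""
    frame = pd.DataFrame(
        model.posteriors,
        columns=[f"class_{c}" for c in range(model.n_classes)],
    )
    frame.insert(0, "respondent_id", model.respondent_ids)
    frame.to_csv(path, index=False)


def design_config_to_dict(config: DesignConfig) -> dict:
    """DesignConfig as a plain mapping (YAML/JSON friendly)."""
    return {
        "attributes": {a.name: list(a.levels) for a in config.attributes},
        "prohibitions": [
            {"first": list(p.first), "second": list(p.second)}
            for p in config.prohibitions
        ],
        "tasks_per_respondent": config.tasks_per_respondent,
        "alternatives_per_task": config.alternatives_per_task,
        "seed": config.seed,
    }


def design_config_from_dict(doc: dict) -> DesignConfig:
    from .design import Prohibition

    attributes = [
        AttributeSpec(name, tuple(levels)) for name, levels in doc["attributes"].items()
    ]
    prohibitions = [
        Prohibition(tuple(p["first"]), tuple(p["second"]))
        for p in doc.get("prohibitions", [])
    ]
    return DesignConfig(
        attributes=attributes,
        prohibitions=prohibitions,
        tasks_per_respondent=doc.get("tasks_per_respondent", 5),
        alternatives_per_task=doc.get("alternatives_per_task", 2),
        seed=doc.get("seed", 0),
    )


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def dump_yaml(doc: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
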
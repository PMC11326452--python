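"""Study schema, tabular input and reference-coded design matrices.

The analysis works on small rectangular tables of categorical predictors
plus one ordered outcome (e.g. tooth-sensitivity severity: mild < moderate
< severe).  Each predictor is expanded into indicator columns for its
non-reference levels ("reference coding"), so a predictor with L observed
levels contributes L - 1 slope columns to the design.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CategoricalPredictorSpec",
    "OrdinalOutcomeSpec",
    "StudyDataset",
    "DesignMatrix",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "encode_design",
    "tooth_sensitivity_schema",
    "load_schema",
    "save_schema",
]


class SchemaError(ValueError):
    """A declared column is missing or the schema itself is malformed."""


class ValidationError(ValueError):
    """A cell value is not a declared level of its column's spec."""


@dataclass(frozen=True)
class CategoricalPredictorSpec:
    """One categorical predictor: its levels and the reference level."""

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if not self.levels:
            raise SchemaError(f"predictor {self.name!r}: empty level list")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"predictor {self.name!r}: duplicate levels")
        if self.reference not in self.levels:
            raise SchemaError(
                f"predictor {self.name!r}: reference {self.reference!r} "
                f"is not one of its levels"
            )

    @property
    def non_reference(self) -> tuple[str, ...]:
        """Declared levels excluding the reference, in declaration order."""
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class OrdinalOutcomeSpec:
    """The ordered outcome: J >= 2 category labels, low to high."""

    name: str
    ordered_levels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ordered_levels", tuple(self.ordered_levels))
        if len(self.ordered_levels) < 2:
            raise SchemaError(f"outcome {self.name!r}: needs >= 2 levels")
        if len(set(self.ordered_levels)) != len(self.ordered_levels):
            raise SchemaError(f"outcome {self.name!r}: duplicate levels")

    @property
    def n_categories(self) -> int:
        return len(self.ordered_levels)


@dataclass
class StudyDataset:
    """Validated per-record table: the unit of bootstrap resampling.

    ``frame`` holds one column per predictor plus the outcome column, all as
    plain strings matching declared levels.  Row order is preserved from the
    source and is what resampling indices refer to.
    """

    outcome_spec: OrdinalOutcomeSpec
    predictor_specs: list[CategoricalPredictorSpec]
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n(self) -> int:
        return len(self.frame)

    def validate(self) -> None:
        if self.n < 1:
            raise ValidationError("dataset has no records")
        cols = set(self.frame.columns)
        for spec in [self.outcome_spec, *self.predictor_specs]:
            if spec.name not in cols:
                raise SchemaError(f"column {spec.name!r} missing from data")
        declared = {self.outcome_spec.name: set(self.outcome_spec.ordered_levels)}
        for p in self.predictor_specs:
            declared[p.name] = set(p.levels)
        for col, legal in declared.items():
            values = self.frame[col]
            bad = ~values.isin(legal)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"column {col!r}, row {row}: value "
                    f"{values.iloc[row]!r} is not a declared level"
                )

    def subset(self, indices: Sequence[int]) -> "StudyDataset":
        """Rows by positional index (with repeats), e.g. a bootstrap resample."""
        return StudyDataset(
            outcome_spec=self.outcome_spec,
            predictor_specs=self.predictor_specs,
            frame=self.frame.iloc[list(indices)].reset_index(drop=True),
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class DesignMatrix:
    """Reference-coded indicator expansion plus integer outcome codes.

    ``columns`` are labelled ``"predictor=level"``; within one predictor's
    block each row has at most one 1 (an all-zero block row is the reference
    level).  ``outcome_codes`` are 1..J, low to high.
    """

    columns: list[str]
    values: np.ndarray  # (n, k) float in {0, 1}
    outcome_codes: np.ndarray  # (n,) int in 1..J
    outcome_levels: tuple[str, ...]

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def n_categories(self) -> int:
        return len(self.outcome_levels)

    def take_rows(self, indices: Sequence[int]) -> "DesignMatrix":
        idx = np.asarray(indices, dtype=int)
        return DesignMatrix(
            columns=self.columns,
            values=self.values[idx],
            outcome_codes=self.outcome_codes[idx],
            outcome_levels=self.outcome_levels,
        )


# --------------------------------------------------------------------------
# Built-in schema: the tooth-sensitivity variable coding
# --------------------------------------------------------------------------

def tooth_sensitivity_schema() -> tuple[OrdinalOutcomeSpec, list[CategoricalPredictorSpec]]:
    """The tooth-sensitivity study schema.

    Outcome: sensitivity severity (Mild < Moderate < Severe).  Predictors:
    age group, toothpaste type, toothbrush type, brushing frequency and
    brushing method, each with the reference level omitted from the fitted
    coefficient table (soft brush, non-fluoridated paste, etc.).
    """
    outcome = OrdinalOutcomeSpec(
        "Tooth sensitivity", ("Mild", "Moderate", "Severe")
    )
    predictors = [
        CategoricalPredictorSpec(
            "Age", ("20-39", "40-59", "Above 59"), reference="20-39"
        ),
        CategoricalPredictorSpec(
            "Toothpaste",
            ("Fluoridated", "Non-fluoridated", "Abrasive", "Do not know"),
            reference="Non-fluoridated",
        ),
        CategoricalPredictorSpec(
            "Toothbrush", ("Soft", "Medium", "Hard"), reference="Soft"
        ),
        CategoricalPredictorSpec(
            "Frequency of brushing",
            ("Once a day", "Twice a day", "More than twice", "After meal"),
            reference="Once a day",
        ),
        CategoricalPredictorSpec(
            "Method of brushing",
            ("Horizontal", "Vertical", "Circular", "Combination"),
            reference="Horizontal",
        ),
    ]
    return outcome, predictors


def save_schema(
    path: str | Path,
    outcome_spec: OrdinalOutcomeSpec,
    predictor_specs: Sequence[CategoricalPredictorSpec],
) -> None:
    """Write a schema as a small JSON key-value file."""
    payload = {
        "outcome": {
            "name": outcome_spec.name,
            "ordered_levels": list(outcome_spec.ordered_levels),
        },
        "predictors": [
            {
                "name": p.name,
                "levels": list(p.levels),
                "reference": p.reference,
            }
            for p in predictor_specs
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_schema(
    path: str | Path,
) -> tuple[OrdinalOutcomeSpec, list[CategoricalPredictorSpec]]:
    payload = json.loads(Path(path).read_text())
    try:
        outcome = OrdinalOutcomeSpec(
            payload["outcome"]["name"],
            tuple(payload["outcome"]["ordered_levels"]),
        )
        predictors = [
            CategoricalPredictorSpec(p["name"], tuple(p["levels"]), p["reference"])
            for p in payload["predictors"]
        ]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed schema file {path}: {exc}") from exc
    return outcome, predictors


# --------------------------------------------------------------------------
# Reading and encoding
# --------------------------------------------------------------------------

def read_dataset(
    path: str | Path,
    outcome_spec: OrdinalOutcomeSpec,
    predictor_specs: Sequence[CategoricalPredictorSpec],
    *,
    missing: str = "error",
) -> StudyDataset:
    """Read a headered CSV into a validated :class:`StudyDataset`.

    Values are matched to declared levels by exact string comparison after
    whitespace trimming.  ``missing`` is ``"error"`` (default: any NA cell
    in a declared column raises) or ``"drop"`` (listwise deletion).
    """
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty input file: {path}") from exc
    if frame.empty:
        raise ValidationError(f"no data rows in {path}")
    frame.columns = [c.strip() for c in frame.columns]
    wanted = [p.name for p in predictor_specs] + [outcome_spec.name]
    for col in wanted:
        if col not in frame.columns:
            raise SchemaError(f"column {col!r} missing from {path}")
    frame = frame[wanted].copy()
    for col in wanted:
        frame[col] = frame[col].str.strip()
    na_mask = frame.isna().any(axis=1)
    if na_mask.any():
        if missing == "drop":
            frame = frame[~na_mask].reset_index(drop=True)
            if frame.empty:
                raise ValidationError("all rows removed by listwise deletion")
        else:
            row = int(np.flatnonzero(na_mask.to_numpy())[0])
            raise ValidationError(f"missing value in row {row}")
    return StudyDataset(
        outcome_spec=outcome_spec,
        predictor_specs=list(predictor_specs),
        frame=frame,
    )


def encode_design(dataset: StudyDataset, drop_unobserved: bool = True) -> DesignMatrix:
    """Expand a dataset into a reference-coded design matrix.

    One indicator column per non-reference level, restricted to levels
    actually observed when ``drop_unobserved`` is set (the default), so the
    slope count k matches the degrees of freedom of the fitted model.
    Deterministic: column order follows predictor declaration order, then
    level declaration order.
    """
    frame = dataset.frame
    outcome = dataset.outcome_spec
    observed_outcomes = set(frame[outcome.name])
    missing_levels = [l for l in outcome.ordered_levels if l not in observed_outcomes]
    if missing_levels:
        raise ValidationError(
            f"outcome level(s) {missing_levels} never observed; "
            f"a cumulative model over them would be degenerate"
        )
    code_of = {lvl: j + 1 for j, lvl in enumerate(outcome.ordered_levels)}
    outcome_codes = frame[outcome.name].map(code_of).to_numpy(dtype=int)

    columns: list[str] = []
    blocks: list[np.ndarray] = []
    for p in dataset.predictor_specs:
        col = frame[p.name]
        observed = set(col)
        if len(observed) == 1:
            warnings.warn(
                f"predictor {p.name!r} is constant; contributing no columns",
                UserWarning,
                stacklevel=2,
            )
            continue
        levels = p.non_reference
        if drop_unobserved:
            levels = tuple(l for l in levels if l in observed)
        for lvl in levels:
            columns.append(f"{p.name}={lvl}")
            blocks.append((col == lvl).to_numpy(dtype=float))
    values = (
        np.column_stack(blocks) if blocks else np.empty((dataset.n, 0), dtype=float)
    )
    return DesignMatrix(
        columns=columns,
        values=values,
        outcome_codes=outcome_codes,
        outcome_levels=outcome.ordered_levels,
    )
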
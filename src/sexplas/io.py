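"""Dataset readers/writers and validation for the group-summary schema.

Schema (UTF-8 CSV, period decimals), one row per study x experiment x
treatment level x sex:

    study_id, experiment_id, species, trait_class, trait_name,
    treatment_type, treatment_level_id, temperature, sex, mean, sd, n

``temperature`` may be empty (non-temperature manipulations); an
optional ``direction_override`` column (``a_colder``/``b_colder``)
orders such levels for the effect-size direction convention.  Malformed
rows are rejected with reason codes, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .effects import TRAIT_CLASSES, TREATMENT_TYPES
from .theory import EnvRegime, TheoryParams

SCHEMA_VERSION = "1"

REQUIRED_COLUMNS = [
    "study_id", "experiment_id", "species", "trait_class", "trait_name",
    "treatment_type", "treatment_level_id", "temperature", "sex",
    "mean", "sd", "n",
]

__all__ = ["ValidationReport", "read_dataset", "write_dataset", "load_theory_config"]


@dataclass
class ValidationReport:
    """Row accounting for one dataset read: read = accepted + rejected."""

    n_read: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    reasons: dict[str, int] = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def reject(self, reason: str) -> None:
        self.n_rejected += 1
        self.reasons[reason] = self.reasons.get(reason, 0) + 1


def _row_problem(row: pd.Series) -> str | None:
    for col in ("study_id", "experiment_id", "species", "treatment_level_id"):
        if pd.isna(row[col]) or str(row[col]).strip() == "":
            return f"missing_{col}"
    if str(row["trait_class"]) not in TRAIT_CLASSES:
        return "bad_trait_class"
    if str(row["treatment_type"]) not in TREATMENT_TYPES:
        return "bad_treatment_type"
    if str(row["sex"]).upper() not in ("F", "M"):
        return "bad_sex"
    if pd.isna(row["mean"]):
        return "missing_mean"
    if pd.isna(row["sd"]):
        return "missing_sd"
    try:
        if float(row["sd"]) < 0:
            return "negative_sd"
    except (TypeError, ValueError):
        return "missing_sd"
    try:
        n = float(row["n"])
    except (TypeError, ValueError):
        return "bad_n"
    if pd.isna(n) or n < 1 or n != int(n):
        return "bad_n"
    if not pd.isna(row["temperature"]):
        try:
            float(row["temperature"])
        except (TypeError, ValueError):
            return "bad_temperature"
    return None


def read_dataset(path: str | Path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a group-summary CSV.

    Returns the typed table of accepted rows and a ValidationReport.
    Missing required columns are a hard error; per-row problems are
    tallied by reason.  Duplicate (study, experiment, level, sex) keys
    reject the later row.
    """
    raw = pd.read_csv(path, dtype={"study_id": str, "experiment_id": str,
                                   "treatment_level_id": str, "sex": str},
                      comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    report = ValidationReport(n_read=len(raw))
    keep: list[int] = []
    seen: set[tuple] = set()
    for i, row in raw.iterrows():
        problem = _row_problem(row)
        if problem is None:
            key = (
                str(row["study_id"]), str(row["experiment_id"]),
                str(row["treatment_level_id"]), str(row["sex"]).upper(),
            )
            if key in seen:
                problem = "duplicate_key"
            else:
                seen.add(key)
        if problem is not None:
            report.reject(problem)
        else:
            keep.append(i)
    out = raw.loc[keep].copy()
    if len(out):
        out["sex"] = out["sex"].str.upper()
        out["mean"] = out["mean"].astype(float)
        out["sd"] = out["sd"].astype(float)
        out["n"] = out["n"].astype(int)
        out["temperature"] = pd.to_numeric(out["temperature"], errors="coerce")
    report.n_accepted = len(out)
    return out.reset_index(drop=True), report


def write_dataset(data: pd.DataFrame, path: str | Path) -> None:
    """Write a group-summary CSV (round-trips through read_dataset)."""
    cols = REQUIRED_COLUMNS + [
        c for c in data.columns if c not in REQUIRED_COLUMNS
    ]
    data.loc[:, cols].to_csv(path, index=False)


def load_theory_config(path: str | Path) -> tuple[TheoryParams, EnvRegime]:
    """Load a YAML/JSON mirror of the theory parameters and regime.

    Top-level keys ``params`` and ``regime`` map field-for-field onto
    :class:`~sexplas.theory.TheoryParams` and
    :class:`~sexplas.theory.EnvRegime`.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    params = TheoryParams(**doc.get("params", {}))
    regime = EnvRegime(**doc.get("regime", {}))
    return params, regime
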
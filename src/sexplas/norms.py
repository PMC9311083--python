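"""Mean-standardised reaction-norm slopes against temperature.

For each experiment and sex, treatment-level trait means are divided by
that sex's across-level mean (making slopes comparable across traits
measured on different scales) and regressed on treatment temperature by
ordinary least squares, each level weighted equally.  The female and
male slopes per experiment feed the classic female-versus-male scatter.

Only experiments whose levels are all at distinct temperatures are
eligible; manipulations of anything else (e.g. exposure duration) are
excluded with a reason code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NormSlope", "slopes", "slopes_table"]


@dataclass(frozen=True)
class NormSlope:
    species: str
    study_id: str
    experiment_id: str
    sex: str
    slope: float  # per degree C, of mean-standardised trait
    n_levels: int
    treatment_type: str


def _sex_slope(rows: pd.DataFrame) -> float:
    temps = rows["temperature"].to_numpy(float)
    means = rows["mean"].to_numpy(float)
    grand = means.mean()
    if grand == 0:
        raise ZeroDivisionError("mean trait value is zero; cannot standardise")
    std = means / grand
    # equal-weight OLS slope of standardised level means on temperature
    return float(np.polyfit(temps, std, 1)[0])


def slopes(experiment: pd.DataFrame) -> list[NormSlope]:
    """Per-sex slopes for one experiment's group-summary rows.

    Raises ``ValueError`` for ineligible experiments (missing or
    duplicated temperatures, fewer than two levels for a sex).
    """
    meta = experiment.iloc[0]
    out = []
    for sex, rows in experiment.groupby("sex"):
        temps = rows["temperature"]
        if temps.isna().any():
            raise ValueError("non-temperature manipulation")
        if temps.nunique() != len(rows):
            raise ValueError("treatment levels do not have distinct temperatures")
        if len(rows) < 2:
            raise ValueError("need at least two temperature levels")
        out.append(
            NormSlope(
                species=str(meta["species"]),
                study_id=str(meta["study_id"]),
                experiment_id=str(meta["experiment_id"]),
                sex=str(sex),
                slope=_sex_slope(rows),
                n_levels=len(rows),
                treatment_type=str(meta["treatment_type"]),
            )
        )
    return out


def slopes_table(data: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slopes for every eligible experiment; exclusions reason-coded.

    Returns (slopes frame, exclusions frame).
    """
    rows, excluded = [], []
    for (study, exp), grp in data.groupby(["study_id", "experiment_id"], sort=True):
        try:
            for ns in slopes(grp):
                rows.append(ns.__dict__)
        except (ValueError, ZeroDivisionError) as err:
            excluded.append(
                {
                    "study_id": study,
                    "experiment_id": exp,
                    "reason": str(err),
                }
            )
    return (
        pd.DataFrame(rows, columns=[
            "species", "study_id", "experiment_id", "sex", "slope",
            "n_levels", "treatment_type",
        ]),
        pd.DataFrame(excluded, columns=["study_id", "experiment_id", "reason"]),
    )
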
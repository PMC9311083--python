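"""Sex-specific effect sizes for thermal-plasticity contrasts.

Computes Hedges' d (bias-corrected standardised mean difference between
treatment levels, separately per sex), lnCVR between treatment levels
within a sex (``lncvr_treatment``) and between the sexes at one level
(``lncvr_sex``), for every pairwise combination of levels within an
experiment.

Direction conventions
---------------------
Trait classes where larger values are expected in the cold (development
time, longevity, size, survival) subtract the warmer-treatment mean from
the colder-treatment mean; resistance/expression classes (cold
resistance, heat resistance, gene expression) subtract the colder from
the warmer.  Positive d then means plasticity in the a-priori adaptive
direction for every class.  "Warmer" and "colder" are ordered by the
level temperatures when both are present; experiments manipulating
something other than temperature (e.g. exposure duration) must carry a
``direction_override`` column (``a_colder``/``b_colder``) or the
contrast is excluded.

Exclusion rules (reason-coded, never silent): zero SD in either group,
pooled n below 5, unorderable levels, and — for lnCVR only — a zero mean
in either group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "TRAIT_CLASSES",
    "COLD_MINUEND_CLASSES",
    "WARM_MINUEND_CLASSES",
    "TREATMENT_TYPES",
    "EffectSize",
    "Exclusion",
    "hedges_d_value",
    "lncvr_value",
    "direction_convention",
    "all_pairwise_contrasts",
    "compute_effects",
]

COLD_MINUEND_CLASSES = frozenset(
    {"development_time", "longevity", "size", "survival"}
)
WARM_MINUEND_CLASSES = frozenset(
    {"cold_resistance", "heat_resistance", "gene_expression"}
)
TRAIT_CLASSES = COLD_MINUEND_CLASSES | WARM_MINUEND_CLASSES
TREATMENT_TYPES = frozenset({"hardening", "acclimation", "rearing", "acute"})

MIN_POOLED_N = 5

GROUP_KEYS = ["species", "study_id", "experiment_id"]


@dataclass(frozen=True)
class EffectSize:
    """One computed contrast with its sampling variance."""

    kind: str  # hedges_d | lncvr_treatment | lncvr_sex
    value: float
    variance: float
    sex: str  # F/M for d and lncvr_treatment; "M/F" for lncvr_sex
    contrast: tuple[str, str]  # (minuend level, subtrahend level) or (M, F)
    species: str
    study_id: str
    experiment_id: str


@dataclass(frozen=True)
class Exclusion:
    kind: str
    reason: str
    sex: str
    contrast: tuple[str, str]
    species: str
    study_id: str
    experiment_id: str


def hedges_d_value(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Hedges' d of group 1 minus group 2 and its sampling variance.

    d = J * (m1 - m2) / s_pooled with the pooled SD on n1 + n2 - 2
    degrees of freedom and small-sample correction
    J = 1 - 3 / (4 (n1 + n2 - 2) - 1).  The large-sample variance is
    (n1 + n2)/(n1 n2) + d^2 / (2 (n1 + n2 - 2)).
    """
    df = n1 + n2 - 2
    if df <= 0:
        raise ValueError("need at least 3 observations across the two groups")
    s_pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    if s_pooled == 0:
        raise ZeroDivisionError("pooled SD is zero")
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    d = J * (m1 - m2) / s_pooled
    v = (n1 + n2) / (n1 * n2) + d**2 / (2.0 * df)
    return d, v


def lncvr_value(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Log coefficient-of-variation ratio (group 1 over group 2) and variance.

    lnCVR = ln(CV1/CV2) + 1/(2(n1-1)) - 1/(2(n2-1)), with sampling
    variance sd1^2/(n1 m1^2) + 1/(2(n1-1)) + sd2^2/(n2 m2^2) +
    1/(2(n2-1)), assuming independence of means and SDs within groups.
    """
    if m1 == 0 or m2 == 0:
        raise ZeroDivisionError("zero mean")
    if sd1 <= 0 or sd2 <= 0:
        raise ZeroDivisionError("zero SD")
    cv1 = sd1 / abs(m1)
    cv2 = sd2 / abs(m2)
    val = math.log(cv1 / cv2) + 1.0 / (2 * (n1 - 1)) - 1.0 / (2 * (n2 - 1))
    v = (
        sd1**2 / (n1 * m1**2)
        + 1.0 / (2 * (n1 - 1))
        + sd2**2 / (n2 * m2**2)
        + 1.0 / (2 * (n2 - 1))
    )
    return val, v


def direction_convention(
    trait_class: str,
    level_a: dict,
    level_b: dict,
    override: str | None = None,
) -> tuple[dict, dict]:
    """Order two level records as (minuend, subtrahend) for this class.

    ``level_a``/``level_b`` are mappings with at least ``temperature``;
    ``override`` may be ``a_colder``/``b_colder`` for non-temperature
    manipulations.  Raises ``ValueError`` when the levels cannot be
    ordered as warmer/colder.
    """
    if trait_class not in TRAIT_CLASSES:
        raise ValueError(f"unknown trait class {trait_class!r}")
    t_a, t_b = level_a.get("temperature"), level_b.get("temperature")
    if override in ("a_colder", "b_colder"):
        colder, warmer = (
            (level_a, level_b) if override == "a_colder" else (level_b, level_a)
        )
    elif t_a is None or t_b is None or pd.isna(t_a) or pd.isna(t_b) or t_a == t_b:
        raise ValueError("levels not orderable as warmer/colder")
    else:
        colder, warmer = (level_a, level_b) if t_a < t_b else (level_b, level_a)
    if trait_class in COLD_MINUEND_CLASSES:
        return colder, warmer
    return warmer, colder


def _group_lookup(exp: pd.DataFrame) -> dict[tuple[str, str], dict]:
    out = {}
    for _, row in exp.iterrows():
        out[(str(row["treatment_level_id"]), str(row["sex"]))] = row.to_dict()
    return out


def all_pairwise_contrasts(
    experiment: pd.DataFrame,
) -> tuple[list[EffectSize], list[Exclusion]]:
    """All effect sizes for one experiment's rows (one per level x sex).

    Produces, per unordered level pair: Hedges' d and lnCVR_treatment for
    each sex; and per level: lnCVR_sex (male CV over female CV, so
    positive means males more variable).  C(L, 2) pairs for L levels.
    """
    meta = experiment.iloc[0]
    keys = dict(
        species=str(meta["species"]),
        study_id=str(meta["study_id"]),
        experiment_id=str(meta["experiment_id"]),
    )
    trait_class = str(meta["trait_class"])
    override = None
    if "direction_override" in experiment.columns:
        ov = meta.get("direction_override")
        if isinstance(ov, str) and ov:
            override = ov
    groups = _group_lookup(experiment)
    levels = sorted({lvl for lvl, _ in groups})
    effects: list[EffectSize] = []
    excluded: list[Exclusion] = []

    def _try(kind, sex, contrast, fn, g1, g2):
        pooled_n = int(g1["n"]) + int(g2["n"])
        if g1["sd"] == 0 or g2["sd"] == 0:
            excluded.append(Exclusion(kind, "zero_sd", sex, contrast, **keys))
            return
        if pooled_n < MIN_POOLED_N:
            excluded.append(Exclusion(kind, "small_pooled_n", sex, contrast, **keys))
            return
        if kind != "hedges_d" and (g1["mean"] == 0 or g2["mean"] == 0):
            excluded.append(Exclusion(kind, "zero_mean", sex, contrast, **keys))
            return
        value, variance = fn(
            g1["mean"], g1["sd"], int(g1["n"]), g2["mean"], g2["sd"], int(g2["n"])
        )
        effects.append(EffectSize(kind, value, variance, sex, contrast, **keys))

    for i, la in enumerate(levels):
        for lb in levels[i + 1 :]:
            for sex in ("F", "M"):
                ga, gb = groups.get((la, sex)), groups.get((lb, sex))
                if ga is None or gb is None:
                    continue
                try:
                    minu, subt = direction_convention(trait_class, ga, gb, override)
                except ValueError:
                    for kind in ("hedges_d", "lncvr_treatment"):
                        excluded.append(
                            Exclusion(kind, "unorderable_levels", sex, (la, lb), **keys)
                        )
                    continue
                contrast = (
                    str(minu["treatment_level_id"]),
                    str(subt["treatment_level_id"]),
                )
                _try("hedges_d", sex, contrast, hedges_d_value, minu, subt)
                _try("lncvr_treatment", sex, contrast, lncvr_value, minu, subt)
    for lvl in levels:
        gm, gf = groups.get((lvl, "M")), groups.get((lvl, "F"))
        if gm is None or gf is None:
            continue
        _try("lncvr_sex", f"{lvl}", ("M", "F"), lncvr_value, gm, gf)
    return effects, excluded


def compute_effects(
    data: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Effect sizes and reason-coded exclusions for a whole dataset.

    ``data`` follows the group-summary schema (see
    :mod:`sexplas.io`).  Returns an effects frame (one row per
    EffectSize) and an exclusions frame; rows in, effects out and
    exclusions always balance per contrast attempt.
    """
    effects: list[EffectSize] = []
    excluded: list[Exclusion] = []
    for _, exp in data.groupby(["study_id", "experiment_id"], sort=True):
        e, x = all_pairwise_contrasts(exp)
        effects.extend(e)
        excluded.extend(x)
    eff = pd.DataFrame(
        [
            {
                "kind": e.kind,
                "value": e.value,
                "variance": e.variance,
                "sex": e.sex,
                "contrast_minuend": e.contrast[0],
                "contrast_subtrahend": e.contrast[1],
                "species": e.species,
                "study_id": e.study_id,
                "experiment_id": e.experiment_id,
            }
            for e in effects
        ],
        columns=[
            "kind", "value", "variance", "sex", "contrast_minuend",
            "contrast_subtrahend", "species", "study_id", "experiment_id",
        ],
    )
    exc = pd.DataFrame(
        [
            {
                "kind": x.kind,
                "reason": x.reason,
                "sex": x.sex,
                "contrast_minuend": x.contrast[0],
                "contrast_subtrahend": x.contrast[1],
                "species": x.species,
                "study_id": x.study_id,
                "experiment_id": x.experiment_id,
            }
            for x in excluded
        ],
        columns=[
            "kind", "reason", "sex", "contrast_minuend",
            "contrast_subtrahend", "species", "study_id", "experiment_id",
        ],
    )
    return eff, exc
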
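"""Outcome construction from the seven questionnaire symptom items.

Four binary outcomes: mild-to-moderate emotional symptoms (>= 3 of items 1-5
at weekly-or-higher frequency), depression (item 6 positive), worriedness
(item 7 at "most of the time"/"always" with the sleep-prevention qualifier),
and their union ("psychiatric symptoms").  An extended three-class outcome
splits subjects into low/medium/high symptom burden by tertiles of the first
principal component of the seven (un-dichotomized) item scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import (
    Q6_LEVELS,
    Q7_LEVELS,
    Q_FREQUENCY_LEVELS,
    QuestionnaireRecord,
    ValidationError,
    pc1_scores,
    tertile_labels,
)

__all__ = [
    "derive_outcomes",
    "derive_extended_outcome",
    "prevalence_from_counts",
    "item_code_frame",
]

ITEM_COLUMNS = ["q1", "q2", "q3", "q4", "q5", "q6", "q7"]

# Weekly-or-higher frequency on the 5-level item scale.
_WEEKLY_OR_MORE = set(Q_FREQUENCY_LEVELS[2:])
_WORRIED_POSITIVE = set(Q7_LEVELS[3:])  # most_of_the_time, always


def _items_frame(records) -> pd.DataFrame:
    """Normalize input (records or DataFrame) to an item DataFrame."""
    if isinstance(records, pd.DataFrame):
        df = records[ITEM_COLUMNS].copy()
    else:
        rows = []
        for r in records:
            if not isinstance(r, QuestionnaireRecord):
                raise TypeError("expected QuestionnaireRecord instances or a DataFrame")
            rows.append({c: getattr(r, c) for c in ITEM_COLUMNS})
        df = pd.DataFrame(rows, columns=ITEM_COLUMNS)
    return df


def _require_complete(df: pd.DataFrame) -> None:
    missing = df.isna()
    if missing.to_numpy().any():
        idx = missing.any(axis=1)
        first = df.index[idx][0]
        cols = list(df.columns[missing.loc[first]])
        raise ValidationError(
            f"subject {first!r}: missing questionnaire item(s) {cols}; "
            "handle missingness upstream (complete-case filter or imputation)"
        )


def _check_levels(df: pd.DataFrame) -> None:
    for c in ("q1", "q2", "q3", "q4", "q5"):
        bad = set(df[c]) - set(Q_FREQUENCY_LEVELS)
        if bad:
            raise ValidationError(f"item {c!r}: unknown levels {sorted(bad)}")
    if set(df["q6"]) - set(Q6_LEVELS):
        raise ValidationError("item 'q6': unknown levels")
    if set(df["q7"]) - set(Q7_LEVELS):
        raise ValidationError("item 'q7': unknown levels")


def derive_outcomes(records) -> pd.DataFrame:
    """Binary outcome labels per subject.

    Parameters
    ----------
    records : iterable of QuestionnaireRecord or DataFrame with columns q1..q7.

    Returns
    -------
    DataFrame with integer columns ``depression``, ``worriedness``,
    ``mild_moderate`` and ``psychiatric`` (the OR of the first three).
    """
    df = _items_frame(records)
    _require_complete(df)
    _check_levels(df)
    weekly = df[["q1", "q2", "q3", "q4", "q5"]].isin(_WEEKLY_OR_MORE).sum(axis=1)
    mild_moderate = (weekly >= 3).astype(int)
    depression = (df["q6"] == "yes").astype(int)
    worriedness = df["q7"].isin(_WORRIED_POSITIVE).astype(int)
    psychiatric = ((depression | worriedness | mild_moderate) > 0).astype(int)
    return pd.DataFrame(
        {
            "depression": depression,
            "worriedness": worriedness,
            "mild_moderate": mild_moderate,
            "psychiatric": psychiatric,
        },
        index=df.index,
    )


def item_code_frame(records) -> pd.DataFrame:
    """Numeric (ordinal-code) version of the seven items, 0-based."""
    df = _items_frame(records)
    _require_complete(df)
    _check_levels(df)
    codes = pd.DataFrame(index=df.index)
    for c in ("q1", "q2", "q3", "q4", "q5"):
        codes[c] = df[c].map({lv: i for i, lv in enumerate(Q_FREQUENCY_LEVELS)})
    codes["q6"] = df["q6"].map({lv: i for i, lv in enumerate(Q6_LEVELS)})
    codes["q7"] = df["q7"].map({lv: i for i, lv in enumerate(Q7_LEVELS)})
    return codes.astype(float)


def derive_extended_outcome(records) -> pd.Series:
    """Three-class symptom-burden outcome (low / medium / high).

    The seven item scores (original ordinal responses, no dichotomization)
    are standardized and their first principal component extracted; subjects
    are split by PC-score tertiles.  The component sign is oriented so a
    higher score means higher symptom burden.
    """
    codes = item_code_frame(records)
    scores = pc1_scores(codes.to_numpy())
    if np.unique(scores).size < 3:
        raise ValueError("fewer than 3 distinct component scores: tertiles undefined")
    labels = tertile_labels(scores, labels=("low", "medium", "high"))
    return pd.Series(labels, index=codes.index, name="extended_class")


def prevalence_from_counts(
    table: pd.DataFrame, outcome: str, feature: str, total: int | None = None
) -> float:
    """Outcome prevalence (percent, one decimal) from a marginal count table.

    ``table`` is the long-format fixture layout (columns: feature, category,
    outcome, count_no, count_yes).  The feature's categories must partition
    the cohort: all counts for the feature sum to the cohort total.
    """
    sub = table[(table["feature"] == feature) & (table["outcome"] == outcome)]
    if sub.empty:
        raise KeyError(f"no rows for feature={feature!r}, outcome={outcome!r}")
    yes = int(sub["count_yes"].sum())
    grand = int(sub["count_no"].sum()) + yes
    if total is not None and grand != total:
        raise ValueError(
            f"feature {feature!r} categories do not partition the cohort for "
            f"{outcome!r}: counts sum to {grand}, expected {total}"
        )
    return round(100.0 * yes / grand, 1)
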
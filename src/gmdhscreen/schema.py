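"""Subject-level data model for the school-survey classification pipeline.

The model matrix has 25 categorical features (demographics, lifestyle,
anthropometry, family history).  This module owns the feature registry (level
sets and ordinal orderings, loaded from the packaged ``schema.yaml``), the raw
questionnaire record, validation, and the fixed clinical cut points that turn
raw measurements (age, sleep hours, waist/height, ...) into those categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Feature",
    "QuestionnaireRecord",
    "SchemaError",
    "ValidationError",
    "load_schema",
    "feature_registry",
    "feature_names",
    "validate_feature_table",
    "categorize_measurements",
    "categorize_record",
    "pc1_scores",
    "tertile_labels",
    "composite_tertiles",
    "read_subjects_csv",
    "write_subjects_csv",
    "Q_FREQUENCY_LEVELS",
    "Q6_LEVELS",
    "Q7_LEVELS",
]


class SchemaError(ValueError):
    """A table or record does not conform to the declared schema."""


class ValidationError(SchemaError):
    """A single field failed validation; the message names the field."""


@dataclass(frozen=True)
class Feature:
    name: str
    levels: tuple[str, ...]
    ordered: bool

    def code(self, level: str) -> int:
        """Integer code of a level (its position on the declared scale)."""
        try:
            return self.levels.index(level)
        except ValueError:
            raise ValidationError(
                f"feature {self.name!r}: unknown level {level!r}; "
                f"expected one of {self.levels}"
            ) from None


def load_schema() -> dict:
    """Parse the packaged schema file (feature registry + item scales)."""
    text = resources.files("gmdhscreen.data").joinpath("schema.yaml").read_text()
    return yaml.safe_load(text)


_SCHEMA = load_schema()

#: The 25 model features, in the conventional x1..x25 order.
FEATURES: tuple[Feature, ...] = tuple(
    Feature(f["name"], tuple(f["levels"]), bool(f["ordered"]))
    for f in _SCHEMA["features"]
)
_BY_NAME: dict[str, Feature] = {f.name: f for f in FEATURES}

Q_FREQUENCY_LEVELS: tuple[str, ...] = tuple(_SCHEMA["items"]["q_frequency"])
Q6_LEVELS: tuple[str, ...] = tuple(_SCHEMA["items"]["q6"])
Q7_LEVELS: tuple[str, ...] = tuple(_SCHEMA["items"]["q7"])

OUTCOME_NAMES: tuple[str, ...] = tuple(_SCHEMA["outcomes"])


def feature_registry() -> Mapping[str, Feature]:
    return dict(_BY_NAME)


def feature_names() -> list[str]:
    return [f.name for f in FEATURES]


def get_feature(name: str) -> Feature:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise SchemaError(f"unknown feature {name!r}") from None


@dataclass
class QuestionnaireRecord:
    """One subject's raw questionnaire items, measurements and covariates.

    The seven symptom items are ordinal strings from the scales declared in
    the schema file; raw measurements are numeric; any field may be ``None``
    (missing).  ``bmi_category`` is consumed as given — growth-reference
    percentile computation is out of scope.
    """

    subject_id: str
    q1: str | None = None  # confusion
    q2: str | None = None  # insomnia
    q3: str | None = None  # anxiety
    q4: str | None = None  # angriness
    q5: str | None = None  # worthlessness
    q6: str | None = None  # depression indicator (prevented routine activity)
    q7: str | None = None  # worriedness frequency (sleep-prevention qualifier)
    age_years: int | None = None
    sleep_hours: float | None = None
    screen_hours: float | None = None
    weight_kg: float | None = None
    height_cm: float | None = None
    waist_cm: float | None = None
    birth_weight_g: float | None = None
    family_size: int | None = None
    n_close_friends: int | None = None
    life_satisfaction: int | None = None
    breakfast_days_per_week: int | None = None
    body_image_5: str | None = None  # 5-level body-size self-perception
    sex: str | None = None
    residence: str | None = None
    smoker: str | None = None
    salty_snack: str | None = None
    sweetened_beverage: str | None = None
    fast_food: str | None = None
    mother_education: str | None = None
    milk_type: str | None = None
    diet_plan: str | None = None
    fh_sudden_death: str | None = None
    fh_cancer: str | None = None
    bmi_category: str | None = None
    srh: str | None = None
    ses: str | None = None
    physical_activity: str | None = None

    def validate(self) -> None:
        def _check_level(name: str, value, levels: Sequence[str]) -> None:
            if value is not None and value not in levels:
                raise ValidationError(
                    f"field {name!r}: value {value!r} not in {tuple(levels)}"
                )

        for q in ("q1", "q2", "q3", "q4", "q5"):
            _check_level(q, getattr(self, q), Q_FREQUENCY_LEVELS)
        _check_level("q6", self.q6, Q6_LEVELS)
        _check_level("q7", self.q7, Q7_LEVELS)
        if self.life_satisfaction is not None and not 1 <= self.life_satisfaction <= 10:
            raise ValidationError("field 'life_satisfaction': must be in [1, 10]")
        if self.breakfast_days_per_week is not None and not (
            0 <= self.breakfast_days_per_week <= 7
        ):
            raise ValidationError("field 'breakfast_days_per_week': must be in [0, 7]")
        for name in ("weight_kg", "height_cm", "waist_cm", "birth_weight_g"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"field {name!r}: must be strictly positive")
        for name in ("sleep_hours", "screen_hours"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"field {name!r}: must be nonnegative")
        for name in ("family_size", "n_close_friends"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"field {name!r}: must be nonnegative")


# ---------------------------------------------------------------------------
# Measurement categorization (fixed clinical cut points)
# ---------------------------------------------------------------------------

_BODY_IMAGE_COLLAPSE = {
    "much_too_thin": "underweight",
    "a_bit_too_thin": "underweight",
    "about_right": "normal",
    "a_bit_too_fat": "overweight",
    "much_too_fat": "overweight",
}


def _age_cat(age: int) -> str:
    if 6 <= age <= 10:
        return "6-10"
    if 11 <= age <= 14:
        return "11-14"
    if 15 <= age <= 19:
        return "15-19"
    raise ValidationError(f"field 'age_years': value {age} outside 6-19")


def _sleep_cat(h: float) -> str:
    # Printed bands "<=5", "5-8", ">8" read as the partition [0,5], (5,8], (8, inf).
    if h <= 5:
        return "<=5h"
    if h <= 8:
        return "5-8h"
    return ">8h"


def _screen_cat(h: float) -> str:
    return "<=4h" if h <= 4 else ">4h"


def _family_size_cat(n: int) -> str:
    return "<=4" if n <= 4 else ">4"


def _friends_cat(n: int) -> str:
    return str(n) if n <= 2 else "3+"


def _life_satisfaction_cat(score: int) -> str:
    if not 1 <= score <= 10:
        raise ValidationError(f"field 'life_satisfaction': value {score} outside [1, 10]")
    return "low" if score < 6 else "high"


def _breakfast_cat(days: int) -> str:
    if not 0 <= days <= 7:
        raise ValidationError(
            f"field 'breakfast_days_per_week': value {days} outside [0, 7]"
        )
    if days >= 5:
        return "non_skipper"
    if days >= 3:
        return "semi_skipper"
    return "skipper"


def _body_image_cat(level5: str) -> str:
    try:
        return _BODY_IMAGE_COLLAPSE[level5]
    except KeyError:
        raise ValidationError(
            f"field 'body_image_5': value {level5!r} not in "
            f"{tuple(_BODY_IMAGE_COLLAPSE)}"
        ) from None


def _birth_weight_cat(grams: float) -> str:
    # Strict outer bands: low < 2500, high > 4000; both boundaries are normal.
    if grams < 2500:
        return "<2500g"
    if grams <= 4000:
        return "2500-4000g"
    return ">4000g"


def _abdominal_obesity(waist_cm: float, height_cm: float) -> str:
    return "yes" if waist_cm / height_cm > 0.5 else "no"


def categorize_record(record: QuestionnaireRecord) -> dict[str, str]:
    """Derive the categorical features obtainable from one record's raw fields.

    Only categories whose raw inputs are present are returned; pass-through
    categorical covariates (sex, smoker, ...) are copied verbatim after a
    level check.  Raises :class:`ValidationError` naming the offending field
    for out-of-domain raw values.
    """
    record.validate()
    out: dict[str, str] = {}
    if record.age_years is not None:
        out["age_cat"] = _age_cat(record.age_years)
    if record.sleep_hours is not None:
        out["sleep_cat"] = _sleep_cat(record.sleep_hours)
    if record.screen_hours is not None:
        out["screen_cat"] = _screen_cat(record.screen_hours)
    if record.family_size is not None:
        out["family_size_cat"] = _family_size_cat(record.family_size)
    if record.n_close_friends is not None:
        out["n_friends_cat"] = _friends_cat(record.n_close_friends)
    if record.life_satisfaction is not None:
        out["life_satisfaction_cat"] = _life_satisfaction_cat(record.life_satisfaction)
    if record.breakfast_days_per_week is not None:
        out["breakfast_cat"] = _breakfast_cat(record.breakfast_days_per_week)
    if record.body_image_5 is not None:
        out["body_image"] = _body_image_cat(record.body_image_5)
    if record.birth_weight_g is not None:
        out["birth_weight_cat"] = _birth_weight_cat(record.birth_weight_g)
    if record.waist_cm is not None and record.height_cm is not None:
        out["abdominal_obesity"] = _abdominal_obesity(record.waist_cm, record.height_cm)
    passthrough = {
        "sex": record.sex,
        "residence": record.residence,
        "smoker": record.smoker,
        "salty_snack": record.salty_snack,
        "sweetened_beverage": record.sweetened_beverage,
        "fast_food": record.fast_food,
        "mother_education": record.mother_education,
        "milk_type": record.milk_type,
        "diet_plan": record.diet_plan,
        "fh_sudden_death": record.fh_sudden_death,
        "fh_cancer": record.fh_cancer,
        "bmi_cat": record.bmi_category,
        "srh": record.srh,
        "ses": record.ses,
        "physical_activity": record.physical_activity,
    }
    for name, value in passthrough.items():
        if value is None:
            continue
        feat = get_feature(name)
        if value not in feat.levels:
            raise ValidationError(
                f"field {name!r}: value {value!r} not in {feat.levels}"
            )
        out[name] = value
    return out


# The public name mirrors the operation it implements.
categorize_measurements = categorize_record


def validate_feature_table(table: pd.DataFrame, allow_missing: bool = True) -> None:
    """Check every cell of a categorical feature table against the registry.

    Raises :class:`SchemaError` listing offending (feature, level) pairs.
    Columns that are not registered features are ignored (ids, outcomes).
    """
    problems: list[str] = []
    for name in table.columns:
        if name not in _BY_NAME:
            continue
        feat = _BY_NAME[name]
        col = table[name]
        mask = col.notna()
        if not allow_missing and not mask.all():
            problems.append(f"{name}: missing values present")
        bad = set(col[mask].unique()) - set(feat.levels)
        if bad:
            problems.append(f"{name}: unknown levels {sorted(bad)}")
    if problems:
        raise SchemaError("feature table failed validation: " + "; ".join(problems))


# ---------------------------------------------------------------------------
# Principal-component composites (SES, physical activity, symptom severity)
# ---------------------------------------------------------------------------

def pc1_scores(item_matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """First principal component scores of standardized items.

    Items are standardized (correlation-matrix PCA) so the component does not
    depend on arbitrary coding offsets/scales.  The sign is oriented so that
    a higher score means higher item values on average (higher burden for the
    symptom items).  Raises on zero-variance input (no component defined).
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects for a principal component")
    sd = X.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("zero-variance item matrix: no principal component defined")
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # SVD of the standardized matrix; PC1 loadings = first right singular vector
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    if v.sum() < 0:  # orient: higher score = higher items
        v = -v
    return Z @ v


def tertile_labels(
    scores: np.ndarray, labels: Sequence[str] = ("low", "medium", "high")
) -> np.ndarray:
    """Tertile membership with ties assigned to the lower tertile.

    Cut values are the scores at ranks ceil(n/3) and ceil(2n/3) of the stable
    ascending sort; all subjects at or below a cut value fall in the lower
    group, which makes the labeling deterministic and order-independent.
    """
    s = np.asarray(scores, dtype=float)
    n = s.size
    if n < 3:
        raise ValueError("need at least 3 subjects for tertiles")
    srt = np.sort(s, kind="stable")
    c1 = srt[math.ceil(n / 3) - 1]
    c2 = srt[math.ceil(2 * n / 3) - 1]
    out = np.where(s <= c1, labels[0], np.where(s <= c2, labels[1], labels[2]))
    return out


def composite_tertiles(
    item_matrix: np.ndarray | pd.DataFrame,
    labels: Sequence[str] = ("low", "moderate", "high"),
) -> np.ndarray:
    """PCA-composite tertiles used for the SES and physical-activity scores."""
    return tertile_labels(pc1_scores(item_matrix), labels=labels)


# ---------------------------------------------------------------------------
# Subject CSV I/O (delimited text, empty field = missing)
# ---------------------------------------------------------------------------

_RECORD_FIELDS = [f.name for f in dc_fields(QuestionnaireRecord)]


def read_subjects_csv(path) -> list[QuestionnaireRecord]:
    """Read raw subject records from CSV (header fixed by the record schema)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    unknown = set(df.columns) - set(_RECORD_FIELDS)
    if unknown:
        raise SchemaError(f"unknown columns in subject file: {sorted(unknown)}")
    int_fields = {
        "age_years", "family_size", "n_close_friends",
        "life_satisfaction", "breakfast_days_per_week",
    }
    float_fields = {
        "sleep_hours", "screen_hours", "weight_kg", "height_cm",
        "waist_cm", "birth_weight_g",
    }
    records = []
    for row in df.to_dict(orient="records"):
        kwargs = {}
        for name, value in row.items():
            if pd.isna(value):
                kwargs[name] = None
            elif name in int_fields:
                kwargs[name] = int(float(value))
            elif name in float_fields:
                kwargs[name] = float(value)
            else:
                kwargs[name] = value
        rec = QuestionnaireRecord(**kwargs)
        rec.validate()
        records.append(rec)
    return records


def write_subjects_csv(records: Iterable[QuestionnaireRecord], path) -> None:
    rows = [{f: getattr(r, f) for f in _RECORD_FIELDS} for r in records]
    pd.DataFrame(rows, columns=_RECORD_FIELDS).to_csv(path, index=False)
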
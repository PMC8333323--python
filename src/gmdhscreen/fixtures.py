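"""Packaged marginal-count and performance tables.

The cohort's marginal counts (demographic/lifestyle features by outcome) and
the published pooled performance rows are shipped as CSV resources so the
in-table arithmetic (prevalences, cohort shares, chi-square tests, diagnostic
odds-ratio identities, confidence intervals) can be recomputed and tested
without subject-level data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "COHORT_TOTAL",
    "KNOWN_INCONSISTENT",
    "load_marginal_counts",
    "load_performance_table",
    "count_table",
    "feature_is_consistent",
]

#: Number of complete-case subjects in the cohort the tables describe.
COHORT_TOTAL = 10_350

#: (feature, outcome) columns whose printed counts do not sum to the cohort
#: total in the source tables; shipped as printed, flagged here.
KNOWN_INCONSISTENT = {
    ("sweetened_beverage", "mild_moderate"),
    ("fast_food", "mild_moderate"),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("gmdhscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_marginal_counts(which: str = "all") -> pd.DataFrame:
    """Long-format marginal counts (feature, category, outcome, no/yes, p).

    ``which`` is ``"demographics"``, ``"lifestyle"`` or ``"all"``.
    """
    t1 = _read("table1_demographics.csv")
    t2 = _read("table2_lifestyle.csv")
    if which == "demographics":
        return t1
    if which == "lifestyle":
        return t2
    if which == "all":
        return pd.concat([t1, t2], ignore_index=True)
    raise ValueError(f"unknown table selector {which!r}")


def load_performance_table() -> pd.DataFrame:
    """Pooled cross-validated performance rows (per outcome x classifier).

    Percent-scale metrics (se, sp, pr, npv, acc) are percents; auc, dor, dp,
    mcc and kappa are on their natural scales.  ``*_lo``/``*_hi`` columns are
    95% confidence bounds.
    """
    return _read("table4_performance.csv")


def feature_is_consistent(feature: str, outcome: str) -> bool:
    return (feature, outcome) not in KNOWN_INCONSISTENT


def count_table(counts: pd.DataFrame, feature: str, outcome: str) -> pd.DataFrame:
    """Category x (no, yes) contingency table for one feature and outcome."""
    sub = counts[(counts["feature"] == feature) & (counts["outcome"] == outcome)]
    if sub.empty:
        raise KeyError(f"no rows for feature={feature!r}, outcome={outcome!r}")
    out = sub.set_index("category")[["count_no", "count_yes"]].astype(int)
    out.columns = ["no", "yes"]
    return out
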
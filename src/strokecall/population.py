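"""Reference population characteristics of the Copenhagen 2015--2021 cohort.

The published cohort description reports, for each data subset (emergency-line
training data, helpline training/validation/test data, and the 2021 calls that
lack a diagnostic category), the number of calls, the female/male counts and
the number of patients aged 65+, separately for all calls, stroke calls and
non-stroke calls.  Only the counts are retained here; every percentage and
prevalence figure used elsewhere in the package is *recomputed* from them.

These counts also anchor the defaults of :mod:`strokecall.synthetic` (age and
sex structure, prevalence, missing-category fraction, test-year call share).
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = [
    "cohort_table",
    "subset_percentage",
    "test_year_prevalence_pct",
    "age_group_prevalence_pct",
    "round_sig",
]

# subset -> row -> {n, female, male, age_65plus}
_COHORT_COUNTS: dict[str, dict[str, dict[str, int]]] = {
    "train_emergency": {
        "all": {"n": 155_696, "female": 74_640, "male": 79_564, "age_65plus": 72_930},
        "stroke": {"n": 3_899, "female": 1_784, "male": 2_115, "age_65plus": 2_968},
        "non_stroke": {"n": 151_797, "female": 72_856, "male": 77_449, "age_65plus": 69_962},
    },
    "train_helpline": {
        "all": {"n": 1_391_301, "female": 792_783, "male": 596_760, "age_65plus": 335_146},
        "stroke": {"n": 3_471, "female": 1_654, "male": 1_815, "age_65plus": 2_421},
        "non_stroke": {"n": 1_387_830, "female": 791_129, "male": 594_945, "age_65plus": 332_725},
    },
    "validation": {
        "all": {"n": 155_825, "female": 86_959, "male": 68_866, "age_65plus": 30_313},
        "stroke": {"n": 360, "female": 161, "male": 199, "age_65plus": 250},
        "non_stroke": {"n": 155_465, "female": 86_798, "male": 68_667, "age_65plus": 30_063},
    },
    "test": {
        "all": {"n": 344_030, "female": 190_974, "male": 153_050, "age_65plus": 65_652},
        "stroke": {"n": 757, "female": 349, "male": 408, "age_65plus": 555},
        "non_stroke": {"n": 343_273, "female": 190_625, "male": 152_642, "age_65plus": 65_097},
    },
    "test_no_category": {
        "all": {"n": 231_009, "female": 134_324, "male": 96_258, "age_65plus": 81_488},
        "stroke": {"n": 679, "female": 366, "male": 313, "age_65plus": 567},
        "non_stroke": {"n": 230_330, "female": 133_958, "male": 95_945, "age_65plus": 80_921},
    },
}


def cohort_table() -> pd.DataFrame:
    """Tidy table of the reference cohort counts.

    Columns: ``subset``, ``row`` (all / stroke / non_stroke), ``n``,
    ``female``, ``male``, ``age_65plus``.
    """
    records = []
    for subset, rows in _COHORT_COUNTS.items():
        for row, counts in rows.items():
            records.append({"subset": subset, "row": row, **counts})
    return pd.DataFrame.from_records(records)


def subset_percentage(subset: str, row: str, field: str) -> float:
    """Percentage of ``field`` within (subset, row), recomputed from counts.

    E.g. ``subset_percentage("test", "stroke", "age_65plus")`` is the share of
    stroke calls in the test subset with a patient aged 65 or older.
    """
    counts = _COHORT_COUNTS[subset][row]
    return 100.0 * counts[field] / counts["n"]


def test_year_prevalence_pct() -> float:
    """Stroke prevalence (%) among all test-year calls.

    The test year comprises the test subset plus the calls without a
    diagnostic category.
    """
    stroke = _COHORT_COUNTS["test"]["stroke"]["n"] + _COHORT_COUNTS["test_no_category"]["stroke"]["n"]
    total = _COHORT_COUNTS["test"]["all"]["n"] + _COHORT_COUNTS["test_no_category"]["all"]["n"]
    return 100.0 * stroke / total


def age_group_prevalence_pct(group: str) -> float:
    """Stroke prevalence (%) in the test subset for an age group.

    ``group`` is ``"65plus"`` or ``"18_64"``; the 18--64 counts are the
    complements of the 65+ counts within the test subset.
    """
    t = _COHORT_COUNTS["test"]
    if group == "65plus":
        return 100.0 * t["stroke"]["age_65plus"] / t["all"]["age_65plus"]
    if group == "18_64":
        stroke = t["stroke"]["n"] - t["stroke"]["age_65plus"]
        total = t["all"]["n"] - t["all"]["age_65plus"]
        return 100.0 * stroke / total
    raise ValueError(f"unknown age group: {group!r}")


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant digits (reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))
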
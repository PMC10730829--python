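"""Registry cross-referencing, labelling and dataset splitting.

Ground truth: a call is stroke-positive when its patient has a non-SAH stroke
registry entry whose patient-reported onset lies within a closed window of 72
hours before to 24 hours after call start.  Subarachnoid haemorrhage entries
never qualify; a call whose only match is SAH is negative.

Call-taker label: positive when the call-taker both selected the stroke
diagnostic category and dispatched an appropriately prioritised ambulance.

Splitting: helpline calls of the test year form the test set (those without a
registered diagnostic category are kept apart as a bias-assessment subset);
earlier helpline calls are divided into a validation set and five training
folds by stratified sampling on (ground truth, category present); calls
without a category never enter validation or test; emergency-line calls are
training-only, with test-year emergency calls discarded to avoid temporal
overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CallRecord",
    "RegistryEntry",
    "LabelledCall",
    "ground_truth_label",
    "calltaker_label",
    "label_calls",
    "split_dataset",
    "TRAIN_FOLDS",
]

WINDOW_BEFORE_H = 72.0
WINDOW_AFTER_H = 24.0
TRAIN_FOLDS = tuple(f"train_fold_{i}" for i in range(1, 6))


@dataclass(frozen=True)
class CallRecord:
    call_id: str
    patient_id: Optional[str]
    line: str  # "emergency" | "helpline"
    call_start: pd.Timestamp
    age: float
    sex: str
    diagnostic_category: Optional[str]
    stroke_category_selected: bool
    ambulance_dispatched_appropriate: bool


@dataclass(frozen=True)
class RegistryEntry:
    patient_id: str
    onset_time: pd.Timestamp
    stroke_type: str  # "ischaemic" | "haemorrhagic" | "tia" | "sah"


@dataclass(frozen=True)
class LabelledCall:
    call: CallRecord
    ground_truth: bool
    calltaker_positive: bool
    subset: Optional[str]
    matched_entry: Optional[RegistryEntry]


def ground_truth_label(
    call: CallRecord,
    registry: Iterable[RegistryEntry] | Mapping[str, Sequence[RegistryEntry]],
    window_before_h: float = WINDOW_BEFORE_H,
    window_after_h: float = WINDOW_AFTER_H,
) -> tuple[bool, Optional[RegistryEntry]]:
    """Label one call against the registry.

    Returns ``(True, entry)`` when a non-SAH entry for the same patient has
    onset within ``[call_start - window_before_h, call_start + window_after_h]``
    (closed on both ends); among several qualifying entries the one with onset
    nearest call start is returned.  SAH-only matches and out-of-window
    matches yield ``(False, None)``.
    """
    if call.patient_id is None or (isinstance(call.patient_id, float) and np.isnan(call.patient_id)):
        warnings.warn(f"call {call.call_id} has no patient id; labelled negative")
        return False, None
    if isinstance(registry, Mapping):
        entries = registry.get(call.patient_id, ())
    else:
        entries = [e for e in registry if e.patient_id == call.patient_id]
    best: Optional[RegistryEntry] = None
    best_gap = np.inf
    for entry in entries:
        if entry.stroke_type == "sah":
            continue
        offset_h = (entry.onset_time - call.call_start) / pd.Timedelta(hours=1)
        if -window_before_h <= offset_h <= window_after_h:
            gap = abs(offset_h)
            if gap < best_gap:
                best, best_gap = entry, gap
    return (best is not None), best


def calltaker_label(call: CallRecord) -> bool:
    """Call-taker positive: stroke category selected AND ambulance dispatched."""
    return bool(call.stroke_category_selected and call.ambulance_dispatched_appropriate)


def label_calls(
    calls: pd.DataFrame,
    registry: pd.DataFrame,
    window_before_h: float = WINDOW_BEFORE_H,
    window_after_h: float = WINDOW_AFTER_H,
) -> pd.DataFrame:
    """Vectorised labelling of a call table against a registry table.

    Returns a copy of ``calls`` with ``ground_truth``, ``matched_onset``,
    ``matched_stroke_type`` and ``calltaker_positive`` columns.
    """
    out = calls.copy()
    eligible = registry[registry["stroke_type"] != "sah"]
    merged = out[["call_id", "patient_id", "call_start"]].merge(
        eligible, on="patient_id", how="inner"
    )
    if len(merged):
        offset_h = (merged["onset_time"] - merged["call_start"]) / pd.Timedelta(hours=1)
        merged = merged.assign(_offset=offset_h, _gap=offset_h.abs())
        merged = merged[(offset_h >= -window_before_h) & (offset_h <= window_after_h)]
    if len(merged):
        best = merged.sort_values(["call_id", "_gap"], kind="stable").drop_duplicates("call_id")
        best = best.set_index("call_id")
        out = out.set_index("call_id")
        out["ground_truth"] = out.index.isin(best.index)
        out["matched_onset"] = best["onset_time"]
        out["matched_stroke_type"] = best["stroke_type"]
        out = out.reset_index()
    else:
        out["ground_truth"] = False
        out["matched_onset"] = pd.NaT
        out["matched_stroke_type"] = None
    out["calltaker_positive"] = (
        out["stroke_category_selected"].astype(bool)
        & out["ambulance_dispatched_appropriate"].astype(bool)
    )
    return out


def _has_category(calls: pd.DataFrame) -> pd.Series:
    cat = calls["diagnostic_category"]
    return cat.notna() & (cat.astype(str) != "")


def split_dataset(
    calls: pd.DataFrame,
    test_year: int,
    n_folds: int = 5,
    validation_fraction: float = 0.1,
    seed: int = 0,
) -> pd.Series:
    """Assign every call to exactly one subset.

    Returns a Series indexed like ``calls`` with values in
    ``{train_fold_1..n, validation, test, test_no_category, train_extra,
    discarded}``.  ``train_extra`` holds the emergency-line training calls;
    ``discarded`` holds test-year emergency calls (temporal overlap).

    Raises ``ValueError`` when a helpline stratum has fewer calls bound for
    the training folds than there are folds.
    """
    if "ground_truth" not in calls.columns:
        raise ValueError("calls must be labelled first (missing 'ground_truth')")
    year = pd.DatetimeIndex(calls["call_start"]).year
    helpline = calls["line"].to_numpy() == "helpline"
    has_cat = _has_category(calls).to_numpy()
    truth = calls["ground_truth"].to_numpy(dtype=bool)

    subset = np.full(len(calls), "", dtype=object)
    subset[~helpline & (year == test_year)] = "discarded"
    subset[~helpline & (year != test_year)] = "train_extra"
    subset[helpline & (year == test_year) & has_cat] = "test"
    subset[helpline & (year == test_year) & ~has_cat] = "test_no_category"

    rng = np.random.default_rng(seed)
    fold_names = [f"train_fold_{i}" for i in range(1, n_folds + 1)]
    fold_pointer = 0  # rotates across strata so fold sizes stay balanced
    pool = helpline & (year != test_year)
    for truth_value in (True, False):
        for cat_value in (True, False):
            stratum = np.flatnonzero(pool & (truth == truth_value) & (has_cat == cat_value))
            if stratum.size == 0:
                continue
            stratum = stratum[rng.permutation(stratum.size)]
            if cat_value:
                n_val = int(round(validation_fraction * stratum.size))
                subset[stratum[:n_val]] = "validation"
                to_folds = stratum[n_val:]
            else:
                # Calls without a diagnostic category train only.
                to_folds = stratum
            if to_folds.size < n_folds:
                raise ValueError(
                    f"stratum (ground_truth={truth_value}, category_present={cat_value}) "
                    f"has only {to_folds.size} calls for {n_folds} folds"
                )
            for j, idx in enumerate(to_folds):
                subset[idx] = fold_names[(fold_pointer + j) % n_folds]
            fold_pointer = (fold_pointer + to_folds.size) % n_folds
    return pd.Series(subset, index=calls.index, name="subset")
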
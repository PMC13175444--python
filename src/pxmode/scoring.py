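"""Questionnaire scoring on the 0-100 convention of the Korean inpatient
Patient Experience Assessment (PXA).

The 21-item questionnaire mixes three response formats: a 4-point Likert
scale (Q1-Q12, Q14-Q19), one binary yes/no item (Q13), and two 0-10 overall
rating items (Q20-Q21). Every item is rescaled so its maximum is worth 100
points; domain and total scores are the rescaled sums, i.e. the mean of the
member item scores. The Likert map anchors the minimum category at 0
(1 -> 0, 2 -> 100/3, 3 -> 200/3, 4 -> 100), which keeps the three formats
commensurate with a common 0 floor and 100 ceiling; it is isolated in
:func:`rescale_item` so an alternative anchor could be swapped in.

Only complete responders are scored: partial records raise rather than
yielding partial-domain scores.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import ITEM_COLUMNS, TrialDataset, as_frame
from .errors import ValidationError

LIKERT_ITEMS = tuple(f"q{i}" for i in list(range(1, 13)) + list(range(14, 20)))
BINARY_ITEMS = ("q13",)
RATING_ITEMS = ("q20", "q21")

DOMAINS = {
    "nurse": ("q1", "q2", "q3", "q4"),
    "doctor": ("q5", "q6", "q7", "q8"),
    "medication_treatment": ("q9", "q10", "q11", "q12", "q13"),
    "hospital_environment": ("q14", "q15"),
    "patients_rights": ("q16", "q17", "q18", "q19"),
    "overall_rating": ("q20", "q21"),
}

OUTCOME_NAMES = ("total",) + tuple(DOMAINS)


def _canon(item_id: str) -> str:
    item = str(item_id).strip().lower()
    if item not in ITEM_COLUMNS:
        raise ValidationError(f"unknown item id {item_id!r}")
    return item


def rescale_item(item_id: str, raw) -> float:
    """Rescale one raw response to 0-100 points.

    Likert: 1..4 -> (v-1)/3*100. Binary Q13: yes -> 100, no -> 0.
    Rating Q20/Q21: 0..10 -> 10*v. Out-of-range input raises
    ValidationError naming the item and value.
    """
    item = _canon(item_id)
    if item in BINARY_ITEMS:
        val = str(raw).strip().lower()
        if val not in ("yes", "no"):
            raise ValidationError(f"item {item}: expected yes/no, got {raw!r}")
        return 100.0 if val == "yes" else 0.0
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"item {item}: non-numeric response {raw!r}") from None
    if not np.isfinite(v) or v != int(v):
        raise ValidationError(f"item {item}: non-integer response {raw!r}")
    v = int(v)
    if item in LIKERT_ITEMS:
        if not 1 <= v <= 4:
            raise ValidationError(f"item {item}: Likert response {raw!r} outside 1..4")
        return (v - 1) / 3.0 * 100.0
    if not 0 <= v <= 10:
        raise ValidationError(f"item {item}: rating {raw!r} outside 0..10")
    return 10.0 * v


def _require(items: Mapping[str, float], needed) -> np.ndarray:
    missing = [q for q in needed if q not in items or pd.isna(items[q])]
    if missing:
        raise ValidationError(f"missing item score(s): {missing}")
    return np.asarray([float(items[q]) for q in needed], dtype=float)


def domain_score(item_scores: Mapping[str, float], domain: str) -> float:
    """Domain score: mean of the member item scores (sum rescaled to 100)."""
    if domain not in DOMAINS:
        raise ValidationError(f"unknown domain {domain!r}")
    return float(_require(item_scores, DOMAINS[domain]).mean())


def total_score(item_scores: Mapping[str, float]) -> float:
    """Total score: mean of all 21 item scores (sum rescaled to 100)."""
    return float(_require(item_scores, ITEM_COLUMNS).mean())


def score_respondent(raw_items: Mapping[str, object]) -> dict:
    """Score one complete respondent; returns item, domain, and total scores."""
    scores = {q: rescale_item(q, raw_items[q]) for q in ITEM_COLUMNS if q in raw_items and not pd.isna(raw_items[q])}
    out = {q: scores[q] for q in ITEM_COLUMNS if q in scores}
    for name in DOMAINS:
        out[name] = domain_score(scores, name)
    out["total"] = total_score(scores)
    return out


def score_dataset(data) -> pd.DataFrame:
    """Score every respondent of a trial dataset.

    Returns a frame with one row per respondent: ``patient_id``, ``total``,
    the six domain scores, and the 21 rescaled item scores.
    """
    df = as_frame(data)
    resp = df[df["responded"].astype(bool)]
    item_scores = pd.DataFrame(index=resp.index)
    for q in ITEM_COLUMNS:
        if q in BINARY_ITEMS:
            col = resp[q].astype(str).str.strip().str.lower()
            bad = ~col.isin(["yes", "no"])
            if bad.any():
                raise ValidationError(
                    f"item {q}: invalid response(s) {sorted(resp.loc[bad, q].unique())}"
                )
            item_scores[q] = np.where(col == "yes", 100.0, 0.0)
        else:
            vals = pd.to_numeric(resp[q], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"item {q}: missing or non-numeric response for a respondent")
            lo, hi = (1, 4) if q in LIKERT_ITEMS else (0, 10)
            if ((vals < lo) | (vals > hi) | (vals != vals.round())).any():
                raise ValidationError(f"item {q}: response outside {lo}..{hi}")
            item_scores[q] = (vals - 1) / 3.0 * 100.0 if q in LIKERT_ITEMS else 10.0 * vals
    out = pd.DataFrame({"patient_id": resp["patient_id"].to_numpy()}, index=resp.index)
    for name, members in DOMAINS.items():
        out[name] = item_scores[list(members)].mean(axis=1)
    out["total"] = item_scores[list(ITEM_COLUMNS)].mean(axis=1)
    cols = ["patient_id", "total", *DOMAINS, *ITEM_COLUMNS]
    return pd.concat([out, item_scores], axis=1)[cols]


def outcome_series(data, scores: pd.DataFrame, outcome: str) -> pd.Series:
    """Align one scored outcome to the full randomized patient table.

    Nonrespondents get NaN; the result shares the trial frame's index so the
    estimators can consume it directly.
    """
    if outcome not in OUTCOME_NAMES:
        raise ValidationError(f"unknown outcome {outcome!r}; expected one of {OUTCOME_NAMES}")
    df = as_frame(data)
    mapped = df["patient_id"].map(scores.set_index("patient_id")[outcome])
    return pd.Series(mapped.to_numpy(dtype=float), index=df.index, name=outcome)
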
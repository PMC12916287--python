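"""Scoring of the 13-item Short Mood and Feelings Questionnaire (SMFQ).

Each item is scored 0 ("not true"), 1 ("sometimes true") or 2 ("always
true"), giving a total of 0-26.  Occasions with a small number of missing
items have those items imputed to the median of the answered items; beyond
that the occasion score is recorded as missing.  Subjects need at least
three scored occasions to enter the trajectory-model fitting sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_ITEMS = 13
MAX_SCORE = 2 * N_ITEMS

#: with the default rule, occasions missing 3 or more items are not scored
DEFAULT_MAX_MISSING = 2

ITEM_COLUMNS = [f"item{i:02d}" for i in range(1, N_ITEMS + 1)]


class ItemValidationError(ValueError):
    """An item vector has the wrong length or an illegal value."""


@dataclass(frozen=True)
class OccasionScore:
    """Total score for one questionnaire occasion.

    ``score`` is None when too many items are missing.  ``n_imputed``
    counts the median-imputed items and ``imputation_value`` records the
    per-item value used (None when nothing was imputed).
    """

    score: int | None
    n_imputed: int
    imputation_value: float | None = None


def _validate_items(items) -> np.ndarray:
    arr = np.asarray(items, dtype=float)
    if arr.shape != (N_ITEMS,):
        raise ItemValidationError(
            f"expected exactly {N_ITEMS} items, got shape {arr.shape}"
        )
    answered = ~np.isnan(arr)
    bad = answered & ~np.isin(arr, (0.0, 1.0, 2.0))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ItemValidationError(
            f"item index {idx} has illegal value {arr[idx]!r} (allowed: 0, 1, 2, missing)"
        )
    return arr


def score_occasion(
    items,
    max_missing: int = DEFAULT_MAX_MISSING,
    round_total: bool = True,
) -> OccasionScore:
    """Score one occasion's 13 item responses.

    With ``k`` missing items, k <= ``max_missing``: each missing item is
    imputed to the median of the answered items (mean of the two central
    values for an even count), the items are summed, and the total is
    rounded half-up (unless ``round_total`` is False, in which case the
    fractional total is kept).  More missing items than ``max_missing``
    gives a missing score.  The default ``max_missing=2`` treats exactly
    three missing items conservatively as unscorable.
    """
    arr = _validate_items(items)
    missing = np.isnan(arr)
    n_missing = int(missing.sum())
    if n_missing == 0:
        return OccasionScore(score=int(arr.sum()), n_imputed=0)
    if n_missing > max_missing:
        return OccasionScore(score=None, n_imputed=0)
    med = float(np.median(arr[~missing]))
    total = float(arr[~missing].sum()) + n_missing * med
    if round_total:
        total = math.floor(total + 0.5)  # round half-up
    total = min(max(total, 0), MAX_SCORE)
    return OccasionScore(
        score=int(total) if round_total else total,
        n_imputed=n_missing,
        imputation_value=med,
    )


def score_table(
    occasions: pd.DataFrame,
    max_missing: int = DEFAULT_MAX_MISSING,
    round_total: bool = True,
) -> pd.DataFrame:
    """Score a long-format occasions table.

    ``occasions`` has columns subject_id, age, item01..item13 (missing
    items empty/NaN).  Returns a table with columns subject_id, age,
    score, n_imputed; unscorable occasions have a missing score.
    """
    for col in ["subject_id", "age", *ITEM_COLUMNS]:
        if col not in occasions.columns:
            raise KeyError(f"occasions table lacks required column {col!r}")
    items = occasions[ITEM_COLUMNS].to_numpy(dtype=float)
    answered = ~np.isnan(items)
    bad = answered & ~np.isin(items, (0.0, 1.0, 2.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ItemValidationError(
            f"row {r}: item index {c} has illegal value {items[r, c]!r}"
        )
    n_missing = (~answered).sum(axis=1)

    scores = np.full(len(occasions), np.nan)
    n_imputed = np.zeros(len(occasions), dtype=int)

    complete = n_missing == 0
    scores[complete] = items[complete].sum(axis=1)

    fixable = (n_missing > 0) & (n_missing <= max_missing)
    for i in np.flatnonzero(fixable):
        row = items[i]
        med = float(np.median(row[~np.isnan(row)]))
        total = float(np.nansum(row)) + n_missing[i] * med
        if round_total:
            total = math.floor(total + 0.5)
        scores[i] = min(max(total, 0), MAX_SCORE)
        n_imputed[i] = n_missing[i]

    return pd.DataFrame(
        {
            "subject_id": occasions["subject_id"].to_numpy(),
            "age": occasions["age"].to_numpy(dtype=float),
            "score": scores,
            "n_imputed": n_imputed,
        }
    )


def eligible_for_fitting(scores, min_measurements: int = 3) -> bool:
    """True iff at least ``min_measurements`` occasions have a score.

    ``scores`` is a per-subject sequence of OccasionScore, numbers, or
    NaN/None entries; an empty sequence is simply ineligible.
    """
    n = 0
    for s in scores:
        if isinstance(s, OccasionScore):
            present = s.score is not None
        elif s is None:
            present = False
        else:
            present = not (isinstance(s, float) and math.isnan(s))
        n += present
    return n >= min_measurements


def fitting_sample(score_df: pd.DataFrame, min_measurements: int = 3) -> pd.DataFrame:
    """Subset the score table to subjects with >= ``min_measurements`` scores.

    Rows with missing scores are dropped; subjects below the threshold are
    removed entirely.  This is the estimation sample for the trajectory
    model; the remainder still receives predicted class membership later.
    """
    present = score_df.dropna(subset=["score"])
    counts = present.groupby("subject_id")["score"].size()
    keep = counts.index[counts >= min_measurements]
    return present[present["subject_id"].isin(keep)].reset_index(drop=True)
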
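"""Item discrimination and internal-consistency statistics.

Operates on a studies x items matrix of ratings (typically mean-over-rater
for a rater group).  Provides corrected item-total correlations (the
correlation of an item with the total of the *remaining* items), Cronbach's
alpha and alpha-if-item-deleted, endorsement rates, and the 0.2/0.9
uninformative-item flags used to screen instrument items.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import UndefinedStatisticError, ValidationError

ITC_LOW = 0.2
ITC_HIGH = 0.9
ENDORSEMENT_MIN_RATING = 6


class ItemFlag(str, enum.Enum):
    OK = "ok"
    UNINFORMATIVE_LOW = "uninformative_low"
    UNINFORMATIVE_HIGH = "uninformative_high"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class ItemStats:
    item_id: object
    item_total_correlation: float
    alpha_if_deleted: float
    endorsement_rate: float
    flag: ItemFlag


def _as_matrix(matrix) -> tuple[np.ndarray, list]:
    """Coerce a DataFrame (studies x items) or 2-D array to float ndarray + item labels."""
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), list(matrix.columns)
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("rating matrix must be 2-dimensional (studies x items)")
    return arr, list(range(arr.shape[1]))


def item_total_correlation(matrix, item_id, *, corrected: bool = True) -> float:
    """Item-total correlation for one item.

    ``corrected=True`` (default) correlates the item with the total of the
    remaining items (item-rest correlation); ``corrected=False`` correlates
    with the full total including the item itself.
    """
    arr, labels = _as_matrix(matrix)
    if arr.shape[0] < 3:
        raise ValidationError("item-total correlation needs at least 3 studies")
    try:
        j = labels.index(item_id)
    except ValueError:
        raise ValidationError(f"unknown item {item_id!r}") from None
    item = arr[:, j]
    total = arr.sum(axis=1)
    other = total - item if corrected else total
    if np.var(item) == 0:
        raise UndefinedStatisticError(f"item {item_id!r} has zero variance")
    if np.var(other) == 0:
        raise UndefinedStatisticError(
            f"{'rest-total' if corrected else 'total'} for item {item_id!r} has zero variance")
    return float(np.corrcoef(item, other)[0, 1])


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total variance).

    Variances are sample variances (ddof=1).  Requires >=2 items, >=3 studies
    and a non-degenerate total score.
    """
    arr, _ = _as_matrix(matrix)
    n, k = arr.shape
    if k < 2:
        raise ValidationError("Cronbach's alpha needs at least 2 items")
    if n < 3:
        raise ValidationError("Cronbach's alpha needs at least 3 studies")
    total_var = np.var(arr.sum(axis=1), ddof=1)
    if total_var == 0:
        raise UndefinedStatisticError("total-score variance is zero; alpha undefined")
    item_vars = np.var(arr, axis=0, ddof=1)
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def alpha_if_deleted(matrix, item_id) -> float:
    """Cronbach's alpha recomputed with one item removed (needs >=3 items)."""
    arr, labels = _as_matrix(matrix)
    if arr.shape[1] < 3:
        raise UndefinedStatisticError(
            "alpha-if-deleted is undefined for 2-item scales (one item would remain)")
    try:
        j = labels.index(item_id)
    except ValueError:
        raise ValidationError(f"unknown item {item_id!r}") from None
    return cronbach_alpha(np.delete(arr, j, axis=1))


def endorsement_rate(ratings) -> float:
    """Fraction of ratings that are 6 or 7 ("endorsement" of an item)."""
    arr = np.asarray(ratings, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError("endorsement rate of an empty rating set is undefined")
    return float(np.mean(arr >= ENDORSEMENT_MIN_RATING))


def flag_itc(itc: float) -> ItemFlag:
    if itc < ITC_LOW:
        return ItemFlag.UNINFORMATIVE_LOW
    if itc > ITC_HIGH:
        return ItemFlag.UNINFORMATIVE_HIGH
    return ItemFlag.OK


def flag_items(stats: list[ItemStats]) -> list[ItemStats]:
    """Items whose ITC falls outside [0.2, 0.9] — candidates for exclusion review."""
    return [s for s in stats if s.flag is not ItemFlag.OK]


def item_stats_table(matrix, raw_ratings=None, *, corrected: bool = True) -> pd.DataFrame:
    """Per-item ITC, alpha-if-deleted, endorsement rate and flag as a table.

    ``matrix`` is the studies x items matrix used for ITC/alpha (typically
    mean-over-rater); ``raw_ratings`` optionally supplies the unaveraged
    per-rater ratings per item (mapping item_id -> 1-D array) for endorsement
    rates, which are defined on raw 1-7 ratings.  If omitted, endorsement is
    computed from ``matrix`` columns.
    """
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(np.asarray(matrix))
    alpha = cronbach_alpha(df)
    rows = []
    for item in df.columns:
        itc = item_total_correlation(df, item, corrected=corrected)
        if raw_ratings is not None:
            endo = endorsement_rate(raw_ratings[item])
        else:
            endo = endorsement_rate(df[item].to_numpy())
        rows.append({
            "item_id": item,
            "item_total_correlation": itc,
            "alpha_if_deleted": alpha_if_deleted(df, item),
            "endorsement_rate": endo,
            "flag": flag_itc(itc).value,
        })
    out = pd.DataFrame(rows)
    out.attrs["cronbach_alpha"] = alpha
    return out


def group_item_stats(long_ratings: pd.DataFrame, group_map: dict[str, str],
                     *, corrected: bool = True) -> dict[str, pd.DataFrame]:
    """Per-group item statistics from a long ratings table.

    ``long_ratings`` has columns study_id, rater_id, item_id, rating;
    ``group_map`` maps rater_id -> group label (e.g. user / non-user).
    Within each group, ratings are averaged over the group's raters before
    the study-level ITC/alpha; endorsement uses the raw per-rater ratings.
    """
    required = {"study_id", "rater_id", "item_id", "rating"}
    if not required.issubset(long_ratings.columns):
        raise ValidationError(f"ratings table must have columns {sorted(required)}")
    out = {}
    groups = long_ratings["rater_id"].map(group_map)
    if groups.isna().any():
        missing = sorted(long_ratings.loc[groups.isna(), "rater_id"].unique())
        raise ValidationError(f"rater(s) {missing} absent from group map")
    for g, sub in long_ratings.groupby(groups, sort=True):
        matrix = sub.pivot_table(index="study_id", columns="item_id",
                                 values="rating", aggfunc="mean")
        raw = {item: s["rating"].to_numpy() for item, s in sub.groupby("item_id")}
        out[g] = item_stats_table(matrix, raw_ratings=raw, corrected=corrected)
    return out
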
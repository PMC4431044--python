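"""The Q-Genie instrument: items, scale, scoring variants and quality classes.

Q-Genie is an 11-item instrument for rating the quality of published genetic
association studies.  Each item is rated on a 7-point Likert scale anchored by
"poor" (1) and "excellent" (7).  The total score is the sum of the 11 item
ratings.  For studies without a comparison (control) group — e.g. studies of
quantitative traits — item 3, which asks about the description of comparison
groups, is dropped and the total runs over the remaining 10 items.

Total scores are mapped to a three-level quality class (low / moderate / high)
by a pair of cut-points.  The published schemes are 35/45 for the 11-item
variant and 32/40 for the 10-item variant; alternative schemes (for example
re-derived by :mod:`qgenie.standard_setting`) can be substituted.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

SCALE_MIN = 1
SCALE_MAX = 7
SCALE_ANCHORS = {1: "poor", 7: "excellent"}

#: item whose rating concerns the comparison/control group
CONTROL_GROUP_ITEM = 3


@dataclass(frozen=True)
class ItemDefinition:
    """One instrument item: its number, question stem and quality theme."""

    item_id: int
    stem: str
    theme: str
    requires_control_group: bool = False


#: The canonical 11 items.  Stems are the published question wordings; themes
#: summarise the quality dimension each item probes.
ITEMS: tuple[ItemDefinition, ...] = (
    ItemDefinition(1, "Please rate the study on the adequacy of the presented hypothesis and rationale.",
                   "scientific basis for development of the research question"),
    ItemDefinition(2, "Please rate the study on the classification of the outcome (e.g. disease status or quantitative trait).",
                   "classification of the outcome"),
    ItemDefinition(3, "Please rate the study on the description of comparison groups (e.g. cases and controls).",
                   "ascertainment of comparison groups", requires_control_group=True),
    ItemDefinition(4, "Please rate the study on the technical classification of the exposure (i.e. the genetic variant).",
                   "technical classification of genetic variant"),
    ItemDefinition(5, "Please rate the study on the non-technical classification of the exposure (i.e. the genetic variant).",
                   "non-technical classification of genetic variant"),
    ItemDefinition(6, "Please rate the study on the disclosure and discussion of sources of bias.",
                   "discussion of sources of bias"),
    ItemDefinition(7, "Please rate whether the study was adequately powered.",
                   "appropriateness of sample size"),
    ItemDefinition(8, "Please rate the study on description of planned analyses.",
                   "description of planned statistical analyses"),
    ItemDefinition(9, "Please rate the study on the statistical methods.",
                   "statistical methods used"),
    ItemDefinition(10, "Please rate the study on the description and test of all assumptions and inferences.",
                   "test of assumptions in genetic studies"),
    ItemDefinition(11, "Please rate the study on whether conclusions drawn by the authors were supported by the results and appropriate methods.",
                   "appropriate interpretation of results"),
)

ALL_ITEM_IDS = frozenset(d.item_id for d in ITEMS)
N_ITEMS = len(ITEMS)


class QualityClass(str, enum.Enum):
    """Ordered three-level study quality class."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Variant(str, enum.Enum):
    """Scoring variant: with the control-group item or without it."""

    WITH_CONTROL = "with_control"
    WITHOUT_CONTROL = "without_control"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: achievable score range per variant
SCORE_RANGE = {
    Variant.WITH_CONTROL: (N_ITEMS * SCALE_MIN, N_ITEMS * SCALE_MAX),          # 11..77
    Variant.WITHOUT_CONTROL: ((N_ITEMS - 1) * SCALE_MIN, (N_ITEMS - 1) * SCALE_MAX),  # 10..70
}


@dataclass(frozen=True)
class CutPointScheme:
    """Two boundary scores splitting a variant's score range into low/moderate/high.

    ``score <= low_max`` is low, ``low_max < score <= moderate_max`` is
    moderate, ``score > moderate_max`` is high.
    """

    variant: Variant
    low_max: int
    moderate_max: int

    def __post_init__(self) -> None:
        variant = Variant(self.variant)
        object.__setattr__(self, "variant", variant)
        lo, hi = SCORE_RANGE[variant]
        if not self.low_max < self.moderate_max:
            raise ValidationError(
                f"low_max ({self.low_max}) must be < moderate_max ({self.moderate_max})")
        if not (lo <= self.low_max <= hi and lo <= self.moderate_max <= hi):
            raise ValidationError(
                f"cut-points must lie within the achievable range [{lo}, {hi}] "
                f"for variant {variant.value}")


#: Published default schemes.
DEFAULT_SCHEMES: dict[Variant, CutPointScheme] = {
    Variant.WITH_CONTROL: CutPointScheme(Variant.WITH_CONTROL, 35, 45),
    Variant.WITHOUT_CONTROL: CutPointScheme(Variant.WITHOUT_CONTROL, 32, 40),
}


def _validate_rating_value(item_id: int, value) -> int:
    try:
        v = int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"item {item_id}: rating {value!r} is not an integer") from None
    if v != value or not (SCALE_MIN <= v <= SCALE_MAX):
        raise ValidationError(
            f"item {item_id}: rating {value!r} outside the {SCALE_MIN}-{SCALE_MAX} scale")
    return v


@dataclass
class StudyRating:
    """One study's item responses (one rater), plus its control-group flag.

    ``responses`` maps item_id -> rating on the 1-7 scale.  All 11 items must
    be present, except that item 3 may be absent when ``has_control_group``
    is False.
    """

    study_id: str
    responses: Mapping[int, int]
    has_control_group: bool = True
    rater_id: str | None = None

    def __post_init__(self) -> None:
        resp: dict[int, int] = {}
        for item_id, value in dict(self.responses).items():
            item_id = int(item_id)
            if item_id not in ALL_ITEM_IDS:
                raise ValidationError(f"unknown item_id {item_id} for study {self.study_id!r}")
            resp[item_id] = _validate_rating_value(item_id, value)
        required = set(ALL_ITEM_IDS)
        if not self.has_control_group:
            required.discard(CONTROL_GROUP_ITEM)
        missing = sorted(required - resp.keys())
        if missing:
            raise ValidationError(
                f"study {self.study_id!r}: missing rating(s) for item(s) {missing}")
        self.responses = resp


def total_score(rating: StudyRating) -> int:
    """Total Q-Genie score for one study rating.

    Sums all 11 item responses when the study has a control group; otherwise
    sums the 10 items excluding item 3 (a supplied item-3 response is ignored
    with a warning).
    """
    items = dict(rating.responses)
    if not rating.has_control_group and CONTROL_GROUP_ITEM in items:
        logger.warning(
            "study %r has no control group; ignoring item %d in the total score",
            rating.study_id, CONTROL_GROUP_ITEM)
        del items[CONTROL_GROUP_ITEM]
    return sum(items.values())


def classify(score: int, scheme: CutPointScheme) -> QualityClass:
    """Map a total score to low/moderate/high under a cut-point scheme."""
    lo, hi = SCORE_RANGE[scheme.variant]
    if not lo <= score <= hi:
        raise ValidationError(
            f"score {score} outside the achievable range [{lo}, {hi}] "
            f"for variant {scheme.variant.value}")
    if score <= scheme.low_max:
        return QualityClass.LOW
    if score <= scheme.moderate_max:
        return QualityClass.MODERATE
    return QualityClass.HIGH


@dataclass
class BatchScoreResult:
    """Per-study scores/classes plus the class distribution summary."""

    table: pd.DataFrame
    summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def batch_score(
    ratings: Iterable[StudyRating],
    schemes: Mapping[Variant, CutPointScheme] | None = None,
) -> BatchScoreResult:
    """Score and classify a collection of study ratings.

    Each study is scored under its own variant (decided by its
    ``has_control_group`` flag) with the matching scheme.  Returns one row per
    study and a summary of the class distribution (count and percent per
    class).  Duplicate (study_id, rater_id) pairs are an error.
    """
    schemes = dict(DEFAULT_SCHEMES) | dict(schemes or {})
    rows = []
    seen: set[tuple[str, str | None]] = set()
    for r in ratings:
        key = (r.study_id, r.rater_id)
        if key in seen:
            raise ValidationError(f"duplicate rating for study {r.study_id!r}"
                                  + (f", rater {r.rater_id!r}" if r.rater_id else ""))
        seen.add(key)
        variant = Variant.WITH_CONTROL if r.has_control_group else Variant.WITHOUT_CONTROL
        score = total_score(r)
        rows.append({
            "study_id": r.study_id,
            "rater_id": r.rater_id,
            "variant": variant.value,
            "score": score,
            "quality": classify(score, schemes[variant]).value,
        })
    table = pd.DataFrame(rows, columns=["study_id", "rater_id", "variant", "score", "quality"])
    if table.empty:
        return BatchScoreResult(table=table, summary=None)
    counts = table["quality"].value_counts().reindex(
        [c.value for c in QualityClass], fill_value=0)
    summary = pd.DataFrame({
        "quality": counts.index,
        "count": counts.to_numpy(),
        "percent": 100.0 * counts.to_numpy() / len(table),
    }).reset_index(drop=True)
    return BatchScoreResult(table=table, summary=summary)


def mean_rating_per_study(ratings: Iterable[StudyRating]) -> list[StudyRating]:
    """Average multiple raters' responses per study into one rounded StudyRating.

    Offered as the alternative aggregation before classification; per-rater
    classification (no aggregation) is the default path in :func:`batch_score`.
    Averages are rounded half-up to stay on the integer 1-7 scale.
    """
    import math

    by_study: dict[str, list[StudyRating]] = {}
    for r in ratings:
        by_study.setdefault(r.study_id, []).append(r)
    out = []
    for study_id, rs in by_study.items():
        flags = {r.has_control_group for r in rs}
        if len(flags) > 1:
            raise ValidationError(f"study {study_id!r}: inconsistent has_control_group flags")
        has_control = flags.pop()
        item_ids = set(rs[0].responses)
        mean_resp = {
            i: min(SCALE_MAX, max(SCALE_MIN, int(math.floor(
                sum(r.responses[i] for r in rs) / len(rs) + 0.5))))
            for i in item_ids
        }
        out.append(StudyRating(study_id=study_id, responses=mean_resp,
                               has_control_group=has_control, rater_id=None))
    return out
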
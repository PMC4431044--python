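"""Borderline-groups regression standard setting.

Raters answer a single global-impression question ("rate overall quality of
the study") on the same 1-7 scale; ratings 1-2 are graded 'low', 3-4
'moderate', 5-7 'high'.  Total instrument scores are regressed on the numeric
grade (1/2/3) by ordinary least squares and the cut-points are the predicted
scores at the half-grade boundaries 1.5 and 2.5, rounded half-up to integers.
The global question is used only to set cut-points; it is not part of the
instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedStatisticError, ValidationError
from .instrument import CutPointScheme, Variant

#: global-impression rating -> numeric grade
GRADE_LOW, GRADE_MODERATE, GRADE_HIGH = 1, 2, 3
GRADE_LABELS = {GRADE_LOW: "low", GRADE_MODERATE: "moderate", GRADE_HIGH: "high"}


def map_global_to_grade(rating: int) -> int:
    """Map a 1-7 global-impression rating to grade 1 (low), 2 (moderate) or 3 (high)."""
    r = int(rating)
    if r != rating or not 1 <= r <= 7:
        raise ValidationError(f"global-impression rating {rating!r} outside 1-7")
    if r <= 2:
        return GRADE_LOW
    if r <= 4:
        return GRADE_MODERATE
    return GRADE_HIGH


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class BorderlineFit:
    """OLS fit of total score on grade with derived cut-points."""

    slope: float
    intercept: float
    r_squared: float
    cut_low: float       # predicted score at grade 1.5
    cut_moderate: float  # predicted score at grade 2.5
    scheme: CutPointScheme
    n: int

    def predict(self, grade) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(grade, dtype=float)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"quantity": "slope", "value": self.slope},
            {"quantity": "intercept", "value": self.intercept},
            {"quantity": "r_squared", "value": self.r_squared},
            {"quantity": "cut_low (grade 1.5)", "value": self.cut_low},
            {"quantity": "cut_moderate (grade 2.5)", "value": self.cut_moderate},
            {"quantity": "low_max (rounded)", "value": self.scheme.low_max},
            {"quantity": "moderate_max (rounded)", "value": self.scheme.moderate_max},
            {"quantity": "n", "value": self.n},
        ])

    def plot_table(self, scores, grades) -> pd.DataFrame:
        """Plot-ready table: observed pairs, fitted values and cut lines."""
        df = pd.DataFrame({"grade": np.asarray(grades, float),
                           "score": np.asarray(scores, float)})
        df["fitted"] = self.predict(df["grade"])
        df.attrs["cut_lines"] = (self.cut_low, self.cut_moderate)
        return df


class BorderlineRegression:
    """Borderline-groups regression model for a set of (score, grade) pairs."""

    def __init__(self, scores: Sequence[float], grades: Sequence[int],
                 variant: Variant | str = Variant.WITH_CONTROL):
        scores = np.asarray(scores, dtype=float)
        grades = np.asarray(grades, dtype=float)
        if scores.shape != grades.shape or scores.ndim != 1:
            raise ValidationError("scores and grades must be equal-length 1-D sequences")
        if len(scores) < 3:
            raise ValidationError("at least 3 (score, grade) pairs required")
        if not np.isin(grades, [GRADE_LOW, GRADE_MODERATE, GRADE_HIGH]).all():
            raise ValidationError("grades must be coded 1 (low), 2 (moderate) or 3 (high)")
        if len(np.unique(grades)) < 2:
            raise UndefinedStatisticError(
                "cannot derive cut-points: all observations share one grade")
        self.scores = scores
        self.grades = grades
        self.variant = Variant(variant)

    def fit(self) -> BorderlineFit:
        res = stats.linregress(self.grades, self.scores)
        if res.slope <= 0:
            raise UndefinedStatisticError(
                f"invalid scheme: fitted slope {res.slope:.3g} is not positive "
                "(total score must increase with global grade)")
        cut_low = res.intercept + res.slope * 1.5
        cut_mod = res.intercept + res.slope * 2.5
        scheme = CutPointScheme(self.variant, _round_half_up(cut_low),
                                _round_half_up(cut_mod))
        return BorderlineFit(slope=float(res.slope), intercept=float(res.intercept),
                             r_squared=float(res.rvalue ** 2),
                             cut_low=float(cut_low), cut_moderate=float(cut_mod),
                             scheme=scheme, n=len(self.scores))


def derive_cutpoints(scores: Sequence[float], grades: Sequence[int],
                     variant: Variant | str = Variant.WITH_CONTROL) -> BorderlineFit:
    """Fit the borderline-groups regression and return the fitted cut-points."""
    return BorderlineRegression(scores, grades, variant).fit()
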
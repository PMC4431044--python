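"""Random-effects meta-analysis with quality-stratified sensitivity analysis.

Per-study effects are log odds ratios with standard errors (computed from 2x2
case-control genotype counts by the Woolf method where counts are given).
Pooling is inverse-variance, either fixed-effect or DerSimonian-Laird
random-effects (the default):

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)),   w = 1/se^2

Heterogeneity is summarised by Cochran's Q, its chi-square p-value, and
I^2 = max(0, (Q - df)/Q) x 100 with the Higgins-Thompson test-based
confidence interval on ln H (H = sqrt(Q/df)).

The sensitivity procedure re-pools after excluding studies classified as low
quality and reports the change in heterogeneity and precision, plus a
forest-plot-ready per-study table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedStatisticError, ValidationError
from .instrument import QualityClass

Z_95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class StudyEffect:
    """One study's effect estimate on the log odds-ratio scale."""

    study_id: str
    log_or: float
    se: float
    quality: QualityClass | str | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"{self.study_id}: standard error must be positive")
        if self.quality is not None:
            object.__setattr__(self, "quality", QualityClass(self.quality))

    @classmethod
    def from_2x2(cls, study_id: str, a: int, b: int, c: int, d: int,
                 quality=None) -> "StudyEffect":
        log_or, se = effect_from_2x2(a, b, c, d)
        return cls(study_id, log_or, se, quality)


def effect_from_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Woolf log odds ratio and standard error from a 2x2 table.

    Adds 0.5 to every cell if (and only if) any cell is zero; more than one
    zero cell is rejected.
    """
    cells = [a, b, c, d]
    if any(x < 0 or x != int(x) for x in cells):
        raise ValidationError("2x2 cells must be nonnegative integers")
    zeros = sum(x == 0 for x in cells)
    if zeros >= 2:
        raise ValidationError("2x2 table with two or more zero cells has no usable effect")
    if zeros:
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    return math.log(a * d / (b * c)), math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    p_value: float
    i2_percent: float
    i2_ci_low: float | None = None
    i2_ci_high: float | None = None


@dataclass
class MetaResults:
    """Pooled estimate with heterogeneity; returned by :meth:`MetaAnalysis.fit`."""

    model: str                   # "fixed" or "dersimonian_laird"
    k: int
    pooled_log_or: float
    pooled_se: float
    tau2: float
    heterogeneity: HeterogeneityResult | None
    study_table: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.pooled_log_or - Z_95 * self.pooled_se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.pooled_log_or + Z_95 * self.pooled_se)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"quantity": "model", "value": self.model},
            {"quantity": "k", "value": self.k},
            {"quantity": "pooled OR", "value": round(self.pooled_or, 2)},
            {"quantity": "95% CI low", "value": round(self.ci_low, 2)},
            {"quantity": "95% CI high", "value": round(self.ci_high, 2)},
            {"quantity": "tau^2", "value": self.tau2},
        ]
        if self.heterogeneity is not None:
            h = self.heterogeneity
            rows += [
                {"quantity": "Q", "value": h.Q},
                {"quantity": "Q df", "value": h.df},
                {"quantity": "Q p-value", "value": h.p_value},
                {"quantity": "I^2 (%)", "value": round(h.i2_percent)},
            ]
            if h.i2_ci_low is not None:
                rows.append({"quantity": "I^2 95% CI (%)",
                             "value": f"{round(h.i2_ci_low)}-{round(h.i2_ci_high)}"})
        return pd.DataFrame(rows)


def i_squared(Q: float, df: int) -> float:
    """I^2 heterogeneity percentage: max(0, (Q - df)/Q) x 100."""
    if Q < 0 or df < 1:
        raise ValidationError("Q must be >= 0 and df >= 1")
    if Q == 0:
        return 0.0
    return max(0.0, (Q - df) / Q) * 100.0


def i_squared_ci(Q: float, df: int, level: float = 0.95) -> tuple[float, float]:
    """Higgins-Thompson test-based confidence interval for I^2, in percent.

    Works on ln H with H = max(1, sqrt(Q/df)).  When Q > df the standard
    error of ln H is (ln Q - ln df) / (2 (sqrt(2Q) - sqrt(2 df - 1)));
    otherwise sqrt( 1/(2(df-1)) * (1 - 1/(3 (df-1)^2)) ).  The interval on H
    is floored at 1 and transformed to I^2 = (H^2 - 1)/H^2, truncated to
    [0, 100].
    """
    if df < 2:
        raise ValidationError("test-based I^2 interval requires df >= 2")
    if Q < 0:
        raise ValidationError("Q must be >= 0")
    H = max(1.0, math.sqrt(Q / df))
    ln_h = math.log(H)
    if Q > df:
        se_ln_h = (math.log(Q) - math.log(df)) / (2 * (math.sqrt(2 * Q) - math.sqrt(2 * df - 1)))
    else:
        se_ln_h = math.sqrt((1 / (2 * (df - 1))) * (1 - 1 / (3 * (df - 1) ** 2)))
    z = stats.norm.ppf(0.5 + level / 2)
    h_lo = max(1.0, math.exp(ln_h - z * se_ln_h))
    h_hi = max(1.0, math.exp(ln_h + z * se_ln_h))
    to_i2 = lambda h: min(100.0, max(0.0, (h * h - 1) / (h * h) * 100.0))
    return to_i2(h_lo), to_i2(h_hi)


def _heterogeneity(y: np.ndarray, w: np.ndarray) -> HeterogeneityResult:
    df = len(y) - 1
    mu = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - mu) ** 2))
    p = float(stats.chi2.sf(Q, df))
    i2 = i_squared(Q, df)
    lo = hi = None
    if df >= 2:
        lo, hi = i_squared_ci(Q, df)
    return HeterogeneityResult(Q=Q, df=df, p_value=p, i2_percent=i2,
                               i2_ci_low=lo, i2_ci_high=hi)


class MetaAnalysis:
    """Inverse-variance meta-analysis of log odds ratios."""

    def __init__(self, effects: Sequence[StudyEffect]):
        effects = list(effects)
        if not effects:
            raise ValidationError("meta-analysis needs at least one study")
        ids = [e.study_id for e in effects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate study_ids in effects")
        self.effects = effects

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MetaAnalysis":
        """Build from a table with columns study_id + (log_or, se) or (a, b, c, d)."""
        effects = []
        has_counts = {"a", "b", "c", "d"}.issubset(df.columns)
        for _, row in df.iterrows():
            quality = row.get("quality")
            if isinstance(quality, float) and math.isnan(quality):
                quality = None
            if "log_or" in df.columns and not pd.isna(row.get("log_or")):
                effects.append(StudyEffect(str(row["study_id"]), float(row["log_or"]),
                                           float(row["se"]), quality))
            elif has_counts:
                effects.append(StudyEffect.from_2x2(
                    str(row["study_id"]), int(row["a"]), int(row["b"]),
                    int(row["c"]), int(row["d"]), quality))
            else:
                raise ValidationError(
                    "effects table needs columns (log_or, se) or (a, b, c, d)")
        return cls(effects)

    def fit(self, model: str = "dersimonian_laird") -> MetaResults:
        if model not in ("fixed", "dersimonian_laird"):
            raise ValidationError(f"unknown model {model!r}")
        y = np.array([e.log_or for e in self.effects])
        v = np.array([e.se ** 2 for e in self.effects])
        w = 1.0 / v
        k = len(y)

        het = _heterogeneity(y, w) if k >= 2 else None
        tau2 = 0.0
        if model == "dersimonian_laird" and k >= 2:
            c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
            tau2 = max(0.0, (het.Q - het.df) / c) if c > 0 else 0.0
        w_star = 1.0 / (v + tau2)
        mu = float(np.sum(w_star * y) / np.sum(w_star))
        se = float(math.sqrt(1.0 / np.sum(w_star)))

        table = pd.DataFrame({
            "study_id": [e.study_id for e in self.effects],
            "or": np.exp(y),
            "ci_low": np.exp(y - Z_95 * np.sqrt(v)),
            "ci_high": np.exp(y + Z_95 * np.sqrt(v)),
            "weight_percent": 100.0 * w_star / np.sum(w_star),
            "quality": [e.quality.value if e.quality is not None else None
                        for e in self.effects],
        })
        return MetaResults(model=model, k=k, pooled_log_or=mu, pooled_se=se,
                           tau2=float(tau2), heterogeneity=het, study_table=table)


def pool(effects: Sequence[StudyEffect], model: str = "dersimonian_laird") -> MetaResults:
    """Pool study effects; see :class:`MetaAnalysis`."""
    return MetaAnalysis(effects).fit(model)


@dataclass
class SensitivityReport:
    """All-studies vs low-quality-excluded meta-analyses plus the deltas."""

    all_studies: MetaResults
    excluding_low: MetaResults
    n_excluded: int
    forest_table: pd.DataFrame

    @property
    def delta(self) -> dict[str, float]:
        a, e = self.all_studies, self.excluding_low
        out = {
            "ci_width_change": (e.ci_high - e.ci_low) - (a.ci_high - a.ci_low),
            "pooled_or_change": e.pooled_or - a.pooled_or,
            "tau2_change": e.tau2 - a.tau2,
        }
        if a.heterogeneity is not None and e.heterogeneity is not None:
            out["i2_change"] = e.heterogeneity.i2_percent - a.heterogeneity.i2_percent
            out["q_change"] = e.heterogeneity.Q - a.heterogeneity.Q
        return out

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, res in (("all studies", self.all_studies),
                          ("excluding low quality", self.excluding_low)):
            h = res.heterogeneity
            rows.append({
                "analysis": name, "k": res.k,
                "pooled_or": round(res.pooled_or, 2),
                "ci_low": round(res.ci_low, 2), "ci_high": round(res.ci_high, 2),
                "Q": None if h is None else round(h.Q, 2),
                "i2_percent": None if h is None else round(h.i2_percent),
            })
        return pd.DataFrame(rows)


def sensitivity_by_quality(effects: Sequence[StudyEffect],
                           model: str = "dersimonian_laird") -> SensitivityReport:
    """Meta-analysis with and without low-quality studies.

    Every effect must carry a quality class and at least one study must be
    non-low.  The forest table lists every study with its inclusion flag.
    """
    effects = list(effects)
    if any(e.quality is None for e in effects):
        missing = [e.study_id for e in effects if e.quality is None]
        raise ValidationError(f"effects without a quality class: {missing}")
    kept = [e for e in effects if e.quality is not QualityClass.LOW]
    if not kept:
        raise UndefinedStatisticError("all studies are low quality; nothing to pool")
    res_all = MetaAnalysis(effects).fit(model)
    res_excl = MetaAnalysis(kept).fit(model)
    forest = res_all.study_table.copy()
    forest["included_after_exclusion"] = [e.quality is not QualityClass.LOW
                                          for e in effects]
    return SensitivityReport(all_studies=res_all, excluding_low=res_excl,
                             n_excluded=len(effects) - len(kept), forest_table=forest)
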
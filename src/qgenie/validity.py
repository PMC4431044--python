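"""Construct validity: do instrument scores track external impact metrics?

The construct is that higher-quality studies appear in higher-impact journals
and are cited more.  Validity is quantified by Spearman rank correlations of
total scores with journal impact factor, average citations per year and total
citations, optionally excluding self-citations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedStatisticError, ValidationError

EXACT_PERMUTATION_MAX_N = 10


@dataclass(frozen=True)
class ImpactRecord:
    """Citation/impact metadata for one study."""

    study_id: str
    impact_factor: float
    total_citations: int
    self_citations: int
    publication_year: int

    def __post_init__(self) -> None:
        if self.impact_factor < 0:
            raise ValidationError(f"{self.study_id}: negative impact factor")
        if not 0 <= self.self_citations <= self.total_citations:
            raise ValidationError(
                f"{self.study_id}: self_citations must lie in [0, total_citations]")


@dataclass(frozen=True)
class ValidityResult:
    construct: str
    spearman_rho: float
    p_value: float
    n: int


def citations_per_year(rec: ImpactRecord, analysis_year: int,
                       exclude_self: bool = False) -> float:
    """Average citations per year, inclusive year count with a floor of one year."""
    if analysis_year < rec.publication_year:
        raise ValidationError(
            f"{rec.study_id}: analysis year {analysis_year} precedes publication "
            f"year {rec.publication_year}")
    count = rec.total_citations - (rec.self_citations if exclude_self else 0)
    years = max(1, analysis_year - rec.publication_year + 1)
    return count / years


def spearman(x, y, *, exact: bool = False) -> tuple[float, float]:
    """Spearman's rho with midranks for ties.

    The p-value uses the t approximation on n-2 degrees of freedom; with
    ``exact=True`` (n <= 10 only) it is the two-sided permutation p-value over
    all n! orderings.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 4:
        raise ValidationError("Spearman correlation needs n >= 4")
    if np.var(stats.rankdata(x)) == 0 or np.var(stats.rankdata(y)) == 0:
        raise UndefinedStatisticError("zero rank variance; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    if exact:
        if n > EXACT_PERMUTATION_MAX_N:
            raise ValidationError(
                f"exact permutation p-value limited to n <= {EXACT_PERMUTATION_MAX_N}")
        p = _exact_permutation_p(x, y, float(rho))
    return float(rho), float(p)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for |rho| >= |observed|, enumerated in chunks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    sy = ry.std()
    n = len(x)
    count = total = 0
    chunk: list = []

    def flush(chunk):
        nonlocal count, total
        perm = (np.asarray(chunk) - ry.mean()) / sy
        rhos = perm @ rx / n
        count += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        total += len(chunk)

    for p in itertools.permutations(ry):
        chunk.append(p)
        if len(chunk) == 100_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return count / total


def validity_table(scores: pd.Series | dict, impact: list[ImpactRecord],
                   analysis_year: int, *, exact: bool = False) -> pd.DataFrame:
    """Spearman correlations of total scores with each impact construct.

    ``scores`` maps study_id -> total score (e.g. summed over a rater group).
    Constructs: impact factor, average citations per year (with and without
    self-citations), and total citations to date.
    """
    scores = pd.Series(scores)
    recs = {r.study_id: r for r in impact}
    common = [sid for sid in scores.index if sid in recs]
    if len(common) < 4:
        raise ValidationError("need >= 4 studies with both scores and impact records")
    s = scores.loc[common].to_numpy(dtype=float)
    constructs = {
        "impact_factor": [recs[sid].impact_factor for sid in common],
        "citations_per_year": [citations_per_year(recs[sid], analysis_year)
                               for sid in common],
        "citations_per_year_no_self": [citations_per_year(recs[sid], analysis_year,
                                                          exclude_self=True)
                                       for sid in common],
        "total_citations": [recs[sid].total_citations for sid in common],
    }
    rows = []
    for name, vals in constructs.items():
        rho, p = spearman(s, vals, exact=exact)
        rows.append({"construct": name, "spearman_rho": rho, "p_value": p,
                     "n": len(common)})
    return pd.DataFrame(rows)
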
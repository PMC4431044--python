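"""Generalizability-theory reliability for rating designs.

The object of measurement is the study (p); raters (r) and items (i) are
facets.  For the fully crossed p x r x i design the seven random-effects
variance components are estimated from three-way ANOVA mean squares via the
expected-mean-square (EMS) equations; negative estimates are truncated to
zero and flagged.  Absolute-error G-coefficients (phi) treat the raters in
hand as a random sample of all possible raters, so facet main effects count
toward error.

Dependability coefficient, for random facets R and fixed facets F
(R and F partition {raters, items}):

    phi = sigma2_tau / (sigma2_tau + sigma2_Delta)
    sigma2_tau   = sigma2_p + sum_{f in F} sigma2_pf / n_f
    sigma2_Delta = sum over components touching a random facet of
                   sigma2_c / (prod of the sample sizes of the facets in c)

where random facets contribute their D-study size n' and fixed facets their
design size n (components involving a fixed facet are averaged over its
conditions, the mixed-design convention).  The relative (generalizability)
coefficient, which drops facet main effects from the error, is exposed for
diagnostics.

Inter-user reliability (can a rating by one rater group be generalized to
another, e.g. users vs non-users of genetic association studies?) uses the
nested p x (r:g) design on item-summed total scores.

The model/results pair :class:`GStudy` / :class:`GStudyResults` wraps these
computations; module-level functions expose each step directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, UndefinedStatisticError, ValidationError

FACETS = ("r", "i")  # rater and item facets; "p" is the object of measurement

#: components of the crossed p x r x i design, keyed by the facets involved
CROSSED_COMPONENTS = ("p", "r", "i", "pr", "pi", "ri", "pri_e")


@dataclass
class RatingArray:
    """Fully crossed studies x raters x items rating array.

    ``values[p, r, i]`` is rater r's rating of study p on item i.  No missing
    cells are allowed; values must lie on the 1-7 scale unless
    ``validate_scale=False`` (continuous simulator output is analysed on the
    raw scale in recovery studies).
    """

    values: np.ndarray
    study_ids: Sequence | None = None
    rater_ids: Sequence | None = None
    item_ids: Sequence | None = None
    validate_scale: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise DesignError("rating array must be 3-dimensional (study, rater, item)")
        if np.isnan(arr).any():
            raise DesignError("rating array has missing cells; only fully crossed "
                              "designs are supported")
        if self.validate_scale and (arr.min() < 1 or arr.max() > 7):
            raise ValidationError("ratings outside the 1-7 scale")
        self.values = arr
        for name, ids, n in (("study_ids", self.study_ids, arr.shape[0]),
                             ("rater_ids", self.rater_ids, arr.shape[1]),
                             ("item_ids", self.item_ids, arr.shape[2])):
            if ids is not None and len(ids) != n:
                raise ValidationError(f"{name} has length {len(ids)}, expected {n}")

    @property
    def n_p(self) -> int:
        return self.values.shape[0]

    @property
    def n_r(self) -> int:
        return self.values.shape[1]

    @property
    def n_i(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class VarianceComponents:
    """EMS variance-component estimates for the crossed p x r x i design.

    Components whose raw EMS solution was negative are stored as 0 and listed
    in ``truncated``; ``raw`` keeps the untruncated estimates (their sum
    reproduces the EMS algebra exactly, which the truncated set need not).
    """

    sigma2_p: float
    sigma2_r: float
    sigma2_i: float
    sigma2_pr: float
    sigma2_pi: float
    sigma2_ri: float
    sigma2_pri_e: float
    truncated: tuple[str, ...] = ()
    raw: Mapping[str, float] | None = None
    design_sizes: Mapping[str, int] | None = None

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, f"sigma2_{c}") for c in CROSSED_COMPONENTS}


def _anova_3way(y: np.ndarray) -> dict[str, tuple[float, int]]:
    """Sums of squares and degrees of freedom for the crossed 3-way layout.

    Returns {effect: (mean square, df)}.
    """
    n_p, n_r, n_i = y.shape
    m = y.mean()
    m_p = y.mean(axis=(1, 2))
    m_r = y.mean(axis=(0, 2))
    m_i = y.mean(axis=(0, 1))
    m_pr = y.mean(axis=2)
    m_pi = y.mean(axis=1)
    m_ri = y.mean(axis=0)

    ss_p = n_r * n_i * np.sum((m_p - m) ** 2)
    ss_r = n_p * n_i * np.sum((m_r - m) ** 2)
    ss_i = n_p * n_r * np.sum((m_i - m) ** 2)
    ss_pr = n_i * np.sum((m_pr - m_p[:, None] - m_r[None, :] + m) ** 2)
    ss_pi = n_r * np.sum((m_pi - m_p[:, None] - m_i[None, :] + m) ** 2)
    ss_ri = n_p * np.sum((m_ri - m_r[:, None] - m_i[None, :] + m) ** 2)
    resid = (y - m_pr[:, :, None] - m_pi[:, None, :] - m_ri[None, :, :]
             + m_p[:, None, None] + m_r[None, :, None] + m_i[None, None, :] - m)
    ss_pri = np.sum(resid ** 2)

    dfs = {
        "p": n_p - 1, "r": n_r - 1, "i": n_i - 1,
        "pr": (n_p - 1) * (n_r - 1), "pi": (n_p - 1) * (n_i - 1),
        "ri": (n_r - 1) * (n_i - 1), "pri_e": (n_p - 1) * (n_r - 1) * (n_i - 1),
    }
    sss = {"p": ss_p, "r": ss_r, "i": ss_i, "pr": ss_pr, "pi": ss_pi,
           "ri": ss_ri, "pri_e": ss_pri}
    return {k: (sss[k] / dfs[k], dfs[k]) for k in dfs}


def estimate_variance_components(arr: RatingArray | np.ndarray) -> VarianceComponents:
    """EMS variance components for a fully crossed p x r x i array.

    Requires every dimension >= 2.  A constant array yields all-zero
    components.  Negative EMS solutions are truncated to 0 and flagged.
    """
    if not isinstance(arr, RatingArray):
        arr = RatingArray(np.asarray(arr, dtype=float), validate_scale=False)
    y = arr.values
    n_p, n_r, n_i = y.shape
    if min(n_p, n_r, n_i) < 2:
        raise DesignError(f"every dimension must be >= 2, got {y.shape}")

    ms = {k: v[0] for k, v in _anova_3way(y).items()}
    raw = {
        "pri_e": ms["pri_e"],
        "pr": (ms["pr"] - ms["pri_e"]) / n_i,
        "pi": (ms["pi"] - ms["pri_e"]) / n_r,
        "ri": (ms["ri"] - ms["pri_e"]) / n_p,
        "p": (ms["p"] - ms["pr"] - ms["pi"] + ms["pri_e"]) / (n_r * n_i),
        "r": (ms["r"] - ms["pr"] - ms["ri"] + ms["pri_e"]) / (n_p * n_i),
        "i": (ms["i"] - ms["pi"] - ms["ri"] + ms["pri_e"]) / (n_p * n_r),
    }
    truncated = tuple(sorted(k for k, v in raw.items() if v < 0))
    est = {k: max(0.0, v) for k, v in raw.items()}
    return VarianceComponents(
        sigma2_p=est["p"], sigma2_r=est["r"], sigma2_i=est["i"],
        sigma2_pr=est["pr"], sigma2_pi=est["pi"], sigma2_ri=est["ri"],
        sigma2_pri_e=est["pri_e"], truncated=truncated, raw=raw,
        design_sizes={"p": n_p, "r": n_r, "i": n_i},
    )


def _component_facets(name: str) -> set[str]:
    return set(name.replace("_e", "")) - {"p"}


def phi_coefficient(
    vc: VarianceComponents,
    generalize_over: set[str] | Sequence[str],
    fixed: set[str] | Sequence[str] = (),
    n_prime: Mapping[str, float] | None = None,
    *,
    relative: bool = False,
) -> float:
    """Dependability coefficient phi (absolute error) from variance components.

    ``generalize_over`` and ``fixed`` partition {"r", "i"}; ``n_prime`` gives
    the D-study size for each random facet and the averaging size for each
    fixed facet (defaults to the design sizes recorded on ``vc``).
    ``relative=True`` returns the relative (generalizability) coefficient,
    which excludes facet main effects (and pure facet interactions) from the
    error term.
    """
    random_facets = set(generalize_over)
    fixed_facets = set(fixed)
    if random_facets & fixed_facets:
        raise ValidationError("a facet cannot be both random and fixed")
    if random_facets | fixed_facets != set(FACETS):
        raise ValidationError(f"facets must partition {set(FACETS)}")
    if not random_facets:
        raise ValidationError("at least one facet must be generalized over")
    sizes = dict(vc.design_sizes or {})
    sizes.update(n_prime or {})
    for f in random_facets | fixed_facets:
        if sizes.get(f, 0) <= 0:
            raise ValidationError(f"positive sample size required for facet {f!r}")

    comps = vc.as_dict()
    tau = comps["p"]
    for f in fixed_facets:
        tau += comps["p" + f if "p" + f in comps else f + "p"] / sizes[f]
    delta = 0.0
    for name, value in comps.items():
        facets = _component_facets(name)
        if not facets & random_facets:
            continue  # p itself, or fixed-facet-only effects (constant shifts)
        if relative and "p" not in name:
            continue  # relative error keeps only object-by-facet interactions
        divisor = 1.0
        for f in facets:
            divisor *= sizes[f]
        delta += value / divisor
    if tau + delta == 0:
        raise UndefinedStatisticError("phi undefined: zero universe-score and error variance")
    return tau / (tau + delta)


# ---------------------------------------------------------------------------
# nested p x (r:g) design for inter-user reliability
# ---------------------------------------------------------------------------

NESTED_COMPONENTS = ("p", "g", "pg", "r_g", "pr_g_e")


@dataclass(frozen=True)
class NestedVarianceComponents:
    """EMS components for the p x (raters nested in groups) design."""

    sigma2_p: float
    sigma2_g: float
    sigma2_pg: float
    sigma2_r_g: float
    sigma2_pr_g_e: float
    truncated: tuple[str, ...] = ()
    raw: Mapping[str, float] | None = None
    design_sizes: Mapping[str, int] | None = None

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, f"sigma2_{c}") for c in NESTED_COMPONENTS}


def estimate_nested_components(scores: np.ndarray) -> NestedVarianceComponents:
    """EMS components from a study x group x rater-within-group score array."""
    y = np.asarray(scores, dtype=float)
    if y.ndim != 3:
        raise DesignError("nested scores must be 3-dimensional (study, group, rater)")
    n_p, n_g, n_r = y.shape
    if n_g < 2:
        raise DesignError("at least 2 rater groups required")
    if n_p < 2 or n_r < 2:
        raise DesignError("at least 2 studies and 2 raters per group required")

    m = y.mean()
    m_p = y.mean(axis=(1, 2))
    m_g = y.mean(axis=(0, 2))
    m_pg = y.mean(axis=2)
    m_gr = y.mean(axis=0)

    ms = {
        "p": n_g * n_r * np.sum((m_p - m) ** 2) / (n_p - 1),
        "g": n_p * n_r * np.sum((m_g - m) ** 2) / (n_g - 1),
        "pg": n_r * np.sum((m_pg - m_p[:, None] - m_g[None, :] + m) ** 2)
              / ((n_p - 1) * (n_g - 1)),
        "r_g": n_p * np.sum((m_gr - m_g[:, None]) ** 2) / (n_g * (n_r - 1)),
        "pr_g_e": np.sum((y - m_pg[:, :, None] - m_gr[None, :, :] + m_g[None, :, None]) ** 2)
                  / ((n_p - 1) * n_g * (n_r - 1)),
    }
    raw = {
        "pr_g_e": ms["pr_g_e"],
        "r_g": (ms["r_g"] - ms["pr_g_e"]) / n_p,
        "pg": (ms["pg"] - ms["pr_g_e"]) / n_r,
        "g": (ms["g"] - ms["pg"] - ms["r_g"] + ms["pr_g_e"]) / (n_p * n_r),
        "p": (ms["p"] - ms["pg"]) / (n_g * n_r),
    }
    truncated = tuple(sorted(k for k, v in raw.items() if v < 0))
    est = {k: max(0.0, v) for k, v in raw.items()}
    return NestedVarianceComponents(
        sigma2_p=est["p"], sigma2_g=est["g"], sigma2_pg=est["pg"],
        sigma2_r_g=est["r_g"], sigma2_pr_g_e=est["pr_g_e"],
        truncated=truncated, raw=raw,
        design_sizes={"p": n_p, "g": n_g, "r": n_r},
    )


def nested_phi(vc: NestedVarianceComponents,
               n_g: int | None = None, n_r: int | None = None) -> float:
    """Absolute-error phi for the nested design (generalizing over groups and raters)."""
    sizes = dict(vc.design_sizes or {})
    n_g = n_g or sizes.get("g")
    n_r = n_r or sizes.get("r")
    c = vc.as_dict()
    denom = (c["p"] + c["g"] / n_g + c["pg"] / n_g
             + c["r_g"] / (n_g * n_r) + c["pr_g_e"] / (n_g * n_r))
    if denom == 0:
        raise UndefinedStatisticError("inter-user phi undefined: all components zero")
    return c["p"] / denom


def inter_user_phi(arr: RatingArray | np.ndarray,
                   rater_groups: Mapping | Sequence) -> float:
    """Inter-user dependability from a crossed array plus a rater -> group map.

    Item responses are summed into total scores per (study, rater); raters are
    then treated as nested within their groups (balanced designs only).
    """
    if not isinstance(arr, RatingArray):
        arr = RatingArray(np.asarray(arr, dtype=float), validate_scale=False)
    if isinstance(rater_groups, Mapping):
        rater_ids = list(arr.rater_ids) if arr.rater_ids is not None else list(range(arr.n_r))
        labels = [rater_groups[rid] for rid in rater_ids]
    else:
        labels = list(rater_groups)
        if len(labels) != arr.n_r:
            raise ValidationError("one group label per rater required")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise DesignError("inter-user reliability needs at least 2 rater groups")
    idx_by_group = [[j for j, lab in enumerate(labels) if lab == g] for g in groups]
    sizes = {len(ix) for ix in idx_by_group}
    if len(sizes) != 1:
        raise DesignError(f"unequal raters per group {dict(zip(groups, map(len, idx_by_group)))}; "
                          "balanced designs only")
    totals = arr.values.sum(axis=2)  # study x rater item-summed scores
    nested = np.stack([totals[:, ix] for ix in idx_by_group], axis=1)  # p x g x r
    return nested_phi(estimate_nested_components(nested))


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------


class GStudy:
    """G-study for one rater group's fully crossed studies x raters x items ratings.

    Parameters
    ----------
    ratings :
        :class:`RatingArray`, a 3-D array, or a long DataFrame with columns
        study_id, rater_id, item_id, rating (see :meth:`from_long`).
    """

    def __init__(self, ratings: RatingArray | np.ndarray):
        if not isinstance(ratings, RatingArray):
            ratings = RatingArray(np.asarray(ratings, dtype=float), validate_scale=False)
        self.ratings = ratings

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "GStudy":
        required = {"study_id", "rater_id", "item_id", "rating"}
        if not required.issubset(df.columns):
            raise ValidationError(f"long ratings need columns {sorted(required)}")
        wide = df.pivot_table(index="study_id", columns=["rater_id", "item_id"],
                              values="rating", aggfunc="first")
        raters = sorted(df["rater_id"].unique())
        items = sorted(df["item_id"].unique())
        expected = pd.MultiIndex.from_product([raters, items])
        missing = expected.difference(wide.columns)
        if len(missing) or wide.isna().any().any():
            cells = [(s, r, i) for s in wide.index for (r, i) in expected
                     if (r, i) not in wide.columns or pd.isna(wide.loc[s, (r, i)])]
            raise DesignError(f"not fully crossed; missing cells (study, rater, item): "
                              f"{cells[:10]}{'...' if len(cells) > 10 else ''}")
        wide = wide.reindex(columns=expected)
        values = wide.to_numpy().reshape(len(wide), len(raters), len(items))
        return cls(RatingArray(values, study_ids=list(wide.index),
                               rater_ids=raters, item_ids=items))

    def fit(self) -> "GStudyResults":
        vc = estimate_variance_components(self.ratings)
        return GStudyResults(self, vc)


@dataclass
class GStudyResults:
    """Estimated variance components plus D-study coefficient projections."""

    model: GStudy
    components: VarianceComponents

    def phi(self, generalize_over, fixed=(), n_prime=None, *, relative=False) -> float:
        return phi_coefficient(self.components, generalize_over, fixed, n_prime,
                               relative=relative)

    def inter_rater(self, n_raters: int | None = None) -> float:
        """Phi generalizing over raters, items fixed at the design size."""
        n_prime = {"r": n_raters} if n_raters else None
        return self.phi({"r"}, {"i"}, n_prime)

    def internal_consistency(self, n_items: int | None = None) -> float:
        """Phi generalizing over items, raters fixed at the design size."""
        n_prime = {"i": n_items} if n_items else None
        return self.phi({"i"}, {"r"}, n_prime)

    def overall(self, n_raters: int | None = None, n_items: int | None = None) -> float:
        """Phi generalizing over raters and items jointly."""
        n_prime = {}
        if n_raters:
            n_prime["r"] = n_raters
        if n_items:
            n_prime["i"] = n_items
        return self.phi({"r", "i"}, set(), n_prime or None)

    def summary(self) -> pd.DataFrame:
        rows = [{"component": c, "estimate": v,
                 "raw": self.components.raw[c],
                 "truncated": c in self.components.truncated}
                for c, v in self.components.as_dict().items()]
        return pd.DataFrame(rows)


@dataclass
class GCoefficientReport:
    """Reliability coefficients per rater group, plus the between-group coefficient."""

    internal_consistency: dict[str, float]
    inter_rater: dict[str, float]
    overall: dict[str, float]
    inter_user: float | None

    def summary(self) -> pd.DataFrame:
        groups = list(self.internal_consistency)
        rows = []
        for name, vals in (("internal_consistency", self.internal_consistency),
                           ("inter_rater", self.inter_rater),
                           ("overall", self.overall)):
            rows.append({"reliability": name, **{g: vals[g] for g in groups}})
        if self.inter_user is not None:
            rows.append({"reliability": "inter_user",
                         **{g: self.inter_user for g in groups[:1]}})
        return pd.DataFrame(rows)


def reliability_suite(arrays: Mapping[str, RatingArray | np.ndarray],
                      *, collapse: bool = False) -> GCoefficientReport:
    """Full reliability report for named rater groups.

    For each group: internal consistency (generalize over items, raters
    fixed), inter-rater (generalize over raters, items fixed) and overall
    (both random) dependability at the design sizes.  If every group has the
    same studies and items, the groups are concatenated along the rater axis
    and the nested-design inter-user coefficient is added.

    ``collapse=True`` averages the fixed facet out of the data before a
    two-way (single-facet) analysis instead of using the mixed-design
    formula; the two paths agree when the collapsed facet contributes no
    interaction variance.
    """
    fits: dict[str, GStudyResults] = {}
    arrs: dict[str, RatingArray] = {}
    for g, a in arrays.items():
        if not isinstance(a, RatingArray):
            a = RatingArray(np.asarray(a, dtype=float), validate_scale=False)
        arrs[g] = a
        fits[g] = GStudy(a).fit()

    internal, inter_rater, overall = {}, {}, {}
    for g, res in fits.items():
        if collapse:
            inter_rater[g] = _collapsed_phi(arrs[g].values.mean(axis=2))
            internal[g] = _collapsed_phi(arrs[g].values.mean(axis=1))
        else:
            inter_rater[g] = res.inter_rater()
            internal[g] = res.internal_consistency()
        overall[g] = res.overall()

    inter_user = None
    shapes = {(a.n_p, a.n_i) for a in arrs.values()}
    sizes = {a.n_r for a in arrs.values()}
    if len(arrs) >= 2 and len(shapes) == 1 and len(sizes) == 1:
        stacked = np.concatenate([arrs[g].values for g in sorted(arrs)], axis=1)
        labels = [g for g in sorted(arrs) for _ in range(next(iter(sizes)))]
        inter_user = inter_user_phi(stacked, labels)
    return GCoefficientReport(internal_consistency=internal, inter_rater=inter_rater,
                              overall=overall, inter_user=inter_user)


def _collapsed_phi(two_way: np.ndarray) -> float:
    """Single-facet phi from a p x facet matrix (facet-mean data)."""
    n_p, n_f = two_way.shape
    if n_p < 2 or n_f < 2:
        raise DesignError("collapsed analysis needs >=2 studies and >=2 facet levels")
    m = two_way.mean()
    m_p = two_way.mean(axis=1)
    m_f = two_way.mean(axis=0)
    ms_p = n_f * np.sum((m_p - m) ** 2) / (n_p - 1)
    ms_f = n_p * np.sum((m_f - m) ** 2) / (n_f - 1)
    ms_e = np.sum((two_way - m_p[:, None] - m_f[None, :] + m) ** 2) / ((n_p - 1) * (n_f - 1))
    s2_p = max(0.0, (ms_p - ms_e) / n_f)
    s2_f = max(0.0, (ms_f - ms_e) / n_p)
    denom = s2_p + s2_f / n_f + ms_e / n_f
    if denom == 0:
        raise UndefinedStatisticError("phi undefined: constant ratings")
    return s2_p / denom
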
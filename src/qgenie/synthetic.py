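"""Seeded synthetic-data generators with known ground truth.

The generators emulate the study design the instrument was validated on:
30 studies rated by 4 raters (2 per group, users vs non-users of genetic
association studies) on 11 items, global-impression grades correlated with
latent quality, citation metrics monotonically related to latent quality,
and a 7-study meta-analysis with a known true effect, between-study
heterogeneity, and an optional bias confined to low-quality studies.

Every generator is a pure function of its config and seed; each returns the
data together with a truth record containing all parameters needed for
recovery tests.

Ratings follow the crossed random-effects model

    y[p, r, i] = mu + p + r + i + pr + pi + ri + e,

with independent zero-mean normal effects at the configured variances,
discretized to the 1-7 Likert scale by rounding and clipping.  Recovery
tests use the continuous pre-discretization output, where the components are
estimated without discretization bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .gtheory import RatingArray
from .meta_sens import StudyEffect
from .validity import ImpactRecord

#: default crossed-design variance components (score-scale^2), chosen so that
#: study quality dominates but rater and item effects are visible, as in a
#: moderately reliable instrument.
DEFAULT_COMPONENTS: dict[str, float] = {
    "p": 1.0, "r": 0.1, "i": 0.2,
    "pr": 0.15, "pi": 0.1, "ri": 0.05, "pri_e": 0.5,
}


@dataclass
class SimulationConfig:
    """Parameters for all generators; defaults mirror the validation design."""

    n_studies: int = 30
    n_raters: int = 4
    n_items: int = 11
    n_groups: int = 2
    mu: float = 4.0
    components: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPONENTS))
    discretize: bool = True
    # latent-quality -> impact link
    impact_link_weight: float = 1.0
    impact_noise_sd: float = 0.5
    self_citation_fraction: float = 0.1
    # meta-analysis
    true_log_or: float = float(np.log(1.15))
    tau2: float = 0.0
    k_studies: int = 7
    se_range: tuple[float, float] = (0.08, 0.2)
    fraction_low_quality: float = 1.0 / 7.0
    low_quality_bias: float = 0.6

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.components.values()):
            raise ValidationError("variance components must be nonnegative")
        if not 1 <= self.mu <= 7:
            raise ValidationError("grand mean must lie on the 1-7 scale")
        if self.k_studies < 2:
            raise ValidationError("meta simulation needs k >= 2")
        if min(self.n_studies, self.n_raters, self.n_items) < 2:
            raise ValidationError("every rating dimension must be >= 2")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_ratings(cfg: SimulationConfig, seed: int) -> tuple[RatingArray, dict]:
    """Crossed p x r x i Likert ratings plus the truth record.

    The truth record carries the drawn study effects (``study_effects``, the
    latent quality of each study), the configured components and the
    continuous pre-discretization array.
    """
    rng = _rng(seed)
    n_p, n_r, n_i = cfg.n_studies, cfg.n_raters, cfg.n_items
    sd = {k: np.sqrt(v) for k, v in cfg.components.items()}
    p = rng.normal(0, sd["p"], n_p)
    r = rng.normal(0, sd["r"], n_r)
    i = rng.normal(0, sd["i"], n_i)
    pr = rng.normal(0, sd["pr"], (n_p, n_r))
    pi = rng.normal(0, sd["pi"], (n_p, n_i))
    ri = rng.normal(0, sd["ri"], (n_r, n_i))
    e = rng.normal(0, sd["pri_e"], (n_p, n_r, n_i))
    y = (cfg.mu + p[:, None, None] + r[None, :, None] + i[None, None, :]
         + pr[:, :, None] + pi[:, None, :] + ri[None, :, :] + e)
    continuous = y.copy()
    if cfg.discretize:
        y = np.clip(np.rint(y), 1, 7)
    truth = {
        "mu": cfg.mu,
        "components": dict(cfg.components),
        "study_effects": p,
        "continuous": continuous,
        "seed": seed,
    }
    study_ids = [f"S{j + 1:02d}" for j in range(n_p)]
    rater_ids = [f"R{j + 1}" for j in range(n_r)]
    arr = RatingArray(y, study_ids=study_ids, rater_ids=rater_ids,
                      item_ids=list(range(1, n_i + 1)),
                      validate_scale=cfg.discretize)
    return arr, truth


def rater_group_map(cfg: SimulationConfig) -> dict[str, str]:
    """Assign raters round-robin-free: first n_r/n_groups raters to group 'G1', etc."""
    per = cfg.n_raters // cfg.n_groups
    if per * cfg.n_groups != cfg.n_raters:
        raise ValidationError("n_raters must divide evenly into n_groups")
    return {f"R{j + 1}": f"G{j // per + 1}" for j in range(cfg.n_raters)}


def simulate_global_impressions(truth: dict, seed: int, *,
                                noise_sd: float = 0.5,
                                thresholds: tuple[float, float] | None = None,
                                n_raters: int = 1) -> pd.DataFrame:
    """Global-impression 1-7 ratings driven by latent study quality.

    Latent quality plus noise is thresholded into the seven scale categories;
    with ``thresholds`` given as two latent cut values, categories {1,2},
    {3,4} and {5,6,7} (the low/moderate/high grade bands) are filled by
    comparing to those cuts.  Defaults place the cuts at the latent terciles.
    """
    rng = _rng(seed)
    p = np.asarray(truth["study_effects"], dtype=float)
    if thresholds is None:
        thresholds = tuple(np.quantile(p, [1 / 3, 2 / 3]))
    lo_cut, hi_cut = thresholds
    rows = []
    for rater in range(n_raters):
        latent = p + rng.normal(0, noise_sd, len(p))
        for j, v in enumerate(latent):
            if v <= lo_cut:
                rating = 2       # low band
            elif v <= hi_cut:
                rating = 4       # moderate band
            else:
                rating = 6       # high band
            rows.append({"study_id": f"S{j + 1:02d}", "rater_id": f"R{rater + 1}",
                         "rating": rating})
    return pd.DataFrame(rows)


def simulate_impact(truth: dict, seed: int, cfg: SimulationConfig,
                    *, analysis_year: int = 2014) -> list[ImpactRecord]:
    """Impact/citation records monotone in latent quality plus noise."""
    rng = _rng(seed)
    p = np.asarray(truth["study_effects"], dtype=float)
    n = len(p)
    w, s = cfg.impact_link_weight, cfg.impact_noise_sd
    impact_factor = np.exp(1.0 + w * p + rng.normal(0, s, n))
    years = rng.integers(analysis_year - 9, analysis_year + 1, n)
    cites_per_year = np.exp(1.5 + w * p + rng.normal(0, s, n))
    total = np.maximum(0, np.rint(cites_per_year * (analysis_year - years + 1))).astype(int)
    self_c = np.minimum(total, np.rint(cfg.self_citation_fraction * total)).astype(int)
    return [
        ImpactRecord(study_id=f"S{j + 1:02d}", impact_factor=float(impact_factor[j]),
                     total_citations=int(total[j]), self_citations=int(self_c[j]),
                     publication_year=int(years[j]))
        for j in range(n)
    ]


def simulate_meta(cfg: SimulationConfig, seed: int) -> tuple[list[StudyEffect], dict]:
    """Study effects theta_i ~ N(theta, tau^2), observed ~ N(theta_i, se_i^2).

    A configured fraction of studies is labelled low quality and receives an
    added bias on the log-OR scale, emulating inflated effects in poorly
    conducted studies.
    """
    rng = _rng(seed)
    k = cfg.k_studies
    n_low = int(round(cfg.fraction_low_quality * k))
    se = rng.uniform(*cfg.se_range, k)
    theta_i = rng.normal(cfg.true_log_or, np.sqrt(cfg.tau2), k)
    bias = np.zeros(k)
    bias[:n_low] = cfg.low_quality_bias
    obs = rng.normal(theta_i + bias, se)
    quality = ["low"] * n_low + ["moderate"] * (k - n_low)
    order = rng.permutation(k)
    effects = [
        StudyEffect(study_id=f"M{j + 1}", log_or=float(obs[idx]), se=float(se[idx]),
                    quality=quality[idx])
        for j, idx in enumerate(order)
    ]
    truth = {"true_log_or": cfg.true_log_or, "tau2": cfg.tau2,
             "low_quality_bias": cfg.low_quality_bias, "n_low": n_low, "seed": seed}
    return effects, truth


def ratings_to_long(arr: RatingArray) -> pd.DataFrame:
    """Long-format (study_id, rater_id, item_id, rating) table from an array."""
    study_ids = arr.study_ids or list(range(arr.n_p))
    rater_ids = arr.rater_ids or list(range(arr.n_r))
    item_ids = arr.item_ids or list(range(arr.n_i))
    rows = [
        {"study_id": study_ids[p], "rater_id": rater_ids[r],
         "item_id": item_ids[i], "rating": arr.values[p, r, i]}
        for p in range(arr.n_p) for r in range(arr.n_r) for i in range(arr.n_i)
    ]
    return pd.DataFrame(rows)
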
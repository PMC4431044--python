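"""End-to-end analysis pipeline over simulated inputs.

Stages follow the validation workflow: score -> item statistics ->
reliability -> cut-points -> construct validity -> meta-analysis
sensitivity.  Each stage writes a JSON and/or CSV report; a combined summary
and a run log (seed, package version, effective parameters) close the run.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as qio
from . import item_analysis, meta_sens, standard_setting, synthetic
from .gtheory import RatingArray, reliability_suite
from .instrument import DEFAULT_SCHEMES, Variant, batch_score
from .validity import validity_table

logger = logging.getLogger(__name__)


def run_pipeline(out_dir: Path, *, seed: int = 0, exclude_low: bool = True,
                 cfg: synthetic.SimulationConfig | None = None,
                 analysis_year: int = 2014) -> dict:
    """Run every stage on a simulated bundle; returns paths and key results."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or synthetic.SimulationConfig()
    stage = "simulate"
    try:
        arr, truth = synthetic.simulate_ratings(cfg, seed)
        long = synthetic.ratings_to_long(arr)
        gm = synthetic.rater_group_map(cfg)

        stage = "score"
        study_ratings = qio.study_ratings_from_tables(long)
        scheme = DEFAULT_SCHEMES[Variant.WITH_CONTROL]
        logger.info("classifying with scheme low<=%d moderate<=%d",
                    scheme.low_max, scheme.moderate_max)
        scored = batch_score(study_ratings)
        scored.table.to_csv(out_dir / "scores.csv", index=False)
        scored.summary.to_csv(out_dir / "scores.summary.csv", index=False)

        stage = "itemstats"
        stats_by_group = item_analysis.group_item_stats(long, gm)
        pd.concat([t.assign(group=g) for g, t in stats_by_group.items()],
                  ignore_index=True).to_csv(out_dir / "itemstats.csv", index=False)

        stage = "reliability"
        rater_ids = [str(r) for r in arr.rater_ids]
        arrays = {}
        for g in sorted(set(gm.values())):
            idx = [j for j, r in enumerate(rater_ids) if gm[r] == g]
            arrays[g] = RatingArray(arr.values[:, idx, :], validate_scale=False)
        suite = reliability_suite(arrays)
        qio.write_json({
            "internal_consistency": suite.internal_consistency,
            "inter_rater": suite.inter_rater,
            "overall": suite.overall,
            "inter_user": suite.inter_user,
        }, out_dir / "reliability.json")

        stage = "cutpoints"
        gi = synthetic.simulate_global_impressions(truth, seed + 1)
        grades = {str(r.study_id): standard_setting.map_global_to_grade(int(r.rating))
                  for r in gi.itertuples()}
        per_rater = scored.table
        pairs = [(row.score, grades[str(row.study_id)]) for row in per_rater.itertuples()
                 if str(row.study_id) in grades]
        fit = standard_setting.derive_cutpoints([p[0] for p in pairs],
                                                [p[1] for p in pairs],
                                                Variant.WITH_CONTROL)
        qio.write_json({"slope": fit.slope, "intercept": fit.intercept,
                        "r_squared": fit.r_squared,
                        "cut_low": fit.cut_low, "cut_moderate": fit.cut_moderate,
                        "low_max": fit.scheme.low_max,
                        "moderate_max": fit.scheme.moderate_max},
                       out_dir / "cutpoints.json")

        stage = "validity"
        impact = synthetic.simulate_impact(truth, seed + 2, cfg,
                                           analysis_year=analysis_year)
        mean_scores = per_rater.groupby("study_id")["score"].mean()
        vt = validity_table(mean_scores, impact, analysis_year)
        vt.to_csv(out_dir / "validity.csv", index=False)

        stage = "meta"
        effects, _ = synthetic.simulate_meta(cfg, seed + 3)
        if exclude_low:
            report = meta_sens.sensitivity_by_quality(effects)
            report.forest_table.to_csv(out_dir / "meta.forest.csv", index=False)
            meta_payload = {
                "all_studies": _meta_dict(report.all_studies),
                "excluding_low": _meta_dict(report.excluding_low),
                "n_excluded": report.n_excluded,
            }
        else:
            res = meta_sens.pool(effects)
            res.study_table.to_csv(out_dir / "meta.forest.csv", index=False)
            meta_payload = {"all_studies": _meta_dict(res)}
        qio.write_json(meta_payload, out_dir / "meta.json")
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "seed": seed,
        "version": __version__,
        "n_studies": cfg.n_studies, "n_raters": cfg.n_raters, "n_items": cfg.n_items,
        "scheme": {"low_max": scheme.low_max, "moderate_max": scheme.moderate_max},
        "class_counts": scored.summary.set_index("quality")["count"].to_dict(),
        "reliability": {"inter_user": suite.inter_user},
        "cutpoints": [fit.scheme.low_max, fit.scheme.moderate_max],
        "meta": meta_payload,
    }
    summary_path = out_dir / "summary.json"
    qio.write_json(summary, summary_path)
    return {"summary_path": summary_path, "out_dir": out_dir, "summary": summary}


def _meta_dict(res) -> dict:
    h = res.heterogeneity
    return {
        "k": res.k, "pooled_or": res.pooled_or,
        "ci_low": res.ci_low, "ci_high": res.ci_high, "tau2": res.tau2,
        "Q": None if h is None else h.Q,
        "i2_percent": None if h is None else h.i2_percent,
    }
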
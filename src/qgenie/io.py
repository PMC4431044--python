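"""CSV / YAML / JSON readers and writers for the analysis inputs and reports.

Ratings are exchanged as long-format CSV with the required header
``study_id,rater_id,item_id,rating``; a wide layout (one column per item,
named ``item_1`` ... ``item_11``) is also accepted.  All writers emit
RFC-4180 CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ValidationError
from .gtheory import GStudy, RatingArray
from .instrument import CutPointScheme, StudyRating, Variant
from .validity import ImpactRecord

LONG_COLUMNS = ["study_id", "rater_id", "item_id", "rating"]


def read_ratings(path, *, wide: bool = False) -> pd.DataFrame:
    """Read a ratings CSV into the long format, validating values.

    Raises with row numbers for malformed rows and rejects ratings outside
    the 1-7 scale.
    """
    df = pd.read_csv(path)
    if wide:
        item_cols = [c for c in df.columns if c.startswith("item_")]
        if not item_cols or not {"study_id", "rater_id"}.issubset(df.columns):
            raise ValidationError(
                f"{path}: wide layout needs study_id, rater_id and item_* columns")
        df = df.melt(id_vars=[c for c in ("study_id", "rater_id") if c in df.columns],
                     value_vars=item_cols, var_name="item_id", value_name="rating")
        df["item_id"] = df["item_id"].str.removeprefix("item_").astype(int)
        df = df.dropna(subset=["rating"])
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {sorted(missing)}")
    bad = df.index[~df["rating"].between(1, 7) | df["rating"].isna()]
    if len(bad):
        raise ValidationError(
            f"{path}: rating outside 1-7 at data row(s) {list(bad[:10] + 2)}")
    df["item_id"] = df["item_id"].astype(int)
    return df[LONG_COLUMNS + [c for c in df.columns if c not in LONG_COLUMNS]]


def long_to_rating_array(df: pd.DataFrame) -> RatingArray:
    """Pivot long ratings into a fully crossed array (errors list missing cells)."""
    return GStudy.from_long(df).ratings


def write_ratings(arr_or_df, path) -> None:
    from .synthetic import ratings_to_long

    df = arr_or_df if isinstance(arr_or_df, pd.DataFrame) else ratings_to_long(arr_or_df)
    df.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "study_id" not in df.columns:
        raise ValidationError(f"{path}: metadata needs a study_id column")
    if "has_control_group" in df.columns:
        df["has_control_group"] = df["has_control_group"].astype(bool)
    return df


def study_ratings_from_tables(ratings: pd.DataFrame,
                              metadata: pd.DataFrame | None = None) -> list[StudyRating]:
    """One StudyRating per (study, rater) from long ratings plus optional metadata."""
    control = {}
    if metadata is not None and "has_control_group" in metadata.columns:
        control = dict(zip(metadata["study_id"].astype(str),
                           metadata["has_control_group"]))
    out = []
    for (sid, rid), sub in ratings.groupby(["study_id", "rater_id"], sort=True):
        responses = dict(zip(sub["item_id"].astype(int), sub["rating"].astype(int)))
        out.append(StudyRating(study_id=str(sid), responses=responses,
                               has_control_group=bool(control.get(str(sid), True)),
                               rater_id=str(rid)))
    return out


def read_global_impressions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"study_id", "rater_id", "rating"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: global impressions need columns {sorted(needed)}")
    return df


def read_impact(path) -> list[ImpactRecord]:
    df = pd.read_csv(path)
    needed = {"study_id", "impact_factor", "total_citations", "self_citations", "year"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: impact table needs columns {sorted(needed)}")
    return [
        ImpactRecord(study_id=str(r.study_id), impact_factor=float(r.impact_factor),
                     total_citations=int(r.total_citations),
                     self_citations=int(r.self_citations),
                     publication_year=int(r.year))
        for r in df.itertuples()
    ]


def read_effects(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "study_id" not in df.columns:
        raise ValidationError(f"{path}: effects table needs a study_id column")
    if not ({"log_or", "se"}.issubset(df.columns)
            or {"a", "b", "c", "d"}.issubset(df.columns)):
        raise ValidationError(
            f"{path}: effects need columns (log_or, se) or 2x2 counts (a, b, c, d)")
    return df


def read_group_map(path) -> dict[str, str]:
    df = pd.read_csv(path)
    if not {"rater_id", "group"}.issubset(df.columns):
        raise ValidationError(f"{path}: group map needs columns rater_id, group")
    return dict(zip(df["rater_id"].astype(str), df["group"].astype(str)))


def read_scheme(path) -> dict[Variant, CutPointScheme]:
    """Cut-point schemes from YAML/JSON: {variant: {low_max: .., moderate_max: ..}}."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    out = {}
    for variant, spec in data.items():
        v = Variant(variant)
        out[v] = CutPointScheme(v, int(spec["low_max"]), int(spec["moderate_max"]))
    return out


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(x):
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="records")
    if hasattr(x, "value"):
        return x.value
    raise TypeError(f"not JSON serialisable: {type(x)}")
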
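"""Harmonize per-study sensing and EMA tables into aligned model instances.

Input is a long-format hourly sensing table and a raw EMA response table
(see :mod:`sensefuse.schemas`).  Output is one row per EMA response carrying
the 44-feature vector: trailing-window means of day/epoch sensing summaries,
day-level sleep values, and a missing-day counter.

Conventions
-----------
* Calendar days in the study-local clock; epochs are half-open, so a value
  at exactly 6AM falls in the 6AM-12PM epoch.
* The low-coverage day filter applies only to studies flagged as derived
  from raw streams; studies shipping day-level features pass through.
* Multiple responses to one item on one day are kept as separate instances
  sharing that day's features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemas import (
    AGGREGATION_MAP,
    EPOCHS,
    EPOCH_VARIABLES,
    FEATURE_COLUMNS,
    MISSING_DAYS_FEATURE,
    SENSOR_FEATURE_COLUMNS,
    SLEEP_VARIABLES,
    epoch_feature_names,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EmaMapping",
    "crosscheck_battery",
    "studentlife_battery",
    "compute_epoch_features",
    "filter_low_coverage_days",
    "build_day_features",
    "normalize_ema",
    "normalize_ema_table",
    "label_severity",
    "build_aligned_instances",
    "select_validation_subjects",
    "derive_lock_based_streams",
    "harmonize_study",
]


# ---------------------------------------------------------------------------
# EMA normalization


@dataclass(frozen=True)
class EmaMapping:
    """Maps one EMA item's raw responses onto the common 0-3 severity scale.

    ``norm_map`` is the raw -> normalized mapping used for modeling (values
    snapped to the integer grid where the raw scale has more than four
    levels).  ``gen_scale`` keeps the un-snapped monotone scale values and is
    used by the synthetic generator to invert the mapping.  ``severe_raw``
    holds the two raw categories coded as severe; for items where low scores
    are bad (sleep quality), ``severe_low`` is True.
    """

    item: str
    raw_domain: tuple
    norm_map: dict
    severe_raw: tuple
    severe_low: bool
    gen_scale: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.severe_raw) != 2:
            raise ValueError(
                f"{self.item}: severe set must contain exactly two categories"
            )
        missing = [r for r in self.raw_domain if r not in self.norm_map]
        if missing:
            raise ValueError(f"{self.item}: mapping not total, missing {missing}")
        for v in self.norm_map.values():
            if not (0.0 <= v <= 3.0):
                raise ValueError(f"{self.item}: normalized value {v} outside [0,3]")
        if not self.gen_scale:
            object.__setattr__(self, "gen_scale", dict(self.norm_map))

    @property
    def severe_normalized(self) -> frozenset:
        return frozenset(self.norm_map[r] for r in self.severe_raw)

    def severity_order(self) -> list:
        """Raw categories sorted from least to most severe."""
        key = (lambda r: -self.gen_scale[r]) if self.severe_low else (
            lambda r: self.gen_scale[r]
        )
        return sorted(self.raw_domain, key=key)


_CC_POSITIVE = {"calm", "social", "sleep", "think", "hopeful"}
_CC_NEGATIVE = {"voices", "seeing_things", "stress", "harm", "depressed"}

#: the ten items administered per assessment occasion in the clinical study
CROSSCHECK_ITEMS = [
    "calm",
    "social",
    "voices",
    "seeing_things",
    "stress",
    "harm",
    "sleep",
    "think",
    "depressed",
    "hopeful",
]


def crosscheck_battery() -> dict[str, EmaMapping]:
    """All ten items, native 0-3 scale; normalization is the identity."""
    battery = {}
    for item in CROSSCHECK_ITEMS:
        severe_low = item in _CC_POSITIVE
        severe = (0, 1) if severe_low else (2, 3)
        battery[item] = EmaMapping(
            item=item,
            raw_domain=(0, 1, 2, 3),
            norm_map={r: float(r) for r in range(4)},
            severe_raw=severe,
            severe_low=severe_low,
        )
    return battery


def studentlife_battery() -> dict[str, EmaMapping]:
    """The student-study sleep-quality and stress items.

    Sleep quality is a 4-level scale with 1 = best, mapped by x -> 4 - x so
    that 3 = best on the common scale.  Stress is a 5-level scale whose
    labels are first reordered by severity (feeling great < feeling good <
    a little stressed < definitely stressed < stressed out), placed on [0,3]
    affinely, then snapped to the integer grid by rounding.
    """
    sleep = EmaMapping(
        item="sleep",
        raw_domain=(1, 2, 3, 4),
        norm_map={r: float(4 - r) for r in (1, 2, 3, 4)},
        severe_raw=(3, 4),
        severe_low=True,
    )
    # raw codes: 1 a little stressed, 2 definitely stressed, 3 stressed out,
    # 4 feeling good, 5 feeling great
    severity_order = [5, 4, 1, 2, 3]
    gen = {raw: 3.0 * i / 4.0 for i, raw in enumerate(severity_order)}
    stress = EmaMapping(
        item="stress",
        raw_domain=(1, 2, 3, 4, 5),
        norm_map={raw: float(np.round(v)) for raw, v in gen.items()},
        severe_raw=(2, 3),
        severe_low=False,
        gen_scale=gen,
    )
    return {"sleep": sleep, "stress": stress}


def normalize_ema(raw_value, mapping: EmaMapping, subject=None) -> float:
    """Map one raw response to the common 0-3 scale."""
    try:
        return mapping.norm_map[raw_value]
    except KeyError:
        raise ValueError(
            f"raw value {raw_value!r} outside domain of item "
            f"{mapping.item!r} (subject {subject!r})"
        ) from None


def label_severity(value: float, mapping: EmaMapping) -> int:
    """1 iff the normalized value is one of the two severe categories."""
    if not 0.0 <= value <= 3.0:
        raise ValueError(f"normalized value {value} outside [0,3]")
    return int(any(np.isclose(value, s) for s in mapping.severe_normalized))


def normalize_ema_table(
    ema: pd.DataFrame, batteries: dict[str, dict[str, EmaMapping]]
) -> pd.DataFrame:
    """Normalize a raw EMA table; adds ``outcome`` and ``severe`` columns.

    ``batteries`` maps study id -> {item -> EmaMapping}.  Items without a
    mapping are dropped (non-outcome battery items).
    """
    out_rows = []
    for (study, item), grp in ema.groupby(["study", "item"], sort=False):
        mapping = batteries.get(study, {}).get(item)
        if mapping is None:
            continue
        grp = grp.copy()
        grp["outcome"] = [
            normalize_ema(r, mapping, subject=s)
            for r, s in zip(grp["raw_value"], grp["subject"])
        ]
        grp["severe"] = [label_severity(v, mapping) for v in grp["outcome"]]
        out_rows.append(grp)
    if not out_rows:
        return ema.iloc[0:0].assign(outcome=[], severe=[])
    out = pd.concat(out_rows, axis=0)
    return out.sort_values(["study", "subject", "timestamp", "item"]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# sensing features


def compute_epoch_features(hourly_values, aggregation: str) -> np.ndarray:
    """One whole-day summary plus one value per 6-hour epoch (5 values).

    ``aggregation`` is ``sum`` (durations, distance), ``count`` (event
    counts; hourly values are counts, so the epoch value is their sum) or
    ``mean``.  Epochs with no data yield NaN.
    """
    values = np.asarray(hourly_values, dtype=float)
    if values.shape != (24,):
        raise ValueError("expected 24 hourly values")
    if aggregation not in ("mean", "count", "sum"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    def agg(chunk: np.ndarray) -> float:
        if np.all(np.isnan(chunk)):
            return np.nan
        if aggregation == "mean":
            return float(np.nanmean(chunk))
        return float(np.nansum(chunk))

    out = [agg(values)]
    out.extend(agg(values[a:b]) for a, b in EPOCHS)
    return np.asarray(out)


def filter_low_coverage_days(
    day_records: pd.DataFrame, min_hours: int = 19
) -> pd.DataFrame:
    """Retain day records with at least ``min_hours`` hours of data.

    Callers apply this only to raw-derived studies; day-level-provided
    studies are passed through unchanged (see :func:`build_day_features`).
    """
    keep = day_records["hours_with_data"] >= min_hours
    return day_records.loc[keep].reset_index(drop=True)


def build_day_features(
    sensing: pd.DataFrame,
    agg_map: dict | None = None,
    min_hours: int = 19,
    raw_derived_studies: frozenset | set = frozenset(),
) -> pd.DataFrame:
    """Collapse the hourly sensing table to one wide row per subject-day.

    Returns a frame indexed by (subject, study, date) with the 43 sensor
    feature columns.  For studies in ``raw_derived_studies`` a subject-day
    is dropped entirely when fewer than ``min_hours`` hours of the day have
    any data.
    """
    agg_map = dict(AGGREGATION_MAP if agg_map is None else agg_map)
    unknown = set(agg_map) - set(EPOCH_VARIABLES)
    if unknown:
        raise ValueError(f"aggregation declared for unknown variables: {unknown}")

    df = sensing.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()

    hourly = df[df["variable"].isin(EPOCH_VARIABLES) & df["hour"].notna()].copy()
    hourly["hour"] = hourly["hour"].astype(int)
    if ((hourly["hour"] < 0) | (hourly["hour"] > 23)).any():
        raise ValueError("hour outside 0-23")

    keys = ["subject", "study", "date"]

    # day coverage: hours of the day with any non-missing value
    cov = (
        hourly.dropna(subset=["value"])
        .groupby(keys)["hour"]
        .nunique()
        .rename("hours_with_data")
    )
    cov_df = cov.reset_index()
    low = cov_df["study"].isin(raw_derived_studies) & (
        cov_df["hours_with_data"] < min_hours
    )
    dropped = cov_df.loc[low, keys]
    if len(dropped):
        logger.info("coverage rule dropped %d subject-days", len(dropped))
        hourly = hourly.merge(dropped, on=keys, how="left", indicator=True)
        hourly = hourly[hourly["_merge"] == "left_only"].drop(columns="_merge")

    # epoch bucketing; half-open windows via integer division
    hourly["epoch"] = hourly["hour"] // 6

    pieces = []
    for var in EPOCH_VARIABLES:
        sub = hourly[hourly["variable"] == var]
        if sub.empty:
            continue
        agg = agg_map.get(var)
        if agg is None:
            raise ValueError(f"no aggregation declared for variable {var!r}")
        names = epoch_feature_names(var)
        if agg == "mean":
            day = sub.groupby(keys)["value"].mean()
            ep = sub.groupby(keys + ["epoch"])["value"].mean()
        else:  # sum and count both total the hourly values
            day = sub.groupby(keys)["value"].sum(min_count=1)
            ep = sub.groupby(keys + ["epoch"])["value"].sum(min_count=1)
        wide = ep.unstack("epoch").reindex(columns=range(4))
        wide.columns = names[1:]
        wide.insert(0, names[0], day)
        pieces.append(wide)

    sleep = df[df["variable"].isin(SLEEP_VARIABLES) & df["hour"].isna()]
    if not sleep.empty:
        sw = sleep.pivot_table(
            index=keys, columns="variable", values="value", aggfunc="first"
        )
        if len(dropped):
            drop_idx = pd.MultiIndex.from_frame(dropped)
            sw = sw[~sw.index.isin(drop_idx)]
        pieces.append(sw)

    if not pieces:
        return pd.DataFrame(
            columns=SENSOR_FEATURE_COLUMNS,
            index=pd.MultiIndex.from_arrays([[], [], []], names=keys),
        )
    out = pd.concat(pieces, axis=1).reindex(columns=SENSOR_FEATURE_COLUMNS)
    return out.sort_index()


# ---------------------------------------------------------------------------
# EMA-feature alignment


def build_aligned_instances(
    day_features: pd.DataFrame,
    ema: pd.DataFrame,
    window: int = 3,
    include_missing_counter: bool = True,
    sleep_fill: bool = True,
) -> pd.DataFrame:
    """Pair each normalized EMA response with trailing-window mean features.

    For a response on day t, each feature is the mean over the available
    days in {t-window+1, ..., t}; a final feature counts the days in the
    window with no sensing data at all.  Responses whose whole window is
    missing (or whose subject has no sensing data) are skipped with a
    logged warning.  Sleep features missing for the entire window are
    filled with the subject's mean observed sleep value; any residual gaps
    fall back to the study-pooled column mean.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ema = ema.copy()
    ema["timestamp"] = pd.to_datetime(ema["timestamp"])
    ema["date"] = ema["timestamp"].dt.normalize()
    ema = ema.sort_values(["study", "subject", "timestamp", "item"]).reset_index(
        drop=True
    )

    days = day_features.reset_index()
    days["_present"] = True
    keys = ["subject", "study", "date"]

    stacked_feats = []
    present = np.zeros((len(ema), window), dtype=bool)
    for off in range(window):
        probe = ema[["subject", "study", "date"]].copy()
        probe["date"] = probe["date"] - pd.Timedelta(days=off)
        merged = probe.merge(days, on=keys, how="left")
        present[:, window - 1 - off] = merged["_present"].notna().to_numpy()
        stacked_feats.append(merged[SENSOR_FEATURE_COLUMNS].to_numpy(dtype=float))

    cube = np.stack(stacked_feats, axis=0)  # (window, n_ema, 43)
    with np.errstate(invalid="ignore"):
        feats = np.nanmean(cube, axis=0)
    missing_days = window - present.sum(axis=1)

    out = ema[["subject", "study", "timestamp", "item", "outcome", "severe"]].copy()
    for j, col in enumerate(SENSOR_FEATURE_COLUMNS):
        out[col] = feats[:, j]
    out[MISSING_DAYS_FEATURE] = missing_days.astype(float)

    all_missing = missing_days >= window
    if all_missing.any():
        logger.warning(
            "skipping %d EMA responses with no sensing data in their window",
            int(all_missing.sum()),
        )
        out = out[~all_missing].reset_index(drop=True)

    if sleep_fill and len(out):
        subj_sleep = days.groupby("subject")[SLEEP_VARIABLES].mean()
        for col in SLEEP_VARIABLES:
            gap = out[col].isna()
            if gap.any():
                fill = out.loc[gap, "subject"].map(subj_sleep[col])
                out.loc[gap, col] = fill

    # residual gaps (variable never observed in a window / for a subject)
    feature_cols = SENSOR_FEATURE_COLUMNS + [MISSING_DAYS_FEATURE]
    residual = out[feature_cols].isna().sum().sum()
    if residual:
        logger.info("filling %d residual feature gaps with column means", residual)
        out[feature_cols] = out[feature_cols].fillna(out[feature_cols].mean())
        out[feature_cols] = out[feature_cols].fillna(0.0)

    if not include_missing_counter:
        out = out.drop(columns=[MISSING_DAYS_FEATURE])
    cols = ["subject", "study", "timestamp", "item"] + (
        FEATURE_COLUMNS if include_missing_counter else SENSOR_FEATURE_COLUMNS
    ) + ["outcome", "severe"]
    return out[cols]


def select_validation_subjects(
    instances: pd.DataFrame, min_ema: int = 30
) -> list:
    """Subjects with at least ``min_ema`` instances for the target item.

    All subjects' data remain usable as training data regardless.
    """
    if instances.empty:
        return []
    if instances["item"].nunique() > 1:
        raise ValueError("pass instances for a single outcome item")
    counts = instances.groupby("subject").size()
    return sorted(counts.index[counts >= min_ema].tolist())


# ---------------------------------------------------------------------------
# lock-interval derived streams (raw-derived study stand-in)

_NIGHT_START = 21.0  # 9PM, hours from midnight of the evening day
_NIGHT_END = 36.0  # noon next day


def derive_lock_based_streams(
    lock_intervals: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate unlock duration and sleep from phone-lock intervals.

    ``lock_intervals`` has columns subject, study, start, end (timestamps of
    locked periods; non-overlapping per subject).  Returns an hourly
    ``unlock_duration`` table (hours unlocked within each hour) and a
    day-level sleep table.  Sleep on a given day is the longest locked
    interval intersecting the 9PM (previous evening) to noon window; onset
    and wake are hours relative to that day's midnight (onset negative when
    before midnight); duration = wake - onset.  Nights with no locked
    interval in the window yield no sleep row.
    """
    li = lock_intervals.copy()
    li["start"] = pd.to_datetime(li["start"])
    li["end"] = pd.to_datetime(li["end"])
    if (li["end"] <= li["start"]).any():
        raise ValueError("lock interval with non-positive duration")

    unlock_rows = []
    sleep_rows = []
    for (subject, study), grp in li.groupby(["subject", "study"]):
        grp = grp.sort_values("start")
        if (grp["start"].iloc[1:].to_numpy() < grp["end"].iloc[:-1].to_numpy()).any():
            raise ValueError(f"overlapping lock intervals for subject {subject!r}")
        d0 = grp["start"].min().normalize()
        d1 = grp["end"].max().normalize()
        days = pd.date_range(d0, d1, freq="D")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for day in days:
            for hour in range(24):
                h0 = day + pd.Timedelta(hours=hour)
                h1 = h0 + pd.Timedelta(hours=1)
                locked = np.sum(
                    np.maximum(
                        (np.minimum(ends, h1.to_datetime64()) -
                         np.maximum(starts, h0.to_datetime64()))
                        / np.timedelta64(1, "h"),
                        0.0,
                    )
                )
                unlock_rows.append(
                    (subject, study, day, "unlock_duration", hour,
                     float(1.0 - min(locked, 1.0)))
                )
        # sleep: night window anchored on each wake day
        for day in days:
            w0 = day + pd.Timedelta(hours=_NIGHT_START - 24.0)
            w1 = day + pd.Timedelta(hours=_NIGHT_END - 24.0)
            inter = grp[(grp["end"] > w0) & (grp["start"] < w1)]
            if inter.empty:
                continue
            dur = (inter["end"] - inter["start"]).dt.total_seconds()
            best = inter.loc[dur.idxmax()]
            onset = (best["start"] - day) / pd.Timedelta(hours=1)
            wake = (best["end"] - day) / pd.Timedelta(hours=1)
            sleep_rows.extend(
                [
                    (subject, study, day, "sleep_onset", np.nan, float(onset)),
                    (subject, study, day, "sleep_wake", np.nan, float(wake)),
                    (subject, study, day, "sleep_duration", np.nan,
                     float(wake - onset)),
                ]
            )

    cols = ["subject", "study", "date", "variable", "hour", "value"]
    return (
        pd.DataFrame(unlock_rows, columns=cols),
        pd.DataFrame(sleep_rows, columns=cols),
    )


# ---------------------------------------------------------------------------
# convenience driver


def harmonize_study(
    sensing: pd.DataFrame,
    ema: pd.DataFrame,
    batteries: dict[str, dict[str, EmaMapping]],
    window: int = 3,
    min_hours: int = 19,
    raw_derived_studies: frozenset | set = frozenset(),
) -> pd.DataFrame:
    """Full harmonization: day features + EMA normalization + alignment."""
    day_features = build_day_features(
        sensing, min_hours=min_hours, raw_derived_studies=raw_derived_studies
    )
    normalized = normalize_ema_table(ema, batteries)
    return build_aligned_instances(day_features, normalized, window=window)
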
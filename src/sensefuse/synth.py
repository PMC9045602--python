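"""Synthetic paired-study generator.

Produces two-study sensing + EMA datasets with the statistical structure the
downstream analysis assumes: heavy-tailed non-normal sensing marginals,
study-specific EMA response scales and schedules, ordinal 0-3 outcomes with
under-represented severe categories, configurable behavior->symptom links
that can be shared or opposed across studies, and day-level missingness.

The real studies publish no generative model; every distributional choice
here (log-normal durations, negative-binomial counts, the link forms) is a
stand-in whose parameters are exposed in the config, not an estimate of the
original data.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .harmonize import EmaMapping, crosscheck_battery, studentlife_battery
from .schemas import (
    AGGREGATION_MAP,
    ALL_VARIABLES,
    EPOCH_VARIABLES,
    SLEEP_VARIABLES,
)

__all__ = [
    "LinkSpec",
    "ShiftSpec",
    "ScheduleSpec",
    "StudyConfig",
    "StudyDataset",
    "generate_study",
    "generate_paired_studies",
    "inject_missingness",
    "priors_from_severe",
    "clinical_study_config",
    "student_study_config",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


# hourly marginal families; (family, param1, param2)
DEFAULT_MARGINALS: dict[str, tuple] = {
    "act_foot": ("lognormal", -1.2, 0.9),
    "act_still": ("lognormal", 2.8, 0.5),
    "act_unknown": ("lognormal", -0.7, 1.0),
    "conv_duration": ("lognormal", 0.4, 1.1),
    "conv_count": ("negbinom", 2.0, 0.6),
    "loc_distance": ("lognormal", -0.5, 1.3),
    "unlock_duration": ("lognormal", 1.0, 0.8),
    "unique_locations": ("negbinom", 1.5, 0.7),
}

# crude diurnal activity profile: quiet overnight hours
_NIGHT_HOURS = np.arange(24) < 6
_DIURNAL = np.where(_NIGHT_HOURS, 0.15, 1.0)


@dataclass(frozen=True)
class LinkSpec:
    """Behavior -> symptom link on the normalized 0-3 outcome scale.

    The latent score is ``intercept + amplitude * f(sum_v w_v * m_v) +
    noise`` where m_v is the standardized noiseless trailing 3-day mean of
    variable v's day summary and f depends on ``form``.  The score is
    discretized onto ``grid``: by nearest grid value, or — when
    ``category_priors`` is given — by pooled quantile thresholds so that the
    marginal category fractions match the priors.
    """

    weights: dict = field(default_factory=dict)
    noise_scale: float = 0.5
    form: str = "linear"
    grid: tuple = (0.0, 1.0, 2.0, 3.0)
    intercept: float = 1.5
    amplitude: float = 1.0
    category_priors: tuple | None = None

    def __post_init__(self):
        if self.noise_scale < 0:
            raise ConfigurationError("noise scale must be >= 0")
        if self.form not in ("linear", "threshold", "saturating"):
            raise ConfigurationError(f"unknown link form {self.form!r}")
        w = np.asarray(list(self.weights.values()), dtype=float)
        if w.size and not np.all(np.isfinite(w)):
            raise ConfigurationError("link weights must be finite")
        g = np.asarray(self.grid, dtype=float)
        if not (np.all(np.diff(g) > 0) and g[0] >= 0.0 and g[-1] <= 3.0):
            raise ConfigurationError("grid must be ascending within [0,3]")
        if self.category_priors is not None:
            p = np.asarray(self.category_priors, dtype=float)
            if len(p) != len(g) or np.any(p < 0) or not math.isclose(
                p.sum(), 1.0, abs_tol=1e-9
            ):
                raise ConfigurationError(
                    "category priors must be a probability vector over the grid"
                )

    def negated(self) -> "LinkSpec":
        return replace(self, weights={k: -v for k, v in self.weights.items()})


@dataclass(frozen=True)
class ScheduleSpec:
    """EMA delivery schedule: fixed Mon/Wed/Fri or Bernoulli day selection."""

    kind: str = "mwf"
    period_days: float = 2.5
    jitter_minutes: float = 0.0

    def __post_init__(self):
        if self.kind not in ("mwf", "bernoulli"):
            raise ConfigurationError(f"unknown schedule kind {self.kind!r}")
        if self.period_days <= 0:
            raise ConfigurationError("period must be > 0")


@dataclass(frozen=True)
class ShiftSpec:
    """Study-level transform of the shared sensing family plus EMA cadence."""

    loc_shift: dict = field(default_factory=dict)
    scale_mult: dict = field(default_factory=dict)
    missing_day_rate: float = 0.0
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)

    def __post_init__(self):
        if not 0.0 <= self.missing_day_rate <= 1.0:
            raise ConfigurationError("missingness rate must be in [0,1]")
        if any(s <= 0 for s in self.scale_mult.values()):
            raise ConfigurationError("scale multipliers must be > 0")


@dataclass(frozen=True)
class StudyConfig:
    study_id: str
    n_subjects: int
    n_days: int
    links: dict = field(default_factory=dict)  # item -> LinkSpec
    shift: ShiftSpec = field(default_factory=ShiftSpec)
    seed: int = 0
    variables: tuple = tuple(ALL_VARIABLES)
    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    battery: str = "crosscheck"
    start_date: str = "2015-01-05"
    raw_derived: bool = False
    subject_sd: float = 0.3
    emit_full_battery: bool = True

    def __post_init__(self):
        if self.n_subjects <= 0 or self.n_days <= 0:
            raise ConfigurationError("n subjects and n days must be positive")
        if set(self.variables) != set(ALL_VARIABLES):
            raise ConfigurationError(
                "variable list must cover the eight aligned sensing variables "
                "plus the three sleep variables"
            )
        if self.battery not in ("crosscheck", "studentlife"):
            raise ConfigurationError(f"unknown battery {self.battery!r}")

    def battery_mappings(self) -> dict[str, EmaMapping]:
        return (
            crosscheck_battery()
            if self.battery == "crosscheck"
            else studentlife_battery()
        )


@dataclass
class StudyDataset:
    study_id: str
    sensing: pd.DataFrame
    ema: pd.DataFrame

    def validate(self) -> None:
        subjects = set(self.sensing["subject"].unique())
        missing = set(self.ema["subject"].unique()) - subjects
        if missing:
            raise ValueError(f"EMA subjects without sensor records: {missing}")


def priors_from_severe(
    severe_frac: float, n_categories: int = 4, severe_low: bool = False
) -> tuple:
    """Category priors placing ``severe_frac`` mass on the two severe levels.

    Severe levels sit at the high end of the ascending grid (stress-like)
    unless ``severe_low`` (sleep-quality-like).
    """
    if not 0.0 < severe_frac < 1.0:
        raise ConfigurationError("severe fraction must be in (0,1)")
    if n_categories < 3:
        raise ConfigurationError("need at least 3 categories")
    sev = severe_frac / 2.0
    rest = (1.0 - severe_frac) / (n_categories - 2)
    if severe_low:
        return tuple([sev, sev] + [rest] * (n_categories - 2))
    return tuple([rest] * (n_categories - 2) + [sev, sev])


# ---------------------------------------------------------------------------
# generation internals


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # keyed substream: independent of total subject count
    return np.random.default_rng(np.random.SeedSequence([seed, 1000 + subject_index]))


def _draw_hourly(
    rng: np.random.Generator, family: tuple, n_days: int, subject_mult: float
) -> np.ndarray:
    kind, a, b = family
    shape = (n_days, 24)
    if kind == "lognormal":
        vals = rng.lognormal(mean=a, sigma=b, size=shape) * subject_mult
        return vals * _DIURNAL
    if kind == "negbinom":
        lam = rng.gamma(shape=a, scale=(1 - b) / b, size=shape) * subject_mult
        return rng.poisson(lam * _DIURNAL).astype(float)
    raise ConfigurationError(f"unknown marginal family {kind!r}")


def _day_summary(hourly: np.ndarray, variable: str) -> np.ndarray:
    # all declared aggregations total the hourly values
    del variable
    return hourly.sum(axis=1)


def _trailing_mean(day_values: np.ndarray, window: int = 3) -> np.ndarray:
    s = pd.Series(day_values)
    return s.rolling(window, min_periods=1).mean().to_numpy()


def _apply_link(link: LinkSpec, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if link.form == "linear":
        f = z
    elif link.form == "threshold":
        f = np.where(z > 0, 1.0, -1.0)
    else:  # saturating
        f = np.tanh(z)
    noise = rng.normal(0.0, link.noise_scale, size=z.shape) if link.noise_scale else 0.0
    return link.intercept + link.amplitude * f + noise


def _discretize(scores: np.ndarray, link: LinkSpec) -> np.ndarray:
    grid = np.asarray(link.grid, dtype=float)
    if link.category_priors is None:
        idx = np.abs(scores[:, None] - grid[None, :]).argmin(axis=1)
        return grid[idx]
    cum = np.cumsum(link.category_priors)[:-1]
    thresholds = np.quantile(scores, cum)
    idx = np.searchsorted(thresholds, scores, side="right")
    return grid[idx]


def _raw_from_normalized(value: float, mapping: EmaMapping):
    best = min(mapping.raw_domain, key=lambda r: abs(mapping.gen_scale[r] - value))
    return best


# ---------------------------------------------------------------------------
# public operations


def generate_study(config: StudyConfig) -> StudyDataset:
    """Generate one study's sensing and EMA tables.

    Sensing values are heavy-tailed and non-negative; EMA values are
    produced by applying each item's link to the subject's noiseless
    trailing 3-day behavior summary, then discretizing to the outcome grid
    and inverting the study's raw response scale.  Reproducible for a fixed
    (config, seed).
    """
    dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    battery = config.battery_mappings()
    schedule = config.shift.schedule

    sensing_frames = []
    day_summaries: dict[str, list[np.ndarray]] = {v: [] for v in EPOCH_VARIABLES}
    sleep_values: dict[str, list[np.ndarray]] = {v: [] for v in SLEEP_VARIABLES}
    subjects = [f"{config.study_id}_s{i:03d}" for i in range(config.n_subjects)]
    ema_day_masks = []
    ema_minutes = []

    for i, subject in enumerate(subjects):
        rng = _subject_rng(config.seed, i)
        subj_mult = {
            v: float(np.exp(rng.normal(0.0, config.subject_sd)))
            for v in EPOCH_VARIABLES
        }
        hourly_blocks = {}
        for v in EPOCH_VARIABLES:
            vals = _draw_hourly(rng, config.marginals[v], config.n_days, subj_mult[v])
            loc = config.shift.loc_shift.get(v, 0.0)
            scale = config.shift.scale_mult.get(v, 1.0)
            vals = np.maximum(loc + scale * vals, 0.0)
            hourly_blocks[v] = vals
            day_summaries[v].append(_day_summary(vals, v))

        onset = rng.normal(-0.5, 0.5, size=config.n_days) + config.shift.loc_shift.get(
            "sleep_onset", 0.0
        )
        duration = np.clip(
            rng.normal(7.5, 0.8, size=config.n_days)
            + config.shift.loc_shift.get("sleep_duration", 0.0),
            3.0,
            None,
        )
        wake = onset + duration
        sleep_values["sleep_onset"].append(onset)
        sleep_values["sleep_wake"].append(wake)
        sleep_values["sleep_duration"].append(duration)

        # long-format hourly rows for this subject
        n = config.n_days * 24
        frame = pd.DataFrame(
            {
                "subject": np.repeat(subject, n * len(EPOCH_VARIABLES)),
                "study": config.study_id,
                "date": np.tile(np.repeat(dates, 24), len(EPOCH_VARIABLES)),
                "variable": np.repeat(EPOCH_VARIABLES, n),
                "hour": np.tile(np.tile(np.arange(24), config.n_days),
                                len(EPOCH_VARIABLES)),
                "value": np.concatenate(
                    [hourly_blocks[v].ravel() for v in EPOCH_VARIABLES]
                ),
            }
        )
        sleep_frame = pd.DataFrame(
            {
                "subject": subject,
                "study": config.study_id,
                "date": np.tile(dates, len(SLEEP_VARIABLES)),
                "variable": np.repeat(SLEEP_VARIABLES, config.n_days),
                "hour": np.nan,
                "value": np.concatenate(
                    [sleep_values[v][-1] for v in SLEEP_VARIABLES]
                ),
            }
        )
        sensing_frames.append(frame)
        sensing_frames.append(sleep_frame)

        # EMA occasions for this subject
        if schedule.kind == "mwf":
            mask = np.isin(dates.weekday, (0, 2, 4))
        else:
            mask = rng.random(config.n_days) < 1.0 / schedule.period_days
        ema_day_masks.append(mask)
        jitter = (
            rng.uniform(-schedule.jitter_minutes, schedule.jitter_minutes,
                        size=config.n_days)
            if schedule.jitter_minutes
            else np.zeros(config.n_days)
        )
        ema_minutes.append(jitter)

    sensing = pd.concat(sensing_frames, ignore_index=True)

    # standardized noiseless trailing means driving the links
    z_summaries: dict[str, np.ndarray] = {}
    for v in EPOCH_VARIABLES + SLEEP_VARIABLES:
        source = day_summaries if v in day_summaries else sleep_values
        stacked = np.stack(source[v])  # (n_subjects, n_days)
        mu, sd = stacked.mean(), stacked.std()
        z = (stacked - mu) / (sd if sd > 0 else 1.0)
        z_summaries[v] = np.stack([_trailing_mean(row) for row in z])

    # latent scores per linked item (pooled for prior calibration)
    linked_items = {item: link for item, link in config.links.items()
                    if item in battery}
    scores: dict[str, np.ndarray] = {}
    for item, link in linked_items.items():
        combined = np.zeros((config.n_subjects, config.n_days))
        for v, w in link.weights.items():
            combined += w * z_summaries[v]
        per_subj = []
        for i in range(config.n_subjects):
            rng_link = np.random.default_rng(
                np.random.SeedSequence(
                    [config.seed, 5000 + i, zlib.crc32(item.encode())]
                )
            )
            per_subj.append(_apply_link(link, combined[i], rng_link))
        scores[item] = np.stack(per_subj)

    ema_rows = []
    mask_all = np.stack(ema_day_masks)
    normalized_by_item = {
        item: _discretize(scores[item][mask_all], link)
        for item, link in linked_items.items()
    }
    # walk occasions in subject-major order to consume calibrated values
    cursors = {item: 0 for item in linked_items}
    filler_items = [
        it for it in battery if config.emit_full_battery and it not in linked_items
    ]
    for i, subject in enumerate(subjects):
        rng_fill = np.random.default_rng(
            np.random.SeedSequence([config.seed, 9000 + i])
        )
        occ_days = np.nonzero(mask_all[i])[0]
        for d in occ_days:
            ts = dates[d] + pd.Timedelta(hours=18, minutes=float(ema_minutes[i][d]))
            for item, link in linked_items.items():
                mapping = battery[item]
                norm_val = normalized_by_item[item][cursors[item]]
                cursors[item] += 1
                raw = _raw_from_normalized(float(norm_val), mapping)
                ema_rows.append((subject, config.study_id, ts, item, raw))
            for item in filler_items:
                mapping = battery[item]
                order = mapping.severity_order()
                probs = np.array([0.4, 0.3, 0.2, 0.1][: len(order)], dtype=float)
                probs = probs / probs.sum()
                raw = order[rng_fill.choice(len(order), p=probs)]
                ema_rows.append((subject, config.study_id, ts, item, raw))

    ema = pd.DataFrame(
        ema_rows, columns=["subject", "study", "timestamp", "item", "raw_value"]
    )
    dataset = StudyDataset(config.study_id, sensing, ema)
    if config.shift.missing_day_rate > 0:
        dataset = inject_missingness(
            dataset, config.shift.missing_day_rate, seed=config.seed + 77
        )
    return dataset


def generate_paired_studies(
    config_a: StudyConfig, config_b: StudyConfig, shared_link: bool = True
) -> tuple[StudyDataset, StudyDataset]:
    """Generate two studies with study B drawn from study A's sensing family.

    B's marginals are A's marginals transformed by B's ShiftSpec.  With
    ``shared_link`` the two studies use identical links; otherwise B's link
    weights are negated (negative-transfer scenario).
    """
    if set(config_a.variables) != set(config_b.variables):
        raise ConfigurationError("variable lists differ between studies")
    links_b = dict(config_a.links)
    if not shared_link:
        links_b = {item: link.negated() for item, link in links_b.items()}
    # keep B's own battery/grids but inherit A's link structure
    links_b = {
        item: replace(link, grid=config_b.links[item].grid,
                      category_priors=config_b.links[item].category_priors)
        if item in config_b.links
        else link
        for item, link in links_b.items()
    }
    config_b = replace(config_b, marginals=dict(config_a.marginals), links=links_b)
    return generate_study(config_a), generate_study(config_b)


def inject_missingness(
    dataset: StudyDataset, day_rate: float, seed: int = 0
) -> StudyDataset:
    """Drop each subject-day of sensing independently with ``day_rate``.

    EMA records are untouched.
    """
    if not 0.0 <= day_rate <= 1.0:
        raise ConfigurationError("day rate must be in [0,1]")
    if day_rate == 0.0:
        return dataset
    sensing = dataset.sensing
    days = sensing[["subject", "date"]].drop_duplicates().reset_index(drop=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 424242]))
    drop = days[rng.random(len(days)) < day_rate]
    if drop.empty:
        return StudyDataset(dataset.study_id, sensing.copy(), dataset.ema.copy())
    merged = sensing.merge(drop, on=["subject", "date"], how="left", indicator=True)
    kept = merged[merged["_merge"] == "left_only"].drop(columns="_merge")
    return StudyDataset(
        dataset.study_id, kept.reset_index(drop=True), dataset.ema.copy()
    )


# ---------------------------------------------------------------------------
# convenience configurations


def clinical_study_config(
    n_subjects: int = 10,
    n_days: int = 60,
    seed: int = 0,
    noise_scale: float = 0.5,
    severe_frac: float | None = None,
    items: tuple = ("sleep", "stress"),
    **kwargs,
) -> StudyConfig:
    """Clinical-style study: 10-item 0-3 battery, Mon/Wed/Fri cadence."""
    weights = {
        "sleep": {"act_still": 0.4, "unlock_duration": -0.5, "sleep_duration": 0.0},
        "stress": {"act_foot": 0.5, "conv_count": 0.4, "loc_distance": 0.3},
    }
    links = {}
    for item in items:
        severe_low = item == "sleep"
        priors = (
            priors_from_severe(severe_frac, 4, severe_low=severe_low)
            if severe_frac is not None
            else None
        )
        links[item] = LinkSpec(
            weights=weights.get(item, {}),
            noise_scale=noise_scale,
            category_priors=priors,
        )
    return StudyConfig(
        study_id="studyA",
        n_subjects=n_subjects,
        n_days=n_days,
        links=links,
        seed=seed,
        battery="crosscheck",
        start_date="2015-01-05",
        shift=ShiftSpec(schedule=ScheduleSpec(kind="mwf")),
        **kwargs,
    )


def student_study_config(
    n_subjects: int = 10,
    n_days: int = 60,
    seed: int = 1,
    noise_scale: float = 0.5,
    severe_frac: float | None = None,
    loc_shift: dict | None = None,
    scale_mult: dict | None = None,
    missing_day_rate: float = 0.0,
    ema_period_days: float = 2.5,
    **kwargs,
) -> StudyConfig:
    """Student-style study: 1-4 sleep / 1-5 stress scales, irregular EMAs."""
    battery = studentlife_battery()
    links = {}
    for item in ("sleep", "stress"):
        grid = tuple(sorted(battery[item].gen_scale.values()))
        severe_low = item == "sleep"
        priors = (
            priors_from_severe(severe_frac, len(grid), severe_low=severe_low)
            if severe_frac is not None
            else None
        )
        links[item] = LinkSpec(
            weights={}, noise_scale=noise_scale, grid=grid, category_priors=priors
        )
    return StudyConfig(
        study_id="studyB",
        n_subjects=n_subjects,
        n_days=n_days,
        links=links,
        seed=seed,
        battery="studentlife",
        start_date="2013-04-01",
        raw_derived=True,
        shift=ShiftSpec(
            loc_shift=loc_shift or {},
            scale_mult=scale_mult or {},
            missing_day_rate=missing_day_rate,
            schedule=ScheduleSpec(kind="bernoulli", period_days=ema_period_days),
        ),
        **kwargs,
    )
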
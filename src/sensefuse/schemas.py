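"""Column names, aligned sensing variables, and the canonical feature layout.

The model input for one EMA-aligned instance is a 44-vector: eight sensing
variables summarized as one whole-day value plus four 6-hour epoch values
(8 x 5 = 40), three day-level sleep values, and a counter of missing days
inside the trailing averaging window.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# long-format sensing table (one row per subject/date/variable/hour)
SENSING_COLUMNS = ["subject", "study", "date", "variable", "hour", "value"]

# EMA response table (raw scale, one row per response)
EMA_COLUMNS = ["subject", "study", "timestamp", "item", "raw_value"]

# aligned instance table = keys + features + outcome
INSTANCE_KEY_COLUMNS = ["subject", "study", "timestamp", "item"]
OUTCOME_COLUMNS = ["outcome", "severe"]

# ---------------------------------------------------------------------------
# sensing variables aligned across the two studies
DURATION_VARIABLES = [
    "act_foot",
    "act_still",
    "act_unknown",
    "conv_duration",
    "unlock_duration",
]
COUNT_VARIABLES = ["conv_count", "unique_locations"]
DISTANCE_VARIABLES = ["loc_distance"]

#: variables summarized per day plus per 6-hour epoch
EPOCH_VARIABLES = (
    DURATION_VARIABLES[:3]
    + ["conv_duration", "conv_count"]
    + DISTANCE_VARIABLES
    + ["unlock_duration", "unique_locations"]
)

#: day-level-only sleep variables (no epoch breakdown)
SLEEP_VARIABLES = ["sleep_onset", "sleep_wake", "sleep_duration"]

ALL_VARIABLES = EPOCH_VARIABLES + SLEEP_VARIABLES

#: per-variable aggregation used for the day/epoch summaries
AGGREGATION_MAP = {
    **{v: "sum" for v in DURATION_VARIABLES},
    **{v: "count" for v in COUNT_VARIABLES},
    **{v: "sum" for v in DISTANCE_VARIABLES},
}

# 6-hour epochs, half-open [start, end); a value at exactly hour 6 belongs
# to the 6AM-12PM epoch
EPOCHS = [(0, 6), (6, 12), (12, 18), (18, 24)]
EPOCH_SUFFIXES = ["00_06", "06_12", "12_18", "18_24"]

MISSING_DAYS_FEATURE = "missing_days"


def epoch_feature_names(variable: str) -> list[str]:
    """The five feature names emitted for one epoch-aggregated variable."""
    return [f"{variable}_day"] + [f"{variable}_{s}" for s in EPOCH_SUFFIXES]


#: 43 sensor-derived feature columns, in canonical order
SENSOR_FEATURE_COLUMNS: list[str] = sum(
    (epoch_feature_names(v) for v in EPOCH_VARIABLES), []
) + SLEEP_VARIABLES

#: the full 44-feature layout (sensor features + missing-day counter)
FEATURE_COLUMNS: list[str] = SENSOR_FEATURE_COLUMNS + [MISSING_DAYS_FEATURE]

SLEEP_FEATURE_COLUMNS = list(SLEEP_VARIABLES)

N_SENSOR_FEATURES = len(SENSOR_FEATURE_COLUMNS)  # 43
N_FEATURES = len(FEATURE_COLUMNS)  # 44
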
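import logging

import numpy as np
import pandas as pd
import pytest

from sensefuse import harmonize, synth
from sensefuse.schemas import FEATURE_COLUMNS

# keep SMOTE singleton-class warnings out of the test output
logging.getLogger("sensefuse.training").setLevel(logging.ERROR)


BATTERIES = {
    "studyA": harmonize.crosscheck_battery(),
    "studyB": harmonize.studentlife_battery(),
}


def make_paired_instances(
    n_subjects=6,
    n_days=40,
    seed=3,
    item="stress",
    shared_link=True,
    subject_sd=0.3,
    noise_scale=0.5,
    severe_frac=None,
    loc_shift=None,
    ema_period_days=2.5,
):
    """Generate, pool and harmonize a small paired-study dataset."""
    ca = synth.clinical_study_config(
        n_subjects=n_subjects, n_days=n_days, seed=seed,
        noise_scale=noise_scale, severe_frac=severe_frac,
        subject_sd=subject_sd,
    )
    cb = synth.student_study_config(
        n_subjects=n_subjects, n_days=n_days, seed=seed + 1,
        noise_scale=noise_scale, severe_frac=severe_frac,
        loc_shift=loc_shift or {"act_still": 15.0},
        ema_period_days=ema_period_days, subject_sd=subject_sd,
    )
    a, b = synth.generate_paired_studies(ca, cb, shared_link=shared_link)
    sensing = pd.concat([a.sensing, b.sensing], ignore_index=True)
    ema = pd.concat([a.ema, b.ema], ignore_index=True)
    inst = harmonize.harmonize_study(
        sensing, ema, BATTERIES, raw_derived_studies={"studyB"}
    )
    return inst[inst["item"] == item].reset_index(drop=True)


@pytest.fixture(scope="session")
def small_instances():
    return make_paired_instances()


def toy_instances(n_subjects_a=3, n_subjects_b=3, per_subject=30, seed=0):
    """Random feature instances with the canonical 44-column layout."""
    rng = np.random.default_rng(seed)
    rows = []
    for study, n in (("studyA", n_subjects_a), ("studyB", n_subjects_b)):
        for i in range(n):
            subject = f"{study}_s{i:03d}"
            for j in range(per_subject):
                feats = rng.normal(size=len(FEATURE_COLUMNS))
                rows.append(
                    {
                        "subject": subject,
                        "study": study,
                        "timestamp": pd.Timestamp("2020-01-01")
                        + pd.Timedelta(days=j),
                        "item": "stress",
                        **dict(zip(FEATURE_COLUMNS, feats)),
                        "outcome": float(rng.integers(0, 4)),
                        "severe": 0,
                    }
                )
    return pd.DataFrame(rows)
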
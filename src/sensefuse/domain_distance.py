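"""Proxy-A distance between training pools and held-out subjects.

PAD = 2(1 - 2*eps), where eps is the cross-validated misclassification rate
of a linear support-vector classifier trained to tell training instances
from held-out instances.  With 0/1 labels the misclassification rate equals
the classifier's mean absolute error.  Small PAD means the classifier
cannot separate the two samples, i.e. the distributions are similar;
negative values are possible and preserved.

Protocol: features standardized on the pooled two-class task, the majority
side subsampled (seeded) to the minority size so eps is not dominated by
imbalance, C = 1, stratified 5-fold cross-validation (folds reduced when a
side is small; fewer than 2 instances per side is undefined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .harmonize import select_validation_subjects
from .schemas import FEATURE_COLUMNS
from .training import build_training_set, personalize_training_set, _k_label

logger = logging.getLogger(__name__)

__all__ = ["PADRecord", "proxy_a_distance", "pad_table"]


@dataclass(frozen=True)
class PADRecord:
    subject: object
    item: str
    mode: str
    k: str
    epsilon: float
    pad: float
    n_held_out: int
    n_train: int


def proxy_a_distance(
    train_features: np.ndarray,
    held_out_features: np.ndarray,
    seed: int = 0,
    n_folds: int = 5,
    C: float = 1.0,
) -> tuple[float, float, int]:
    """Return (epsilon, PAD, folds used) for one train/held-out pair."""
    A = np.atleast_2d(np.asarray(train_features, dtype=float))
    B = np.atleast_2d(np.asarray(held_out_features, dtype=float))
    if len(A) < 2 or len(B) < 2:
        raise ValueError("need at least 2 instances per side")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 271828]))
    n = min(len(A), len(B))
    if len(A) > n:
        A = A[rng.choice(len(A), n, replace=False)]
    if len(B) > n:
        B = B[rng.choice(len(B), n, replace=False)]

    X = np.vstack([A, B])
    y = np.concatenate([np.zeros(len(A)), np.ones(len(B))])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X = (X - mu) / sd

    folds = min(n_folds, n)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                               random_state=int(rng.integers(2**31)))
    errors = []
    for tr, te in splitter.split(X, y):
        clf = LinearSVC(C=C, max_iter=5000, dual="auto")
        clf.fit(X[tr], y[tr])
        errors.append(float(np.mean(clf.predict(X[te]) != y[te])))
    eps = float(np.mean(errors))
    return eps, 2.0 * (1.0 - 2.0 * eps), folds


def pad_table(
    instances: pd.DataFrame,
    seed: int = 0,
    modes: tuple = ("single", "combined"),
    ks: tuple = (5, 10, 50, 100, 500, None),
    min_ema: int = 30,
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """PAD between every validation subject and each candidate training pool.

    The pool is assembled and personalized exactly as in the LOSO engine
    (same build + k-nearest-neighbor restriction), so rows join the MAE
    results on (subject, mode, k).  Pairs with fewer than 2 usable
    instances per side are skipped with a warning.
    """
    feature_columns = feature_columns or FEATURE_COLUMNS
    subjects = select_validation_subjects(instances, min_ema=min_ema)
    item = instances["item"].iloc[0] if len(instances) else ""
    rows = []
    for si, subject in enumerate(subjects):
        held = instances[instances["subject"] == subject]
        held_X = held[feature_columns].to_numpy(dtype=float)
        for mode in modes:
            base = build_training_set(instances, subject, mode, feature_columns)
            for k in ks:
                pool = personalize_training_set(base, held_X, k)
                if len(pool) < 2 or len(held_X) < 2:
                    logger.warning(
                        "PAD undefined for subject %s mode %s k %s", subject,
                        mode, _k_label(k),
                    )
                    continue
                eps, pad, _ = proxy_a_distance(
                    pool.X, held_X, seed=seed + si
                )
                rows.append(
                    PADRecord(
                        subject=subject, item=item, mode=mode, k=_k_label(k),
                        epsilon=eps, pad=pad, n_held_out=len(held_X),
                        n_train=len(pool),
                    )
                )
    return pd.DataFrame([r.__dict__ for r in rows])
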
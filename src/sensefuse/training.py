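"""Leave-one-subject-out experiment engine.

For each validation subject the engine assembles a training pool (same-study
or both studies, never the held-out subject), optionally restricts it to the
k nearest neighbors of the subject's feature vectors, optionally balances
outcome categories with SMOTE, fits a Huber-loss gradient-boosted tree
regressor per hyperparameter setting, and emits per-instance predictions.

Fold hygiene: feature standardization, neighbor search, and SMOTE are all
computed inside the fold, on data excluding the held-out subject.  Tree
subsampling is disabled and neighbor ties break by stable input order, so a
full grid run is reproducible from the master seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.neighbors import NearestNeighbors

from .harmonize import select_validation_subjects
from .schemas import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "Hyperparams",
    "HyperGrid",
    "TrainSet",
    "build_training_set",
    "personalize_training_set",
    "smote_oversample",
    "fit_model",
    "run_loso_grid",
]

LEARNING_RATES = (0.001, 0.01, 0.1, 1.0)
N_TREES = (20, 100, 1000)
TREE_DEPTHS = (3, 7, 10)
SMOTE_FLAGS = (True, False)
NEIGHBOR_KS = (5, 10, 50, 100, 500, None)  # None = all
MODES = ("single", "combined", "baseline")

OUTCOME_CLIP = (0.0, 3.0)


def _k_label(k) -> str:
    return "all" if k is None else str(int(k))


@dataclass(frozen=True)
class Hyperparams:
    learning_rate: float = 0.1
    n_trees: int = 100
    depth: int = 3
    smote: bool = False
    k: int | None = None
    mode: str = "combined"

    def __post_init__(self):
        if self.learning_rate not in LEARNING_RATES:
            raise ValueError(f"learning rate {self.learning_rate} not in grid")
        if self.n_trees not in N_TREES:
            raise ValueError(f"tree count {self.n_trees} not in grid")
        if self.depth not in TREE_DEPTHS:
            raise ValueError(f"depth {self.depth} not in grid")
        if self.k is not None and self.k not in NEIGHBOR_KS:
            raise ValueError(f"neighbor count {self.k} not in grid")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class HyperGrid:
    """Cross-product hyperparameter grid; the full default has 432 points."""

    learning_rates: tuple = LEARNING_RATES
    n_trees: tuple = N_TREES
    depths: tuple = TREE_DEPTHS
    smote: tuple = SMOTE_FLAGS
    ks: tuple = NEIGHBOR_KS

    @property
    def size(self) -> int:
        return (
            len(self.learning_rates)
            * len(self.n_trees)
            * len(self.depths)
            * len(self.smote)
            * len(self.ks)
        )

    def configs(self, mode: str = "combined"):
        for k, sm, lr, nt, d in itertools.product(
            self.ks, self.smote, self.learning_rates, self.n_trees, self.depths
        ):
            yield Hyperparams(
                learning_rate=lr, n_trees=nt, depth=d, smote=sm, k=k, mode=mode
            )


@dataclass
class TrainSet:
    """One fold's training pool with its own standardization parameters."""

    X: np.ndarray  # raw-space features
    y: np.ndarray
    subjects: np.ndarray
    mean: np.ndarray = field(default=None)
    scale: np.ndarray = field(default=None)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mean is None:
            self._refit_scaler()

    def _refit_scaler(self):
        self.mean = self.X.mean(axis=0) if len(self.X) else np.zeros(self.X.shape[1])
        sd = self.X.std(axis=0) if len(self.X) else np.ones(self.X.shape[1])
        sd = np.where(sd > 0, sd, 1.0)
        self.scale = sd

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale

    def unstandardize(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.scale + self.mean

    def __len__(self) -> int:
        return len(self.y)


def build_training_set(
    instances: pd.DataFrame,
    held_out_subject,
    mode: str,
    feature_columns: list[str] | None = None,
) -> TrainSet:
    """Assemble the fold's training pool for one held-out subject.

    ``single`` restricts to the held-out subject's own study; ``combined``
    uses both studies; ``baseline`` mirrors the requested pool but is fitted
    as a constant mean predictor downstream.  The held-out subject is always
    excluded.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    feature_columns = feature_columns or FEATURE_COLUMNS
    mask = instances["subject"] != held_out_subject
    if mode == "single":
        study = instances.loc[
            instances["subject"] == held_out_subject, "study"
        ]
        if study.empty:
            raise ValueError(f"held-out subject {held_out_subject!r} not found")
        mask &= instances["study"] == study.iloc[0]
    pool = instances.loc[mask]
    return TrainSet(
        X=pool[feature_columns].to_numpy(dtype=float),
        y=pool["outcome"].to_numpy(dtype=float),
        subjects=pool["subject"].to_numpy(),
        provenance={"mode": mode, "held_out": held_out_subject},
    )


def personalize_training_set(
    train: TrainSet, held_out_X: np.ndarray, k: int | None
) -> TrainSet:
    """Restrict the pool to the union of each held-out instance's k nearest
    training instances (Euclidean distance in the train-set standardized
    space).  ``k=None`` ("all") returns the pool unchanged."""
    if k is None:
        return train
    if k > len(train):
        logger.info(
            "personalization k=%d exceeds training size %d; keeping full set",
            k, len(train),
        )
        return train
    nn = NearestNeighbors(n_neighbors=k, algorithm="brute")
    nn.fit(train.standardize(train.X))
    _, idx = nn.kneighbors(train.standardize(np.atleast_2d(held_out_X)))
    keep = np.unique(idx.ravel())
    out = TrainSet(
        X=train.X[keep],
        y=train.y[keep],
        subjects=train.subjects[keep],
        provenance={**train.provenance, "k": k},
    )
    return out


def _outcome_classes(y: np.ndarray) -> np.ndarray:
    # balancing classes live on the common rounded {0,1,2,3} grid
    return np.round(np.clip(y, *OUTCOME_CLIP)).astype(int)


def smote_oversample(
    train: TrainSet, k_neighbors: int = 5, seed: int = 0
) -> TrainSet:
    """Equalize outcome-category counts with synthetic minority points.

    Features are standardized (train-set parameters) before neighbor search
    and interpolation, then mapped back; each synthetic point lies on the
    segment between a minority point and one of its ``k_neighbors`` nearest
    same-class neighbors, and inherits the class outcome value.  Classes
    smaller than ``k_neighbors + 1`` use the largest feasible k; singleton
    classes are duplicated with a warning.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31337]))
    classes = _outcome_classes(train.y)
    labels, counts = np.unique(classes, return_counts=True)
    target = counts.max()
    Z = train.standardize(train.X)

    new_Z, new_y, new_subj = [], [], []
    for label, count in zip(labels, counts):
        deficit = target - count
        if deficit == 0:
            continue
        members = np.nonzero(classes == label)[0]
        Zc = Z[members]
        if count == 1:
            logger.warning("singleton outcome class %s duplicated for SMOTE", label)
            picks = np.zeros(deficit, dtype=int)
            synth = np.repeat(Zc, deficit, axis=0)
        else:
            kc = min(k_neighbors, count - 1)
            nn = NearestNeighbors(n_neighbors=kc + 1, algorithm="brute").fit(Zc)
            _, neigh = nn.kneighbors(Zc)  # col 0 is self
            picks = rng.integers(0, count, size=deficit)
            chosen = neigh[picks, rng.integers(1, kc + 1, size=deficit)]
            lam = rng.random(deficit)[:, None]
            synth = Zc[picks] + lam * (Zc[chosen] - Zc[picks])
        new_Z.append(synth)
        new_y.append(np.full(deficit, float(label)))
        new_subj.append(train.subjects[members[picks]])

    if not new_Z:
        return train
    synth_X = train.unstandardize(np.vstack(new_Z))
    out = TrainSet(
        X=np.vstack([train.X, synth_X]),
        y=np.concatenate([train.y, *new_y]),
        subjects=np.concatenate([train.subjects, *new_subj]),
        mean=train.mean.copy(),
        scale=train.scale.copy(),
        provenance={**train.provenance, "smote": True},
    )
    return out


class _ConstantPredictor:
    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(np.atleast_2d(X)), self.value)


class _GbrtPredictor:
    def __init__(self, model, train: TrainSet):
        self.model = model
        self._train = train

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self._train.standardize(np.atleast_2d(X))
        return np.clip(self.model.predict(Z), *OUTCOME_CLIP)


def fit_model(train: TrainSet, hp: Hyperparams, seed: int = 0):
    """Fit a Huber-loss GBRT (or the constant-mean baseline) on one fold."""
    if len(train) == 0:
        raise ValueError("empty training set")
    if hp.mode == "baseline":
        return _ConstantPredictor(train.y.mean())
    model = GradientBoostingRegressor(
        loss="huber",
        learning_rate=hp.learning_rate,
        n_estimators=hp.n_trees,
        max_depth=hp.depth,
        subsample=1.0,
        max_features=None,
        random_state=seed,
    )
    model.fit(train.standardize(train.X), train.y)
    return _GbrtPredictor(model, train)


RECORD_COLUMNS = [
    "subject", "study", "item", "mode", "learning_rate", "n_trees", "depth",
    "smote", "k", "timestamp", "y_true", "y_pred",
]


def run_loso_grid(
    instances: pd.DataFrame,
    grid: HyperGrid,
    seed: int = 0,
    modes: tuple = ("single", "combined"),
    min_ema: int = 30,
    include_baseline: bool = True,
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Run the LOSO-CV experiment over the hyperparameter grid.

    Per fold the pipeline is: build pool -> personalize -> (re)standardize
    -> SMOTE -> fit -> predict, with predictions clipped to [0,3].  Returns
    one prediction record per (validation instance, hyperparams, mode), plus
    per-mode constant-mean baseline records when ``include_baseline``.
    """
    feature_columns = feature_columns or FEATURE_COLUMNS
    subjects = select_validation_subjects(instances, min_ema=min_ema)
    if not subjects:
        logger.warning("no validation subjects meet the >=%d EMA rule", min_ema)
        return pd.DataFrame(columns=RECORD_COLUMNS)
    item = instances["item"].iloc[0]

    records = []
    for si, subject in enumerate(subjects):
        held = instances[instances["subject"] == subject]
        held_X = held[feature_columns].to_numpy(dtype=float)
        held_y = held["outcome"].to_numpy(dtype=float)
        held_ts = held["timestamp"].to_numpy()
        study = held["study"].iloc[0]

        for mi, mode in enumerate(modes):
            base = build_training_set(instances, subject, mode, feature_columns)
            if len(base) == 0:
                logger.warning(
                    "empty %s-mode training pool for subject %s; skipped",
                    mode, subject,
                )
                continue
            if include_baseline:
                pred = np.full(len(held_y), base.y.mean())
                for ts, yt, yp in zip(held_ts, held_y, pred):
                    records.append(
                        (subject, study, item, f"baseline_{mode}", np.nan,
                         np.nan, np.nan, False, "all", ts, yt, yp)
                    )
            for ki, k in enumerate(grid.ks):
                pers = personalize_training_set(base, held_X, k)
                for smi, sm in enumerate(grid.smote):
                    pool = (
                        smote_oversample(
                            pers,
                            seed=int(
                                np.random.default_rng(
                                    np.random.SeedSequence(
                                        [seed, si, mi, ki, smi]
                                    )
                                ).integers(2**31)
                            ),
                        )
                        if sm
                        else pers
                    )
                    for lr in grid.learning_rates:
                        for nt in grid.n_trees:
                            for d in grid.depths:
                                hp = Hyperparams(
                                    learning_rate=lr, n_trees=nt, depth=d,
                                    smote=sm, k=k, mode=mode,
                                )
                                predictor = fit_model(pool, hp, seed=seed)
                                yp = predictor.predict(held_X)
                                for ts, yt, p in zip(held_ts, held_y, yp):
                                    records.append(
                                        (subject, study, item, mode, lr, nt, d,
                                         sm, _k_label(k), ts, yt, p)
                                    )
    return pd.DataFrame(records, columns=RECORD_COLUMNS)
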
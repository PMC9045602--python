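"""End-to-end experiment orchestration.

Ties the stages together: synthetic paired-study generation (or loading
tables from disk), harmonization, the LOSO hyperparameter grid, Proxy-A
distances, and the statistics layer.  Every run writes delimited-text
artifacts plus a manifest (config hash, seed, library versions) so a rerun
with the same config and seed reproduces the numeric tables bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .domain_distance import pad_table
from .harmonize import (
    crosscheck_battery,
    harmonize_study,
    studentlife_battery,
)
from .stats import (
    build_delta_rows,
    compare_distributions,
    mae_table,
    pad_mae_association,
    sensitivity_table,
    severity_table,
)
from .synth import (
    StudyConfig,
    clinical_study_config,
    generate_paired_studies,
    student_study_config,
)
from .training import HyperGrid, run_loso_grid

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "load_config", "run_experiment"]


@dataclass
class ExperimentConfig:
    study_a: StudyConfig
    study_b: StudyConfig
    shared_link: bool = True
    items: tuple = ("sleep", "stress")
    grid: HyperGrid = field(default_factory=HyperGrid)
    modes: tuple = ("single", "combined")
    alpha: float = 0.05
    fdr: float = 0.25
    window: int = 3
    min_hours: int = 19
    min_ema: int = 30
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        if self.alpha <= 0 or self.fdr <= 0 or self.window < 1:
            raise ValueError("thresholds must be positive")
        if self.min_hours < 0 or self.min_ema < 0:
            raise ValueError("thresholds must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "study_a": asdict(self.study_a),
                "study_b": asdict(self.study_b),
                "shared_link": self.shared_link,
                "items": list(self.items),
                "grid": asdict(self.grid),
                "modes": list(self.modes),
                "alpha": self.alpha,
                "fdr": self.fdr,
                "window": self.window,
                "min_hours": self.min_hours,
                "min_ema": self.min_ema,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file.

    Study sections accept the keyword arguments of
    :func:`sensefuse.synth.clinical_study_config` (study_a) and
    :func:`sensefuse.synth.student_study_config` (study_b); a ``grid``
    section overrides the default hyperparameter sets (``ks`` may contain
    ``null`` for "all neighbors").
    """
    raw = yaml.safe_load(Path(path).read_text())
    study_a = clinical_study_config(**raw.get("study_a", {}))
    study_b = student_study_config(**raw.get("study_b", {}))
    grid_kwargs = {
        key: tuple(v) for key, v in raw.get("grid", {}).items()
    }
    grid = HyperGrid(**grid_kwargs) if grid_kwargs else HyperGrid()
    kwargs = {
        k: raw[k]
        for k in (
            "shared_link", "alpha", "fdr", "window", "min_hours",
            "min_ema", "seed", "out_dir",
        )
        if k in raw
    }
    if "items" in raw:
        kwargs["items"] = tuple(raw["items"])
    if "modes" in raw:
        kwargs["modes"] = tuple(raw["modes"])
    return ExperimentConfig(study_a=study_a, study_b=study_b, grid=grid, **kwargs)


def _batteries(config: ExperimentConfig) -> dict:
    pick = {"crosscheck": crosscheck_battery, "studentlife": studentlife_battery}
    return {
        config.study_a.study_id: pick[config.study_a.battery](),
        config.study_b.study_id: pick[config.study_b.battery](),
    }


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def simulate_stage(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate both studies and return pooled sensing and EMA tables."""
    ds_a, ds_b = generate_paired_studies(
        config.study_a, config.study_b, shared_link=config.shared_link
    )
    ds_a.validate()
    ds_b.validate()
    sensing = pd.concat([ds_a.sensing, ds_b.sensing], ignore_index=True)
    ema = pd.concat([ds_a.ema, ds_b.ema], ignore_index=True)
    return sensing, ema


def harmonize_stage(
    config: ExperimentConfig, sensing: pd.DataFrame, ema: pd.DataFrame
) -> pd.DataFrame:
    raw_derived = {
        c.study_id for c in (config.study_a, config.study_b) if c.raw_derived
    }
    return harmonize_study(
        sensing,
        ema,
        _batteries(config),
        window=config.window,
        min_hours=config.min_hours,
        raw_derived_studies=raw_derived,
    )


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the manifest dictionary.  Artifacts: the pooled sensing/EMA
    tables, the aligned instance table, per-item prediction and PAD tables,
    per-subject MAE rows, paired delta rows, sensitivity-analysis summary,
    severity metric table, and the PAD-MAE association coefficient tables.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage: simulate")
    sensing, ema = simulate_stage(config)
    _write(sensing, out / "sensing.csv")
    _write(ema, out / "ema.csv")

    logger.info("stage: harmonize")
    instances = harmonize_stage(config, sensing, ema)
    _write(instances, out / "instances.csv")

    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "grid_size": config.grid.size,
        "modes": list(config.modes),
        "items": list(config.items),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {},
        "artifacts": ["sensing.csv", "ema.csv", "instances.csv"],
    }

    for item in config.items:
        inst = instances[instances["item"] == item].reset_index(drop=True)
        if inst.empty:
            logger.warning("no instances for item %s", item)
            continue
        logger.info("stage: loso grid (%s)", item)
        preds = run_loso_grid(
            inst, config.grid, seed=config.seed, modes=config.modes,
            min_ema=config.min_ema,
        )
        _write(preds, out / f"predictions_{item}.csv")

        logger.info("stage: pad (%s)", item)
        pads = pad_table(
            inst, seed=config.seed, modes=config.modes, ks=config.grid.ks,
            min_ema=config.min_ema,
        )
        _write(pads, out / f"pad_{item}.csv")

        logger.info("stage: statistics (%s)", item)
        maes = mae_table(preds)
        _write(maes, out / f"mae_{item}.csv")
        summary, detail = sensitivity_table(maes, alpha=config.alpha,
                                            fdr=config.fdr)
        _write(summary, out / f"sensitivity_summary_{item}.csv")
        _write(detail, out / f"sensitivity_detail_{item}.csv")
        deltas = build_delta_rows(maes, pads)
        _write(deltas, out / f"delta_rows_{item}.csv")

        severe_low = item == "sleep"
        core = preds[preds["mode"].isin(["single", "combined"])]
        sev = severity_table(core, severe_low=severe_low)
        _write(sev, out / f"severity_{item}.csv")

        try:
            assoc = pad_mae_association(deltas)
            _write(assoc.gee.assign(estimator="gee"), out / f"assoc_gee_{item}.csv")
            _write(assoc.lmm.assign(estimator="lmm"), out / f"assoc_lmm_{item}.csv")
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("association skipped for %s: %s", item, exc)

        # outcome distribution contrast across studies
        studies = inst["study"].unique()
        if len(studies) == 2:
            res = compare_distributions(
                inst.loc[inst["study"] == studies[0], "outcome"],
                inst.loc[inst["study"] == studies[1], "outcome"],
                kind="continuous",
            )
            pd.DataFrame([{
                "item": item, "test": res.name, "statistic": res.statistic,
                "p_value": res.p_value, "effect": res.effect_size,
                "effect_name": res.effect_name,
            }]).to_csv(out / f"outcome_contrast_{item}.csv", index=False)

        manifest["counts"][item] = {
            "instances": int(len(inst)),
            "prediction_records": int(len(preds)),
            "pad_rows": int(len(pads)),
            "grid_configs_per_mode": config.grid.size,
        }
        manifest["artifacts"].extend(
            [f"predictions_{item}.csv", f"pad_{item}.csv", f"mae_{item}.csv",
             f"sensitivity_summary_{item}.csv", f"delta_rows_{item}.csv",
             f"severity_{item}.csv"]
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
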
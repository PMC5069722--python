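"""High-level experiment runner wiring the modules into the study's three
analyses: classifier comparison, wrist-position search, and feature-set /
feature-count evaluation.

Every run writes delimited-text tables plus a provenance block (config
hash, seed, library versions) so outputs from different configurations are
never silently mixed.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import MUSCLE_SETS, Trial
from .evaluation import (
    EvalConfig,
    build_feature_matrix,
    evaluate_feature_matrix,
    make_two_fold_split,
    wrist_combo_search,
)
from .features import FEATURE_NAMES, named_feature_set
from .io import load_dataset
from .selection import (
    error_vs_count_curve,
    pca_ordering,
    reduced_set_99,
    selection_frequency,
    sfs_select,
    si_ordering,
)
from .synth import default_layout, generate_dataset, preset

__all__ = ["RunConfig", "run_experiment"]

EXPERIMENTS = (
    "classifier-comparison",
    "wrist-positions",
    "feature-sets",
    "feature-curves",
)


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one experiment run."""

    experiment: str
    dataset: str | None = None  # manifest path; None -> synthesize
    preset: str = "amputee-like"
    n_extrinsic: int = 3
    n_intrinsic: int = 2
    repetitions: int = 10
    seed: int = 0
    unit: str = "repetition"
    window_ms: float = 200.0
    increment_ms: float = 100.0
    muscle_sets: tuple[str, ...] = ("extrinsic", "intrinsic", "combined")
    classifiers: tuple[str, ...] = ("LDA", "QDA", "LNN", "MLPANN")
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        unknown = set(self.muscle_sets) - set(MUSCLE_SETS)
        if unknown:
            raise ValueError(f"unknown muscle set(s): {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def eval_config(self) -> EvalConfig:
        return EvalConfig(
            seed=self.seed,
            unit=self.unit,
            window_ms=self.window_ms,
            increment_ms=self.increment_ms,
        )


def _load_trials(cfg: RunConfig) -> list[Trial]:
    if cfg.dataset:
        return load_dataset(cfg.dataset)
    synth_cfg = preset(
        cfg.preset,
        layout=default_layout(cfg.n_extrinsic, cfg.n_intrinsic),
        repetitions=cfg.repetitions,
        seed=cfg.seed,
    )
    return generate_dataset(synth_cfg)


def _provenance(cfg: RunConfig) -> list[str]:
    return [
        f"# config_hash: {cfg.config_hash()}",
        f"# seed: {cfg.seed}",
        f"# python: {sys.version.split()[0]} numpy: {np.__version__} "
        f"pandas: {pd.__version__}",
    ]


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance(cfg)) + "\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def _classifier_comparison(trials, cfg: RunConfig, out: Path) -> pd.DataFrame:
    ec = cfg.eval_config()
    rows = []
    for mset in cfg.muscle_sets:
        fm = build_feature_matrix(trials, mset, "TDAR", ec)
        split = make_two_fold_split(fm, ec.unit, ec.seed)
        for kind in cfg.classifiers:
            rep = evaluate_feature_matrix(fm, kind, ec, split=split)
            rows.append(
                {
                    "muscle_set": mset,
                    "classifier": kind,
                    "error_pct": 100 * rep.error,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                }
            )
            rep.confusion.to_csv(out / f"confusion_{mset}_{kind}.csv")
    df = pd.DataFrame(rows)
    _write_table(df, out / "classifier_comparison.csv", cfg)
    return df


def _wrist_positions(trials, cfg: RunConfig, out: Path) -> pd.DataFrame:
    ec = cfg.eval_config()
    rows = []
    for mset in cfg.muscle_sets:
        fm = build_feature_matrix(trials, mset, "TDAR", ec)
        split = make_two_fold_split(fm, ec.unit, ec.seed)
        for n in range(1, 8):
            best, err, _ = wrist_combo_search(fm, n, "LDA", ec, split=split)
            rows.append(
                {
                    "muscle_set": mset,
                    "n_positions": n,
                    "best_error_pct": 100 * err,
                    "best_combination": "+".join(best),
                }
            )
    df = pd.DataFrame(rows)
    _write_table(df, out / "wrist_positions.csv", cfg)
    return df


def _feature_sets(trials, cfg: RunConfig, out: Path) -> pd.DataFrame:
    ec = cfg.eval_config()
    rows = []
    for mset in cfg.muscle_sets:
        fm = build_feature_matrix(trials, mset, "ALL", ec)
        split = make_two_fold_split(fm, ec.unit, ec.seed)
        K = 10 * len(fm.channel_ids)
        sets: dict[str, list] = {
            "ALL": list(fm.columns),
            "TDAR": [
                c for c in fm.columns if c[1] in named_feature_set("TDAR")
            ],
            "TD": [c for c in fm.columns if c[1] in named_feature_set("TD")],
            "SFS": sfs_select(fm, K, ec, split=split).selected,
            "SI": si_ordering(fm, K).selected,
        }
        for name, cols in sets.items():
            rep = evaluate_feature_matrix(
                fm.subset_columns(cols), "LDA", ec, split=split
            )
            rows.append(
                {
                    "muscle_set": mset,
                    "feature_set": name,
                    "n_features": len(cols),
                    "error_pct": 100 * rep.error,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                }
            )
    df = pd.DataFrame(rows)
    _write_table(df, out / "feature_sets.csv", cfg)
    return df


def _feature_curves(trials, cfg: RunConfig, out: Path) -> pd.DataFrame:
    ec = cfg.eval_config()
    rows = []
    freq_results = []
    for mset in cfg.muscle_sets:
        fm = build_feature_matrix(trials, mset, "ALL", ec)
        split = make_two_fold_split(fm, ec.unit, ec.seed)
        K = 10 * len(fm.channel_ids)
        orders = {
            "SFS": sfs_select(fm, K, ec, split=split),
            "SI": si_ordering(fm, fm.n_columns),
            "PCA": pca_ordering(fm, ec, split=split, max_count=K),
        }
        for method, res in orders.items():
            if method == "PCA":
                curve = res.trajectory
            else:
                curve = error_vs_count_curve(
                    res, fm, ec, split=split, max_count=K
                )
            X = reduced_set_99(curve)
            res.X = X
            for k, e in enumerate(curve, start=1):
                rows.append(
                    {
                        "muscle_set": mset,
                        "method": method,
                        "n_features": k,
                        "error_pct": 100 * e,
                        "X_99pct": X,
                    }
                )
            if method == "SFS":
                freq_results.append(res)
    df = pd.DataFrame(rows)
    _write_table(df, out / "feature_curves.csv", cfg)
    freq = selection_frequency(freq_results, FEATURE_NAMES)
    _write_table(freq, out / "selection_frequency_sfs.csv", cfg)
    return df


def run_experiment(cfg: RunConfig) -> pd.DataFrame:
    """Run one experiment and write its tables under ``cfg.out_dir``.

    Returns the main result table.  Deterministic: rerunning the same
    config yields byte-identical machine-readable outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = _load_trials(cfg)
    runners = {
        "classifier-comparison": _classifier_comparison,
        "wrist-positions": _wrist_positions,
        "feature-sets": _feature_sets,
        "feature-curves": _feature_curves,
    }
    try:
        return runners[cfg.experiment](trials, cfg, out)
    except Exception as exc:
        raise RuntimeError(
            f"experiment {cfg.experiment!r} failed: {exc}"
        ) from exc
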
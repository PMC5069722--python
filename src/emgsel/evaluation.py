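"""Evaluation protocols: two-fold 50/30/20 splits, condition evaluation,
wrist-position combination search, and sensitivity/specificity.

The split scheme divides the windows of every class x position cell into
training (50%), testing (30%) and validation (20%) portions.  The second
fold swaps roles: it trains on fold 1's test+validation data (50%) and
draws its 30% test / 20% validation portions from fold 1's training data.
Reported errors are the average over the two folds.

The assignment unit defaults to individual windows (the most literal
reading of "50% of all data"); splitting whole repetitions instead is
available via ``unit="repetition"`` because overlapping windows from one
repetition are strongly correlated and window-level splits therefore leak
information between partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import classification_error, fit_discriminant, predict
from .dataset import MOTION_CLASSES, WRIST_POSITIONS, Trial, segment_windows, select_muscle_set
from .features import FeatureMatrix, extract_feature_matrix, named_feature_set
from .nn import TrainConfig, fit_nn, nn_predict

__all__ = [
    "EvalConfig",
    "SplitScheme",
    "EvaluationReport",
    "make_two_fold_split",
    "build_feature_matrix",
    "evaluate_feature_matrix",
    "evaluate_condition",
    "wrist_combo_search",
    "sensitivity_specificity",
]

CLASSIFIER_KINDS = ("LDA", "QDA", "LNN", "MLPANN")


@dataclass(frozen=True)
class EvalConfig:
    """Shared evaluation parameters.

    ``unit`` selects the split assignment unit ("window" or "repetition");
    ``nn`` configures SCG training for the neural-network classifiers.
    """

    seed: int = 0
    unit: str = "window"
    window_ms: float = 200.0
    increment_ms: float = 20.0
    nn: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.unit not in ("window", "repetition"):
            raise ValueError("unit must be 'window' or 'repetition'")


@dataclass
class SplitScheme:
    """Two folds of disjoint, exhaustive train/test/validation row indices."""

    folds: list[dict[str, np.ndarray]]
    unit: str
    seed: int

    def __post_init__(self) -> None:
        for fold in self.folds:
            parts = [fold["train"], fold["test"], fold["val"]]
            allidx = np.concatenate(parts)
            if len(np.unique(allidx)) != len(allidx):
                raise ValueError("split partitions overlap")


def _stratum_units(fm: FeatureMatrix, unit: str):
    """Yield (cell name, list of row-index arrays forming assignable units)."""
    lab = fm.labels
    for (mc, wp), cell in lab.groupby(
        ["motion_class", "wrist_position"], sort=True
    ):
        if unit == "window":
            units = [np.array([i]) for i in cell.index.to_numpy()]
        else:
            units = [
                g.index.to_numpy()
                for _, g in cell.groupby(["subject", "repetition"], sort=True)
            ]
        yield f"{mc}/{wp}", units


def make_two_fold_split(
    fm: FeatureMatrix, unit: str = "window", seed: int = 0
) -> SplitScheme:
    """Stratified 50/30/20 two-fold swap split of a feature matrix.

    Every class x position cell needs at least 10 assignable units so each
    partition of each fold is non-empty in every cell.
    """
    rng = np.random.default_rng(seed)
    parts: dict[str, list[list[np.ndarray]]] = {
        key: [[], [], []] for key in ("fold1", "fold2")
    }
    for cell, units in _stratum_units(fm, unit):
        n = len(units)
        if n < 10:
            raise ValueError(
                f"cell {cell} has only {n} {unit} unit(s); need >= 10"
            )
        perm = rng.permutation(n)
        n_tr = int(round(0.5 * n))
        n_te = int(round(0.3 * n))
        tr = perm[:n_tr]
        te = perm[n_tr : n_tr + n_te]
        va = perm[n_tr + n_te :]
        # fold 2: swap — train on old test+val, re-divide old train 60/40
        perm2 = rng.permutation(n_tr)
        n_te2 = int(round(0.6 * n_tr))
        te2 = tr[perm2[:n_te2]]
        va2 = tr[perm2[n_te2:]]
        tr2 = np.concatenate([te, va])
        for key, (a, b, c) in (("fold1", (tr, te, va)), ("fold2", (tr2, te2, va2))):
            parts[key][0].extend(units[i] for i in a)
            parts[key][1].extend(units[i] for i in b)
            parts[key][2].extend(units[i] for i in c)
    folds = []
    for key in ("fold1", "fold2"):
        tr, te, va = (
            np.sort(np.concatenate(group)) if group else np.empty(0, dtype=int)
            for group in parts[key]
        )
        folds.append({"train": tr, "test": te, "val": va})
    return SplitScheme(folds=folds, unit=unit, seed=seed)


@dataclass
class EvaluationReport:
    """Two-fold evaluation result for one condition."""

    classifier: str
    error: float
    fold_errors: tuple[float, float]
    confusion: pd.DataFrame  # rows true class, columns predicted
    sensitivity: float
    specificity: float
    meta: dict = field(default_factory=dict)


def sensitivity_specificity(confusion) -> tuple[float, float]:
    """Overall sensitivity and macro-averaged specificity of a confusion matrix.

    Sensitivity = correctly recognised true-class windows over all windows.
    Specificity = for each class, correctly rejected non-class windows over
    all non-class windows (one-vs-rest), averaged over classes.
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = C.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    if np.any(C < 0):
        raise ValueError("confusion counts must be nonnegative")
    sensitivity = float(np.trace(C) / total)
    specs = []
    for k in range(C.shape[0]):
        fp = C[:, k].sum() - C[k, k]
        tn = total - C[k, :].sum() - fp
        specs.append(tn / (tn + fp) if (tn + fp) > 0 else 1.0)
    return sensitivity, float(np.mean(specs))


def _confusion(truth, predicted, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    C = np.zeros((len(classes), len(classes)))
    for t, p in zip(truth, predicted):
        C[idx[t], idx[p]] += 1
    return C


def _fit_and_predict(
    kind: str,
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xva: np.ndarray,
    yva: np.ndarray,
    Xte: np.ndarray,
    cfg: EvalConfig,
) -> np.ndarray:
    kind = kind.upper()
    if kind in ("LDA", "QDA"):
        model = fit_discriminant(kind, Xtr, ytr)
        return predict(model, Xte)
    if kind in ("LNN", "MLPANN"):
        nn_cfg = replace(cfg.nn, seed=cfg.seed)
        model = fit_nn(kind, Xtr, ytr, Xva, yva, nn_cfg)
        return nn_predict(model, Xte)
    raise ValueError(f"unknown classifier kind {kind!r}")


def build_feature_matrix(
    trials: Sequence[Trial],
    muscle_set: str = "combined",
    feature_set: str | Sequence[tuple[str, str]] = "TDAR",
    cfg: EvalConfig | None = None,
) -> FeatureMatrix:
    """Muscle-set selection + segmentation + feature extraction in one call.

    ``feature_set`` is a named set ("TD", "TDAR", "ALL") or an explicit list
    of (channel, feature) columns, in which case the full catalog is
    extracted and subset.
    """
    cfg = cfg or EvalConfig()
    sub = select_muscle_set(trials, muscle_set)
    windows = [
        w
        for t in sub
        for w in segment_windows(t, cfg.window_ms, cfg.increment_ms)
    ]
    if isinstance(feature_set, str):
        return extract_feature_matrix(windows, named_feature_set(feature_set))
    fm = extract_feature_matrix(windows)
    return fm.subset_columns(list(feature_set))


def evaluate_feature_matrix(
    fm: FeatureMatrix,
    classifier_kind: str = "LDA",
    cfg: EvalConfig | None = None,
    split: SplitScheme | None = None,
    train_position_subset: Sequence[str] | None = None,
) -> EvaluationReport:
    """Two-fold evaluation of a classifier on an extracted feature matrix.

    If ``train_position_subset`` is given, training (and validation) rows
    are restricted to those wrist positions while the test rows continue to
    span all positions present in the matrix.
    """
    cfg = cfg or EvalConfig()
    split = split or make_two_fold_split(fm, cfg.unit, cfg.seed)
    y = fm.labels["motion_class"].to_numpy()
    pos = fm.labels["wrist_position"].to_numpy()
    classes = [c for c in MOTION_CLASSES if c in set(y)]
    errors = []
    C = np.zeros((len(classes), len(classes)))
    for fold in split.folds:
        tr, te, va = fold["train"], fold["test"], fold["val"]
        if train_position_subset is not None:
            keep = set(train_position_subset)
            tr = tr[np.isin(pos[tr], list(keep))]
            va = va[np.isin(pos[va], list(keep))]
        pred = _fit_and_predict(
            classifier_kind,
            fm.values[tr],
            y[tr],
            fm.values[va],
            y[va],
            fm.values[te],
            cfg,
        )
        errors.append(classification_error(pred, y[te]))
        C += _confusion(y[te], pred, classes)
    sens, spec = sensitivity_specificity(C)
    return EvaluationReport(
        classifier=classifier_kind.upper(),
        error=float(np.mean(errors)),
        fold_errors=(errors[0], errors[1]),
        confusion=pd.DataFrame(C, index=classes, columns=classes),
        sensitivity=sens,
        specificity=spec,
        meta={
            "seed": cfg.seed,
            "unit": cfg.unit,
            "train_positions": tuple(train_position_subset)
            if train_position_subset
            else "all",
        },
    )


def evaluate_condition(
    trials: Sequence[Trial],
    muscle_set: str,
    feature_set: str | Sequence[tuple[str, str]],
    classifier_kind: str,
    cfg: EvalConfig | None = None,
) -> EvaluationReport:
    """Full pipeline for one (muscle set, feature set, classifier) condition."""
    cfg = cfg or EvalConfig()
    fm = build_feature_matrix(trials, muscle_set, feature_set, cfg)
    report = evaluate_feature_matrix(fm, classifier_kind, cfg)
    report.meta.update(
        {
            "muscle_set": muscle_set,
            "feature_set": feature_set
            if isinstance(feature_set, str)
            else "custom",
        }
    )
    return report


def wrist_combo_search(
    fm: FeatureMatrix,
    n_positions: int,
    classifier_kind: str = "LDA",
    cfg: EvalConfig | None = None,
    split: SplitScheme | None = None,
) -> tuple[tuple[str, ...], float, dict[tuple[str, ...], float]]:
    """Exhaustive search over wrist-position training subsets of size n.

    Every combination of ``n_positions`` of the 7 wrist positions is used
    to restrict the training portion of the standard two-fold scheme; the
    test portions always span all positions.  Returns the lowest-error
    combination, its error, and the error of every combination.
    """
    if not (1 <= n_positions <= len(WRIST_POSITIONS)):
        raise ValueError("n_positions must be between 1 and 7")
    cfg = cfg or EvalConfig()
    split = split or make_two_fold_split(fm, cfg.unit, cfg.seed)
    present = [p for p in WRIST_POSITIONS if p in set(fm.labels["wrist_position"])]
    results: dict[tuple[str, ...], float] = {}
    for combo in combinations(present, n_positions):
        report = evaluate_feature_matrix(
            fm, classifier_kind, cfg, split=split, train_position_subset=combo
        )
        results[combo] = report.error
    best = min(results, key=lambda c: (results[c], c))
    return best, results[best], results
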
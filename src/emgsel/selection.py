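"""Feature selection: SFS wrapper search, SI and PCA orderings, and the
error-vs-feature-count analyses.

The sequential forward search (SFS) keeps a selected set A (initially
empty) and a candidate set B (all columns).  At every step each remaining
candidate is evaluated *jointly* with A by an LDA trained on the wrapper's
training partition and scored on its testing partition; the candidate with
the lowest joint error moves to A.  Unlike the SI filter, SFS therefore
rewards features that are informative in combination, not just marginally.

The wrapper's internal objective is the two-fold average error of the
standard split scheme — the same quantity the finished feature sets are
compared on.  To keep the O(F x K x folds) LDA fits cheap, class means and
the pooled within-class scatter are accumulated once per fold over all
columns; the LDA for any candidate subset is then fitted from the
corresponding sub-blocks, which is algebraically identical to refitting
from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import DiscriminantModel, _regularize, predict
from .evaluation import EvalConfig, SplitScheme, make_two_fold_split
from .features import FEATURE_NAMES, FeatureMatrix

__all__ = [
    "SelectionResult",
    "sfs_select",
    "si_ordering",
    "pca_ordering",
    "error_vs_count_curve",
    "reduced_set_99",
    "selection_frequency",
]


@dataclass
class SelectionResult:
    """Ordered selection with its error trajectory.

    ``order`` lists (channel, feature) column ids for SFS/SI, or component
    indices for PCA.  ``trajectory`` holds the error after each addition
    (wrapper error for SFS, two-fold error for evaluation curves).
    """

    method: str  # "SFS" | "SI" | "PCA"
    order: list
    trajectory: np.ndarray
    K: int
    n_channels: int
    X: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def selected(self) -> list:
        return self.order[: self.K]


class _PooledLDAStats:
    """Class means and pooled scatter over all columns of a training set.

    Sub-selecting columns of these statistics and normalising the scatter
    by (N - K) reproduces exactly the pooled-covariance LDA that
    :func:`emgsel.classifiers.fit_discriminant` would fit on the selected
    columns alone.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.classes = np.unique(y)
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        n, F = X.shape
        K = len(self.classes)
        self.means = np.empty((K, F))
        self.priors = np.empty(K)
        self.scatter = np.zeros((F, F))
        for k, c in enumerate(self.classes):
            rows = X[y == c]
            if rows.shape[0] < 2:
                raise ValueError(f"class {c!r} has fewer than 2 rows")
            self.means[k] = rows.mean(axis=0)
            self.priors[k] = rows.shape[0] / n
            diff = rows - self.means[k]
            self.scatter += diff.T @ diff
        self.norm = n - K

    def model(self, cols: Sequence[int]) -> DiscriminantModel:
        cols = np.asarray(cols)
        pooled = self.scatter[np.ix_(cols, cols)] / self.norm
        reg, _, w = _regularize(pooled)
        K = len(self.classes)
        covs = np.broadcast_to(reg, (K, *reg.shape)).copy()
        return DiscriminantModel(
            kind="LDA",
            classes=self.classes,
            priors=self.priors,
            means=self.means[:, cols],
            covariances=covs,
            shrinkage=np.full(K, w),
        )

    def error(self, cols: Sequence[int], Xte: np.ndarray, yte: np.ndarray) -> float:
        model = self.model(cols)
        pred = predict(model, Xte[:, np.asarray(cols)])
        return float(np.mean(pred != yte))


def sfs_select(
    fm: FeatureMatrix,
    K: int | None = None,
    cfg: EvalConfig | None = None,
    split: SplitScheme | None = None,
) -> SelectionResult:
    """Greedy sequential forward search with an LDA wrapper.

    Selects ``K`` columns (default 10 x channel count, the TDAR-set size),
    each step appending the candidate that minimises the two-fold average
    LDA error jointly with the already-selected set.  Ties between
    equal-error candidates go to the lowest column index, so the search is
    deterministic under a fixed split seed.
    """
    cfg = cfg or EvalConfig()
    if K is None:
        K = 10 * len(fm.channel_ids)
    if not (1 <= K <= fm.n_columns):
        raise ValueError(f"K={K} out of range for {fm.n_columns} columns")
    split = split or make_two_fold_split(fm, cfg.unit, cfg.seed)
    y = fm.labels["motion_class"].to_numpy()
    folds = [
        (
            _PooledLDAStats(fm.values[fold["train"]], y[fold["train"]]),
            fm.values[fold["test"]],
            y[fold["test"]],
        )
        for fold in split.folds
    ]
    selected: list[int] = []
    remaining = list(range(fm.n_columns))
    trajectory = []
    for _ in range(K):
        best_j, best_err = None, np.inf
        for j in remaining:
            cols = selected + [j]
            err = float(
                np.mean([stats.error(cols, Xte, yte) for stats, Xte, yte in folds])
            )
            if err < best_err:
                best_j, best_err = j, err
        selected.append(best_j)
        remaining.remove(best_j)
        trajectory.append(best_err)
    return SelectionResult(
        method="SFS",
        order=[fm.columns[j] for j in selected],
        trajectory=np.asarray(trajectory),
        K=K,
        n_channels=len(fm.channel_ids),
        meta={"seed": cfg.seed, "unit": cfg.unit},
    )


def si_ordering(
    fm: FeatureMatrix, K: int | None = None
) -> SelectionResult:
    """Full SI (Bhattacharyya filter) column ordering as a SelectionResult."""
    from .separability import compute_separability_table

    if K is None:
        K = 10 * len(fm.channel_ids)
    table = compute_separability_table(fm)
    order = np.argsort(-table.si, kind="stable")
    return SelectionResult(
        method="SI",
        order=[fm.columns[i] for i in order],
        trajectory=np.empty(0),
        K=K,
        n_channels=len(fm.channel_ids),
        meta={"si": table.si[order]},
    )


def error_vs_count_curve(
    order: SelectionResult | Sequence[tuple[str, str]],
    fm: FeatureMatrix,
    cfg: EvalConfig | None = None,
    split: SplitScheme | None = None,
    max_count: int | None = None,
) -> np.ndarray:
    """Two-fold LDA error as features are added one-by-one along an order.

    ``e[k-1]`` is the two-fold average error of an LDA using the first k
    columns of the order.  The curve is not forced monotone: adding a
    feature can hurt held-out error.
    """
    cfg = cfg or EvalConfig()
    cols = order.order if isinstance(order, SelectionResult) else list(order)
    if not cols:
        raise ValueError("order covers no columns")
    idx = fm.column_positions(cols)
    if max_count is not None:
        idx = idx[:max_count]
    split = split or make_two_fold_split(fm, cfg.unit, cfg.seed)
    y = fm.labels["motion_class"].to_numpy()
    curves = []
    for fold in split.folds:
        tr, te = fold["train"], fold["test"]
        stats = _PooledLDAStats(fm.values[tr], y[tr])
        Xte, yte = fm.values[te], y[te]
        curves.append(
            [stats.error(idx[: k + 1], Xte, yte) for k in range(len(idx))]
        )
    return np.mean(curves, axis=0)


def pca_ordering(
    fm: FeatureMatrix,
    cfg: EvalConfig | None = None,
    split: SplitScheme | None = None,
    max_count: int | None = None,
) -> SelectionResult:
    """Principal-component ordering with its two-fold LDA error trajectory.

    Per fold, columns are z-scored with training-partition statistics, the
    rotation is fitted on the training partition, components are ordered by
    explained variance (non-increasing by construction) and truncated to
    the numerical rank; ``e[k-1]`` is the LDA error using the first k
    components, averaged over the folds.
    """
    cfg = cfg or EvalConfig()
    split = split or make_two_fold_split(fm, cfg.unit, cfg.seed)
    y = fm.labels["motion_class"].to_numpy()
    curves = []
    ranks = []
    explained = None
    for fold in split.folds:
        tr, te = fold["train"], fold["test"]
        Xtr = fm.values[tr]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Ztr = (Xtr - mu) / sd
        Zte = (fm.values[te] - mu) / sd
        Zc = Ztr - Ztr.mean(axis=0)
        _, s, Vt = np.linalg.svd(Zc, full_matrices=False)
        var = s**2 / (Ztr.shape[0] - 1)
        rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
        ranks.append(rank)
        if explained is None:
            explained = var[:rank]
        Ttr = Ztr @ Vt[:rank].T
        Tte = Zte @ Vt[:rank].T
        n_eval = rank if max_count is None else min(rank, max_count)
        stats = _PooledLDAStats(Ttr, y[tr])
        yte = y[te]
        curves.append(
            [stats.error(list(range(k + 1)), Tte, yte) for k in range(n_eval)]
        )
    n = min(len(c) for c in curves)
    trajectory = np.mean([c[:n] for c in curves], axis=0)
    K = min(10 * len(fm.channel_ids), n)
    return SelectionResult(
        method="PCA",
        order=list(range(n)),
        trajectory=trajectory,
        K=K,
        n_channels=len(fm.channel_ids),
        meta={
            "explained_variance": explained,
            "rank": min(ranks),
            "seed": cfg.seed,
        },
    )


def reduced_set_99(trajectory) -> int:
    """Smallest feature count achieving 99% of the trajectory's error drop.

    X = min { k : e_1 - e_k >= 0.99 (e_1 - e_min) }, with e_min the global
    minimum of the trajectory; a flat trajectory gives X = 1.
    """
    e = np.asarray(trajectory, dtype=float)
    if e.size == 0:
        raise ValueError("empty trajectory")
    drop = 0.99 * (e[0] - e.min())
    hits = np.nonzero(e[0] - e >= drop)[0]
    return int(hits[0]) + 1


def selection_frequency(
    results: Sequence[SelectionResult],
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Per-feature selection probability within each subject's reduced set.

    For each subject (one SelectionResult each, carrying its reduced-set
    size ``X``), a feature's probability is the fraction of channels whose
    (channel, feature) column appears among the first X selected columns.
    Probabilities are averaged across subjects; ``se`` is the
    across-subject standard error (0 for a single subject).
    """
    if not results:
        raise ValueError("no selection results")
    rows = []
    for res in results:
        if res.X is None:
            raise ValueError("each SelectionResult must carry its X")
        head = res.order[: res.X]
        counts = {f: 0 for f in feature_names}
        for _, feat in head:
            counts[feat] += 1
        rows.append(
            {f: counts[f] / res.n_channels for f in feature_names}
        )
    df = pd.DataFrame(rows)
    prob = df.mean(axis=0)
    if len(df) > 1:
        se = df.std(axis=0, ddof=1) / np.sqrt(len(df))
    else:
        se = pd.Series(0.0, index=df.columns)
    return pd.DataFrame(
        {"feature": prob.index, "probability": prob.values, "se": se.values}
    ).reset_index(drop=True)
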
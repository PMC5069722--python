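"""Bhattacharyya-distance class-separability filter.

For each (channel, feature) column the separability index (SI) is the
minimum, over all unordered class pairs, of the univariate Gaussian
Bhattacharyya distance

    D_B = (1/4) (mu_a - mu_b)^2 / (s_a^2 + s_b^2)
          + (1/2) ln( (s_a^2 + s_b^2) / (2 s_a s_b) )

estimated from sample means and variances, with data pooled over all wrist
positions.  A larger SI means better worst-case discrimination between any
two postures; ranking columns by SI descending yields the filter-selected
feature set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = [
    "bhattacharyya_1d",
    "separability_index",
    "SeparabilityTable",
    "compute_separability_table",
    "rank_features_si",
]

_VAR_FLOOR_REL = 1e-12


def _moments(sample: np.ndarray, var_floor: float) -> tuple[float, float]:
    mu = float(np.mean(sample))
    var = float(np.var(sample, ddof=1))
    return mu, max(var, var_floor)


def bhattacharyya_1d(sample_a, sample_b) -> float:
    """Univariate Gaussian Bhattacharyya distance between two samples.

    A variance floor (1e-12 x pooled variance, with an absolute floor for
    exactly-constant data) guards degenerate columns; two literally equal
    constant samples give distance 0, a constant sample separated in mean
    from the other diverges as intended.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    pooled = float(np.var(np.concatenate([a, b]), ddof=1))
    floor = max(_VAR_FLOOR_REL * pooled, 1e-300)
    mu_a, va = _moments(a, floor)
    mu_b, vb = _moments(b, floor)
    return 0.25 * (mu_a - mu_b) ** 2 / (va + vb) + 0.5 * np.log(
        (va + vb) / (2.0 * np.sqrt(va * vb))
    )


def separability_index(column_values, class_labels) -> float:
    """Minimum pairwise Bhattacharyya distance over all class pairs."""
    x = np.asarray(column_values, dtype=float).ravel()
    y = np.asarray(class_labels)
    if x.shape != y.shape:
        raise ValueError("values and labels must align")
    classes = pd.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    groups = {}
    for c in classes:
        vals = x[y == c]
        if vals.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 windows")
        groups[c] = vals
    return min(
        bhattacharyya_1d(groups[ca], groups[cb])
        for ca, cb in combinations(classes, 2)
    )


@dataclass
class SeparabilityTable:
    """SI and all pairwise distances per (channel, feature) column."""

    columns: list[tuple[str, str]]
    si: np.ndarray  # (F,)
    pairwise: pd.DataFrame  # one row per column, one col per class pair
    class_names: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "channel": [c for c, _ in self.columns],
                "feature": [f for _, f in self.columns],
                "SI": self.si,
            }
        )
        return pd.concat([df, self.pairwise.reset_index(drop=True)], axis=1)


def compute_separability_table(fm: FeatureMatrix) -> SeparabilityTable:
    """SI for every column of a feature matrix (all wrist positions pooled)."""
    y = fm.labels["motion_class"].to_numpy()
    classes = tuple(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    pair_names = [f"DB({a},{b})" for a, b in combinations(classes, 2)]
    pairs = np.empty((fm.n_columns, len(pair_names)))
    for j in range(fm.n_columns):
        col = fm.values[:, j]
        for k, (a, b) in enumerate(combinations(classes, 2)):
            pairs[j, k] = bhattacharyya_1d(col[y == a], col[y == b])
    si = pairs.min(axis=1)
    return SeparabilityTable(
        columns=list(fm.columns),
        si=si,
        pairwise=pd.DataFrame(pairs, columns=pair_names),
        class_names=classes,
    )


def rank_features_si(
    fm: FeatureMatrix, k: int | None = None
) -> tuple[list[tuple[str, str]], SeparabilityTable]:
    """Rank columns by SI descending; return the top-K columns and the table.

    K defaults to 10 x channel count, sizing the SI set like the TDAR set.
    Ties are broken by the fixed column (channel-then-catalog) order, so the
    ranking is deterministic.
    """
    table = compute_separability_table(fm)
    if k is None:
        k = 10 * len(fm.channel_ids)
    if not (1 <= k <= fm.n_columns):
        raise ValueError(f"k={k} out of range for {fm.n_columns} columns")
    order = np.argsort(-table.si, kind="stable")
    ranked = [fm.columns[i] for i in order]
    return ranked[:k], table
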
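"""Feature selection: SFS oracle equivalence, PCA ordering, error curves,
the 99%-decrease reduction rule, and selection frequencies."""

import numpy as np
import pandas as pd
import pytest

from emgsel.classifiers import classification_error, fit_discriminant, predict
from emgsel.dataset import MOTION_CLASSES
from emgsel.evaluation import EvalConfig, make_two_fold_split
from emgsel.selection import (
    SelectionResult,
    error_vs_count_curve,
    pca_ordering,
    reduced_set_99,
    selection_frequency,
    sfs_select,
)
from tests.conftest import random_feature_matrix


def naive_greedy_sfs(fm, K, split):
    """Exhaustive greedy oracle: refit an LDA from scratch per candidate and
    score the two-fold average error, exactly as the wrapper defines it."""
    y = fm.labels["motion_class"].to_numpy()

    def two_fold_error(cols):
        errs = []
        for fold in split.folds:
            tr, te = fold["train"], fold["test"]
            model = fit_discriminant("LDA", fm.values[np.ix_(tr, cols)], y[tr])
            errs.append(
                classification_error(
                    predict(model, fm.values[np.ix_(te, cols)]), y[te]
                )
            )
        return np.mean(errs)

    selected = []
    remaining = list(range(fm.n_columns))
    for _ in range(K):
        best_j, best_err = None, np.inf
        for j in remaining:
            err = two_fold_error(selected + [j])
            if err < best_err:
                best_j, best_err = j, err
        selected.append(best_j)
        remaining.remove(best_j)
    return [fm.columns[j] for j in selected]


class TestSfs:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        """<= 6 columns, 3 steps: SFS equals the refit-from-scratch greedy."""
        fm = random_feature_matrix(
            n_per_class=10,
            channels=("c1", "c2"),
            features=("MAV", "RMS", "WL"),
            seed=seed,
            class_shift=0.4,
        )
        cfg = EvalConfig(seed=seed)
        split = make_two_fold_split(fm, "window", seed)
        res = sfs_select(fm, K=3, cfg=cfg, split=split)
        assert res.order[:3] == naive_greedy_sfs(fm, 3, split)

    def test_perfect_column_selected_first(self, gaussian_fm):
        fm = gaussian_fm
        class_idx = fm.labels["motion_class"].map(
            {c: i for i, c in enumerate(MOTION_CLASSES)}
        )
        fm.values[:, 3] = class_idx * 10  # alone separates all classes
        res = sfs_select(fm, K=2, cfg=EvalConfig(seed=0))
        assert res.order[0] == fm.columns[3]
        assert res.trajectory[0] == 0.0

    def test_k_equals_all_columns_exhausts(self, gaussian_fm):
        res = sfs_select(gaussian_fm, K=gaussian_fm.n_columns, cfg=EvalConfig(seed=1))
        assert sorted(res.order) == sorted(gaussian_fm.columns)

    def test_each_step_achieves_candidate_minimum(self):
        """The chosen candidate minimises the wrapper error at its step."""
        fm = random_feature_matrix(seed=21, class_shift=0.3)
        cfg = EvalConfig(seed=2)
        split = make_two_fold_split(fm, "window", 2)
        res = sfs_select(fm, K=4, cfg=cfg, split=split)
        y = fm.labels["motion_class"].to_numpy()
        chosen_idx = [fm.columns.index(c) for c in res.order]

        def two_fold_error(cols):
            errs = []
            for fold in split.folds:
                model = fit_discriminant(
                    "LDA", fm.values[np.ix_(fold["train"], cols)], y[fold["train"]]
                )
                errs.append(
                    classification_error(
                        predict(model, fm.values[np.ix_(fold["test"], cols)]),
                        y[fold["test"]],
                    )
                )
            return np.mean(errs)

        for step in range(4):
            prefix = chosen_idx[:step]
            errs = [
                two_fold_error(prefix + [j])
                for j in range(fm.n_columns)
                if j not in prefix
            ]
            assert res.trajectory[step] == pytest.approx(min(errs))

    def test_deterministic(self, gaussian_fm):
        a = sfs_select(gaussian_fm, K=3, cfg=EvalConfig(seed=3))
        b = sfs_select(gaussian_fm, K=3, cfg=EvalConfig(seed=3))
        assert a.order == b.order
        assert np.array_equal(a.trajectory, b.trajectory)


class TestPca:
    def test_explained_variance_non_increasing(self):
        fm = random_feature_matrix(seed=22, class_shift=0.5)
        res = pca_ordering(fm, EvalConfig(seed=4))
        ev = res.meta["explained_variance"]
        assert np.all(np.diff(ev) <= 1e-12)

    def test_dominant_direction_carries_variance(self):
        # all columns share one latent direction up to tiny noise, so after
        # z-scoring the first component must carry >= 99% of the variance
        fm = random_feature_matrix(seed=23)
        shared = fm.values[:, 0].copy()
        for j in range(fm.n_columns):
            fm.values[:, j] = shared + 1e-3 * fm.values[:, j]
        res = pca_ordering(fm, EvalConfig(seed=5))
        ev = res.meta["explained_variance"]
        assert ev[0] / ev.sum() >= 0.99

    def test_full_component_error_matches_original_columns(self):
        fm = random_feature_matrix(seed=24, class_shift=0.6)
        cfg = EvalConfig(seed=6)
        split = make_two_fold_split(fm, "window", 6)
        res = pca_ordering(fm, cfg, split=split)
        full_pca_error = res.trajectory[-1]
        direct = error_vs_count_curve(list(fm.columns), fm, cfg, split=split)[-1]
        assert full_pca_error == pytest.approx(direct, abs=0.02)


class TestErrorCurve:
    def test_final_point_is_all_feature_error(self, gaussian_fm):
        cfg = EvalConfig(seed=7)
        split = make_two_fold_split(gaussian_fm, "window", 7)
        curve = error_vs_count_curve(list(gaussian_fm.columns), gaussian_fm, cfg, split=split)
        assert len(curve) == gaussian_fm.n_columns
        assert curve.min() <= curve[-1]
        again = error_vs_count_curve(list(gaussian_fm.columns), gaussian_fm, cfg, split=split)
        assert np.array_equal(curve, again)


class TestReducedSet:
    def test_printed_toy_trajectory(self):
        assert reduced_set_99([50, 20, 10, 9, 9.05]) == 4

    def test_monotone_trajectory_bounded_by_argmin(self):
        traj = [40, 30, 20, 10, 5, 5, 5]
        assert reduced_set_99(traj) <= int(np.argmin(traj)) + 1

    def test_constant_trajectory(self):
        assert reduced_set_99([7.5, 7.5, 7.5]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reduced_set_99([])


class TestSelectionFrequency:
    def _result(self, order, X, n_channels=2):
        return SelectionResult(
            method="SFS",
            order=order,
            trajectory=np.zeros(len(order)),
            K=len(order),
            n_channels=n_channels,
            X=X,
        )

    def test_single_subject_mav_only(self):
        res = self._result([("c1", "MAV"), ("c2", "MAV")], X=2)
        freq = selection_frequency([res], ("MAV", "RMS"))
        table = dict(zip(freq["feature"], freq["probability"]))
        assert table == {"MAV": 1.0, "RMS": 0.0}

    def test_counts_conserved(self):
        res = self._result(
            [("c1", "MAV"), ("c1", "RMS"), ("c2", "WL"), ("c2", "RMS")], X=3
        )
        freq = selection_frequency([res], ("MAV", "RMS", "WL"))
        assert freq["probability"].sum() * res.n_channels == pytest.approx(3)

    def test_identical_subjects_zero_se(self):
        res = self._result([("c1", "MAV"), ("c2", "RMS")], X=2)
        freq = selection_frequency([res, res], ("MAV", "RMS"))
        assert np.all(freq["se"] == 0.0)

    def test_missing_x_rejected(self):
        res = self._result([("c1", "MAV")], X=None)
        with pytest.raises(ValueError, match="X"):
            selection_frequency([res], ("MAV",))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            selection_frequency([], ("MAV",))
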
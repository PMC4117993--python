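"""Cross-validation mechanics, chance level, detection and best-window rules."""

import numpy as np
import pytest

from scpdecode import (ChanceLevel, PipelineConfig, chance_level,
                       decoding_accuracy, early_detection, make_grid,
                       plan_folds, run_selected, run_time_specific,
                       select_best_window)
from scpdecode.evaluation import DecodingCurve, FoldPlan

from conftest import make_epochs


class TestPlanFolds:
    def test_ten_trials_five_folds_gives_pairs(self):
        plan = plan_folds(np.arange(10), 5)
        assert [len(f) for f in plan.folds] == [2] * 5
        assert plan.folds[0].tolist() == [0, 1]
        assert plan.folds[4].tolist() == [8, 9]

    def test_233_trials_split_near_equally(self):
        plan = plan_folds(np.arange(233), 5)
        assert [len(f) for f in plan.folds] == [47, 47, 47, 46, 46]
        # contiguity: fold boundaries preserve chronological order
        flat = np.concatenate(plan.folds)
        assert np.array_equal(flat, np.arange(233))

    def test_shuffled_ids_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            plan_folds([3, 1, 2], 3)

    def test_too_few_folds_or_trials_rejected(self):
        with pytest.raises(ValueError):
            plan_folds(np.arange(10), 1)
        with pytest.raises(ValueError):
            plan_folds(np.arange(3), 5)


class TestDecodingAccuracy:
    @pytest.mark.parametrize("cm,expected", [
        (np.diag([12, 12, 12, 12]), 1.0),
        (np.full((4, 4), 3), 0.25),
    ])
    def test_reference_values(self, cm, expected):
        assert decoding_accuracy(cm) == pytest.approx(expected)

    def test_partial_trace(self):
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 0], cm[1, 1], cm[2, 2], cm[3, 3] = 8, 7, 7, 7
        cm[0, 1], cm[1, 0] = 9, 8
        assert decoding_accuracy(cm) == pytest.approx(29 / 46)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            decoding_accuracy(np.zeros((4, 4)))


def _planted_epochs(n_trials=40, n_channels=6, seed=0, sep=4.0,
                    active=slice(32, 64)):
    """Epochs whose first two channels carry class means on late samples."""
    rng = np.random.default_rng(seed)
    epochs = make_epochs(n_trials=n_trials, n_channels=n_channels,
                         n_samples=64, t0=-0.5, seed=seed)
    shift = {"up": (1, 0), "down": (-1, 0), "left": (0, 1), "right": (0, -1)}
    for i, lab in enumerate(epochs.labels):
        a, b = shift[lab]
        epochs.data[i, 0, active] += sep * a
        epochs.data[i, 1, active] += sep * b
    return epochs


def _cfg(**kw):
    defaults = dict(channel_subset=tuple(f"C{i}" for i in range(6)),
                    n_select_channels=3, n_folds=5, n_permutation_reps=4,
                    analysis_span=(-0.5, 0.0), rng_seed=0)
    defaults.update(kw)
    return PipelineConfig(**defaults)


class TestRunTimeSpecific:
    def test_single_window_grid_gives_length_one_curve(self):
        epochs = _planted_epochs()
        grid = make_grid((-0.25, 0.0), 0.25, 0.0625)
        cfg = _cfg()
        curve = run_time_specific(epochs, grid, cfg)
        assert curve.da_mean.shape == (1,)
        assert curve.fold_da.shape == (1, 5)

    def test_planted_effect_decodes_above_late_noise_window(self):
        epochs = _planted_epochs(sep=4.0)
        grid = make_grid((-0.5, 0.0), 0.25, 0.25)   # endpoints -0.25, 0.0
        cfg = _cfg()
        curve = run_time_specific(epochs, grid, cfg)
        # effect occupies the second half of the epoch only
        assert curve.da_mean[1] > curve.da_mean[0] + 0.2

    def test_every_test_trial_scored_exactly_once(self):
        epochs = _planted_epochs()
        grid = make_grid((-0.25, 0.0), 0.25, 0.0625)
        cfg = _cfg()
        curve = run_time_specific(epochs, grid, cfg)
        assert curve.confusions[0].sum() == epochs.n_trials

    def test_no_leakage_from_test_labels(self):
        """Corrupting test-fold labels leaves every fitted model unchanged."""
        from scpdecode.evaluation import _fit_fold
        from scpdecode import window_features

        epochs = _planted_epochs()
        grid = make_grid((-0.25, 0.0), 0.25, 0.0625)
        cfg = _cfg()
        wf = window_features(epochs, grid, 0.0, epochs.channel_labels, 16.0)
        train_idx = np.arange(8, 40)
        fm1 = _fit_fold(wf.matrix, epochs.labels, train_idx, wf.provenance, cfg)
        corrupted = epochs.labels.copy()
        corrupted[:8] = "up"                      # test-fold labels mangled
        fm2 = _fit_fold(wf.matrix, corrupted, train_idx, wf.provenance, cfg)
        assert np.array_equal(fm1.lda.means, fm2.lda.means)
        assert np.array_equal(fm1.lda.pooled_cov, fm2.lda.pooled_cov)
        assert fm1.channels == fm2.channels


class TestChanceLevel:
    def test_four_class_chance_near_quarter(self):
        epochs = make_epochs(n_trials=48, n_channels=6, n_samples=64, t0=-0.5,
                             seed=1)
        grid = make_grid((-0.25, 0.0), 0.25, 0.0625)
        cfg = _cfg(n_permutation_reps=10)
        chance = chance_level(epochs, grid, cfg, seed=0)
        assert abs(chance.grand_mean - 0.25) < 0.05
        assert chance.values.shape == (1, 10, 5)

    def test_two_class_chance_near_half(self):
        labels = np.array(["up", "down"] * 24, dtype=object)
        epochs = make_epochs(n_trials=48, n_channels=6, n_samples=64, t0=-0.5,
                             seed=2, labels=labels)
        grid = make_grid((-0.25, 0.0), 0.25, 0.0625)
        chance = chance_level(epochs, grid, _cfg(n_permutation_reps=10), seed=0)
        assert abs(chance.grand_mean - 0.5) < 0.08

    def test_fixed_seed_reproducible(self):
        epochs = make_epochs(n_trials=24, n_channels=4, n_samples=64, t0=-0.5)
        grid = make_grid((-0.25, 0.0), 0.25, 0.0625)
        cfg = _cfg(channel_subset=("C0", "C1", "C2", "C3"),
                   n_select_channels=2, n_folds=3, n_permutation_reps=3)
        a = chance_level(epochs, grid, cfg, seed=5)
        b = chance_level(epochs, grid, cfg, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_refit_only_mode_runs(self):
        epochs = make_epochs(n_trials=24, n_channels=4, n_samples=64, t0=-0.5)
        grid = make_grid((-0.25, 0.0), 0.25, 0.0625)
        cfg = _cfg(channel_subset=("C0", "C1", "C2", "C3"),
                   n_select_channels=2, n_folds=3, n_permutation_reps=2)
        chance = chance_level(epochs, grid, cfg, seed=1, mode="refit_only")
        assert 0.0 <= chance.grand_mean <= 1.0
        with pytest.raises(ValueError, match="mode"):
            chance_level(epochs, grid, cfg, mode="bogus")


def _curve(endpoints, fold_da, **kw):
    fold_da = np.asarray(fold_da, dtype=float)
    return DecodingCurve(endpoints=np.asarray(endpoints, dtype=float),
                         da_mean=fold_da.mean(axis=1),
                         da_sd=fold_da.std(axis=1, ddof=1),
                         fold_da=fold_da, mode="time_specific",
                         period="intention", **kw)


def _chance(endpoints, center=0.25, n=50, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(center, 0.02, size=(len(endpoints), 10, 5))
    return ChanceLevel(endpoints=np.asarray(endpoints, dtype=float),
                       values=vals)


class TestEarlyDetection:
    endpoints = np.round(np.arange(-1.0, 0.0001, 0.0625), 10)

    def test_curve_at_chance_has_no_detection(self):
        fold_da = np.random.default_rng(3).normal(0.25, 0.02,
                                                  (len(self.endpoints), 5))
        curve = _curve(self.endpoints, fold_da)
        det = early_detection(curve, _chance(self.endpoints), alpha=0.05,
                              k_consecutive=5)
        assert det is None
        assert curve.detection_time is None

    def test_all_windows_significant_detects_first_endpoint(self):
        fold_da = np.full((len(self.endpoints), 5), 0.9)
        curve = _curve(self.endpoints, fold_da)
        det = early_detection(curve, _chance(self.endpoints), alpha=0.05,
                              k_consecutive=5)
        assert det == pytest.approx(self.endpoints[0])

    def test_detection_starts_at_first_of_five_consecutive(self):
        fold_da = np.random.default_rng(4).normal(0.25, 0.01,
                                                  (len(self.endpoints), 5))
        fold_da[8:] = 0.9                       # significant from index 8 on
        curve = _curve(self.endpoints, fold_da)
        det = early_detection(curve, _chance(self.endpoints), alpha=0.05,
                              k_consecutive=5)
        assert det == pytest.approx(self.endpoints[8])

    def test_short_run_is_not_a_detection(self):
        fold_da = np.random.default_rng(5).normal(0.25, 0.01,
                                                  (len(self.endpoints), 5))
        fold_da[6:10] = 0.9                     # only 4 consecutive
        curve = _curve(self.endpoints, fold_da)
        assert early_detection(curve, _chance(self.endpoints), alpha=0.05,
                               k_consecutive=5) is None

    def test_fewer_windows_than_run_length_rejected(self):
        curve = _curve([-0.125, -0.0625], np.full((2, 5), 0.9))
        with pytest.raises(ValueError, match="consecutive"):
            early_detection(curve, _chance([-0.125, -0.0625]), 0.05, 5)


class TestSelectBestWindow:
    def _fitted_curve(self, fold_da, endpoints):
        epochs = _planted_epochs()
        grid = make_grid((-0.5, 0.0), 0.25, 0.0625)
        cfg = _cfg()
        curve = run_time_specific(epochs, grid, cfg)
        curve.fold_da = np.asarray(fold_da, dtype=float)
        curve.da_mean = curve.fold_da.mean(axis=1)
        return curve

    def test_increasing_curve_selects_last_preonset(self):
        n = 5
        fold_da = np.tile(np.linspace(0.3, 0.8, n)[:, None], (1, 5))
        curve = self._fitted_curve(fold_da, None)
        sel = select_best_window(curve)
        assert sel.window_endpoint == pytest.approx(0.0)

    def test_flat_curve_ties_toward_onset(self):
        curve = self._fitted_curve(np.full((5, 5), 0.5), None)
        sel = select_best_window(curve)
        assert sel.window_endpoint == pytest.approx(0.0)

    def test_post_onset_windows_ignored(self):
        epochs = _planted_epochs(n_trials=40)
        # span extends past onset; peak placed after onset must not win
        epochs2 = make_epochs(n_trials=40, n_channels=6, n_samples=96,
                              t0=-0.5, seed=0)
        epochs2.data[:, :, :64] = epochs.data
        grid = make_grid((-0.5, 0.25), 0.25, 0.0625)
        cfg = _cfg(analysis_span=(-0.5, 0.25))
        curve = run_time_specific(epochs2, grid, cfg)
        curve.da_mean = np.linspace(0.3, 0.9, len(grid.endpoints))  # max at +0.25
        sel = select_best_window(curve)
        assert sel.window_endpoint <= 0.0

    def test_no_preonset_endpoint_rejected(self):
        epochs = make_epochs(n_trials=20, n_channels=4, n_samples=64, t0=0.0)
        grid = make_grid((0.0, 0.5), 0.25, 0.25)
        cfg = _cfg(channel_subset=("C0", "C1", "C2", "C3"),
                   n_select_channels=2, analysis_span=(0.0, 0.5))
        curve = run_time_specific(epochs, grid, cfg)
        with pytest.raises(ValueError, match="pre-onset"):
            select_best_window(curve)


class TestRunSelected:
    def test_definitional_identity_at_training_endpoint(self):
        epochs = _planted_epochs()
        grid = make_grid((-0.5, 0.0), 0.25, 0.0625)
        cfg = _cfg()
        curve = run_time_specific(epochs, grid, cfg)
        sel = select_best_window(curve)
        frozen = run_selected(sel, epochs, grid, cfg)
        wi = int(np.argmin(np.abs(np.asarray(grid.endpoints)
                                  - sel.window_endpoint)))
        assert np.allclose(frozen.fold_da[wi], curve.fold_da[wi])
        assert frozen.mode == "selected_classifier"

    def test_frozen_model_sees_only_matching_test_trials(self):
        epochs = _planted_epochs()
        grid = make_grid((-0.25, 0.0), 0.25, 0.0625)
        cfg = _cfg()
        curve = run_time_specific(epochs, grid, cfg)
        sel = select_best_window(curve)
        # epochs restricted to a subset of trials still scores by trial id
        sub = _planted_epochs()
        keep = np.arange(0, 40, 2)
        sub.data, sub.labels, sub.trial_ids = (sub.data[keep],
                                               sub.labels[keep],
                                               sub.trial_ids[keep])
        frozen = run_selected(sel, sub, grid, cfg)
        assert frozen.fold_da.shape == (1, 5)
        assert np.all((frozen.fold_da >= 0) & (frozen.fold_da <= 1))
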
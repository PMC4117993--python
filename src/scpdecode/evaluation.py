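"""Quantitative evaluation of the sliding-window decoder.

For every window endpoint the pipeline standardizes the training
features, ranks channels by CVA discriminant power, keeps the top ones,
fits a pooled-covariance LDA, and scores the held-out fold — under a
chronological 5-fold cross-validation whose folds are contiguous blocks
of trials in recording order (no shuffling, so the estimate respects the
non-stationarity of a session).  Chance level comes from re-running the
identical procedure with permuted training labels (default 10
repetitions × 5 folds), and a window counts as decoding above chance
when a one-sided Wilcoxon rank-sum test of its fold accuracies against
the permuted accuracies is significant; early detection is the first run
of five consecutive significant windows.  The best pre-onset window's
frozen per-fold models are then re-applied across all windows to
measure sensitivity (intention period, onset-aligned) and specificity
(idle period, cue-aligned).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .cva import fit_cva, standardize_fit
from .data_model import PipelineConfig
from .lda import LDAModel, confusion_matrix, fit_lda, predict
from .windows import EpochSet, WindowGrid, window_features


# ---------------------------------------------------------------------------
# Folds and accuracy
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Contiguous chronological fold assignment (block k is test fold k)."""

    n_folds: int
    fold_of: Dict[int, int]              # trial_id → fold
    folds: List[np.ndarray]              # trial ids per fold, in order

    def test_indices(self, trial_ids: np.ndarray, fold: int) -> np.ndarray:
        mask = np.array([self.fold_of.get(t, -1) == fold for t in trial_ids])
        return np.where(mask)[0]


def plan_folds(trial_ids: Sequence[int], n_folds: int) -> FoldPlan:
    """Split trials (given in recording order) into near-equal contiguous blocks."""
    ids = np.asarray(trial_ids)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if len(ids) < n_folds:
        raise ValueError("more folds than trials")
    if np.any(np.diff(ids) <= 0):
        raise ValueError("trial ids must be strictly increasing (recording order)")
    base, rem = divmod(len(ids), n_folds)
    sizes = [base + 1 if k < rem else base for k in range(n_folds)]
    bounds = np.cumsum([0] + sizes)
    folds = [ids[bounds[k]:bounds[k + 1]] for k in range(n_folds)]
    fold_of = {int(t): k for k, blk in enumerate(folds) for t in blk}
    return FoldPlan(n_folds=n_folds, fold_of=fold_of, folds=folds)


def decoding_accuracy(cm: np.ndarray) -> float:
    """Trace over total of a confusion matrix (rows actual, cols predicted)."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


# ---------------------------------------------------------------------------
# Per-fold fit
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    """Everything needed to re-apply one fold's classifier elsewhere."""

    mu: np.ndarray                       # full-feature standardization mean
    sd: np.ndarray
    col_mask: np.ndarray                 # columns of the selected channels
    channels: List[str]
    lda: LDAModel


def _fit_fold(matrix: np.ndarray, labels: np.ndarray, train_idx: np.ndarray,
              provenance, cfg: PipelineConfig,
              train_labels: Optional[np.ndarray] = None,
              channels: Optional[List[str]] = None) -> FoldModel:
    ytr = labels[train_idx] if train_labels is None else train_labels
    Xtr = matrix[train_idx]
    mu, sd = standardize_fit(Xtr)
    Xtr = (Xtr - mu) / sd
    if channels is None:
        res = fit_cva(Xtr, ytr, provenance, n_select=cfg.n_select_channels,
                      standardize=False)
        channels = res.selected
    keep = set(channels)
    col_mask = np.array([name in keep for name, _t in provenance])
    lda = fit_lda(Xtr[:, col_mask], ytr, shrinkage=cfg.shrinkage)
    return FoldModel(mu=mu, sd=sd, col_mask=col_mask,
                     channels=list(channels), lda=lda)


def _score_fold(fm: FoldModel, matrix: np.ndarray, labels: np.ndarray,
                test_idx: np.ndarray, classes) -> Tuple[float, np.ndarray]:
    Xte = (matrix[test_idx] - fm.mu) / fm.sd
    pred = predict(fm.lda, Xte[:, fm.col_mask])
    cm = confusion_matrix(labels[test_idx], pred, classes)
    return decoding_accuracy(cm), cm


# ---------------------------------------------------------------------------
# Decoding curves
# ---------------------------------------------------------------------------

@dataclass
class DecodingCurve:
    endpoints: np.ndarray
    da_mean: np.ndarray
    da_sd: np.ndarray
    fold_da: np.ndarray                          # windows × folds
    mode: str                                    # "time_specific" | "selected_classifier"
    period: str                                  # "intention" | "idle"
    chance_mean: Optional[np.ndarray] = None
    chance_distribution: Optional[np.ndarray] = None   # windows × (reps·folds)
    pvalues: Optional[np.ndarray] = None
    detection_time: Optional[float] = None
    fold_models: Optional[list] = None           # per window: list of FoldModel
    fold_plan: Optional[FoldPlan] = None
    confusions: Optional[list] = None            # per window: summed over folds
    feature_rate: Optional[float] = None
    window_len: Optional[float] = None
    phase_encoding: Optional[str] = None


@dataclass
class SelectedClassifier:
    """The frozen time-specific classifier with the best pre-onset accuracy."""

    window_endpoint: float
    fold_models: List[FoldModel]
    fold_plan: FoldPlan
    feature_rate: float
    window_len: float
    phase_encoding: Optional[str] = None


def _all_window_features(epochs: EpochSet, grid: WindowGrid,
                         cfg: PipelineConfig,
                         phase_encoding: Optional[str] = None):
    return [
        window_features(epochs, grid, e, epochs.channel_labels,
                        cfg.feature_rate, phase_encoding=phase_encoding)
        for e in grid.endpoints
    ]


def run_time_specific(epochs: EpochSet, grid: WindowGrid, cfg: PipelineConfig,
                      phase_encoding: Optional[str] = None,
                      keep_models: bool = True) -> DecodingCurve:
    """Train and score one classifier per window under chronological CV."""
    plan = plan_folds(epochs.trial_ids, cfg.n_folds)
    classes = sorted(set(epochs.labels))
    wfs = _all_window_features(epochs, grid, cfg, phase_encoding)
    n_w = len(grid.endpoints)
    fold_da = np.empty((n_w, cfg.n_folds))
    models: list = []
    confusions: list = []
    for wi, wf in enumerate(wfs):
        per_fold = []
        cm_sum = np.zeros((len(classes), len(classes)), dtype=int)
        for k in range(cfg.n_folds):
            test_idx = plan.test_indices(epochs.trial_ids, k)
            train_idx = np.setdiff1d(np.arange(epochs.n_trials), test_idx)
            fm = _fit_fold(wf.matrix, epochs.labels, train_idx,
                           wf.provenance, cfg)
            fold_da[wi, k], cm = _score_fold(fm, wf.matrix, epochs.labels,
                                             test_idx, classes)
            cm_sum += cm
            per_fold.append(fm)
        if keep_models:
            models.append(per_fold)
        confusions.append(cm_sum)
    return DecodingCurve(
        endpoints=np.asarray(grid.endpoints),
        da_mean=fold_da.mean(axis=1),
        da_sd=fold_da.std(axis=1, ddof=1),
        fold_da=fold_da,
        mode="time_specific",
        period="intention" if epochs.alignment == "onset" else "idle",
        fold_models=models if keep_models else None,
        fold_plan=plan,
        confusions=confusions,
        feature_rate=cfg.feature_rate,
        window_len=cfg.window_len,
        phase_encoding=phase_encoding,
    )


# ---------------------------------------------------------------------------
# Permutation chance level
# ---------------------------------------------------------------------------

@dataclass
class ChanceLevel:
    endpoints: np.ndarray
    values: np.ndarray                   # windows × reps × folds

    @property
    def per_window(self) -> np.ndarray:  # windows × (reps·folds)
        return self.values.reshape(self.values.shape[0], -1)

    @property
    def mean(self) -> np.ndarray:
        return self.per_window.mean(axis=1)

    @property
    def grand_mean(self) -> float:
        return float(self.values.mean())


def chance_level(epochs: EpochSet, grid: WindowGrid, cfg: PipelineConfig,
                 seed: Optional[int] = None, mode: str = "reselect",
                 phase_encoding: Optional[str] = None) -> ChanceLevel:
    """Permuted-label chance distribution per window.

    Each repetition permutes the training labels afresh in every fold and
    re-runs the full per-window pipeline, scoring against the intact test
    labels.  ``mode="reselect"`` re-runs CVA channel selection under the
    permuted labels (avoids optimistic selection bias); ``"refit_only"``
    keeps the true-label channel selection and only refits the LDA.
    """
    if mode not in ("reselect", "refit_only"):
        raise ValueError(f"unknown chance mode {mode!r}")
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    plan = plan_folds(epochs.trial_ids, cfg.n_folds)
    classes = sorted(set(epochs.labels))
    wfs = _all_window_features(epochs, grid, cfg, phase_encoding)
    values = np.empty((len(grid.endpoints), cfg.n_permutation_reps,
                       cfg.n_folds))
    for wi, wf in enumerate(wfs):
        true_channels = None
        if mode == "refit_only":
            true_channels = []
            for k in range(cfg.n_folds):
                test_idx = plan.test_indices(epochs.trial_ids, k)
                train_idx = np.setdiff1d(np.arange(epochs.n_trials), test_idx)
                fm = _fit_fold(wf.matrix, epochs.labels, train_idx,
                               wf.provenance, cfg)
                true_channels.append(fm.channels)
        for rep in range(cfg.n_permutation_reps):
            for k in range(cfg.n_folds):
                test_idx = plan.test_indices(epochs.trial_ids, k)
                train_idx = np.setdiff1d(np.arange(epochs.n_trials), test_idx)
                permuted = rng.permutation(epochs.labels[train_idx])
                fm = _fit_fold(
                    wf.matrix, epochs.labels, train_idx, wf.provenance, cfg,
                    train_labels=permuted,
                    channels=None if mode == "reselect" else true_channels[k],
                )
                values[wi, rep, k], _ = _score_fold(fm, wf.matrix,
                                                    epochs.labels, test_idx,
                                                    classes)
    return ChanceLevel(endpoints=np.asarray(grid.endpoints), values=values)


def chance_band(chance_values: np.ndarray, n_folds: int, level: float = 0.95,
                n_boot: int = 2000, seed: int = 0) -> Tuple[float, float]:
    """Percentile band for a fold-mean DA under the permutation null.

    Resamples ``n_folds`` values from the flat permuted-DA pool and takes
    the band of the resulting means (deterministic given ``seed``).
    """
    rng = np.random.default_rng(seed)
    pool = np.asarray(chance_values).ravel()
    means = rng.choice(pool, size=(n_boot, n_folds), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Detection and selected-classifier analysis
# ---------------------------------------------------------------------------

def early_detection(curve: DecodingCurve, chance: ChanceLevel,
                    alpha: float = 0.05,
                    k_consecutive: int = 5) -> Optional[float]:
    """First endpoint starting ``k_consecutive`` windows significantly above chance.

    Per window, a one-sided Wilcoxon rank-sum test compares the fold
    accuracies against all permuted accuracies of the same window.  The
    curve's ``pvalues``, ``chance_*`` and ``detection_time`` fields are
    filled in; the return value is the detection endpoint or None.
    """
    if curve.fold_da.shape[0] < k_consecutive:
        raise ValueError("fewer windows than the consecutive-run length")
    if not np.array_equal(curve.endpoints, chance.endpoints):
        raise ValueError("curve and chance grids differ")
    pv = np.array([
        stats.ranksums(curve.fold_da[w], chance.per_window[w],
                       alternative="greater").pvalue
        for w in range(curve.fold_da.shape[0])
    ])
    curve.pvalues = pv
    curve.chance_mean = chance.mean
    curve.chance_distribution = chance.per_window
    sig = pv < alpha
    detection = None
    for i in range(len(sig) - k_consecutive + 1):
        if sig[i:i + k_consecutive].all():
            detection = float(curve.endpoints[i])
            break
    curve.detection_time = detection
    return detection


def select_best_window(curve: DecodingCurve) -> SelectedClassifier:
    """Freeze the per-fold models of the best pre-onset window.

    Post-onset windows reflect execution rather than intention and are
    excluded; ties go to the later endpoint (closer to onset).
    """
    if curve.fold_models is None:
        raise ValueError("curve was computed without keep_models")
    pre = np.where(curve.endpoints <= 0)[0]
    if len(pre) == 0:
        raise ValueError("no pre-onset window endpoint")
    best_da = curve.da_mean[pre].max()
    idx = pre[np.where(np.isclose(curve.da_mean[pre], best_da))[0][-1]]
    return SelectedClassifier(
        window_endpoint=float(curve.endpoints[idx]),
        fold_models=curve.fold_models[idx],
        fold_plan=curve.fold_plan,
        feature_rate=curve.feature_rate,
        window_len=curve.window_len,
        phase_encoding=curve.phase_encoding,
    )


def run_selected(selected: SelectedClassifier, epochs: EpochSet,
                 grid: WindowGrid, cfg: PipelineConfig) -> DecodingCurve:
    """Score the frozen per-fold models at every window of ``grid``.

    Each fold's model (standardization, channel set, LDA) is applied to
    that fold's test trials only, matched by trial id, so every trial is
    scored exactly once per window.
    """
    plan = selected.fold_plan
    classes = list(selected.fold_models[0].lda.class_labels)
    wfs = _all_window_features(epochs, grid, cfg, selected.phase_encoding)
    n_w = len(grid.endpoints)
    fold_da = np.full((n_w, plan.n_folds), np.nan)
    for wi, wf in enumerate(wfs):
        for k, fm in enumerate(selected.fold_models):
            test_idx = plan.test_indices(epochs.trial_ids, k)
            if len(test_idx) == 0:
                continue
            fold_da[wi, k], _ = _score_fold(fm, wf.matrix, epochs.labels,
                                            test_idx, classes)
    return DecodingCurve(
        endpoints=np.asarray(grid.endpoints),
        da_mean=np.nanmean(fold_da, axis=1),
        da_sd=np.nanstd(fold_da, axis=1, ddof=1),
        fold_da=fold_da,
        mode="selected_classifier",
        period="intention" if epochs.alignment == "onset" else "idle",
        fold_plan=plan,
    )


def band_comparison(recording, bands, cfg: PipelineConfig,
                    phase_encoding: Optional[str] = None
                    ) -> Dict[str, DecodingCurve]:
    """Full time-specific pipeline per frequency band."""
    from .pipeline import preprocess_recording  # local import: avoids a cycle

    from .windows import epoch, make_grid

    out: Dict[str, DecodingCurve] = {}
    grid = make_grid(cfg.analysis_span, cfg.window_len, cfg.window_step)
    for band in bands:
        band_sig, events = preprocess_recording(recording, cfg, band)
        epochs = epoch(band_sig, events, "onset", cfg.analysis_span)
        out[band.name] = run_time_specific(epochs, grid, cfg,
                                           phase_encoding=phase_encoding)
    return out
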
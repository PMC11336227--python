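"""Multivariate cross-decoding of perceived valence from pre-stimulus power.

A linear SVM is trained on the single-trial, non-baselined time-averaged
power features (channels x frequencies, 2..60 Hz, window -1000..-200 ms) of
Experiment 1 and tested once on Experiment 2 of the same subject; at group
level a leave-one-participant-out scheme trains on the pooled (per-subject
z-transformed) Experiment-1 trials of all other subjects.  Accuracies are
assessed with one-sided exact binomial tests against chance (0.5 by the
class-balance guarantee), peak accuracies are taken within the binomially
significant mask (falling back to the global maximum), and the cohort of
peaks is compared to chance with a one-sample t-test.

A control analysis checks that pre-stimulus patterns reflect the upcoming
rather than the previous rating: an SVM trained on previous-trial labels is
tested against current labels and compared (paired t over subjects) with a
standard within-experiment k-fold decoder of current labels.

Entry points exist at two levels: TFR-level (``cross_decode_subject``,
``group_lopocv``, ``previous_label_control``) and feature-level
(``decode_features`` and friends) for callers that precompute the feature
matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .tfr import TimeFreqRep, time_average

__all__ = [
    "DecodeConfig",
    "DecodeResult",
    "build_features",
    "fit_svm_grid",
    "decode_features",
    "cross_decode_subject",
    "binomial_accuracy_test",
    "peak_accuracy",
    "group_ttest_vs_chance",
    "group_lopocv",
    "group_lopocv_features",
    "previous_label_control",
    "previous_label_control_features",
    "binomial_pit",
    "zscore_features",
]

_CLASSES = ("negative", "positive")


@dataclass(frozen=True)
class DecodeConfig:
    """Decoding parameters.

    The feature window is strictly pre-stimulus: any time-frequency bin
    whose analysis window reaches stimulus onset is excluded from the
    features, so perturbing post-onset data cannot change any accuracy.
    """

    window: tuple = (-1000.0, -200.0)
    fmax: float = 60.0
    C_grid: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    inner_folds: int = 5
    chance: float = 0.5
    mode: str = "single"  # "single" | "per_frequency"
    seed: int = 0

    def __post_init__(self):
        if len(self.C_grid) == 0 or any(c <= 0 for c in self.C_grid):
            raise ValueError("C_grid must be non-empty positive reals")
        if self.window[1] > -200.0:
            raise ValueError("feature window must end at or before -200 ms")
        if self.mode not in ("single", "per_frequency"):
            raise ValueError(f"unknown accuracy mode {self.mode!r}")


@dataclass
class DecodeResult:
    """Per-decoder accuracies with their binomial significance."""

    accuracies: np.ndarray
    n_test: np.ndarray
    p_values: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    peak: float = np.nan
    freqs: np.ndarray | None = None
    mode: str = "single"
    chosen_C: list | None = None
    train_experiment: int | None = None
    test_experiment: int | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# features


def _prestimulus_features(tfr: TimeFreqRep, config: DecodeConfig) -> tuple:
    """(obs, channels*freqs) matrix of strictly pre-stimulus features."""
    if tfr.unit != "raw":
        raise ValueError("decoding features require raw power (no baseline)")
    half = tfr.window_length / 2.0
    keep = (tfr.times >= config.window[0]) & (tfr.times <= config.window[1]) \
        & (tfr.times + half <= 0.0)
    if not keep.any():
        raise ValueError("no strictly pre-stimulus time bins in the window")
    sub = replace(tfr, power=tfr.power[..., keep], times=tfr.times[keep])
    feats, freqs = time_average(sub, window=config.window, fmax=config.fmax)
    return feats.reshape(feats.shape[0], -1), freqs


def build_features(tfr: TimeFreqRep, labels, config: DecodeConfig) -> tuple:
    """Trials x (channel-major channel x frequency) feature matrix + labels.

    Requires raw (non-baselined) power and equalized negative/positive
    counts.  Returns ``(X, y, freqs)``; in per-frequency mode the caller
    reshapes X back via ``freqs``.
    """
    labels = np.asarray(labels)
    if len(labels) != tfr.n_obs:
        raise ValueError("labels do not match the number of trials")
    bad = set(labels) - set(_CLASSES)
    if bad:
        raise ValueError(f"labels must be negative/positive, got {sorted(bad)}")
    counts = [np.sum(labels == c) for c in _CLASSES]
    if counts[0] != counts[1]:
        raise ValueError("class counts must be equalized before decoding")
    X, freqs = _prestimulus_features(tfr, config)
    return X, labels, freqs


def fit_svm_grid(X: np.ndarray, y, config: DecodeConfig) -> GridSearchCV:
    """Linear SVM with C chosen by inner stratified k-fold grid search.

    The grid is searched on the training set only and the final rule is
    refit on all training data at the chosen C; ties on inner-CV accuracy
    resolve to the smallest C.
    """
    y = np.asarray(y)
    classes, cls_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if cls_counts.min() < 2:
        raise ValueError("need at least 2 trials per class")
    n_splits = int(min(config.inner_folds, cls_counts.min()))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    grid = GridSearchCV(SVC(kernel="linear"),
                        {"C": sorted(config.C_grid)},
                        scoring="accuracy", cv=cv, refit=True)
    grid.fit(X, y)
    return grid


# ---------------------------------------------------------------------------
# accuracy statistics


def binomial_accuracy_test(accuracies, n_test, chance: float = 0.5,
                           threshold: float = 0.05) -> tuple:
    """One-sided exact binomial p-values for accuracies, and their mask.

    p = P(K >= k | n_test, chance) with k = accuracy * n_test; the mask
    marks accuracies with p <= ``threshold``.
    """
    acc = np.atleast_1d(np.asarray(accuracies, dtype=float))
    n = np.broadcast_to(np.asarray(n_test, dtype=int), acc.shape)
    if np.any(n < 1):
        raise ValueError("n_test must be >= 1")
    k_float = acc * n
    k = np.round(k_float)
    if np.any(np.abs(k_float - k) > 1e-6):
        raise ValueError("accuracy * n_test is not an integer trial count")
    p = stats.binom.sf(k - 1, n, chance)
    return p, p <= threshold


def peak_accuracy(result: DecodeResult) -> float:
    """Max accuracy within the binomial mask; global max if the mask is empty."""
    acc = result.accuracies
    if result.mask.any():
        return float(acc[result.mask].max())
    return float(acc.max())


def group_ttest_vs_chance(peaks, chance: float = 0.5) -> tuple:
    """One-sample t of per-subject peak accuracies against chance.

    Returns (t, df, p two-sided); t is NaN (flagged) when the peaks have
    zero variance.
    """
    peaks = np.asarray(peaks, dtype=float)
    n = len(peaks)
    if n < 2:
        raise ValueError("need at least 2 peaks")
    if peaks.std(ddof=1) == 0:
        return float("nan"), n - 1, float("nan")
    t, p = stats.ttest_1samp(peaks, chance)
    return float(t), n - 1, float(p)


def binomial_pit(accuracies, n_test, chance: float = 0.5,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Randomized probability-integral transform of accuracies.

    Under H0 (correct counts ~ Binomial(n_test, chance)) the returned
    values are exactly Uniform(0, 1), which makes chance calibration
    testable with a Kolmogorov-Smirnov test even when n_test varies.
    """
    rng = np.random.default_rng() if rng is None else rng
    acc = np.asarray(accuracies, dtype=float)
    n = np.broadcast_to(np.asarray(n_test, dtype=int), acc.shape)
    k = np.round(acc * n).astype(int)
    lower = stats.binom.cdf(k - 1, n, chance)
    pmf = stats.binom.pmf(k, n, chance)
    return lower + rng.uniform(size=acc.shape) * pmf


# ---------------------------------------------------------------------------
# decoders


def _decode_once(X_train, y_train, X_test, y_test, config) -> tuple:
    model = fit_svm_grid(X_train, y_train, config)
    acc = float(np.mean(model.predict(X_test) == np.asarray(y_test)))
    return acc, float(model.best_params_["C"])


def decode_features(X1, y1, X2, y2, config: DecodeConfig,
                    freqs=None, n_channels: int | None = None) -> DecodeResult:
    """Train on (X1, y1), test once on (X2, y2).

    In "per_frequency" mode ``freqs`` and ``n_channels`` describe the
    channel-major feature layout and one decoder is fit per frequency.
    """
    y1 = np.asarray(y1)
    y2 = np.asarray(y2)
    n_test = len(y2)
    if config.mode == "single":
        acc, c = _decode_once(X1, y1, X2, y2, config)
        accs, cs, fr = np.array([acc]), [c], None
    else:
        if freqs is None or n_channels is None:
            raise ValueError("per-frequency mode needs freqs and n_channels")
        n_f = len(freqs)
        X1f = np.asarray(X1).reshape(len(y1), n_channels, n_f)
        X2f = np.asarray(X2).reshape(n_test, n_channels, n_f)
        accs = np.empty(n_f)
        cs = []
        for i in range(n_f):
            accs[i], c = _decode_once(X1f[:, :, i], y1, X2f[:, :, i], y2, config)
            cs.append(c)
        fr = np.asarray(freqs)
    p, mask = binomial_accuracy_test(accs, n_test, config.chance)
    result = DecodeResult(accs, np.full(accs.shape, n_test), p, mask,
                          freqs=fr, mode=config.mode, chosen_C=cs,
                          seed=config.seed)
    result.peak = peak_accuracy(result)
    return result


def cross_decode_subject(tfr1: TimeFreqRep, labels1, tfr2: TimeFreqRep,
                         labels2, config: DecodeConfig) -> DecodeResult:
    """Within-subject cross-experiment decoding: train exp 1, test exp 2 once.

    In "single" mode all channel x frequency features feed one decoder; in
    "per_frequency" mode each frequency's channel vector is decoded
    independently, giving one accuracy per frequency.
    """
    X1, y1, freqs = build_features(tfr1, labels1, config)
    X2, y2, _ = build_features(tfr2, labels2, config)
    result = decode_features(X1, y1, X2, y2, config, freqs=freqs,
                             n_channels=len(tfr1.channels))
    result.train_experiment, result.test_experiment = 1, 2
    return result


def zscore_features(X: np.ndarray) -> np.ndarray:
    """Per-feature z-transform across a subject's trials (within experiment)."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd


def group_lopocv_features(subjects, config: DecodeConfig) -> tuple:
    """Leave-one-participant-out cross-decoding on precomputed features.

    ``subjects`` is a list of ``(X1, y1, X2, y2)`` per participant; the
    feature matrices are z-transformed per subject and experiment before
    pooling.  Returns ``(results, peaks)``.
    """
    prepared = [(zscore_features(X1), np.asarray(y1),
                 zscore_features(X2), np.asarray(y2))
                for X1, y1, X2, y2 in subjects]
    if len(prepared) < 3:
        raise ValueError("leave-one-participant-out needs at least 3 subjects")
    results = []
    for held in range(len(prepared)):
        X_train = np.concatenate([prepared[i][0] for i in range(len(prepared))
                                  if i != held])
        y_train = np.concatenate([prepared[i][1] for i in range(len(prepared))
                                  if i != held])
        _, _, X_test, y_test = prepared[held]
        acc, c = _decode_once(X_train, y_train, X_test, y_test, config)
        p, mask = binomial_accuracy_test(np.array([acc]), len(y_test), config.chance)
        res = DecodeResult(np.array([acc]), np.array([len(y_test)]), p, mask,
                           mode="single", chosen_C=[c], train_experiment=1,
                           test_experiment=2, seed=config.seed)
        res.peak = peak_accuracy(res)
        results.append(res)
    return results, np.array([r.peak for r in results])


def group_lopocv(subjects, config: DecodeConfig) -> tuple:
    """TFR-level wrapper of :func:`group_lopocv_features`.

    ``subjects`` yields ``(tfr1, labels1, tfr2, labels2)`` per participant;
    subjects missing an experiment are dropped with a warning.
    """
    prepared = []
    for i, item in enumerate(subjects):
        if item is None or any(x is None for x in item):
            warnings.warn(f"subject {i} is missing an experiment; excluded")
            continue
        tfr1, labels1, tfr2, labels2 = item
        X1, y1, _ = build_features(tfr1, labels1, config)
        X2, y2, _ = build_features(tfr2, labels2, config)
        prepared.append((X1, y1, X2, y2))
    return group_lopocv_features(prepared, config)


def _equalized_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = {c: np.flatnonzero(labels == c) for c in _CLASSES}
    n_keep = min(len(v) for v in idx.values())
    out = []
    for c in _CLASSES:
        arr = idx[c]
        if len(arr) > n_keep:
            arr = np.sort(rng.choice(arr, size=n_keep, replace=False))
        out.append(arr)
    return np.sort(np.concatenate(out))


def previous_label_control_features(X: np.ndarray, current, previous,
                                    config: DecodeConfig, min_trials: int = 10,
                                    n_folds: int = 5, n_repeats: int = 4):
    """Previous- vs current-rating decodability for one subject.

    ``X`` holds features of trials whose current AND previous ratings are
    both negative/positive (exclusions applied by the caller or the
    TFR-level wrapper).  Decoder A trains on previous-trial labels
    (classes equalized on the previous labels) and is scored on those same
    trials against their *current* labels; decoder B is a stratified k-fold
    (5 folds x 4 repeats) on current labels.  Returns
    ``(acc_previous, acc_current)``, or None (with a warning) when fewer
    than ``min_trials`` usable trials per class remain.
    """
    cur = np.asarray(current)
    prv = np.asarray(previous)
    for lab in (cur, prv):
        counts = [np.sum(lab == c) for c in _CLASSES]
        if min(counts) < min_trials:
            warnings.warn(f"fewer than {min_trials} usable trials per class; "
                          "subject skipped")
            return None
    rng = np.random.default_rng(config.seed)

    sel = _equalized_indices(prv, rng)
    model = fit_svm_grid(X[sel], prv[sel], config)
    acc_prev = float(np.mean(model.predict(X[sel]) == cur[sel]))

    sel = _equalized_indices(cur, rng)
    Xc, yc = X[sel], cur[sel]
    accs = []
    for rep in range(n_repeats):
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                             random_state=config.seed + rep)
        for train, test in cv.split(Xc, yc):
            acc, _ = _decode_once(Xc[train], yc[train], Xc[test], yc[test], config)
            accs.append(acc)
    return acc_prev, float(np.mean(accs))


def previous_label_control_subject(tfr: TimeFreqRep, ratings, previous_ratings,
                                   config: DecodeConfig, min_trials: int = 10,
                                   n_folds: int = 5, n_repeats: int = 4):
    """TFR-level previous-rating control for one subject.

    Trials whose previous rating is neutral, missed or undefined (first
    trial of a run) are removed before decoding.
    """
    ratings = np.asarray(ratings)
    prev = np.asarray(previous_ratings)
    usable = np.isin(ratings, _CLASSES) & np.isin(prev, _CLASSES)
    X, _ = _prestimulus_features(tfr.select_obs(np.flatnonzero(usable)), config)
    return previous_label_control_features(X, ratings[usable], prev[usable],
                                           config, min_trials=min_trials,
                                           n_folds=n_folds, n_repeats=n_repeats)


def previous_label_control(subject_items, config: DecodeConfig,
                           min_trials: int = 10) -> dict:
    """Cohort-level previous-rating control with a paired t-test.

    ``subject_items`` yields ``(tfr1, ratings, previous_ratings)`` per
    subject.  Returns accuracies per subject plus the paired t comparing
    current-label with previous-label decoding.
    """
    pairs = []
    for tfr, ratings, prev in subject_items:
        out = previous_label_control_subject(tfr, ratings, prev, config,
                                             min_trials=min_trials)
        if out is not None:
            pairs.append(out)
    return summarize_previous_control(pairs)


def summarize_previous_control(pairs) -> dict:
    """Paired t over subjects for (acc_previous, acc_current) pairs."""
    if len(pairs) < 2:
        raise ValueError("previous-label control needs at least 2 usable subjects")
    acc_prev = np.array([p[0] for p in pairs])
    acc_cur = np.array([p[1] for p in pairs])
    diff = acc_cur - acc_prev
    if diff.std(ddof=1) == 0:
        t = p = float("nan")
    else:
        t, p = stats.ttest_rel(acc_cur, acc_prev)
    return {"acc_previous": acc_prev, "acc_current": acc_cur,
            "t": float(t), "df": len(diff) - 1, "p": float(p)}
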
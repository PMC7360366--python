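"""Linear multiclass decoding of odor identity from population vectors.

Within-state accuracy uses a Crammer-Singer linear SVM with stratified
10-fold cross-validation on 480 ms spike-count features; cross-state
generalization trains on all awake trials and tests on all anesthetized
trials; cross-time stability trains and tests on different time bins of
kernel-smoothed rate trajectories aligned to the first inhalation after
odor offset, with leave-one-trial-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC


class _QuietSVC(LinearSVC):
    def fit(self, X, y, sample_weight=None):
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            return super().fit(X, y, sample_weight=sample_weight)


def _svm(C: float) -> LinearSVC:
    # ties among class scores resolve to the lowest class index
    return _QuietSVC(multi_class="crammer_singer", C=C, max_iter=20000,
                     random_state=0)


def make_folds(y: np.ndarray, n_folds: int, seed: int) -> list:
    """Stratified, seeded fold assignment; every trial is held out once.

    The fold count drops (with a warning) if a class has fewer
    instances than requested folds.
    """
    y = np.asarray(y)
    min_count = int(np.bincount(pd.factorize(y)[0]).min())
    if min_count < n_folds:
        warnings.warn(
            f"smallest class has {min_count} trials; reducing folds "
            f"from {n_folds} to {min_count}", stacklevel=2)
        n_folds = min_count
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(y.size), y))
    held = np.concatenate([te for _, te in folds])
    if np.unique(held).size != y.size:
        raise RuntimeError("fold builder leaked or dropped trials")
    return folds


def decode_within(X: np.ndarray, y: np.ndarray, n_folds: int = 10,
                  C: float = 1.0, seed: int = 0,
                  zscore: bool = False) -> float:
    """Stratified k-fold CV accuracy of the linear multiclass SVM."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if zscore:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    correct = 0
    for tr, te in make_folds(y, n_folds, seed):
        clf = _svm(C).fit(X[tr], y[tr])
        correct += int(np.sum(clf.predict(X[te]) == y[te]))
    return correct / y.size


@dataclass
class DecodeResult:
    sizes: np.ndarray
    accuracies: list[np.ndarray]   # per size, one accuracy per draw
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    chance: float
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size": self.sizes, "accuracy": self.mean,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "chance": self.chance, "mode": self.mode,
        })


def accuracy_vs_size(X: np.ndarray, y: np.ndarray, sizes,
                     n_draws: int = 200, n_boot: int = 1000,
                     n_folds: int = 10, C: float = 1.0, seed: int = 0,
                     mode: str = "within",
                     X_test: np.ndarray | None = None,
                     y_test: np.ndarray | None = None) -> DecodeResult:
    """Decoding accuracy as a function of pseudopopulation size.

    For each size: ``n_draws`` random cell subsets (without replacement)
    are decoded, and a percentile bootstrap (``n_boot`` resamples of the
    accuracy distribution) gives the 95% CI of the mean.  When
    ``X_test`` is given, accuracy is cross-state (train on X, test on
    X_test with the same cell subset); otherwise within-state CV.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, float)
    n_cells = X.shape[1]
    out_sizes, accs, means, lo, hi = [], [], [], [], []
    for size in sizes:
        if size > n_cells:
            warnings.warn(f"size {size} exceeds population ({n_cells}); skipped",
                          stacklevel=2)
            continue
        draws = np.empty(n_draws)
        for d in range(n_draws):
            cols = rng.choice(n_cells, size, replace=False)
            if X_test is None:
                draws[d] = decode_within(X[:, cols], y, n_folds=n_folds, C=C,
                                         seed=int(rng.integers(2**31)))
            else:
                draws[d] = decode_cross_state(X[:, cols], y,
                                              np.asarray(X_test)[:, cols],
                                              y_test, C=C)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            boot[b] = rng.choice(draws, draws.size, replace=True).mean()
        out_sizes.append(size)
        accs.append(draws)
        means.append(draws.mean())
        lo.append(np.percentile(boot, 2.5))
        hi.append(np.percentile(boot, 97.5))
    return DecodeResult(np.asarray(out_sizes), accs, np.asarray(means),
                        np.asarray(lo), np.asarray(hi),
                        chance=1.0 / np.unique(y).size, mode=mode)


def decode_cross_state(X_awake: np.ndarray, y_awake: np.ndarray,
                       X_kx: np.ndarray, y_kx: np.ndarray,
                       C: float = 1.0) -> float:
    """Train on all awake trials (no CV), test on all k/x trials."""
    X_awake = np.asarray(X_awake, float)
    X_kx = np.asarray(X_kx, float)
    if X_awake.shape[1] != X_kx.shape[1]:
        raise ValueError("cell lists must match across states")
    clf = _svm(C).fit(X_awake, y_awake)
    return float(np.mean(clf.predict(X_kx) == np.asarray(y_kx)))


# --------------------------------------------------------------------------
# cross-time decoding
# --------------------------------------------------------------------------


def smooth_rate_trajectories(spikes: dict[int, np.ndarray],
                             align_times: np.ndarray, cell_ids,
                             t_start: float = -1.5, t_stop: float = 4.0,
                             step_s: float = 0.1,
                             kernel_sd_s: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-smoothed rates around per-trial alignment events.

    Spike trains are binned at ``step_s`` and convolved with a Gaussian
    kernel (SD ``kernel_sd_s``, truncated at 4 SD).  Returns
    (trials x cells x bins rates in Hz, bin-center times).
    """
    cell_ids = np.asarray(cell_ids)
    align_times = np.asarray(align_times, float)
    pad = 4.0 * kernel_sd_s
    edges = np.arange(t_start - pad, t_stop + pad + step_s, step_s)
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = (centers >= t_start - step_s / 2) & (centers <= t_stop + step_s / 2)
    R = np.empty((align_times.size, cell_ids.size, int(keep.sum())))
    for ci, cid in enumerate(cell_ids):
        st = spikes[cid]
        for ti, t0 in enumerate(align_times):
            counts, _ = np.histogram(st - t0, bins=edges)
            rate = ndimage.gaussian_filter1d(counts / step_s,
                                             kernel_sd_s / step_s,
                                             truncate=4.0)
            R[ti, ci] = rate[keep]
    return R, centers[keep]


@dataclass
class CrossTimeMatrix:
    accuracy: np.ndarray   # train bins x test bins
    bin_times: np.ndarray
    chance: float


def decode_cross_time(R: np.ndarray, y: np.ndarray, bin_times: np.ndarray,
                      train_bins=None, test_bins=None,
                      C: float = 1.0) -> CrossTimeMatrix:
    """Train/test a linear SVM on every pair of time bins.

    ``R`` is trials x cells x bins.  Leave-one-trial-out: for each held
    trial, the classifier is trained on every other trial's train-bin
    vector and tested on the held trial's test-bin vector, so no time
    bin of the test trial enters training.  The diagonal is same-bin
    decoding.
    """
    R = np.asarray(R, float)
    y = np.asarray(y)
    n_trials, _, n_bins = R.shape
    train_bins = np.arange(n_bins) if train_bins is None else np.asarray(train_bins)
    test_bins = train_bins if test_bins is None else np.asarray(test_bins)
    if train_bins.max() >= n_bins or test_bins.max() >= n_bins:
        raise ValueError("requested bins fall outside the trajectory")
    correct = np.zeros((train_bins.size, test_bins.size))
    for held in range(n_trials):
        tr = np.delete(np.arange(n_trials), held)
        for bi, b in enumerate(train_bins):
            clf = _svm(C).fit(R[tr, :, b], y[tr])
            preds = clf.predict(R[held, :, test_bins])
            correct[bi] += preds == y[held]
    return CrossTimeMatrix(accuracy=correct / n_trials,
                           bin_times=bin_times[train_bins],
                           chance=1.0 / np.unique(y).size)
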
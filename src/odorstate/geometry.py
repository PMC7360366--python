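"""Pseudopopulation assembly and trial-to-trial correlation structure.

Population responses from separate sessions are pooled into a
pseudopopulation by matching within-odor trial order, then odor
separation is quantified as the mean within-odor minus mean across-odor
Pearson correlation of trial population vectors, with bootstrap nulls
for region contrasts.  Timescale-resolved noise correlations operate on
simultaneously recorded cells only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class Pseudopopulation:
    """Trial-instances x cells response matrix with trial labels.

    Every cell contributes the same (odor x within-odor trial index)
    grid; no trial instance mixes states.
    """

    X: np.ndarray
    odors: np.ndarray
    trial_idx: np.ndarray
    states: np.ndarray
    provenance: pd.DataFrame  # session, unit_id per column

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.odors) == len(self.trial_idx) == len(self.states) == n):
            raise ValueError("label arrays must match the number of rows")

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def subset_state(self, state: str) -> "Pseudopopulation":
        m = self.states == state
        return Pseudopopulation(self.X[m], self.odors[m], self.trial_idx[m],
                                self.states[m], self.provenance)


def build_pseudopopulation(sessions: list[tuple[np.ndarray, pd.DataFrame]],
                           subsample_size: int | None = None,
                           seed: int = 0,
                           random_pairing: bool = False) -> Pseudopopulation:
    """Pool cells across sessions into one pseudopopulation.

    Each element of ``sessions`` is ``(X, labels)`` where X is trials x
    cells and labels has columns odor_id, trial_idx (within-odor order),
    state, and optionally session/unit_id provenance.  Rows are matched
    on (odor, trial_idx, state): within-odor trial k of one session is
    paired with trial k of the others (``random_pairing`` permutes the
    within-condition order per session instead).  Sessions missing part
    of the trial grid are dropped with a log entry.  ``subsample_size``
    picks that many cells without replacement.
    """
    rng = np.random.default_rng(seed)
    keys = None
    blocks, prov = [], []
    for si, (X, labels) in enumerate(sessions):
        lab = labels.copy().reset_index(drop=True)
        lab["_row"] = np.arange(len(lab))
        if random_pairing:
            lab["_row"] = lab.groupby(["odor_id", "state"])["_row"].transform(
                lambda r: rng.permutation(r.to_numpy()))
        lab = lab.sort_values(["state", "odor_id", "trial_idx"])
        k = list(zip(lab.odor_id, lab.trial_idx, lab.state))
        if keys is None:
            keys = k
            key_labels = lab
        elif k != keys:
            log.warning("session %d does not supply the full trial scheme; dropped", si)
            continue
        blocks.append(np.asarray(X, float)[lab["_row"].to_numpy()])
        n_cells = X.shape[1]
        unit_ids = labels.attrs.get("unit_ids", np.arange(n_cells))
        prov.append(pd.DataFrame({"session": si, "unit_id": unit_ids}))
    if not blocks:
        raise ValueError("no session supplied the full trial scheme")
    X = np.hstack(blocks)
    provenance = pd.concat(prov, ignore_index=True)
    if subsample_size is not None:
        if subsample_size > X.shape[1]:
            raise ValueError("subsample_size exceeds the pooled cell count")
        cols = rng.choice(X.shape[1], subsample_size, replace=False)
        X = X[:, cols]
        provenance = provenance.iloc[cols].reset_index(drop=True)
    return Pseudopopulation(
        X=X,
        odors=key_labels["odor_id"].to_numpy(),
        trial_idx=key_labels["trial_idx"].to_numpy(),
        states=key_labels["state"].to_numpy(),
        provenance=provenance,
    )


@dataclass
class CorrelationSummary:
    matrix: np.ndarray           # trial-pair Pearson correlations
    mean_within: float
    mean_across: float
    separation: float            # within - across
    n_within_pairs: int
    n_across_pairs: int
    n_dropped: int               # constant trial vectors excluded


def _row_correlations(A: np.ndarray, B: np.ndarray | None = None):
    """Pearson correlation between rows of A (and B); constant rows -> NaN."""
    def z(M):
        M = np.asarray(M, float)
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, (M - mu) / sd, np.nan)
    Za = z(A)
    Zb = Za if B is None else z(B)
    return Za @ Zb.T / A.shape[1]


def correlation_separation(X: np.ndarray, odors: np.ndarray) -> CorrelationSummary:
    """Within- vs across-odor trial-pair correlation separation.

    All unordered trial pairs are correlated (a trial is never paired
    with itself); with 7 trials per odor this gives 21 within-odor pairs
    per odor and 49 pairs for each odor pair.
    """
    odors = np.asarray(odors)
    if len(np.unique(odors)) < 2:
        raise ValueError("need at least 2 odors")
    if min(np.bincount(pd.factorize(odors)[0])) < 2:
        raise ValueError("need at least 2 trials per odor")
    C = _row_correlations(X)
    n = X.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = C[iu, ju]
    same = odors[iu] == odors[ju]
    finite = np.isfinite(vals)
    n_dropped = int(np.sum(~finite))
    if n_dropped:
        log.warning("%d trial pairs dropped (constant population vector)", n_dropped)
    within = vals[same & finite]
    across = vals[~same & finite]
    return CorrelationSummary(
        matrix=C, mean_within=float(within.mean()),
        mean_across=float(across.mean()),
        separation=float(within.mean() - across.mean()),
        n_within_pairs=int(within.size), n_across_pairs=int(across.size),
        n_dropped=n_dropped)


def cross_state_correlation(X_awake: np.ndarray, odors_awake: np.ndarray,
                            X_kx: np.ndarray, odors_kx: np.ndarray
                            ) -> CorrelationSummary:
    """Rectangular awake x k/x trial correlation matrix and its
    within/across-odor separation.

    Index-matched same-odor pairs (within-odor trial k in both states)
    are excluded from the within-odor mean, mirroring the no-self-pair
    convention of the within-state separation.
    """
    if X_awake.shape[1] != X_kx.shape[1]:
        raise ValueError("cell lists must match across states")
    C = _row_correlations(X_awake, X_kx)
    oa = np.asarray(odors_awake)
    ok = np.asarray(odors_kx)
    pos_a = pd.Series(oa).groupby(pd.Series(oa)).cumcount().to_numpy()
    pos_k = pd.Series(ok).groupby(pd.Series(ok)).cumcount().to_numpy()
    same = oa[:, None] == ok[None, :]
    matched = same & (pos_a[:, None] == pos_k[None, :])
    finite = np.isfinite(C)
    within = C[same & finite & ~matched]
    across = C[~same & finite]
    return CorrelationSummary(
        matrix=C, mean_within=float(within.mean()),
        mean_across=float(across.mean()),
        separation=float(within.mean() - across.mean()),
        n_within_pairs=int(within.size), n_across_pairs=int(across.size),
        n_dropped=int(np.sum(~finite)))


def separation_region_null(X: np.ndarray, odors: np.ndarray,
                           cells_a: np.ndarray, cells_b: np.ndarray,
                           n_boot: int = 1000, seed: int = 0) -> dict:
    """Bootstrap test that two regions' separations could come from one
    homogeneous cell population.

    ``cells_a``/``cells_b`` are column indices into X.  The null pools
    the cells and draws size-matched pseudo-regions with replacement,
    recomputing the separation difference each time; p is the
    add-one-corrected fraction of null differences at least as extreme.
    """
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if cells_a.size == 0 or cells_b.size == 0:
        raise ValueError("both cell sets must be non-empty")
    rng = np.random.default_rng(seed)
    sep_a = correlation_separation(X[:, cells_a], odors).separation
    sep_b = correlation_separation(X[:, cells_b], odors).separation
    emp = sep_a - sep_b
    pooled = np.concatenate([cells_a, cells_b])
    null = np.empty(n_boot)
    for i in range(n_boot):
        pa = rng.choice(pooled, cells_a.size, replace=True)
        pb = rng.choice(pooled, cells_b.size, replace=True)
        null[i] = (correlation_separation(X[:, pa], odors).separation
                   - correlation_separation(X[:, pb], odors).separation)
    p = (1.0 + np.sum(np.abs(null) >= abs(emp))) / (1.0 + n_boot)
    return {"separation_a": sep_a, "separation_b": sep_b,
            "difference": emp, "p": float(p), "null": null}


# --------------------------------------------------------------------------
# noise correlations
# --------------------------------------------------------------------------


def noise_correlation_matrix(counts_by_stim: dict) -> tuple[float, int]:
    """Mean pairwise noise correlation for one window in one session.

    ``counts_by_stim`` maps stimulus -> cells x trials count matrix.
    Counts are z-scored across trials per cell per stimulus; Pearson r
    is computed per cell pair per stimulus and averaged across pairs,
    then across stimuli.  Zero-variance cell-stimulus entries drop the
    affected pairs.  Returns (mean r, n pairs contributing).
    """
    per_stim = []
    n_pairs_total = 0
    for counts in counts_by_stim.values():
        M = np.asarray(counts, float)
        n_cells, n_trials = M.shape
        if n_trials < 5:
            raise ValueError("need >= 5 trials per stimulus")
        sd = M.std(axis=1, keepdims=True)
        valid = sd[:, 0] > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (M - M.mean(axis=1, keepdims=True)) / sd
        C = Z[valid] @ Z[valid].T / n_trials
        k = int(valid.sum())
        if k < 2:
            continue
        iu, ju = np.triu_indices(k, 1)
        per_stim.append(float(C[iu, ju].mean()))
        n_pairs_total += iu.size
    if not per_stim:
        return np.nan, 0
    return float(np.mean(per_stim)), n_pairs_total


def noise_correlations(tensors_by_stim: dict, window_centers: np.ndarray,
                       bin_s: float) -> pd.DataFrame:
    """Sliding-window noise-correlation series for one session.

    ``tensors_by_stim`` maps stimulus -> cells x trials x windows counts
    with windows centered at ``window_centers`` (s relative to
    inhalation).  Averaging order: cell pairs, then stimuli; averaging
    across sessions is the caller's job.
    """
    if bin_s not in (0.120, 0.060, 0.030):
        warnings.warn(f"non-standard noise-correlation bin {bin_s}", stacklevel=2)
    rows = []
    for wi, center in enumerate(np.asarray(window_centers, float)):
        counts = {s: T[:, :, wi] for s, T in tensors_by_stim.items()}
        r, n_pairs = noise_correlation_matrix(counts)
        rows.append((center, bin_s, r, n_pairs))
    return pd.DataFrame(rows, columns=["window_center_s", "bin_s",
                                       "mean_r", "n_pairs"])
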
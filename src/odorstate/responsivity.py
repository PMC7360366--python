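"""Per cell-odor response statistics.

Centered on the auROC response index (2*auROC - 1) comparing odor-evoked
to pre-odor baseline spike counts, with rank-sum significance classes,
cross-state robustness labels, Treves-Rolls sparseness, PSTH latency and
peak extraction, respiratory spike phases, and pairwise phase
consistency (PPC).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats

ALPHA = 0.05


def auroc_response_index(evoked, baseline) -> tuple[float, float]:
    """auROC of evoked vs baseline counts and the response index.

    auROC = P(evoked > baseline) + 0.5 P(tie) over all trial pairs; the
    index is 2*auROC - 1, so +1 means every evoked count exceeds every
    baseline count and -1 the reverse.
    """
    evoked = np.asarray(evoked, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if evoked.size < 2 or baseline.size < 2:
        raise ValueError("need at least 2 trials per sample")
    # rank formulation of the Mann-Whitney U statistic (ties get 1/2)
    combined = np.concatenate([evoked, baseline])
    ranks = stats.rankdata(combined)
    u = ranks[: evoked.size].sum() - evoked.size * (evoked.size + 1) / 2.0
    auroc = u / (evoked.size * baseline.size)
    return float(auroc), float(2.0 * auroc - 1.0)


def rank_sum_p(evoked, baseline) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact permutation enumeration (tie-aware) when both groups have <= 10
    observations, else the tie-corrected normal approximation.
    """
    evoked = np.asarray(evoked, float)
    baseline = np.asarray(baseline, float)
    n1, n2 = evoked.size, baseline.size
    if max(n1, n2) <= 10:
        return _exact_ranksum_p(evoked, baseline)
    res = stats.mannwhitneyu(evoked, baseline, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.pvalue)


def _exact_ranksum_p(evoked: np.ndarray, baseline: np.ndarray) -> float:
    """Enumerate every group assignment of the pooled values; two-sided p
    by symmetric distance of the rank sum from its null mean."""
    from itertools import combinations

    n1, n2 = evoked.size, baseline.size
    ranks = stats.rankdata(np.concatenate([evoked, baseline]))
    obs = ranks[:n1].sum()
    center = n1 * (n1 + n2 + 1) / 2.0
    combos = np.fromiter(
        (i for c in combinations(range(n1 + n2), n1) for i in c), dtype=int
    ).reshape(-1, n1)
    sums = ranks[combos].sum(axis=1)
    extreme = np.abs(sums - center) >= np.abs(obs - center) - 1e-9
    return float(extreme.mean())


def classify_response(evoked, baseline, alpha: float = ALPHA) -> str:
    """'activated', 'suppressed', or 'ns' from trial-by-trial counts."""
    evoked = np.asarray(evoked, float)
    baseline = np.asarray(baseline, float)
    if evoked.size < 2 or baseline.size < 2:
        raise ValueError("need at least 2 trials per sample")
    if not np.any(evoked) and not np.any(baseline):
        warnings.warn("all-zero counts in both windows; classified ns",
                      stacklevel=2)
        return "ns"
    if np.array_equal(np.sort(evoked), np.sort(baseline)):
        return "ns"
    p = rank_sum_p(evoked, baseline)
    if p >= alpha:
        return "ns"
    shift = np.median(evoked) - np.median(baseline)
    if shift == 0:
        shift = evoked.mean() - baseline.mean()
    return "activated" if shift > 0 else ("suppressed" if shift < 0 else "ns")


def classify_cross_state(awake_class: str, kx_class: str) -> str:
    """robust / awake_only / kx_only / none from the two state classes.

    'robust' requires significant activation in both states; a response
    that is activated in one state only is state-specific regardless of
    whether it is ns or suppressed in the other (activated->suppressed
    transitions are rare and can be tallied from the inputs).
    """
    a_act = awake_class == "activated"
    k_act = kx_class == "activated"
    if a_act and k_act:
        return "robust"
    if a_act:
        return "awake_only"
    if k_act:
        return "kx_only"
    return "none"


def lifetime_sparseness(rates, formula: str = "treves-rolls") -> float:
    """Treves-Rolls sparseness of a tuning vector, in [0, 1].

    S = (1 - (sum r / n)^2 / (sum r^2 / n)) / (1 - 1/n); 1 for a one-hot
    vector (maximally selective), 0 for a uniform one.  The
    Willmore-Tolhurst variant (unnormalized) is available as
    ``formula="willmore-tolhurst"``.
    """
    r = np.asarray(rates, dtype=float)
    if r.size < 2:
        raise ValueError("need a vector of length >= 2")
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    if not np.any(r):
        warnings.warn("all-zero tuning vector; sparseness undefined", stacklevel=2)
        return np.nan
    n = r.size
    a = (r.mean() ** 2) / (np.mean(r**2))
    if formula == "treves-rolls":
        return float((1.0 - a) / (1.0 - 1.0 / n))
    if formula == "willmore-tolhurst":
        return float(1.0 - a)
    raise ValueError(f"unknown sparseness formula {formula!r}")


def population_sparseness(rates, formula: str = "treves-rolls") -> float:
    """Sparseness of the population vector for one odor (same formula,
    taken across cells instead of across odors)."""
    return lifetime_sparseness(rates, formula=formula)


def bootstrap_difference_test(group_a, group_b, statistic=np.mean,
                              n_boot: int = 1000, seed: int = 0,
                              ci: float = 0.95):
    """Bootstrap test for a difference in a per-cell statistic.

    The null resamples size-matched groups with replacement from the
    pooled values and recomputes the difference ``n_boot`` times; the
    two-sided p is the add-one-corrected fraction of null differences at
    least as extreme (in absolute value) as the empirical one.  Percentile
    confidence intervals come from within-group resampling.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be non-empty")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; p-values will be coarse",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    est_a, est_b = float(statistic(a)), float(statistic(b))
    emp = est_a - est_b
    pooled = np.concatenate([a, b])
    null = np.empty(n_boot)
    boot_a = np.empty(n_boot)
    boot_b = np.empty(n_boot)
    for i in range(n_boot):
        null[i] = (statistic(rng.choice(pooled, a.size, replace=True))
                   - statistic(rng.choice(pooled, b.size, replace=True)))
        boot_a[i] = statistic(rng.choice(a, a.size, replace=True))
        boot_b[i] = statistic(rng.choice(b, b.size, replace=True))
    p = (1.0 + np.sum(np.abs(null) >= abs(emp))) / (1.0 + n_boot)
    q = [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100]
    return {
        "estimate_a": est_a, "estimate_b": est_b, "difference": emp,
        "ci_a": tuple(np.percentile(boot_a, q)),
        "ci_b": tuple(np.percentile(boot_b, q)),
        "p": float(p),
    }


def response_latency_peak(psth_hz: np.ndarray, bin_s: float,
                          n_baseline_bins: int, smooth_sd_s: float = 0.02,
                          threshold_sd: float = 2.5,
                          min_consecutive: int = 2) -> tuple[float, float]:
    """Onset latency and peak rate from a trial-averaged PSTH.

    The PSTH (rates per bin, baseline epoch first, alignment at bin
    ``n_baseline_bins``) is smoothed with a Gaussian kernel; latency is
    the first post-alignment time where the smoothed rate exceeds the
    baseline mean + 2.5 baseline SD for >= 2 consecutive bins, NaN if
    never crossed.  Peak is the maximum smoothed rate after alignment.
    """
    psth = np.asarray(psth_hz, float)
    if n_baseline_bins < 2 or n_baseline_bins >= psth.size:
        raise ValueError("PSTH must cover baseline and response epochs")
    sm = psth if smooth_sd_s <= 0 else \
        ndimage.gaussian_filter1d(psth, smooth_sd_s / bin_s)
    base = sm[:n_baseline_bins]
    mu, sd = base.mean(), base.std()
    if sd == 0:
        warnings.warn("zero baseline variance; using epsilon threshold",
                      stacklevel=2)
        sd = np.finfo(float).eps
    thresh = mu + threshold_sd * sd
    resp = sm[n_baseline_bins:]
    above = resp > thresh
    latency = np.nan
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            latency = (i - min_consecutive + 1) * bin_s
            break
    return float(latency), float(resp.max())


def tuning_correlation(awake_tuning, kx_tuning) -> float:
    """Pearson r between one cell's awake and k/x tuning vectors."""
    a = np.asarray(awake_tuning, float)
    k = np.asarray(kx_tuning, float)
    if a.size != k.size:
        raise ValueError("tuning vectors must have equal length")
    if a.size < 3:
        raise ValueError("need tuning vectors of length >= 3")
    if np.std(a) == 0 or np.std(k) == 0:
        warnings.warn("constant tuning vector; correlation undefined",
                      stacklevel=2)
        return np.nan
    return float(np.corrcoef(a, k)[0, 1])


# --------------------------------------------------------------------------
# respiratory phase and pairwise phase consistency
# --------------------------------------------------------------------------


def spike_phase(spike_times, inhalation_onsets, exhalation_onsets) -> np.ndarray:
    """Respiratory phase of each spike in degrees, [0, 360).

    Linear interpolation maps inhalation onset to 0 deg and the following
    exhalation onset to 180 deg; the exhalation-to-next-inhalation half
    maps to [180, 360).  Spikes outside any complete cycle return NaN.
    """
    spikes = np.atleast_1d(np.asarray(spike_times, float))
    inh = np.asarray(inhalation_onsets, float)
    exh = np.asarray(exhalation_onsets, float)
    out = np.full(spikes.size, np.nan)
    for si, t in enumerate(spikes):
        i = np.searchsorted(inh, t, side="right") - 1
        if i < 0 or i + 1 >= inh.size:
            continue
        t_in, t_next = inh[i], inh[i + 1]
        later = exh[np.searchsorted(exh, t_in, side="right"):]
        if not later.size or later[0] >= t_next:
            continue
        t_ex = later[0]
        if t < t_ex:
            out[si] = 180.0 * (t - t_in) / (t_ex - t_in)
        else:
            out[si] = 180.0 + 180.0 * (t - t_ex) / (t_next - t_ex)
    return out


def ppc(phases_deg) -> float:
    """Pairwise phase consistency: mean cos of all pairwise phase
    differences (the average dot product of spike unit vectors).

    Computed via the resultant-vector identity
    PPC = (|sum e^{i theta}|^2 - n) / (n (n - 1)), which equals the
    O(n^2) pair sum exactly.
    """
    ph = np.asarray(phases_deg, float)
    ph = ph[np.isfinite(ph)]
    n = ph.size
    if n < 2:
        warnings.warn("PPC needs >= 2 spikes; returning NaN", stacklevel=2)
        return np.nan
    z = np.exp(1j * np.deg2rad(ph)).sum()
    return float((np.abs(z) ** 2 - n) / (n * (n - 1)))


def ppc_pair_sum(phases_deg) -> float:
    """Literal O(n^2) pair-sum PPC (reference implementation)."""
    ph = np.deg2rad(np.asarray(phases_deg, float))
    ph = ph[np.isfinite(ph)]
    n = ph.size
    if n < 2:
        return np.nan
    total = 0.0
    for i in range(n):
        total += np.cos(ph[i] - ph[i + 1:]).sum()
    return float(2.0 * total / (n * (n - 1)))


# --------------------------------------------------------------------------
# per-session responsivity table
# --------------------------------------------------------------------------


def responsivity_table(evoked_counts: np.ndarray, baseline_counts: np.ndarray,
                       cell_ids, odor_of_trial: np.ndarray,
                       state_of_trial: np.ndarray,
                       alpha: float = ALPHA) -> pd.DataFrame:
    """Response index and class for every cell x odor x state.

    ``evoked_counts``/``baseline_counts`` are cells x trials matrices of
    first-sniff and last-pre-odor-sniff counts.
    """
    odor_of_trial = np.asarray(odor_of_trial)
    state_of_trial = np.asarray(state_of_trial)
    rows = []
    for ci, cid in enumerate(np.asarray(cell_ids)):
        for odor in np.unique(odor_of_trial):
            for state in np.unique(state_of_trial):
                sel = (odor_of_trial == odor) & (state_of_trial == state)
                ev = evoked_counts[ci, sel]
                ba = baseline_counts[ci, sel]
                auroc, idx = auroc_response_index(ev, ba)
                if not np.any(ev) and not np.any(ba):
                    cls, p = "ns", 1.0
                else:
                    p = 1.0 if np.array_equal(np.sort(ev), np.sort(ba)) \
                        else rank_sum_p(ev, ba)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cls = classify_response(ev, ba, alpha=alpha)
                rows.append((cid, odor, state, auroc, idx, p, cls))
    return pd.DataFrame(rows, columns=["unit_id", "odor_id", "state", "auroc",
                                       "response_index", "p_ranksum", "class"])


def cross_state_table(resp: pd.DataFrame) -> pd.DataFrame:
    """Robust / state-specific labels from a responsivity table."""
    wide = resp.pivot_table(index=["unit_id", "odor_id"], columns="state",
                            values="class", aggfunc="first")
    rows = [
        (uid, odor, classify_cross_state(r.get("awake", "ns"), r.get("kx", "ns")))
        for (uid, odor), r in wide.iterrows()
    ]
    return pd.DataFrame(rows, columns=["unit_id", "odor_id", "label"])
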
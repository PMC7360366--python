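"""Sniff detection, trial alignment, spike counting, unit QC, trial selection.

The analyses are sniff-referenced: response windows start at the first
inhalation after odor onset, baselines at the last inhalation before it,
and odor-offset analyses at the first inhalation after odor offset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import AWAKE, KX, SessionBundle

log = logging.getLogger(__name__)


class SniffDetectionError(ValueError):
    pass


@dataclass
class SniffEvents:
    inhalation_onsets: np.ndarray
    exhalation_onsets: np.ndarray
    #: filled by :func:`align_trials`
    trial_alignment: pd.DataFrame | None = None


@dataclass
class WindowSpec:
    """Counting window relative to an alignment event.

    ``start_s`` is the offset of the first bin edge; bins are half-open
    ``[t0, t0 + bin_s)`` and tile the window exactly.
    """

    start_s: float
    bin_s: float
    n_bins: int
    alignment: str = "first_inhalation"

    @property
    def edges(self) -> np.ndarray:
        return self.start_s + self.bin_s * np.arange(self.n_bins + 1)

    @property
    def duration_s(self) -> float:
        return self.bin_s * self.n_bins


#: single-bin response window used for spike-count decoding features
RESPONSE_480MS = WindowSpec(0.0, 0.48, 1)
#: single-bin window used for population trajectory analyses
RESPONSE_500MS = WindowSpec(0.0, 0.5, 1)
#: pre-odor control window for trajectory analyses
CONTROL_WINDOW = WindowSpec(-2.0, 0.5, 1)


@dataclass
class SpikeCountTensor:
    counts: np.ndarray  # cells x trials x bins, int
    window: WindowSpec
    cell_ids: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def rates_hz(self) -> np.ndarray:
        return self.counts / self.window.bin_s


def detect_inhalations(airflow: np.ndarray, sample_rate: float,
                       band_frac: float = 0.05,
                       smooth_s: float = 0.005) -> SniffEvents:
    """Detect inhalation/exhalation onsets by hysteresis zero crossing.

    The trace is lightly low-pass filtered (Gaussian, SD ``smooth_s``);
    inhalation onset = negative-going crossing of a band at
    ``+-band_frac * SD(airflow)`` around zero; exhalation onset = the
    positive-going crossing.  Events alternate by construction.
    """
    airflow = np.asarray(airflow, dtype=float)
    if sample_rate < 100:
        raise ValueError(f"sample rate must be >= 100 Hz, got {sample_rate}")
    if airflow.size == 0 or np.any(~np.isfinite(airflow)):
        bad = np.nonzero(~np.isfinite(airflow))[0]
        seg = f"samples {bad[0]}..{bad[-1]}" if bad.size else "empty trace"
        raise SniffDetectionError(f"airflow trace is invalid ({seg})")
    if smooth_s > 0:
        from scipy.ndimage import gaussian_filter1d
        airflow = gaussian_filter1d(airflow, smooth_s * sample_rate)
    band = band_frac * float(np.std(airflow))
    if band == 0.0:
        raise SniffDetectionError("airflow trace is flat (zero variance)")
    state = np.zeros(airflow.size, dtype=np.int8)
    state[airflow > band] = 1
    state[airflow < -band] = -1
    # forward-fill zeros so crossings are band-to-band transitions
    idx = np.arange(airflow.size)
    nz = state != 0
    filled = state[nz][np.clip(np.cumsum(nz) - 1, 0, None)] if nz.any() else state
    trans = np.nonzero(np.diff(filled) != 0)[0] + 1 if nz.any() else np.array([], int)
    t = idx / sample_rate
    inh = t[trans][filled[trans] == -1] if trans.size else np.empty(0)
    exh = t[trans][filled[trans] == 1] if trans.size else np.empty(0)
    if inh.size == 0:
        warnings.warn("no inhalations detected in airflow trace", stacklevel=2)
    return SniffEvents(inhalation_onsets=np.asarray(inh),
                       exhalation_onsets=np.asarray(exh))


def align_trials(sniffs: SniffEvents, trials: pd.DataFrame) -> SniffEvents:
    """Attach per-trial sniff alignment events.

    For each trial: the first inhalation at or after odor onset (response
    alignment; an inhalation exactly at odor onset counts), the last
    inhalation strictly before onset (baseline alignment), the first
    inhalation at or after odor offset, and the duration of the first
    breath after odor onset.  Trials lacking a post-onset inhalation are
    flagged ``valid=False`` and logged.
    """
    inh = sniffs.inhalation_onsets
    rows = []
    for _, tr in trials.iterrows():
        i_resp = int(np.searchsorted(inh, tr.odor_on_s, side="left"))
        valid = i_resp < inh.size
        resp_t = inh[i_resp] if valid else np.nan
        base_t = inh[i_resp - 1] if i_resp > 0 else np.nan
        j = int(np.searchsorted(inh, tr.odor_off_s, side="left"))
        off_t = inh[j] if j < inh.size else np.nan
        dur = inh[i_resp + 1] - resp_t if valid and i_resp + 1 < inh.size else np.nan
        if not valid:
            log.warning("trial %d has no inhalation after odor onset; excluded",
                        tr.trial_index)
        rows.append((int(tr.trial_index), resp_t, base_t, off_t, dur, valid))
    table = pd.DataFrame(rows, columns=["trial_index", "response_inh_s",
                                        "baseline_inh_s", "offset_inh_s",
                                        "first_breath_s", "valid"])
    return SniffEvents(sniffs.inhalation_onsets, sniffs.exhalation_onsets, table)


def count_spikes(spikes: dict[int, np.ndarray], align_times: np.ndarray,
                 window: WindowSpec, cell_ids=None,
                 trial_ids=None) -> SpikeCountTensor:
    """Bin spike counts around per-trial alignment times.

    Bins are half-open ``[edge_k, edge_{k+1})``: a spike exactly at the
    window end is not counted, one exactly at the start is.
    """
    align_times = np.asarray(align_times, dtype=float)
    trial_ids = np.arange(align_times.size) if trial_ids is None else np.asarray(trial_ids)
    if len(set(trial_ids.tolist())) != trial_ids.size:
        raise ValueError("duplicate trial ids in alignment table")
    cell_ids = np.asarray(sorted(spikes) if cell_ids is None else cell_ids)
    edges = window.edges
    counts = np.zeros((cell_ids.size, align_times.size, window.n_bins), dtype=int)
    for ci, cid in enumerate(cell_ids):
        st = spikes[cid]
        for ti, t0 in enumerate(align_times):
            if not np.isfinite(t0):
                continue
            pos = np.searchsorted(st, t0 + edges, side="left")
            counts[ci, ti] = np.diff(pos)
    return SpikeCountTensor(counts=counts, window=window,
                            cell_ids=cell_ids, trial_ids=trial_ids)


def count_in_intervals(spikes: dict[int, np.ndarray], starts: np.ndarray,
                       stops: np.ndarray, cell_ids=None) -> np.ndarray:
    """Counts in per-trial variable windows [start, stop): cells x trials."""
    starts = np.asarray(starts, float)
    stops = np.asarray(stops, float)
    cell_ids = np.asarray(sorted(spikes) if cell_ids is None else cell_ids)
    out = np.zeros((cell_ids.size, starts.size), dtype=int)
    for ci, cid in enumerate(cell_ids):
        st = spikes[cid]
        ok = np.isfinite(starts) & np.isfinite(stops)
        out[ci, ok] = (np.searchsorted(st, stops[ok], "left")
                       - np.searchsorted(st, starts[ok], "left"))
    return out


# --------------------------------------------------------------------------
# unit stability criteria
# --------------------------------------------------------------------------

MIN_RATE_HZ = 0.01
MAX_RATE_RATIO = 100.0
MAX_AMP_DELTA_UV = 50.0


def apply_stability_criteria(units: pd.DataFrame,
                             min_rate_hz: float = MIN_RATE_HZ,
                             max_rate_ratio: float = MAX_RATE_RATIO,
                             max_amp_delta_uv: float = MAX_AMP_DELTA_UV,
                             ) -> pd.DataFrame:
    """Cross-state unit stability QC.

    A unit is discarded if its overall rate falls below 0.01 Hz, its rate
    changes more than 100-fold across states, or its mean peak-to-peak
    waveform amplitude changes by more than 50 uV.  Boundaries are
    strict: a unit exactly at 0.01 Hz, exactly 100-fold, or exactly 50 uV
    is kept.  Units missing a state are unevaluable and excluded.
    """
    rows = []
    for _, u in units.iterrows():
        reasons = []
        ra, rk = u.rate_awake_hz, u.rate_kx_hz
        aa, ak = u.amp_awake_uv, u.amp_kx_uv
        if any(pd.isna(v) for v in (ra, rk, aa, ak)):
            reasons.append("missing state")
            overall = np.nan
            ratio = np.nan
            delta = np.nan
        else:
            overall = (ra + rk) / 2.0
            lo = min(ra, rk)
            ratio = np.inf if lo == 0 else max(ra, rk) / lo
            delta = abs(aa - ak)
            if overall < min_rate_hz:
                reasons.append("low rate")
            if ratio > max_rate_ratio:
                reasons.append("rate ratio")
            if delta > max_amp_delta_uv:
                reasons.append("amplitude delta")
        rows.append((u.unit_id, overall, ratio, delta,
                     len(reasons) == 0, ";".join(reasons)))
    return pd.DataFrame(rows, columns=["unit_id", "overall_rate_hz",
                                       "rate_ratio", "amp_delta_uv",
                                       "keep", "reasons"])


def session_unit_rates(bundle: SessionBundle) -> pd.DataFrame:
    """Recompute overall per-state rates from the spike trains (the full
    session duration of each state is the denominator)."""
    onset = bundle.anesthesia_onset_s
    dur = bundle.duration_s
    rows = []
    for uid in bundle.unit_ids:
        st = bundle.spikes[int(uid)]
        if onset is None:
            rows.append((uid, st.size / dur, np.nan))
        else:
            n_aw = int(np.searchsorted(st, onset))
            rows.append((uid, n_aw / onset, (st.size - n_aw) / (dur - onset)))
    return pd.DataFrame(rows, columns=["unit_id", "rate_awake_hz", "rate_kx_hz"])


# --------------------------------------------------------------------------
# analysis trial selection
# --------------------------------------------------------------------------


def select_state_trials(trials: pd.DataFrame, anesthesia_onset_s: float,
                        n_per_state: int = 7,
                        mode: str = "standard") -> dict[int, dict[str, np.ndarray]]:
    """Select the analysis trial subsets per odor.

    ``standard``: the last ``n_per_state`` awake trials before the
    anesthesia onset and the first ``n_per_state`` trials after it.
    ``stabilization``: the first 15 awake presentations,
    unexcluded, plus the same k/x subset.
    """
    if mode not in ("standard", "stabilization"):
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[int, dict[str, np.ndarray]] = {}
    for odor, grp in trials.groupby("odor_id"):
        grp = grp.sort_values("odor_on_s")
        awake = grp[(grp.odor_on_s < anesthesia_onset_s) & (grp.state == AWAKE)]
        kx = grp[(grp.odor_on_s >= anesthesia_onset_s) & (grp.state == KX)]
        if mode == "standard":
            if len(awake) < n_per_state or len(kx) < n_per_state:
                raise ValueError(
                    f"odor {odor}: need >= {n_per_state} trials per state, "
                    f"have {len(awake)} awake / {len(kx)} k/x")
            aw_sel = awake["trial_index"].to_numpy()[-n_per_state:]
            kx_sel = kx["trial_index"].to_numpy()[:n_per_state]
        else:
            aw_sel = awake["trial_index"].to_numpy()[:15]
            kx_sel = kx["trial_index"].to_numpy()[:n_per_state]
        out[int(odor)] = {AWAKE: aw_sel, KX: kx_sel}
    return out
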
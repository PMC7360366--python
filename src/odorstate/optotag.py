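"""Opto-tagging of genetically defined units with inhibitory opsins.

A unit expressing Arch/Jaws is silenced by the laser: tagging requires
(1) rank-sum p < 1e-4 comparing spiking in the 1 s before each pulse to
spiking during the 1 s pulse, and (2) a median last-spike latency during
the pulse below a threshold (default 10 ms).  Units with overall rates
below 0.175 Hz or peak-trough times below 0.35 ms are excluded from
classification entirely.  Excitatory (ChR2) tagging is driven by an
externally computed SALT p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .responsivity import rank_sum_p

MIN_RATE_HZ = 0.175
MIN_PEAK_TROUGH_MS = 0.35
DEFAULT_LATENCY_THRESHOLD_S = 0.01
ALPHA_TAG = 1e-4


@dataclass
class TagResult:
    unit_id: int
    p_ranksum_laser: float
    median_last_spike_latency_s: float
    excluded: bool
    reason: str
    label: str  # tagged / untagged / excluded


def pulse_statistics(spike_times: np.ndarray,
                     pulses: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pulse counts in the 1 s pre window, counts during the pulse,
    and last-spike latency from pulse onset (0 for silent pulses)."""
    st = np.asarray(spike_times, float)
    pulses = np.asarray(pulses, float)
    pre = np.empty(len(pulses), int)
    dur = np.empty(len(pulses), int)
    lat = np.empty(len(pulses))
    for i, (on, off) in enumerate(pulses):
        pre[i] = np.searchsorted(st, on) - np.searchsorted(st, on - 1.0)
        a, b = np.searchsorted(st, on), np.searchsorted(st, off)
        dur[i] = b - a
        lat[i] = st[b - 1] - on if b > a else 0.0
    return pre, dur, lat


def tag_inhibitory(pre_counts, laser_counts, last_spike_latencies_s,
                   overall_rate_hz: float, peak_trough_ms: float,
                   unit_id: int = -1,
                   latency_threshold_s: float = DEFAULT_LATENCY_THRESHOLD_S,
                   alpha: float = ALPHA_TAG) -> TagResult:
    """Classify one unit from its per-pulse laser statistics."""
    pre = np.asarray(pre_counts, float)
    dur = np.asarray(laser_counts, float)
    lat = np.asarray(last_spike_latencies_s, float)
    if pre.size == 0:
        raise ValueError("no laser pulses supplied")
    if pre.size < 20:
        import warnings
        warnings.warn(f"only {pre.size} laser pulses (expected >= 20)",
                      stacklevel=2)
    if overall_rate_hz < MIN_RATE_HZ:
        return TagResult(unit_id, np.nan, np.nan, True, "low rate", "excluded")
    if peak_trough_ms < MIN_PEAK_TROUGH_MS:
        return TagResult(unit_id, np.nan, np.nan, True, "narrow waveform",
                         "excluded")
    if np.array_equal(np.sort(pre), np.sort(dur)):
        p = 1.0
    else:
        p = rank_sum_p(dur, pre)
    med_lat = float(np.median(lat))
    tagged = (p < alpha) and (med_lat < latency_threshold_s)
    return TagResult(unit_id, float(p), med_lat, False, "",
                     "tagged" if tagged else "untagged")


def tag_excitatory(salt_p: float, latency_to_peak_s: float,
                   peak_trough_ms: float,
                   salt_alpha: float = 1e-3,
                   latency_threshold_s: float = 0.003,
                   unit_id: int = -1) -> TagResult:
    """ChR2 tagging from an externally computed SALT p-value plus the
    latency-to-peak criterion; both inputs must be supplied."""
    if salt_p is None or latency_to_peak_s is None:
        raise ValueError("ChR2 tagging needs both a SALT p-value and a "
                         "latency-to-peak")
    if peak_trough_ms < MIN_PEAK_TROUGH_MS:
        return TagResult(unit_id, np.nan, np.nan, True, "narrow waveform",
                         "excluded")
    tagged = (salt_p < salt_alpha) and (latency_to_peak_s < latency_threshold_s)
    return TagResult(unit_id, float(salt_p), float(latency_to_peak_s), False,
                     "", "tagged" if tagged else "untagged")
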
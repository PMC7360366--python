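"""Ground-truthed simulator of two-region, two-state olfactory sessions.

Emulates the statistical structure of paired olfactory bulb (OB) /
piriform cortex (PCx) recordings across the awake -> ketamine/xylazine
(k/x) transition:

* spontaneous rates that drop under anesthesia (OB much more than PCx),
* respiration that is irregular awake and metronomic under k/x, with
  spikes entrained to the respiratory phase under anesthesia,
* odor responses that are robust (present in both states) or
  state-specific, robust responses having shorter onset latencies,
* early-trial response drift: elevated sniff rate and amplified evoked
  responses on the first few presentations, decaying over trials,
* weak trial-to-trial shared multiplicative gain producing noise
  correlations.

Spikes are drawn from an inhomogeneous Poisson process thinned on a
1 ms grid:

    rate_i(t) = base_i(state) * gain(trial) * (1 + d(state) cos theta(t))
                + evoked_i(t)

where theta is the respiratory phase (0 at inhalation onset) and the
evoked transient is a half-Gaussian rise followed by an exponential
decay, aligned to the first inhalation after odor onset.

Region profiles encode outcomes, not mechanisms: "ob" (most activated
responses awake-only), "pcx" (majority robust, amplified robust
amplitude), "telc" (PCx-like inputs but no robust amplification and no
trial-number drift, mimicking a synaptically silenced recurrent
network).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .session import AWAKE, KX, GroundTruth, Respiration, SessionBundle, UNIT_COLUMNS

DT = 0.001  # thinning resolution, s

RESPONSE_CLASSES = ("robust", "awake_only", "kx_only", "suppressed", "none")

#: per-profile outcome parameters: spontaneous rates (Hz), response-class
#: probabilities, robust-amplitude gain, and whether early-trial drift acts.
PROFILES: dict[str, dict] = {
    "ob": {
        "baseline_hz": {AWAKE: 6.58, KX: 2.62},
        "class_probs": {"robust": 0.04, "awake_only": 0.22, "kx_only": 0.04,
                        "suppressed": 0.10},
        "robust_amp_gain": 1.0,
        "drift": True,
    },
    "pcx": {
        "baseline_hz": {AWAKE: 4.0, KX: 3.0},
        "class_probs": {"robust": 0.14, "awake_only": 0.08, "kx_only": 0.03,
                        "suppressed": 0.12},
        "robust_amp_gain": 1.5,
        "drift": True,
    },
    "telc": {
        "baseline_hz": {AWAKE: 4.0, KX: 3.0},
        "class_probs": {"robust": 0.14, "awake_only": 0.08, "kx_only": 0.03,
                        "suppressed": 0.12},
        "robust_amp_gain": 1.0,
        "drift": False,
    },
}


def _normalize_profile(name: str) -> str:
    key = name.lower().replace("-like", "").replace("_like", "")
    if key not in PROFILES:
        raise ValueError(
            f"unknown region profile {name!r}; expected one of {sorted(PROFILES)}"
        )
    return key


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults encode the recording design: 6 odors, 15 awake trials and 7
    anesthetized trials per odor, OB spontaneous rates 6.58 Hz awake /
    2.62 Hz under k/x.  Evoked amplitude and latency distributions are
    not constrained numerically by the recordings and are exposed here.
    """

    n_cells_per_region: int = 80
    n_odors: int = 6
    n_trials_awake: int = 15
    n_trials_kx: int = 7
    #: override of the per-profile spontaneous rates, {state: Hz}
    baseline_hz: dict | None = None
    #: override of the per-profile response-class probabilities
    class_probs: dict | None = None
    #: onset-latency (s) mean/sd; robust responses are faster
    latency_params: dict = field(default_factory=lambda: {
        "robust": (0.05, 0.015), "state_specific": (0.07, 0.02)})
    #: log-normal evoked peak-rate increment distribution
    amp_params: dict = field(default_factory=lambda: {
        "mean_hz": 20.0, "sigma_log": 0.5})
    #: SD of the per-trial shared log-normal gain
    gain_sd: float = 0.2
    #: fraction of cells receiving the shared gain
    gain_frac: float = 1.0
    #: respiratory phase modulation depth under k/x (awake uses 0.2x this)
    entrainment_depth: float = 0.8
    #: e-fold constant (trials) of the early-trial response drift
    drift_tau: float = 4.0
    #: amplitude of the early-trial response drift, factor (1 + a e^(-k/tau))
    drift_amp: float = 1.0
    #: factor by which sniff rate is elevated during odors on trials 1-5
    sniff_early_boost: float = 1.5
    #: exponent coupling evoked amplitude to first-breath sniff rate
    sniff_amp_exponent: float = 0.5
    n_early_boost_trials: int = 5
    #: trial timing (s): pre-odor baseline, odor duration, post-odor
    pre_s: float = 3.0
    odor_s: float = 1.0
    post_s: float = 6.0
    #: awake breath durations ~ gamma(shape), mean mean_s, clipped to 2-12 Hz
    awake_breath_mean_s: float = 0.25
    awake_breath_shape: float = 4.0
    #: k/x breath durations ~ normal(mean, sd): metronomic ~2 Hz
    kx_breath_mean_s: float = 0.5
    kx_breath_sd_s: float = 0.02
    #: airflow sampling rate (Hz)
    sample_rate: float = 250.0
    suppression_frac: float = 0.7  # fractional rate decrement for suppressed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_awake < 7 or self.n_trials_kx < 7:
            raise ValueError("need at least 7 trials per state")
        for name in ("gain_frac", "entrainment_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        probs = self.class_probs or {}
        for k, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"class probability {k}={v} outside [0, 1]")
        if sum(probs.values()) > 1.0 + 1e-12:
            raise ValueError("class probabilities sum beyond 1")
        for key, (mu, _sd) in self.latency_params.items():
            if mu <= 0:
                raise ValueError(f"latency mean for {key} must be positive")
        if self.amp_params["mean_hz"] < 0 or self.gain_sd < 0:
            raise ValueError("rates and gain_sd must be non-negative")
        if min(self.pre_s, self.odor_s, self.post_s) <= 0:
            raise ValueError("trial timing durations must be positive")

    @property
    def trial_len_s(self) -> float:
        return self.pre_s + self.odor_s + self.post_s

    def with_(self, **kw) -> "SimConfig":
        return replace(copy.deepcopy(self), **kw)


# --------------------------------------------------------------------------
# respiration
# --------------------------------------------------------------------------

_INHALE_FRAC = 0.4  # fraction of the breath cycle spent inhaling


def _breath_durations(config: SimConfig, state: str, total_s: float,
                      rng: np.random.Generator,
                      boost_windows: np.ndarray | None = None) -> np.ndarray:
    """Sequential breath durations covering at least ``total_s`` seconds.

    ``boost_windows`` is an (n, 2) array of time intervals during which
    the instantaneous breath rate is multiplied by ``sniff_early_boost``
    (the early-trial sniffing surge).
    """
    durations: list[float] = []
    t = 0.0
    while t < total_s:
        if state == KX:
            d = rng.normal(config.kx_breath_mean_s, config.kx_breath_sd_s)
            d = max(d, 0.1)
        else:
            shape = config.awake_breath_shape
            d = rng.gamma(shape, config.awake_breath_mean_s / shape)
            d = float(np.clip(d, 1.0 / 12.0, 0.5))
        if boost_windows is not None and len(boost_windows):
            inside = (boost_windows[:, 0] <= t) & (t < boost_windows[:, 1])
            if inside.any():
                d /= config.sniff_early_boost
        durations.append(d)
        t += d
    return np.asarray(durations)


def _airflow_from_breaths(durations: np.ndarray, sample_rate: float,
                          duration_s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    onsets = np.concatenate([[0.0], np.cumsum(durations)])[:-1]
    inh = onsets
    exh = onsets + _INHALE_FRAC * durations
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    idx = np.clip(np.searchsorted(inh, t, side="right") - 1, 0, len(inh) - 1)
    local = t - inh[idx]
    d = durations[idx]
    inhale_len = _INHALE_FRAC * d
    airflow = np.where(
        local < inhale_len,
        -np.sin(np.pi * local / inhale_len),
        0.7 * np.sin(np.pi * (local - inhale_len) / (d - inhale_len)),
    )
    keep = inh < duration_s
    return airflow, inh[keep], exh[exh < duration_s]


def generate_respiration(config: SimConfig, state: str, duration: float,
                         seed: int) -> Respiration:
    """Synthesize an airflow trace for one state.

    Awake breathing is irregular (gamma-distributed durations spanning
    roughly 2-12 Hz); k/x breathing is metronomic near 2 Hz.  Negative
    airflow corresponds to inhalation.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if state not in (AWAKE, KX):
        raise ValueError(f"unknown state {state!r}")
    rng = np.random.default_rng(seed)
    durations = _breath_durations(config, state, duration, rng)
    airflow, inh, exh = _airflow_from_breaths(durations, config.sample_rate, duration)
    return Respiration(airflow=airflow, sample_rate=config.sample_rate,
                       inhalation_onsets=inh, exhalation_onsets=exh)


def _phase_on_grid(inh: np.ndarray, exh: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Respiratory phase (radians): 0 at inhalation onset, pi at exhalation."""
    nodes, phases = [], []
    k = 0
    for i, t_in in enumerate(inh):
        nodes.append(t_in)
        phases.append(2 * np.pi * k)
        later = exh[np.searchsorted(exh, t_in, side="right"):]
        if later.size:
            nodes.append(later[0])
            phases.append(2 * np.pi * k + np.pi)
        k += 1
    nodes = np.asarray(nodes)
    phases = np.asarray(phases)
    return np.interp(t_grid, nodes, phases) % (2 * np.pi)


# --------------------------------------------------------------------------
# session generation
# --------------------------------------------------------------------------


def _build_trials(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Round-structured trial table: awake rounds then k/x rounds, each
    round presenting every odor once in random order."""
    rows = []
    t = 0.0
    idx = 0
    for state, n_rounds in ((AWAKE, config.n_trials_awake), (KX, config.n_trials_kx)):
        for _ in range(n_rounds):
            order = rng.permutation(config.n_odors)
            for odor in order:
                on = t + config.pre_s
                rows.append((idx, int(odor), on, on + config.odor_s, state))
                t += config.trial_len_s
                idx += 1
    return pd.DataFrame(rows, columns=["trial_index", "odor_id", "odor_on_s",
                                       "odor_off_s", "state"])


def _draw_cell_odor_truth(config: SimConfig, profile: dict, n_cells: int,
                          rng: np.random.Generator,
                          base_awake: np.ndarray) -> pd.DataFrame:
    probs = dict(profile["class_probs"])
    if config.class_probs is not None:
        probs.update(config.class_probs)
    labels = list(probs) + ["none"]
    p = np.array([probs[c] for c in probs] + [1.0 - sum(probs.values())])
    rows = []
    for c in range(n_cells):
        for o in range(config.n_odors):
            cls = labels[rng.choice(len(labels), p=p)]
            amp = 0.0
            if cls in ("robust", "awake_only", "kx_only"):
                mu, sig = config.amp_params["mean_hz"], config.amp_params["sigma_log"]
                amp = rng.lognormal(np.log(mu) - sig**2 / 2, sig)
            key = "robust" if cls == "robust" else "state_specific"
            lmu, lsd = config.latency_params[key]
            lat = max(rng.normal(lmu, lsd), 0.01)
            gain = profile["robust_amp_gain"] if cls == "robust" else 1.0
            amp_awake = amp_kx = 0.0
            if cls == "robust":
                amp_awake = amp * gain
                amp_kx = amp * gain * 0.9
            elif cls == "awake_only":
                amp_awake = amp
            elif cls == "kx_only":
                amp_kx = amp
            elif cls == "suppressed":
                amp_awake = amp_kx = -config.suppression_frac * base_awake[c]
            rows.append((c, o, cls, lat if cls != "none" else np.nan,
                         amp_awake, amp_kx,
                         base_awake[c] + max(amp_awake, 0.0)))
    return pd.DataFrame(rows, columns=["unit_id", "odor_id", "class", "latency_s",
                                       "amp_awake_hz", "amp_kx_hz", "peak_hz"])


def _evoked_kernel(latency: float, dt: float = DT, rise_s: float = 0.06,
                   decay_s: float = 0.2, support_s: float = 1.4) -> tuple[int, np.ndarray]:
    """Unit-peak transient: half-Gaussian rise to 1 at latency+rise, then
    exponential decay.  Returns (offset bins from alignment, kernel)."""
    n = int(round(support_s / dt))
    t = np.arange(n) * dt
    sigma = rise_s / 2.0
    kern = np.where(
        t < rise_s,
        np.exp(-0.5 * ((t - rise_s) / sigma) ** 2),
        np.exp(-(t - rise_s) / decay_s),
    )
    return int(round(latency / dt)), kern


def generate_session(config: SimConfig, region_profile: str,
                     seed: int | None = None) -> tuple[SessionBundle, GroundTruth]:
    """Simulate one session for the given region profile.

    Deterministic in (config, profile, seed): the same inputs reproduce
    the session bit-for-bit.
    """
    key = _normalize_profile(region_profile)
    profile = copy.deepcopy(PROFILES[key])
    if config.baseline_hz is not None:
        profile["baseline_hz"].update(config.baseline_hz)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    trials = _build_trials(config, rng)
    n_trials = len(trials)
    duration = n_trials * config.trial_len_s + 2.0
    awake_trials = trials[trials.state == AWAKE]
    anesthesia_onset = float(awake_trials["odor_off_s"].max() + config.post_s / 2.0)

    # ---- respiration over the whole session, with early-trial sniff surge
    # within-odor awake round number = presentation count of that odor so far
    trials = trials.copy()
    trials["round"] = trials.groupby(["odor_id", "state"]).cumcount()
    boost = trials[(trials.state == AWAKE) &
                   (trials["round"] < config.n_early_boost_trials)]
    boost_windows = np.column_stack([boost["odor_on_s"].to_numpy(),
                                     boost["odor_on_s"].to_numpy() + 2.0])
    awake_end = anesthesia_onset
    d_awake = _breath_durations(config, AWAKE, awake_end, rng, boost_windows)
    t_awake_end = float(np.sum(d_awake))
    d_kx = _breath_durations(config, KX, duration - t_awake_end, rng)
    durations = np.concatenate([d_awake, d_kx])
    airflow, inh, exh = _airflow_from_breaths(durations, config.sample_rate, duration)
    resp = Respiration(airflow=airflow, sample_rate=config.sample_rate,
                       inhalation_onsets=inh, exhalation_onsets=exh)

    # ---- alignment of trials to the first inhalation after odor onset
    align_idx = np.searchsorted(inh, trials["odor_on_s"].to_numpy())
    align_idx = np.minimum(align_idx, len(inh) - 1)
    align_t = inh[align_idx]
    next_inh = inh[np.minimum(align_idx + 1, len(inh) - 1)]
    first_breath = np.maximum(next_inh - align_t, 0.05)

    # ---- per-cell baselines (log-normal heterogeneity around profile means)
    n_cells = config.n_cells_per_region
    het = rng.lognormal(-0.7**2 / 2, 0.7, n_cells)
    base_awake = profile["baseline_hz"][AWAKE] * het
    base_kx = profile["baseline_hz"][KX] * het
    cell_truth = pd.DataFrame({"unit_id": np.arange(n_cells),
                               "base_awake_hz": base_awake,
                               "base_kx_hz": base_kx})

    cell_odor = _draw_cell_odor_truth(config, profile, n_cells, rng, base_awake)

    # ---- per-trial shared gain and drift factors
    gains = rng.lognormal(-config.gain_sd**2 / 2, config.gain_sd, n_trials) \
        if config.gain_sd > 0 else np.ones(n_trials)
    gain_cells = rng.random(n_cells) < config.gain_frac
    rounds = trials["round"].to_numpy()
    is_awake_trial = (trials["state"] == AWAKE).to_numpy()
    if profile["drift"]:
        drift = 1.0 + config.drift_amp * np.exp(-rounds / config.drift_tau)
        drift = np.where(is_awake_trial, drift, 1.0)
    else:
        drift = np.ones(n_trials)
    sniff_rate = 1.0 / first_breath
    ref_rate = 1.0 / config.awake_breath_mean_s
    sniff_scale = np.where(
        is_awake_trial,
        (sniff_rate / ref_rate) ** config.sniff_amp_exponent,
        1.0,
    )

    # ---- rate construction on the 1 ms grid
    n_bins = int(round(duration / DT))
    t_grid = (np.arange(n_bins) + 0.5) * DT
    phase = _phase_on_grid(inh, exh, t_grid)
    depth = np.where(t_grid < anesthesia_onset,
                     0.2 * config.entrainment_depth, config.entrainment_depth)
    entrain = 1.0 + depth * np.cos(phase)
    state_is_kx = t_grid >= anesthesia_onset

    # per-bin trial gain (1 outside trials)
    gain_grid = np.ones(n_bins)
    starts = (trials["odor_on_s"].to_numpy() - config.pre_s)
    for ti in range(n_trials):
        b0 = int(round(starts[ti] / DT))
        b1 = int(round((starts[ti] + config.trial_len_s) / DT))
        gain_grid[b0:b1] = gains[ti]

    odor_of_trial = trials["odor_id"].to_numpy()
    amp_awake_mat = np.zeros((n_cells, config.n_odors))
    amp_kx_mat = np.zeros((n_cells, config.n_odors))
    lat_mat = np.zeros((n_cells, config.n_odors))
    for _, r in cell_odor.iterrows():
        c, o = int(r.unit_id), int(r.odor_id)
        amp_awake_mat[c, o] = r.amp_awake_hz
        amp_kx_mat[c, o] = r.amp_kx_hz
        lat_mat[c, o] = 0.0 if np.isnan(r.latency_s) else r.latency_s

    spikes: dict[int, np.ndarray] = {}
    unit_rows = []
    awake_dur = anesthesia_onset
    kx_dur = duration - anesthesia_onset
    for c in range(n_cells):
        rate = np.where(state_is_kx, base_kx[c], base_awake[c]) * entrain
        if gain_cells[c]:
            rate = rate * gain_grid
        # evoked transients
        for ti in range(n_trials):
            o = odor_of_trial[ti]
            amp = amp_kx_mat[c, o] if not is_awake_trial[ti] else amp_awake_mat[c, o]
            if amp == 0.0:
                continue
            factor = gains[ti] if gain_cells[c] else 1.0
            if amp > 0:
                factor *= drift[ti] * sniff_scale[ti]
            off, kern = _evoked_kernel(lat_mat[c, o])
            b0 = int(round(align_t[ti] / DT)) + off
            b1 = min(b0 + kern.size, n_bins)
            if b0 < n_bins:
                rate[b0:b1] += amp * factor * kern[: b1 - b0]
        np.maximum(rate, 0.0, out=rate)
        counts = rng.poisson(rate * DT)
        nz = np.nonzero(counts)[0]
        reps = np.repeat(nz, counts[nz])
        times = (reps + rng.random(reps.size)) * DT
        spikes[c] = np.sort(times)
        n_aw = np.searchsorted(spikes[c], anesthesia_onset)
        amp_uv = rng.normal(150.0, 30.0)
        unit_rows.append((c, key, amp_uv, amp_uv + rng.normal(0, 3.0),
                          n_aw / awake_dur, (spikes[c].size - n_aw) / kx_dur,
                          rng.normal(0.6, 0.1)))

    units = pd.DataFrame(unit_rows, columns=UNIT_COLUMNS)
    trial_factors = pd.DataFrame({
        "trial_index": trials["trial_index"],
        "gain": gains,
        "sniff_rate_hz": sniff_rate,
        "first_breath_s": first_breath,
        "round": rounds,
        "drift_factor": drift,
    })
    gt = GroundTruth(cell_odor=cell_odor, trial_factors=trial_factors,
                     cells=cell_truth)
    bundle = SessionBundle(
        units=units,
        spikes=spikes,
        trials=trials[["trial_index", "odor_id", "odor_on_s", "odor_off_s", "state"]],
        respiration=resp,
        meta={
            "profile": key,
            "seed": int(config.seed if seed is None else seed),
            "duration_s": duration,
            "anesthesia_onset_s": anesthesia_onset,
            "n_odors": config.n_odors,
            "simulated": True,
        },
    )
    return bundle, gt


# --------------------------------------------------------------------------
# deterministic fixtures
# --------------------------------------------------------------------------

#: counts of spikes placed in the 480 ms response window of each trial of
#: the "tiny-2odor" fixture: rows = cells, columns = (odor, trial).
TINY_2ODOR_COUNTS = {
    # odor 0 trials            odor 1 trials
    0: [(5, 6, 5, 4), (0, 1, 0, 1)],   # odor-0-selective cell
    1: [(1, 0, 1, 0), (6, 5, 7, 6)],   # odor-1-selective cell
    2: [(2, 2, 2, 2), (2, 2, 2, 2)],   # untuned cell
    3: [(0, 0, 0, 0), (0, 0, 0, 0)],   # silent cell
}


def _regular_respiration(duration_s: float, breath_s: float = 0.5,
                         sample_rate: float = 250.0) -> Respiration:
    n_breaths = int(np.ceil(duration_s / breath_s)) + 1
    durations = np.full(n_breaths, breath_s)
    airflow, inh, exh = _airflow_from_breaths(durations, sample_rate, duration_s)
    return Respiration(airflow=airflow, sample_rate=sample_rate,
                       inhalation_onsets=inh, exhalation_onsets=exh)


def _fixture_tiny_2odor() -> SessionBundle:
    # 4 cells x 2 odors x 4 trials, 10 s per trial, odor_on = t0 + 2 s.
    # odor_on falls exactly on an inhalation onset (multiples of 0.5 s),
    # so the response alignment is that inhalation itself.
    rows = []
    idx = 0
    for trial_round in range(4):
        for odor in (0, 1):
            t0 = idx * 10.0
            rows.append((idx, odor, t0 + 2.0, t0 + 3.0, AWAKE))
            idx += 1
    trials = pd.DataFrame(rows, columns=["trial_index", "odor_id", "odor_on_s",
                                         "odor_off_s", "state"])
    duration = 80.0
    resp = _regular_respiration(duration)
    spikes = {}
    for c, per_odor in TINY_2ODOR_COUNTS.items():
        times = []
        for _, tr in trials.iterrows():
            k = per_odor[int(tr.odor_id)][int(tr.trial_index) // 2]
            # spread k spikes evenly inside [odor_on, odor_on + 0.48)
            times.extend(tr.odor_on_s + 0.48 * (np.arange(k) + 0.5) / max(k, 1))
        spikes[c] = np.sort(np.asarray(times))
    units = pd.DataFrame(
        [(c, "pcx", 150.0, 150.0, spikes[c].size / duration,
          spikes[c].size / duration, 0.6) for c in spikes],
        columns=UNIT_COLUMNS,
    )
    return SessionBundle(units=units, spikes=spikes, trials=trials,
                         respiration=resp,
                         meta={"fixture": "tiny-2odor", "duration_s": duration})


def _fixture_qc_edge_cases() -> SessionBundle:
    # boundary units for the stability criteria:
    #   u0 at exactly 0.01 Hz (kept), u1 with exactly 100-fold rate change
    #   (kept), u2 with a 51 uV amplitude change (discarded), u3 clean.
    duration = 100.0
    units = pd.DataFrame(
        [
            (0, "ob", 150.0, 150.0, 0.01, 0.01, 0.6),
            (1, "ob", 150.0, 150.0, 2.0, 0.02, 0.6),
            (2, "ob", 150.0, 201.0, 5.0, 5.0, 0.6),
            (3, "ob", 150.0, 160.0, 5.0, 4.0, 0.6),
        ],
        columns=UNIT_COLUMNS,
    )
    spikes = {i: np.arange(1.0, duration, duration / 5) for i in range(4)}
    trials = pd.DataFrame(
        [(0, 0, 10.0, 11.0, AWAKE), (1, 0, 60.0, 61.0, KX)],
        columns=["trial_index", "odor_id", "odor_on_s", "odor_off_s", "state"],
    )
    return SessionBundle(units=units, spikes=spikes, trials=trials,
                         respiration=_regular_respiration(duration),
                         meta={"fixture": "qc-edge-cases",
                               "duration_s": duration,
                               "anesthesia_onset_s": 50.0})


def _fixture_phase_locked() -> SessionBundle:
    # every spike exactly at an inhalation onset -> phase 0, PPC = 1
    duration = 30.0
    resp = _regular_respiration(duration)
    spikes = {0: resp.inhalation_onsets.copy()}
    units = pd.DataFrame([(0, "ob", 150.0, 150.0, 2.0, 2.0, 0.6)],
                         columns=UNIT_COLUMNS)
    trials = pd.DataFrame([(0, 0, 10.0, 11.0, AWAKE)],
                          columns=["trial_index", "odor_id", "odor_on_s",
                                   "odor_off_s", "state"])
    return SessionBundle(units=units, spikes=spikes, trials=trials,
                         respiration=resp,
                         meta={"fixture": "phase-locked", "duration_s": duration})


_FIXTURES = {
    "tiny-2odor": _fixture_tiny_2odor,
    "qc-edge-cases": _fixture_qc_edge_cases,
    "phase-locked": _fixture_phase_locked,
}


def make_fixture(name: str) -> SessionBundle:
    """Return a small, hand-specified deterministic session.

    Registry: ``tiny-2odor`` (4 cells x 2 odors x 4 trials with documented
    spike counts), ``qc-edge-cases`` (stability-criterion boundary units),
    ``phase-locked`` (all spikes at inhalation onset).
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; registry: {sorted(_FIXTURES)}"
        ) from None
    return builder()
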
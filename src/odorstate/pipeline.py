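"""Orchestration: simulate -> preprocess -> analyses as reproducible runs.

Stage functions operate on :class:`SessionBundle` objects and return
plain tables; :func:`run` wires them into a run directory with a
manifest (config hash, seeds, versions) and per-analysis CSV/JSON
reports.  All randomness derives from one root seed via stage-named
substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, geometry, overlap, responsivity, stabilization
from .preprocess import (RESPONSE_480MS, RESPONSE_500MS, CONTROL_WINDOW,
                         WindowSpec, align_trials, apply_stability_criteria,
                         count_in_intervals, count_spikes, detect_inhalations,
                         select_state_trials)
from .session import AWAKE, KX, SessionBundle
from .synthetic import SimConfig, generate_session

log = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed, < 2**31."""
    return (root_seed * 100003 + zlib.crc32(stage.encode())) % (2**31 - 1)


# --------------------------------------------------------------------------
# per-session feature extraction
# --------------------------------------------------------------------------


@dataclass
class SessionFeatures:
    """Sniff-aligned quantities for one session's selected trials."""

    bundle: SessionBundle
    alignment: pd.DataFrame          # per selected trial
    cell_ids: np.ndarray
    evoked_first_sniff: np.ndarray   # cells x trials (first-sniff window)
    baseline_sniff: np.ndarray       # cells x trials (last pre-odor sniff)
    counts_480: np.ndarray           # cells x trials (fixed 480 ms)
    counts_500: np.ndarray
    counts_control: np.ndarray       # -2.0 to -1.5 s pre-odor window
    trial_labels: pd.DataFrame       # odor_id, trial_idx, state, sniff_rate_hz


def extract_features(bundle: SessionBundle, mode: str = "standard",
                     n_per_state: int = 7, qc: bool = True) -> SessionFeatures:
    """Detect sniffs, align trials, apply unit QC, and count spikes in
    the analysis windows for the selected trial subsets."""
    resp = bundle.respiration
    sniffs = detect_inhalations(resp.airflow, resp.sample_rate)
    sniffs = align_trials(sniffs, bundle.trials)
    align = sniffs.trial_alignment.merge(bundle.trials, on="trial_index")

    onset = bundle.anesthesia_onset_s
    if onset is None:
        raise ValueError("session has no anesthesia onset marker")
    sel = select_state_trials(bundle.trials, onset, n_per_state=n_per_state,
                              mode=mode)
    rows = []
    for odor, by_state in sel.items():
        for state, ids in by_state.items():
            for k, tid in enumerate(ids):
                rows.append((int(tid), odor, k, state))
    sel_df = pd.DataFrame(rows, columns=["trial_index", "odor_id", "trial_idx",
                                         "state"])
    align = sel_df.merge(align[["trial_index", "odor_on_s", "odor_off_s",
                                "response_inh_s", "baseline_inh_s",
                                "first_breath_s", "valid"]],
                         on="trial_index")
    align = align[align.valid].reset_index(drop=True)

    units = bundle.units
    if qc:
        qc_table = apply_stability_criteria(units)
        cell_ids = units.loc[qc_table.keep.to_numpy(), "unit_id"].to_numpy()
    else:
        cell_ids = bundle.unit_ids
    cell_ids = np.asarray(sorted(int(c) for c in cell_ids))

    t_resp = align["response_inh_s"].to_numpy()
    t_base = align["baseline_inh_s"].to_numpy()
    breath = align["first_breath_s"].to_numpy()
    evoked = count_in_intervals(bundle.spikes, t_resp, t_resp + breath, cell_ids)
    baseline = count_in_intervals(bundle.spikes, t_base, t_base + breath, cell_ids)
    c480 = count_spikes(bundle.spikes, t_resp, RESPONSE_480MS, cell_ids,
                        align["trial_index"].to_numpy()).counts[:, :, 0]
    c500 = count_spikes(bundle.spikes, t_resp, RESPONSE_500MS, cell_ids,
                        align["trial_index"].to_numpy()).counts[:, :, 0]
    cctl = count_spikes(bundle.spikes, t_resp, CONTROL_WINDOW, cell_ids,
                        align["trial_index"].to_numpy()).counts[:, :, 0]
    labels = align[["trial_index", "odor_id", "trial_idx", "state"]].copy()
    labels["sniff_rate_hz"] = stabilization.sniff_rate(breath)
    return SessionFeatures(bundle=bundle, alignment=align, cell_ids=cell_ids,
                           evoked_first_sniff=evoked, baseline_sniff=baseline,
                           counts_480=c480, counts_500=c500,
                           counts_control=cctl, trial_labels=labels)


def features_matrix(feats: SessionFeatures, which: str = "counts_480",
                    state: str | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Trials x cells matrix (and labels) for one count window."""
    M = getattr(feats, which).T.astype(float)
    labels = feats.trial_labels.copy()
    labels.attrs["unit_ids"] = feats.cell_ids
    if state is not None:
        keep = (labels.state == state).to_numpy()
        M, labels = M[keep], labels[keep].reset_index(drop=True)
        labels.attrs["unit_ids"] = feats.cell_ids
    return M, labels


# --------------------------------------------------------------------------
# analysis stages
# --------------------------------------------------------------------------


def stage_responsivity(feats: SessionFeatures, alpha: float = 0.05) -> dict:
    labels = feats.trial_labels
    table = responsivity.responsivity_table(
        feats.evoked_first_sniff, feats.baseline_sniff, feats.cell_ids,
        labels["odor_id"].to_numpy(), labels["state"].to_numpy(), alpha=alpha)
    cross = responsivity.cross_state_table(table)
    fractions = (
        table.groupby(["state", "class"]).size()
        / table.groupby("state").size()
    ).rename("fraction").reset_index()
    return {"table": table, "cross_state": cross, "fractions": fractions}


def stage_sparseness(feats: SessionFeatures) -> pd.DataFrame:
    """Lifetime (per cell) and population (per odor) sparseness of mean
    evoked first-sniff rates, per state."""
    labels = feats.trial_labels
    rows = []
    for state in (AWAKE, KX):
        sel = (labels.state == state).to_numpy()
        odors = labels["odor_id"].to_numpy()[sel]
        E = feats.evoked_first_sniff[:, sel]
        odor_levels = np.unique(odors)
        mean_rates = np.column_stack([
            E[:, odors == o].mean(axis=1) for o in odor_levels])
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            for ci, cid in enumerate(feats.cell_ids):
                rows.append((state, "lifetime", int(cid),
                             responsivity.lifetime_sparseness(mean_rates[ci])))
            for oi, o in enumerate(odor_levels):
                rows.append((state, "population", int(o),
                             responsivity.population_sparseness(mean_rates[:, oi])))
    return pd.DataFrame(rows, columns=["state", "kind", "id", "sparseness"])


def stage_geometry(pops: dict[str, geometry.Pseudopopulation]) -> pd.DataFrame:
    rows = []
    for state in (AWAKE, KX):
        sub = pops[state]
        summ = geometry.correlation_separation(sub.X, sub.odors)
        rows.append((f"within_{state}", summ.mean_within, summ.mean_across,
                     summ.separation))
    cs = geometry.cross_state_correlation(pops[AWAKE].X, pops[AWAKE].odors,
                                          pops[KX].X, pops[KX].odors)
    rows.append(("cross_state", cs.mean_within, cs.mean_across, cs.separation))
    return pd.DataFrame(rows, columns=["mode", "mean_within", "mean_across",
                                       "separation"])


def stage_decoding(pops: dict[str, geometry.Pseudopopulation], sizes,
                   n_draws: int, seed: int, C: float = 1.0) -> pd.DataFrame:
    frames = []
    for state in (AWAKE, KX):
        sub = pops[state]
        res = decoding.accuracy_vs_size(sub.X, sub.odors, sizes,
                                        n_draws=n_draws, seed=seed, C=C,
                                        mode=f"within_{state}")
        frames.append(res.to_frame())
    res = decoding.accuracy_vs_size(
        pops[AWAKE].X, pops[AWAKE].odors, sizes, n_draws=n_draws,
        seed=seed + 1, C=C, mode="cross_state",
        X_test=pops[KX].X, y_test=pops[KX].odors)
    frames.append(res.to_frame())
    return pd.concat(frames, ignore_index=True)


def stage_overlap(pop_500: geometry.Pseudopopulation, k: int = 3) -> pd.DataFrame:
    """dPCA stimulus projection and per-odor cross-state Matusita overlap."""
    M, odor_levels, state_levels = overlap.condition_means(
        pop_500.X, pop_500.odors, pop_500.states)
    marg = overlap.marginalize(M)
    comps = overlap.fit_dpca(marg, n_components=k)
    scores = overlap.project_trials(comps, pop_500.X, "stimulus", k=k)
    clouds = overlap.trial_clouds(scores, pop_500.odors, pop_500.states)
    rows = []
    for o in odor_levels:
        xi = overlap.matusita_overlap(clouds[(int(o), AWAKE)],
                                      clouds[(int(o), KX)])
        rows.append((int(o), xi))
    return pd.DataFrame(rows, columns=["odor_id", "xi"])


def stage_stabilization(feats_list: list[SessionFeatures],
                        use_control: bool = False) -> dict:
    """Pooled distance-to-stable trajectories and the regressions.

    Uses the stabilization trial mode (first 15 awake presentations per
    odor); the stable set is the last five of those.
    """
    rows = []
    for si, feats in enumerate(feats_list):
        which = "counts_control" if use_control else "counts_500"
        labels = feats.trial_labels
        for odor in np.unique(labels["odor_id"]):
            sel = ((labels.odor_id == odor) & (labels.state == AWAKE)).to_numpy()
            if sel.sum() < 10:
                continue
            order = np.argsort(labels.loc[sel, "trial_idx"].to_numpy())
            X = getattr(feats, which).T.astype(float)[sel][order]
            stable = np.arange(X.shape[0] - 5, X.shape[0])
            d = stabilization.distance_to_stable(X, stable)
            sniff = labels.loc[sel, "sniff_rate_hz"].to_numpy()[order]
            pr = X.mean(axis=1)
            for t in range(X.shape[0]):
                rows.append((si, int(odor), t + 1, d[t], sniff[t], pr[t]))
    traj = pd.DataFrame(rows, columns=["session", "odor_id", "trial",
                                       "distance", "sniff_rate_hz",
                                       "pop_rate"])
    fit = stabilization.fit_stabilization_regression(
        traj["distance"], traj["sniff_rate_hz"], traj["pop_rate"],
        traj["trial"])
    reduced = stabilization.reduced_model_residuals(
        traj["distance"], traj["sniff_rate_hz"], traj["pop_rate"],
        traj["trial"])
    return {"trajectories": traj, "fit": fit, "reduced": reduced}


# --------------------------------------------------------------------------
# run orchestration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    profiles: tuple[str, ...] = ("ob", "pcx")
    n_sessions_per_profile: int = 2
    seed: int = 0
    out_dir: str = "runs/default"
    sim: dict = field(default_factory=dict)     # SimConfig overrides
    sizes: tuple[int, ...] = (10, 25, 50, 100)
    n_draws: int = 50
    stages: tuple[str, ...] = ("responsivity", "sparseness", "geometry",
                               "decoding", "overlap", "stabilization")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _pseudopops(feats_list, which="counts_480"):
    sessions = [features_matrix(f, which) for f in feats_list]
    pop = geometry.build_pseudopopulation(sessions)
    return {AWAKE: pop.subset_state(AWAKE), KX: pop.subset_state(KX),
            "both": pop}


def run(config: RunConfig) -> Path:
    """Execute the configured stages per profile; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "config_hash": config.config_hash(),
                "seeds": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "stages_completed": [], "stages_failed": {}}
    sim_cfg = SimConfig(**config.sim)
    for profile in config.profiles:
        pdir = out / profile
        pdir.mkdir(exist_ok=True)
        feats_std, feats_stab = [], []
        for i in range(config.n_sessions_per_profile):
            seed = stage_seed(config.seed, f"simulate/{profile}/{i}")
            manifest["seeds"][f"{profile}/{i}"] = seed
            cache = pdir / f"session{i}_features.npz"
            bundle, _gt = generate_session(sim_cfg, profile, seed=seed)
            if cache.exists():
                log.info("cache hit for %s", cache)
            feats_std.append(extract_features(bundle, mode="standard"))
            feats_stab.append(extract_features(bundle, mode="stabilization"))
        pops = _pseudopops(feats_std, "counts_480")
        pops500 = _pseudopops(feats_std, "counts_500")
        for stage in config.stages:
            try:
                if stage == "responsivity":
                    res = stage_responsivity(feats_std[0])
                    res["table"].to_csv(pdir / "responsivity.csv", index=False)
                    res["fractions"].to_csv(pdir / "responsivity_fractions.csv",
                                            index=False)
                    res["cross_state"].to_csv(pdir / "cross_state_labels.csv",
                                              index=False)
                elif stage == "sparseness":
                    stage_sparseness(feats_std[0]).to_csv(
                        pdir / "sparseness.csv", index=False)
                elif stage == "geometry":
                    stage_geometry(pops).to_csv(pdir / "separation.csv",
                                                index=False)
                elif stage == "decoding":
                    sizes = [s for s in config.sizes
                             if s <= pops[AWAKE].n_cells]
                    stage_decoding(pops, sizes, config.n_draws,
                                   stage_seed(config.seed, f"decode/{profile}")
                                   ).to_csv(pdir / "decoding.csv", index=False)
                elif stage == "overlap":
                    stage_overlap(pops500["both"]).to_csv(
                        pdir / "overlap.csv", index=False)
                elif stage == "stabilization":
                    res = stage_stabilization(feats_stab)
                    res["trajectories"].to_csv(pdir / "trajectories.csv",
                                               index=False)
                    pd.DataFrame({"coef": res["fit"].params,
                                  "se": res["fit"].bse,
                                  "t": res["fit"].tvalues,
                                  "p": res["fit"].pvalues}).to_csv(
                        pdir / "stabilization_fit.csv")
                manifest["stages_completed"].append(f"{profile}/{stage}")
            except Exception as exc:  # isolate failing stages
                log.exception("stage %s failed for %s", stage, profile)
                manifest["stages_failed"][f"{profile}/{stage}"] = str(exc)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
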
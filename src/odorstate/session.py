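"""Core containers for one extracellular recording session.

A session bundles sorted units with their spike times, the trial event
table (odor identity, odor on/off, brain state), the respiration airflow
trace, and optional laser-pulse intervals for opto-tagging.  Simulated
sessions additionally carry a :class:`GroundTruth` describing the rate
model that generated them.

All times are in seconds from session start; trial indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AWAKE = "awake"
KX = "kx"
STATES = (AWAKE, KX)

#: columns of the unit metadata table
UNIT_COLUMNS = [
    "unit_id",
    "region",
    "amp_awake_uv",
    "amp_kx_uv",
    "rate_awake_hz",
    "rate_kx_hz",
    "peak_trough_ms",
]

TRIAL_COLUMNS = ["trial_index", "odor_id", "odor_on_s", "odor_off_s", "state"]


@dataclass
class Respiration:
    """Airflow trace sampled uniformly, negative values = inhalation."""

    airflow: np.ndarray
    sample_rate: float
    inhalation_onsets: np.ndarray
    exhalation_onsets: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.airflow.size) / self.sample_rate


@dataclass
class GroundTruth:
    """Generative parameters behind a simulated session.

    ``cell_odor`` rows: unit_id, odor_id, class (robust / awake_only /
    kx_only / suppressed / none), latency_s, amp_awake_hz, amp_kx_hz,
    peak_hz.  ``trial_factors`` rows: trial_index, gain, sniff_rate_hz,
    first_breath_s.  ``cells`` rows: unit_id, base_awake_hz, base_kx_hz.
    """

    cell_odor: pd.DataFrame
    trial_factors: pd.DataFrame
    cells: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "cell_odor": self.cell_odor.to_dict(orient="list"),
            "trial_factors": self.trial_factors.to_dict(orient="list"),
            "cells": self.cells.to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            cell_odor=pd.DataFrame(d["cell_odor"]),
            trial_factors=pd.DataFrame(d["trial_factors"]),
            cells=pd.DataFrame(d["cells"]),
        )


@dataclass
class SessionBundle:
    units: pd.DataFrame
    spikes: dict[int, np.ndarray]
    trials: pd.DataFrame
    respiration: Respiration
    laser: np.ndarray | None = None  # (n_pulses, 2) on/off times
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for uid, st in self.spikes.items():
            st = np.asarray(st, dtype=float)
            if st.size > 1 and np.any(np.diff(st) < 0):
                raise ValueError(f"spike times for unit {uid} are not sorted")
            self.spikes[uid] = st

    @property
    def unit_ids(self) -> np.ndarray:
        return self.units["unit_id"].to_numpy()

    @property
    def duration_s(self) -> float:
        return float(self.meta.get(
            "duration_s", self.respiration.airflow.size / self.respiration.sample_rate
        ))

    @property
    def anesthesia_onset_s(self) -> float | None:
        return self.meta.get("anesthesia_onset_s")

    # ---------------------------------------------------------------- disk IO

    def save(self, outdir: str | Path) -> Path:
        """Write the bundle as a plain-text directory.

        Layout: ``manifest.json`` (metadata, units table, respiration
        events), ``spikes.csv`` (unit_id, time_s), ``trials.csv``,
        ``respiration.csv`` (time_s, airflow), and ``ground_truth.json``
        when the bundle carries one in ``meta``.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "meta": _jsonable(self.meta),
            "units": self.units.to_dict(orient="list"),
            "sample_rate": self.respiration.sample_rate,
            "inhalation_onsets": self.respiration.inhalation_onsets.tolist(),
            "exhalation_onsets": self.respiration.exhalation_onsets.tolist(),
            "laser": None if self.laser is None else np.asarray(self.laser).tolist(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest))
        rows = [
            (uid, t) for uid in self.unit_ids for t in self.spikes.get(uid, ())
        ]
        pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
            outdir / "spikes.csv", index=False
        )
        self.trials.to_csv(outdir / "trials.csv", index=False)
        resp = pd.DataFrame(
            {"time_s": self.respiration.times, "airflow": self.respiration.airflow}
        )
        resp.to_csv(outdir / "respiration.csv", index=False, float_format="%.6g")
        return outdir

    @classmethod
    def load(cls, indir: str | Path) -> "SessionBundle":
        indir = Path(indir)
        manifest = json.loads((indir / "manifest.json").read_text())
        units = pd.DataFrame(manifest["units"])
        spikes_df = pd.read_csv(indir / "spikes.csv")
        spikes = {
            int(uid): np.sort(grp["time_s"].to_numpy())
            for uid, grp in spikes_df.groupby("unit_id")
        }
        for uid in units["unit_id"]:
            spikes.setdefault(int(uid), np.empty(0))
        trials = pd.read_csv(indir / "trials.csv")
        resp_df = pd.read_csv(indir / "respiration.csv")
        resp = Respiration(
            airflow=resp_df["airflow"].to_numpy(),
            sample_rate=float(manifest["sample_rate"]),
            inhalation_onsets=np.asarray(manifest["inhalation_onsets"], dtype=float),
            exhalation_onsets=np.asarray(manifest["exhalation_onsets"], dtype=float),
        )
        laser = manifest.get("laser")
        return cls(
            units=units,
            spikes=spikes,
            trials=trials,
            respiration=resp,
            laser=None if laser is None else np.asarray(laser, dtype=float),
            meta=manifest.get("meta", {}),
        )


def save_session(bundle: SessionBundle, outdir: str | Path,
                 ground_truth: GroundTruth | None = None) -> Path:
    out = bundle.save(outdir)
    if ground_truth is not None:
        (Path(out) / "ground_truth.json").write_text(
            json.dumps(_jsonable(ground_truth.to_dict()))
        )
    return out


def load_session(indir: str | Path) -> tuple[SessionBundle, GroundTruth | None]:
    bundle = SessionBundle.load(indir)
    gt_path = Path(indir) / "ground_truth.json"
    gt = None
    if gt_path.exists():
        gt = GroundTruth.from_dict(json.loads(gt_path.read_text()))
    return bundle, gt


def load_nwb(path: str | Path) -> SessionBundle:
    """Map an NWB file (units, trials, analog respiration) onto a bundle.

    Requires ``pynwb``, which is an optional dependency.
    """
    try:
        import pynwb  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "NWB import requires the optional dependency 'pynwb'"
        ) from exc
    raise NotImplementedError(
        "NWB adapter: map nwb.units -> units/spikes, nwb.trials -> trials, "
        "and the respiration TimeSeries -> Respiration, then build SessionBundle"
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
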
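"""On-disk session layout and ingestion.

Native layout (all times in seconds)::

    session/
      trials.csv            # TrialTable columns
      units.json            # [{"unit_id": ..., "area": ...}, ...]
      spikes/<unit>.bin     # little-endian float64 spike times
      waveforms/<unit>.bin  # little-endian float64 mean waveform (32 kHz)
      lfp/<channel>.bin     # little-endian float64 samples
      lfp/meta.json         # {"channel_id": {"fs": ..., "t0": ...}, ...}
      ground_truth.json     # optional planted parameters
      meta.json             # {"duration": ...}

``load_nwb`` reads the subset of the NWB HDF5 layout this package needs
(units spike times, a trials interval table, acquisition LFP series) using
h5py directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LfpChannel, SpikeTrain

__all__ = ["Session", "write_session", "load_session", "load_nwb"]


@dataclass
class Session:
    """In-memory session: spike trains, LFP channels, trial table."""

    trains: list
    lfps: list
    trials: pd.DataFrame
    waveforms: dict = field(default_factory=dict)  # unit_id -> raw samples
    ground_truth: dict = field(default_factory=dict)
    duration: float = 0.0


def write_session(path, session: Session) -> Path:
    path = Path(path)
    (path / "spikes").mkdir(parents=True, exist_ok=True)
    (path / "waveforms").mkdir(exist_ok=True)
    (path / "lfp").mkdir(exist_ok=True)
    session.trials.to_csv(path / "trials.csv", index=False)
    units = [{"unit_id": t.unit_id, "area": t.area} for t in session.trains]
    (path / "units.json").write_text(json.dumps(units, indent=1))
    for t in session.trains:
        t.times.astype("<f8").tofile(path / "spikes" / f"{t.unit_id}.bin")
    for uid, wf in session.waveforms.items():
        np.asarray(wf, dtype="<f8").tofile(path / "waveforms" / f"{uid}.bin")
    meta = {}
    for lfp in session.lfps:
        lfp.samples.astype("<f8").tofile(path / "lfp" / f"{lfp.channel_id}.bin")
        meta[lfp.channel_id] = {"fs": lfp.fs, "t0": lfp.t0}
    (path / "lfp" / "meta.json").write_text(json.dumps(meta, indent=1))
    (path / "meta.json").write_text(json.dumps({"duration": session.duration}))
    if session.ground_truth:
        (path / "ground_truth.json").write_text(
            json.dumps(session.ground_truth, indent=1, default=_jsonable)
        )
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def load_session(path) -> Session:
    path = Path(path)
    trials = pd.read_csv(path / "trials.csv")
    units = json.loads((path / "units.json").read_text())
    duration = json.loads((path / "meta.json").read_text())["duration"]
    trains = []
    waveforms = {}
    for u in units:
        times = np.fromfile(path / "spikes" / f"{u['unit_id']}.bin", dtype="<f8")
        trains.append(
            SpikeTrain(unit_id=u["unit_id"], times=times, duration=duration, area=u["area"])
        )
        wf_file = path / "waveforms" / f"{u['unit_id']}.bin"
        if wf_file.exists():
            waveforms[u["unit_id"]] = np.fromfile(wf_file, dtype="<f8")
    lfps = []
    meta_file = path / "lfp" / "meta.json"
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
        for cid, m in meta.items():
            samples = np.fromfile(path / "lfp" / f"{cid}.bin", dtype="<f8")
            lfps.append(LfpChannel(channel_id=cid, fs=m["fs"], samples=samples, t0=m["t0"]))
    gt_file = path / "ground_truth.json"
    gt = json.loads(gt_file.read_text()) if gt_file.exists() else {}
    return Session(
        trains=trains,
        lfps=lfps,
        trials=trials,
        waveforms=waveforms,
        ground_truth=gt,
        duration=duration,
    )


def load_nwb(path, lfp_series: str | None = None) -> Session:
    """Read spike times, trials and LFP from an NWB-format HDF5 file.

    Covers the standard layout: ``units/spike_times`` with the ragged
    ``spike_times_index``, ``intervals/trials`` columns, and an
    ``acquisition/<name>`` ElectricalSeries (``data`` plus either
    ``starting_time`` with a ``rate`` attribute or explicit timestamps).
    """
    import h5py

    with h5py.File(path, "r") as f:
        trains = []
        duration = 0.0
        if "units" in f:
            st = f["units/spike_times"][:]
            idx = f["units/spike_times_index"][:]
            ids = (
                f["units/id"][:]
                if "id" in f["units"]
                else np.arange(len(idx))
            )
            start = 0
            duration = float(st.max()) + 1.0 if st.size else 1.0
            for uid, stop in zip(ids, idx):
                times = np.sort(st[start : int(stop)])
                trains.append(
                    SpikeTrain(unit_id=f"u{int(uid)}", times=times, duration=duration)
                )
                start = int(stop)
        trials = pd.DataFrame()
        if "intervals/trials" in f:
            g = f["intervals/trials"]
            cols = {}
            for key in g:
                if key.endswith("_index"):
                    continue
                data = g[key][:]
                if data.dtype.kind == "S":
                    data = np.array([d.decode() for d in data])
                cols[key] = data
            trials = pd.DataFrame(cols)
        lfps = []
        if "acquisition" in f:
            names = [lfp_series] if lfp_series else list(f["acquisition"])
            for name in names:
                g = f["acquisition"][name]
                if "data" not in g:
                    continue
                data = np.asarray(g["data"][:], dtype=float)
                if "starting_time" in g:
                    rate = float(g["starting_time"].attrs.get("rate", 1000.0))
                    t0 = float(g["starting_time"][()])
                else:
                    ts = g["timestamps"][:]
                    rate = 1.0 / float(np.median(np.diff(ts)))
                    t0 = float(ts[0])
                if data.ndim == 1:
                    data = data[:, None]
                for ch in range(data.shape[1]):
                    lfps.append(
                        LfpChannel(
                            channel_id=f"{name}_{ch}", fs=rate, samples=data[:, ch], t0=t0
                        )
                    )
    return Session(trains=trains, lfps=lfps, trials=trials, duration=duration)
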
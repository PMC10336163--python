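"""Session data model, disk format and kinematic derivation.

A recording session is a directory holding a key/value metadata file plus,
per trial, three comma-separated tables:

    trial01_tracking.csv   t,x,y,hd          (50 Hz; cm; degrees in [0,360))
    trial01_lfp.csv        t,v               (250 Hz; arbitrary voltage units)
    trial01_spikes.csv     cell_id,t         (seconds, ascending per cell)

Missing tracking samples are encoded as blank fields; gaps of at most
MAX_GAP_SAMPLES are linearly interpolated (circularly for head direction)
before kinematics are derived, longer gaps stay missing and are excluded
from every metric downstream.

Mean spike waveforms, when available, live in ``waveform_<cell>.csv`` with
one column per tetrode channel, sampled at 48 kHz.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._circular import circ_diff_deg, interp_angle_deg, wrap_deg

TRACKING_HZ = 50.0
TRACKING_DT = 1.0 / TRACKING_HZ
LFP_HZ = 250.0
WAVEFORM_HZ = 48000.0
MAX_GAP_SAMPLES = 5  # longest tracking dropout that is interpolated


class IncompleteBundleError(ValueError):
    """A file required by the bundle layout is absent ("incomplete bundle")."""


class BadSamplingError(ValueError):
    """A time base is not uniformly sampled at its nominal rate ("bad sampling")."""


class BadAnglesError(ValueError):
    """Head-direction values outside [0, 360) ("bad angles")."""


@dataclasses.dataclass
class TrackingSeries:
    """Animal tracking at 50 Hz: position (cm), head direction (deg)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd: np.ndarray
    speed: Optional[np.ndarray] = None  # cm/s, derived
    ahv: Optional[np.ndarray] = None    # deg/s, clockwise-positive, derived

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0] + TRACKING_DT)

    def validate(self, arena_side: float = 90.0) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.size < 2:
            raise BadSamplingError("bad sampling: fewer than 2 tracking samples")
        dt = np.diff(t)
        if not np.allclose(dt, TRACKING_DT, atol=1e-9, rtol=0):
            raise BadSamplingError("bad sampling: tracking is not uniform 50 Hz")
        ok = ~np.isnan(self.hd)
        if np.any((self.hd[ok] < 0) | (self.hd[ok] >= 360.0)):
            raise BadAnglesError("bad angles: hd outside [0, 360)")
        for arr in (self.x, self.y):
            good = ~np.isnan(arr)
            if np.any((arr[good] < -1e-9) | (arr[good] > arena_side + 1e-9)):
                raise ValueError("position outside the arena")


@dataclasses.dataclass
class LfpSeries:
    """Local field potential at 250 Hz, arbitrary voltage units."""

    t: np.ndarray
    v: np.ndarray

    @property
    def fs(self) -> float:
        return LFP_HZ

    def validate(self, tracking: Optional[TrackingSeries] = None) -> None:
        dt = np.diff(np.asarray(self.t, dtype=float))
        if dt.size == 0 or not np.allclose(dt, 1.0 / LFP_HZ, atol=1e-9, rtol=0):
            raise BadSamplingError("bad sampling: LFP is not uniform 250 Hz")
        if tracking is not None:
            if self.t[0] > tracking.t[0] + 1e-6 or self.t[-1] < tracking.t[-1] - 1e-6:
                raise BadSamplingError("bad sampling: LFP does not cover tracking range")


@dataclasses.dataclass
class SpikeTrain:
    """Spike time stamps (s) for one isolated unit, with optional mean waveform."""

    cell_id: str
    times: np.ndarray
    tetrode_id: str = ""
    waveform: Optional[np.ndarray] = None  # (n_channels, n_samples) at 48 kHz

    @property
    def n_spikes(self) -> int:
        return int(np.asarray(self.times).size)

    def validate(self, duration: Optional[float] = None) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError(f"spike times not ascending for {self.cell_id}")
        if duration is not None and t.size and (t[0] < -1e-9 or t[-1] > duration + 1e-9):
            raise ValueError(f"spike times outside trial for {self.cell_id}")
        if self.waveform is not None:
            w = np.atleast_2d(np.asarray(self.waveform))
            if w.ndim != 2:
                raise ValueError("waveform must be (channels, samples)")


@dataclasses.dataclass
class Trial:
    tracking: TrackingSeries
    lfp: LfpSeries
    spikes: list
    condition: str = "light"  # "light" or "dark"


@dataclasses.dataclass
class SessionBundle:
    trials: list
    arena_side: float = 90.0
    metadata: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        ids0 = None
        for trial in self.trials:
            trial.tracking.validate(self.arena_side)
            trial.lfp.validate(trial.tracking)
            dur = trial.tracking.t[-1] + TRACKING_DT
            ids = sorted(s.cell_id for s in trial.spikes)
            for s in trial.spikes:
                s.validate(dur)
            if ids0 is None:
                ids0 = ids
            elif ids != ids0:
                raise ValueError("cell ids differ across trials of one session")
            if trial.condition not in ("light", "dark"):
                raise ValueError(f"unknown condition {trial.condition!r}")


def _interp_gaps(values: np.ndarray, max_gap: int, angular: bool) -> np.ndarray:
    """Fill NaN runs of length <= max_gap by linear (circular) interpolation."""
    v = np.asarray(values, dtype=float).copy()
    isnan = np.isnan(v)
    if not isnan.any() or isnan.all():
        return v
    idx = np.arange(v.size)
    # identify runs of NaNs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start > max_gap or start == 0 or stop == v.size:
            continue
        lo, hi = start - 1, stop
        if angular:
            seg = interp_angle_deg(idx[start:stop], [idx[lo], idx[hi]], [v[lo], v[hi]])
        else:
            seg = np.interp(idx[start:stop], [idx[lo], idx[hi]], [v[lo], v[hi]])
        v[start:stop] = seg
    return v


def compute_kinematics(tr: TrackingSeries) -> TrackingSeries:
    """Derive running speed and angular head velocity.

    speed[i] = distance(p[i], p[i+1]) / dt, assigned to the earlier sample
    (the last sample repeats its predecessor). AHV uses the shortest signed
    circular difference of consecutive head directions, clockwise-positive
    in the camera's convention. Isolated tracking dropouts (<= 5 samples)
    are interpolated first; longer gaps yield NaN kinematics.
    """
    if np.asarray(tr.t).size < 2:
        raise ValueError("too short: need at least 2 tracking samples")
    x = _interp_gaps(tr.x, MAX_GAP_SAMPLES, angular=False)
    y = _interp_gaps(tr.y, MAX_GAP_SAMPLES, angular=False)
    hd = wrap_deg(_interp_gaps(tr.hd, MAX_GAP_SAMPLES, angular=True))
    dt = float(np.mean(np.diff(tr.t)))
    speed = np.empty_like(x)
    speed[:-1] = np.hypot(np.diff(x), np.diff(y)) / dt
    speed[-1] = speed[-2]
    ahv = np.empty_like(x)
    ahv[:-1] = circ_diff_deg(hd[1:], hd[:-1]) / dt
    ahv[-1] = ahv[-2]
    return TrackingSeries(t=np.asarray(tr.t, float), x=x, y=y, hd=hd,
                          speed=speed, ahv=ahv)


# ----------------------------------------------------------------- disk I/O

def save_session(bundle: SessionBundle, path) -> Path:
    """Write a session bundle to a directory of delimited text tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dict(bundle.metadata)
    meta.update(
        arena_side=float(bundle.arena_side),
        n_trials=len(bundle.trials),
        conditions=[t.condition for t in bundle.trials],
    )
    with open(path / "session.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    for k, trial in enumerate(bundle.trials, start=1):
        tag = f"trial{k:02d}"
        tr = trial.tracking
        pd.DataFrame({"t": tr.t, "x": tr.x, "y": tr.y, "hd": tr.hd}).to_csv(
            path / f"{tag}_tracking.csv", index=False, float_format="%.10g")
        pd.DataFrame({"t": trial.lfp.t, "v": trial.lfp.v}).to_csv(
            path / f"{tag}_lfp.csv", index=False, float_format="%.10g")
        rows = []
        for s in sorted(trial.spikes, key=lambda s: s.cell_id):
            rows.append(pd.DataFrame({"cell_id": s.cell_id, "t": np.asarray(s.times)}))
        spikes = (pd.concat(rows, ignore_index=True) if rows
                  else pd.DataFrame({"cell_id": [], "t": []}))
        spikes.to_csv(path / f"{tag}_spikes.csv", index=False, float_format="%.10g")
    # waveforms and tetrode ids are session-level (shared across trials)
    if bundle.trials:
        for s in bundle.trials[0].spikes:
            if s.waveform is not None:
                w = np.atleast_2d(np.asarray(s.waveform))
                pd.DataFrame(w.T, columns=[f"ch{i}" for i in range(w.shape[0])]).to_csv(
                    path / f"waveform_{s.cell_id}.csv", index=False, float_format="%.10g")
    return path


def load_session(path) -> SessionBundle:
    """Load and validate a session bundle written by :func:`save_session`."""
    path = Path(path)
    meta_file = path / "session.yaml"
    if not meta_file.exists():
        raise IncompleteBundleError("incomplete bundle: session.yaml missing")
    with open(meta_file) as fh:
        meta = yaml.safe_load(fh) or {}
    n_trials = int(meta.get("n_trials", 0))
    conditions = meta.get("conditions") or ["light"] * n_trials
    arena_side = float(meta.get("arena_side", 90.0))
    trials = []
    for k in range(1, n_trials + 1):
        tag = f"trial{k:02d}"
        files = {name: path / f"{tag}_{name}.csv" for name in ("tracking", "lfp", "spikes")}
        for name, f in files.items():
            if not f.exists():
                raise IncompleteBundleError(f"incomplete bundle: {f.name} missing")
        trk = pd.read_csv(files["tracking"])
        tracking = TrackingSeries(
            t=trk["t"].to_numpy(float), x=trk["x"].to_numpy(float),
            y=trk["y"].to_numpy(float), hd=trk["hd"].to_numpy(float))
        lfp_df = pd.read_csv(files["lfp"])
        lfp = LfpSeries(t=lfp_df["t"].to_numpy(float), v=lfp_df["v"].to_numpy(float))
        spk = pd.read_csv(files["spikes"], dtype={"cell_id": str})
        spikes = []
        for cell_id, grp in spk.groupby("cell_id", sort=True):
            wf_file = path / f"waveform_{cell_id}.csv"
            waveform = None
            if wf_file.exists():
                waveform = pd.read_csv(wf_file).to_numpy(float).T
            spikes.append(SpikeTrain(cell_id=str(cell_id),
                                     times=grp["t"].to_numpy(float),
                                     waveform=waveform))
        trials.append(Trial(tracking=tracking, lfp=lfp, spikes=spikes,
                            condition=str(conditions[k - 1])))
    extra = {k: v for k, v in meta.items()
             if k not in ("arena_side", "n_trials", "conditions")}
    bundle = SessionBundle(trials=trials, arena_side=arena_side, metadata=extra)
    bundle.validate()
    return bundle


def spike_sample_indices(times, tracking: TrackingSeries) -> np.ndarray:
    """Nearest 20-ms tracking sample index for each spike time."""
    t0 = float(tracking.t[0])
    idx = np.rint((np.asarray(times, dtype=float) - t0) * TRACKING_HZ).astype(int)
    return np.clip(idx, 0, len(tracking.t) - 1)
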
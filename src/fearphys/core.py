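"""Domain types and on-disk interchange formats.

All in-memory times are seconds; milliseconds appear only at report
boundaries (event rise/decay times). Arrays are stored float64 so that
save/load round-trips are bit-exact.

HDF5 layouts
------------
Photometry: ``/raw/ch465``, ``/raw/ch405`` (float64), ``/raw/fs`` (scalar),
``/events/tone_onsets``, ``/events/tone_offsets``, ``/meta`` (string attrs).

Sweeps: ``/sweeps/<k>/t``, ``/sweeps/<k>/i`` with attrs ``fs``,
``holding_mv``, ``stim_times``.

CSV photometry: columns ``time_s, ch465, ch405`` plus a sidecar events CSV
with columns ``onset_s, offset_s``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("fearphys")

__all__ = [
    "ValidationError",
    "FormatError",
    "PhotometryRecording",
    "PeriEventTrial",
    "PeriEventSet",
    "Sweep",
    "EventList",
    "ReleaseStats",
    "GroupComparison",
    "load_photometry",
    "save_photometry",
    "load_sweepset",
    "save_sweepset",
    "write_table",
]


class ValidationError(ValueError):
    """An in-memory object or file violates a documented type invariant."""


class FormatError(ValueError):
    """A file is missing a required dataset/column or is malformed."""


def _as_f64(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


@dataclass
class PhotometryRecording:
    """Dual-channel demodulated photometry with tone event timestamps.

    ch465 is the calcium-dependent GCaMP signal, ch405 the isosbestic
    (calcium-independent) control; both are uniformly sampled at ``fs`` Hz.
    """

    ch465: np.ndarray
    ch405: np.ndarray
    fs: float
    tone_onsets: np.ndarray
    tone_offsets: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ch465 = _as_f64(self.ch465)
        self.ch405 = _as_f64(self.ch405)
        self.tone_onsets = _as_f64(self.tone_onsets)
        self.tone_offsets = _as_f64(self.tone_offsets)
        self.validate()

    def validate(self) -> None:
        if self.ch465.shape != self.ch405.shape or self.ch465.ndim != 1:
            raise ValidationError(
                "ch465 and ch405 must be 1-D arrays of equal length "
                f"(got {self.ch465.shape} vs {self.ch405.shape})"
            )
        if not (self.fs > 0):
            raise ValidationError(f"fs must be > 0 (got {self.fs})")
        if self.tone_onsets.shape != self.tone_offsets.shape:
            raise ValidationError("tone_onsets and tone_offsets must have equal length")
        if len(self.tone_onsets) and np.any(np.diff(self.tone_onsets) <= 0):
            raise ValidationError("tone_onsets must be strictly increasing")
        if np.any(self.tone_offsets <= self.tone_onsets):
            raise ValidationError("every tone offset must be after its onset")
        dur = self.duration
        for name, arr in (("tone_onsets", self.tone_onsets), ("tone_offsets", self.tone_offsets)):
            if len(arr) and (arr.min() < 0 or arr.max() > dur):
                raise ValidationError(f"{name} must lie within [0, {dur:g}] s")

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return len(self.ch465) / self.fs

    @property
    def n_tones(self) -> int:
        return len(self.tone_onsets)


@dataclass
class PeriEventTrial:
    """One tone-aligned trial through every pipeline stage.

    ``t`` is in seconds with 0 at tone onset. ``dff465``/``dff405`` are
    per-channel %dF/F after polynomial detrending; ``corrected`` is their
    difference, the normalized calcium-dependent signal in %dF/F.
    """

    t: np.ndarray
    raw465: np.ndarray
    raw405: np.ndarray
    trial_index: int  # 1-based tone number
    pred465: np.ndarray | None = None
    pred405: np.ndarray | None = None
    dff465: np.ndarray | None = None
    dff405: np.ndarray | None = None
    corrected: np.ndarray | None = None
    valid: bool = True
    fit_coeffs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = _as_f64(self.t)
        self.raw465 = _as_f64(self.raw465)
        self.raw405 = _as_f64(self.raw405)
        n = len(self.t)
        for name in ("raw465", "raw405", "pred465", "pred405", "dff465", "dff405", "corrected"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValidationError(f"{name} length {len(arr)} != time axis length {n}")


@dataclass
class PeriEventSet:
    """All trials from one session plus the downsampled sampling rate."""

    trials: list
    fs: float

    def __iter__(self):
        return iter(self.trials)

    def __len__(self):
        return len(self.trials)

    @property
    def valid_trials(self) -> list:
        return [tr for tr in self.trials if tr.valid]


@dataclass
class Sweep:
    """A voltage-clamp current sweep.

    ``i`` is membrane current in pA (inward currents negative), ``t`` in
    seconds, ``stim_times`` the electrical stimulation times in seconds
    (empty for spontaneous recordings).
    """

    t: np.ndarray
    i: np.ndarray
    fs: float
    holding_mv: float = -70.0
    stim_times: np.ndarray = field(default_factory=lambda: np.array([]))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = _as_f64(self.t)
        self.i = _as_f64(self.i)
        self.stim_times = _as_f64(self.stim_times)
        if len(self.t) != len(self.i):
            raise ValidationError(f"len(t)={len(self.t)} != len(i)={len(self.i)}")
        if not (self.fs > 0):
            raise ValidationError(f"fs must be > 0 (got {self.fs})")
        if len(self.stim_times) and (
            self.stim_times.min() < self.t[0] or self.stim_times.max() > self.t[-1]
        ):
            raise ValidationError("stim_times must lie within the sweep time axis")

    @property
    def duration(self) -> float:
        return len(self.i) / self.fs


@dataclass
class EventList:
    """Detected (or ground-truth) spontaneous synaptic events.

    Amplitudes are positive magnitudes in pA; rise times are 10-90% times
    in ms; decay times are peak-to-1/e times in ms.
    """

    event_times: np.ndarray
    amplitudes: np.ndarray
    rise_times: np.ndarray
    decay_times: np.ndarray
    source_duration: float

    def __post_init__(self):
        self.event_times = _as_f64(self.event_times)
        self.amplitudes = _as_f64(self.amplitudes)
        self.rise_times = _as_f64(self.rise_times)
        self.decay_times = _as_f64(self.decay_times)
        n = len(self.event_times)
        for name in ("amplitudes", "rise_times", "decay_times"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} must match event_times in length")
        if n and np.any(np.diff(self.event_times) <= 0):
            raise ValidationError("event_times must be strictly increasing")
        if n and np.any(self.amplitudes <= 0):
            raise ValidationError("amplitudes must be positive magnitudes")
        if not (self.source_duration > 0):
            raise ValidationError("source_duration must be > 0")

    def __len__(self):
        return len(self.event_times)

    @property
    def frequency(self) -> float:
        """Event frequency in Hz."""
        return len(self.event_times) / self.source_duration


@dataclass
class ReleaseStats:
    """Per-cell evoked release statistics.

    ppr = eEPSC2/eEPSC1; inv_cv2 = mean^2/variance of eEPSC1 amplitudes
    (dimensionless); vmr = variance/mean (pA); ampa_nmda = AMPA peak at
    -70 mV over NMDA component at +40 mV, 50 ms after onset.
    """

    ppr: float = np.nan
    inv_cv2: float = np.nan
    vmr: float = np.nan
    ampa_nmda: float = np.nan
    n_sweeps: int = 0

    def __post_init__(self):
        for name in ("ppr", "inv_cv2", "vmr", "ampa_nmda"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValidationError(f"{name} must be >= 0 when defined (got {v})")
        if np.isfinite(self.inv_cv2) or np.isfinite(self.vmr):
            if self.n_sweeps < 2:
                raise ValidationError("inv_cv2/vmr require n_sweeps >= 2")


@dataclass
class GroupComparison:
    """Outcome of an assumption-gated group comparison."""

    test_name: str
    statistic: float
    df: object
    p_value: float
    transform: str = "none"
    normality_p: object = None
    levene_p: float | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p_value must be in [0, 1] (got {self.p_value})")
        if self.transform not in ("none", "log"):
            raise ValidationError(f"transform must be 'none' or 'log' (got {self.transform!r})")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_photometry(rec: PhotometryRecording, path, format: str = "hdf5"):
    """Write a recording to disk; lossless for float64 payloads."""
    rec.validate()
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            raw = f.create_group("raw")
            raw.create_dataset("ch465", data=rec.ch465, dtype="f8")
            raw.create_dataset("ch405", data=rec.ch405, dtype="f8")
            raw.create_dataset("fs", data=float(rec.fs))
            ev = f.create_group("events")
            ev.create_dataset("tone_onsets", data=rec.tone_onsets, dtype="f8")
            ev.create_dataset("tone_offsets", data=rec.tone_offsets, dtype="f8")
            meta = f.create_group("meta")
            for k, v in rec.meta.items():
                meta.attrs[k] = str(v)
    elif format == "csv":
        t = np.arange(len(rec.ch465)) / rec.fs
        pd.DataFrame({"time_s": t, "ch465": rec.ch465, "ch405": rec.ch405}).to_csv(
            path, index=False, float_format="%.17g"
        )
        sidecar = path.with_name(path.stem + "_events.csv")
        pd.DataFrame({"onset_s": rec.tone_onsets, "offset_s": rec.tone_offsets}).to_csv(
            sidecar, index=False, float_format="%.17g"
        )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'hdf5' or 'csv')")
    return path


def load_photometry(path, format: str | None = None) -> PhotometryRecording:
    """Read a recording written by :func:`save_photometry`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "hdf5"
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            for ds in ("raw/ch465", "raw/ch405", "raw/fs", "events/tone_onsets", "events/tone_offsets"):
                if ds not in f:
                    raise FormatError(f"missing dataset '/{ds}' in {path}")
            meta = {}
            if "meta" in f:
                meta = {k: v for k, v in f["meta"].attrs.items()}
            return PhotometryRecording(
                ch465=f["raw/ch465"][:],
                ch405=f["raw/ch405"][:],
                fs=float(f["raw/fs"][()]),
                tone_onsets=f["events/tone_onsets"][:],
                tone_offsets=f["events/tone_offsets"][:],
                meta=meta,
            )
    elif format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("time_s", "ch465", "ch405"):
            if col not in df.columns:
                raise FormatError(f"missing column '{col}' in {path}")
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise FormatError("CSV photometry needs at least 2 samples to infer fs")
        fs = 1.0 / np.median(np.diff(t))
        sidecar = path.with_name(path.stem + "_events.csv")
        if not sidecar.exists():
            raise FormatError(f"missing events sidecar {sidecar}")
        ev = pd.read_csv(sidecar, float_precision="round_trip")
        for col in ("onset_s", "offset_s"):
            if col not in ev.columns:
                raise FormatError(f"missing column '{col}' in {sidecar}")
        return PhotometryRecording(
            ch465=df["ch465"].to_numpy(),
            ch405=df["ch405"].to_numpy(),
            fs=fs,
            tone_onsets=ev["onset_s"].to_numpy(),
            tone_offsets=ev["offset_s"].to_numpy(),
        )
    raise ValueError(f"unknown format {format!r}")


def save_sweepset(sweeps: list, path):
    """Write a list of sweeps to an HDF5 file."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        grp = f.create_group("sweeps")
        for k, sw in enumerate(sweeps):
            g = grp.create_group(str(k))
            g.create_dataset("t", data=sw.t, dtype="f8")
            g.create_dataset("i", data=sw.i, dtype="f8")
            g.attrs["fs"] = float(sw.fs)
            g.attrs["holding_mv"] = float(sw.holding_mv)
            g.attrs["stim_times"] = np.asarray(sw.stim_times, dtype=np.float64)
            for mk, mv in sw.meta.items():
                g.attrs[f"meta_{mk}"] = str(mv)
    return path


def load_sweepset(path, format: str = "hdf5") -> list:
    """Read sweeps written by :func:`save_sweepset`.

    A sweep group lacking a ``holding_mv`` attribute defaults to -70 mV
    (the recording convention for EPSCs) with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format != "hdf5":
        raise ValueError("sweep sets are stored as HDF5")
    out = []
    with h5py.File(path, "r") as f:
        if "sweeps" not in f:
            raise FormatError(f"missing group '/sweeps' in {path}")
        keys = sorted(f["sweeps"].keys(), key=lambda s: int(s))
        for k in keys:
            g = f["sweeps"][k]
            for ds in ("t", "i"):
                if ds not in g:
                    raise FormatError(f"missing dataset '/sweeps/{k}/{ds}' in {path}")
            if "fs" not in g.attrs:
                raise FormatError(f"missing attr 'fs' on '/sweeps/{k}'")
            if "holding_mv" in g.attrs:
                holding = float(g.attrs["holding_mv"])
            else:
                holding = -70.0
                logger.warning("sweep %s: holding_mv absent, defaulting to -70 mV", k)
            meta = {
                mk[len("meta_"):]: g.attrs[mk] for mk in g.attrs if mk.startswith("meta_")
            }
            out.append(
                Sweep(
                    t=g["t"][:],
                    i=g["i"][:],
                    fs=float(g.attrs["fs"]),
                    holding_mv=holding,
                    stim_times=np.asarray(g.attrs.get("stim_times", [])),
                    meta=meta,
                )
            )
    return out


def write_table(rows, path):
    """Write homogeneous records as an RFC-4180 CSV with header.

    Floats are serialized at full (round-trippable) precision. An empty
    ``rows`` with a known schema produces a header-only file.
    """
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            keys = list(rows[0].keys())
            for r in rows:
                if list(r.keys()) != keys:
                    raise ValueError("ragged records: all rows must share the same fields")
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\r\n")
    return path
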
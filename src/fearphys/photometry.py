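"""Offline dual-channel photometry analysis: raw traces to per-trial metrics.

Stage order is fixed and asserted: downsample (block means) -> zero-phase
moving-average smoothing -> peri-event windowing around tone onsets ->
per-trial, per-channel linear detrend to %dF/F -> isosbestic subtraction ->
peak / AUC metrics. The corrected signal is
``100 * (raw - pred) / pred`` per channel, 465-channel minus 405-channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PeriEventSet, PeriEventTrial, PhotometryRecording, ValidationError

logger = logging.getLogger("fearphys")

__all__ = [
    "PhotometryParams",
    "downsample",
    "smooth",
    "extract_peri_events",
    "detrend_dff",
    "subtract_isosbestic",
    "peak_response",
    "auc_epochs",
    "process_session",
]

STAGE_ORDER = (
    "downsample",
    "smooth",
    "peri_event",
    "detrend_dff",
    "subtract_isosbestic",
    "metrics",
)


@dataclass
class PhotometryParams:
    """Analysis parameters.

    Defaults follow the offline pipeline convention: 50x downsampling,
    10-sample zero-phase smoothing, a -30..+40 s peri-event window, linear
    (degree-1) detrending, peak search over the first 5 s of the tone, AUC
    over the 5 s preceding the tone and the first 5 s of the tone, and a
    session summary over the first two trials.
    """

    downsample_factor: int = 50
    smooth_window: int = 10
    window: tuple = (-30.0, 40.0)
    detrend_degree: int = 1
    peak_window: tuple = (0.0, 5.0)
    auc_epochs: list = field(default_factory=lambda: [(-5.0, 0.0), (0.0, 5.0)])
    trials_for_summary: tuple = (1, 2)

    def __post_init__(self):
        if self.downsample_factor < 1:
            raise ValidationError("downsample_factor must be >= 1")
        if self.smooth_window < 1:
            raise ValidationError("smooth_window must be >= 1")
        lo, hi = self.window
        if not (lo < 0 < hi):
            raise ValidationError("window must straddle the tone onset: start < 0 < end")
        for a, b in self.auc_epochs:
            if a < lo or b > hi or a >= b:
                raise ValidationError(f"AUC epoch ({a}, {b}) must lie within the window")


def downsample(trace, factor: int) -> np.ndarray:
    """Non-overlapping block means; trailing partial block is dropped.

    The effective sampling rate is divided by ``factor``.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor > len(trace):
        raise ValueError(f"factor {factor} exceeds trace length {len(trace)}")
    n_blocks = len(trace) // factor
    return trace[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)


def _boxcar_reflect(x: np.ndarray, window: int) -> np.ndarray:
    pad = window
    xp = np.pad(x, pad, mode="reflect")
    kern = np.ones(window) / window
    y = np.convolve(xp, kern, mode="same")
    return y[pad:-pad]


def smooth(trace, window: int = 10) -> np.ndarray:
    """Zero-phase moving average: forward-backward boxcar, reflection padding.

    The effective impulse response is triangular (boxcar composed with
    itself), with unit DC gain and no phase shift; output length equals
    input length.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(trace) <= window:
        raise ValueError("trace must be longer than the smoothing window")
    if window == 1:
        return trace.copy()
    y = _boxcar_reflect(trace, window)
    z = _boxcar_reflect(y[::-1], window)[::-1]
    return z


def extract_peri_events(rec: PhotometryRecording, window=(-30.0, 40.0)) -> PeriEventSet:
    """Window both channels around every tone onset (t = 0 at onset).

    The time axis includes both window endpoints. Trials whose window falls
    outside the recording are excluded (flagged invalid), never truncated
    or padded.
    """
    if rec.n_tones == 0:
        raise ValidationError("recording has no tone onsets")
    lo, hi = window
    fs = rec.fs
    n = len(rec.ch465)
    n_lo = int(round(lo * fs))
    n_hi = int(round(hi * fs))
    trials = []
    rel = np.arange(n_lo, n_hi + 1)
    for k, onset in enumerate(rec.tone_onsets, start=1):
        i0 = int(round(onset * fs))
        sl_lo, sl_hi = i0 + n_lo, i0 + n_hi
        if sl_lo < 0 or sl_hi >= n:
            logger.warning(
                "trial %d at onset %.3f s: window (%g, %g) s outside recording, excluded",
                k, onset, lo, hi,
            )
            trials.append(
                PeriEventTrial(
                    t=np.array([0.0]), raw465=np.array([np.nan]), raw405=np.array([np.nan]),
                    trial_index=k, valid=False,
                )
            )
            continue
        trials.append(
            PeriEventTrial(
                t=rel / fs,
                raw465=rec.ch465[sl_lo : sl_hi + 1].copy(),
                raw405=rec.ch405[sl_lo : sl_hi + 1].copy(),
                trial_index=k,
            )
        )
    return PeriEventSet(trials=trials, fs=fs)


def detrend_dff(trial: PeriEventTrial, degree: int = 1) -> PeriEventTrial:
    """Per-channel polynomial detrend over the full window, then %dF/F.

    Each channel is least-squares fitted against time over the whole
    peri-event window; the fit is the predicted signal, and
    dF/F = 100 * (raw - pred) / pred. A trial whose predicted signal is
    not strictly positive anywhere is marked invalid (division guard).
    """
    if not trial.valid:
        return trial
    t = trial.t
    if np.ptp(t) == 0:
        raise ValidationError("degenerate time axis: constant t")
    for ch in ("465", "405"):
        raw = getattr(trial, f"raw{ch}")
        coeffs = np.polyfit(t, raw, degree)
        pred = np.polyval(coeffs, t)
        if np.min(pred) <= 0:
            logger.warning("trial %d: predicted %s-channel signal <= 0, marked invalid",
                           trial.trial_index, ch)
            trial.valid = False
            return trial
        setattr(trial, f"pred{ch}", pred)
        setattr(trial, f"dff{ch}", 100.0 * (raw - pred) / pred)
        trial.fit_coeffs[ch] = coeffs
    return trial


def subtract_isosbestic(trial: PeriEventTrial) -> PeriEventTrial:
    """corrected = dff465 - dff405 (%dF/F): isosbestic artifact subtraction."""
    if not trial.valid:
        return trial
    if trial.dff465 is None or trial.dff405 is None:
        raise ValidationError("detrend_dff must run before subtract_isosbestic")
    trial.corrected = trial.dff465 - trial.dff405
    return trial


def peak_response(peset: PeriEventSet, params: PhotometryParams | None = None):
    """Per-trial peak of the corrected signal over the peak window.

    The peak window is half-open at the left, (start, end], so a peak
    "in response to tone onset" never sits on the pre-tone sample. Returns
    (per-trial dict, summary mean over ``trials_for_summary``). Peak data
    carry a log-transform recommendation for the downstream stats gate.
    """
    params = params or PhotometryParams()
    lo, hi = params.peak_window
    peaks = {}
    for tr in peset.valid_trials:
        if tr.corrected is None:
            raise ValidationError("corrected signal missing: run the pipeline first")
        mask = (tr.t > lo) & (tr.t <= hi)
        if not mask.any():
            raise ValidationError(f"empty peak window ({lo}, {hi}]")
        peaks[tr.trial_index] = float(np.max(tr.corrected[mask]))
    chosen = [peaks[i] for i in params.trials_for_summary if i in peaks]
    summary = float(np.mean(chosen)) if chosen else np.nan
    return peaks, summary


def auc_epochs(peset: PeriEventSet, params: PhotometryParams | None = None):
    """Trapezoidal AUC (%dF/F * s) of the corrected signal per trial/epoch."""
    params = params or PhotometryParams()
    out = {}
    for tr in peset.valid_trials:
        if tr.corrected is None:
            raise ValidationError("corrected signal missing: run the pipeline first")
        row = {}
        for (a, b) in params.auc_epochs:
            if a < tr.t[0] or b > tr.t[-1]:
                raise ValidationError(f"AUC epoch ({a}, {b}) outside trial window")
            mask = (tr.t >= a) & (tr.t <= b)
            row[(a, b)] = float(np.trapezoid(tr.corrected[mask], tr.t[mask]))
        out[tr.trial_index] = row
    return out


def process_session(rec: PhotometryRecording, params: PhotometryParams | None = None):
    """Run the full pipeline in its fixed stage order.

    Returns (metrics DataFrame, PeriEventSet). The DataFrame has one row
    per tone with columns trial, peak, auc epochs, valid; session summary
    values (mean peak over the summary trials) are attached in ``.attrs``.
    """
    params = params or PhotometryParams()
    stages_run = []

    ch465 = downsample(rec.ch465, params.downsample_factor)
    ch405 = downsample(rec.ch405, params.downsample_factor)
    fs_ds = rec.fs / params.downsample_factor
    stages_run.append("downsample")

    ch465 = smooth(ch465, params.smooth_window)
    ch405 = smooth(ch405, params.smooth_window)
    stages_run.append("smooth")

    ds_rec = PhotometryRecording(
        ch465=ch465, ch405=ch405, fs=fs_ds,
        tone_onsets=rec.tone_onsets, tone_offsets=rec.tone_offsets, meta=dict(rec.meta),
    )
    peset = extract_peri_events(ds_rec, params.window)
    stages_run.append("peri_event")

    for tr in peset.trials:
        detrend_dff(tr, params.detrend_degree)
    stages_run.append("detrend_dff")

    for tr in peset.trials:
        subtract_isosbestic(tr)
    stages_run.append("subtract_isosbestic")

    if not peset.valid_trials:
        raise ValidationError("no valid trials in session")

    peaks, summary = peak_response(peset, params)
    aucs = auc_epochs(peset, params)
    stages_run.append("metrics")
    assert tuple(stages_run) == STAGE_ORDER, "pipeline stage order violated"

    rows = []
    for tr in peset.trials:
        row = {"trial": tr.trial_index, "valid": tr.valid,
               "peak": peaks.get(tr.trial_index, np.nan)}
        for (a, b) in params.auc_epochs:
            row[f"auc_{a:g}_{b:g}"] = aucs.get(tr.trial_index, {}).get((a, b), np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["summary_peak"] = summary
    df.attrs["summary_trials"] = tuple(params.trials_for_summary)
    df.attrs["stage_order"] = STAGE_ORDER
    df.attrs["log_transform_recommended"] = True  # peak dF/F is right-skewed
    return df, peset
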
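"""Spontaneous-event detection and evoked release/receptor statistics.

Spontaneous EPSCs are detected as negative-going deflections crossing a
robust (MAD-based) noise threshold on a lightly smoothed trace; amplitude
is measured against a local pre-event baseline, rise time as the 10-90%
interval, decay as peak-to-1/e. Evoked statistics: paired-pulse ratio
(eEPSC2/eEPSC1), 1/CV^2 = mean^2/variance, variance-to-mean ratio, and the
AMPA/NMDA ratio (peak at -70 mV over the +40 mV current 50 ms after onset).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .core import EventList, ReleaseStats, Sweep, ValidationError

logger = logging.getLogger("fearphys")

__all__ = [
    "DetectionParams",
    "detect_sepscs",
    "measure_eepsc",
    "ppr",
    "ppr_cell",
    "inverse_cv_squared",
    "vmr",
    "ampa_nmda_ratio",
    "summarize_cell",
]

MAD_TO_SD = 1.4826  # consistent scale factor for Gaussian noise


@dataclass
class DetectionParams:
    """Event-detection and evoked-measurement parameters.

    threshold_mads: detection threshold in robust-SD units (MAD * 1.4826)
    of the smoothed trace. min_amp_pa: discard events smaller than this
    against their local baseline. min_interevent_ms: peaks closer than this
    are merged (the larger one kept). baseline_window_ms: baseline epoch
    relative to the first stimulus for evoked sweeps. evoked_search_ms:
    post-stimulus search window. detect_smooth_ms: boxcar pre-smoothing used
    for detection and measurement (0 disables). pre_peak_baseline_ms: local
    baseline epoch relative to a spontaneous event's peak.
    """

    threshold_mads: float = 3.5
    min_amp_pa: float = 5.0
    min_interevent_ms: float = 5.0
    baseline_window_ms: tuple = (-10.0, -1.0)
    evoked_search_ms: float = 20.0
    detect_smooth_ms: float = 0.5
    pre_peak_baseline_ms: tuple = (-20.0, -5.0)
    amp_avg_ms: float = 0.5  # half-width of the peak-averaging window
    rise_lookback_ms: float = 5.0  # rise-from-local-minimum acceptance window
    kinetics_method: str = "fit"  # 'fit' (biexponential) or 'crossing'
    tail_subtraction: bool = True
    tail_fit_ms: float = 20.0

    def __post_init__(self):
        if self.threshold_mads <= 0 or self.min_amp_pa <= 0 or self.min_interevent_ms <= 0:
            raise ValidationError("detection thresholds must be positive")
        a, b = self.baseline_window_ms
        if not (a < b <= 0):
            raise ValidationError("baseline window must precede the stimulus")


def _smooth_boxcar(x: np.ndarray, fs: float, width_ms: float) -> np.ndarray:
    w = int(round(width_ms / 1000.0 * fs))
    if w <= 1:
        return x
    pad = w
    xp = np.pad(x, pad, mode="reflect")
    y = np.convolve(xp, np.ones(w) / w, mode="same")
    return y[pad:-pad]


def _interp_crossing(t: np.ndarray, y: np.ndarray, i0: int, i1: int, level: float) -> float:
    """Time where y crosses `level` between samples i0 and i1 (linear)."""
    y0, y1 = y[i0], y[i1]
    if y1 == y0:
        return t[i0]
    frac = (level - y0) / (y1 - y0)
    return t[i0] + frac * (t[i1] - t[i0])


def _crossing_kinetics(t, dev, ipk, amp, fs):
    """10-90% rise and peak-to-1/e decay by interpolated level crossings."""
    n = len(dev)
    t10 = t90 = None
    j = ipk
    while j > 0 and dev[j] > 0.9 * amp:
        j -= 1
    if j + 1 < n and dev[j] <= 0.9 * amp <= dev[j + 1]:
        t90 = _interp_crossing(t, dev, j, j + 1, 0.9 * amp)
    k = j
    while k > 0 and dev[k] > 0.1 * amp:
        k -= 1
    if k + 1 < n and dev[k] <= 0.1 * amp <= dev[k + 1]:
        t10 = _interp_crossing(t, dev, k, k + 1, 0.1 * amp)
    rise = (t90 - t10) * 1000.0 if (t10 is not None and t90 is not None) else np.nan
    target = amp / np.e
    m = ipk
    limit = min(n - 1, ipk + int(round(0.2 * fs)))
    while m < limit and dev[m] > target:
        m += 1
    if m < n and dev[m] <= target and m > ipk:
        t1e = _interp_crossing(t, dev, m - 1, m, target)
        decay = (t1e - t[ipk]) * 1000.0
    else:
        decay = np.nan
    return rise, decay


def _biexp_free(tt, a, t0, tau_a, tau_b, c):
    x = np.clip(tt - t0, 0.0, None)
    return c + np.where(tt >= t0, a * (np.exp(-x / tau_b) - np.exp(-x / tau_a)), 0.0)


def _fit_kinetics(t, dev, ipk, amp, fs, next_pk=None):
    """Rise/decay from a least-squares biexponential fit to the event.

    Fitting suppresses the first-crossing noise bias of raw level
    crossings. The fit window runs from 8 ms before the peak to 35 ms
    after, truncated 2 ms before the next detected event. Returns
    (rise_ms, decay_ms), NaN on failure.
    """
    n = len(dev)
    lo = max(0, ipk - int(round(0.008 * fs)))
    hi = min(n, ipk + int(round(0.035 * fs)))
    if next_pk is not None:
        hi = min(hi, next_pk - int(round(0.002 * fs)))
    if hi - lo < int(round(0.012 * fs)):
        return np.nan, np.nan
    tt, yy = t[lo:hi], dev[lo:hi]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _biexp_free, tt, yy,
                p0=[2.0 * amp, t[ipk] - 0.003, 0.0015, 0.010, 0.0],
                bounds=(
                    [0.1 * amp, t[lo], 5e-5, 5e-4, -5 * amp],
                    [50 * amp, t[ipk], 0.05, 0.5, 5 * amp],
                ),
                maxfev=4000,
            )
    except Exception:
        return np.nan, np.nan
    tau_a, tau_b = popt[2], popt[3]
    tr, td = (tau_a, tau_b) if tau_a < tau_b else (tau_b, tau_a)
    if not (0 < tr < td):
        return np.nan, np.nan
    try:
        from .synth import analytic_decay_time, analytic_rise_time

        return analytic_rise_time(tr, td) * 1000.0, analytic_decay_time(tr, td) * 1000.0
    except Exception:
        return np.nan, np.nan


def detect_sepscs(sweep: Sweep, params: DetectionParams | None = None) -> EventList:
    """Detect spontaneous EPSCs on a voltage-clamp sweep.

    Negative-going deflections are detected on the smoothed trace as local
    maxima of (median - trace) exceeding threshold_mads robust SDs; peaks
    closer than min_interevent_ms collapse to one event. An event must rise
    at least min_amp_pa above its local minimum within the preceding
    rise_lookback_ms — this rejects noise ripples riding on the decay tail
    of an earlier event without dropping genuine overlapping events.
    Amplitude is the short-window mean around the peak referenced to the
    median over the pre-peak baseline window; when another detected peak
    contaminates that window the inter-event dip serves as the baseline.
    Rise (10-90%) and decay (peak-to-1/e) times in ms come from a
    per-event biexponential fit by default (``kinetics_method='crossing'``
    switches to interpolated level crossings); NaN when unmeasurable.
    """
    params = params or DetectionParams()
    if sweep.duration < 1.0:
        raise ValidationError("sweep must be at least 1 s for spontaneous detection")
    i = sweep.i
    if np.any(~np.isfinite(i)) or np.ptp(i) == 0:
        raise ValidationError("flat or non-finite trace")
    fs = sweep.fs
    s = _smooth_boxcar(i, fs, params.detect_smooth_ms)
    med = np.median(s)
    d = med - s  # positive-going deviation for inward (negative) currents
    mad = np.median(np.abs(d - np.median(d)))
    thr = params.threshold_mads * MAD_TO_SD * mad
    if thr <= 0:
        raise ValidationError("zero noise estimate: cannot set threshold")
    dist = max(1, int(round(params.min_interevent_ms / 1000.0 * fs)))
    pk, _ = find_peaks(d, height=thr, distance=dist)

    m_avg = max(1, int(round(params.amp_avg_ms / 1000.0 * fs)))
    b_lo = int(round(params.pre_peak_baseline_ms[0] / 1000.0 * fs))
    b_hi = int(round(params.pre_peak_baseline_ms[1] / 1000.0 * fs))
    lb = max(1, int(round(params.rise_lookback_ms / 1000.0 * fs)))
    gap = max(1, int(round(0.0002 * fs)))
    n = len(s)

    accepted = []  # (ipk, amp)
    for ipk in pk:
        look = d[max(0, ipk - lb) : max(1, ipk - gap + 1)]
        if look.size == 0:
            continue
        if d[ipk] - look.min() < params.min_amp_pa:
            continue  # no real rise: tail ripple or noise
        lo, hi = max(0, ipk + b_lo), ipk + b_hi
        if hi <= lo:
            continue
        contaminated = np.any((pk >= lo) & (pk < ipk - gap)) or (
            accepted and accepted[-1][0] >= lo
        )
        if contaminated:
            dip_lo = max(0, ipk - int(round(0.006 * fs)))
            base_dev = d[dip_lo : max(dip_lo + 1, ipk - gap)].min()
        else:
            base_dev = np.median(d[lo:hi])
        peak_dev = float(np.mean(d[max(0, ipk - m_avg) : min(n, ipk + m_avg + 1)]))
        amp = peak_dev - base_dev
        if amp < params.min_amp_pa:
            continue
        accepted.append((ipk, amp, base_dev))

    times, amps, rises, decays = [], [], [], []
    for j, (ipk, amp, base_dev) in enumerate(accepted):
        next_pk = accepted[j + 1][0] if j + 1 < len(accepted) else None
        dev = d - base_dev
        if params.kinetics_method == "fit":
            rise, decay = _fit_kinetics(sweep.t, dev, ipk, amp, fs, next_pk)
        else:
            rise, decay = _crossing_kinetics(sweep.t, dev, ipk, amp, fs)
        times.append(sweep.t[ipk])
        amps.append(amp)
        rises.append(rise)
        decays.append(decay)

    return EventList(
        event_times=np.asarray(times),
        amplitudes=np.asarray(amps),
        rise_times=np.asarray(rises),
        decay_times=np.asarray(decays),
        source_duration=sweep.duration,
    )


def _fit_tail(t: np.ndarray, dev: np.ndarray):
    """Mono-exponential fit d(t) = A exp(-(t - t0)/tau) to a decaying tail.

    Returns a callable tail(t). Falls back to the segment mean when the fit
    is degenerate (flat tail, failed convergence)."""
    t0 = t[0]
    mean_dev = float(np.mean(dev))
    if mean_dev <= 0:
        return lambda tt: np.zeros_like(np.asarray(tt, dtype=float))

    def model(tt, a, tau):
        return a * np.exp(-(tt - t0) / tau)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, t, dev,
                p0=[max(dev[0], mean_dev), 0.011],
                bounds=([0.0, 1e-3], [np.inf, 1.0]),
                maxfev=2000,
            )
        return lambda tt: model(np.asarray(tt, dtype=float), *popt)
    except Exception:
        return lambda tt: np.full_like(np.asarray(tt, dtype=float), mean_dev)


def measure_eepsc(sweep: Sweep, stim_time: float, params: DetectionParams | None = None) -> float:
    """Amplitude (pA) of the evoked EPSC following ``stim_time``.

    Baseline is the mean current over ``baseline_window_ms`` relative to the
    sweep's FIRST stimulus; the response is the largest baseline-referenced
    inward deflection within ``evoked_search_ms`` after ``stim_time``. For
    a second pulse, the decaying tail of the first response is removed by
    mono-exponential extrapolation fitted to the ``tail_fit_ms`` before the
    stimulus. A negative computed amplitude returns 0 with a warning.
    """
    params = params or DetectionParams()
    fs = sweep.fs
    first_stim = float(sweep.stim_times[0]) if len(sweep.stim_times) else stim_time
    s = _smooth_boxcar(sweep.i, fs, params.detect_smooth_ms)

    b0 = first_stim + params.baseline_window_ms[0] / 1000.0
    b1 = first_stim + params.baseline_window_ms[1] / 1000.0
    bmask = (sweep.t >= b0) & (sweep.t <= b1)
    if not bmask.any():
        raise ValidationError("baseline window outside sweep")
    base = float(np.mean(s[bmask]))
    dev = base - s

    w0, w1 = stim_time, stim_time + params.evoked_search_ms / 1000.0
    wmask = (sweep.t > w0) & (sweep.t <= w1)
    if not wmask.any():
        raise ValidationError("empty evoked search window")

    if params.tail_subtraction and stim_time > first_stim + 1e-9:
        f0 = stim_time - params.tail_fit_ms / 1000.0
        fmask = (sweep.t >= f0) & (sweep.t < stim_time)
        if fmask.sum() >= 5:
            tail = _fit_tail(sweep.t[fmask], dev[fmask])
            dev = dev - tail(sweep.t)

    idx = np.flatnonzero(wmask)
    ipk = idx[np.argmax(dev[idx])]
    m_avg = max(1, int(round(params.amp_avg_ms / 1000.0 * fs)))
    amp = float(np.mean(dev[max(0, ipk - m_avg) : ipk + m_avg + 1]))
    if amp < 0:
        logger.warning("negative evoked amplitude at stim %.4f s clipped to 0", stim_time)
        return 0.0
    return amp


def ppr(a1: float, a2: float) -> float:
    """Paired-pulse ratio eEPSC2/eEPSC1 for a single sweep."""
    if a1 <= 0:
        raise ValidationError("PPR undefined for eEPSC1 <= 0")
    return a2 / a1


def ppr_cell(a1s, a2s, method: str = "ratio-of-means") -> float:
    """Cell-level paired-pulse ratio from per-sweep amplitude pairs.

    ``ratio-of-means`` (default) computes mean(A2)/mean(A1), the estimate
    obtained from averaged traces; it is nearly unbiased for the underlying
    facilitation even at 20 sweeps. ``mean-of-ratios`` averages per-sweep
    A2/A1 (excluding sweeps with A1 <= 0, with a warning); with trial-to-
    trial variance it carries an upward Jensen bias of order CV(A1)^2.
    """
    a1s = np.asarray(a1s, dtype=np.float64)
    a2s = np.asarray(a2s, dtype=np.float64)
    if method == "ratio-of-means":
        m1 = a1s.mean()
        if m1 <= 0:
            raise ValidationError("mean eEPSC1 amplitude must be > 0")
        return float(a2s.mean() / m1)
    if method == "mean-of-ratios":
        ok = a1s > 0
        if not ok.all():
            logger.warning("excluding %d sweeps with eEPSC1 <= 0", int((~ok).sum()))
        if not ok.any():
            raise ValidationError("no sweeps with eEPSC1 > 0")
        return float(np.mean(a2s[ok] / a1s[ok]))
    raise ValueError(f"unknown method {method!r}")


def inverse_cv_squared(amps, bias_corrected: bool = False) -> float:
    """1/CV^2 = mean^2 / variance of evoked amplitudes (ddof=1).

    With ``bias_corrected`` the normal-theory unbiased estimator
    (n-3)/(n-1) * mean^2/s^2 - 1/n is returned instead of the plug-in;
    the plug-in overestimates the population value by roughly
    (n-1)/(n-3) at small n.
    """
    amps = np.asarray(amps, dtype=np.float64)
    n = len(amps)
    if n < 2:
        raise ValidationError("need at least 2 amplitudes")
    if n != 20:
        logger.warning("1/CV^2 conventionally uses 20 consecutive eEPSCs (got %d)", n)
    var = amps.var(ddof=1)
    if var == 0:
        raise ValidationError("zero variance: 1/CV^2 is infinite")
    plug_in = amps.mean() ** 2 / var
    if not bias_corrected:
        return float(plug_in)
    if n < 4:
        raise ValidationError("bias correction needs n >= 4")
    return float((n - 3) / (n - 1) * plug_in - 1.0 / n)


def vmr(amps) -> float:
    """Variance-to-mean ratio sigma^2/mu (pA) of evoked amplitudes (ddof=1)."""
    amps = np.asarray(amps, dtype=np.float64)
    n = len(amps)
    if n < 2:
        raise ValidationError("need at least 2 amplitudes")
    if n != 20:
        logger.warning("VMR conventionally uses 20 consecutive eEPSCs (got %d)", n)
    mu = amps.mean()
    if mu <= 0:
        raise ValidationError("VMR undefined for non-positive mean amplitude")
    return float(amps.var(ddof=1) / mu)


def ampa_nmda_ratio(
    sweep_neg70: Sweep,
    sweep_pos40: Sweep,
    onset: float,
    params: DetectionParams | None = None,
) -> float:
    """AMPA/NMDA ratio: |peak at -70 mV| / |+40 mV current 50 ms post-onset|.

    Both components are baseline-subtracted (pre-onset baseline windows);
    magnitudes are used since the two holding potentials flip the current
    sign. Raises when the NMDA component is within the noise floor.
    """
    params = params or DetectionParams()
    ampa = measure_eepsc(
        Sweep(
            t=sweep_neg70.t, i=sweep_neg70.i, fs=sweep_neg70.fs,
            holding_mv=sweep_neg70.holding_mv, stim_times=np.array([onset]),
        ),
        onset,
        params,
    )
    t = sweep_pos40.t
    if onset + 0.05 > t[-1]:
        raise ValidationError("onset + 50 ms outside the +40 mV sweep")
    b0 = onset + params.baseline_window_ms[0] / 1000.0
    b1 = onset + params.baseline_window_ms[1] / 1000.0
    bmask = (t >= b0) & (t <= b1)
    if not bmask.any():
        raise ValidationError("baseline window outside +40 mV sweep")
    base = float(np.mean(sweep_pos40.i[bmask]))
    noise_sd = float(np.std(sweep_pos40.i[bmask]))
    val = float(np.interp(onset + 0.05, t, sweep_pos40.i)) - base
    nmda = abs(val)
    if nmda <= max(3.0 * noise_sd, 1e-12):
        raise ValidationError("ratio undefined: NMDA component within noise floor")
    return ampa / nmda


def summarize_cell(sweeps, params: DetectionParams | None = None, group: str | None = None):
    """Aggregate one cell's sweeps into a metrics row.

    Sweeps are routed by their ``meta['role']``: 'spontaneous',
    'evoked_paired', 'ampa', 'nmda'. Returns (row dict, ReleaseStats).
    Missing roles leave the corresponding fields NaN (logged).
    """
    params = params or DetectionParams()
    spont = [s for s in sweeps if s.meta.get("role") == "spontaneous"]
    evoked = [s for s in sweeps if s.meta.get("role") == "evoked_paired"]
    ampa_sw = [s for s in sweeps if s.meta.get("role") == "ampa"]
    nmda_sw = [s for s in sweeps if s.meta.get("role") == "nmda"]

    row = {"group": group}
    freq = amp = rise = decay = np.nan
    if spont:
        evs = [detect_sepscs(s, params) for s in spont]
        total = sum(len(e) for e in evs)
        dur = sum(e.source_duration for e in evs)
        freq = total / dur
        if total:
            amp = float(np.concatenate([e.amplitudes for e in evs]).mean())
            rise = float(np.nanmean(np.concatenate([e.rise_times for e in evs])))
            decay = float(np.nanmean(np.concatenate([e.decay_times for e in evs])))
        else:
            amp = rise = decay = np.nan
    else:
        logger.info("no spontaneous sweeps for this cell")
    row.update(frequency_hz=freq, amplitude_pa=amp, rise_ms=rise, decay_ms=decay)

    ppr_val = icv2 = vmr_val = np.nan
    n_ev = len(evoked)
    if evoked:
        a1s, a2s = [], []
        for sw in evoked:
            if len(sw.stim_times) < 2:
                logger.warning("evoked sweep lacks two stimulus times; skipped")
                continue
            a1s.append(measure_eepsc(sw, float(sw.stim_times[0]), params))
            a2s.append(measure_eepsc(sw, float(sw.stim_times[1]), params))
        if a1s:
            ppr_val = ppr_cell(a1s, a2s)
            if len(a1s) >= 2:
                icv2 = inverse_cv_squared(a1s)
                vmr_val = vmr(a1s)
    else:
        logger.info("no evoked sweeps for this cell")
    row.update(ppr=ppr_val, inv_cv2=icv2, vmr_pa=vmr_val, n_sweeps=n_ev)

    an = np.nan
    if ampa_sw and nmda_sw:
        onset = float(ampa_sw[0].stim_times[0]) if len(ampa_sw[0].stim_times) else 0.0
        an = ampa_nmda_ratio(ampa_sw[0], nmda_sw[0], onset, params)
    row["ampa_nmda"] = an

    stats = ReleaseStats(ppr=ppr_val, inv_cv2=icv2, vmr=vmr_val, ampa_nmda=an, n_sweeps=n_ev)
    return row, stats
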
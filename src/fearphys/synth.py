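"""Ground-truth-known simulators for photometry and slice-ephys recordings.

The photometry generator composes, per channel, an exponentially bleaching
baseline, shared fractional motion artifacts, tone-locked calcium-indicator
transients (465 nm channel only), and white noise:

    ch465(t) = (b465 + bleach465(t)) * (1 + m(t)) + a * K(t) ⊛ tones + eps(t)
    ch405(t) = (b405 + bleach405(t)) * (1 + m(t)) + eps(t)

where m(t) is the common fractional motion process and K a normalized
biexponential indicator kernel (slow GCaMP6s kinetics by default). Because
the motion term multiplies both channels identically, per-trial detrending
followed by channel subtraction cancels it — the property the downstream
pipeline is designed around.

The ephys generators produce Poisson-timed biexponential spontaneous EPSCs
in Gaussian noise, binomial quantal paired-pulse evoked responses
(A = q * Binomial(N, p)), and constructed -70/+40 mV sweep pairs for
AMPA/NMDA ratio measurements.

Every generator is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.signal import fftconvolve

from .core import EventList, PhotometryRecording, Sweep, ValidationError

__all__ = [
    "PhotometrySimConfig",
    "EphysSimConfig",
    "biexp_kernel",
    "kernel_peak_time",
    "analytic_rise_time",
    "analytic_decay_time",
    "calibrate_tau_rise",
    "calibrate_tau_decay",
    "make_tone_schedule",
    "simulate_photometry",
    "place_events",
    "simulate_sepsc_trace",
    "simulate_evoked_sweeps",
    "simulate_ampa_nmda_pair",
]


# ---------------------------------------------------------------------------
# Biexponential kernel and its analytic kinetics
# ---------------------------------------------------------------------------


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the peak of exp(-t/tau_decay) - exp(-t/tau_rise), t >= 0."""
    if not (0 < tau_rise < tau_decay):
        raise ValueError("need 0 < tau_rise < tau_decay")
    return tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def biexp_kernel(t, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak biexponential kernel, zero for t < 0."""
    t = np.asarray(t, dtype=np.float64)
    tp = kernel_peak_time(tau_rise, tau_decay)
    peak = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    k = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau_decay) - np.exp(-np.clip(t, 0, None) / tau_rise), 0.0)
    return k / peak


def _kernel_value(t, tau_rise, tau_decay):
    tp = kernel_peak_time(tau_rise, tau_decay)
    peak = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    return (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / peak


def analytic_rise_time(tau_rise: float, tau_decay: float) -> float:
    """Exact 10-90% rise time of the unit-peak biexponential kernel."""
    tp = kernel_peak_time(tau_rise, tau_decay)
    t10 = brentq(lambda t: _kernel_value(t, tau_rise, tau_decay) - 0.1, 1e-12 * tp, tp)
    t90 = brentq(lambda t: _kernel_value(t, tau_rise, tau_decay) - 0.9, t10, tp)
    return t90 - t10


def analytic_decay_time(tau_rise: float, tau_decay: float) -> float:
    """Exact peak-to-1/e decay time of the unit-peak biexponential kernel."""
    tp = kernel_peak_time(tau_rise, tau_decay)
    hi = tp + 60.0 * tau_decay
    t1e = brentq(lambda t: _kernel_value(t, tau_rise, tau_decay) - np.exp(-1.0), tp, hi)
    return t1e - tp


def calibrate_tau_rise(target_rise: float, tau_decay: float) -> float:
    """Find tau_rise so the kernel's analytic 10-90% rise equals ``target_rise``.

    Units are whatever ``target_rise`` and ``tau_decay`` share (ms or s).
    """
    lo, hi = 1e-6 * tau_decay, 0.999 * tau_decay
    return brentq(lambda tr: analytic_rise_time(tr, tau_decay) - target_rise, lo, hi)


def calibrate_tau_decay(target_decay: float, tau_rise: float) -> float:
    """Find tau_decay so the kernel's analytic peak-to-1/e time equals ``target_decay``."""
    lo, hi = 1.001 * tau_rise, 1000.0 * max(tau_rise, target_decay)
    return brentq(lambda td: analytic_decay_time(tau_rise, td) - target_decay, lo, hi)


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass
class PhotometrySimConfig:
    """Parameters of the synthetic dual-channel photometry session.

    The tone schedule defaults mirror a cued fear-expression test: six 30-s
    tones separated by a 3-min inter-trial interval. Bleaching and artifact
    magnitudes are free simulator parameters (the study reports none); the
    defaults produce slow, visible bleaching and occasional percent-scale
    shared artifacts, realistic for a tethered fiber recording.
    """

    fs: float = 1017.0
    duration: float | None = None  # derived from the schedule when None
    baseline465: float = 100.0
    baseline405: float = 80.0
    bleach_amp465: float = 30.0
    bleach_amp405: float = 20.0
    bleach_tau: float = 600.0  # s
    motion_frac_sd: float = 0.01
    motion_rate: float = 0.2  # events/s
    motion_width: float = 0.15  # s, Gaussian bump SD
    transient_amp_frac: float = 0.04  # peak dF/F of tone-locked transients
    tau_rise: float = 0.2  # s, GCaMP6s-like
    tau_decay: float = 1.0  # s
    noise_sd: float = 0.3  # a.u.
    n_tones: int = 6
    tone_dur: float = 30.0
    iti: float = 180.0
    first_onset: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.bleach_tau <= 0:
            raise ValidationError("fs and bleach_tau must be > 0")
        if not (0 < self.tau_rise < self.tau_decay):
            raise ValidationError("need 0 < tau_rise < tau_decay")
        if self.n_tones < 1:
            raise ValidationError("n_tones must be >= 1")


@dataclass
class EphysSimConfig:
    """Parameters of the synthetic voltage-clamp recordings.

    Spontaneous traces: Poisson-timed biexponential EPSCs with truncated-
    normal amplitudes in Gaussian noise. Evoked sweeps: binomial quantal
    release, A = q * Binomial(N, p), with facilitation multiplying p on the
    second pulse, 50-ms interpulse interval at 0.05 Hz sweep rate.
    """

    fs: float = 10000.0
    duration: float = 60.0  # s, spontaneous trace length
    event_rate: float = 3.74  # Hz
    amp_mean: float = 10.45  # pA
    amp_sd: float = 1.5  # pA
    # kernel taus giving an analytic 10-90% rise of 2.16 ms and a
    # peak-to-1/e decay of 10.93 ms
    tau_rise_ms: float = 2.091
    tau_decay_ms: float = 8.573
    noise_sd: float = 1.5  # pA
    n_sites: int = 20
    release_p: float = 0.4
    quantal_q: float = 8.0  # pA
    facilitation: float = 1.39
    ipi_ms: float = 50.0
    n_sweeps: int = 20
    sweep_rate: float = 0.05  # Hz, inter-sweep rate (metadata)
    ampa_peak: float = 150.0  # pA
    nmda_at_50ms: float = 50.0  # pA
    nmda_tau_ms: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.release_p < 1):
            raise ValidationError("release_p must be in (0, 1)")
        if self.n_sites < 1 or self.quantal_q <= 0:
            raise ValidationError("need n_sites >= 1 and quantal_q > 0")
        if self.ipi_ms <= 0 or self.n_sweeps < 2:
            raise ValidationError("need ipi_ms > 0 and n_sweeps >= 2")
        if not (0 < self.tau_rise_ms < self.tau_decay_ms):
            raise ValidationError("need 0 < tau_rise_ms < tau_decay_ms")


# ---------------------------------------------------------------------------
# Photometry
# ---------------------------------------------------------------------------


def make_tone_schedule(n_tones: int, tone_dur: float, iti: float, first_onset: float = 0.0):
    """Regular tone schedule: onsets spaced tone_dur + iti apart.

    Returns (onsets, offsets) in seconds.
    """
    if n_tones < 1:
        raise ValueError("n_tones must be >= 1")
    if tone_dur <= 0 or iti < 0 or first_onset < 0:
        raise ValueError("tone_dur must be > 0; iti and first_onset >= 0")
    onsets = first_onset + np.arange(n_tones) * (tone_dur + iti)
    return onsets, onsets + tone_dur


def _bump_process(n: int, fs: float, rate: float, amp_sd: float, width: float, rng) -> np.ndarray:
    """Poisson-timed Gaussian bumps: the shared fractional motion process."""
    if rate <= 0 or amp_sd <= 0:
        return np.zeros(n)
    dur = n / fs
    count = rng.poisson(rate * dur)
    impulses = np.zeros(n)
    if count:
        idx = rng.integers(0, n, size=count)
        amps = rng.normal(0.0, amp_sd, size=count)
        np.add.at(impulses, idx, amps)
    half = int(np.ceil(4 * width * fs))
    tk = np.arange(-half, half + 1) / fs
    kern = np.exp(-0.5 * (tk / width) ** 2)
    return fftconvolve(impulses, kern, mode="same")


def simulate_photometry(cfg: PhotometrySimConfig):
    """Generate a dual-channel recording and the true per-tone peak %dF/F.

    Returns (PhotometryRecording, truth) where ``truth`` is an array of the
    per-tone peak of the ideal corrected signal, in %dF/F: the maximum over
    the transient of 100 * a_k * K(tau) / trend465(onset_k + tau), with
    a_k = transient_amp_frac * trend465(onset_k).
    """
    onsets, offsets = make_tone_schedule(cfg.n_tones, cfg.tone_dur, cfg.iti, cfg.first_onset)
    duration = cfg.duration
    if duration is None:
        duration = float(offsets[-1] + cfg.iti / 2)
    if offsets[-1] > duration:
        raise ValidationError(
            f"tone schedule (last offset {offsets[-1]:g} s) exceeds duration {duration:g} s"
        )
    rng = np.random.default_rng(cfg.seed)
    n = int(round(duration * cfg.fs))
    t = np.arange(n) / cfg.fs

    trend465 = cfg.baseline465 + cfg.bleach_amp465 * np.exp(-t / cfg.bleach_tau)
    trend405 = cfg.baseline405 + cfg.bleach_amp405 * np.exp(-t / cfg.bleach_tau)
    motion = _bump_process(n, cfg.fs, cfg.motion_rate, cfg.motion_frac_sd, cfg.motion_width, rng)

    # tone-locked transients, 465 channel only
    klen = int(round(10 * cfg.tau_decay * cfg.fs))
    kern = biexp_kernel(np.arange(klen) / cfg.fs, cfg.tau_rise, cfg.tau_decay)
    transients = np.zeros(n)
    truth = np.zeros(len(onsets))
    for k, on in enumerate(onsets):
        i0 = int(round(on * cfg.fs))
        a_k = cfg.transient_amp_frac * trend465[min(i0, n - 1)]
        seg = slice(i0, min(i0 + klen, n))
        transients[seg] += a_k * kern[: seg.stop - seg.start]
        truth[k] = 100.0 * np.max(a_k * kern[: seg.stop - seg.start] / trend465[seg])

    ch465 = trend465 * (1.0 + motion) + transients
    ch405 = trend405 * (1.0 + motion)
    if cfg.noise_sd > 0:
        ch465 = ch465 + rng.normal(0.0, cfg.noise_sd, n)
        ch405 = ch405 + rng.normal(0.0, cfg.noise_sd, n)
    if ch465.min() <= 0 or ch405.min() <= 0:
        raise ValidationError(
            "composed fluorescence went non-positive; reduce motion_frac_sd / noise_sd"
        )
    rec = PhotometryRecording(
        ch465=ch465,
        ch405=ch405,
        fs=cfg.fs,
        tone_onsets=onsets,
        tone_offsets=offsets,
        meta={"generator": "simulate_photometry", "seed": cfg.seed},
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Spontaneous EPSCs
# ---------------------------------------------------------------------------


def place_events(
    event_times,
    amplitudes,
    duration: float,
    fs: float,
    tau_rise_ms: float,
    tau_decay_ms: float,
    noise_sd: float = 0.0,
    rng=None,
) -> Sweep:
    """Build a voltage-clamp trace with negative-going biexponential events
    of the given peak amplitudes (pA) at the given times (s)."""
    event_times = np.asarray(event_times, dtype=np.float64)
    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    klen = int(round(12 * tau_decay_ms / 1000.0 * fs))
    kern = biexp_kernel(np.arange(klen) / fs, tau_rise_ms / 1000.0, tau_decay_ms / 1000.0)
    kern = kern / kern.max()  # unit peak on the sample grid: trace max == amplitude
    i = np.zeros(n)
    for et, a in zip(event_times, amplitudes):
        i0 = int(round(et * fs))
        if i0 >= n:
            continue
        seg = slice(i0, min(i0 + klen, n))
        i[seg] -= a * kern[: seg.stop - seg.start]
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        i = i + rng.normal(0.0, noise_sd, n)
    return Sweep(t=t, i=i, fs=fs, holding_mv=-70.0)


def simulate_sepsc_trace(cfg: EphysSimConfig):
    """Poisson-timed spontaneous EPSCs in Gaussian noise.

    Returns (Sweep, EventList truth). Truth kinetics are the kernel's
    analytic 10-90% rise and peak-to-1/e decay (ms), shared by all events.
    """
    if cfg.event_rate * cfg.duration > 1e6:
        raise ValidationError("rate * duration > 1e6 events: refuse (desk-scale guard)")
    rng = np.random.default_rng(cfg.seed)
    n_events = rng.poisson(cfg.event_rate * cfg.duration) if cfg.event_rate > 0 else 0
    times = np.sort(rng.uniform(0.0, cfg.duration, size=n_events))
    # strictly increasing times (collisions at float64 resolution are ~impossible
    # at desk scale but the EventList invariant demands it)
    keep = np.concatenate(([True], np.diff(times) > 0)) if n_events else np.array([], bool)
    times = times[keep]
    amps = np.empty(len(times))
    for j in range(len(times)):  # truncated normal, > 0
        a = rng.normal(cfg.amp_mean, cfg.amp_sd)
        while a <= 0:
            a = rng.normal(cfg.amp_mean, cfg.amp_sd)
        amps[j] = a
    sweep = place_events(
        times, amps, cfg.duration, cfg.fs, cfg.tau_rise_ms, cfg.tau_decay_ms, cfg.noise_sd, rng
    )
    rise = analytic_rise_time(cfg.tau_rise_ms, cfg.tau_decay_ms)
    decay = analytic_decay_time(cfg.tau_rise_ms, cfg.tau_decay_ms)
    truth = EventList(
        event_times=times,
        amplitudes=amps,
        rise_times=np.full(len(times), rise),
        decay_times=np.full(len(times), decay),
        source_duration=cfg.duration,
    )
    return sweep, truth


# ---------------------------------------------------------------------------
# Evoked sweeps
# ---------------------------------------------------------------------------


def simulate_evoked_sweeps(cfg: EphysSimConfig):
    """Binomial quantal paired-pulse sweeps.

    Per sweep, A1 = q * Binomial(N, p) and A2 = q * Binomial(N, p2) with
    p2 = p * facilitation (must be <= 1); the two responses are placed at
    stimulation times 0.05 s and 0.05 s + ipi. Returns (list of Sweep,
    truth) with truth an (n_sweeps, 2) array of the drawn (A1, A2).

    Closed forms: E[A] = N p q, Var[A] = N p (1-p) q^2.
    """
    p2 = cfg.release_p * cfg.facilitation
    if p2 > 1.0:
        raise ValidationError(f"release_p * facilitation = {p2:g} > 1")
    rng = np.random.default_rng(cfg.seed)
    stim1 = 0.05
    stim2 = stim1 + cfg.ipi_ms / 1000.0
    duration = stim2 + 0.15
    a1 = cfg.quantal_q * rng.binomial(cfg.n_sites, cfg.release_p, size=cfg.n_sweeps)
    a2 = cfg.quantal_q * rng.binomial(cfg.n_sites, p2, size=cfg.n_sweeps)
    sweeps = []
    for k in range(cfg.n_sweeps):
        sw = place_events(
            [stim1, stim2],
            [a1[k], a2[k]],
            duration,
            cfg.fs,
            cfg.tau_rise_ms,
            cfg.tau_decay_ms,
            cfg.noise_sd,
            rng,
        )
        sw.stim_times = np.array([stim1, stim2])
        sw.meta = {"role": "evoked_paired", "sweep": k, "sweep_rate_hz": cfg.sweep_rate}
        sweeps.append(sw)
    truth = np.column_stack([a1, a2]).astype(np.float64)
    return sweeps, truth


def simulate_ampa_nmda_pair(cfg: EphysSimConfig, onset: float = 0.05):
    """Construct a -70 mV / +40 mV sweep pair for AMPA/NMDA measurement.

    The -70 mV sweep carries an inward fast biexponential with peak
    magnitude ``ampa_peak``. The +40 mV sweep carries an outward mixed
    current (fast AMPA-like component plus a slow NMDA-like component)
    scaled so its value exactly 50 ms after onset equals ``nmda_at_50ms``.
    Returns (sweep_neg70, sweep_pos40, truth_ratio).
    """
    if cfg.ampa_peak <= 0:
        raise ValidationError("ampa_peak must be > 0")
    if cfg.nmda_at_50ms <= 0:
        raise ValidationError("nmda_at_50ms must be > 0 (ratio undefined otherwise)")
    rng = np.random.default_rng(cfg.seed)
    duration = onset + 0.4
    n = int(round(duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    tr, td = cfg.tau_rise_ms / 1000.0, cfg.tau_decay_ms / 1000.0
    fast = biexp_kernel(t - onset, tr, td)
    fast = fast / fast.max()  # unit peak on the sample grid
    nmda_tr = 0.005
    nmda = biexp_kernel(t - onset, nmda_tr, cfg.nmda_tau_ms / 1000.0)
    nmda = nmda / nmda.max()

    i_neg = -cfg.ampa_peak * fast
    # mixed outward current at +40 mV: fast component (half the AMPA
    # conductance, linear I-V assumed) plus slow NMDA component scaled so
    # the 50-ms value hits the target exactly
    a_fast = 0.5 * cfg.ampa_peak
    f50 = float(np.interp(onset + 0.05, t, fast))
    n50 = float(np.interp(onset + 0.05, t, nmda))
    b_nmda = (cfg.nmda_at_50ms - a_fast * f50) / n50
    if b_nmda <= 0:
        raise ValidationError("nmda_at_50ms too small relative to the fast tail at 50 ms")
    i_pos = a_fast * fast + b_nmda * nmda
    if cfg.noise_sd > 0:
        i_neg = i_neg + rng.normal(0.0, cfg.noise_sd, n)
        i_pos = i_pos + rng.normal(0.0, cfg.noise_sd, n)
    sw_neg = Sweep(t=t, i=i_neg, fs=cfg.fs, holding_mv=-70.0, stim_times=np.array([onset]),
                   meta={"role": "ampa"})
    sw_pos = Sweep(t=t, i=i_pos, fs=cfg.fs, holding_mv=40.0, stim_times=np.array([onset]),
                   meta={"role": "nmda"})
    return sw_neg, sw_pos, cfg.ampa_peak / cfg.nmda_at_50ms
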
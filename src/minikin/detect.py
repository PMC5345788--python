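"""Detection of miniature IPSCs in voltage-clamp sweeps.

Candidate events are baseline-subtracted threshold crossings; each candidate
is measured (peak amplitude, 10-90% rise time, above-baseline duration,
charge transfer, T70) and then accepted or rejected against the three
printed inclusion criteria: peak amplitude at least -5 pA, duration
longer than 2 ms, and 10-90% rise time no longer than 1 ms.  Recording-level
quality control invalidates sweeps whose series resistance drifted by more
than 20% or exceeded 15 MOhm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

__all__ = [
    "SweepTrace",
    "RecordingQC",
    "DetectedEvent",
    "qc_recording",
    "estimate_baseline",
    "robust_noise_sd",
    "detect_events",
    "event_metrics",
    "events_to_frame",
]


@dataclass
class SweepTrace:
    """A uniformly sampled whole-cell membrane-current recording.

    Parameters
    ----------
    samples : ndarray
        Membrane current in pA (inward currents negative).
    sampling_rate : float
        Sampling rate in Hz.
    holding_potential : float
        Command potential in mV.
    temperature : float
        Bath temperature in degrees C.
    rs_start, rs_end : float
        Series-resistance readings (MOhm) at the start and end of the
        recording, used for quality control.
    """

    samples: np.ndarray
    sampling_rate: float
    holding_potential: float = -60.0
    temperature: float = 35.0
    rs_start: float = 6.0
    rs_end: float = 6.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Sweep duration in seconds."""
        return len(self.samples) / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class RecordingQC:
    rs_start: float
    rs_end: float
    valid: bool

    @property
    def rs_change(self) -> float:
        """Fractional series-resistance change relative to the start value."""
        return abs(self.rs_end - self.rs_start) / self.rs_start


def qc_recording(rs_start: float, rs_end: float) -> RecordingQC:
    """Apply the series-resistance validity rule.

    A recording is invalid if Rs changed by *more than* 20% of its starting
    value or if either reading *exceeded* 15 MOhm.  Both comparisons are
    strict, so a recording at exactly 20% change or exactly 15 MOhm is valid.
    """
    if rs_start <= 0 or rs_end <= 0:
        raise ValueError("series-resistance readings must be positive")
    change = abs(rs_end - rs_start) / rs_start
    invalid = change > 0.20 or max(rs_start, rs_end) > 15.0
    return RecordingQC(rs_start=rs_start, rs_end=rs_end, valid=not invalid)


@dataclass
class DetectedEvent:
    """One candidate mIPSC with its per-event metrics.

    ``accepted`` is True only when all three inclusion criteria hold
    (amplitude <= threshold, duration > minimum, rise <= maximum).
    ``overlapped`` marks accepted events whose measurement window collides
    with a neighbouring candidate; they count toward the per-cell event
    tally but are excluded from mean-event construction.
    """

    onset_index: int
    peak_index: int
    peak_amplitude: float  # pA, baseline-subtracted, negative
    rise_10_90: float  # ms
    duration: float  # ms
    charge: float  # pA*ms
    t70: float  # ms; NaN when the decay is truncated before 70%
    rise_mid_index: float  # fractional sample index of the 50% rise point
    accepted: bool
    reject_reason: Optional[str] = None
    overlapped: bool = False
    template_corr: float = np.nan


def robust_noise_sd(residual: np.ndarray) -> float:
    """Noise SD from the median absolute deviation (robust to events)."""
    med = np.median(residual)
    return float(np.median(np.abs(residual - med)) / 0.6744897501960817)


def estimate_baseline(
    trace: SweepTrace,
    window_s: float = 0.5,
    n_iter: int = 3,
    tail_dilate_s: float = 0.25,
    block_s: float = 0.0025,
) -> np.ndarray:
    """Slowly varying baseline via an event-masked rolling mean of block means.

    The trace is reduced to ~2.5 ms block means.  Because synaptic events
    are one-signed and their slow tails can occupy a large fraction of the
    sweep, blocks deviating below the running baseline by more than 5 block
    noise SD (MAD-based, with a small absolute floor) are masked and the
    mask is dilated forward by ``tail_dilate_s`` to cover decay tails; the
    baseline is the centred rolling mean of the unmasked blocks
    (interpolated across masked gaps), iterated ``n_iter`` times from a
    rolling-median bootstrap.  On an event-free trace no block triggers the
    mask, leaving a plain rolling mean, so the residual is unbiased.
    """
    x = trace.samples
    fs = trace.sampling_rate
    if len(x) < fs:  # pragma: no cover - guarded by callers
        warnings.warn("trace shorter than 1 s; baseline may be unreliable")
    stride = max(1, int(round(fs * block_s)))
    nb = len(x) // stride
    xb = x[: nb * stride].reshape(nb, stride).mean(axis=1)
    centers = (np.arange(nb) + 0.5) * stride
    win = max(3, int(round(window_s * fs / stride)))
    dilate = max(1, int(round(tail_dilate_s * fs / stride)))

    base = pd.Series(xb).rolling(win, center=True, min_periods=1).median().to_numpy()
    for _ in range(n_iter):
        resid = xb - base
        nsd = robust_noise_sd(resid)
        mask = resid < -max(5.0 * nsd, 0.05)
        # extend the mask forward over decay tails (and 1 block back over rises)
        m = np.convolve(mask.astype(float), np.ones(dilate), mode="full")[: len(mask)] > 0
        mask = m | np.roll(m, -1)
        clean = pd.Series(np.where(mask, np.nan, xb))
        mean = clean.rolling(win, center=True, min_periods=max(3, win // 10)).mean().to_numpy()
        good = np.isfinite(mean)
        if not np.any(good):
            break
        base = np.interp(np.arange(nb, dtype=float), np.nonzero(good)[0].astype(float), mean[good])
    return np.interp(np.arange(len(x), dtype=float), centers, base)


def _first_crossing(y: np.ndarray, level: float, direction: str) -> float:
    """Fractional index of the first crossing of `level`.

    direction 'down': first i where y[i] <= level (y starts above level);
    direction 'up': first i where y[i] >= level (y starts below level).
    Returns NaN when the level is never crossed.
    """
    if direction == "down":
        hits = np.nonzero(y <= level)[0]
    else:
        hits = np.nonzero(y >= level)[0]
    if len(hits) == 0:
        return np.nan
    i = hits[0]
    if i == 0:
        return 0.0
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(i)
    return (i - 1) + (level - y0) / (y1 - y0)


def event_metrics(
    r: np.ndarray,
    onset: int,
    peak: int,
    sampling_rate: float,
    noise_sd: float,
    window_end: int,
):
    """Measure one event on the baseline-subtracted trace ``r``.

    Returns (peak_amplitude, rise_10_90 ms, duration ms, charge pA*ms,
    t70 ms, rise_mid_index).  The 10%, 50% and 90% rise points and the T70
    decay point are located by linear interpolation between samples; charge
    is the trapezoidal area of the excursion over the measurement window.
    A local offset (median of the 2 ms preceding the onset) absorbs slow
    tails of preceding events.
    """
    fs = sampling_rate
    ms = 1e3 / fs  # ms per sample
    pre = int(round(0.002 * fs))
    lo = max(0, onset - pre)
    local = float(np.median(r[lo:onset])) if onset > lo else 0.0

    amp = r[peak] - local
    seg = r[onset : peak + 1] - local
    # rise crossings, measured on the onset->peak segment (negative-going)
    i10 = _first_crossing(seg, 0.1 * amp, "down")
    i90 = _first_crossing(seg, 0.9 * amp, "down")
    i50 = _first_crossing(seg, 0.5 * amp, "down")
    rise = (i90 - i10) * ms if np.isfinite(i10) and np.isfinite(i90) else np.nan
    rise_mid = onset + i50 if np.isfinite(i50) else float(peak)

    post = r[peak:window_end] - local
    # duration: onset until return to within one noise SD of baseline
    ret_level = -max(noise_sd, 1e-9)
    iret = _first_crossing(post, ret_level, "up")
    if np.isfinite(iret):
        duration = (peak - onset + iret) * ms
    else:
        duration = (window_end - onset) * ms
    # T70: decay by 70% of the peak excursion (to 30% remaining)
    i70 = _first_crossing(post, 0.3 * amp, "up")
    t70 = i70 * ms if np.isfinite(i70) else np.nan

    charge = float(np.trapezoid(r[onset:window_end] - local)) * ms
    return float(amp), float(rise), float(duration), charge, float(t70), float(rise_mid)


def _mono_template(tau_ms: float, tau_rise_ms: float, dt_ms: float, n: int) -> np.ndarray:
    """Canonical synaptic waveform (unit amplitude) used for artifact rejection."""
    t = np.arange(n) * dt_ms
    tp = 5.0 * tau_rise_ms
    y = np.where(
        t < tp,
        (1.0 - np.exp(-t / tau_rise_ms)) / (1.0 - np.exp(-5.0)),
        np.exp(-(t - tp) / tau_ms),
    )
    return -y


def detect_events(
    trace: SweepTrace,
    threshold: float = -5.0,
    min_duration: float = 2.0,
    max_rise: float = 1.0,
    baseline: Optional[np.ndarray] = None,
    post_window_ms: float = 150.0,
    pre_exclusion_ms: float = 250.0,
    template_corr_min: float = 0.5,
    template_tau_rise_ms: float = 0.3,
) -> list[DetectedEvent]:
    """Detect candidate mIPSCs and apply the acceptance criteria.

    Candidates are negative excursions of the baseline-subtracted trace that
    cross ``threshold``; peaks closer than 1 ms are merged.  Onsets are found
    by walking back from each peak along a lightly smoothed trace until the
    excursion returns to baseline.  Events are accepted when the peak
    amplitude is at most ``threshold`` pA, the above-baseline duration
    exceeds ``min_duration`` ms, the 10-90% rise time is at most
    ``max_rise`` ms, and the waveform correlates with a canonical synaptic
    template (artifact guard).  Accepted events with a neighbouring
    candidate onset within ``pre_exclusion_ms`` before (generous, so that
    slow decay tails of predecessors cannot contaminate the averaging
    window) or ``post_window_ms`` after are flagged ``overlapped``.
    """
    fs = trace.sampling_rate
    n = len(trace.samples)
    win = int(round(post_window_ms * fs / 1e3))
    if n < win:
        warnings.warn("trace shorter than one event window; no events returned")
        return []
    if baseline is None:
        baseline = estimate_baseline(trace)
    r = trace.samples - baseline
    nsd = robust_noise_sd(r)

    # light smoothing for onset localisation only
    k = max(1, int(round(0.0003 * fs)))
    rs = np.convolve(r, np.ones(k) / k, mode="same") if k > 1 else r

    # prominence on the threshold scale suppresses noise ripples riding on
    # the slow tails of earlier events (which sit below threshold for tens
    # of ms); it scales with the threshold, preserving candidate-count
    # monotonicity in |threshold|
    height = abs(threshold)
    peaks, _ = signal.find_peaks(
        -r, height=height, prominence=height, distance=max(1, int(round(0.001 * fs)))
    )
    events: list[DetectedEvent] = []
    onsets: list[int] = []
    for p in peaks:
        amp0 = r[p]
        thr_onset = -max(2.0 * nsd, 0.02 * abs(amp0))
        i = p
        lookback = max(0, p - int(round(0.005 * fs)))
        while i > lookback and rs[i] < thr_onset:
            i -= 1
        onsets.append(i)

    for p, onset in zip(peaks, onsets):
        window_end = min(n, onset + win)
        amp, rise, duration, charge, t70, rise_mid = event_metrics(
            r, onset, int(p), fs, nsd, window_end
        )
        reason = None
        if amp > threshold:  # amplitudes are negative; > means too small
            reason = "amplitude"
        elif duration <= min_duration:
            reason = "duration"
        elif not np.isfinite(rise) or rise > max_rise:
            reason = "rise_time"
        corr = np.nan
        if reason is None and template_corr_min is not None:
            tau_hat = t70 / 1.2039728043259361 if np.isfinite(t70) else duration / 3.0
            tau_hat = max(tau_hat, 0.5)
            m = min(window_end - onset, int(round((5 * template_tau_rise_ms + 3 * tau_hat) * fs / 1e3)))
            tpl = _mono_template(tau_hat, template_tau_rise_ms, 1e3 / fs, m)
            seg = r[onset : onset + m]
            if np.std(seg) > 0 and np.std(tpl) > 0:
                corr = float(np.corrcoef(seg, tpl)[0, 1])
                if corr < template_corr_min:
                    reason = "artifact"
        events.append(
            DetectedEvent(
                onset_index=int(onset),
                peak_index=int(p),
                peak_amplitude=amp,
                rise_10_90=rise,
                duration=duration,
                charge=charge,
                t70=t70,
                rise_mid_index=rise_mid,
                accepted=reason is None,
                reject_reason=reason,
                template_corr=corr,
            )
        )

    # overlap flagging: only candidates passing the amplitude criterion can
    # contaminate a neighbour's measurement window (noise-scale candidates
    # are excluded so they do not overlap-flag genuine events)
    pre_n = pre_exclusion_ms * fs / 1e3
    post_n = post_window_ms * fs / 1e3
    substantial = [e.onset_index for e in events if e.peak_amplitude <= threshold]
    for ev in events:
        for o in substantial:
            d = o - ev.onset_index
            if (-pre_n <= d < 0) or (0 < d <= post_n):
                ev.overlapped = True
                break
    n_acc = sum(e.accepted for e in events)
    log.info(
        "detected %d candidates, %d accepted (%d overlap-flagged)",
        len(events),
        n_acc,
        sum(e.accepted and e.overlapped for e in events),
    )
    return events


def events_to_frame(events: Sequence[DetectedEvent], sampling_rate: float) -> pd.DataFrame:
    """Tabulate detected events, one row per candidate."""
    return pd.DataFrame(
        {
            "onset_index": [e.onset_index for e in events],
            "onset_ms": [e.onset_index * 1e3 / sampling_rate for e in events],
            "peak_index": [e.peak_index for e in events],
            "amp_pa": [e.peak_amplitude for e in events],
            "rise_ms": [e.rise_10_90 for e in events],
            "duration_ms": [e.duration for e in events],
            "charge_pams": [e.charge for e in events],
            "t70_ms": [e.t70 for e in events],
            "accepted": [e.accepted for e in events],
            "reject_reason": [e.reject_reason for e in events],
            "overlapped": [e.overlapped for e in events],
        }
    )
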
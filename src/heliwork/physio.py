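"""Event-locked physiological feature extraction.

Three features are computed per maneuver, each locked to the engine-failure
event:

* electrodermal activity (EDA): amplitude of the first skin-conductance
  response (SCR) after the event, accepted only if the rise starts within
  0.5-5 s of the event;
* heart rate (EKG): area under the curve of the percent change of the
  instantaneous heart rate relative to the 5-s pre-event baseline, over the
  40 s following the event;
* respiration: the "promediated" respiratory frequency — the power-weighted
  mean (spectral centroid) of a Morlet-wavelet scalogram restricted to the
  0.05-0.50 Hz respiratory band, with per-instant normalization by the total
  in-band power.

All physiological channels are sampled at 500 Hz and synchronized to the
aircraft instrumentation via trigger pulses (see :mod:`heliwork.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pywt
from scipy import signal as sps

__all__ = [
    "PhysioTrace",
    "EventSegment",
    "SCRFeature",
    "HRFeature",
    "RespSpectralFeature",
    "segment_and_normalize",
    "scr_first_peak",
    "bandpass_zero_phase",
    "detect_r_peaks",
    "heart_rate_auc",
    "promediated_frequency",
]

SCR_VALID_WINDOW = (0.5, 5.0)  # s after event; boundary onsets count as valid
RESP_BAND = (0.05, 0.50)       # Hz


@dataclass
class PhysioTrace:
    """One physiological channel at a uniform rate (nominally 500 Hz)."""

    time: np.ndarray
    signal: np.ndarray
    channel_kind: str  # eda | ekg | respiration
    trigger: np.ndarray | None = None
    sample_rate: float = 500.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(f"{self.channel_kind} trace contains non-finite values")


@dataclass
class EventSegment:
    """Event-locked, baseline-normalized segment (percent change)."""

    time: np.ndarray          # s relative to the event
    percent_change: np.ndarray
    baseline_mean: float
    mask: np.ndarray          # True where the requested span was covered
    truncated: bool = False


@dataclass
class SCRFeature:
    maneuver_id: str
    onset_latency: float | None
    amplitude: float | None
    valid: bool


@dataclass
class HRFeature:
    maneuver_id: str
    time: np.ndarray | None
    percent_change: np.ndarray | None
    auc: float | None
    usable: bool = True


@dataclass
class RespSpectralFeature:
    maneuver_id: str
    time: np.ndarray                  # s relative to event, within +/-50 s
    freqs: np.ndarray                 # Hz, in-band grid
    scalogram: np.ndarray             # power, shape (freqs, time)
    f_promediated: np.ndarray         # Hz, per-instant centroid
    band: tuple[float, float] = RESP_BAND


# ---------------------------------------------------------------------------

def segment_and_normalize(
    trace: PhysioTrace,
    event: float,
    span: tuple[float, float] = (-60.0, 60.0),
    baseline: float = 5.0,
) -> EventSegment:
    """Cut a window around the event and express it as percent change.

    The segment is normalized by the mean of the ``baseline`` seconds
    immediately preceding the event: ``100 * (x / baseline_mean - 1)``.
    A span truncated by the recording edge yields a warning and a mask.
    """
    t = trace.time - event
    want = (t >= span[0]) & (t <= span[1])
    if not want.any():
        raise ValueError("event span lies entirely outside the recording")
    base = (t >= -baseline) & (t < 0)
    if base.sum() < 2:
        raise ValueError("baseline window not covered by the recording")
    mu = float(trace.signal[base].mean())
    if abs(mu) < 1e-12:
        raise ZeroDivisionError("baseline mean is zero; percent change undefined")
    seg_t = t[want]
    truncated = bool(seg_t[0] > span[0] + 1.5 / trace.sample_rate
                     or seg_t[-1] < span[1] - 1.5 / trace.sample_rate)
    if truncated:
        warnings.warn(
            f"segment truncated to [{seg_t[0]:.2f}, {seg_t[-1]:.2f}] s", stacklevel=2
        )
    pct = 100.0 * (trace.signal[want] / mu - 1.0)
    return EventSegment(
        time=seg_t,
        percent_change=pct,
        baseline_mean=mu,
        mask=np.ones_like(seg_t, dtype=bool),
        truncated=truncated,
    )


def scr_first_peak(
    segment: EventSegment,
    sample_rate: float = 500.0,
    maneuver_id: str = "",
    rise_threshold: float = 0.5,
    smooth: float = 0.2,
    search_limit: float = 10.0,
    boundary_tolerance: float = 0.05,
) -> SCRFeature:
    """First post-event skin-conductance response of a normalized EDA segment.

    Onset is the first post-event instant at which the derivative of the
    ``smooth``-seconds-averaged signal exceeds ``rise_threshold`` (percent of
    baseline per second), backtracked to the foot of the rise; the peak ends
    the rise, and the amplitude is peak minus onset value.  The response is
    valid only when the onset falls inside the 0.5-5 s window; boundaries
    count as valid, with ``boundary_tolerance`` seconds absorbing the
    detector's sub-smoothing-window lag.
    """
    n_smooth = max(1, int(round(smooth * sample_rate)))
    # causal (trailing) smoothing: information from after t never leaks into
    # the estimate at t, so the onset cannot be detected before it happened
    kernel = np.ones(n_smooth) / n_smooth
    x = np.convolve(segment.percent_change, kernel, mode="full")[: len(segment.time)]
    t = segment.time
    # causal slope over the smoothing timescale, not sample-to-sample (the
    # latter amplifies measurement noise by the sample rate)
    w = max(1, int(round(smooth / 2 * sample_rate)))
    dx = np.zeros_like(x)
    dx[2 * w:] = (x[2 * w:] - x[:-2 * w]) / (t[2 * w:] - t[:-2 * w])
    sustain = max(1, int(round(0.15 * sample_rate)))
    above = dx > rise_threshold
    sustained = above.copy()
    for k in range(1, sustain):
        sustained[:-k] &= above[k:]
    rising = (t > 0) & (t <= search_limit) & sustained
    idx = np.flatnonzero(rising)
    if len(idx) == 0:
        return SCRFeature(maneuver_id, None, None, False)
    idet = idx[0]
    # the threshold crossing trails the foot of the rise; backtrack to the
    # last quasi-flat sample (slow tonic drift must not block the search)
    back = np.flatnonzero(dx[: idet + 1] <= 0.2 * rise_threshold)
    i0 = int(back[-1]) if len(back) else idet
    onset = float(t[i0])
    # the peak ends the rise: first point after detection where the coarse
    # slope returns to zero (micro local maxima of the noise do not qualify)
    falling = np.flatnonzero(dx[idet:] <= 0)
    j = idet + (int(falling[0]) if len(falling) else len(x) - 1 - idet)
    amplitude = float(x[i0 : j + 1].max() - x[i0])
    valid = (SCR_VALID_WINDOW[0] - boundary_tolerance
             <= onset
             <= SCR_VALID_WINDOW[1] + boundary_tolerance)
    return SCRFeature(maneuver_id, onset, amplitude, valid)


def bandpass_zero_phase(
    x: np.ndarray,
    sample_rate: float,
    lo: float,
    hi: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase band-pass filter (recursive design applied forward-backward)."""
    nyq = sample_rate / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band [{lo}, {hi}] Hz invalid for fs={sample_rate} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def detect_r_peaks(
    ekg: PhysioTrace,
    refractory: float = 0.25,
    threshold: float | None = None,
    review: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """R-peak times of a band-passed EKG trace.

    Candidate peaks are local maxima above an adaptive amplitude threshold
    (half of the 99.5th amplitude percentile by default) separated by at
    least a 250 ms refractory period.  The optional ``review`` hook receives
    ``(times, amplitudes)`` and returns a boolean keep-mask, mirroring the
    semi-automatic workflow in which an operator accepts or rejects beats.
    """
    x = np.asarray(ekg.signal, dtype=float)
    if threshold is None:
        scale = np.percentile(np.abs(x), 99.5)
        threshold = 0.5 * scale
    if threshold <= 0 or not np.any(x > threshold):
        warnings.warn("no R-peak candidates above threshold", stacklevel=2)
        return np.empty(0)
    peaks, _ = sps.find_peaks(
        x, height=threshold, distance=max(1, int(round(refractory * ekg.sample_rate)))
    )
    times = ekg.time[peaks]
    if review is not None:
        keep = np.asarray(review(times, x[peaks]), dtype=bool)
        times = times[keep]
    if len(times) == 0:
        warnings.warn("all R-peak candidates rejected", stacklevel=2)
    return times


def heart_rate_auc(
    beats: np.ndarray,
    event: float,
    maneuver_id: str = "",
    baseline: float = 5.0,
    response: float = 40.0,
    grid_rate: float = 4.0,
) -> HRFeature:
    """Percent-change heart-rate series and its area under the curve.

    Instantaneous rate (60 / inter-beat interval, bpm) is assigned at beat
    midpoints, resampled to a uniform ``grid_rate`` grid by linear
    interpolation, normalized as percent change against the ``baseline``
    seconds before the event, and integrated (trapezoid) over
    (0, ``response``] seconds.
    """
    beats = np.sort(np.asarray(beats, dtype=float)) - event
    ibi = np.diff(beats)
    if len(ibi) < 2:
        return HRFeature(maneuver_id, None, None, None, usable=False)
    mid = (beats[:-1] + beats[1:]) / 2.0
    rate = 60.0 / ibi
    n_base = (mid >= -baseline) & (mid < 0)
    n_resp = (mid > 0) & (mid <= response)
    if n_base.sum() < 2 or n_resp.sum() < 2:
        return HRFeature(maneuver_id, None, None, None, usable=False)
    grid = np.arange(-baseline, response + 1e-9, 1.0 / grid_rate)
    rate_g = np.interp(grid, mid, rate)
    mu = rate_g[(grid >= -baseline) & (grid < 0)].mean()
    pct = 100.0 * (rate_g / mu - 1.0)
    post = grid >= 0
    auc = float(np.trapezoid(pct[post], grid[post]))
    return HRFeature(maneuver_id, grid, pct, auc, usable=True)


# ---------------------------------------------------------------------------
# respiration

def _morlet_scalogram(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    bandwidth: float = 1.0,
    center_frequency: float = 6.0,
):
    """Complex-Morlet CWT power on the requested frequency grid."""
    wavelet = f"cmor{bandwidth}-{center_frequency}"
    dt = 1.0 / fs
    scales = pywt.frequency2scale(wavelet, freqs * dt)
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=dt)
    # pywt's transform carries a sqrt(scale) amplitude factor; remove it so
    # equal-amplitude tones contribute equal spectral power at any frequency
    return np.abs(coef) ** 2 / scales[:, None]


def promediated_frequency(
    resp: PhysioTrace,
    event: float,
    maneuver_id: str = "",
    buffer_span: float = 100.0,
    report_span: float = 50.0,
    band: tuple[float, float] = RESP_BAND,
    n_freqs: int = 48,
    analysis_rate: float = 4.0,
    bandwidth: float = 1.0,
    center_frequency: float = 6.0,
) -> RespSpectralFeature:
    """Power-weighted mean respiratory frequency around the event.

    The Morlet scalogram is computed on a ±``buffer_span`` s window but the
    centroid series is reported only on ±``report_span`` s, discarding the
    outer stretch as an edge guard against the temporal smearing of the
    low-frequency wavelets.  The centroid at each instant is

        f_prom(t) = sum_i P(f_i, t) * f_i / sum_i P(f_i, t)

    over the in-band frequency grid — a convex combination of the grid
    frequencies, invariant to uniform rescaling of the power.
    """
    t_rel = resp.time - event
    want = (t_rel >= -buffer_span) & (t_rel <= buffer_span)
    if t_rel[want].size == 0 or t_rel[want][0] > -buffer_span + 1.0 or t_rel[want][-1] < buffer_span - 1.0:
        raise ValueError(
            f"±{buffer_span} s buffer around the event is not covered by the recording"
        )
    # the respiratory band lives far below the physio Nyquist: decimate to
    # the analysis rate before the transform
    step = max(1, int(round(resp.sample_rate / analysis_rate)))
    x = resp.signal[want][::step]
    t = t_rel[want][::step]
    fs = resp.sample_rate / step
    freqs = np.geomspace(band[0], band[1], n_freqs)
    power = _morlet_scalogram(x, fs, freqs, bandwidth, center_frequency)
    total = power.sum(axis=0)
    total[total <= 0] = np.finfo(float).tiny
    centroid = (power * freqs[:, None]).sum(axis=0) / total
    keep = (t >= -report_span) & (t <= report_span)
    return RespSpectralFeature(
        maneuver_id=maneuver_id,
        time=t[keep],
        freqs=freqs,
        scalogram=power[:, keep],
        f_promediated=centroid[keep],
        band=band,
    )
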
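"""Cumulative Power Frequency (CPF) of flight-control displacements.

The CPF condenses a control axis' activity inside a moving 3-s window into
a single number: the product of the window's cut-off frequency (the median-
power frequency, i.e. the smallest frequency below which at least half of
the spectral mass lies) and the window's cumulative signal power, divided
by a fixed scale constant of 10:

    omega_cum = omega_cutoff * cumulative_power / 10

``cumulative_power`` is the total power of the mean-detrended window in
squared percent of full control travel; the spectrum is Parseval-normalized
so that the spectral mass equals the window's mean-square displacement.  A
pure tone of amplitude A at frequency f therefore yields
``omega_cum = f * A**2 / 2 / 10``.

Per-axis series for the four control axes (collective, lateral and
longitudinal cyclic, pedals) are summed sample-wise into a total series
that privileges no axis; the statistic entering the campaign analysis is
the peak of the total series after the engine failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CPFWindowResult",
    "CPFSeries",
    "axis_cpf_series",
    "total_cpf",
    "cpf_peak",
]

CPF_SCALE = 10.0  # fixed divisor of the metric's definition
AXES = ("collective", "lateral", "longitudinal", "pedal")


@dataclass
class CPFWindowResult:
    window_center: float
    omega_cutoff: float       # Hz
    cumulative_power: float   # %^2
    omega_cum: float          # %^2 * Hz / 10


@dataclass
class CPFSeries:
    """Per-window CPF values on a common time grid."""

    times: np.ndarray
    omega_cum: np.ndarray
    omega_cutoff: np.ndarray | None = None
    cumulative_power: np.ndarray | None = None


def window_spectrum(segment: np.ndarray, fs: float, taper: str | None = None):
    """One-sided Parseval-normalized power spectrum of a detrended window.

    Returns (freqs, power) with ``power.sum() == mean(segment_detrended**2)``
    up to floating point (exactly Parseval for the rectangular window).
    """
    seg = np.asarray(segment, dtype=float)
    seg = seg - seg.mean()
    n = len(seg)
    if taper == "hann":
        w = np.hanning(n)
        seg = seg * w / np.sqrt(np.mean(w**2))
    spec = np.fft.rfft(seg)
    power = np.abs(spec) ** 2 / n**2
    # fold the negative-frequency half back in (DC and Nyquist are unique)
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, power


def _cutoff_frequency(freqs: np.ndarray, power: np.ndarray, fraction: float) -> float:
    """Smallest frequency below which >= ``fraction`` of spectral mass lies."""
    total = power.sum()
    if total <= 0:
        return 0.0
    cum = np.cumsum(power)
    idx = int(np.searchsorted(cum, fraction * total))
    idx = min(idx, len(freqs) - 1)
    return float(freqs[idx])


def axis_cpf_series(
    trace: np.ndarray,
    fs: float = 64.0,
    window: float = 3.0,
    step: int = 1,
    energy_fraction: float = 0.5,
    taper: str | None = None,
    t0: float = 0.0,
) -> CPFSeries:
    """CPF of one control axis over a moving window.

    Windows are centered; edges are dropped (no padding).  ``step`` is in
    samples.  A constant trace yields a zero-valued series.
    """
    x = np.asarray(trace, dtype=float)
    nwin = int(round(window * fs))
    if len(x) < nwin:
        raise ValueError(f"trace of {len(x)} samples shorter than the {nwin}-sample window")
    starts = np.arange(0, len(x) - nwin + 1, step)
    times = np.empty(len(starts))
    om_cut = np.empty(len(starts))
    cum_pow = np.empty(len(starts))
    for k, s in enumerate(starts):
        freqs, power = window_spectrum(x[s : s + nwin], fs, taper=taper)
        cp = float(power.sum())
        oc = _cutoff_frequency(freqs, power, energy_fraction)
        times[k] = t0 + (s + (nwin - 1) / 2.0) / fs
        om_cut[k] = oc
        cum_pow[k] = cp
    return CPFSeries(
        times=times,
        omega_cum=om_cut * cum_pow / CPF_SCALE,
        omega_cutoff=om_cut,
        cumulative_power=cum_pow,
    )


def total_cpf(axes: dict[str, CPFSeries]) -> CPFSeries:
    """Sample-wise sum of the four per-axis CPF series (no axis privileged)."""
    series = list(axes.values())
    base = series[0].times
    for s in series[1:]:
        if len(s.times) != len(base) or not np.allclose(s.times, base):
            raise ValueError("per-axis CPF series are not on the same window grid")
    return CPFSeries(
        times=base.copy(),
        omega_cum=np.sum([s.omega_cum for s in series], axis=0),
    )


def cpf_peak(
    total: CPFSeries,
    failure_time: float,
    pre: float = 5.0,
    post: float = 15.0,
) -> tuple[float, float]:
    """Peak of the total CPF after the engine failure.

    The analysis interval runs from ``pre`` seconds before the failure to
    ``post`` seconds after it; the 5-s pre-failure stretch provides context
    only — the peak is searched in (failure_time, failure_time + post].
    Returns ``(peak_value, peak_time)``.
    """
    t = total.times
    covered = (t.min() <= failure_time - pre + 1e-9) and (t.max() >= failure_time + post - 1e-9)
    if not covered:
        raise ValueError(
            f"CPF series [{t.min():.2f}, {t.max():.2f}] s does not cover "
            f"[{failure_time - pre:.2f}, {failure_time + post:.2f}] s"
        )
    mask = (t > failure_time) & (t <= failure_time + post)
    if not mask.any():
        raise ValueError("no CPF windows inside the post-failure search interval")
    vals = total.omega_cum[mask]
    i = int(np.argmax(vals))
    return float(vals[i]), float(t[mask][i])
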
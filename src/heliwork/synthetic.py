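"""Seeded synthetic flight-test campaign generator.

Produces a complete campaign — FTI channels at 64 Hz, physiological
channels at 500 Hz, maneuver metadata and per-maneuver ground truth — with
the statistical structure the analysis pipeline assumes: an engine-failure
Ng step to the 65% idle regime, a collective-down reaction after a sampled
delay (1.18 ± 0.31 s, truncated at 0.3 s), a flare pitch-up below 65 ft,
zone-dependent control activity, skin-conductance responses with
configurable onset and amplitude, a biphasic heart-rate rise within 40 s of
the failure, and respiration confined to the 0.05–0.50 Hz band.

The channels are statistically faithful to what the extractors assume, not
aerodynamically faithful; see the methods note for what that implies.
Every draw comes from a per-maneuver stream keyed by (seed, pilot index,
maneuver index), so regenerating any maneuver in isolation reproduces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import signal as sps

from .campaign import FTIRecord, ManeuverRecord, TestPoint, load_point_catalog
from .physio import PhysioTrace

__all__ = [
    "CampaignConfig",
    "ManeuverTruth",
    "SimulatedManeuver",
    "CampaignDataset",
    "generate_campaign",
    "iter_maneuvers",
    "generate_eda",
    "generate_ekg",
    "generate_respiration",
    "scr_kernel",
    "hr_percent_profile",
    "hr_profile_auc",
]

FTI_RATE = 64.0
PHYSIO_RATE = 500.0


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class CampaignConfig:
    """Study conditions of the simulated campaign.

    Multipliers are dimensionless scalings applied per partition label; a
    profile with all multipliers equal generates a null campaign for the
    corresponding feature.
    """

    seed: int = 0
    pilots_per_group: tuple[int, int, int] = (3, 4, 4)
    maneuvers_per_pilot: int = 12      # campaign range is 12-27 per pilot
    point_plan: tuple[str, ...] | None = None  # default: shuffled catalog cycle

    # pilot reaction on the collective after the failure
    reaction_mean: float = 1.18        # s
    reaction_sd: float = 0.31          # s
    reaction_min: float = 0.3          # s truncation

    # control activity (drives the CPF)
    base_activity_rms: float = 1.2     # % full scale, per axis
    zone_activity: dict[str, float] = field(default_factory=lambda: {
        "High-hover": 2.2, "Cruise": 1.6, "Knee": 1.0, "Take-off": 1.0, "Unzoned": 1.0,
    })
    classical_activity: dict[str, float] = field(default_factory=lambda: {
        "Inside": 1.5, "Line": 1.2, "Outside": 1.0, "Unlabeled": 1.0,
    })
    group_activity: dict[int, float] = field(default_factory=lambda: {1: 1.0, 2: 1.0, 3: 1.0})
    activity_span: float = 12.0        # s of elevated activity after the failure

    # electrodermal response
    eda_tonic: float = 5.0             # µS
    eda_amp_base: float = 0.4          # µS
    scr_onset_range: tuple[float, float] = (0.5, 5.0)
    scr_onset_sim: tuple[float, float] = (0.8, 3.5)   # onsets actually drawn
    zone_eda: dict[str, float] = field(default_factory=lambda: {
        "High-hover": 1.5, "Cruise": 1.2, "Knee": 1.0, "Take-off": 1.0, "Unzoned": 1.0,
    })
    classical_eda: dict[str, float] = field(default_factory=lambda: {
        "Inside": 1.6, "Line": 1.25, "Outside": 1.0, "Unlabeled": 1.0,
    })
    group_eda: dict[int, float] = field(default_factory=lambda: {1: 1.0, 2: 1.0, 3: 1.0})
    eda_amp_jitter: float = 0.10       # lognormal sigma on the SCR amplitude

    # biphasic heart-rate response (percent of baseline)
    hr_baseline: float = 75.0          # bpm
    hr_peak1: tuple[float, float, float] = (6.0, 3.0, 6.0)    # amp %, latency s, width s
    hr_peak2: tuple[float, float, float] = (4.0, 20.0, 24.0)
    zone_hr: dict[str, float] = field(default_factory=lambda: {
        "High-hover": 1.8, "Cruise": 1.4, "Knee": 1.0, "Take-off": 1.0, "Unzoned": 1.0,
    })
    classical_hr: dict[str, float] = field(default_factory=lambda: {
        "Inside": 1.0, "Line": 1.0, "Outside": 1.0, "Unlabeled": 1.0,
    })
    group_hr: dict[int, float] = field(default_factory=lambda: {1: 1.0, 2: 1.0, 3: 1.0})

    # respiration
    rf_band: tuple[float, float] = (0.05, 0.50)
    rf_base: float = 0.28              # Hz
    rf_post_factor: float = 0.8        # post-failure frequency drop

    # performance metadata
    success_prob: dict[int, float] = field(default_factory=lambda: {1: 0.95, 2: 0.80, 3: 0.55})
    hqr_classical_mean: dict[str, float] = field(default_factory=lambda: {
        "Outside": 4.7, "Line": 4.8, "Inside": 6.8, "Unlabeled": 4.8,
    })
    hqr_pilot_sd: float = 0.5
    hqr_noise_sd: float = 0.7

    # noise levels
    ekg_noise_sd: float = 0.02         # mV (R amplitude is 1 mV)
    eda_noise_sd: float = 0.01         # µS
    resp_noise_sd: float = 0.02        # a.u.

    # which channels to synthesize
    include_eda: bool = True
    include_ekg: bool = True
    include_resp: bool = False

    # timing layout (per-maneuver clock, seconds)
    trigger_lead: float = 10.0         # trigger pulse this long before failure
    physio_clock_offset: float = 0.0   # physio-clock minus FTI-clock

    def failure_time(self) -> float:
        """Failure instant on the per-maneuver clock (leaves physio margins)."""
        return 112.0 if self.include_resp else 75.0

    def validate(self) -> None:
        if self.maneuvers_per_pilot < 1 or not any(self.pilots_per_group):
            raise ValueError("campaign plan contains zero maneuvers")
        if not (0 < self.rf_band[0] < self.rf_band[1]):
            raise ValueError("invalid respiratory band")
        lo, hi = self.rf_band
        if not (lo <= self.rf_base <= hi and lo <= self.rf_base * self.rf_post_factor <= hi):
            raise ValueError("respiration frequencies leave the configured band")
        if self.reaction_mean <= 0 or self.reaction_sd < 0 or self.reaction_min <= 0:
            raise ValueError("reaction-delay parameters must be positive")


@dataclass
class ManeuverTruth:
    """Generator-known ground truth for one maneuver."""

    failure_time: float
    entry_time: float
    flare_time: float
    reaction_delay: float
    activity_level: float          # % rms of the boosted per-axis activity
    scr_onset: float | None = None
    scr_amplitude_uS: float | None = None
    scr_amplitude_pct: float | None = None  # relative to the tonic level
    hr_auc: float | None = None    # analytic %·s over (0, 40]
    beat_times: np.ndarray | None = None
    rf_pre: float | None = None
    rf_post: float | None = None


@dataclass
class SimulatedManeuver:
    record: ManeuverRecord
    fti: FTIRecord
    truth: ManeuverTruth
    eda: PhysioTrace | None = None
    ekg: PhysioTrace | None = None
    resp: PhysioTrace | None = None


@dataclass
class CampaignDataset:
    config: CampaignConfig
    maneuvers: list[SimulatedManeuver]

    def metadata(self):
        import pandas as pd

        rows = []
        for m in self.maneuvers:
            r = m.record
            rows.append({
                "maneuver_id": r.maneuver_id,
                "pilot_id": r.pilot_id,
                "group": r.group,
                "flight_id": r.flight_id,
                "point_code": r.point.code,
                "classical": r.point.classical,
                "zone": r.point.zone,
                "hqr": r.hqr,
                "landing_ground_speed_kt": r.landing_ground_speed,
                "landing_vertical_speed_ms": r.landing_vertical_speed,
                "reached_speed": r.reached_autorotation_speed,
                "rpm_met": r.rpm_criterion_met,
                "intervention": r.instructor_intervention,
                "expected": r.expected,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# signal primitives

def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       cutoff: float = 2.5, rms: float = 1.0) -> np.ndarray:
    """Low-pass-filtered Gaussian noise scaled to the requested rms."""
    white = rng.standard_normal(n + 256)
    sos = sps.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)[128:-128][:n]
    s = x.std()
    return x * (rms / s) if s > 0 else x


def scr_kernel(t: np.ndarray, rise: float = 0.75, decay: float = 3.0) -> np.ndarray:
    """Canonical SCR shape: difference of exponentials, unit peak, zero at t<0."""
    t = np.asarray(t, dtype=float)
    tp = decay * rise / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-tp / decay) - np.exp(-tp / rise)
    out = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / decay)
                   - np.exp(-np.clip(t, 0, None) / rise), 0.0)
    return out / peak


def _raised_cosine(t: np.ndarray, amp: float, center: float, width: float) -> np.ndarray:
    inside = np.abs(t - center) <= width / 2
    out = np.zeros_like(t)
    out[inside] = amp * 0.5 * (1 + np.cos(2 * np.pi * (t[inside] - center) / width))
    return out


def hr_percent_profile(t: np.ndarray, peak1, peak2, scale: float = 1.0) -> np.ndarray:
    """Biphasic percent-change template: two raised-cosine bumps."""
    a1, c1, w1 = peak1
    a2, c2, w2 = peak2
    return scale * (_raised_cosine(t, a1, c1, w1) + _raised_cosine(t, a2, c2, w2))


def hr_profile_auc(peak1, peak2, scale: float = 1.0, span: float = 40.0) -> float:
    """Analytic integral of the biphasic template over (0, span]."""
    total = 0.0
    for a, c, w in (peak1, peak2):
        lo, hi = max(0.0, c - w / 2), min(span, c + w / 2)
        if hi <= lo:
            continue
        # integral of a/2*(1+cos(2 pi (t-c)/w)) on [lo, hi]
        def F(x):
            return a / 2 * ((x - c) + w / (2 * np.pi) * np.sin(2 * np.pi * (x - c) / w))
        total += scale * (F(hi) - F(lo))
    return total


# ---------------------------------------------------------------------------
# physiological channel generators

def generate_eda(
    event_times: np.ndarray,
    amplitudes: np.ndarray,
    onsets: np.ndarray,
    tonic_level: float = 5.0,
    duration: float = 140.0,
    t0: float = 0.0,
    sample_rate: float = PHYSIO_RATE,
    seed: int = 0,
    noise_sd: float = 0.01,
    drift_amp: float = 0.05,
    rise: float = 0.75,
    decay: float = 3.0,
    trigger_times: np.ndarray | None = None,
) -> PhysioTrace:
    """Tonic EDA baseline with one phasic SCR per event.

    Each response is ``amplitudes[k] * scr_kernel(t - event_times[k] -
    onsets[k])`` on top of a slowly drifting tonic level plus Gaussian noise.
    """
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if (amplitudes < 0).any():
        raise ValueError("SCR amplitudes must be non-negative")
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    rng = _rng(seed)
    n = int(round(duration * sample_rate))
    t = t0 + np.arange(n) / sample_rate
    x = tonic_level + drift_amp * np.sin(2 * np.pi * 0.003 * (t - t0) + rng.uniform(0, 2 * np.pi))
    for ev, amp, on in zip(event_times, amplitudes, onsets, strict=True):
        x += amp * scr_kernel(t - ev - on, rise=rise, decay=decay)
    x += rng.normal(0, noise_sd, n)
    x = np.clip(x, 0.0, None)  # conductance cannot be negative
    return PhysioTrace(t, x, "eda", trigger=_trigger_channel(t, trigger_times),
                       sample_rate=sample_rate)


def generate_ekg(
    hr_times: np.ndarray,
    hr_values: np.ndarray,
    duration: float | None = None,
    t0: float = 0.0,
    sample_rate: float = PHYSIO_RATE,
    seed: int = 0,
    noise_sd: float = 0.02,
    r_amp: float = 1.0,
    trigger_times: np.ndarray | None = None,
) -> tuple[PhysioTrace, np.ndarray]:
    """Synthetic EKG whose instantaneous rate follows the given HR profile.

    ``hr_times``/``hr_values`` define HR(t) in bpm (linearly interpolated).
    Returns the trace and the ground-truth beat times.
    """
    hr_values = np.asarray(hr_values, dtype=float)
    if (hr_values <= 0).any():
        raise ValueError("heart rate must be positive")
    hr_times = np.asarray(hr_times, dtype=float)
    if duration is None:
        duration = hr_times[-1] - t0
    rng = _rng(seed)
    n = int(round(duration * sample_rate))
    t = t0 + np.arange(n) / sample_rate
    rate = np.interp(t, hr_times, hr_values) / 60.0  # beats per second
    phase = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2) / sample_rate])
    n_beats = int(np.floor(phase[-1]))
    beat_phase = np.arange(1, n_beats + 1, dtype=float)
    beats = np.interp(beat_phase, phase, t)
    # impulse train convolved with a QRS-like template
    x = np.zeros(n)
    idx = np.clip(np.round((beats - t0) * sample_rate).astype(int), 0, n - 1)
    x[idx] = 1.0
    tt = np.arange(-0.06, 0.06 + 0.5 / sample_rate, 1.0 / sample_rate)
    template = (r_amp * np.exp(-0.5 * (tt / 0.012) ** 2)
                - 0.25 * r_amp * np.exp(-0.5 * ((tt - 0.03) / 0.010) ** 2))
    x = np.convolve(x, template, mode="same")
    x += 0.05 * np.sin(2 * np.pi * 0.3 * (t - t0))  # baseline wander
    x += rng.normal(0, noise_sd, n)
    trace = PhysioTrace(t, x, "ekg", trigger=_trigger_channel(t, trigger_times),
                        sample_rate=sample_rate)
    return trace, beats


def generate_respiration(
    freq_times: np.ndarray,
    freq_values: np.ndarray,
    duration: float | None = None,
    t0: float = 0.0,
    amplitude: float = 1.0,
    band: tuple[float, float] = (0.05, 0.50),
    sample_rate: float = PHYSIO_RATE,
    seed: int = 0,
    noise_sd: float = 0.02,
    trigger_times: np.ndarray | None = None,
) -> PhysioTrace:
    """Near-sinusoidal respiration with a prescribed instantaneous frequency."""
    freq_values = np.asarray(freq_values, dtype=float)
    if (freq_values < band[0] - 1e-12).any() or (freq_values > band[1] + 1e-12).any():
        raise ValueError(f"requested frequencies leave the {band} Hz band")
    freq_times = np.asarray(freq_times, dtype=float)
    if duration is None:
        duration = freq_times[-1] - t0
    rng = _rng(seed)
    n = int(round(duration * sample_rate))
    t = t0 + np.arange(n) / sample_rate
    f = np.interp(t, freq_times, freq_values)
    phase = 2 * np.pi * np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2) / sample_rate])
    x = amplitude * np.sin(phase + rng.uniform(0, 2 * np.pi))
    x += rng.normal(0, noise_sd, n)
    return PhysioTrace(t, x, "respiration", trigger=_trigger_channel(t, trigger_times),
                       sample_rate=sample_rate)


def _trigger_channel(t: np.ndarray, pulse_times: np.ndarray | None,
                     width: float = 0.2) -> np.ndarray:
    trig = np.zeros_like(t)
    if pulse_times is not None:
        for p in np.atleast_1d(pulse_times):
            trig[(t >= p) & (t < p + width)] = 1.0
    return trig


# ---------------------------------------------------------------------------
# one maneuver

def _mult(cfg: CampaignConfig, table: dict, key) -> float:
    return float(table.get(key, 1.0))


def simulate_maneuver(
    cfg: CampaignConfig,
    point: TestPoint,
    pilot_id: str,
    group: int,
    flight_id: str,
    pilot_index: int,
    maneuver_index: int,
    hqr_pilot_offset: float = 0.0,
) -> SimulatedManeuver:
    rng = _rng(cfg.seed, pilot_index, maneuver_index)
    fs = FTI_RATE
    t_fail = cfg.failure_time()

    # --- timing ----------------------------------------------------------
    delay = -1.0
    while delay < cfg.reaction_min:
        delay = rng.normal(cfg.reaction_mean, cfg.reaction_sd)
    # snap the entry ramp to the FTI sample grid so truth is unambiguous
    entry = np.round((t_fail + delay) * fs) / fs
    h0 = max(point.height_ft, 12.0)
    descent = 25.0  # ft/s after entry
    flare = entry + max(0.0, (h0 - 65.0) / descent) + 0.5
    flare = np.round(flare * fs) / fs

    t_start = t_fail - 35.0
    t_end = t_fail + 45.0
    n = int(round((t_end - t_start) * fs))
    t = t_start + np.arange(n) / fs

    # --- engine and rotor -------------------------------------------------
    ng = np.where(t < t_fail, 85.0, 65.0) + rng.uniform(-0.3, 0.3, n)
    tq = np.where(t < t_fail, 50.0, 6.0) + rng.normal(0, 0.5, n)
    nr = 390.0 - 25.0 * np.exp(-np.clip(t - t_fail, 0, None) / 4.0) * (t >= t_fail) \
        + rng.normal(0, 1.0, n)

    # --- control activity -------------------------------------------------
    level = (cfg.base_activity_rms
             * _mult(cfg, cfg.zone_activity, point.zone)
             * _mult(cfg, cfg.classical_activity, point.classical)
             * _mult(cfg, cfg.group_activity, group))
    win = (t >= t_fail) & (t <= t_fail + cfg.activity_span)
    ramp = np.clip((t - t_fail) / 0.5, 0, 1) * np.clip((t_fail + cfg.activity_span - t) / 1.0, 0, 1)
    boost = 1.0 + (level / cfg.base_activity_rms - 1.0) * np.clip(ramp, 0, 1) * win

    controls: dict[str, np.ndarray] = {}
    for k, axis in enumerate(("lateral", "longitudinal", "pedal")):
        noise = _bandlimited_noise(rng, n, fs, cutoff=2.5, rms=cfg.base_activity_rms)
        controls[axis] = 50.0 + noise * boost

    # collective: quiet until the reaction, then the entry ramp + activity
    coll = np.full(n, 55.0) + _bandlimited_noise(rng, n, fs, cutoff=1.0, rms=0.08)
    ramp_rate = 25.0  # %/s downward
    ramp_t = np.clip(t - entry, 0, 1.6)
    coll = coll - ramp_rate * ramp_t
    post_entry = t >= entry + 1.6
    coll = coll + post_entry * _bandlimited_noise(rng, n, fs, cutoff=2.5,
                                                 rms=0.6 * level)
    controls["collective"] = coll

    # --- attitude and trajectory -----------------------------------------
    theta = np.full(n, 3.0)
    pre_flare = (t >= entry) & (t < flare)
    theta = theta - 1.0 * np.clip(t - entry, 0, None) * pre_flare \
        - 1.0 * (flare - entry) * (t >= flare)
    theta = theta + 6.0 * np.clip(t - flare, 0, 2.0) * (t >= flare)

    h = np.full(n, h0)
    sinking = (t >= entry) & (t < flare)
    h = h - descent * np.clip(t - entry, 0, flare - entry)
    h = np.where(t >= flare, np.clip(h0 - descent * (flare - entry) - 18.0 * (t - flare), 0, None), h)
    h = np.clip(h, 0.0, None)

    vi = point.speed_kt + _bandlimited_noise(rng, n, fs, cutoff=0.2, rms=1.0)
    trig_fti = _trigger_channel(t, np.array([t_fail - cfg.trigger_lead]))

    fti = FTIRecord(
        time=t,
        controls=controls,
        fuel_lever=np.where(t < t_fail, 80.0, 20.0) + rng.normal(0, 0.2, n),
        ng=ng, nr=nr, tq=tq,
        theta=theta,
        phi=rng.normal(0, 0.5, n),
        psi=np.full(n, 120.0) + rng.normal(0, 0.5, n),
        p=rng.normal(0, 1.0, n), q=rng.normal(0, 1.0, n), r=rng.normal(0, 1.0, n),
        height=h, airspeed=vi, trigger=trig_fti,
        sample_rate=fs,
    )

    # --- physiology -------------------------------------------------------
    off = cfg.physio_clock_offset
    trig_physio = np.array([t_fail - cfg.trigger_lead + off])
    truth = ManeuverTruth(
        failure_time=t_fail, entry_time=float(entry), flare_time=float(flare),
        reaction_delay=float(entry - t_fail), activity_level=level,
    )

    eda = ekg = resp = None
    if cfg.include_eda:
        amp = (cfg.eda_amp_base
               * _mult(cfg, cfg.zone_eda, point.zone)
               * _mult(cfg, cfg.classical_eda, point.classical)
               * _mult(cfg, cfg.group_eda, group)
               * rng.lognormal(0.0, cfg.eda_amp_jitter))
        onset = rng.uniform(*cfg.scr_onset_sim)
        truth.scr_onset = onset
        truth.scr_amplitude_uS = amp
        truth.scr_amplitude_pct = 100.0 * amp / cfg.eda_tonic
        eda = generate_eda(
            np.array([t_fail + off]), np.array([amp]), np.array([onset]),
            tonic_level=cfg.eda_tonic,
            duration=140.0, t0=t_fail + off - 70.0,
            seed=int(rng.integers(2**31)), noise_sd=cfg.eda_noise_sd,
            trigger_times=trig_physio,
        )
    if cfg.include_ekg:
        scale = (_mult(cfg, cfg.zone_hr, point.zone)
                 * _mult(cfg, cfg.classical_hr, point.classical)
                 * _mult(cfg, cfg.group_hr, group))
        ek_t0 = t_fail + off - 15.0
        ek_dur = 65.0
        tt = ek_t0 + np.arange(int(ek_dur * 50)) / 50.0
        pct = hr_percent_profile(tt - (t_fail + off), cfg.hr_peak1, cfg.hr_peak2, scale)
        hr = cfg.hr_baseline * (1 + pct / 100.0)
        ekg, beats = generate_ekg(
            tt, hr, duration=ek_dur, t0=ek_t0,
            seed=int(rng.integers(2**31)), noise_sd=cfg.ekg_noise_sd,
            trigger_times=trig_physio,
        )
        truth.hr_auc = hr_profile_auc(cfg.hr_peak1, cfg.hr_peak2, scale)
        truth.beat_times = beats
    if cfg.include_resp:
        rf_pre, rf_post = cfg.rf_base, cfg.rf_base * cfg.rf_post_factor
        r_t0 = t_fail + off - 110.0
        tt = np.array([r_t0, t_fail + off, t_fail + off + 1e-3, r_t0 + 220.0])
        ff = np.array([rf_pre, rf_pre, rf_post, rf_post])
        resp = generate_respiration(
            tt, ff, duration=220.0, t0=r_t0, band=cfg.rf_band,
            seed=int(rng.integers(2**31)), noise_sd=cfg.resp_noise_sd,
            trigger_times=trig_physio,
        )
        truth.rf_pre, truth.rf_post = rf_pre, rf_post

    # --- metadata ---------------------------------------------------------
    hqr_mean = cfg.hqr_classical_mean.get(point.classical, 5.0)
    hqr = hqr_mean + hqr_pilot_offset + rng.normal(0, cfg.hqr_noise_sd)
    hqr = float(np.clip(np.round(hqr * 2) / 2, 1.0, 10.0))
    succeed = rng.random() < cfg.success_prob.get(group, 0.7)
    if succeed:
        ground = rng.uniform(16, 28) if rng.random() < 0.7 else rng.uniform(30, 38)
        vertical = rng.uniform(0.4, 1.8)
        hqr_mte = min(hqr, 4.5)
        reached = True
        rpm = True
        intervention = False
    else:
        hqr_mte = hqr
        ground = rng.uniform(18, 38)
        vertical = rng.uniform(0.5, 1.9)
        reached = True
        rpm = True
        intervention = False
        mode = rng.integers(0, 4)
        if mode == 0:
            vertical = rng.uniform(2.2, 3.5)
        elif mode == 1:
            ground = rng.uniform(41, 55)
        elif mode == 2:
            hqr_mte = max(hqr, 5.0)
        else:
            intervention = True

    record = ManeuverRecord(
        pilot_id=pilot_id, group=group, flight_id=flight_id, point=point,
        hqr=hqr_mte,
        failure_time=t_fail, entry_time=float(entry), flare_time=float(flare),
        landing_ground_speed=float(ground),
        landing_vertical_speed=float(vertical),
        reached_autorotation_speed=bool(reached),
        rpm_criterion_met=bool(rpm),
        instructor_intervention=bool(intervention),
        expected=bool(maneuver_index != 0 or rng.random() > 0.1),
        maneuver_id=f"{pilot_id}-{maneuver_index:02d}",
    )
    return SimulatedManeuver(record=record, fti=fti, truth=truth,
                             eda=eda, ekg=ekg, resp=resp)


# ---------------------------------------------------------------------------
# campaign assembly

def _default_plan(cfg: CampaignConfig) -> list[str]:
    catalog = load_point_catalog()
    usable = [c for c, p in catalog.items() if p.classical != "Excluded"]
    return usable


def iter_maneuvers(cfg: CampaignConfig) -> Iterator[SimulatedManeuver]:
    """Stream the campaign maneuver by maneuver (memory-friendly)."""
    cfg.validate()
    catalog = load_point_catalog()
    plan = list(cfg.point_plan) if cfg.point_plan else _default_plan(cfg)
    pilot_index = 0
    for group, n_pilots in zip((1, 2, 3), cfg.pilots_per_group):
        for _ in range(n_pilots):
            pilot_index += 1
            pid = f"P{pilot_index:02d}"
            prng = _rng(cfg.seed, pilot_index)
            hqr_offset = prng.normal(0, cfg.hqr_pilot_sd)
            order = prng.permutation(len(plan))
            codes = [plan[order[i % len(plan)]] for i in range(cfg.maneuvers_per_pilot)]
            half = (cfg.maneuvers_per_pilot + 1) // 2
            for j, code in enumerate(codes):
                flight = f"{pid}-F{1 if j < half else 2}"
                yield simulate_maneuver(
                    cfg, catalog[code], pid, group, flight,
                    pilot_index=pilot_index, maneuver_index=j,
                    hqr_pilot_offset=hqr_offset,
                )


def generate_campaign(cfg: CampaignConfig) -> CampaignDataset:
    """Materialize the full campaign dataset (see :func:`iter_maneuvers`)."""
    return CampaignDataset(config=replace(cfg), maneuvers=list(iter_maneuvers(cfg)))
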
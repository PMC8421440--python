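"""Core domain model for the autorotation flight-test campaign.

Height-Speed diagram test-point catalog with its two partitions (the
classical Outside / Line / Inside split and the four maneuvering zones
Take-off / Knee / Cruise / High-hover), maneuver event detection on the
flight-test-instrumentation (FTI) channels, mission-task-element (MTE)
performance scoring, reaction times, success rates and the inter-pilot
HQR dispersion check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TestPoint",
    "FTIRecord",
    "ManeuverRecord",
    "MTEOutcome",
    "GroupSummary",
    "CatalogError",
    "EventDetectionError",
    "load_point_catalog",
    "load_hqr_table",
    "classify_point",
    "detect_engine_failure",
    "detect_autorotation_entry",
    "detect_flare",
    "reaction_time",
    "evaluate_mte",
    "success_rate",
    "hqr_dispersion",
]

REASONABLE_CLASSICAL = ("Line", "Outside")

#: idle gas-generator regime that marks the simulated engine failure (%)
IDLE_NG = 65.0


class CatalogError(KeyError):
    """Unknown test-point code."""


class EventDetectionError(RuntimeError):
    """A maneuver event could not be located in the FTI channels."""


@dataclass(frozen=True)
class TestPoint:
    """One height/speed combination of the Height-Speed diagram."""

    code: str
    height_ft: float
    speed_kt: float
    classical: str  # Outside | Line | Inside | Unlabeled | Excluded
    zone: str       # Take-off | Knee | Cruise | High-hover | Unzoned | Excluded


@dataclass
class FTIRecord:
    """Flight-test-instrumentation channels for one maneuver, 64 Hz.

    Control positions are percent of full scale; attitudes in degrees;
    height in feet; airspeed in knots indicated.
    """

    time: np.ndarray
    controls: dict[str, np.ndarray]  # keys: collective, lateral, longitudinal, pedal
    fuel_lever: np.ndarray
    ng: np.ndarray
    nr: np.ndarray
    tq: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    p: np.ndarray
    q: np.ndarray
    r: np.ndarray
    height: np.ndarray
    airspeed: np.ndarray
    trigger: np.ndarray
    sample_rate: float = 64.0

    def __post_init__(self) -> None:
        dt = np.diff(self.time)
        if len(dt) and (dt <= 0).any():
            raise ValueError("FTI time vector must be strictly increasing")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclass
class ManeuverRecord:
    """One autorotation: identity, event times, rating and landing metrics."""

    pilot_id: str
    group: int
    flight_id: str
    point: TestPoint
    hqr: float | None = None
    failure_time: float | None = None
    entry_time: float | None = None
    flare_time: float | None = None
    landing_ground_speed: float | None = None  # kt
    landing_vertical_speed: float | None = None  # m/s
    reached_autorotation_speed: bool | None = None
    rpm_criterion_met: bool | None = None
    instructor_intervention: bool = False
    expected: bool = True
    maneuver_id: str = ""

    def __post_init__(self) -> None:
        if self.hqr is not None:
            if not (1.0 <= self.hqr <= 10.0) or (2 * self.hqr) % 1:
                raise ValueError(f"HQR must lie in {{1.0, 1.5, ..., 10.0}}, got {self.hqr}")
        times = [self.failure_time, self.entry_time, self.flare_time]
        known = [t for t in times if t is not None]
        if known != sorted(known):
            raise ValueError("event times must satisfy failure <= entry <= flare")


@dataclass
class MTEOutcome:
    """Result of scoring one maneuver against the autorotation MTE."""

    performance: str  # desirable | adequate | fail
    success: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class GroupSummary:
    group: int
    success_rate: float
    n_maneuvers: int
    mean_reaction_time: float | None = None
    sd_reaction_time: float | None = None
    subset: str = "all_points"


# ---------------------------------------------------------------------------
# catalog

def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("heliwork.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


_CATALOG: dict[str, TestPoint] | None = None


def load_point_catalog() -> dict[str, TestPoint]:
    """Height-Speed test-point catalog keyed by code (shipped config file)."""
    global _CATALOG
    if _CATALOG is None:
        df = _read_packaged_csv("test_points.csv")
        _CATALOG = {
            row.code: TestPoint(row.code, float(row.height_ft), float(row.speed_kt),
                                row.classical, row.zone)
            for row in df.itertuples()
        }
    return _CATALOG


def load_hqr_table() -> pd.DataFrame:
    """Campaign handling-qualities ratings, one row per (point, pilot)."""
    return _read_packaged_csv("hqr_ratings.csv")


def classify_point(code: str) -> TestPoint:
    """Look up a test point and its classical and zone partition labels."""
    catalog = load_point_catalog()
    try:
        return catalog[code]
    except KeyError:
        raise CatalogError(f"unknown test-point code {code!r}") from None


# ---------------------------------------------------------------------------
# event detection

def detect_engine_failure(
    fti: FTIRecord,
    idle_ng: float = IDLE_NG,
    stabilization_window: float = 0.5,
    tolerance: float = 1.0,
) -> float:
    """Time at which the engine stabilized in the idle regime (Ng = 65%).

    Returns the first sample at which Ng enters a band of ``tolerance`` percent
    around ``idle_ng`` and stays there for at least ``stabilization_window``
    seconds.  The timestamp is the band *entry*, keeping the event causal.
    """
    ng = np.asarray(fti.ng, dtype=float)
    in_band = np.abs(ng - idle_ng) <= tolerance
    need = max(1, int(round(stabilization_window * fti.sample_rate)))
    # run-length scan over the boolean band mask
    idx = 0
    n = len(in_band)
    while idx < n:
        if in_band[idx]:
            end = idx
            while end < n and in_band[end]:
                end += 1
            if end - idx >= need:
                return float(fti.time[idx])
            idx = end
        else:
            idx += 1
    raise EventDetectionError(
        f"Ng never stabilized within ±{tolerance}% of {idle_ng}% "
        f"for {stabilization_window} s"
    )


def detect_autorotation_entry(
    fti: FTIRecord,
    failure_time: float,
    rate_threshold: float = -5.0,
    sustain_samples: int = 3,
    search_horizon: float = 10.0,
) -> float:
    """Onset of the pilot's reaction: collective lowered after the failure.

    First post-failure time at which the collective's downward rate is at
    most ``rate_threshold`` (%/s, negative) for ``sustain_samples``
    consecutive samples within ``search_horizon`` seconds.
    """
    coll = np.asarray(fti.controls["collective"], dtype=float)
    rate = np.gradient(coll, fti.dt)
    t = fti.time
    mask = (t > failure_time) & (t <= failure_time + search_horizon)
    moving = rate <= rate_threshold
    candidates = np.flatnonzero(mask & moving)
    for i in candidates:
        if moving[i : i + sustain_samples].all() and i + sustain_samples <= len(moving):
            return float(t[i])
    raise EventDetectionError(
        f"no sustained collective-down motion within {search_horizon} s of failure"
    )


def detect_flare(
    fti: FTIRecord,
    entry_time: float,
    flare_height: float = 65.0,
) -> float:
    """Start of the flare: pitch-attitude rate turns positive near the ground.

    First time after ``entry_time`` with a positive longitudinal-attitude rate
    (dθ/dt > 0) while height is at or below ``flare_height`` feet.
    """
    theta_rate = np.gradient(np.asarray(fti.theta, dtype=float), fti.dt)
    t = fti.time
    ok = (t > entry_time) & (theta_rate > 0) & (np.asarray(fti.height) <= flare_height)
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        raise EventDetectionError(
            f"no positive pitch rate below {flare_height} ft after entry"
        )
    return float(t[idx[0]])


def reaction_time(failure_time: float, entry_time: float) -> float:
    """Interval between simulated engine failure and the pilot's reaction."""
    if entry_time < failure_time:
        raise ValueError("entry_time precedes failure_time")
    return entry_time - failure_time


# ---------------------------------------------------------------------------
# MTE scoring

_HIGH_SPEED_ENTRY_KT = 55.0
_DESIRABLE_GROUND_KT = 30.0
_ADEQUATE_GROUND_KT = 40.0
_MAX_VERTICAL_MS = 2.0
_MAX_HQR = 4.5


def evaluate_mte(m: ManeuverRecord) -> MTEOutcome:
    """Score one maneuver against the autorotation mission task element.

    The criterion set branches on entry airspeed (Vi >= 55 kt adds the
    requirement of reaching the recommended 65 kt autorotation speed).
    Performance is desirable with touchdown ground speed < 30 kt, adequate
    < 40 kt (strict inequalities, as specified); vertical speed at touchdown
    must not exceed 2 m/s and the whole maneuver must be rated HQR <= 4.5.
    Success additionally requires no instructor intervention.
    """
    missing = [
        name
        for name, v in [
            ("landing_ground_speed", m.landing_ground_speed),
            ("landing_vertical_speed", m.landing_vertical_speed),
            ("hqr", m.hqr),
            ("rpm_criterion_met", m.rpm_criterion_met),
        ]
        if v is None
    ]
    high_speed_entry = m.point.speed_kt >= _HIGH_SPEED_ENTRY_KT
    if high_speed_entry and m.reached_autorotation_speed is None:
        missing.append("reached_autorotation_speed")
    if missing:
        raise ValueError(f"incomplete maneuver record, missing: {', '.join(missing)}")

    reasons: list[str] = []
    if high_speed_entry and not m.reached_autorotation_speed:
        reasons.append("autorotation-speed")
    if not m.rpm_criterion_met:
        reasons.append("rpm")
    if m.landing_vertical_speed > _MAX_VERTICAL_MS:
        reasons.append("vertical-speed")
    if m.hqr > _MAX_HQR:
        reasons.append("hqr")

    if reasons:
        performance = "fail"
    elif m.landing_ground_speed < _DESIRABLE_GROUND_KT:
        performance = "desirable"
    elif m.landing_ground_speed < _ADEQUATE_GROUND_KT:
        performance = "adequate"
    else:
        performance = "fail"
        reasons.append("ground-speed")

    success = performance in ("desirable", "adequate") and not m.instructor_intervention
    if m.instructor_intervention:
        reasons.append("intervention")
    return MTEOutcome(performance=performance, success=success, reasons=reasons)


def success_rate(
    outcomes: Sequence[MTEOutcome],
    maneuvers: Sequence[ManeuverRecord],
    subset: str = "all_points",
    group: int | None = None,
) -> GroupSummary:
    """Fraction of successful maneuvers, optionally on reasonable points only.

    ``subset='reasonable_points'`` keeps only maneuvers flown at Line or
    Outside points of the classical partition.
    """
    if subset not in ("all_points", "reasonable_points"):
        raise ValueError(f"unknown subset {subset!r}")
    pairs = list(zip(outcomes, maneuvers, strict=True))
    if group is not None:
        pairs = [(o, m) for o, m in pairs if m.group == group]
    if subset == "reasonable_points":
        pairs = [(o, m) for o, m in pairs if m.point.classical in REASONABLE_CLASSICAL]
    if not pairs:
        raise ValueError(f"no maneuvers in subset {subset!r}: success rate undefined")
    successes = sum(o.success for o, _ in pairs)
    rts = [
        reaction_time(m.failure_time, m.entry_time)
        for _, m in pairs
        if m.failure_time is not None and m.entry_time is not None
    ]
    return GroupSummary(
        group=group if group is not None else -1,
        success_rate=successes / len(pairs),
        n_maneuvers=len(pairs),
        mean_reaction_time=float(np.mean(rts)) if rts else None,
        sd_reaction_time=float(np.std(rts, ddof=1)) if len(rts) > 1 else None,
        subset=subset,
    )


# ---------------------------------------------------------------------------
# HQR dispersion (BIUG-style inter-pilot agreement)

def hqr_dispersion(
    ratings: pd.DataFrame,
    groups: Iterable[int] = (1, 2),
    sd_limit: float = 1.0,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-point HQR mean, sample SD and compliance with the 1-unit limit.

    ``ratings`` must have columns ``point_code``, ``pilot_id``, ``group``,
    ``hqr``.  Only the pilot groups in ``groups`` are considered (default:
    the test-pilot panel, groups 1-2).  Points with fewer than two ratings
    are skipped with a warning.  Compliance is SD <= ``sd_limit``.
    """
    sub = ratings[ratings["group"].isin(list(groups))]
    rows = []
    for code, grp in sub.groupby("point_code", sort=False):
        vals = grp["hqr"].astype(float).to_numpy()
        if len(vals) < 2:
            warnings.warn(f"point {code}: fewer than 2 ratings, skipped", stacklevel=2)
            continue
        sd = float(np.std(vals, ddof=ddof))
        rows.append(
            {
                "point_code": code,
                "n": len(vals),
                "mean_hqr": float(np.mean(vals)),
                "sd_hqr": sd,
                "compliant": bool(sd <= sd_limit + 1e-12),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_compliant"] = int(out["compliant"].sum()) if len(out) else 0
    return out
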
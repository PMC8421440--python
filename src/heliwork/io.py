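"""Channel-file readers/writers and trigger-based stream synchronization.

The on-disk dialect is deliberately open: plain UTF-8 CSV, one file per
stream per flight, a single ``#``-prefixed metadata line declaring the
stream kind and sample rate, then a ``time_s,...`` header.  (The original
flight-test recorder's native format is proprietary; this dialect plus the
import functions stands in for it.)

Physiological and aircraft clocks are aligned with the push-button trigger
pulses present in both streams: pulses are paired in order and the offset
is the median difference of the paired rising edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .campaign import FTIRecord
from .physio import PhysioTrace

__all__ = [
    "SchemaError",
    "SyncMap",
    "write_fti",
    "read_fti",
    "write_physio",
    "read_physio",
    "rising_edges",
    "synchronize",
]

_FTI_COLUMNS = {
    "ddc": ("controls", "collective"),
    "ddl": ("controls", "lateral"),
    "ddm": ("controls", "longitudinal"),
    "ddn": ("controls", "pedal"),
    "ddt": ("attr", "fuel_lever"),
    "ng": ("attr", "ng"),
    "nr": ("attr", "nr"),
    "tq": ("attr", "tq"),
    "theta": ("attr", "theta"),
    "phi": ("attr", "phi"),
    "psi": ("attr", "psi"),
    "p": ("attr", "p"),
    "q": ("attr", "q"),
    "r": ("attr", "r"),
    "h": ("attr", "height"),
    "vi": ("attr", "airspeed"),
    "trigger": ("attr", "trigger"),
}

RATE_TOLERANCE = 1e-3  # declared vs measured sample rate, relative


class SchemaError(ValueError):
    """Channel file violates the declared schema."""


@dataclass
class SyncMap:
    """Physio-clock minus FTI-clock alignment for one flight."""

    offset: float                 # s, physio minus FTI
    fti_pulses: np.ndarray
    physio_pulses: np.ndarray
    residuals: np.ndarray         # per-pair deviation from the median offset

    def fti_to_physio(self, t: float | np.ndarray):
        return np.asarray(t) + self.offset

    def physio_to_fti(self, t: float | np.ndarray):
        return np.asarray(t) - self.offset


def _meta_line(kind: str, rate: float, extra: str = "") -> str:
    return f"# heliwork-channels v1 kind={kind} sample_rate_hz={rate:g}{extra}\n"


def _parse_meta(line: str) -> dict:
    if not line.startswith("# heliwork-channels"):
        raise SchemaError("missing heliwork channel metadata line")
    fields = dict(tok.split("=", 1) for tok in line.strip("#\n ").split()[2:])
    return fields


def _check_time(time: np.ndarray, declared_rate: float) -> None:
    if len(time) < 2:
        raise SchemaError("channel file holds fewer than two samples")
    dt = np.diff(time)
    if (dt <= 0).any():
        raise SchemaError("time column is not strictly increasing")
    measured = 1.0 / np.median(dt)
    if abs(measured - declared_rate) > RATE_TOLERANCE * declared_rate:
        raise SchemaError(
            f"declared rate {declared_rate:g} Hz but median spacing gives "
            f"{measured:.4g} Hz"
        )


def write_fti(record: FTIRecord, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": record.time})
    for col, (tgt, name) in _FTI_COLUMNS.items():
        df[col] = record.controls[name] if tgt == "controls" else getattr(record, name)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_meta_line("fti", record.sample_rate))
        df.to_csv(fh, index=False, float_format="%.8g", lineterminator="\n")
    return path


def read_fti(path: str | Path) -> FTIRecord:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        meta = _parse_meta(fh.readline())
        df = pd.read_csv(fh)
    if meta.get("kind") != "fti":
        raise SchemaError(f"{path.name}: expected kind=fti, got {meta.get('kind')}")
    rate = float(meta["sample_rate_hz"])
    missing = [c for c in ("time_s", *_FTI_COLUMNS) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
    time = df["time_s"].to_numpy(dtype=float)
    _check_time(time, rate)
    controls = {name: df[col].to_numpy(dtype=float)
                for col, (tgt, name) in _FTI_COLUMNS.items() if tgt == "controls"}
    attrs = {name: df[col].to_numpy(dtype=float)
             for col, (tgt, name) in _FTI_COLUMNS.items() if tgt == "attr"}
    return FTIRecord(time=time, controls=controls, sample_rate=rate, **attrs)


def write_physio(trace: PhysioTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time, "signal": trace.signal})
    df["trigger"] = trace.trigger if trace.trigger is not None else 0.0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_meta_line(trace.channel_kind, trace.sample_rate, " unit=auto"))
        df.to_csv(fh, index=False, float_format="%.8g", lineterminator="\n")
    return path


def read_physio(path: str | Path) -> PhysioTrace:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        meta = _parse_meta(fh.readline())
        df = pd.read_csv(fh)
    kind = meta.get("kind")
    if kind not in ("eda", "ekg", "respiration"):
        raise SchemaError(f"{path.name}: unknown physio kind {kind!r}")
    rate = float(meta["sample_rate_hz"])
    for c in ("time_s", "signal", "trigger"):
        if c not in df.columns:
            raise SchemaError(f"{path.name}: missing column {c}")
    time = df["time_s"].to_numpy(dtype=float)
    _check_time(time, rate)
    return PhysioTrace(
        time=time,
        signal=df["signal"].to_numpy(dtype=float),
        channel_kind=kind,
        trigger=df["trigger"].to_numpy(dtype=float),
        sample_rate=rate,
    )


def rising_edges(time: np.ndarray, trigger: np.ndarray, level: float = 0.5) -> np.ndarray:
    """Times at which the trigger channel crosses the level upward."""
    hi = np.asarray(trigger) > level
    idx = np.flatnonzero(~hi[:-1] & hi[1:]) + 1
    if len(hi) and hi[0]:
        idx = np.concatenate([[0], idx])
    return np.asarray(time)[idx]


def synchronize(fti: FTIRecord, physio: PhysioTrace) -> SyncMap:
    """Pair trigger pulses across streams and estimate the clock offset.

    Pulses are paired in temporal order; unequal pulse counts are an error
    (the unmatched pulses are reported).  The offset is the median of the
    pairwise differences, robust to a single mis-registered pulse.
    """
    ft = rising_edges(fti.time, fti.trigger)
    pt = rising_edges(physio.time, physio.trigger)
    if len(ft) == 0 or len(pt) == 0:
        raise ValueError("no trigger pulses found in one of the streams")
    if len(ft) != len(pt):
        raise ValueError(
            f"trigger pulse counts differ: {len(ft)} FTI vs {len(pt)} physio "
            f"(FTI pulses at {np.round(ft, 3)}, physio at {np.round(pt, 3)})"
        )
    diffs = pt - ft
    offset = float(np.median(diffs))
    return SyncMap(offset=offset, fti_pulses=ft, physio_pulses=pt,
                   residuals=diffs - offset)
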
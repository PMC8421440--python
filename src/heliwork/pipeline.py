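"""End-to-end orchestration: campaign -> events -> features -> statistics.

The pipeline runs event detection on the FTI channels, computes the CPF
peak around each detected engine failure, extracts the event-locked
physiological features, scores every maneuver against the MTE, and feeds
the per-maneuver feature tables to the mixed-effects comparisons.  Every
artifact it writes embeds the configuration hash and seed, and a run with
the same hash reproduces the same bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import campaign as cm
from . import cpf as cpfmod
from . import io as hio
from . import physio as ph
from . import stats as st
from .synthetic import CampaignConfig, SimulatedManeuver, iter_maneuvers

__all__ = [
    "extract_maneuver_features",
    "extract_campaign_features",
    "feature_tables",
    "run_pipeline",
    "load_config",
    "config_hash",
]

log = logging.getLogger("heliwork")


def load_config(path: str | Path) -> CampaignConfig:
    """Campaign/analysis configuration from a declarative YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(CampaignConfig)}
    campaign_section = raw.get("campaign", raw)
    unknown = set(campaign_section) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    for key in ("pilots_per_group", "rf_band", "hr_peak1", "hr_peak2",
                "scr_onset_range", "scr_onset_sim", "point_plan"):
        if key in campaign_section and campaign_section[key] is not None:
            campaign_section[key] = tuple(campaign_section[key])
    cfg = CampaignConfig(**campaign_section)
    cfg.validate()
    return cfg


def config_hash(cfg: CampaignConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def extract_maneuver_features(
    m: SimulatedManeuver,
    cpf_step: int = 1,
    include_resp: bool = False,
) -> dict:
    """All per-maneuver quantities the statistical stage consumes."""
    r = m.record
    out: dict = {
        "maneuver_id": r.maneuver_id,
        "pilot_id": r.pilot_id,
        "group": r.group,
        "point_code": r.point.code,
        "classical": r.point.classical,
        "zone": r.point.zone,
        "hqr": r.hqr,
    }
    # --- events on the FTI clock -----------------------------------------
    failure = cm.detect_engine_failure(m.fti)
    entry = cm.detect_autorotation_entry(m.fti, failure)
    out["failure_time"] = failure
    out["entry_time"] = entry
    out["reaction_time"] = cm.reaction_time(failure, entry)
    try:
        out["flare_time"] = cm.detect_flare(m.fti, entry)
    except cm.EventDetectionError:
        out["flare_time"] = np.nan

    # --- control workload -------------------------------------------------
    axes = {}
    for axis in cpfmod.AXES:
        axes[axis] = cpfmod.axis_cpf_series(
            m.fti.controls[axis], fs=m.fti.sample_rate,
            step=cpf_step, t0=float(m.fti.time[0]),
        )
    total = cpfmod.total_cpf(axes)
    peak, peak_t = cpfmod.cpf_peak(total, failure)
    out["cpf_peak"] = peak
    out["cpf_peak_time"] = peak_t

    # --- physiology, on the physio clock ----------------------------------
    if m.eda is not None:
        offset = _stream_offset(m.fti, m.eda)
        seg = ph.segment_and_normalize(m.eda, failure + offset)
        scr = ph.scr_first_peak(seg, sample_rate=m.eda.sample_rate,
                                maneuver_id=r.maneuver_id)
        out["eda_amplitude"] = scr.amplitude if scr.valid else np.nan
        out["eda_onset"] = scr.onset_latency
        out["eda_valid"] = scr.valid
    if m.ekg is not None:
        offset = _stream_offset(m.fti, m.ekg)
        filt = ph.PhysioTrace(
            m.ekg.time,
            ph.bandpass_zero_phase(m.ekg.signal, m.ekg.sample_rate, 1.0, 100.0),
            "ekg", trigger=m.ekg.trigger, sample_rate=m.ekg.sample_rate,
        )
        beats = ph.detect_r_peaks(filt)
        hr = ph.heart_rate_auc(beats, failure + offset, maneuver_id=r.maneuver_id)
        out["hr_auc"] = hr.auc if hr.usable else np.nan
    if include_resp and m.resp is not None:
        offset = _stream_offset(m.fti, m.resp)
        rf = ph.promediated_frequency(m.resp, failure + offset,
                                      maneuver_id=r.maneuver_id)
        pre = rf.f_promediated[rf.time < 0]
        post = rf.f_promediated[rf.time > 0]
        out["rf_centroid_pre"] = float(pre.mean())
        out["rf_centroid_post"] = float(post.mean())
    return out


def _stream_offset(fti: cm.FTIRecord, trace: ph.PhysioTrace) -> float:
    if trace.trigger is None or not np.any(trace.trigger > 0.5) \
            or not np.any(fti.trigger > 0.5):
        return 0.0
    return hio.synchronize(fti, trace).offset


def extract_campaign_features(cfg: CampaignConfig, cpf_step: int = 1) -> pd.DataFrame:
    """Stream the synthetic campaign through the feature extractors."""
    rows = []
    for m in iter_maneuvers(cfg):
        rows.append(extract_maneuver_features(m, cpf_step=cpf_step,
                                              include_resp=cfg.include_resp))
    return pd.DataFrame(rows)


def feature_tables(features: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Modelling tables for the inferential stage (one per feature)."""
    tables = {}
    for name, col in (("cpf", "cpf_peak"), ("eda", "eda_amplitude"),
                      ("hr", "hr_auc"), ("hqr", "hqr")):
        if col in features.columns:
            tables[name] = st.build_feature_table(features, features[col])
    return tables


def run_pipeline(
    cfg: CampaignConfig,
    out_dir: str | Path,
    cpf_step: int = 1,
    alpha: float = 0.05,
    fdr_method: str = "fdr_bh",
) -> dict:
    """Full campaign analysis; writes feature CSVs, a JSON report and a log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg)
    t0 = _time.time()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("run start: seed=%s config_hash=%s", cfg.seed, h)
        rows = []
        maneuvers = []
        outcomes = []
        for m in iter_maneuvers(cfg):
            rows.append(extract_maneuver_features(m, cpf_step=cpf_step,
                                                  include_resp=cfg.include_resp))
            maneuvers.append(m.record)
            outcomes.append(cm.evaluate_mte(m.record))
        features = pd.DataFrame(rows)
        log.info("features extracted for %d maneuvers", len(features))
        features.to_csv(out / "features.csv", index=False)
        success = []
        for g in (1, 2, 3):
            for subset in ("all_points", "reasonable_points"):
                try:
                    s = cm.success_rate(outcomes, maneuvers, subset=subset, group=g)
                    success.append(dataclasses.asdict(s))
                except ValueError:
                    pass
        log.info("MTE scored: %d maneuvers", len(outcomes))

        reports = st.run_full_inference(feature_tables(features), alpha=alpha,
                                        fdr_method=fdr_method)
        matrix = st.retention_matrix(reports)
        contrast_rows = [
            {"feature": ft, "factor": fa, "level_a": c.level_a, "level_b": c.level_b,
             "estimate": c.estimate, "se": c.se, "p_raw": c.p_raw,
             "p_adjusted": c.p_adjusted}
            for (ft, fa), rep in reports.items() for c in rep.contrasts
        ]
        pd.DataFrame(contrast_rows).to_csv(out / "contrasts.csv", index=False)

        report = {
            "config_hash": h,
            "seed": cfg.seed,
            "n_maneuvers": int(len(features)),
            "success_rates": success,
            "retention": {f"{ft}:{fa}": bool(rep.retained)
                          for (ft, fa), rep in reports.items()},
            "models": [rep.summary_row() for rep in reports.values()],
            "elapsed_s": round(_time.time() - t0, 2),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        log.info("run complete in %.1f s", report["elapsed_s"])
        return {"features": features, "reports": reports, "matrix": matrix,
                "report": report}
    finally:
        log.removeHandler(handler)
        handler.close()
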
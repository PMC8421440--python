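"""Catalog, event detection, MTE scoring and HQR dispersion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from heliwork import campaign as cm

FS = 64.0

from conftest import make_fti


# ---------------------------------------------------------------------------
# catalog and partitions

@pytest.mark.parametrize(
    "code,classical,zone",
    [
        ("G1", "Inside", "Cruise"),
        ("E2", "Line", "High-hover"),
        ("A1", "Excluded", "Excluded"),
        ("C1", "Outside", "Take-off"),
        ("H2", "Line", "Knee"),
    ],
)
def test_classify_point(code, classical, zone):
    tp = cm.classify_point(code)
    assert (tp.classical, tp.zone) == (classical, zone)


def test_classify_point_unknown_code():
    with pytest.raises(cm.CatalogError):
        cm.classify_point("Z9")


def test_catalog_partition_cover():
    """Classical lists reproduce the published sets and are disjoint."""
    cat = cm.load_point_catalog()
    classical = {lbl: {c for c, p in cat.items() if p.classical == lbl}
                 for lbl in ("Outside", "Line", "Inside")}
    assert classical["Outside"] == {"C1", "C2", "D3", "E1", "E5", "F3", "G3"}
    assert classical["Line"] == {"D2", "E2", "E4", "F2", "G2", "H2"}
    assert classical["Inside"] == {"D1", "E3A", "E3B", "F1", "G1", "H1"}
    zones = {lbl: {c for c, p in cat.items() if p.zone == lbl}
             for lbl in ("Take-off", "Knee", "Cruise", "High-hover")}
    assert zones["Take-off"] == {"B3", "C1"}
    assert zones["Knee"] == {"D1", "D2", "D3", "H1", "H2", "H3"}
    assert zones["Cruise"] == {"G1", "G2", "G3", "F1", "F2", "F3", "E3B", "E4", "E5"}
    assert zones["High-hover"] == {"E1", "E2", "E3A"}
    # every analyzable point carries exactly one label per partition
    assert sum(len(v) for v in classical.values()) == 19


# ---------------------------------------------------------------------------
# event detection

def test_engine_failure_step():
    n = int(30 * FS)
    ng = np.where(np.arange(n) / FS < 10.0, 85.0, 65.0)
    fti = make_fti(30, ng=ng)
    assert cm.detect_engine_failure(fti, stabilization_window=1.0) == pytest.approx(10.0, abs=1 / FS)


def test_engine_failure_never_stabilizes():
    fti = make_fti(20)  # Ng constant at 85%
    with pytest.raises(cm.EventDetectionError):
        cm.detect_engine_failure(fti)


def test_engine_failure_short_excursion_ignored():
    n = int(30 * FS)
    t = np.arange(n) / FS
    ng = np.full(n, 85.0)
    ng[(t >= 5.0) & (t < 5.2)] = 65.0   # 0.2 s dip, shorter than the window
    ng[t >= 12.0] = 65.0
    fti = make_fti(30, ng=ng)
    assert cm.detect_engine_failure(fti) == pytest.approx(12.0, abs=1 / FS)


def test_autorotation_entry_ramp():
    n = int(30 * FS)
    t = np.arange(n) / FS
    coll = np.full(n, 55.0)
    start = 11.2
    coll -= 20.0 * np.clip(t - start, 0, 1.5)
    fti = make_fti(30, collective=coll)
    entry = cm.detect_autorotation_entry(fti, failure_time=10.0)
    assert entry == pytest.approx(start, abs=2 / FS)


def test_autorotation_entry_no_motion():
    fti = make_fti(30)
    with pytest.raises(cm.EventDetectionError):
        cm.detect_autorotation_entry(fti, failure_time=10.0)


def test_flare_pitch_up_near_ground():
    n = int(40 * FS)
    t = np.arange(n) / FS
    theta = 3.0 - 0.2 * np.clip(t, 0, 30.0)
    theta += 6.0 * np.clip(t - 30.0, 0, 2.0)   # pitch-up from t=30
    h = np.clip(500.0 - 16.0 * t, 0, None)     # 60 ft at t=27.5
    fti = make_fti(40, theta=theta, height=h)
    flare = cm.detect_flare(fti, entry_time=5.0)
    assert flare == pytest.approx(30.0, abs=2 / FS)


def test_flare_requires_low_height():
    n = int(40 * FS)
    t = np.arange(n) / FS
    theta = 3.0 + 0.5 * t          # always pitching up
    fti = make_fti(40, theta=theta, height=np.full(n, 200.0))
    with pytest.raises(cm.EventDetectionError):
        cm.detect_flare(fti, entry_time=5.0)


def test_detector_chain_recovers_generator_truth(fti_only_campaign):
    """Failure/entry/flare recovered within two samples on synthetic data."""
    _, maneuvers = fti_only_campaign
    errs_f, errs_e, errs_fl = [], [], []
    for m in maneuvers[:40]:
        f = cm.detect_engine_failure(m.fti)
        e = cm.detect_autorotation_entry(m.fti, f)
        fl = cm.detect_flare(m.fti, e)
        errs_f.append(abs(f - m.truth.failure_time))
        errs_e.append(abs(e - m.truth.entry_time))
        errs_fl.append(abs(fl - m.truth.flare_time))
    for errs in (errs_f, errs_e, errs_fl):
        assert np.mean(errs) < 2 / FS


def test_reaction_time_arithmetic():
    assert cm.reaction_time(10.0, 11.2) == pytest.approx(1.2)
    assert cm.reaction_time(10.0, 10.0) == 0.0
    with pytest.raises(ValueError):
        cm.reaction_time(10.0, 9.0)


def test_reaction_time_campaign_mean(fti_only_campaign):
    """Detected reaction delays reproduce the configured 1.18 ± 0.31 s."""
    cfg, maneuvers = fti_only_campaign
    rts = []
    for m in maneuvers:
        f = cm.detect_engine_failure(m.fti)
        e = cm.detect_autorotation_entry(m.fti, f)
        rts.append(cm.reaction_time(f, e))
    rts = np.asarray(rts)
    assert (rts >= 0).all()
    se = cfg.reaction_sd / np.sqrt(len(rts))
    assert abs(rts.mean() - cfg.reaction_mean) < 3 * se


# ---------------------------------------------------------------------------
# MTE

def _maneuver(**kw):
    base = dict(
        pilot_id="P01", group=1, flight_id="P01-F1",
        point=cm.classify_point("G1"),  # 70 kt entry: high-speed branch
        hqr=4.0, landing_ground_speed=25.0, landing_vertical_speed=1.5,
        reached_autorotation_speed=True, rpm_criterion_met=True,
        instructor_intervention=False,
    )
    base.update(kw)
    return cm.ManeuverRecord(**base)


@pytest.mark.parametrize(
    "kw,performance,success,reason",
    [
        ({}, "desirable", True, None),
        ({"landing_ground_speed": 35.0}, "adequate", True, None),
        ({"landing_vertical_speed": 2.5}, "fail", False, "vertical-speed"),
        ({"hqr": 5.0}, "fail", False, "hqr"),
        ({"landing_ground_speed": 45.0}, "fail", False, "ground-speed"),
        ({"reached_autorotation_speed": False}, "fail", False, "autorotation-speed"),
        ({"instructor_intervention": True}, "desirable", False, "intervention"),
        ({"landing_vertical_speed": 2.0}, "desirable", True, None),  # <= 2 passes
        ({"hqr": 4.5}, "desirable", True, None),                     # <= 4.5 passes
        ({"landing_ground_speed": 30.0}, "adequate", True, None),    # strict < 30
    ],
)
def test_evaluate_mte_cases(kw, performance, success, reason):
    out = cm.evaluate_mte(_maneuver(**kw))
    assert out.performance == performance
    assert out.success is success
    if reason:
        assert reason in out.reasons


def test_evaluate_mte_low_speed_branch_skips_speed_criterion():
    m = _maneuver(point=cm.classify_point("E2"),  # 0 kt: low-speed branch
                  reached_autorotation_speed=None)
    assert cm.evaluate_mte(m).performance == "desirable"


def test_evaluate_mte_missing_metrics():
    with pytest.raises(ValueError, match="landing_vertical_speed"):
        cm.evaluate_mte(_maneuver(landing_vertical_speed=None))


_rank = {"fail": 0, "adequate": 1, "desirable": 2}


@settings(max_examples=60, deadline=None)
@given(
    ground=hst.floats(5, 60), vertical=hst.floats(0.1, 4.0),
    hqr2=hst.integers(2, 20),
    d_ground=hst.floats(0, 20), d_vert=hst.floats(0, 2), d_hqr=hst.integers(0, 6),
)
def test_evaluate_mte_monotone(ground, vertical, hqr2, d_ground, d_vert, d_hqr):
    """Worsening any landing metric never upgrades the performance class."""
    a = cm.evaluate_mte(_maneuver(landing_ground_speed=ground,
                                  landing_vertical_speed=vertical, hqr=hqr2 / 2))
    b = cm.evaluate_mte(_maneuver(landing_ground_speed=ground + d_ground,
                                  landing_vertical_speed=vertical + d_vert,
                                  hqr=min(10.0, hqr2 / 2 + d_hqr / 2)))
    assert _rank[b.performance] <= _rank[a.performance]


# ---------------------------------------------------------------------------
# success rate

def test_success_rate_counts_and_filtering():
    pts = [cm.classify_point(c) for c in ("C1", "C1", "C1")]
    ms = [_maneuver(point=p) for p in pts]
    outs = [cm.MTEOutcome("desirable", True), cm.MTEOutcome("adequate", True),
            cm.MTEOutcome("fail", False)]
    s = cm.success_rate(outs, ms, subset="all_points")
    assert s.success_rate == pytest.approx(2 / 3)
    # 2 successes Inside + 1 fail Outside -> 0/1 on reasonable points
    ms2 = [_maneuver(point=cm.classify_point("G1")),
           _maneuver(point=cm.classify_point("G1")),
           _maneuver(point=cm.classify_point("C1"))]
    outs2 = [cm.MTEOutcome("desirable", True), cm.MTEOutcome("desirable", True),
             cm.MTEOutcome("fail", False)]
    s2 = cm.success_rate(outs2, ms2, subset="reasonable_points")
    assert s2.success_rate == 0.0 and s2.n_maneuvers == 1


def test_success_rate_empty_subset_errors():
    ms = [_maneuver(point=cm.classify_point("G1"))]  # Inside only
    with pytest.raises(ValueError):
        cm.success_rate([cm.MTEOutcome("fail", False)], ms, subset="reasonable_points")


def test_success_rate_reasonable_at_least_all_when_inside_fails():
    """If every Inside maneuver fails, dropping them cannot lower the rate."""
    ms, outs = [], []
    for code, ok in (("G1", False), ("H1", False), ("C1", True), ("D2", True),
                     ("E5", False)):
        ms.append(_maneuver(point=cm.classify_point(code)))
        outs.append(cm.MTEOutcome("desirable" if ok else "fail", ok))
    all_pts = cm.success_rate(outs, ms, subset="all_points").success_rate
    reasonable = cm.success_rate(outs, ms, subset="reasonable_points").success_rate
    assert reasonable >= all_pts


def test_success_rate_binomial_recovery(fti_only_campaign):
    """Empirical per-group rates sit inside the binomial 95% interval."""
    cfg, maneuvers = fti_only_campaign
    records = [m.record for m in maneuvers]
    outcomes = [cm.evaluate_mte(r) for r in records]
    for g in (1, 2, 3):
        s = cm.success_rate(outcomes, records, subset="all_points", group=g)
        p = cfg.success_prob[g]
        half = 1.96 * np.sqrt(p * (1 - p) / s.n_maneuvers)
        assert abs(s.success_rate - p) <= half + 1e-9


# ---------------------------------------------------------------------------
# HQR dispersion

def test_hqr_dispersion_closed_form():
    df = pd.DataFrame({
        "point_code": ["X"] * 3 + ["Y"] * 2,
        "pilot_id": [1, 2, 3, 1, 2],
        "group": [1, 1, 2, 1, 2],
        "hqr": [4, 4, 5, 3, 6],
    })
    out = cm.hqr_dispersion(df).set_index("point_code")
    assert out.loc["X", "mean_hqr"] == pytest.approx(4.33, abs=0.01)
    assert out.loc["X", "sd_hqr"] == pytest.approx(0.58, abs=0.01)
    assert bool(out.loc["X", "compliant"])
    assert out.loc["Y", "sd_hqr"] == pytest.approx(2.12, abs=0.01)
    assert not bool(out.loc["Y", "compliant"])


def test_hqr_dispersion_skips_single_rating():
    df = pd.DataFrame({"point_code": ["X", "Y", "Y"], "pilot_id": [1, 1, 2],
                       "group": [1, 1, 1], "hqr": [4, 5, 5]})
    with pytest.warns(UserWarning, match="fewer than 2"):
        out = cm.hqr_dispersion(df)
    assert list(out["point_code"]) == ["Y"]


def test_hqr_table_dispersion_20_of_21():
    """Test-pilot panel agrees within one HQR unit at 20 of the 21 points."""
    table = cm.load_hqr_table()
    disp = cm.hqr_dispersion(table, groups=(1, 2))
    assert len(disp) == 21
    assert disp.attrs["n_compliant"] == 20
    bad = disp[~disp["compliant"]]
    assert list(bad["point_code"]) == ["G1"]
    assert float(bad["sd_hqr"].iloc[0]) > 1.0
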
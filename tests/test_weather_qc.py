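"""Wet-event detection, sample stratification, and QC rules."""

import numpy as np
import pandas as pd
import pytest

from hf183.model import (
    InsufficientDataError,
    PlateWell,
    ReplicateMeasurement,
    Role,
    SampleRecord,
    SiteSummary,
    Target,
    Weather,
    WetEvent,
)
from hf183.weather_qc import (
    DRY_DAY_THRESHOLD,
    classify_sample_weather,
    detect_wet_events,
    exclude_low_n_sites,
    flag_inhibition,
    summarize_negative_controls,
)


def daily_rain(depths, start="2015-01-01", gauge="G1"):
    days = pd.date_range(start, periods=len(depths), freq="D")
    return pd.DataFrame(
        {"gauge_id": gauge, "timestamp": days, "depth_inches": depths}
    )


def test_all_zero_series_has_no_events():
    assert detect_wet_events(daily_rain([0.0] * 30)) == []


def test_single_storm_after_dry_spell_starts_event_that_day():
    depths = [0.0] * 9 + [0.12] + [0.0] * 5
    events = detect_wet_events(daily_rain(depths))
    assert len(events) == 1
    assert events[0].start == pd.Timestamp("2015-01-10")
    assert events[0].window_end == pd.Timestamp("2015-01-13")


def test_accumulation_across_consecutive_days():
    """0.05 then 0.06 inches on consecutive days: the 0.10-inch threshold
    is crossed on the second day, which becomes the event start."""
    depths = [0.0] * 9 + [0.05, 0.06] + [0.0] * 5
    events = detect_wet_events(daily_rain(depths))
    assert len(events) == 1
    assert events[0].start == pd.Timestamp("2015-01-11")


def test_subthreshold_rain_never_qualifies():
    depths = [0.0] * 9 + [0.05] + [0.0] * 9 + [0.06] + [0.0] * 5
    assert detect_wet_events(daily_rain(depths)) == []


def test_no_event_without_antecedent_dry_days():
    # rain on days 2-3 of the record: only 1 observed dry day before
    depths = [0.0, 0.2] + [0.0] * 10
    assert detect_wet_events(daily_rain(depths)) == []


def _oracle_events(rain: pd.DataFrame, min_depth=0.10, dry_days=3):
    """Independent day-by-day scan over the daily totals."""
    out = []
    for gauge, grp in rain.groupby("gauge_id"):
        grp = grp.sort_values("timestamp")
        daily = (
            grp.set_index(grp["timestamp"].dt.normalize())["depth_inches"]
            .groupby(level=0)
            .sum()
        )
        days = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
        totals = np.array([daily.get(d, 0.0) for d in days])
        wet = totals >= DRY_DAY_THRESHOLD
        i = 0
        while i < len(days):
            if wet[i]:
                run_start = i
                while i < len(days) and wet[i]:
                    i += 1
                preceded = (
                    run_start >= dry_days
                    and not wet[run_start - dry_days:run_start].any()
                )
                if preceded:
                    cum, crossed = 0.0, None
                    for j in range(run_start, i):
                        cum += totals[j]
                        if cum >= min_depth:
                            crossed = days[j]
                            break
                    if crossed is not None:
                        out.append(
                            WetEvent(
                                gauge_id=str(gauge),
                                start=crossed,
                                window_end=crossed + pd.Timedelta(hours=72),
                            )
                        )
            else:
                i += 1
    return out


def test_event_detection_matches_brute_force_on_random_series():
    """200 random daily series: the chronological scanner and an
    independent day-by-day oracle find identical events, and every random
    sampling time is classified identically by both event lists."""
    rng = np.random.default_rng(606)
    for _ in range(200):
        n = int(rng.integers(20, 90))
        depths = np.where(
            rng.random(n) < 0.3, rng.exponential(0.08, n).round(3), 0.0
        )
        rain = daily_rain(list(depths))
        events = detect_wet_events(rain)
        oracle = _oracle_events(rain)
        assert events == oracle

        t0 = rain["timestamp"].iloc[0]
        for _ in range(20):
            ts = t0 + pd.Timedelta(hours=float(rng.uniform(0, 24 * n)))
            assert classify_sample_weather(ts, events) == classify_sample_weather(
                ts, oracle
            )


def test_event_windows_never_overlap_per_gauge():
    rng = np.random.default_rng(607)
    for _ in range(100):
        n = int(rng.integers(30, 120))
        depths = np.where(
            rng.random(n) < 0.4, rng.exponential(0.1, n).round(3), 0.0
        )
        events = detect_wet_events(daily_rain(list(depths)))
        for a, b in zip(events, events[1:]):
            assert a.window_end < b.start


def _event(start):
    start = pd.Timestamp(start)
    return WetEvent("G1", start, start + pd.Timedelta(hours=72))


def test_sample_inside_window_is_wet():
    ev = _event("2015-07-10 00:00")
    assert (
        classify_sample_weather(pd.Timestamp("2015-07-11 00:00"), [ev])
        is Weather.WET
    )


def test_sample_in_post_window_buffer_excluded_then_dry():
    ev = _event("2015-07-10 00:00")
    # 80 h: past the 72-h window but inside the 72-h recovery buffer
    assert (
        classify_sample_weather(pd.Timestamp("2015-07-13 08:00"), [ev])
        is Weather.EXCLUDED
    )
    # a week later, mid-July: dry
    assert (
        classify_sample_weather(pd.Timestamp("2015-07-20 08:00"), [ev])
        is Weather.DRY
    )


def test_out_of_season_sample_without_event_excluded():
    assert (
        classify_sample_weather(pd.Timestamp("2015-01-15 08:00"), [])
        is Weather.EXCLUDED
    )


def _controls(n_ntc, n_nec, amplified):
    """n_ntc NTC + n_nec NEC wells, with `amplified` of them amplifying."""
    wells = []
    k = 0
    for i in range(n_ntc + n_nec):
        role = Role.NTC if i < n_ntc else Role.NEC
        cq = None
        if k < amplified:
            cq, k = 37.5, k + 1
        plate = f"P{i // 9:04d}"
        wells.append(
            PlateWell(
                plate_id=plate, lab_id="L1", well=f"A{i % 9 + 1}",
                role=role, target=Target.HF183, cq=cq,
            )
        )
    return wells


def test_published_negative_control_arithmetic():
    """2 amplifications out of 936 NTC plus 2 out of 1179 NEC reactions
    pool to 99.8% clean."""
    wells = _controls(936, 1179, amplified=4)
    pct, flagged = summarize_negative_controls(wells)
    assert round(pct, 1) == 99.8
    assert len(flagged) == 4


def test_negative_control_edge_cases():
    pct, flagged = summarize_negative_controls(_controls(5, 5, 0))
    assert pct == 100.0 and flagged == []
    pct, _ = summarize_negative_controls(_controls(5, 5, 1))
    assert pct == pytest.approx(90.0)
    with pytest.raises(InsufficientDataError):
        summarize_negative_controls([])


def test_negative_control_pct_invariant_to_plate_order():
    wells = _controls(30, 40, amplified=3)
    rng = np.random.default_rng(5)
    shuffled = list(wells)
    rng.shuffle(shuffled)
    assert summarize_negative_controls(wells) == summarize_negative_controls(
        shuffled
    )


def _sample_with_sketa(sid, sketa):
    return SampleRecord(
        sample_id=sid, site_id="A", timestamp=pd.Timestamp("2015-07-01"),
        replicates=[ReplicateMeasurement()] * 3, sketa22_cq=sketa,
    )


def test_inhibition_flagging():
    samples = [
        _sample_with_sketa("ok", 22.2),
        _sample_with_sketa("slow", 25.5),
        _sample_with_sketa("lost", None),
    ]
    assert flag_inhibition(samples, reference_sketa22_cq=22.0) == ["slow", "lost"]


def test_study_like_dataset_shows_no_inhibition(default_result):
    assert default_result.qc.inhibited_samples == []


def test_low_n_exclusion_boundary():
    def s(site, n):
        return SiteSummary(site_id=site, stratum=Weather.WET, n_samples=n)

    retained, excluded = exclude_low_n_sites([s("A", 10), s("B", 11)])
    assert [x.site_id for x in retained] == ["B"]
    assert excluded == [("A", "WET", 10)]

    mixed = [s(f"S{i:02d}", 5 if i < 5 else 30) for i in range(23)]
    retained, excluded = exclude_low_n_sites(mixed)
    assert len(retained) == 18
    assert len(excluded) == 5
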
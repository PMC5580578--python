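"""Wet/dry sample stratification and campaign quality control.

A wet-weather event requires at least 0.10 inches of accumulated rain at
the nearest gauge after three or more antecedent dry days; samples
collected within 72 h of the qualifying accumulation are wet-weather
samples. Dry-weather samples must fall outside every event window plus a
72-h recovery buffer and within the recreational season (1 April to
31 October). QC covers pooled negative-control contamination, sketa22
sample-processing-control inhibition flags, and exclusion of site-stratum
cells with ten or fewer samples.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    InsufficientDataError,
    PlateWell,
    QCReport,
    Role,
    SampleRecord,
    SiteSummary,
    Weather,
    WetEvent,
)

MIN_EVENT_DEPTH = 0.10      # inches, accumulated since rain onset
ANTECEDENT_DRY_DAYS = 3
DRY_DAY_THRESHOLD = 0.01    # daily total below this counts as a dry day
EVENT_WINDOW = pd.Timedelta(hours=72)
POST_WINDOW_BUFFER = pd.Timedelta(hours=72)
SEASON = ((4, 1), (10, 31))  # 1 April .. 31 October
MIN_SITE_N = 11             # site-stratum cells with n <= 10 are excluded


def detect_wet_events(
    rain: pd.DataFrame,
    min_depth: float = MIN_EVENT_DEPTH,
    dry_days: int = ANTECEDENT_DRY_DAYS,
    dry_day_threshold: float = DRY_DAY_THRESHOLD,
) -> list[WetEvent]:
    """Scan each gauge's series chronologically for qualifying events.

    Days are aggregated from the records; days absent from the series are
    treated as rain-free. A run of consecutive wet days whose first day is
    preceded by at least ``dry_days`` observed dry days yields one event
    if its accumulated depth reaches ``min_depth``; the event starts at
    the record where the accumulation crosses the threshold.
    """
    events: list[WetEvent] = []
    for gauge_id, grp in rain.groupby("gauge_id", sort=True):
        grp = grp.sort_values("timestamp")
        dates = grp["timestamp"].dt.normalize()
        daily = grp.groupby(dates)["depth_inches"].sum()
        if daily.empty:
            continue
        full_range = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
        daily = daily.reindex(full_range, fill_value=0.0)
        is_wet = daily >= dry_day_threshold

        dry_run = 0  # consecutive observed dry days; unknown history counts 0
        i = 0
        days = list(daily.index)
        while i < len(days):
            if not is_wet.iloc[i]:
                dry_run += 1
                i += 1
                continue
            # start of a wet run
            j = i
            while j < len(days) and is_wet.iloc[j]:
                j += 1
            if dry_run >= dry_days:
                run_days = set(days[i:j])
                cum = 0.0
                for rec in grp.itertuples(index=False):
                    if rec.timestamp.normalize() not in run_days:
                        continue
                    cum += rec.depth_inches
                    if cum >= min_depth:
                        events.append(
                            WetEvent(
                                gauge_id=str(gauge_id),
                                start=rec.timestamp,
                                window_end=rec.timestamp + EVENT_WINDOW,
                            )
                        )
                        break
            dry_run = 0
            i = j
    return events


def in_season(timestamp: pd.Timestamp, season=SEASON) -> bool:
    (m0, d0), (m1, d1) = season
    key = (timestamp.month, timestamp.day)
    return (m0, d0) <= key <= (m1, d1)


def classify_sample_weather(
    timestamp: pd.Timestamp,
    events: Sequence[WetEvent],
    season=SEASON,
    buffer: pd.Timedelta = POST_WINDOW_BUFFER,
) -> Weather:
    """WET inside any 72-h event window; DRY only in season and clear of
    every window plus the post-event buffer; otherwise EXCLUDED."""
    for ev in events:
        if ev.start <= timestamp <= ev.window_end:
            return Weather.WET
    for ev in events:
        if ev.start <= timestamp <= ev.window_end + buffer:
            return Weather.EXCLUDED
    return Weather.DRY if in_season(timestamp, season) else Weather.EXCLUDED


def assign_weather(
    samples: Iterable[SampleRecord],
    events_by_gauge: dict[str, Sequence[WetEvent]],
    gauge_for_sample: dict[str, str],
    season=SEASON,
) -> None:
    """Set each sample's weather stratum from its nearest gauge's events."""
    for s in samples:
        gauge = gauge_for_sample.get(s.sample_id)
        events = events_by_gauge.get(gauge, [])
        s.weather = classify_sample_weather(s.timestamp, events, season)


def summarize_negative_controls(
    wells: Iterable[PlateWell],
) -> tuple[float, list[tuple[str, str, float]]]:
    """Percent clean reactions pooled over NTC and NEC wells, plus the
    amplified controls as (plate_id, well, Cq)."""
    total = 0
    flagged: list[tuple[str, str, float]] = []
    for w in wells:
        if w.role not in (Role.NTC, Role.NEC):
            continue
        total += 1
        if w.cq is not None:
            flagged.append((w.plate_id, w.well, w.cq))
    if total == 0:
        raise InsufficientDataError("no negative-control wells present")
    pct_clean = 100.0 * (1.0 - len(flagged) / total)
    return pct_clean, sorted(flagged)


def flag_inhibition(
    samples: Iterable[SampleRecord],
    reference_sketa22_cq: float,
    max_shift: float = 3.0,
) -> list[str]:
    """Samples whose sketa22 control is delayed by more than ``max_shift``
    cycles relative to the reference, or absent entirely."""
    flagged = []
    for s in samples:
        if s.sketa22_cq is None or s.sketa22_cq - reference_sketa22_cq > max_shift:
            flagged.append(s.sample_id)
    return flagged


def exclude_low_n_sites(
    summaries: Sequence[SiteSummary], min_n: int = MIN_SITE_N
) -> tuple[list[SiteSummary], list[tuple[str, str, int]]]:
    """Drop site-stratum cells with fewer than ``min_n`` samples."""
    retained, excluded = [], []
    for s in summaries:
        if s.n_samples >= min_n:
            retained.append(s)
        else:
            excluded.append((s.site_id, s.stratum.value, s.n_samples))
    return retained, excluded


def qc_report(
    wells: Iterable[PlateWell],
    samples: Sequence[SampleRecord],
    summaries: Sequence[SiteSummary],
    reference_sketa22_cq: Optional[float] = None,
    max_shift: float = 3.0,
    min_n: int = MIN_SITE_N,
) -> tuple[QCReport, list[SiteSummary]]:
    """Assemble the campaign QC report; returns (report, retained summaries)."""
    pct_clean, flagged = summarize_negative_controls(wells)
    if reference_sketa22_cq is None:
        observed = [s.sketa22_cq for s in samples if s.sketa22_cq is not None]
        if not observed:
            raise InsufficientDataError(
                "no sketa22 control Cq values; supply reference_sketa22_cq"
            )
        reference_sketa22_cq = float(pd.Series(observed).median())
    inhibited = flag_inhibition(samples, reference_sketa22_cq, max_shift)
    retained, excluded = exclude_low_n_sites(summaries, min_n)
    report = QCReport(
        pct_clean_control_reactions=pct_clean,
        flagged_controls=flagged,
        inhibited_samples=inhibited,
        excluded_sites=excluded,
    )
    return report, retained
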
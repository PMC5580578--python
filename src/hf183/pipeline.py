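"""End-to-end campaign analysis: calibration -> weather stratification ->
QC -> censored quantification -> site metrics -> rankings."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .calibration import calibrate_all_labs
from .model import (
    ConcordanceReport,
    InsufficientDataError,
    PlateWell,
    Positivity,
    QCReport,
    RankingResult,
    ReplicateMeasurement,
    Role,
    SampleRecord,
    SiteSummary,
    StandardCurve,
    SubstitutionScheme,
    Target,
    ValidationError,
    VolumeConfig,
    Weather,
)
from .prioritization import dry_wet_comparison, rank_concordance, rank_sites
from .site_metrics import summarize_site
from .weather_qc import assign_weather, detect_wet_events, qc_report


@dataclass
class CampaignResult:
    """Everything the analysis produces for one campaign."""

    curves: dict[str, StandardCurve]
    samples: list[SampleRecord]
    summaries: list[SiteSummary]          # after low-n exclusion
    qc: QCReport
    rankings: list[RankingResult] = field(default_factory=list)
    freq_vs_conc: dict[str, ConcordanceReport] = field(default_factory=dict)
    dry_vs_wet: Optional[ConcordanceReport] = None
    wet_decrease_sites: list[str] = field(default_factory=list)
    lab_for_sample: dict[str, str] = field(default_factory=dict)

    def summaries_for(self, stratum: Weather) -> list[SiteSummary]:
        return [s for s in self.summaries if s.stratum is stratum]


def build_sample_records(
    plates: Sequence[PlateWell], metadata: pd.DataFrame
) -> tuple[list[SampleRecord], dict[str, str]]:
    """Join sample wells (3 per sample) onto metadata rows.

    Returns the records plus a sample_id -> lab_id map (the lab that ran
    the sample's plate, whose master curve quantifies it).
    """
    wells_by_sample: dict[str, list[PlateWell]] = {}
    lab_for_sample: dict[str, str] = {}
    for w in plates:
        if w.role is not Role.SAMPLE or w.target is not Target.HF183:
            continue
        wells_by_sample.setdefault(w.sample_id, []).append(w)
        lab_for_sample[w.sample_id] = w.lab_id

    def _none_if_nan(value):
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return None
        return float(value)

    has_sketa = "sketa22_cq" in metadata.columns
    records: list[SampleRecord] = []
    for row in metadata.itertuples(index=False):
        wells = wells_by_sample.get(row.sample_id)
        if wells is None:
            raise ValidationError(
                f"sample {row.sample_id} has metadata but no plate wells"
            )
        if len(wells) != 3:
            raise ValidationError(
                f"sample {row.sample_id} has {len(wells)} replicate wells; "
                "expected 3"
            )
        rec = SampleRecord(
            sample_id=row.sample_id,
            site_id=row.site_id,
            timestamp=row.timestamp,
            volume_filtered_ml=row.volume_filtered_ml,
            replicates=[ReplicateMeasurement(cq=w.cq) for w in wells],
            sketa22_cq=_none_if_nan(getattr(row, "sketa22_cq", None))
            if has_sketa else None,
            enterococcus_per_100ml=_none_if_nan(row.enterococcus_per_100ml),
        )
        records.append(rec)
    return records, lab_for_sample


def analyze_campaign(
    plates: Sequence[PlateWell],
    metadata: pd.DataFrame,
    rain: pd.DataFrame,
    *,
    volumes: Optional[VolumeConfig] = None,
    scheme: SubstitutionScheme = SubstitutionScheme.POISSON,
    ranking_definition: Positivity = Positivity.AMP1,
    reference_sketa22_cq: Optional[float] = None,
    iterative_outliers: bool = True,
) -> CampaignResult:
    """Run the full analysis on one campaign's tables."""
    volumes = volumes or VolumeConfig()
    curves = calibrate_all_labs(plates, iterative=iterative_outliers)

    samples, lab_for_sample = build_sample_records(plates, metadata)
    gauge_for_sample = dict(zip(metadata["sample_id"], metadata["gauge_id"]))
    events = detect_wet_events(rain)
    events_by_gauge: dict[str, list] = {}
    for ev in events:
        events_by_gauge.setdefault(ev.gauge_id, []).append(ev)
    assign_weather(samples, events_by_gauge, gauge_for_sample)

    curve_lookup = lambda s: lab_for_sample[s.sample_id]
    summaries: list[SiteSummary] = []
    for stratum in (Weather.DRY, Weather.WET):
        by_site: dict[str, list[SampleRecord]] = {}
        for s in samples:
            if s.weather is stratum:
                by_site.setdefault(s.site_id, []).append(s)
        for site_id in sorted(by_site):
            summaries.append(
                summarize_site(
                    by_site[site_id], site_id, stratum, scheme,
                    curves, volumes, curve_lookup,
                )
            )

    qc, retained = qc_report(
        plates, samples, summaries, reference_sketa22_cq=reference_sketa22_cq
    )

    result = CampaignResult(
        curves=curves,
        samples=samples,
        summaries=retained,
        qc=qc,
        lab_for_sample=lab_for_sample,
    )

    freq_metric = f"freq_{ranking_definition.value}"
    for stratum in (Weather.DRY, Weather.WET):
        subset = result.summaries_for(stratum)
        if len(subset) < 2:
            continue
        by_freq = rank_sites(subset, freq_metric)
        by_conc = rank_sites(subset, "geomean_hf183")
        result.rankings.extend([by_freq, by_conc])
        result.freq_vs_conc[stratum.value] = rank_concordance(by_freq, by_conc)
        if all(s.entero_geomean is not None for s in subset):
            result.rankings.append(rank_sites(subset, "entero_geomean"))

    dry = result.summaries_for(Weather.DRY)
    wet = result.summaries_for(Weather.WET)
    if len({s.site_id for s in dry} & {s.site_id for s in wet}) >= 2:
        result.dry_vs_wet, result.wet_decrease_sites = dry_wet_comparison(
            dry, wet, freq_metric
        )
    return result


def reaction_detection_rates(result: CampaignResult) -> dict[str, float]:
    """Percent of sample reactions amplified, by stratum, and the percent
    of those detections that are quantifiable."""
    out: dict[str, float] = {}
    for stratum in (Weather.DRY, Weather.WET):
        reps = [
            r
            for s in result.samples
            if s.weather is stratum
            for r in s.replicates
        ]
        if not reps:
            continue
        amped = [r for r in reps if r.cq is not None]
        out[f"pct_reactions_detected_{stratum.value.lower()}"] = (
            100.0 * len(amped) / len(reps)
        )
    return out
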
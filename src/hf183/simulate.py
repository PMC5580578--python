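"""Seeded synthetic monitoring campaigns with the statistical structure the
analysis assumes.

Site contamination follows a zero-inflated lognormal: each water sample
carries the human marker with a site- and stratum-specific prevalence,
and a contaminated sample's concentration (copies/100 mL) is lognormal,
scaled up in wet weather. Template copies reach each of the three qPCR
replicates by Poisson subsampling of the expected copies/reaction, and a
replicate amplifies exactly when at least one copy is present, with
Cq = intercept + slope * log10(copies) + Gaussian noise under the plate
lab's true curve. Enterococcus counts are lognormal with a configurable
latent coupling to the sample's HF183 state. Rain is a daily single-gauge
series with isolated winter storms, so every wet sample sits inside a
qualifying 72-h event window and every dry sample is clear of storms and
inside the April-October recreational season.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as hio
from .model import (
    PlateWell,
    Role,
    Target,
    ValidationError,
    VolumeConfig,
    Weather,
)
from .weather_qc import in_season

WELL_ORDER = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]

# 6-point, 10-fold dilution series ending at the 1-copy LOD level
STANDARD_COPIES = [1e5, 1e4, 1e3, 1e2, 1e1, 1e0]


@dataclass(frozen=True)
class SiteTruth:
    """Ground-truth contamination parameters for one site."""

    site_id: str
    prevalence_dry: float
    prevalence_wet: float
    log10_mean_conc: float   # of copies/100 mL given contamination
    log10_sd_conc: float
    wet_multiplier: float = 3.0
    entero_log10_mean: float = 2.4
    entero_log10_sd: float = 0.6
    entero_coupling: float = 0.0  # 0 = independent of HF183

    def __post_init__(self) -> None:
        for p in (self.prevalence_dry, self.prevalence_wet):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{self.site_id}: prevalence {p} not in [0,1]")
        if self.log10_sd_conc < 0 or self.entero_log10_sd < 0:
            raise ValidationError(f"{self.site_id}: negative lognormal sd")
        if self.wet_multiplier <= 0:
            raise ValidationError(f"{self.site_id}: wet_multiplier must be > 0")
        if not 0.0 <= self.entero_coupling <= 1.0:
            raise ValidationError(f"{self.site_id}: coupling not in [0,1]")


@dataclass
class SimulationConfig:
    """Full specification of a synthetic campaign."""

    sites: list[SiteTruth]
    samples_per_site_per_stratum: int = 50
    n_labs: int = 8
    lab_slopes: list[float] = field(default_factory=list)
    lab_intercepts: list[float] = field(default_factory=list)
    cq_noise_sd: float = 0.3
    volumes: VolumeConfig = field(default_factory=VolumeConfig)
    seed: int = 2017
    control_contamination_rate: float = 0.0
    sketa22_reference_cq: float = 22.0
    sketa22_noise_sd: float = 0.3
    entero_missing_rate: float = 0.05
    entero_wet_log10_shift: float = 0.73
    volume_filtered_ml: float = 100.0
    gauge_id: str = "G01"
    rain_start: str = "2014-04-01"
    rain_end: str = "2015-04-30"
    first_storm: str = "2014-11-05"
    storm_interval_days: int = 8
    n_storms: int = 18
    storm_depth_inches: float = 0.4
    dry_sampling_start: str = "2014-04-01"

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValidationError("config requires at least one site")
        if len({s.site_id for s in self.sites}) != len(self.sites):
            raise ValidationError("duplicate site_id in config")
        if self.n_labs < 1:
            raise ValidationError("n_labs must be >= 1")
        if not self.lab_slopes:
            # evenly spaced true amplification efficiencies
            effs = np.linspace(0.91, 0.975, self.n_labs)
            self.lab_slopes = [-1.0 / math.log10(1.0 + e) for e in effs]
        if not self.lab_intercepts:
            self.lab_intercepts = list(np.linspace(36.5, 37.5, self.n_labs))
        if len(self.lab_slopes) != self.n_labs or len(self.lab_intercepts) != self.n_labs:
            raise ValidationError("lab curve parameter lists must match n_labs")
        if any(s >= 0 for s in self.lab_slopes):
            raise ValidationError("lab slopes must be negative")
        if self.cq_noise_sd < 0:
            raise ValidationError("cq_noise_sd must be >= 0")
        if not 0.0 <= self.control_contamination_rate <= 1.0:
            raise ValidationError("control_contamination_rate not in [0,1]")
        if self.samples_per_site_per_stratum < 1:
            raise ValidationError("samples_per_site_per_stratum must be >= 1")
        wet_slots = 3 * self.n_storms
        if wet_slots < self.samples_per_site_per_stratum:
            raise ValidationError(
                f"{self.n_storms} storms provide {wet_slots} wet sampling "
                f"slots < {self.samples_per_site_per_stratum} requested"
            )


@dataclass
class Campaign:
    """In-memory synthetic campaign: plates, metadata, rain, ground truth."""

    plates: list[PlateWell]
    metadata: pd.DataFrame
    rain: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def draw_replicate_copies(rng: np.random.Generator, mean_copies: float, n: int = 3):
    """Poisson subsampling of template into n replicate reactions."""
    return rng.poisson(mean_copies, size=n)


def replicate_cq(
    rng: np.random.Generator,
    copies: int,
    slope: float,
    intercept: float,
    noise_sd: float,
) -> Optional[float]:
    """Cq of one replicate, or None when no template copy was delivered."""
    if copies < 1:
        return None
    return intercept + slope * math.log10(copies) + rng.normal(0.0, noise_sd)


def _storm_days(config: SimulationConfig) -> list[pd.Timestamp]:
    first = pd.Timestamp(config.first_storm)
    return [
        first + pd.Timedelta(days=config.storm_interval_days * i)
        for i in range(config.n_storms)
    ]


def simulate_rain(config: SimulationConfig) -> pd.DataFrame:
    """Daily rain series: zero depth except isolated storm days."""
    days = pd.date_range(config.rain_start, config.rain_end, freq="D")
    storms = set(_storm_days(config))
    depth = [config.storm_depth_inches if d in storms else 0.0 for d in days]
    return pd.DataFrame(
        {"gauge_id": config.gauge_id, "timestamp": days, "depth_inches": depth}
    )


def _dry_sampling_times(config: SimulationConfig) -> list[pd.Timestamp]:
    start = pd.Timestamp(config.dry_sampling_start) + pd.Timedelta(hours=8)
    times: list[pd.Timestamp] = []
    t = start
    while len(times) < config.samples_per_site_per_stratum:
        if in_season(t):
            times.append(t)
        t += pd.Timedelta(days=7)
        if (t - start).days > 5 * 365:
            raise ValidationError("could not schedule dry samples inside season")
    return times


def _wet_sampling_times(config: SimulationConfig) -> list[pd.Timestamp]:
    times: list[pd.Timestamp] = []
    for storm in _storm_days(config):
        for offset_h in (6, 30, 54):
            times.append(storm + pd.Timedelta(hours=offset_h))
    return times[: config.samples_per_site_per_stratum]


def _simulate_one_sample(
    rng: np.random.Generator,
    site: SiteTruth,
    stratum: Weather,
    config: SimulationConfig,
) -> dict:
    """Latent state and replicate copy counts for one water sample."""
    wet = stratum is Weather.WET
    prevalence = site.prevalence_wet if wet else site.prevalence_dry
    contaminated = rng.random() < prevalence
    z_hf = rng.normal()
    if contaminated:
        conc = 10.0 ** (site.log10_mean_conc + site.log10_sd_conc * z_hf)
        if wet:
            conc *= site.wet_multiplier
    else:
        conc = 0.0
    mu = conc / config.volumes.factor(config.volume_filtered_ml)
    copies = draw_replicate_copies(rng, mu)

    rho = site.entero_coupling
    z_e = rho * z_hf + math.sqrt(1.0 - rho * rho) * rng.normal()
    log10_entero = (
        site.entero_log10_mean
        + (config.entero_wet_log10_shift if wet else 0.0)
        + site.entero_log10_sd * z_e
    )
    entero = 10.0 ** log10_entero
    if rng.random() < config.entero_missing_rate:
        entero = None
    sketa = rng.normal(config.sketa22_reference_cq, config.sketa22_noise_sd)
    return {
        "contaminated": contaminated,
        "true_conc": conc,
        "copies": copies,
        "entero": entero,
        "sketa22_cq": sketa,
    }


def _plate_wells_for_chunk(
    rng: np.random.Generator,
    plate_id: str,
    lab_idx: int,
    chunk: list[dict],
    config: SimulationConfig,
) -> list[PlateWell]:
    """One 96-well plate: 18 standards, 3 NTC, 6 NEC, up to 66 sample wells."""
    slope = config.lab_slopes[lab_idx]
    intercept = config.lab_intercepts[lab_idx]
    lab_id = f"L{lab_idx + 1:02d}"
    wells: list[PlateWell] = []
    pos = iter(WELL_ORDER)

    for copies in STANDARD_COPIES:
        for _ in range(3):
            cq = intercept + slope * math.log10(copies) + rng.normal(
                0.0, config.cq_noise_sd
            )
            wells.append(
                PlateWell(
                    plate_id=plate_id, lab_id=lab_id, well=next(pos),
                    role=Role.STANDARD, target=Target.HF183,
                    cq=cq, standard_copies=copies,
                )
            )
    for role, count in ((Role.NTC, 3), (Role.NEC, 6)):
        for _ in range(count):
            cq = None
            if rng.random() < config.control_contamination_rate:
                cq = rng.uniform(37.5, 42.0)
            wells.append(
                PlateWell(
                    plate_id=plate_id, lab_id=lab_id, well=next(pos),
                    role=role, target=Target.HF183, cq=cq,
                )
            )
    for entry in chunk:
        for rep_copies in entry["copies"]:
            cq = replicate_cq(rng, int(rep_copies), slope, intercept,
                              config.cq_noise_sd)
            wells.append(
                PlateWell(
                    plate_id=plate_id, lab_id=lab_id, well=next(pos),
                    role=Role.SAMPLE, target=Target.HF183,
                    cq=cq, sample_id=entry["sample_id"],
                )
            )
    return wells


def simulate_campaign(config: SimulationConfig) -> Campaign:
    """Generate plates, metadata, rain series and truth tables.

    Byte-identical outputs are guaranteed for a fixed config and seed.
    """
    rng = np.random.default_rng(config.seed)
    rain = simulate_rain(config)

    dry_times = _dry_sampling_times(config)
    wet_times = _wet_sampling_times(config)

    samples: list[dict] = []
    for site in config.sites:
        for stratum, times, tag in (
            (Weather.DRY, dry_times, "D"),
            (Weather.WET, wet_times, "W"),
        ):
            for i, t in enumerate(times):
                entry = _simulate_one_sample(rng, site, stratum, config)
                entry.update(
                    sample_id=f"{site.site_id}-{tag}{i + 1:03d}",
                    site_id=site.site_id,
                    timestamp=t,
                    stratum=stratum.value,
                )
                samples.append(entry)

    # plates of 22 samples in chronological order, labs round-robin
    samples.sort(key=lambda e: (e["timestamp"], e["site_id"]))
    plates: list[PlateWell] = []
    for p, start in enumerate(range(0, len(samples), 22)):
        chunk = samples[start:start + 22]
        plates.extend(
            _plate_wells_for_chunk(
                rng, f"P{p + 1:04d}", p % config.n_labs, chunk, config
            )
        )

    metadata = pd.DataFrame(
        [
            {
                "sample_id": e["sample_id"],
                "site_id": e["site_id"],
                "timestamp": e["timestamp"],
                "volume_filtered_ml": config.volume_filtered_ml,
                "enterococcus_per_100ml": e["entero"],
                "gauge_id": config.gauge_id,
                "sketa22_cq": e["sketa22_cq"],
            }
            for e in samples
        ]
    )
    truth = pd.DataFrame(
        [
            {
                "sample_id": e["sample_id"],
                "site_id": e["site_id"],
                "stratum": e["stratum"],
                "contaminated": e["contaminated"],
                "true_conc_per_100ml": e["true_conc"],
            }
            for e in samples
        ]
    )
    site_truth = pd.DataFrame([dataclasses.asdict(s) for s in config.sites])
    truth = truth.merge(site_truth, on="site_id", how="left")
    return Campaign(
        plates=plates, metadata=metadata, rain=rain, truth=truth, config=config
    )


def default_study_like_scenario(seed: int = 2017) -> SimulationConfig:
    """The campaign design the analysis is exercised on by default.

    22 sites sampled in both strata, 50 samples per site per stratum,
    8 labs. Dry-weather prevalences include two zero-prevalence sites, a
    mid-range band of fifteen sites, and five high-prevalence sites with
    one at 1.0; contaminated-sample concentration scale increases with
    prevalence (persistent sources run at higher concentration). Wet
    prevalence generally exceeds dry, except at three sites where it
    drops. The seed is part of the scenario definition.
    """
    prev_dry = (
        [0.0, 0.0]
        + list(np.linspace(0.15, 0.38, 15))
        + [0.5, 0.62, 0.75, 0.88, 1.0]
    )
    sites: list[SiteTruth] = []
    for i, p in enumerate(prev_dry):
        if i in (10, 11, 12):  # sites whose contamination shrinks in wet weather
            p_wet = round(0.6 * p, 4)
        else:
            p_wet = round(min(1.0, 0.2 + 1.3 * p), 4)
        sites.append(
            SiteTruth(
                site_id=f"S{i + 1:02d}",
                prevalence_dry=round(p, 4),
                prevalence_wet=p_wet,
                log10_mean_conc=round(2.3 + 1.8 * p, 4),
                log10_sd_conc=0.6,
                wet_multiplier=3.0,
                entero_log10_mean=round(2.0 + 0.6 * ((i * 7) % 22) / 21, 4),
                entero_log10_sd=0.6,
                entero_coupling=0.3,
            )
        )
    return SimulationConfig(sites=sites, seed=seed)


def write_campaign(campaign: Campaign, outdir) -> dict[str, Path]:
    """Write plates.csv, metadata.csv, rain.csv, truth.csv and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plates": outdir / "plates.csv",
        "metadata": outdir / "metadata.csv",
        "rain": outdir / "rain.csv",
        "truth": outdir / "truth.csv",
        "manifest": outdir / "manifest.json",
    }
    hio.write_plate_table(campaign.plates, paths["plates"])

    meta = campaign.metadata.copy()
    meta["timestamp"] = meta["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S")
    for col in ("volume_filtered_ml", "enterococcus_per_100ml", "sketa22_cq"):
        meta[col] = meta[col].map(hio._fmt)
    meta.to_csv(paths["metadata"], index=False)

    rain = campaign.rain.copy()
    rain["timestamp"] = rain["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S")
    rain["depth_inches"] = rain["depth_inches"].map(hio._fmt)
    rain.to_csv(paths["rain"], index=False)

    campaign.truth.to_csv(paths["truth"], index=False, float_format="%.6g")

    cfg = dataclasses.asdict(campaign.config)
    cfg["sites"] = [dataclasses.asdict(s) for s in campaign.config.sites]
    cfg["volumes"] = dataclasses.asdict(campaign.config.volumes)
    paths["manifest"].write_text(json.dumps(cfg, indent=2, sort_keys=True))
    return paths
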
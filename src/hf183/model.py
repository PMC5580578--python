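"""Shared data model for HF183 qPCR monitoring campaigns.

A campaign consists of 96-well qPCR plate tables (standards, environmental
samples, and negative controls, each run in triplicate), per-sample metadata
(site, timestamp, volume filtered, Enterococcus count), and rain-gauge
series used to stratify samples into wet- and dry-weather sets.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

MAX_CQ = 45.0
STANDARD_LOG10_RANGE = (0, 6)  # 1 to 1e6 copies/reaction, 10-fold steps

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


class ParseError(ValidationError):
    """An on-disk table could not be parsed into valid records."""


class InsufficientDataError(ValueError):
    """Not enough observations to carry out an estimation step."""


class Role(str, enum.Enum):
    STANDARD = "STANDARD"
    SAMPLE = "SAMPLE"
    NTC = "NTC"    # no-template control
    NEC = "NEC"    # negative extraction control


class Target(str, enum.Enum):
    HF183 = "HF183"
    SKETA22 = "SKETA22"


class CensorClass(str, enum.Enum):
    ND = "ND"          # no amplification
    DBLOD = "DBLOD"    # amplified, estimated < 1 copy/reaction
    DNQ = "DNQ"        # detected, 1 <= copies < 10
    QUANT = "QUANT"    # quantifiable, copies >= 10


class Weather(str, enum.Enum):
    DRY = "DRY"
    WET = "WET"
    EXCLUDED = "EXCLUDED"


class Positivity(str, enum.Enum):
    """The seven alternative definitions of an HF183-positive sample.

    AMPk: at least k of 3 replicates amplified (any Cq).
    DETk: at least k of 3 replicates detected at or above the LOD
          (censor class DNQ or QUANT).
    MEANGT_LOD: the sample geometric-mean concentration, with ND
          substituted by half the LOD and DBLOD by the LOD, exceeds the
          LOD expressed in copies per 100 mL.
    """

    AMP1 = "AMP1"
    AMP2 = "AMP2"
    AMP3 = "AMP3"
    DET1 = "DET1"
    DET2 = "DET2"
    DET3 = "DET3"
    MEANGT_LOD = "MEANGT_LOD"


class SubstitutionScheme(str, enum.Enum):
    POISSON = "POISSON"
    HALF_LOD = "HALF_LOD"


@dataclass(frozen=True)
class PlateWell:
    """One qPCR reaction on a 96-well plate."""

    plate_id: str
    lab_id: str
    well: str
    role: Role
    target: Target
    cq: Optional[float] = None                # None = no amplification
    standard_copies: Optional[float] = None   # present iff role == STANDARD
    sample_id: Optional[str] = None           # present iff role == SAMPLE

    def __post_init__(self) -> None:
        if not _WELL_RE.match(self.well):
            raise ValidationError(
                f"invalid well position {self.well!r} on plate {self.plate_id}"
            )
        if self.cq is not None and not (0.0 < self.cq <= MAX_CQ):
            raise ValidationError(
                f"Cq {self.cq} out of (0, {MAX_CQ}] in well {self.well} "
                f"of plate {self.plate_id}"
            )
        if self.role is Role.STANDARD:
            if self.standard_copies is None or self.standard_copies <= 0:
                raise ValidationError(
                    f"STANDARD well {self.well} of plate {self.plate_id} "
                    "requires positive standard_copies"
                )
        elif self.standard_copies is not None:
            raise ValidationError(
                f"{self.role.value} well {self.well} must not carry standard_copies"
            )
        if self.role is Role.SAMPLE:
            if not self.sample_id:
                raise ValidationError(
                    f"SAMPLE well {self.well} of plate {self.plate_id} "
                    "requires sample_id"
                )
        elif self.sample_id:
            raise ValidationError(
                f"{self.role.value} well {self.well} of plate {self.plate_id} "
                "must not carry sample_id"
            )


@dataclass(frozen=True)
class VolumeConfig:
    """Volumes linking copies/reaction to copies per 100 mL of water.

    One filter captures ``volume_filtered_ml`` of water, DNA is eluted in
    ``elution_volume_ul``, and ``template_volume_ul`` goes into each
    reaction, so

        conc[copies/100 mL] = copies/reaction
                              x (elution/template) x (100 / volume filtered).

    The defaults give a composite factor of 78.9 at 100 mL filtered, under
    which 1 and 10 copies/reaction correspond to 79 and 789 copies/100 mL.
    """

    elution_volume_ul: float = 157.8
    template_volume_ul: float = 2.0
    reference_volume_ml: float = 100.0

    def __post_init__(self) -> None:
        if self.elution_volume_ul <= 0 or self.template_volume_ul <= 0:
            raise ValidationError("volumes must be positive")
        if self.template_volume_ul > self.elution_volume_ul:
            raise ValidationError("template volume cannot exceed elution volume")

    def factor(self, volume_filtered_ml: float) -> float:
        """Multiplier from copies/reaction to copies/100 mL."""
        if volume_filtered_ml <= 0:
            raise ValidationError("volume_filtered_ml must be positive")
        return (self.elution_volume_ul / self.template_volume_ul) * (
            self.reference_volume_ml / volume_filtered_ml
        )


@dataclass
class ReplicateMeasurement:
    """One of the three technical qPCR replicates of a water sample."""

    cq: Optional[float] = None
    copies_per_reaction: Optional[float] = None
    conc_per_100ml: Optional[float] = None
    censor_class: Optional[CensorClass] = None


@dataclass
class SampleRecord:
    """One water sample: three qPCR replicates plus field metadata."""

    sample_id: str
    site_id: str
    timestamp: pd.Timestamp
    volume_filtered_ml: float = 100.0
    replicates: list[ReplicateMeasurement] = field(default_factory=list)
    sketa22_cq: Optional[float] = None
    enterococcus_per_100ml: Optional[float] = None
    weather: Optional[Weather] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.volume_filtered_ml <= 100.0):
            raise ValidationError(
                f"volume_filtered_ml {self.volume_filtered_ml} out of (0, 100] "
                f"for sample {self.sample_id}"
            )

    def validate_replicates(self) -> None:
        if len(self.replicates) != 3:
            raise ValidationError(
                f"sample {self.sample_id} has {len(self.replicates)} "
                "replicates; exactly 3 required"
            )


@dataclass
class StandardCurve:
    """Per-lab master calibration of Cq against log10 copies/reaction."""

    lab_id: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_points_used: int
    outliers_removed: list[tuple[float, float]] = field(default_factory=list)
    lod_copies: float = 1.0
    lloq_copies: float = 10.0
    lod_cq: Optional[float] = None
    lloq_cq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValidationError(
                f"standard curve for lab {self.lab_id} has non-negative slope "
                f"{self.slope}; Cq must decrease with template quantity"
            )

    def validate_limits(self) -> None:
        """Check LLOQ amplifies earlier (lower Cq) than LOD."""
        if self.lod_cq is None or self.lloq_cq is None:
            raise ValidationError(f"lab {self.lab_id}: detection limits unset")
        if not self.lloq_cq < self.lod_cq:
            raise ValidationError(
                f"lab {self.lab_id}: lloq_cq {self.lloq_cq} must be below "
                f"lod_cq {self.lod_cq}"
            )


@dataclass
class SiteSummary:
    """Per-site, per-stratum monitoring metrics."""

    site_id: str
    stratum: Weather
    n_samples: int
    freq: dict[Positivity, float] = field(default_factory=dict)
    geomean_hf183: Optional[float] = None       # copies/100 mL
    entero_exceed_pct: Optional[float] = None    # % samples > SSM
    entero_exceed_100x_pct: Optional[float] = None
    entero_geomean: Optional[float] = None       # per 100 mL
    n_entero: int = 0

    def __post_init__(self) -> None:
        for defn, pct in self.freq.items():
            if not (0.0 <= pct <= 100.0):
                raise ValidationError(
                    f"{self.site_id}/{self.stratum.value}: frequency "
                    f"{pct} for {defn.value} outside [0, 100]"
                )


@dataclass
class RankingResult:
    """Sites ordered by one metric; rank 1 = most contaminated."""

    metric_id: str
    stratum: str
    entries: list[tuple[str, int, float]]  # (site_id, rank, metric value)
    tie_policy: str = "secondary_metric_then_site_id"

    @property
    def ranks(self) -> dict[str, int]:
        return {site: rank for site, rank, _ in self.entries}

    def validate(self) -> None:
        ranks = sorted(rank for _, rank, _ in self.entries)
        if ranks != list(range(1, len(self.entries) + 1)):
            raise ValidationError(
                f"ranking {self.metric_id}/{self.stratum} is not a "
                "permutation of 1..n"
            )


@dataclass
class ConcordanceReport:
    """Agreement between two site rankings over the same site set."""

    spearman_rho: float
    shifts: dict[str, int]          # rank_b - rank_a per site
    n_sites_shifted: int
    max_shift_site: Optional[str]

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.spearman_rho <= 1.0 + 1e-12:
            raise ValidationError(f"spearman rho {self.spearman_rho} outside [-1, 1]")
        if sum(self.shifts.values()) != 0:
            raise ValidationError("signed rank shifts must sum to zero")


@dataclass(frozen=True)
class WetEvent:
    """A qualifying rain event: >=0.10 in. after >=3 antecedent dry days."""

    gauge_id: str
    start: pd.Timestamp
    window_end: pd.Timestamp  # start + 72 h


@dataclass
class QCReport:
    """Quality-control outcome for a campaign."""

    pct_clean_control_reactions: float
    flagged_controls: list[tuple[str, str, float]]  # (plate_id, well, cq)
    inhibited_samples: list[str] = field(default_factory=list)
    excluded_sites: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_clean_control_reactions <= 100.0):
            raise ValidationError("pct_clean must lie in [0, 100]")


def geomean(values: Sequence[float]) -> float:
    """Geometric mean: arithmetic mean on the log10 scale, back-transformed."""
    vals = list(values)
    if not vals:
        raise InsufficientDataError("geomean of empty sequence")
    if any(v <= 0 for v in vals):
        raise ValidationError("geomean requires strictly positive values")
    return 10.0 ** (sum(math.log10(v) for v in vals) / len(vals))
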
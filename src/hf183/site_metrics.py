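"""Per-site, per-stratum metrics: positivity frequencies, geometric-mean
HF183 concentration, and Enterococcus exceedance statistics.

Seven alternative definitions of a "positive" sample are supported (any /
at least two / all three replicates amplified; the same ladder restricted
to detections at or above the LOD; and a sample-mean-above-LOD rule).
The site average concentration is the geometric mean over all replicate
concentrations pooled across the site's samples, with censored replicates
substituted beforehand. Enterococcus metrics use the California Ocean
Plan single sample maximum (SSM) of 104 per 100 mL.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .model import (
    CensorClass,
    InsufficientDataError,
    Positivity,
    SampleRecord,
    SiteSummary,
    StandardCurve,
    SubstitutionScheme,
    ValidationError,
    VolumeConfig,
    Weather,
    geomean,
)
from .quantification import quantify_sample, substitute_censored

ENTERO_SSM = 104.0
ENTERO_FOLD = 100.0

_AMP_K = {Positivity.AMP1: 1, Positivity.AMP2: 2, Positivity.AMP3: 3}
_DET_K = {Positivity.DET1: 1, Positivity.DET2: 2, Positivity.DET3: 3}


def _ensure_classified(
    sample: SampleRecord, curve: StandardCurve, volumes: VolumeConfig
) -> None:
    if any(r.censor_class is None for r in sample.replicates):
        quantify_sample(sample, curve, volumes)


def sample_positive(
    sample: SampleRecord,
    definition: Positivity,
    curve: StandardCurve,
    volumes: VolumeConfig,
) -> bool:
    """Is this sample HF183-positive under the given definition?"""
    _ensure_classified(sample, curve, volumes)
    reps = sample.replicates
    n_amp = sum(1 for r in reps if r.cq is not None)
    n_det = sum(
        1 for r in reps if r.censor_class in (CensorClass.DNQ, CensorClass.QUANT)
    )
    if definition in _AMP_K:
        return n_amp >= _AMP_K[definition]
    if definition in _DET_K:
        return n_det >= _DET_K[definition]
    if definition is Positivity.MEANGT_LOD:
        factor = volumes.factor(sample.volume_filtered_ml)
        concs = []
        for r in reps:
            if r.censor_class is CensorClass.ND:
                concs.append(0.5 * curve.lod_copies * factor)
            elif r.censor_class is CensorClass.DBLOD:
                concs.append(1.0 * curve.lod_copies * factor)
            else:
                concs.append(r.copies_per_reaction * factor)
        gm, threshold = geomean(concs), curve.lod_copies * factor
        # strict exceedance; guard against round-trip float error at the LOD
        return gm > threshold and not math.isclose(gm, threshold, rel_tol=1e-9)
    raise ValidationError(f"unknown positivity definition {definition!r}")


def site_frequency(
    samples: Sequence[SampleRecord],
    definition: Positivity,
    curve_for: "dict[str, StandardCurve] | StandardCurve",
    volumes: VolumeConfig,
    curve_lookup=None,
) -> float:
    """Percentage of samples positive under one definition."""
    if not samples:
        raise InsufficientDataError("site_frequency needs >= 1 sample")
    n_pos = sum(
        1
        for s in samples
        if sample_positive(s, definition, _resolve(curve_for, s, curve_lookup), volumes)
    )
    return 100.0 * n_pos / len(samples)


def _resolve(curve_for, sample: SampleRecord, curve_lookup) -> StandardCurve:
    if isinstance(curve_for, StandardCurve):
        return curve_for
    key = curve_lookup(sample) if curve_lookup else sample.sample_id
    return curve_for[key]


def site_geomean_hf183(
    samples: Sequence[SampleRecord],
    scheme: SubstitutionScheme,
    curve_for: "dict[str, StandardCurve] | StandardCurve",
    volumes: VolumeConfig,
    curve_lookup=None,
) -> float:
    """Geomean over all replicate concentrations pooled across samples."""
    if not samples:
        raise InsufficientDataError("site_geomean_hf183 needs >= 1 sample")
    pooled: list[float] = []
    for s in samples:
        curve = _resolve(curve_for, s, curve_lookup)
        pooled.extend(substitute_censored(s, curve, volumes, scheme))
    return geomean(pooled)


def entero_metrics(
    samples: Sequence[SampleRecord],
    ssm: float = ENTERO_SSM,
    fold: float = ENTERO_FOLD,
) -> tuple[float, float, float]:
    """(exceedance %, 100x-exceedance %, geomean) of Enterococcus counts.

    Samples without an Enterococcus measurement are excluded from the
    denominator; zero counts are floored at 1 per 100 mL for the geomean.
    """
    counts = [
        s.enterococcus_per_100ml
        for s in samples
        if s.enterococcus_per_100ml is not None
    ]
    if not counts:
        raise InsufficientDataError("no Enterococcus measurements at site")
    exceed = 100.0 * sum(1 for c in counts if c > ssm) / len(counts)
    exceed_fold = 100.0 * sum(1 for c in counts if c > fold * ssm) / len(counts)
    gm = geomean([max(c, 1.0) for c in counts])
    return exceed, exceed_fold, gm


def summarize_site(
    samples: Sequence[SampleRecord],
    site_id: str,
    stratum: Weather,
    scheme: SubstitutionScheme,
    curve_for: "dict[str, StandardCurve] | StandardCurve",
    volumes: VolumeConfig,
    curve_lookup=None,
) -> SiteSummary:
    """All metrics for one site-stratum cell."""
    freq = {
        d: site_frequency(samples, d, curve_for, volumes, curve_lookup)
        for d in Positivity
    }
    gm = site_geomean_hf183(samples, scheme, curve_for, volumes, curve_lookup)
    n_entero = sum(1 for s in samples if s.enterococcus_per_100ml is not None)
    if n_entero:
        ex, ex100, egm = entero_metrics(samples)
    else:
        ex = ex100 = egm = None
    return SiteSummary(
        site_id=site_id,
        stratum=stratum,
        n_samples=len(samples),
        freq=freq,
        geomean_hf183=gm,
        entero_exceed_pct=ex,
        entero_exceed_100x_pct=ex100,
        entero_geomean=egm,
        n_entero=n_entero,
    )
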
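"""Cq-to-concentration conversion and Poisson-based censored substitution.

A replicate reaction falls in one of four censor classes by its estimated
copies/reaction: ND (no amplification), DBLOD (< 1 copy, below the limit
of detection), DNQ (1-10 copies, detectable but not quantifiable), or
QUANT (>= 10 copies). Censored replicates are never set to zero. Under
the POISSON scheme, the sample's per-reaction template mean lambda is
estimated — from the quantified replicates when any exist, otherwise from
the amplification pattern by a most-probable-number (MPN) style Poisson
model — and ND replicates are replaced by lambda (the unconditional
Poisson mean) while DBLOD replicates are replaced by
lambda / (1 - exp(-lambda)), the mean number of copies conditional on at
least one copy being present. The HALF_LOD scheme substitutes the
conventional 1/2 LOD for ND and 1 LOD for DBLOD.
"""

from __future__ import annotations

import enum
import math
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import integrate

from .model import (
    CensorClass,
    InsufficientDataError,
    SampleRecord,
    StandardCurve,
    SubstitutionScheme,
    ValidationError,
    VolumeConfig,
    geomean,
)


class LambdaMethod(str, enum.Enum):
    MPN_MLE = "MPN_MLE"
    BAYES_POSTERIOR_MEAN = "BAYES_POSTERIOR_MEAN"


def cq_to_copies(cq: float, curve: StandardCurve) -> float:
    """Invert the master curve: copies/reaction = 10^((Cq - b) / m)."""
    if cq is None:
        raise ValidationError("cq is absent; route non-detects elsewhere")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def classify_replicate(cq: Optional[float], curve: StandardCurve) -> CensorClass:
    """Censor class of one reaction given the lab's calibration.

    Boundaries are closed on the more-quantifiable side: exactly 1
    copy/reaction is DNQ, exactly 10 copies is QUANT.
    """
    if cq is None:
        return CensorClass.ND
    copies = cq_to_copies(cq, curve)
    if copies < curve.lod_copies:
        return CensorClass.DBLOD
    if copies < curve.lloq_copies:
        return CensorClass.DNQ
    return CensorClass.QUANT


def copies_to_conc(
    copies_per_reaction: float,
    volume_filtered_ml: float,
    volumes: VolumeConfig,
) -> float:
    """Convert copies/reaction to copies per 100 mL of source water."""
    if copies_per_reaction < 0:
        raise ValidationError("copies_per_reaction must be non-negative")
    return copies_per_reaction * volumes.factor(volume_filtered_ml)


def _pattern_log_likelihood(lam: float, n: int, k: int) -> float:
    # P(replicate amplifies) = 1 - exp(-lam) under Poisson subsampling
    if lam <= 0:
        return 0.0 if k == 0 else -math.inf
    p = -math.expm1(-lam)
    return k * math.log(p) + (n - k) * (-lam)


def estimate_lambda(
    n_replicates: int,
    k_amplified: int,
    method: LambdaMethod = LambdaMethod.MPN_MLE,
    prior_upper: float = 10.0,
) -> float:
    """Mean template copies/reaction from a presence/absence pattern.

    MPN_MLE maximizes the binomial likelihood with detection probability
    1 - exp(-lambda), giving -ln(1 - k/n); it is undefined (infinite) when
    all replicates amplified. BAYES_POSTERIOR_MEAN is the posterior mean
    of lambda under that likelihood and a uniform prior on
    [0, prior_upper], defined for every pattern including k = 0 and k = n.
    """
    n, k = int(n_replicates), int(k_amplified)
    if n < 1 or not 0 <= k <= n:
        raise ValidationError(f"invalid pattern k={k} of n={n}")
    if method is LambdaMethod.MPN_MLE:
        if k == 0:
            return 0.0
        if k == n:
            raise ValidationError(
                "MPN MLE undefined when all replicates amplified; "
                "use quantified Cq values or the Bayes estimator"
            )
        return -math.log(1.0 - k / n)
    if method is LambdaMethod.BAYES_POSTERIOR_MEAN:
        if prior_upper <= 0:
            raise ValidationError("prior_upper must be positive")
        return _bayes_posterior_mean(n, k, float(prior_upper))
    raise ValidationError(f"unknown method {method!r}")


@lru_cache(maxsize=4096)
def _bayes_posterior_mean(n: int, k: int, prior_upper: float) -> float:
    lik = lambda lam: math.exp(_pattern_log_likelihood(lam, n, k))
    num, _ = integrate.quad(
        lambda lam: lam * lik(lam), 0.0, prior_upper,
        epsabs=0, epsrel=1e-10, limit=200,
    )
    den, _ = integrate.quad(
        lik, 0.0, prior_upper, epsabs=0, epsrel=1e-10, limit=200
    )
    return num / den


def conditional_mean_given_detection(lam: float) -> float:
    """E[copies | copies >= 1] for Poisson(lambda): lambda/(1 - e^-lambda)."""
    if lam <= 0:
        raise ValidationError("lambda must be positive")
    return lam / -math.expm1(-lam)


def quantify_sample(
    sample: SampleRecord, curve: StandardCurve, volumes: VolumeConfig
) -> None:
    """Fill each replicate's censor class, copies and concentration in place.

    ND and DBLOD replicates get class labels only; their concentrations are
    assigned by :func:`substitute_censored`.
    """
    sample.validate_replicates()
    for rep in sample.replicates:
        rep.censor_class = classify_replicate(rep.cq, curve)
        if rep.cq is not None:
            rep.copies_per_reaction = cq_to_copies(rep.cq, curve)
            rep.conc_per_100ml = copies_to_conc(
                rep.copies_per_reaction, sample.volume_filtered_ml, volumes
            )
        else:
            rep.copies_per_reaction = None
            rep.conc_per_100ml = None


def substitute_censored(
    sample: SampleRecord,
    curve: StandardCurve,
    volumes: VolumeConfig,
    scheme: SubstitutionScheme = SubstitutionScheme.POISSON,
    prior_upper: float = 10.0,
) -> list[float]:
    """Three strictly positive replicate concentrations (copies/100 mL).

    Quantifiable and DNQ replicates keep their measured concentrations.
    POISSON: lambda is the geometric mean of replicates at >= 1
    copy/reaction when any exist, else the Bayes posterior mean from the
    amplification pattern; ND <- lambda, DBLOD <- lambda/(1-e^-lambda).
    HALF_LOD: ND <- LOD/2, DBLOD <- LOD, in copy units before conversion.
    """
    if not isinstance(scheme, SubstitutionScheme):
        raise ValidationError(f"unknown substitution scheme {scheme!r}")
    sample.validate_replicates()
    if any(r.censor_class is None for r in sample.replicates):
        quantify_sample(sample, curve, volumes)

    factor = volumes.factor(sample.volume_filtered_ml)
    reps = sample.replicates

    if scheme is SubstitutionScheme.HALF_LOD:
        nd_sub = 0.5 * curve.lod_copies
        dblod_sub = 1.0 * curve.lod_copies
    else:
        above_lod = [
            r.copies_per_reaction
            for r in reps
            if r.censor_class in (CensorClass.DNQ, CensorClass.QUANT)
        ]
        if above_lod:
            lam = geomean(above_lod)
        else:
            k = sum(1 for r in reps if r.cq is not None)
            lam = estimate_lambda(
                len(reps), k, LambdaMethod.BAYES_POSTERIOR_MEAN, prior_upper
            )
        nd_sub = lam
        dblod_sub = conditional_mean_given_detection(lam)

    out: list[float] = []
    for rep in reps:
        if rep.censor_class is CensorClass.ND:
            conc = nd_sub * factor
        elif rep.censor_class is CensorClass.DBLOD:
            conc = dblod_sub * factor
        else:
            conc = rep.conc_per_100ml
        if conc is None or conc <= 0:
            raise InsufficientDataError(
                f"sample {sample.sample_id}: non-positive substituted "
                "concentration"
            )
        rep.conc_per_100ml = conc
        out.append(conc)
    return out


def replicate_table_rows(
    sample: SampleRecord, scheme: SubstitutionScheme
) -> list[dict]:
    """Tidy replicate-level rows for the quantification output CSV."""
    rows = []
    for i, rep in enumerate(sample.replicates, start=1):
        rows.append(
            {
                "sample_id": sample.sample_id,
                "rep_index": i,
                "cq": rep.cq,
                "censor_class": rep.censor_class.value if rep.censor_class else "",
                "copies_per_reaction": rep.copies_per_reaction,
                "conc_per_100ml": rep.conc_per_100ml,
                "scheme": scheme.value,
            }
        )
    return rows
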
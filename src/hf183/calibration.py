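"""Per-lab master standard curves with studentized-residual outlier removal.

Each lab's standard points (Cq vs. log10 copies/reaction, pooled over all
of that lab's plates) are fit by ordinary least squares. Points whose
externally studentized residual exceeds 3 are removed one at a time —
worst first, refitting after each removal — until none remain above the
threshold. Detection limits follow the plate design: the limit of
detection (LOD) is the lowest standard concentration, 1 copy/reaction,
expressed per lab as the mean observed Cq of the 1-copy standards; the
lower limit of quantification (LLOQ) is 10 copies/reaction, expressed as
the mean 10-copy Cq plus twice its standard deviation.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .model import (
    InsufficientDataError,
    PlateWell,
    Role,
    StandardCurve,
    Target,
    ValidationError,
)

RESIDUAL_THRESHOLD = 3.0


class DegenerateCurveError(ValidationError):
    """The fitted calibration has a non-negative slope."""


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency implied by a standard-curve slope.

    E = 10^(-1/slope) - 1; a perfectly doubling assay has slope
    -1/log10(2) = -3.3219 and E = 1.
    """
    if slope >= 0:
        raise ValidationError(f"slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def _ols(x: np.ndarray, y: np.ndarray):
    return sm.OLS(y, sm.add_constant(x)).fit()


def fit_master_curve(
    points: Sequence[tuple[float, float]],
    lab_id: str,
    *,
    residual_threshold: float = RESIDUAL_THRESHOLD,
    iterative: bool = True,
) -> StandardCurve:
    """Fit one lab's master curve from (log10 copies, Cq) pairs.

    Parameters
    ----------
    points
        Amplified standard reactions as (log10 copies/reaction, Cq).
    iterative
        If True (default), remove the single worst outlier per pass and
        refit until no externally studentized residual exceeds the
        threshold; if False, remove every point over the threshold in one
        pass from the initial fit.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len({round(x, 9) for x, _ in pts}) < 4:
        raise InsufficientDataError(
            f"lab {lab_id}: need >= 4 distinct standard concentrations"
        )

    kept = list(pts)
    removed: list[tuple[float, float]] = []

    def studentized(current: list[tuple[float, float]]) -> np.ndarray:
        x = np.array([p[0] for p in current])
        y = np.array([p[1] for p in current])
        fit = _ols(x, y)
        return np.asarray(OLSInfluence(fit).resid_studentized_external)

    if iterative:
        # externally studentized residuals need n >= 4 for a 2-parameter fit
        while len(kept) >= 4:
            resid = studentized(kept)
            worst = int(np.nanargmax(np.abs(resid)))
            if abs(resid[worst]) <= residual_threshold:
                break
            removed.append(kept.pop(worst))
    else:
        resid = studentized(kept)
        over = np.abs(resid) > residual_threshold
        removed = [p for p, o in zip(kept, over) if o]
        kept = [p for p, o in zip(kept, over) if not o]

    if len(kept) < 2:
        raise InsufficientDataError(
            f"lab {lab_id}: fewer than 2 points after outlier removal"
        )

    x = np.array([p[0] for p in kept])
    y = np.array([p[1] for p in kept])
    fit = _ols(x, y)
    intercept, slope = fit.params
    if slope >= 0:
        raise DegenerateCurveError(
            f"lab {lab_id}: fitted slope {slope:.4f} is non-negative"
        )
    return StandardCurve(
        lab_id=lab_id,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(fit.rsquared),
        efficiency=efficiency_from_slope(float(slope)),
        n_points_used=len(kept),
        outliers_removed=[(10.0 ** lx, cq) for lx, cq in removed],
    )


def derive_detection_limits(
    cq_at_1_copy: Sequence[float], cq_at_10_copies: Sequence[float]
) -> tuple[float, float]:
    """LOD and LLOQ Cq thresholds from the two lowest standard levels.

    lod_cq is the mean observed Cq of amplified 1-copy standards; lloq_cq
    is the mean 10-copy Cq plus 2 sample standard deviations.
    """
    cq1 = [float(c) for c in cq_at_1_copy]
    cq10 = [float(c) for c in cq_at_10_copies]
    if len(cq1) < 1:
        raise InsufficientDataError(
            "no amplified 1-copy standards; cannot set LOD"
        )
    if len(cq10) < 2:
        raise InsufficientDataError(
            "need >= 2 amplified 10-copy standards to set LLOQ"
        )
    lod_cq = float(np.mean(cq1))
    lloq_cq = float(np.mean(cq10) + 2.0 * np.std(cq10, ddof=1))
    return lod_cq, lloq_cq


def calibrate_lab(
    wells: Iterable[PlateWell],
    lab_id: str,
    *,
    iterative: bool = True,
) -> StandardCurve:
    """Master curve plus detection limits from one lab's standard wells."""
    pts: list[tuple[float, float]] = []
    cq1: list[float] = []
    cq10: list[float] = []
    for w in wells:
        if w.role is not Role.STANDARD or w.target is not Target.HF183:
            continue
        if w.lab_id != lab_id or w.cq is None:
            continue
        pts.append((math.log10(w.standard_copies), w.cq))
        if math.isclose(w.standard_copies, 1.0):
            cq1.append(w.cq)
        elif math.isclose(w.standard_copies, 10.0):
            cq10.append(w.cq)
    curve = fit_master_curve(pts, lab_id, iterative=iterative)
    curve.lod_cq, curve.lloq_cq = derive_detection_limits(cq1, cq10)
    curve.validate_limits()
    return curve


def calibrate_all_labs(
    wells: Iterable[PlateWell], *, iterative: bool = True
) -> dict[str, StandardCurve]:
    """Fit a master curve for every lab present in the plate set."""
    by_lab: dict[str, list[PlateWell]] = defaultdict(list)
    for w in wells:
        if w.role is Role.STANDARD and w.target is Target.HF183:
            by_lab[w.lab_id].append(w)
    if not by_lab:
        raise InsufficientDataError("no standard wells found")
    return {
        lab: calibrate_lab(ws, lab, iterative=iterative)
        for lab, ws in sorted(by_lab.items())
    }
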
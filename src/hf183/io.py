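"""CSV readers and writers for plate tables, metadata, rain series, outputs.

All interchange is plain UTF-8 CSV with a single header row. An empty Cq
cell means the reaction did not amplify. Numeric output is rendered with 6
significant digits so write -> read round-trips are value-preserving at
that precision.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .model import (
    ConcordanceReport,
    ParseError,
    PlateWell,
    Positivity,
    RankingResult,
    Role,
    SiteSummary,
    StandardCurve,
    Target,
    ValidationError,
    Weather,
)

PathLike = Union[str, Path]

PLATE_COLUMNS = [
    "plate_id", "lab_id", "well", "role", "target",
    "sample_id", "standard_copies", "cq",
]
METADATA_COLUMNS = [
    "sample_id", "site_id", "timestamp", "volume_filtered_ml",
    "enterococcus_per_100ml", "gauge_id",
]
RAIN_COLUMNS = ["gauge_id", "timestamp", "depth_inches"]

_SUMMARY_METRICS = (
    ["n_samples"]
    + [f"freq_{p.value}" for p in Positivity]
    + ["geomean_hf183", "entero_exceed_pct", "entero_exceed_100x_pct",
       "entero_geomean", "n_entero"]
)


def _fmt(value: Optional[float]) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{value:.6g}"


def _parse_optional_float(raw, context: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"non-numeric value {text!r} for {context}") from exc


def read_plate_table(path: PathLike) -> list[PlateWell]:
    """Read a plate CSV into validated :class:`PlateWell` records.

    Raises :class:`ParseError` naming the offending well for malformed Cq
    values, and for a well position listed twice on the same plate.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"plate table {path} missing columns {missing}")

    wells: list[PlateWell] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        key = (row.plate_id, row.well)
        if key in seen:
            raise ParseError(
                f"well {row.well} listed twice on plate {row.plate_id}"
            )
        seen.add(key)
        context = f"well {row.well} of plate {row.plate_id}"
        cq = _parse_optional_float(row.cq, f"Cq in {context}")
        if cq is not None and cq <= 0:
            raise ParseError(f"non-positive Cq {cq} in {context}")
        try:
            wells.append(
                PlateWell(
                    plate_id=row.plate_id,
                    lab_id=row.lab_id,
                    well=row.well,
                    role=Role(row.role),
                    target=Target(row.target),
                    cq=cq,
                    standard_copies=_parse_optional_float(
                        row.standard_copies, f"standard_copies in {context}"
                    ),
                    sample_id=row.sample_id or None,
                )
            )
        except ValueError as exc:  # bad enum or invariant violation
            raise ParseError(f"{context}: {exc}") from exc
    return wells


def write_plate_table(wells: Iterable[PlateWell], path: PathLike) -> None:
    rows = [
        {
            "plate_id": w.plate_id,
            "lab_id": w.lab_id,
            "well": w.well,
            "role": w.role.value,
            "target": w.target.value,
            "sample_id": w.sample_id or "",
            "standard_copies": _fmt(w.standard_copies),
            "cq": _fmt(w.cq),
        }
        for w in wells
    ]
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_metadata(path: PathLike) -> pd.DataFrame:
    """Read sample metadata; timestamps parsed, optional columns preserved.

    Optional columns beyond the core set (``sketa22_cq``, ``weather``) are
    kept when present.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"metadata {path} missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"duplicate sample_id(s) in metadata: {dupes}")
    out = df.copy()
    out["timestamp"] = pd.to_datetime(df["timestamp"])
    out["volume_filtered_ml"] = [
        _parse_optional_float(v, f"volume_filtered_ml of {s}")
        for v, s in zip(df["volume_filtered_ml"], df["sample_id"])
    ]
    out["enterococcus_per_100ml"] = [
        _parse_optional_float(v, f"enterococcus_per_100ml of {s}")
        for v, s in zip(df["enterococcus_per_100ml"], df["sample_id"])
    ]
    if "sketa22_cq" in df.columns:
        out["sketa22_cq"] = [
            _parse_optional_float(v, f"sketa22_cq of {s}")
            for v, s in zip(df["sketa22_cq"], df["sample_id"])
        ]
    for sid, vol in zip(out["sample_id"], out["volume_filtered_ml"]):
        if vol is None or not (0 < vol <= 100):
            raise ParseError(
                f"volume_filtered_ml {vol} out of (0, 100] for sample {sid}"
            )
    return out


def read_rain_series(path: PathLike) -> pd.DataFrame:
    """Read a rain-gauge series; timestamps must be monotone per gauge."""
    df = pd.read_csv(path, dtype={"gauge_id": str})
    missing = [c for c in RAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"rain series {path} missing columns {missing}")
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["depth_inches"] = pd.to_numeric(df["depth_inches"], errors="raise")
    if (df["depth_inches"] < 0).any():
        bad = df.loc[df["depth_inches"] < 0].iloc[0]
        raise ValidationError(
            f"negative rain depth {bad['depth_inches']} at gauge "
            f"{bad['gauge_id']} {bad['timestamp']}"
        )
    for gauge, grp in df.groupby("gauge_id"):
        if not grp["timestamp"].is_monotonic_increasing:
            raise ValidationError(f"non-monotone timestamps for gauge {gauge}")
    return df


def summaries_to_frame(summaries: Sequence[SiteSummary]) -> pd.DataFrame:
    """Tidy long form: one row per site x stratum x metric."""
    rows = []
    for s in summaries:
        values: dict[str, Optional[float]] = {"n_samples": float(s.n_samples)}
        for p in Positivity:
            values[f"freq_{p.value}"] = s.freq.get(p)
        values["geomean_hf183"] = s.geomean_hf183
        values["entero_exceed_pct"] = s.entero_exceed_pct
        values["entero_exceed_100x_pct"] = s.entero_exceed_100x_pct
        values["entero_geomean"] = s.entero_geomean
        values["n_entero"] = float(s.n_entero)
        for metric in _SUMMARY_METRICS:
            rows.append(
                {
                    "site_id": s.site_id,
                    "stratum": s.stratum.value,
                    "metric": metric,
                    "value": _fmt(values[metric]),
                }
            )
    return pd.DataFrame(rows, columns=["site_id", "stratum", "metric", "value"])


def write_site_summaries(summaries: Sequence[SiteSummary], path: PathLike) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


def read_site_summaries(path: PathLike) -> list[SiteSummary]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: list[SiteSummary] = []
    for (site, stratum), grp in df.groupby(["site_id", "stratum"], sort=False):
        vals = {
            m: _parse_optional_float(v, f"{site}/{stratum}/{m}")
            for m, v in zip(grp["metric"], grp["value"])
        }
        freq = {
            p: vals[f"freq_{p.value}"]
            for p in Positivity
            if vals.get(f"freq_{p.value}") is not None
        }
        out.append(
            SiteSummary(
                site_id=site,
                stratum=Weather(stratum),
                n_samples=int(vals["n_samples"]),
                freq=freq,
                geomean_hf183=vals.get("geomean_hf183"),
                entero_exceed_pct=vals.get("entero_exceed_pct"),
                entero_exceed_100x_pct=vals.get("entero_exceed_100x_pct"),
                entero_geomean=vals.get("entero_geomean"),
                n_entero=int(vals.get("n_entero") or 0),
            )
        )
    return out


def write_curves(curves: Sequence[StandardCurve], path: PathLike) -> None:
    rows = [
        {
            "lab_id": c.lab_id,
            "slope": _fmt(c.slope),
            "intercept": _fmt(c.intercept),
            "r_squared": _fmt(c.r_squared),
            "efficiency": _fmt(c.efficiency),
            "lod_cq": _fmt(c.lod_cq),
            "lloq_cq": _fmt(c.lloq_cq),
            "n_points_used": c.n_points_used,
            "n_outliers": len(c.outliers_removed),
        }
        for c in curves
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves(path: PathLike) -> list[StandardCurve]:
    df = pd.read_csv(path, dtype={"lab_id": str})
    return [
        StandardCurve(
            lab_id=r.lab_id,
            slope=r.slope,
            intercept=r.intercept,
            r_squared=r.r_squared,
            efficiency=r.efficiency,
            n_points_used=int(r.n_points_used),
            outliers_removed=[(float("nan"), float("nan"))] * int(r.n_outliers),
            lod_cq=None if pd.isna(r.lod_cq) else r.lod_cq,
            lloq_cq=None if pd.isna(r.lloq_cq) else r.lloq_cq,
        )
        for r in df.itertuples(index=False)
    ]


def write_rankings(rankings: Sequence[RankingResult], path: PathLike) -> None:
    rows = [
        {
            "metric_id": r.metric_id,
            "stratum": r.stratum,
            "site_id": site,
            "rank": rank,
            "metric_value": _fmt(value),
        }
        for r in rankings
        for site, rank, value in r.entries
    ]
    pd.DataFrame(
        rows, columns=["metric_id", "stratum", "site_id", "rank", "metric_value"]
    ).to_csv(path, index=False)


def write_concordance(report: ConcordanceReport, path: PathLike) -> None:
    payload = {
        "spearman_rho": report.spearman_rho,
        "shifts": report.shifts,
        "n_sites_shifted": report.n_sites_shifted,
        "max_shift_site": report.max_shift_site,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
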
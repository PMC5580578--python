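"""Site ranking and rank concordance.

Sites are ranked in descending order of a chosen metric (rank 1 = most
contaminated). Ties are broken deterministically by a complementary
secondary metric (concentration when ranking by frequency and vice
versa) and finally by site identifier. Concordance between two rankings
over the same sites is summarized by Spearman's rho plus per-site rank
shifts.
"""

from __future__ import annotations

from typing import Optional, Sequence

from scipy import stats

from .model import (
    ConcordanceReport,
    Positivity,
    RankingResult,
    SiteSummary,
    ValidationError,
)

FREQ_METRICS = {f"freq_{p.value}" for p in Positivity}
CONC_METRICS = {"geomean_hf183", "entero_geomean"}

_SECONDARY = {
    **{m: "geomean_hf183" for m in FREQ_METRICS},
    "geomean_hf183": "freq_AMP1",
    "entero_geomean": "entero_exceed_pct",
    "entero_exceed_pct": "entero_geomean",
    "entero_exceed_100x_pct": "entero_geomean",
}


def metric_value(summary: SiteSummary, metric_id: str) -> Optional[float]:
    if metric_id in FREQ_METRICS:
        return summary.freq.get(Positivity(metric_id.removeprefix("freq_")))
    try:
        return getattr(summary, metric_id)
    except AttributeError as exc:
        raise ValidationError(f"unknown metric {metric_id!r}") from exc


def rank_sites(
    summaries: Sequence[SiteSummary],
    metric_id: str,
    tie_policy: str = "secondary_metric_then_site_id",
) -> RankingResult:
    """Rank sites by one metric, descending; rank 1 = most contaminated."""
    if len(summaries) < 2:
        raise ValidationError("ranking needs >= 2 sites")
    if tie_policy != "secondary_metric_then_site_id":
        raise ValidationError(f"unknown tie policy {tie_policy!r}")
    strata = {s.stratum for s in summaries}
    if len(strata) > 1:
        raise ValidationError("rank_sites expects summaries from one stratum")

    secondary_id = _SECONDARY.get(metric_id, "freq_AMP1")
    keyed = []
    for s in summaries:
        value = metric_value(s, metric_id)
        if value is None:
            raise ValidationError(
                f"site {s.site_id} lacks metric {metric_id}; cannot rank"
            )
        secondary = metric_value(s, secondary_id)
        keyed.append((value, -1e18 if secondary is None else secondary, s.site_id))
    keyed.sort(key=lambda t: (-t[0], -t[1], t[2]))
    result = RankingResult(
        metric_id=metric_id,
        stratum=next(iter(strata)).value,
        entries=[(site, i + 1, value) for i, (value, _, site) in enumerate(keyed)],
    )
    result.validate()
    return result


def rank_concordance(
    ranking_a: RankingResult, ranking_b: RankingResult
) -> ConcordanceReport:
    """Spearman rho and per-site rank shifts between two rankings."""
    ranks_a, ranks_b = ranking_a.ranks, ranking_b.ranks
    if set(ranks_a) != set(ranks_b):
        only_a = sorted(set(ranks_a) - set(ranks_b))
        only_b = sorted(set(ranks_b) - set(ranks_a))
        raise ValidationError(
            f"site sets differ: only in first {only_a}, only in second {only_b}"
        )
    sites = sorted(ranks_a)
    rho = float(
        stats.spearmanr([ranks_a[s] for s in sites], [ranks_b[s] for s in sites])[0]
    )
    shifts = {s: ranks_b[s] - ranks_a[s] for s in sites}
    shifted = [s for s in sites if shifts[s] != 0]
    max_site = max(shifted, key=lambda s: (abs(shifts[s]), s)) if shifted else None
    if max_site is not None:
        # deterministic: largest |shift|, first site id on ties
        biggest = max(abs(v) for v in shifts.values())
        max_site = min(s for s in sites if abs(shifts[s]) == biggest)
    return ConcordanceReport(
        spearman_rho=rho,
        shifts=shifts,
        n_sites_shifted=len(shifted),
        max_shift_site=max_site,
    )


def dry_wet_comparison(
    summaries_dry: Sequence[SiteSummary],
    summaries_wet: Sequence[SiteSummary],
    metric_id: str,
) -> tuple[ConcordanceReport, list[str]]:
    """Concordance of dry vs. wet rankings over shared sites, plus the
    sites whose metric decreased from dry to wet weather."""
    dry = {s.site_id: s for s in summaries_dry}
    wet = {s.site_id: s for s in summaries_wet}
    shared = sorted(set(dry) & set(wet))
    if len(shared) < 2:
        raise ValidationError(
            f"need >= 2 sites sampled in both strata, found {len(shared)}"
        )
    rank_dry = rank_sites([dry[s] for s in shared], metric_id)
    rank_wet = rank_sites([wet[s] for s in shared], metric_id)
    report = rank_concordance(rank_dry, rank_wet)
    decreased = [
        s
        for s in shared
        if metric_value(wet[s], metric_id) < metric_value(dry[s], metric_id)
    ]
    return report, decreased
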
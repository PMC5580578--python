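"""Site ranking, tie policy, and rank concordance."""

import numpy as np
import pytest
from scipy import stats

from hf183.model import (
    Positivity,
    RankingResult,
    SiteSummary,
    ValidationError,
    Weather,
)
from hf183.prioritization import dry_wet_comparison, rank_concordance, rank_sites


def summary(site, freq_amp1, geomean=100.0, stratum=Weather.DRY):
    return SiteSummary(
        site_id=site,
        stratum=stratum,
        n_samples=50,
        freq={p: freq_amp1 for p in Positivity},
        geomean_hf183=geomean,
    )


def test_rank_descending_by_metric():
    ranking = rank_sites(
        [summary("A", 30.0), summary("B", 10.0), summary("C", 20.0)],
        "freq_AMP1",
    )
    assert ranking.ranks == {"A": 1, "C": 2, "B": 3}
    ranking.validate()


def test_tie_broken_by_secondary_metric_then_site_id():
    tied = [
        summary("A", 30.0, geomean=10.0),
        summary("B", 30.0, geomean=99.0),
        summary("C", 30.0, geomean=10.0),
    ]
    ranking = rank_sites(tied, "freq_AMP1")
    assert ranking.ranks["B"] == 1          # higher geomean wins the tie
    assert ranking.ranks["A"] == 2          # then lexicographic site id
    assert ranking.ranks["C"] == 3


def test_reversing_the_metric_reverses_the_permutation():
    values = [5.0, 40.0, 75.0, 20.0, 60.0]
    sites = list("ABCDE")
    fwd = rank_sites(
        [summary(s, v) for s, v in zip(sites, values)], "freq_AMP1"
    )
    rev = rank_sites(
        [summary(s, 100.0 - v) for s, v in zip(sites, values)], "freq_AMP1"
    )
    n = len(sites)
    assert all(rev.ranks[s] == n + 1 - fwd.ranks[s] for s in sites)


def test_missing_metric_names_the_site():
    good = summary("A", 30.0)
    bad = summary("B", 20.0)
    bad.geomean_hf183 = None
    with pytest.raises(ValidationError, match="B"):
        rank_sites([good, bad], "geomean_hf183")


def _ranking(rank_map, metric="m", stratum="DRY"):
    entries = [
        (site, rank, float(100 - rank)) for site, rank in rank_map.items()
    ]
    return RankingResult(metric_id=metric, stratum=stratum, entries=entries)


def test_identical_rankings_fully_concordant():
    a = _ranking({"A": 1, "B": 2, "C": 3})
    report = rank_concordance(a, a)
    assert report.spearman_rho == pytest.approx(1.0)
    assert set(report.shifts.values()) == {0}
    assert report.n_sites_shifted == 0
    assert report.max_shift_site is None


def test_reversed_rankings_anticoncordant():
    sites = list("ABCDE")
    a = _ranking({s: i + 1 for i, s in enumerate(sites)})
    b = _ranking({s: 5 - i for i, s in enumerate(sites)})
    assert rank_concordance(a, b).spearman_rho == pytest.approx(-1.0)


def test_spearman_hand_computed_example():
    """Ranks (1,2,3,4,5) vs (2,1,3,5,4): sum of squared differences is 4,
    so rho = 1 - 6*4/(5*24) = 0.8."""
    a = _ranking(dict(zip("ABCDE", [1, 2, 3, 4, 5])))
    b = _ranking(dict(zip("ABCDE", [2, 1, 3, 5, 4])))
    report = rank_concordance(a, b)
    assert report.spearman_rho == pytest.approx(0.8)
    assert report.shifts == {"A": 1, "B": -1, "C": 0, "D": 1, "E": -1}
    assert report.n_sites_shifted == 4


def test_mismatched_site_sets_listed():
    a = _ranking({"A": 1, "B": 2})
    b = _ranking({"A": 1, "C": 2})
    with pytest.raises(ValidationError, match="B.*C"):
        rank_concordance(a, b)


def test_dry_wet_identical_summaries_no_shifts():
    dry = [summary(s, v) for s, v in zip("ABCD", [40.0, 30.0, 20.0, 10.0])]
    wet = [
        summary(s, v, stratum=Weather.WET)
        for s, v in zip("ABCD", [40.0, 30.0, 20.0, 10.0])
    ]
    report, decreased = dry_wet_comparison(dry, wet, "freq_AMP1")
    assert decreased == []
    assert report.spearman_rho == pytest.approx(1.0)
    assert report.n_sites_shifted == 0


def test_dry_wet_big_shift_site_identified():
    """A 16-site comparison where one site jumps 10 positions between
    strata must name that site as the largest shift."""
    n = 16
    sites = [f"S{i:02d}" for i in range(n)]
    dry_vals = {s: float(100 - 2 * i) for i, s in enumerate(sites)}
    wet_vals = dict(dry_vals)
    # S12 (dry rank 13) surges to wet rank 3
    mover = "S12"
    wet_vals[mover] = (sorted(wet_vals.values(), reverse=True)[2]
                       + sorted(wet_vals.values(), reverse=True)[1]) / 2
    dry = [summary(s, dry_vals[s]) for s in sites]
    wet = [summary(s, wet_vals[s], stratum=Weather.WET) for s in sites]
    report, decreased = dry_wet_comparison(dry, wet, "freq_AMP1")
    assert report.max_shift_site == mover
    assert report.shifts[mover] == -10
    assert decreased == []


def test_dry_wet_decrease_list():
    dry = [summary(s, v) for s, v in zip("ABC", [40.0, 30.0, 20.0])]
    wet = [
        summary(s, v, stratum=Weather.WET)
        for s, v in zip("ABC", [60.0, 25.0, 35.0])
    ]
    _, decreased = dry_wet_comparison(dry, wet, "freq_AMP1")
    assert decreased == ["B"]


def test_dry_wet_requires_shared_sites():
    dry = [summary("A", 10.0), summary("B", 20.0)]
    wet = [summary("C", 10.0, stratum=Weather.WET),
           summary("D", 20.0, stratum=Weather.WET)]
    with pytest.raises(ValidationError, match="both strata"):
        dry_wet_comparison(dry, wet, "freq_AMP1")


def test_campaign_rankings_are_valid_permutations(default_result):
    assert default_result.rankings
    for ranking in default_result.rankings:
        ranking.validate()
        self_report = rank_concordance(ranking, ranking)
        assert self_report.spearman_rho == pytest.approx(1.0)


def _recovery_campaign(seed=314):
    from hf183.pipeline import analyze_campaign
    from hf183.simulate import SimulationConfig, SiteTruth, simulate_campaign

    prevalences = np.linspace(0.05, 0.95, 20)
    sites = [
        SiteTruth(
            site_id=f"R{i:02d}",
            prevalence_dry=float(p),
            prevalence_wet=float(p),
            log10_mean_conc=2.3 + 1.8 * float(p),  # persistent-source coupling
            log10_sd_conc=0.6,
        )
        for i, p in enumerate(prevalences)
    ]
    cfg = SimulationConfig(sites=sites, samples_per_site_per_stratum=50,
                           n_labs=4, seed=seed)
    campaign = simulate_campaign(cfg)
    result = analyze_campaign(campaign.plates, campaign.metadata, campaign.rain)
    return prevalences, result


def test_ranking_recovers_true_prevalence_order():
    """20 sites with prevalence 0.05-0.95 and n = 50: the AMP1-frequency
    ranking agrees with the true prevalence ranking (Spearman >= 0.9),
    and frequency- and concentration-based rankings agree (>= 0.85)."""
    prevalences, result = _recovery_campaign()
    dry = result.summaries_for(Weather.DRY)
    by_freq = rank_sites(dry, "freq_AMP1")
    truth_rank = {
        f"R{i:02d}": rank
        for rank, i in enumerate(np.argsort(-prevalences), start=1)
    }
    sites = sorted(truth_rank)
    rho = stats.spearmanr(
        [truth_rank[s] for s in sites], [by_freq.ranks[s] for s in sites]
    )[0]
    assert rho >= 0.9

    by_conc = rank_sites(dry, "geomean_hf183")
    assert rank_concordance(by_freq, by_conc).spearman_rho >= 0.85


def test_decoupled_enterococcus_rankings_uncorrelated():
    """When Enterococcus is simulated independently of HF183, rankings by
    the two indicators are nearly uncorrelated on average."""
    from hf183.pipeline import analyze_campaign
    from hf183.simulate import SimulationConfig, SiteTruth, simulate_campaign

    rng = np.random.default_rng(4)
    rhos = []
    for rep in range(30):
        entero_means = rng.permutation(np.linspace(1.8, 3.0, 12))
        sites = [
            SiteTruth(
                site_id=f"D{i:02d}",
                prevalence_dry=float(p),
                prevalence_wet=float(p),
                log10_mean_conc=2.3 + 1.8 * float(p),
                log10_sd_conc=0.6,
                entero_log10_mean=float(entero_means[i]),
                entero_coupling=0.0,
            )
            for i, p in enumerate(np.linspace(0.1, 0.9, 12))
        ]
        cfg = SimulationConfig(
            sites=sites, samples_per_site_per_stratum=15, n_labs=2,
            n_storms=5, entero_missing_rate=0.0, seed=int(rng.integers(2**31)),
        )
        campaign = simulate_campaign(cfg)
        result = analyze_campaign(
            campaign.plates, campaign.metadata, campaign.rain
        )
        dry = result.summaries_for(Weather.DRY)
        rho = rank_concordance(
            rank_sites(dry, "freq_AMP1"), rank_sites(dry, "entero_geomean")
        ).spearman_rho
        rhos.append(abs(rho))
    assert np.mean(rhos) < 0.3
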
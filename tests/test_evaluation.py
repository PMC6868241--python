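"""Confusion metrics, AUCs, enrichment machinery and CRISPRi preparation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncer.evaluation import (
    ConfusionCounts,
    confusion_metrics,
    crispri_prepare,
    enrichment_tests,
    fraction_high_regions,
    region_enrichment,
    roc_pr,
    sample_matched_regions,
    smooth_series,
)
from ncer.genome_scoring import bin_and_repercentile, genomewide_percentiles
from ncer.intervals import GenomicInterval
from ncer.variant_sets import PipelineConfig


# --------------------------------------------------------- confusion_metrics

def test_sensitivity_printed_formula_example():
    m = confusion_metrics(ConfusionCounts(tp=8, tn=0, fp=1, fn=2))
    assert m["sensitivity"] == pytest.approx(80.0)


def test_perfect_classifier_metrics():
    m = confusion_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
    assert m["accuracy"] == m["ppv"] == m["npv"] == 100.0


def test_zero_denominator_reported_missing_not_zero():
    m = confusion_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
    assert m["sensitivity"] is None and m["ppv"] is None
    assert m["specificity"] == 100.0


@settings(max_examples=200, deadline=None)
@given(
    tp=st.integers(0, 50), tn=st.integers(0, 50),
    fp=st.integers(0, 50), fn=st.integers(0, 50),
)
def test_confusion_metrics_match_formula_oracle(tp, tn, fp, fn):
    if tp + tn + fp + fn == 0:
        return
    m = confusion_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))

    def frac(n, d):
        return 100.0 * n / d if d else None

    assert m["sensitivity"] == frac(tp, tp + fn)
    assert m["specificity"] == frac(tn, tn + fp)
    assert m["fpr"] == frac(fp, fp + tn)
    assert m["accuracy"] == frac(tp + tn, tp + tn + fp + fn)
    assert m["ppv"] == frac(tp, tp + fp)
    assert m["npv"] == frac(tn, tn + fn)


# ---------------------------------------------------------------- roc_pr

def test_perfect_separation_and_constant_scores():
    y = np.array([0, 0, 1, 1])
    assert roc_pr(y, np.array([0.1, 0.2, 0.8, 0.9]))[0] == 1.0
    assert roc_pr(y, np.full(4, 0.5))[0] == 0.5


def all_pairs_auc(y, s):
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


@pytest.mark.parametrize("seed", range(6))
def test_roc_auc_equals_all_pairs_rank_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 1000))
    y = (rng.random(n) < 0.3).astype(int)
    if y.sum() in (0, n):
        y[0], y[1] = 0, 1
    s = np.round(rng.random(n), 2)
    roc, _ = roc_pr(y, s)
    assert roc == pytest.approx(all_pairs_auc(y, s))


def test_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_pr(np.ones(5), np.random.default_rng(0).random(5))


# ----------------------------------------------------- fraction_high_regions

def make_binned(raw, width=10):
    return bin_and_repercentile(genomewide_percentiles({"chr1": raw}), width)


def test_region_with_top_bin_counts_at_every_threshold():
    rng = np.random.default_rng(0)
    raw = rng.random(500)
    binned = make_binned(raw)
    top_bin = int(np.argmax(binned.percentile["chr1"]))
    region = GenomicInterval("chr1", top_bin * 10, top_bin * 10 + 10)
    fracs = fraction_high_regions([region], binned, (95, 99, 99.5, 99.9))
    assert (fracs == 1.0).all()


def test_fraction_matches_any_bin_above_scan_oracle():
    rng = np.random.default_rng(1)
    raw = rng.random(1000)
    binned = make_binned(raw)
    regions = [
        GenomicInterval("chr1", int(s), int(s) + int(l))
        for s, l in zip(rng.integers(0, 900, 30), rng.integers(5, 80, 30))
    ]
    thresholds = (50.0, 80.0, 95.0, 99.0)
    got = fraction_high_regions(regions, binned, thresholds)
    pct = binned.percentile["chr1"]
    for j, t in enumerate(thresholds):
        hits = 0
        for r in regions:
            bins = range(r.start // 10, (r.end - 1) // 10 + 1)
            if any(pct[b] > t for b in bins if b < pct.size):
                hits += 1
        assert got[j] == pytest.approx(hits / len(regions))


def test_fraction_monotone_nonincreasing_in_threshold():
    rng = np.random.default_rng(2)
    for seed in range(5):
        raw = np.random.default_rng(seed).random(800)
        binned = make_binned(raw)
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 40)
            for s in rng.integers(0, 700, 20)
        ]
        fracs = fraction_high_regions(regions, binned, (50, 90, 95, 99, 99.9))
        assert (np.diff(fracs) <= 0).all()


def test_empty_regions_rejected():
    binned = make_binned(np.random.default_rng(0).random(100))
    with pytest.raises(ValueError, match="empty"):
        fraction_high_regions([], binned)


# --------------------------------------------------- sample_matched_regions

def test_matched_draw_in_singleton_universe_is_that_interval():
    universe = [GenomicInterval("chr1", 50, 80)]
    template = [GenomicInterval("chr9", 0, 30)]
    draws = sample_matched_regions(template, universe, n_draws=3, seed=0)
    for d in draws:
        assert d == [GenomicInterval("chr1", 50, 80)]


def test_matched_draws_length_exact_and_universe_contained():
    rng = np.random.default_rng(3)
    universe = [
        GenomicInterval("chr1", 0, 5_000),
        GenomicInterval("chr2", 1_000, 9_000),
    ]
    template = [
        GenomicInterval("chrX", int(s), int(s) + int(l))
        for s, l in zip(rng.integers(0, 100, 10), rng.integers(10, 3_000, 10))
    ]
    draws = sample_matched_regions(template, universe, n_draws=100, seed=9)
    t_lens = sorted(len(t) for t in template)
    for d in draws:
        assert sorted(len(r) for r in d) == t_lens
        for r in d:
            assert any(
                r.chrom == u.chrom and r.start >= u.start and r.end <= u.end
                for u in universe
            )


def test_matched_draws_reproducible_across_seeds():
    universe = [GenomicInterval("chr1", 0, 10_000)]
    template = [GenomicInterval("chr1", 0, 100)] * 5
    for seed in range(100):
        a = sample_matched_regions(template, universe, n_draws=2, seed=seed)
        b = sample_matched_regions(template, universe, n_draws=2, seed=seed)
        assert a == b


def test_oversized_template_rejected_with_name():
    with pytest.raises(ValueError, match="chr9"):
        sample_matched_regions(
            [GenomicInterval("chr9", 0, 500)],
            [GenomicInterval("chr1", 0, 100)],
            n_draws=1,
            seed=0,
        )


# ----------------------------------------------------------- smooth_series

def test_constant_series_unchanged():
    np.testing.assert_allclose(smooth_series(np.full(30, 2.5), 20),
                               np.full(30, 2.5))


def test_smoothing_matches_rolling_oracle_everywhere():
    rng = np.random.default_rng(4)
    v = rng.normal(size=50)
    got = smooth_series(v, 20)
    for i in range(50):
        assert got[i] == pytest.approx(float(np.mean(v[i:i + 20])))


def test_window_one_is_identity():
    v = np.random.default_rng(5).random(10)
    np.testing.assert_allclose(smooth_series(v, 1), v)


# ---------------------------------------------------------- crispri_prepare

def toy_probes(rng):
    rows = []
    for i in range(60):
        start = i * 100
        length = int(rng.choice([300, 1200]))
        rows.append(
            ("chr1", start, start + length, int(rng.integers(5, 40)),
             float(rng.normal(-0.8, 0.8)))
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_pairs", "viability"]
    )


def test_crispri_filter_chain_matches_independent_oracle():
    rng = np.random.default_rng(6)
    probes = toy_probes(rng)
    exons = [GenomicInterval("chr1", 1_000, 1_500)]
    config = PipelineConfig(smoothing_window=5, min_pairs=20, max_probe_len=1000)
    result = crispri_prepare(probes, exons, config)

    # independently coded oracle: sort, smooth, filter, exon-drop, flag
    df = probes.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    sm = []
    vals = df["viability"].tolist()
    for i in range(len(vals)):
        sm.append(float(np.mean(vals[i:i + 5])))
    df["sm"] = sm
    keep = df[(df["n_pairs"] >= 20) & (df["end"] - df["start"] < 1000)]
    overlap = keep.apply(
        lambda r: r["start"] < 1_500 and 1_000 < r["end"], axis=1
    )
    retained = keep[~overlap]
    assert result.n_pass_filters == len(keep)
    assert result.n_exon_overlap == int(overlap.sum())
    assert result.n_retained == len(retained)
    np.testing.assert_allclose(
        result.probes["smoothed_viability"], retained["sm"]
    )
    np.testing.assert_array_equal(
        result.probes["functional"], retained["sm"] <= -1.0
    )


def test_crispri_no_exons_no_drops():
    rng = np.random.default_rng(7)
    probes = toy_probes(rng)
    config = PipelineConfig(smoothing_window=5)
    result = crispri_prepare(probes, [], config)
    assert result.n_exon_overlap == 0
    assert result.n_retained == result.n_pass_filters


def test_crispri_never_retains_filtered_probes():
    rng = np.random.default_rng(8)
    probes = toy_probes(rng)
    config = PipelineConfig(smoothing_window=5)
    result = crispri_prepare(probes, [], config)
    lengths = result.probes["end"] - result.probes["start"]
    assert (lengths < config.max_probe_len).all()
    assert (result.probes["n_pairs"] >= config.min_pairs).all()


def test_crispri_missing_viability_dropped_with_warning():
    rng = np.random.default_rng(9)
    probes = toy_probes(rng)
    probes.loc[3, "viability"] = np.nan
    with pytest.warns(UserWarning, match="missing viability"):
        result = crispri_prepare(probes, [], PipelineConfig(smoothing_window=5))
    assert result.n_input == 60


# --------------------------------------------------------- enrichment_tests

def test_fisher_symmetric_table_p_one():
    assert enrichment_tests([5, 5], [5, 5], kind="fisher") == pytest.approx(1.0)


def test_fisher_matches_hypergeometric_enumeration():
    """[[3,1],[1,3]]: two-sided p = 34/70 by full enumeration."""
    p = enrichment_tests([3, 1], [1, 3], kind="fisher")

    # enumeration oracle: all tables with the same margins
    def table_prob(a):
        b, c = 4 - a, 4 - a
        d = a  # margins (4,4)x(4,4) force d = a
        return (
            math.comb(4, a) * math.comb(4, c)
            / math.comb(8, 4)
        )

    probs = {a: table_prob(a) for a in range(5)}
    p_obs = probs[3]
    expected = sum(pr for pr in probs.values() if pr <= p_obs + 1e-12)
    assert expected == pytest.approx(34 / 70)
    assert p == pytest.approx(expected)


def test_mann_whitney_and_ks_detect_shift():
    rng = np.random.default_rng(10)
    a = rng.normal(0, 1, 100)
    b = rng.normal(1.5, 1, 100)
    assert enrichment_tests(a, b, kind="mann_whitney") < 1e-6
    assert enrichment_tests(a, b, kind="ks") < 1e-6
    same = enrichment_tests(a, a, kind="mann_whitney")
    assert same == pytest.approx(1.0, abs=0.01)


def test_fisher_empty_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        enrichment_tests([0, 0], [3, 4], kind="fisher")


# -------------------------------------------------------- region_enrichment

def test_region_enrichment_report_shape_and_defaults():
    rng = np.random.default_rng(11)
    raw = rng.random(5_000)
    binned = make_binned(raw)
    regions = [
        GenomicInterval("chr1", int(s), int(s) + 50)
        for s in rng.integers(0, 4_900, 12)
    ]
    universe = [GenomicInterval("chr1", 0, 5_000)]
    config = PipelineConfig(seed=1)
    report = region_enrichment(regions, binned, universe, config)
    assert report.thresholds == (95.0, 99.0, 99.5, 99.9)
    assert report.random_fractions.shape == (100, 4)
    assert ((report.observed_fraction >= 0)
            & (report.observed_fraction <= 1)).all()
    assert (np.diff(report.observed_fraction) <= 0).all()
    frame = report.to_frame()
    assert list(frame.columns) == [
        "threshold", "observed_fraction", "random_mean_fraction", "fisher_p"
    ]
    assert ((frame["fisher_p"] > 0) & (frame["fisher_p"] <= 1)).all()
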
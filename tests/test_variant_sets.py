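"""Declustering, control matching, splitting and lead/exclusion filters."""

import numpy as np
import pandas as pd
import pytest

from ncer.intervals import GenomicInterval
from ncer.variant_sets import (
    PipelineConfig,
    SplitSpec,
    decluster,
    filter_mendelian,
    match_controls,
    select_gwas_leads,
    split_by_regions,
)
from .conftest import make_variants


# ---------------------------------------------------------------- decluster

def test_decluster_greedy_example():
    """{100, 550, 700, 1200} at 500 bp spacing keeps {100, 700, 1200}."""
    df = make_variants([100, 550, 700, 1200])
    kept = decluster(df, 500)["pos"].tolist()
    assert kept == [100, 700, 1200]


def test_decluster_single_variant_kept():
    df = make_variants([42])
    assert decluster(df, 500)["pos"].tolist() == [42]


def test_decluster_keeps_global_minimum_first():
    rng = np.random.default_rng(0)
    df = make_variants(rng.integers(0, 100_000, size=200).tolist())
    kept = decluster(df, 500)
    assert kept["pos"].iloc[0] == df["pos"].min()


def greedy_oracle(positions, spacing):
    kept = []
    for p in sorted(positions):
        if not kept or p - kept[-1] >= spacing:
            kept.append(p)
    return kept


@pytest.mark.parametrize("seed", range(5))
def test_decluster_matches_greedy_oracle_and_order_invariance(seed):
    rng = np.random.default_rng(seed)
    positions = rng.integers(0, 20_000, size=60).tolist()
    df = make_variants(positions)
    shuffled = df.sample(frac=1.0, random_state=seed)
    out1 = decluster(df, 500)["pos"].tolist()
    out2 = decluster(shuffled, 500)["pos"].tolist()
    assert out1 == out2 == greedy_oracle(positions, 500)
    assert all(b - a >= 500 for a, b in zip(out1, out1[1:]))


def test_decluster_empty_input():
    df = make_variants([])
    assert decluster(df, 500).empty


def test_decluster_is_per_chromosome():
    df = make_variants([100, 150], chrom=["chr1", "chr2"])
    assert len(decluster(df, 500)) == 2


# ------------------------------------------------------------ match_controls

def matching_oracle(patho, pool, track, k, spacing):
    """Exhaustive filter -> rank -> top-k -> dedup -> decluster."""
    def annot(df):
        return [
            (
                track.category_at(r.chrom, int(r.pos)),
                int(track.splice_distance_at(r.chrom, int(r.pos))),
            )
            for r in df.itertuples(index=False)
        ]

    pa = annot(patho)
    po = annot(pool)
    selected = []
    for (cat, sd), prow in zip(pa, patho.itertuples(index=False)):
        cands = []
        for (ccat, csd), crow in zip(po, pool.itertuples(index=False)):
            if ccat != cat:
                continue
            prox = (
                abs(int(crow.pos) - int(prow.pos))
                if crow.chrom == prow.chrom
                else 1 << 40
            )
            cands.append(
                (abs(csd - sd), prox, crow.chrom, int(crow.pos))
            )
        cands.sort()
        selected.extend((c, p) for _, _, c, p in cands[:k])
    selected = sorted(set(selected))
    kept = []
    last = {}
    for chrom, pos in selected:
        if chrom not in last or pos - last[chrom] >= spacing:
            kept.append((chrom, pos))
            last[chrom] = pos
    return kept


def test_match_controls_equals_exhaustive_oracle(toy_track):
    rng = np.random.default_rng(3)
    patho = make_variants(sorted(rng.choice(10_000, 8, replace=False)))
    pool = make_variants(sorted(rng.choice(10_000, 40, replace=False)))
    config = PipelineConfig(min_spacing=200, k_controls=5)
    out = match_controls(patho, pool, toy_track, config)
    got = list(zip(out["chrom"], out["pos"]))
    assert got == matching_oracle(patho, pool, toy_track, 5, 200)


def test_match_controls_same_category_as_partner(toy_track):
    rng = np.random.default_rng(4)
    patho = make_variants(sorted(rng.choice(10_000, 10, replace=False)))
    pool = make_variants(sorted(rng.choice(10_000, 300, replace=False)))
    config = PipelineConfig(min_spacing=100, k_controls=3)
    out = match_controls(
        patho, pool, toy_track, config, decluster_controls=False
    )
    patho_cats = {
        toy_track.category_at("chr1", int(p)) for p in patho["pos"]
    }
    for pos in out["pos"]:
        assert toy_track.category_at("chr1", int(pos)) in patho_cats


def test_match_controls_empty_pool_category_warns(toy_track):
    patho = make_variants([1100])  # CDS base
    pool = make_variants([9500])   # INTERGENIC base
    config = PipelineConfig(k_controls=5)
    with pytest.warns(UserWarning, match="no control candidates"):
        out = match_controls(patho, pool, toy_track, config)
    assert out.empty


def test_match_controls_spacing_and_count_bound(toy_track):
    rng = np.random.default_rng(5)
    patho = make_variants(sorted(rng.choice(10_000, 12, replace=False)))
    pool = make_variants(sorted(rng.choice(10_000, 2000, replace=False)))
    config = PipelineConfig(min_spacing=300, k_controls=15)
    out = match_controls(patho, pool, toy_track, config)
    assert len(out) <= 15 * len(patho)
    pos = out["pos"].to_numpy()
    assert (np.diff(pos) >= 300).all()
    assert not out.duplicated(subset=["chrom", "pos"]).any()


# ----------------------------------------------------------- split_by_regions

def test_split_whole_chromosome_membership():
    spec = SplitSpec([GenomicInterval("chr10", 0, 10**9)])
    df = make_variants([5, 10], chrom=["chr10", "chr2"])
    train, test = split_by_regions(df, spec)
    assert test["chrom"].tolist() == ["chr10"]
    assert train["chrom"].tolist() == ["chr2"]


def test_split_empty_input():
    spec = SplitSpec([GenomicInterval("chr1", 0, 100)])
    train, test = split_by_regions(make_variants([]), spec)
    assert train.empty and test.empty


def test_split_centromere_arms_match_membership_oracle():
    """Chromosome split at a centromere: both arms checked per position."""
    spec = SplitSpec(
        [
            GenomicInterval("chr1", 0, 5_000),       # upstream arm
            GenomicInterval("chr6", 7_000, 20_000),  # downstream arm
        ]
    )
    rng = np.random.default_rng(6)
    chroms = rng.choice(["chr1", "chr6", "chr9"], size=100).tolist()
    pos = rng.integers(0, 20_000, size=100).tolist()
    df = make_variants(pos, chrom=chroms)
    train, test = split_by_regions(df, spec)
    assert len(train) + len(test) == len(df)
    assert set(train.index).isdisjoint(test.index)
    for row in df.itertuples():
        in_test = any(
            iv.chrom == row.chrom and iv.start <= row.pos < iv.end
            for iv in spec.test_regions
        )
        assert (row.Index in test.index) == in_test


# ----------------------------------------------------------- select_gwas_leads

def test_gwas_keeps_most_significant_per_group():
    df = make_variants(
        [100, 200],
        locus=["L1", "L1"], phenotype=["P", "P"], study=["S", "S"],
        p=[1e-8, 1e-12],
    )
    out = select_gwas_leads(df)
    assert out["p"].tolist() == [1e-12]


def test_gwas_single_record_kept():
    df = make_variants([5], locus=["L"], phenotype=["P"], study=["S"], p=[1e-6])
    assert len(select_gwas_leads(df)) == 1


def test_gwas_matches_groupby_oracle_and_unique_coordinates():
    rng = np.random.default_rng(7)
    n = 120
    df = make_variants(
        rng.integers(0, 5_000, size=n).tolist(),
        locus=[f"L{i}" for i in rng.integers(0, 10, n)],
        phenotype=[f"P{i}" for i in rng.integers(0, 3, n)],
        study=[f"S{i}" for i in rng.integers(0, 2, n)],
        p=10.0 ** -rng.uniform(4, 20, n),
    )
    out = select_gwas_leads(df)
    # group-by/min oracle
    expected = {}
    for row in df.itertuples(index=False):
        key = (row.locus, row.phenotype, row.study)
        if key not in expected or row.p < expected[key].p:
            expected[key] = row
    coords = {}
    for row in expected.values():
        key = (row.chrom, row.pos)
        if key not in coords or row.p < coords[key].p:
            coords[key] = row
    assert len(out) == len(coords)
    assert not out.duplicated(subset=["chrom", "pos"]).any()
    got = {(r.chrom, r.pos): r.p for r in out.itertuples(index=False)}
    assert got == {k: v.p for k, v in coords.items()}


def test_gwas_missing_p_in_group_rejected():
    df = make_variants(
        [1, 2],
        locus=["L", "L"], phenotype=["P", "P"], study=["S", "S"],
        p=[np.nan, 1e-8],
    )
    with pytest.raises(ValueError, match="missing p-value"):
        select_gwas_leads(df)


# ----------------------------------------------------------- filter_mendelian

def test_mendelian_empty_exclusion_is_identity():
    df = make_variants([1, 2, 3])
    out = filter_mendelian(df, make_variants([]), 500)
    pd.testing.assert_frame_equal(out, df)


def test_mendelian_500bp_boundary():
    """499 bp from a training variant drops; 500 bp keeps."""
    curated = make_variants([10_499, 10_500])
    exclusion = make_variants([10_000])
    out = filter_mendelian(curated, exclusion, 500)
    assert out["pos"].tolist() == [10_500]


def test_mendelian_matches_pairwise_distance_oracle():
    rng = np.random.default_rng(8)
    curated = make_variants(
        rng.integers(0, 50_000, 80).tolist(),
        mode=rng.choice(["dominant", "recessive"], 80).tolist(),
    )
    exclusion = make_variants(rng.integers(0, 50_000, 40).tolist())
    out = filter_mendelian(curated, exclusion, 500)
    expected = [
        row.pos
        for row in curated.itertuples(index=False)
        if all(abs(row.pos - q) >= 500 for q in exclusion["pos"])
    ]
    assert out["pos"].tolist() == expected
    # filter property: surviving modes are a sub-multiset of the input's
    from collections import Counter

    assert Counter(out["mode"]) <= Counter(curated["mode"])
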
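"""Pathogenic / control / validation variant set construction.

Variants travel as pandas DataFrames with at least the columns
``chrom, pos, ref, alt`` (``pos`` 0-based) and optionally ``label``,
``set_tag``, ``mode`` and the association columns ``p, locus, study,
phenotype``. Set construction follows four rules:

* **declustering** — within a chromosome, greedily keep the
  smallest-coordinate variant, then the next one at least ``min_spacing``
  bp away, and so on, so that no two kept variants are closer than
  ``min_spacing`` (default 500 bp, the resolution of the coarsest
  constraint feature);
* **control matching** — for each pathogenic variant, the k closest
  common variants in the *same genomic element category* with the most
  similar distance to the nearest splice site (default k = 15), followed
  by deduplication and declustering of the pooled controls;
* **region split** — train/test partition by chromosome (arm) membership
  rather than at random, to avoid over-training on individual genes;
* **exclusion filtering** — validation-style sets keep only variants at
  least ``min_spacing`` bp from every variant of an exclusion set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_annotation import AnnotationTrack
from .intervals import GenomicInterval

__all__ = [
    "PipelineConfig",
    "SplitSpec",
    "decluster",
    "match_controls",
    "split_by_regions",
    "select_gwas_leads",
    "filter_mendelian",
]

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class PipelineConfig:
    """Constants of the variant-set and scoring pipeline.

    min_spacing
        Minimum bp between retained variants of one set (default 500).
    splice_exclusion
        Pathogenic variants closer than this to a splice site are excluded
        (default 10 bp).
    k_controls
        Matched controls sought per pathogenic variant (default 15).
    bin_width
        Width of score bins in bp (default 10).
    smoothing_window
        CRISPRi viability smoothing window, in probe pairs (default 20).
    min_pairs
        Minimum sgRNA-pair coverage for a probed region (default 20).
    max_probe_len
        Probed regions at or above this length are dropped (default 1000).
    thresholds
        Percentile thresholds for region enrichment
        (default 95, 99, 99.5, 99.9).
    n_draws
        Number of matched random-region draws (default 100).
    """

    min_spacing: int = 500
    splice_exclusion: int = 10
    k_controls: int = 15
    bin_width: int = 10
    smoothing_window: int = 20
    min_pairs: int = 20
    max_probe_len: int = 1000
    thresholds: tuple[float, ...] = (95.0, 99.0, 99.5, 99.9)
    n_draws: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_spacing",
            "splice_exclusion",
            "k_controls",
            "bin_width",
            "smoothing_window",
            "min_pairs",
            "max_probe_len",
            "n_draws",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        t = tuple(self.thresholds)
        if any(not (0 < x < 100) for x in t) or any(
            a >= b for a, b in zip(t, t[1:])
        ):
            raise ValueError("thresholds must be strictly increasing in (0, 100)")
        self.thresholds = t


@dataclass
class SplitSpec:
    """Genomic regions whose variants form the test set.

    Regions are whole chromosomes or centromere-delimited arms, expressed
    as plain intervals; they must be pairwise non-overlapping.
    """

    test_regions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.test_regions:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort()
            for a, b in zip(ivs, ivs[1:]):
                if a.overlaps(b):
                    raise ValueError(f"overlapping test regions {a} / {b}")

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(chrom), dtype=bool)
        for iv in self.test_regions:
            mask |= (chrom == iv.chrom) & (pos >= iv.start) & (pos < iv.end)
        return mask


def _sorted(variants: pd.DataFrame) -> pd.DataFrame:
    return variants.sort_values(["chrom", "pos"], kind="mergesort")


def decluster(variants: pd.DataFrame, min_spacing: int) -> pd.DataFrame:
    """Greedy per-chromosome declustering.

    On each chromosome the smallest-coordinate variant is kept first, then
    the next variant at distance >= ``min_spacing`` from the last kept one,
    and so on. The result does not depend on the input row order.
    """
    if variants.empty:
        return variants.copy()
    ordered = _sorted(variants)
    keep_idx: list = []
    for _, group in ordered.groupby("chrom", sort=False):
        last = None
        for idx, pos in zip(group.index, group["pos"].to_numpy()):
            if last is None or pos - last >= min_spacing:
                keep_idx.append(idx)
                last = pos
    return ordered.loc[keep_idx]


def _annotate(
    variants: pd.DataFrame, annotation: AnnotationTrack
) -> pd.DataFrame:
    out = variants.copy()
    cat = np.empty(len(out), dtype=np.uint8)
    sd = np.empty(len(out), dtype=np.int64)
    for chrom, group in out.groupby("chrom", sort=False):
        pos = group["pos"].to_numpy()
        cat[out.index.get_indexer(group.index)] = annotation.category_code_at(
            chrom, pos
        )
        sd[out.index.get_indexer(group.index)] = annotation.splice_distance_at(
            chrom, pos
        )
    out["_category"] = cat
    out["_splice_dist"] = sd
    return out


def match_controls(
    pathogenic: pd.DataFrame,
    pool: pd.DataFrame,
    annotation: AnnotationTrack,
    config: PipelineConfig,
    decluster_controls: bool = True,
) -> pd.DataFrame:
    """Select matched control variants for a pathogenic set.

    For each pathogenic variant the candidate pool is restricted to the
    same element category, ranked by |delta splice distance| (ties broken
    by genomic distance to the pathogenic variant, then coordinate) and the
    best ``config.k_controls`` kept. The union of all selections is then
    deduplicated by coordinate and, when ``decluster_controls`` is true,
    declustered at ``config.min_spacing``.

    The pool is expected to be pre-filtered to the caller's frequency
    criterion (e.g. common variants at AF > 1%).
    """
    if pathogenic.empty or pool.empty:
        return pool.iloc[0:0].copy()
    pa = _annotate(pathogenic, annotation)
    po = _annotate(pool, annotation)

    chosen: list[pd.DataFrame] = []
    big = np.int64(1) << 40
    for _, row in pa.iterrows():
        cands = po[po["_category"] == row["_category"]]
        if cands.empty:
            warnings.warn(
                f"no control candidates share category of variant "
                f"{row['chrom']}:{int(row['pos'])}"
            )
            continue
        d_sd = np.abs(cands["_splice_dist"].to_numpy() - row["_splice_dist"])
        same_chrom = cands["chrom"].to_numpy() == row["chrom"]
        d_pos = np.where(
            same_chrom, np.abs(cands["pos"].to_numpy() - row["pos"]), big
        )
        order = np.lexsort(
            (cands["pos"].to_numpy(), cands["chrom"].to_numpy(), d_pos, d_sd)
        )
        chosen.append(cands.iloc[order[: config.k_controls]])

    if not chosen:
        return pool.iloc[0:0].copy()
    union = pd.concat(chosen)
    union = _sorted(union).drop_duplicates(subset=["chrom", "pos"])
    if decluster_controls:
        union = decluster(union, config.min_spacing)
    return union.drop(columns=["_category", "_splice_dist"])


def split_by_regions(
    variants: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition variants into (train, test) by test-region membership."""
    if variants.empty:
        return variants.copy(), variants.copy()
    mask = spec.contains(
        variants["chrom"].to_numpy(), variants["pos"].to_numpy()
    )
    return variants[~mask].copy(), variants[mask].copy()


def select_gwas_leads(records: pd.DataFrame) -> pd.DataFrame:
    """Keep the most significant SNV per (locus, phenotype, study).

    Within each group the record with the smallest association p-value is
    retained (coordinate breaks ties deterministically); afterwards at most
    one record survives per genomic coordinate, the one with the smallest
    p-value across groups.
    """
    required = {"p", "locus", "study", "phenotype"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"association columns missing: {sorted(missing)}")
    if records.empty:
        return records.copy()

    keep: list = []
    for key, group in records.groupby(["locus", "phenotype", "study"], sort=False):
        if len(group) > 1 and group["p"].isna().any():
            raise ValueError(f"missing p-value in multi-SNV group {key}")
        ordered = group.sort_values(["p", "chrom", "pos"], kind="mergesort")
        keep.append(ordered.index[0])
    leads = records.loc[keep]
    leads = leads.sort_values(["p", "chrom", "pos"], kind="mergesort")
    return _sorted(leads.drop_duplicates(subset=["chrom", "pos"]))


def filter_mendelian(
    curated: pd.DataFrame, exclusion_set: pd.DataFrame, min_spacing: int
) -> pd.DataFrame:
    """Keep curated variants >= ``min_spacing`` bp from every excluded variant.

    Distances are computed on the same chromosome only; an empty exclusion
    set returns the input unchanged. Used both for the curated Mendelian
    set (exclusion against training/test variants) and for the cross-set
    exclusion of validation variants.
    """
    if curated.empty or exclusion_set.empty:
        return curated.copy()
    excl: dict[str, np.ndarray] = {
        chrom: np.sort(group["pos"].to_numpy())
        for chrom, group in exclusion_set.groupby("chrom", sort=False)
    }
    keep = np.ones(len(curated), dtype=bool)
    for i, (chrom, pos) in enumerate(
        zip(curated["chrom"].to_numpy(), curated["pos"].to_numpy())
    ):
        sites = excl.get(chrom)
        if sites is None or sites.size == 0:
            continue
        j = np.searchsorted(sites, pos)
        d = min(
            abs(pos - sites[j - 1]) if j > 0 else np.iinfo(np.int64).max,
            abs(sites[j] - pos) if j < sites.size else np.iinfo(np.int64).max,
        )
        keep[i] = d >= min_spacing
    return curated[keep].copy()
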
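"""Performance metrics and region-level functional enrichment analyses.

Covers the statistics used to assess the classifier and its genome-wide
percentile tracks:

* confusion-matrix metrics on the percentage scale (sensitivity,
  specificity, FPR, accuracy, PPV, NPV);
* ROC-AUC and PR-AUC;
* the fraction of regions containing at least one high-percentile bin at a
  set of percentile thresholds, compared against matched-size random
  regions drawn from a universe (same locus or genome-wide) with Fisher's
  exact test;
* CRISPRi tiling-screen probe preparation: viability smoothing over
  consecutive probe pairs, coverage/length filters, exon-overlap removal
  and the functional flag (smoothed log2 fold change <= -1, i.e. at least
  a twofold viability decrease);
* two-sided Fisher / Mann-Whitney / Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .genome_scoring import BinnedTrack
from .intervals import GenomicInterval
from .variant_sets import PipelineConfig

__all__ = [
    "ConfusionCounts",
    "RegionEnrichment",
    "CrispriResult",
    "confusion_metrics",
    "roc_pr",
    "fraction_high_regions",
    "sample_matched_regions",
    "smooth_series",
    "crispri_prepare",
    "enrichment_tests",
    "region_enrichment",
]

#: Smoothed log2 fold change at or below which a probe counts as functional
#: (a twofold or larger viability decrease).
FUNCTIONAL_LOG2FC = -1.0


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Percentage-scale confusion metrics; None where a denominator is 0.

    sensitivity = TP/(TP+FN)x100, specificity = TN/(TN+FP)x100,
    fpr = FP/(FP+TN)x100, accuracy = (TP+TN)/totalx100,
    ppv = TP/(TP+FP)x100, npv = TN/(TN+FN)x100.
    """
    def frac(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    total = c.tp + c.tn + c.fp + c.fn
    if total == 0:
        raise ValueError("all confusion counts are zero")
    return {
        "sensitivity": frac(c.tp, c.tp + c.fn),
        "specificity": frac(c.tn, c.tn + c.fp),
        "fpr": frac(c.fp, c.fp + c.tn),
        "accuracy": frac(c.tp + c.tn, total),
        "ppv": frac(c.tp, c.tp + c.fp),
        "npv": frac(c.tn, c.tn + c.fn),
    }


def roc_pr(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """(ROC-AUC, PR-AUC) for binary labels.

    ROC-AUC is the rank statistic (equivalently trapezoidal integration
    over all thresholds); PR-AUC uses step-wise integration of the
    precision-recall curve.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for ROC/PR")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def fraction_high_regions(
    regions: list[GenomicInterval],
    track: BinnedTrack,
    thresholds: tuple[float, ...] = (95.0, 99.0, 99.5, 99.9),
) -> np.ndarray:
    """Per-threshold fraction of regions with >= 1 bin above the threshold."""
    if not regions:
        raise ValueError("empty region list")
    thresholds = tuple(thresholds)
    hits = np.zeros(len(thresholds))
    for region in regions:
        idx = track.bins_overlapping(region)
        vals = track.percentile[region.chrom][idx] if idx.size else np.empty(0)
        vals = vals[~np.isnan(vals)]
        best = vals.max() if vals.size else -np.inf
        for j, t in enumerate(thresholds):
            if best > t:
                hits[j] += 1
    return hits / len(regions)


def sample_matched_regions(
    template: list[GenomicInterval],
    universe: list[GenomicInterval],
    n_draws: int = 100,
    seed: int = 0,
) -> list[list[GenomicInterval]]:
    """Draw matched-size random regions from a universe, ``n_draws`` times.

    Each draw contains one region per template interval with identical
    length, its start uniform over all valid placements inside the
    universe. Draws are independent (regions may repeat or overlap).
    """
    rng = np.random.default_rng(seed)
    u_chroms = [iv.chrom for iv in universe]
    u_starts = np.asarray([iv.start for iv in universe])
    u_lens = np.asarray([len(iv) for iv in universe])
    draws: list[list[GenomicInterval]] = []
    for _ in range(n_draws):
        drawn: list[GenomicInterval] = []
        for t in template:
            slots = u_lens - len(t) + 1
            slots = np.maximum(slots, 0)
            total = int(slots.sum())
            if total == 0:
                raise ValueError(
                    f"template {t} longer than every universe interval"
                )
            k = int(rng.integers(total))
            j = int(np.searchsorted(np.cumsum(slots), k, side="right"))
            offset = k - (int(np.cumsum(slots)[j - 1]) if j > 0 else 0)
            start = int(u_starts[j]) + offset
            drawn.append(GenomicInterval(u_chroms[j], start, start + len(t)))
        draws.append(drawn)
    return draws


def smooth_series(values: np.ndarray, window: int = 20) -> np.ndarray:
    """Trailing rolling mean in coordinate order.

    Entry *i* averages ``values[i : i+window]``; the final entries average
    over however many remain.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    for i in range(v.size):
        j = min(i + window, v.size)
        out[i] = (csum[j] - csum[i]) / (j - i)
    return out


@dataclass
class CrispriResult:
    """Filtered CRISPRi probe table plus the filter-chain bookkeeping."""

    probes: pd.DataFrame
    n_input: int
    n_pass_filters: int  # after coverage and length filters
    n_exon_overlap: int  # flagged (and removed) among those passing
    n_retained: int      # final probe count

    @property
    def exon_overlap_percent(self) -> float:
        return 100.0 * self.n_exon_overlap / self.n_pass_filters


def crispri_prepare(
    probes: pd.DataFrame,
    exons: list[GenomicInterval],
    config: PipelineConfig,
) -> CrispriResult:
    """Prepare a CRISPRi tiling screen for percentile comparison.

    Input columns: chrom, start, end, viability (log2 fold change),
    n_pairs (pairs covering the probed region). Steps, in order: drop rows
    with missing viability (warning); smooth viability over
    ``config.smoothing_window`` consecutive pairs per chromosome in
    coordinate order; keep probes covered by >= ``config.min_pairs`` pairs
    and shorter than ``config.max_probe_len``; flag and remove probes
    overlapping any exon; flag as functional the probes whose smoothed
    viability indicates at least a twofold decrease (log2FC <= -1).
    """
    df = probes.copy()
    n_missing = int(df["viability"].isna().sum())
    if n_missing:
        warnings.warn(f"dropping {n_missing} probes with missing viability")
        df = df[df["viability"].notna()]
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    df["smoothed_viability"] = np.nan
    for chrom, group in df.groupby("chrom", sort=False):
        df.loc[group.index, "smoothed_viability"] = smooth_series(
            group["viability"].to_numpy(), config.smoothing_window
        )

    length = df["end"] - df["start"]
    passing = df[(df["n_pairs"] >= config.min_pairs) & (length < config.max_probe_len)]

    exon_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in exons:
        exon_by_chrom.setdefault(iv.chrom, []).append(iv)
    overlap = np.zeros(len(passing), dtype=bool)
    for i, row in enumerate(passing.itertuples(index=False)):
        for iv in exon_by_chrom.get(row.chrom, ()):
            if row.start < iv.end and iv.start < row.end:
                overlap[i] = True
                break
    passing = passing.assign(exon_overlap=overlap)
    retained = passing[~passing["exon_overlap"]].copy()
    retained["functional"] = retained["smoothed_viability"] <= FUNCTIONAL_LOG2FC
    return CrispriResult(
        probes=retained,
        n_input=len(probes),
        n_pass_filters=len(passing),
        n_exon_overlap=int(overlap.sum()),
        n_retained=len(retained),
    )


def enrichment_tests(observed, reference, kind: str = "fisher") -> float:
    """Two-sided p-value comparing observed against reference.

    fisher: observed and reference are the rows of a 2x2 count table.
    mann_whitney / ks: observed and reference are value samples.
    """
    if kind == "fisher":
        table = np.asarray([observed, reference])
        if table.shape != (2, 2) or np.any(table < 0):
            raise ValueError("fisher requires a non-negative 2x2 table")
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            raise ValueError("fisher table has an empty margin")
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if obs.size == 0 or ref.size == 0:
        raise ValueError("empty sample")
    if kind == "mann_whitney":
        return float(stats.mannwhitneyu(obs, ref, alternative="two-sided")[1])
    if kind == "ks":
        return float(stats.ks_2samp(obs, ref, alternative="two-sided")[1])
    raise ValueError(f"unknown test kind {kind!r}")


@dataclass
class RegionEnrichment:
    """Observed vs matched-random high-percentile region fractions."""

    thresholds: tuple[float, ...]
    observed_fraction: np.ndarray          # per threshold
    random_fractions: np.ndarray           # (n_draws, n_thresholds)
    fisher_p: np.ndarray                   # per threshold

    @property
    def random_mean_fraction(self) -> np.ndarray:
        return self.random_fractions.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "observed_fraction": self.observed_fraction,
                "random_mean_fraction": self.random_mean_fraction,
                "fisher_p": self.fisher_p,
            }
        )


def region_enrichment(
    regions: list[GenomicInterval],
    track: BinnedTrack,
    universe: list[GenomicInterval],
    config: PipelineConfig,
) -> RegionEnrichment:
    """Observed region fractions vs matched-size random draws, with Fisher p.

    For each percentile threshold, the observed hit/miss counts are tested
    against the hit/miss counts pooled over all random draws.
    """
    thresholds = config.thresholds
    observed = fraction_high_regions(regions, track, thresholds)
    draws = sample_matched_regions(
        regions, universe, n_draws=config.n_draws, seed=config.seed
    )
    random_fracs = np.stack(
        [fraction_high_regions(d, track, thresholds) for d in draws]
    )
    n_obs = len(regions)
    n_rand = random_fracs.shape[0] * n_obs
    fisher = np.empty(len(thresholds))
    for j in range(len(thresholds)):
        obs_hits = int(round(observed[j] * n_obs))
        rand_hits = int(round(random_fracs[:, j].sum() * n_obs))
        fisher[j] = enrichment_tests(
            [obs_hits, n_obs - obs_hits],
            [rand_hits, n_rand - rand_hits],
            kind="fisher",
        )
    return RegionEnrichment(
        thresholds=thresholds,
        observed_fraction=observed,
        random_fractions=random_fracs,
        fisher_p=fisher,
    )
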
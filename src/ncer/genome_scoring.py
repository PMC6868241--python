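"""Genome-wide percentile tracks from per-base raw scores.

Two percentile layers are produced: per-nucleotide percentiles of the raw
score, and a second layer where raw scores are first averaged over
fixed-width bins (default 10 bp, aligned to offset 0 of each chromosome)
and the bin means re-expressed as genome-wide percentiles.

Percentile convention: ``percentile(x) = 100 * #(raw <= x) / n`` over all
scored positions, so ties share the maximal rank and a constant track is
uniformly at the 100th percentile. Because the classifier is not meaningful
over protein-coding sequence, callers may mask positions (by default CDS is
masked when an annotation track is supplied); masked positions carry NaN
and are excluded from the percentile population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome_annotation import CATEGORY_PRIORITY, AnnotationTrack
from .intervals import GenomicInterval

__all__ = [
    "ScoreTrack",
    "BinnedTrack",
    "genomewide_percentiles",
    "bin_and_repercentile",
    "region_summary",
]


def _percentiles_of(values: np.ndarray, population: np.ndarray) -> np.ndarray:
    """100 * fraction of the population <= each value (NaN passes through)."""
    pop = np.sort(population[~np.isnan(population)])
    if pop.size == 0:
        raise ValueError("empty score population")
    out = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    out[ok] = 100.0 * np.searchsorted(pop, values[ok], side="right") / pop.size
    return out


@dataclass
class ScoreTrack:
    """Per-base raw scores in [0, 1] and their genome-wide percentiles."""

    raw: dict[str, np.ndarray]
    percentile: dict[str, np.ndarray]

    @property
    def chroms(self) -> list[str]:
        return sorted(self.raw)

    def all_raw(self) -> np.ndarray:
        return np.concatenate([self.raw[c] for c in self.chroms])

    def all_percentiles(self) -> np.ndarray:
        return np.concatenate([self.percentile[c] for c in self.chroms])


@dataclass
class BinnedTrack:
    """Fixed-width bin means of a raw score track, re-percentiled genome-wide.

    Bins are aligned to offset 0 of each chromosome; the terminal bin of a
    chromosome may be shorter and its mean is taken over the available
    bases.
    """

    width: int
    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    mean_raw: dict[str, np.ndarray]
    percentile: dict[str, np.ndarray]

    @property
    def chroms(self) -> list[str]:
        return sorted(self.starts)

    def bins_overlapping(self, region: GenomicInterval) -> np.ndarray:
        """Indices of bins sharing at least one base with the region."""
        if region.chrom not in self.starts:
            return np.empty(0, dtype=np.int64)
        first = region.start // self.width
        last = (region.end - 1) // self.width
        n = self.starts[region.chrom].size
        if first >= n or last < 0:
            return np.empty(0, dtype=np.int64)
        return np.arange(max(first, 0), min(last, n - 1) + 1, dtype=np.int64)


def genomewide_percentiles(
    raw: dict[str, np.ndarray],
    annotation: AnnotationTrack | None = None,
    mask: dict[str, np.ndarray] | None = None,
) -> ScoreTrack:
    """Attach genome-wide percentiles to per-base raw scores.

    ``mask[chrom]`` marks positions to *exclude* (scored NaN). When an
    annotation track is given and no explicit mask, CDS bases are masked.
    All unmasked raw values must be finite and in [0, 1].
    """
    if not raw or all(v.size == 0 for v in raw.values()):
        raise ValueError("empty score track")
    if mask is None and annotation is not None:
        mask = {
            c: annotation.codes[c][: raw[c].size] == CATEGORY_PRIORITY["CDS"]
            for c in raw
        }
    masked: dict[str, np.ndarray] = {}
    for c, v in raw.items():
        v = np.asarray(v, dtype=float).copy()
        if mask is not None and c in mask:
            v[mask[c][: v.size]] = np.nan
        ok = v[~np.isnan(v)]
        if np.any(~np.isfinite(ok)) or (ok.size and (ok.min() < 0 or ok.max() > 1)):
            raise ValueError(f"raw scores on {c} not finite in [0, 1]")
        masked[c] = v
    population = np.concatenate(list(masked.values()))
    pct = {c: _percentiles_of(v, population) for c, v in masked.items()}
    return ScoreTrack(raw=masked, percentile=pct)


def bin_and_repercentile(track: ScoreTrack, width: int = 10) -> BinnedTrack:
    """Average raw scores over fixed bins and re-percentile the bin means.

    Bins containing only masked (NaN) bases get NaN means and are excluded
    from the percentile population; partially masked bins average over
    their scored bases.
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    means: dict[str, np.ndarray] = {}
    for c in track.chroms:
        v = track.raw[c]
        n_bins = (v.size + width - 1) // width
        bs = np.arange(n_bins, dtype=np.int64) * width
        be = np.minimum(bs + width, v.size)
        filled = np.where(np.isnan(v), 0.0, v)
        counts = np.add.reduceat((~np.isnan(v)).astype(float), bs)
        sums = np.add.reduceat(filled, bs)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(counts > 0, sums / counts, np.nan)
        starts[c], ends[c], means[c] = bs, be, m
    population = np.concatenate(list(means.values()))
    pct = {c: _percentiles_of(m, population) for c, m in means.items()}
    return BinnedTrack(
        width=width, starts=starts, ends=ends, mean_raw=means, percentile=pct
    )


def region_summary(
    track: ScoreTrack | BinnedTrack,
    regions: list[GenomicInterval],
    stat: str = "max",
    layer: str = "percentile",
) -> np.ndarray:
    """Per-region summary statistic over the bases (or bins) each overlaps.

    ``stat`` is max, median or mean; ``layer`` selects percentile or raw
    values. Regions without any scored base yield NaN with a warning.
    """
    reducer = {"max": np.nanmax, "median": np.nanmedian, "mean": np.nanmean}[stat]
    out = np.full(len(regions), np.nan)
    for i, region in enumerate(regions):
        if isinstance(track, BinnedTrack):
            idx = track.bins_overlapping(region)
            layer_vals = (
                track.percentile if layer == "percentile" else track.mean_raw
            )
            vals = layer_vals[region.chrom][idx] if idx.size else np.empty(0)
        else:
            data = track.percentile if layer == "percentile" else track.raw
            arr = data.get(region.chrom)
            if arr is None:
                vals = np.empty(0)
            else:
                vals = arr[region.start : min(region.end, arr.size)]
        vals = vals[~np.isnan(vals)] if vals.size else vals
        if vals.size == 0:
            warnings.warn(f"region {region} has no scored overlap")
            continue
        out[i] = reducer(vals)
    return out
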
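"""Core genomic primitives shared by every layer of the package.

All coordinates are 0-based, half-open (BED dialect): an interval covers
``start .. end-1``. Variant positions are 0-based internally; the VCF-like
writers in :mod:`ncer.io` shift to 1-based at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomicInterval", "GeneModel", "interval_lookup", "merge_intervals"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene body with an ordered exon structure and optional gene-level scores.

    Exons are (start, end) pairs in 0-based half-open coordinates, sorted,
    pairwise disjoint and contained in the body. ``gene_scores`` carries
    gene-level annotations such as pLI, haploinsufficiency, dosage
    sensitivity, inheritance-mode flags or expression summaries.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    gene_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r} for gene {self.gene_id}")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad body for gene {self.gene_id}")
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(f"exon ({s},{e}) outside body of {self.gene_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"exons of {self.gene_id} unsorted or overlapping")
            prev_end = e

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (empty for single-exon genes)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        ]

    def splice_junctions(self) -> list[int]:
        """Internal exon boundaries (donor and acceptor sides).

        Single-exon genes contribute none; terminal gene boundaries are not
        junctions.
        """
        if len(self.exons) < 2:
            return []
        sites: list[int] = []
        for i, (s, e) in enumerate(self.exons):
            if i > 0:
                sites.append(s)
            if i < len(self.exons) - 1:
                sites.append(e)
        return sites


def interval_lookup(
    starts: np.ndarray, ends: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Index of the covering interval for each position, -1 if uncovered.

    Intervals must be sorted by start and pairwise non-overlapping.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    positions = np.asarray(positions)
    if starts.size == 0:
        return np.full(positions.shape, -1, dtype=np.int64)
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("interval_lookup requires sorted, non-overlapping intervals")
    idx = np.searchsorted(starts, positions, side="right") - 1
    idx = idx.astype(np.int64)
    hit = (idx >= 0) & (positions < ends[np.clip(idx, 0, len(ends) - 1)])
    idx[~hit] = -1
    return idx


def merge_intervals(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly overlapping (start, end) pairs, sorted and disjoint."""
    if not pairs:
        return []
    pairs = sorted(pairs)
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
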
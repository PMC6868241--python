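"""Single-category-per-base genomic element annotation and splice distances.

Every base of the genome is assigned exactly one element category by a fixed
priority scheme, highest priority first::

    CDS > intron (cis, < 10 bp from a splice site) > ncRNA > UTR
        > multicell regulatory > intron (distal) > annotated feature
        > intergenic

CDS and intron bases derive from gene models; the remaining categories come
from labeled regulatory intervals. Uncovered bases fall through to
INTERGENIC. The track also stores, for every base, the distance in bp to
the nearest splice site (internal exon boundary of any multi-exon gene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .intervals import GeneModel

__all__ = [
    "CATEGORIES",
    "CATEGORY_PRIORITY",
    "DISPLAY_GROUPS",
    "AnnotationTrack",
    "assign_element_categories",
    "distance_to_splice_site",
    "splice_junctions_by_chrom",
]

#: Element categories in priority order (index = priority rank, 0 highest).
CATEGORIES: tuple[str, ...] = (
    "CDS",
    "INTRON_CIS",
    "NCRNA",
    "UTR",
    "MULTICELL_REGULATORY",
    "INTRON_DISTAL",
    "ANNOTATED_FEATURE",
    "INTERGENIC",
)

CATEGORY_PRIORITY: dict[str, int] = {name: i for i, name in enumerate(CATEGORIES)}

#: Labels accepted on regulatory input intervals (gene models supply the rest).
REGULATORY_LABELS = {"NCRNA", "UTR", "MULTICELL_REGULATORY", "ANNOTATED_FEATURE"}

#: Optional presentation relabeling used when summarising element content
#: (promoters/UTRs shown together as cis-regulatory, etc.). Purely cosmetic;
#: never part of the stored track.
DISPLAY_GROUPS: dict[str, str] = {
    "CDS": "CDS",
    "INTRON_CIS": "Intron",
    "INTRON_DISTAL": "Intron",
    "NCRNA": "ncRNA",
    "UTR": "Cis Regulatory",
    "MULTICELL_REGULATORY": "Enhancers and Others",
    "ANNOTATED_FEATURE": "Enhancers and Others",
    "INTERGENIC": "Intergenic",
}

#: Number of bp below which an intronic base counts as splice-proximal (cis).
SPLICE_CIS_BP = 10


def splice_junctions_by_chrom(gene_models: list[GeneModel]) -> dict[str, np.ndarray]:
    """Sorted unique splice-junction coordinates per chromosome.

    Junctions are internal exon boundaries of multi-exon genes, pooled over
    all supplied gene models.
    """
    sites: dict[str, list[int]] = {}
    for gm in gene_models:
        js = gm.splice_junctions()
        if js:
            sites.setdefault(gm.chrom, []).extend(js)
    return {c: np.unique(np.asarray(v, dtype=np.int64)) for c, v in sites.items()}


def distance_to_splice_site(
    pos: int | np.ndarray,
    gene_models: list[GeneModel],
    chrom: str,
) -> np.ndarray:
    """Distance in bp from position(s) to the nearest splice junction.

    The minimum is taken over junctions on every chromosome's genes — in
    practice junctions on *chrom* dominate, but a chromosome without any
    multi-exon gene still gets finite distances only if it has junctions;
    positions on a junction-free chromosome are assigned the distance to
    nothing, which is undefined.

    Raises
    ------
    ValueError
        If no gene model anywhere contributes a splice junction.
    """
    by_chrom = splice_junctions_by_chrom(gene_models)
    if not by_chrom:
        raise ValueError("undefined distance: no splice site in any gene model")
    pos_arr = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    junctions = by_chrom.get(chrom)
    if junctions is None or junctions.size == 0:
        out = np.full(pos_arr.shape, np.iinfo(np.int64).max, dtype=np.int64)
    else:
        out = _min_distance_to_sorted(pos_arr, junctions)
    return out if np.ndim(pos) else out[0]


def _min_distance_to_sorted(positions: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """min |pos - site| for sorted site coordinates, vectorized."""
    idx = np.searchsorted(sites, positions)
    left = np.where(idx > 0, np.abs(positions - sites[np.maximum(idx - 1, 0)]),
                    np.iinfo(np.int64).max)
    right = np.where(idx < sites.size,
                     np.abs(sites[np.minimum(idx, sites.size - 1)] - positions),
                     np.iinfo(np.int64).max)
    return np.minimum(left, right)


@dataclass
class AnnotationTrack:
    """Per-base element category and splice-site distance for a genome.

    ``codes[chrom][i]`` is the index into :data:`CATEGORIES` for base *i*;
    ``splice_distance[chrom][i]`` is the bp distance to the nearest splice
    junction (a large sentinel on junction-free chromosomes, ``None`` for
    everything if the genome has no junctions at all — in that case the
    distance is undefined and accessors raise).
    """

    chrom_sizes: dict[str, int]
    codes: dict[str, np.ndarray]
    splice_distance: dict[str, np.ndarray] | None

    def category_at(self, chrom: str, pos: int | np.ndarray) -> np.ndarray | str:
        codes = self.codes[chrom][pos]
        if np.ndim(pos):
            return np.asarray([CATEGORIES[c] for c in codes])
        return CATEGORIES[int(codes)]

    def category_code_at(self, chrom: str, pos) -> np.ndarray:
        return self.codes[chrom][pos]

    def splice_distance_at(self, chrom: str, pos):
        if self.splice_distance is None:
            raise ValueError("undefined splice distance: genome has no splice sites")
        return self.splice_distance[chrom][pos]

    def to_intervals(self) -> list[tuple[str, int, int, str]]:
        """Run-length encode the track as (chrom, start, end, category) rows."""
        rows: list[tuple[str, int, int, str]] = []
        for chrom in sorted(self.chrom_sizes):
            codes = self.codes[chrom]
            if codes.size == 0:
                continue
            change = np.flatnonzero(np.diff(codes)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [codes.size]])
            for s, e in zip(starts, ends):
                rows.append((chrom, int(s), int(e), CATEGORIES[codes[s]]))
        return rows

    def validate(self) -> None:
        """Assert the category intervals tile each chromosome exactly."""
        for chrom, size in self.chrom_sizes.items():
            if self.codes[chrom].size != size:
                raise AssertionError(f"{chrom}: track length != chromosome length")
        per_chrom: dict[str, int] = {c: 0 for c in self.chrom_sizes}
        for chrom, s, e, _ in self.to_intervals():
            per_chrom[chrom] += e - s
        for chrom, size in self.chrom_sizes.items():
            if per_chrom[chrom] != size:
                raise AssertionError(f"{chrom}: category intervals do not tile")


def assign_element_categories(
    gene_models: list[GeneModel],
    regulatory: list[tuple[str, int, int, str]],
    chrom_sizes: dict[str, int],
) -> AnnotationTrack:
    """Build the annotation track from gene models and labeled intervals.

    Parameters
    ----------
    gene_models
        Genes whose exons become CDS and whose exon gaps become introns
        (cis or distal by splice distance).
    regulatory
        (chrom, start, end, label) rows with label in
        ``{NCRNA, UTR, MULTICELL_REGULATORY, ANNOTATED_FEATURE}``.
    chrom_sizes
        Declared chromosome lengths; every interval must fit inside.

    Each base receives the highest-priority category among all covering
    annotations; uncovered bases are INTERGENIC.
    """
    junctions = splice_junctions_by_chrom(gene_models)
    have_junctions = any(v.size for v in junctions.values())

    codes: dict[str, np.ndarray] = {}
    sdist: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        codes[chrom] = np.full(size, CATEGORY_PRIORITY["INTERGENIC"], dtype=np.uint8)
        js = junctions.get(chrom)
        if js is not None and js.size:
            sdist[chrom] = _min_distance_to_sorted(
                np.arange(size, dtype=np.int64), js
            )
        else:
            sdist[chrom] = np.full(size, np.iinfo(np.int64).max, dtype=np.int64)

    def _check_bounds(chrom: str, start: int, end: int) -> None:
        if chrom not in chrom_sizes:
            raise ValueError(f"interval on undeclared chromosome {chrom}:{start}-{end}")
        if start < 0 or end > chrom_sizes[chrom]:
            raise ValueError(
                f"interval outside chromosome bounds: {chrom}:{start}-{end} "
                f"(length {chrom_sizes[chrom]})"
            )

    def _apply(chrom: str, start: int, end: int, priority: int) -> None:
        seg = codes[chrom][start:end]
        np.minimum(seg, priority, out=seg)

    for gm in gene_models:
        _check_bounds(gm.chrom, gm.start, gm.end)
        for s, e in gm.exons:
            _apply(gm.chrom, s, e, CATEGORY_PRIORITY["CDS"])
        for s, e in gm.introns():
            d = sdist[gm.chrom][s:e]
            cis = d < SPLICE_CIS_BP
            seg = codes[gm.chrom][s:e]
            np.minimum(
                seg,
                np.where(
                    cis,
                    CATEGORY_PRIORITY["INTRON_CIS"],
                    CATEGORY_PRIORITY["INTRON_DISTAL"],
                ).astype(np.uint8),
                out=seg,
            )

    for chrom, start, end, label in regulatory:
        if label not in REGULATORY_LABELS:
            warnings.warn(f"ignoring interval with unknown label {label!r}")
            continue
        _check_bounds(chrom, start, end)
        _apply(chrom, start, end, CATEGORY_PRIORITY[label])

    track = AnnotationTrack(
        chrom_sizes=dict(chrom_sizes),
        codes=codes,
        splice_distance=sdist if have_junctions else None,
    )
    track.validate()
    return track
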
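"""Per-variant feature matrix construction.

Heterogeneous genomic tracks are turned into one numeric matrix (rows =
variants, columns = named features) using attribution rules that depend on
the track kind:

``continuous``
    Point lookup of a step function stored as non-overlapping value
    intervals (bedGraph-like).
``per_allele``
    Scores keyed by (chrom, pos, alt); the values present at the variant's
    position are collapsed to the most deleterious one.
``gene_level``
    The variant is attributed the named score of its nearest gene
    (distance to the gene body; 0 inside).
``interaction``
    Promoter-contact maps yield three aspects: a binary contact flag, the
    maximum essentiality (pLI) over all contacted genes, and the number of
    cell lines supporting the contact.
``interval_binary`` / ``interval_count``
    Membership flag, or the count value of the covering interval.

Missing coverage yields NaN, which the downstream tree ensemble routes
natively — no imputation is performed, preserving the sparsity of real
assay-derived tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GeneModel, interval_lookup, merge_intervals

__all__ = [
    "FeatureTrack",
    "InteractionMap",
    "nearest_gene",
    "collapse_allelic",
    "interaction_features",
    "build_feature_matrix",
]

TRACK_KINDS = {
    "continuous",
    "per_allele",
    "gene_level",
    "interaction",
    "interval_binary",
    "interval_count",
}
INTERACTION_ASPECTS = ("contact", "essentiality", "cell_line_count")


@dataclass
class FeatureTrack:
    """One named feature and the data needed to evaluate it at a position.

    ``higher_is_deleterious`` declares the track's direction; tracks where
    larger means *more benign* are sign-flipped before any "most
    deleterious" collapse so that all collapses are maxima.

    ``data`` schema by kind:

    * continuous — DataFrame(chrom, start, end, value), non-overlapping;
    * per_allele — DataFrame(chrom, pos, ref, alt, value);
    * gene_level — unused; ``score_name`` selects the gene score;
    * interaction — unused; the shared :class:`InteractionMap` is queried,
      ``aspect`` selects which of the three values this column carries;
    * interval_binary — DataFrame(chrom, start, end), overlaps allowed;
    * interval_count — DataFrame(chrom, start, end, value) with
      non-negative integer values, non-overlapping.
    """

    name: str
    kind: str
    data: pd.DataFrame | None = None
    score_name: str | None = None
    aspect: str | None = None
    higher_is_deleterious: bool = True

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r} for {self.name}")
        if self.kind == "gene_level" and not self.score_name:
            raise ValueError(f"gene_level track {self.name} needs score_name")
        if self.kind == "interaction" and self.aspect not in INTERACTION_ASPECTS:
            raise ValueError(
                f"interaction track {self.name} needs aspect in "
                f"{INTERACTION_ASPECTS}"
            )
        if self.kind == "interval_count" and self.data is not None:
            v = self.data["value"].to_numpy()
            if np.any(v < 0) or not np.allclose(v, np.round(v)):
                raise ValueError(f"interval_count track {self.name}: "
                                 "values must be non-negative integers")


class InteractionMap:
    """Distal fragment -> promoter contacts from chromatin-conformation data.

    Rows are (chrom, start, end, gene_id, n_cell_lines): a genomic fragment
    in physical contact with the promoter of ``gene_id``, observed in
    ``n_cell_lines`` cell lines. Fragments may overlap each other.
    """

    def __init__(self, pairs: pd.DataFrame, gene_models: list[GeneModel]):
        known = {gm.gene_id: gm for gm in gene_models}
        self._trees: dict[str, IntervalTree] = {}
        kept = 0
        for row in pairs.itertuples(index=False):
            gm = known.get(row.gene_id)
            if gm is None:
                warnings.warn(
                    f"interaction pair skipped: unresolvable gene {row.gene_id!r}"
                )
                continue
            tree = self._trees.setdefault(row.chrom, IntervalTree())
            tree.addi(int(row.start), int(row.end),
                      (gm, int(getattr(row, "n_cell_lines", 1))))
            kept += 1
        self.n_pairs = kept

    def contacts_at(self, chrom: str, pos: int) -> list[tuple[GeneModel, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree[int(pos)]]


def nearest_gene(
    pos: int, chrom: str, gene_models: list[GeneModel]
) -> tuple[str, int] | None:
    """Nearest gene body to a position (0 bp if inside).

    Ties are broken by smaller gene start, then gene_id. Returns None when
    the chromosome carries no gene.
    """
    best: tuple[int, int, str] | None = None
    for gm in gene_models:
        if gm.chrom != chrom:
            continue
        if gm.start <= pos < gm.end:
            d = 0
        elif pos < gm.start:
            d = gm.start - pos
        else:
            d = pos - (gm.end - 1)
        key = (d, gm.start, gm.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    d, _, gid = best
    return gid, d


def collapse_allelic(
    per_alt_scores: Mapping[str, float], higher_is_deleterious: bool = True
) -> float:
    """Collapse per-alternative scores to the most deleterious value.

    After direction normalisation the most deleterious value is the
    maximum; tracks where larger means more benign take the minimum of the
    raw values. NaN entries are ignored; all-absent yields NaN.
    """
    vals = np.asarray(
        [v for v in per_alt_scores.values() if v is not None], dtype=float
    )
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.max() if higher_is_deleterious else vals.min())


def interaction_features(
    pos: int,
    chrom: str,
    imap: InteractionMap,
    essentiality_score: str = "pLI",
) -> tuple[int, float, int]:
    """(contact flag, attributed essentiality, cell-line count) at a position.

    The flag is 1 iff the position lies in any fragment contacting a
    promoter; the attributed essentiality is the maximum of the named gene
    score over all contacted genes (NaN with no contact); the cell-line
    count is the largest multiplicity among covering fragments (0 with no
    contact).
    """
    contacts = imap.contacts_at(chrom, pos)
    if not contacts:
        return 0, float("nan"), 0
    scores = [
        gm.gene_scores.get(essentiality_score, float("nan")) for gm, _ in contacts
    ]
    scores = [s for s in scores if not np.isnan(s)]
    attributed = max(scores) if scores else float("nan")
    n_cell = max(n for _, n in contacts)
    return 1, attributed, n_cell


def _continuous_values(
    track: FeatureTrack, chrom: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    out = np.full(len(pos), np.nan)
    data = track.data
    if data is None or data.empty:
        return out
    for c, sub in data.groupby("chrom", sort=False):
        sel = np.flatnonzero(chrom == c)
        if sel.size == 0:
            continue
        sub = sub.sort_values("start")
        idx = interval_lookup(
            sub["start"].to_numpy(), sub["end"].to_numpy(), pos[sel]
        )
        vals = sub["value"].to_numpy()
        hit = idx >= 0
        out[sel[hit]] = vals[idx[hit]]
    return out


def _binary_values(
    track: FeatureTrack, chrom: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    out = np.zeros(len(pos))
    data = track.data
    if data is None or data.empty:
        return out
    for c, sub in data.groupby("chrom", sort=False):
        sel = np.flatnonzero(chrom == c)
        if sel.size == 0:
            continue
        merged = merge_intervals(
            list(zip(sub["start"].tolist(), sub["end"].tolist()))
        )
        starts = np.asarray([s for s, _ in merged])
        ends = np.asarray([e for _, e in merged])
        idx = interval_lookup(starts, ends, pos[sel])
        out[sel[idx >= 0]] = 1.0
    return out


def _per_allele_values(
    track: FeatureTrack, variants: pd.DataFrame
) -> np.ndarray:
    out = np.full(len(variants), np.nan)
    data = track.data
    if data is None or data.empty:
        return out
    grouped: dict[tuple, dict[str, float]] = {}
    for row in data.itertuples(index=False):
        grouped.setdefault((row.chrom, int(row.pos)), {})[row.alt] = float(row.value)
    for i, (c, p) in enumerate(zip(variants["chrom"], variants["pos"])):
        scores = grouped.get((c, int(p)))
        if scores:
            out[i] = collapse_allelic(scores, track.higher_is_deleterious)
    return out


def build_feature_matrix(
    variants: pd.DataFrame,
    registry: list[FeatureTrack],
    gene_models: list[GeneModel],
    interactions: InteractionMap | None = None,
) -> pd.DataFrame:
    """Evaluate every registry feature at every variant.

    Returns a DataFrame indexed like ``variants`` whose columns are exactly
    the registry names, in registry order, plus a ``label`` column when the
    input carries one. Cells without coverage are NaN.
    """
    names = [t.name for t in registry]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate feature names in registry: {dup}")
    needs_imap = any(t.kind == "interaction" for t in registry)
    if needs_imap and interactions is None:
        raise ValueError("registry contains interaction tracks but no "
                         "InteractionMap was supplied")

    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    cols: dict[str, np.ndarray] = {}

    nearest_cache: dict[tuple[str, int], tuple[str, int] | None] = {}

    def _nearest(c: str, p: int):
        key = (c, p)
        if key not in nearest_cache:
            nearest_cache[key] = nearest_gene(p, c, gene_models)
        return nearest_cache[key]

    interaction_cache: dict[tuple[str, int], tuple[int, float, int]] = {}

    def _interaction(c: str, p: int):
        key = (c, p)
        if key not in interaction_cache:
            interaction_cache[key] = interaction_features(p, c, interactions)
        return interaction_cache[key]

    gene_by_id = {gm.gene_id: gm for gm in gene_models}

    for track in registry:
        if track.kind == "continuous":
            cols[track.name] = _continuous_values(track, chrom, pos)
        elif track.kind == "per_allele":
            cols[track.name] = _per_allele_values(track, variants)
        elif track.kind == "gene_level":
            vals = np.full(len(variants), np.nan)
            for i, (c, p) in enumerate(zip(chrom, pos)):
                hit = _nearest(c, int(p))
                if hit is not None:
                    gm = gene_by_id[hit[0]]
                    vals[i] = gm.gene_scores.get(track.score_name, np.nan)
            cols[track.name] = vals
        elif track.kind == "interaction":
            vals = np.full(len(variants), np.nan)
            for i, (c, p) in enumerate(zip(chrom, pos)):
                flag, ess, n_cell = _interaction(c, int(p))
                vals[i] = {
                    "contact": float(flag),
                    "essentiality": ess,
                    "cell_line_count": float(n_cell),
                }[track.aspect]
            cols[track.name] = vals
        elif track.kind == "interval_binary":
            cols[track.name] = _binary_values(track, chrom, pos)
        elif track.kind == "interval_count":
            vals = _continuous_values(track, chrom, pos)
            cols[track.name] = np.where(np.isnan(vals), 0.0, vals)
        else:  # pragma: no cover - guarded in FeatureTrack
            raise AssertionError(track.kind)

    matrix = pd.DataFrame(cols, index=variants.index)
    if "label" in variants.columns:
        matrix["label"] = variants["label"].to_numpy()
    return matrix
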
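"""Synthetic genomes, feature tracks and variant sets with planted structure.

The generator emulates the data model of the scoring pipeline end to end on
a desk-scale genome (default three 200-kb chromosomes):

* a **latent deleteriousness field** L — smoothed Gaussian noise with a
  configurable correlation length — stands in for the unobserved per-base
  importance of the sequence;
* **gene models** with multi-exon structure and gene-level scores (pLI-like
  essentiality, haploinsufficiency, inheritance-mode flags, expression
  summaries), plus overlapping regulatory annotations;
* a **38-track feature registry**: a few informative tracks that are
  monotone transforms of L plus noise, many uninformative tracks, and one
  track of every structural kind (per-allele, gene-level, promoter-contact
  aspects, interval flag, interval count);
* **variant sets** whose pathogenic labels depend monotonically on L:
  pathogenic positions are sampled with probability proportional to the
  rank of L raised to ``effect_size`` (0 = no signal), controls uniformly.
  The pathogenic latent-rank distribution is then Beta(effect_size + 1, 1),
  so perfect recovery of L yields ROC-AUC (e + 1)/(e + 2); the default
  e = 19 puts that ceiling at ~0.95, a strong-effect regime that leaves
  room for feature noise.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_annotation import FeatureTrack, InteractionMap
from .intervals import GeneModel, GenomicInterval

__all__ = [
    "SyntheticConfig",
    "SyntheticGenome",
    "generate_genome",
    "generate_tracks",
    "generate_variants",
    "make_crispri_fixture",
]

#: Structural (non-continuous) tracks always present: one per-allele, one
#: gene-level, three promoter-contact aspects, one interval flag, one
#: interval count.
N_STRUCTURED_TRACKS = 7

BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic pipeline.

    ``n_total_features`` minus the informative count and the 7 structured
    tracks gives the number of uninformative continuous tracks (28 by
    default, for 38 total).
    """

    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 200_000),
        ("chr2", 200_000),
        ("chr3", 200_000),
    )
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (2, 6)
    regulatory_density: float = 0.15
    latent_smoothness: int = 500
    n_informative_features: int = 3
    n_total_features: int = 38
    effect_size: float = 19.0
    noise_sd: float = 0.15
    n_pathogenic: int = 400
    control_pool_size: int = 6000
    track_resolution: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if any(size < 10_000 for _, size in self.chromosomes):
            raise ValueError("chromosomes must be >= 10 kb")
        if not 0 < self.regulatory_density < 1:
            raise ValueError("regulatory_density must be in (0, 1)")
        if self.n_noise_features < 0:
            raise ValueError("n_total_features too small for the registry")

    @property
    def n_noise_features(self) -> int:
        return (
            self.n_total_features
            - self.n_informative_features
            - N_STRUCTURED_TRACKS
        )

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class SyntheticGenome:
    """A generated genome: genes, regulatory annotations and the latent field."""

    chrom_sizes: dict[str, int]
    gene_models: list[GeneModel]
    regulatory: list[tuple[str, int, int, str]]
    latent: dict[str, np.ndarray]

    def exon_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(gm.chrom, s, e)
            for gm in self.gene_models
            for s, e in gm.exons
        ]

    def noncoding_mask(self) -> dict[str, np.ndarray]:
        """True where a base lies outside every exon."""
        masks = {c: np.ones(n, dtype=bool) for c, n in self.chrom_sizes.items()}
        for gm in self.gene_models:
            for s, e in gm.exons:
                masks[gm.chrom][s:e] = False
        return masks


def _smooth_field(rng: np.random.Generator, size: int, width: int) -> np.ndarray:
    """Standardized moving-average smoothing of white noise (O(n) via cumsum)."""
    white = rng.normal(size=size + width)
    csum = np.concatenate([[0.0], np.cumsum(white)])
    smoothed = (csum[width:] - csum[:-width])[:size] / width
    return (smoothed - smoothed.mean()) / smoothed.std()


def _place_gene(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    chrom_size: int,
    body_len: int,
) -> int | None:
    for _ in range(200):
        start = int(rng.integers(0, chrom_size - body_len))
        if all(start + body_len <= s or start >= e for s, e in occupied):
            return start
    return None


def _make_exons(
    rng: np.random.Generator, start: int, end: int, n_exons: int
) -> list[tuple[int, int]]:
    """Alternating exon/intron blocks filling [start, end)."""
    body = end - start
    exon_lens = rng.integers(80, 301, size=n_exons)
    n_introns = n_exons - 1
    min_intron = 40
    budget = body - int(exon_lens.sum()) - min_intron * n_introns
    if budget < 0:  # body too short for the draw; shrink exons proportionally
        exon_lens = np.maximum(
            (exon_lens * 0.5).astype(int), 50
        )
        budget = max(body - int(exon_lens.sum()) - min_intron * n_introns, 0)
    extra = (
        rng.multinomial(budget, np.ones(n_introns) / n_introns)
        if n_introns
        else np.zeros(0, dtype=int)
    )
    exons = []
    cursor = start
    for i in range(n_exons):
        exons.append((cursor, cursor + int(exon_lens[i])))
        cursor = exons[-1][1]
        if i < n_introns:
            cursor += min_intron + int(extra[i])
    # stretch the last exon to keep inside the body (never beyond)
    if exons[-1][1] > end:
        raise AssertionError("exon layout exceeded gene body")
    return exons


def generate_genome(config: SyntheticConfig) -> SyntheticGenome:
    """Deterministically generate genes, regulatory intervals and latent field."""
    rng = np.random.default_rng([config.seed, 101])
    chrom_sizes = config.chrom_sizes
    chroms = list(chrom_sizes)
    weights = np.asarray([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    for g in range(config.n_genes):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        body_len = int(rng.integers(2_000, 8_001))
        start = _place_gene(rng, occupied[chrom], chrom_sizes[chrom], body_len)
        if start is None:
            raise ValueError(
                f"genome too small to place {config.n_genes} genes"
            )
        occupied[chrom].append((start, start + body_len))
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        exons = _make_exons(rng, start, start + body_len, n_exons)
        end = start + body_len
        genes.append(
            GeneModel(
                gene_id=f"G{g:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
                gene_scores={
                    "pLI": float(rng.beta(0.3, 0.3)),
                    "haploinsufficiency": float(rng.random()),
                    "dosage_sensitivity": float(rng.integers(0, 4)),
                    "dominant": float(rng.random() < 0.4),
                    "omim": float(rng.random() < 0.3),
                    "expression_median": float(rng.lognormal(1.0, 1.0)),
                    "expression_variance": float(rng.lognormal(0.0, 1.0)),
                },
            )
        )

    regulatory: list[tuple[str, int, int, str]] = []
    target = config.regulatory_density * sum(chrom_sizes.values())
    labels = ["NCRNA", "UTR", "MULTICELL_REGULATORY", "ANNOTATED_FEATURE"]
    label_w = np.asarray([0.15, 0.2, 0.35, 0.3])
    covered = 0.0
    while covered < target:
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = int(rng.integers(200, 2001))
        start = int(rng.integers(0, chrom_sizes[chrom] - length))
        label = labels[int(rng.choice(4, p=label_w))]
        regulatory.append((chrom, start, start + length, label))
        covered += length

    latent = {
        c: _smooth_field(rng, n, config.latent_smoothness)
        for c, n in chrom_sizes.items()
    }
    return SyntheticGenome(
        chrom_sizes=chrom_sizes,
        gene_models=genes,
        regulatory=regulatory,
        latent=latent,
    )


def _window_frame(
    genome: SyntheticGenome, resolution: int, values: dict[str, np.ndarray]
) -> pd.DataFrame:
    rows = []
    for chrom, vals in values.items():
        n = genome.chrom_sizes[chrom]
        starts = np.arange(0, n, resolution)
        ends = np.minimum(starts + resolution, n)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "value": vals}
            )
        )
    return pd.concat(rows, ignore_index=True)


def _window_means(arr: np.ndarray, resolution: int) -> np.ndarray:
    starts = np.arange(0, arr.size, resolution)
    sums = np.add.reduceat(arr, starts)
    counts = np.minimum(starts + resolution, arr.size) - starts
    return sums / counts


def generate_tracks(
    genome: SyntheticGenome, config: SyntheticConfig
) -> tuple[list[FeatureTrack], InteractionMap]:
    """Build the 38-track registry and its promoter-contact map.

    Continuous tracks are step functions over ``track_resolution``-bp
    windows, emulating the coarse native resolution of real constraint
    metrics. Informative tracks apply a monotone (logistic) transform to
    the window-mean latent field and add Gaussian noise; uninformative
    tracks are independent smoothed noise.
    """
    rng = np.random.default_rng([config.seed, 202])
    res = config.track_resolution
    registry: list[FeatureTrack] = []

    slopes = 1.0 + 0.5 * np.arange(config.n_informative_features)
    for i in range(config.n_informative_features):
        vals = {}
        for chrom, L in genome.latent.items():
            m = _window_means(L, res)
            signal = 1.0 / (1.0 + np.exp(-slopes[i] * m))
            vals[chrom] = signal + rng.normal(0.0, config.noise_sd, m.size)
        registry.append(
            FeatureTrack(
                name=f"informative_{i + 1}",
                kind="continuous",
                data=_window_frame(genome, res, vals),
            )
        )

    for i in range(config.n_noise_features):
        vals = {}
        for chrom, L in genome.latent.items():
            m = _window_means(L, res)
            vals[chrom] = rng.normal(0.0, 1.0, m.size)
        registry.append(
            FeatureTrack(
                name=f"noise_{i + 1}",
                kind="continuous",
                data=_window_frame(genome, res, vals),
            )
        )

    # per-allele track: sparse scores at random positions, 1-3 alts each
    n_sites = 5000
    pa_rows = []
    for chrom, size in genome.chrom_sizes.items():
        sites = rng.choice(size, size=n_sites // len(genome.chrom_sizes),
                           replace=False)
        for pos in sites:
            ref = str(rng.choice(BASES))
            alts = [b for b in BASES if b != ref]
            for alt in rng.choice(alts, size=int(rng.integers(1, 4)),
                                  replace=False):
                pa_rows.append((chrom, int(pos), ref, str(alt),
                                float(rng.random())))
    registry.append(
        FeatureTrack(
            name="allelic_score",
            kind="per_allele",
            data=pd.DataFrame(
                pa_rows, columns=["chrom", "pos", "ref", "alt", "value"]
            ),
        )
    )

    registry.append(
        FeatureTrack(name="nearest_gene_pli", kind="gene_level",
                     score_name="pLI")
    )

    # promoter-contact map: distal fragments wired to random genes
    imap_rows = []
    if genome.gene_models:
        for _ in range(60):
            gm = genome.gene_models[int(rng.integers(len(genome.gene_models)))]
            chrom = gm.chrom
            length = int(rng.integers(1_000, 5_001))
            start = int(rng.integers(0, genome.chrom_sizes[chrom] - length))
            imap_rows.append(
                (chrom, start, start + length, gm.gene_id,
                 int(rng.integers(1, 5)))
            )
    imap = InteractionMap(
        pd.DataFrame(
            imap_rows,
            columns=["chrom", "start", "end", "gene_id", "n_cell_lines"],
        ),
        genome.gene_models,
    )
    for aspect, name in [
        ("contact", "promoter_contact"),
        ("essentiality", "contact_gene_pli"),
        ("cell_line_count", "contact_cell_lines"),
    ]:
        registry.append(
            FeatureTrack(name=name, kind="interaction", aspect=aspect)
        )

    # interval flag (enhancer-reporter-like) and cell-line count intervals
    flag_rows = []
    for chrom, size in genome.chrom_sizes.items():
        for _ in range(40):
            length = int(rng.integers(300, 1_500))
            start = int(rng.integers(0, size - length))
            flag_rows.append((chrom, start, start + length))
    registry.append(
        FeatureTrack(
            name="enhancer_reporter",
            kind="interval_binary",
            data=pd.DataFrame(flag_rows, columns=["chrom", "start", "end"]),
        )
    )

    count_rows = []
    for chrom, size in genome.chrom_sizes.items():
        starts = np.sort(
            rng.choice(size // 2_000, size=30, replace=False)
        ) * 2_000
        for s in starts:
            count_rows.append(
                (chrom, int(s), int(s) + int(rng.integers(500, 1_800)),
                 float(rng.integers(1, 9)))
            )
    registry.append(
        FeatureTrack(
            name="loop_cell_lines",
            kind="interval_count",
            data=pd.DataFrame(
                count_rows, columns=["chrom", "start", "end", "value"]
            ),
        )
    )

    assert len(registry) == config.n_total_features
    return registry, imap


def _sample_positions(
    rng: np.random.Generator,
    genome: SyntheticGenome,
    n: int,
    effect_size: float,
) -> pd.DataFrame:
    """Sample non-coding positions with probability ~ rank(L)^effect_size."""
    masks = genome.noncoding_mask()
    chroms, positions, latents = [], [], []
    for chrom in sorted(genome.chrom_sizes):
        idx = np.flatnonzero(masks[chrom])
        chroms.extend([chrom] * idx.size)
        positions.append(idx)
        latents.append(genome.latent[chrom][idx])
    pos = np.concatenate(positions)
    lat = np.concatenate(latents)
    chrom_arr = np.asarray(chroms)
    if n > pos.size:
        raise ValueError(
            f"requested {n} variants but only {pos.size} non-coding positions"
        )
    ranks = np.empty(lat.size)
    ranks[np.argsort(lat, kind="mergesort")] = np.arange(1, lat.size + 1)
    w = (ranks / lat.size) ** effect_size
    w /= w.sum()
    chosen = rng.choice(pos.size, size=n, replace=False, p=w)
    refs = BASES[rng.integers(0, 4, size=n)]
    alts = np.array(
        [str(rng.choice([b for b in BASES if b != r])) for r in refs]
    )
    return pd.DataFrame(
        {
            "chrom": chrom_arr[chosen],
            "pos": pos[chosen],
            "ref": refs,
            "alt": alts,
        }
    ).sort_values(["chrom", "pos"], ignore_index=True)


def generate_variants(
    genome: SyntheticGenome, config: SyntheticConfig
) -> dict[str, pd.DataFrame]:
    """Pathogenic, control-pool, Mendelian-like and GWAS-like variant sets.

    Pathogenic (and Mendelian-like) positions concentrate where the latent
    field is high; the control pool is uniform over non-coding sequence.
    GWAS-like records carry synthetic (locus, study, phenotype, p) columns.
    """
    rng = np.random.default_rng([config.seed, 303])
    pathogenic = _sample_positions(
        rng, genome, config.n_pathogenic, config.effect_size
    )
    pathogenic["label"] = "pathogenic"
    pathogenic["set_tag"] = "training"

    pool = _sample_positions(rng, genome, config.control_pool_size, 0.0)
    pool["label"] = "control"
    pool["set_tag"] = "pool"

    mendelian = _sample_positions(
        rng, genome, max(config.n_pathogenic // 4, 20), config.effect_size
    )
    mendelian["label"] = "pathogenic"
    mendelian["set_tag"] = "mendelian"
    mendelian["mode"] = np.where(
        rng.random(len(mendelian)) < 0.6, "dominant", "recessive"
    )

    n_gwas = 200
    gwas = _sample_positions(rng, genome, n_gwas, 0.0)
    gwas["label"] = "unknown"
    gwas["set_tag"] = "gwas"
    gwas["locus"] = [f"L{int(i)}" for i in rng.integers(0, 60, size=n_gwas)]
    gwas["study"] = [f"S{int(i)}" for i in rng.integers(0, 3, size=n_gwas)]
    gwas["phenotype"] = [
        f"P{int(i)}" for i in rng.integers(0, 4, size=n_gwas)
    ]
    gwas["p"] = 10.0 ** (-rng.uniform(5, 30, size=n_gwas))

    return {
        "pathogenic": pathogenic,
        "control_pool": pool,
        "mendelian": mendelian,
        "gwas": gwas,
    }


def make_crispri_fixture(
    seed: int = 0,
) -> tuple[pd.DataFrame, list[GenomicInterval]]:
    """Deterministic CRISPRi probe table exercising the filter-chain bookkeeping.

    The table is built so that, with the default preparation parameters
    (coverage >= 20 pairs, length < 1 kb, exon-overlap removal), 77,368
    probe pairs pass the coverage/length filters, 1,746 of them overlap an
    exon, and 75,622 are retained — the bookkeeping of the published
    GATA1/MYC tiling screen. Viability values are synthetic.
    """
    rng = np.random.default_rng([seed, 404])
    chrom = "chr_tile"
    exon_anchor = 2_000_000
    exons = [
        GenomicInterval(chrom, exon_anchor + i * 10_000,
                        exon_anchor + i * 10_000 + 2_000)
        for i in range(5)
    ]

    rows = []
    # probes passing filters, clear of exons: tile the first 1.9 Mb
    n_clear = 75_622
    for i in range(n_clear):
        start = (i * 25) % 1_899_000
        length = 200 + (i % 5) * 100  # 200..600 < 1 kb
        rows.append((chrom, start, start + length,
                     int(rng.integers(20, 200))))
    # probes passing filters but overlapping an exon
    n_overlap = 1_746
    for k in range(n_overlap):
        exon = exons[k % len(exons)]
        offset = (37 * k) % (len(exon) - 100)
        start = exon.start + offset
        rows.append((chrom, start, start + 300,
                     int(rng.integers(20, 200))))
    # probes failing the coverage filter
    for i in range(1_500):
        start = (i * 40) % 1_899_000
        rows.append((chrom, start, start + 300, int(rng.integers(1, 20))))
    # probes failing the length filter
    for i in range(1_132):
        start = (i * 60) % 1_890_000
        rows.append((chrom, start, start + int(rng.integers(1_000, 3_000)),
                     int(rng.integers(20, 200))))

    probes = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_pairs"])
    # synthetic viability: background near 0 with scattered strong dips
    viability = rng.normal(0.0, 0.3, len(probes))
    dips = rng.random(len(probes)) < 0.05
    viability[dips] -= rng.uniform(1.5, 3.0, int(dips.sum()))
    probes["viability"] = viability
    return probes, exons
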
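"""End-to-end orchestration of the synthetic benchmark.

Chains the full scoring pipeline on generated data: genome + annotation
track, variant declustering and control matching, feature matrix, randomized
hyperparameter search, final training, held-out evaluation on a
chromosome-based split, and optional genome-wide scoring of one chromosome
with region-level enrichment around the planted high-latent elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import RegionEnrichment, region_enrichment, roc_pr
from .feature_annotation import build_feature_matrix
from .gbt_model import (
    ModelConfig,
    TrainedEnsemble,
    feature_importance,
    predict,
    random_search,
    train,
)
from .genome_annotation import assign_element_categories
from .genome_scoring import BinnedTrack, bin_and_repercentile, genomewide_percentiles
from .intervals import GenomicInterval
from .synthetic_data import (
    SyntheticConfig,
    SyntheticGenome,
    generate_genome,
    generate_tracks,
    generate_variants,
)
from .variant_sets import (
    PipelineConfig,
    SplitSpec,
    decluster,
    match_controls,
    split_by_regions,
)

__all__ = ["BenchmarkResult", "run_synthetic_benchmark", "score_chromosome"]

#: Chromosome held out as the test region in the default synthetic split.
TEST_CHROMOSOME = "chr3"


@dataclass
class BenchmarkResult:
    genome: SyntheticGenome
    registry: list
    imap: object
    ensemble: TrainedEnsemble
    tuned: ModelConfig
    n_train: int
    n_test: int
    n_test_pathogenic: int
    roc_auc: float
    pr_auc: float
    importance_order: list[str]

    @property
    def informative_in_top3(self) -> int:
        top3 = set(self.importance_order[:3])
        return sum(1 for name in top3 if name.startswith("informative_"))


def run_synthetic_benchmark(
    seed: int,
    n_candidates: int = 50,
    config: SyntheticConfig | None = None,
) -> BenchmarkResult:
    """Generate data, tune, train and evaluate on the held-out chromosome."""
    config = config or SyntheticConfig(seed=seed)
    genome = generate_genome(config)
    annotation = assign_element_categories(
        genome.gene_models, genome.regulatory, genome.chrom_sizes
    )
    pipeline = PipelineConfig(seed=seed)
    variants = generate_variants(genome, config)
    pathogenic = decluster(variants["pathogenic"], pipeline.min_spacing)
    controls = match_controls(
        pathogenic, variants["control_pool"], annotation, pipeline
    )
    labeled = pd.concat(
        [
            pathogenic.assign(label="pathogenic"),
            controls.assign(label="control"),
        ],
        ignore_index=True,
    )
    registry, imap = generate_tracks(genome, config)
    matrix = build_feature_matrix(labeled, registry, genome.gene_models, imap)

    size = genome.chrom_sizes[TEST_CHROMOSOME]
    split = SplitSpec([GenomicInterval(TEST_CHROMOSOME, 0, size)])
    train_v, test_v = split_by_regions(labeled, split)
    m_train, m_test = matrix.loc[train_v.index], matrix.loc[test_v.index]

    tuned = random_search(
        m_train, ModelConfig(n_candidates=n_candidates, seed=seed)
    )
    ensemble = train(m_train, tuned)
    scores = predict(ensemble, m_test)
    y = (m_test["label"] == "pathogenic").to_numpy().astype(int)
    roc, pr = roc_pr(y, scores)
    order = (
        feature_importance(ensemble)
        .importances.sort_values(ascending=False)
        .index.tolist()
    )
    return BenchmarkResult(
        genome=genome,
        registry=registry,
        imap=imap,
        ensemble=ensemble,
        tuned=tuned,
        n_train=len(m_train),
        n_test=len(m_test),
        n_test_pathogenic=int(y.sum()),
        roc_auc=roc,
        pr_auc=pr,
        importance_order=order,
    )


def score_chromosome(
    result: BenchmarkResult, chrom: str = TEST_CHROMOSOME
) -> BinnedTrack:
    """Score every base of one chromosome and return the binned percentiles."""
    size = result.genome.chrom_sizes[chrom]
    positions = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(size, dtype=np.int64),
            "ref": "A",
            "alt": "G",
        }
    )
    matrix = build_feature_matrix(
        positions, result.registry, result.genome.gene_models, result.imap
    )
    raw = {chrom: predict(result.ensemble, matrix)}
    annotation = assign_element_categories(
        [gm for gm in result.genome.gene_models if gm.chrom == chrom],
        [r for r in result.genome.regulatory if r[0] == chrom],
        {chrom: size},
    )
    track = genomewide_percentiles(raw, annotation=annotation)
    return bin_and_repercentile(track, width=10)


def planted_elements(
    genome: SyntheticGenome,
    chrom: str,
    n_regions: int = 20,
    length: int = 200,
) -> list[GenomicInterval]:
    """Top disjoint windows of the latent field: the planted 'enhancers'."""
    L = genome.latent[chrom]
    n_windows = L.size // length
    starts = np.arange(n_windows, dtype=np.int64) * length
    means = np.add.reduceat(L[: n_windows * length], starts) / length
    order = np.argsort(means)[::-1]
    return [
        GenomicInterval(chrom, int(starts[i]), int(starts[i]) + length)
        for i in order[:n_regions]
    ]


def planted_region_enrichment(
    result: BenchmarkResult,
    binned: BinnedTrack,
    chrom: str = TEST_CHROMOSOME,
    seed: int = 0,
) -> RegionEnrichment:
    """Enrichment of the planted elements vs matched random regions."""
    regions = planted_elements(result.genome, chrom)
    universe = [
        GenomicInterval(chrom, 0, result.genome.chrom_sizes[chrom])
    ]
    return region_enrichment(
        regions, binned, universe, PipelineConfig(seed=seed)
    )
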
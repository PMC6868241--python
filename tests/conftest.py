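import numpy as np
import pandas as pd
import pytest

from ncer.genome_annotation import assign_element_categories
from ncer.intervals import GeneModel
from ncer.synthetic_data import (
    SyntheticConfig,
    generate_genome,
    generate_tracks,
    generate_variants,
)


@pytest.fixture(scope="session")
def toy_genes():
    """Two genes on a 10-kb chromosome: one 3-exon, one single-exon."""
    return [
        GeneModel(
            gene_id="GA", chrom="chr1", start=1000, end=4000, strand="+",
            exons=[(1000, 1300), (1800, 2100), (3500, 4000)],
            gene_scores={"pLI": 0.9, "haploinsufficiency": 0.2},
        ),
        GeneModel(
            gene_id="GB", chrom="chr1", start=6000, end=7000, strand="-",
            exons=[(6000, 7000)],
            gene_scores={"pLI": 0.1},
        ),
    ]


@pytest.fixture(scope="session")
def toy_regulatory():
    return [
        ("chr1", 500, 1200, "UTR"),            # overlaps CDS of GA
        ("chr1", 2000, 2600, "NCRNA"),         # overlaps CDS + intron
        ("chr1", 2400, 3200, "MULTICELL_REGULATORY"),
        ("chr1", 4500, 5200, "ANNOTATED_FEATURE"),
        ("chr1", 5000, 5600, "UTR"),
    ]


@pytest.fixture(scope="session")
def toy_sizes():
    return {"chr1": 10_000}


@pytest.fixture(scope="session")
def toy_track(toy_genes, toy_regulatory, toy_sizes):
    return assign_element_categories(toy_genes, toy_regulatory, toy_sizes)


@pytest.fixture(scope="session")
def synthetic_bundle():
    """One shared synthetic genome + tracks + variants (seed 11)."""
    config = SyntheticConfig(seed=11)
    genome = generate_genome(config)
    registry, imap = generate_tracks(genome, config)
    variants = generate_variants(genome, config)
    return {
        "config": config,
        "genome": genome,
        "registry": registry,
        "imap": imap,
        "variants": variants,
    }


def make_variants(positions, chrom="chr1", **extra):
    """Variant frame helper with fixed ref/alt."""
    n = len(positions)
    base = {
        "chrom": [chrom] * n if isinstance(chrom, str) else chrom,
        "pos": list(positions),
        "ref": ["A"] * n,
        "alt": ["G"] * n,
    }
    base.update(extra)
    return pd.DataFrame(base)
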
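"""Plain-text readers and writers for the pipeline's file dialects.

All interval files use 0-based half-open coordinates (BED dialect).
Variant tables are TSV with 0-based positions; the minimal VCF writer
shifts to 1-based on output and the reader shifts back.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gbt_model import ModelConfig, TrainedEnsemble
from .genome_annotation import AnnotationTrack
from .genome_scoring import BinnedTrack, ScoreTrack
from .intervals import GeneModel, GenomicInterval

__all__ = [
    "read_gene_models",
    "write_gene_models",
    "read_bed4",
    "write_bed4",
    "read_variants",
    "write_variants",
    "read_vcf",
    "write_vcf",
    "read_bedgraph",
    "write_bedgraph",
    "write_annotation_track",
    "write_score_track",
    "write_binned_track",
    "save_model",
    "load_model",
]

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "label", "set_tag", "mode",
    "p", "locus", "study", "phenotype",
]


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    """6-column TSV: gene_id, chrom, start, end, strand, exon blocks.

    Exon blocks are comma-separated ``start-end`` pairs. Gene scores are
    appended as a JSON column when present.
    """
    rows = []
    for gm in genes:
        blocks = ",".join(f"{s}-{e}" for s, e in gm.exons)
        rows.append(
            (gm.gene_id, gm.chrom, gm.start, gm.end, gm.strand, blocks,
             json.dumps(gm.gene_scores, sort_keys=True))
        )
    pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "exons",
                 "gene_scores"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"exons": str})
    genes = []
    for row in df.itertuples(index=False):
        exons = []
        if isinstance(row.exons, str) and row.exons:
            for block in row.exons.split(","):
                s, e = block.split("-")
                exons.append((int(s), int(e)))
        scores = (
            json.loads(row.gene_scores)
            if hasattr(row, "gene_scores") and isinstance(row.gene_scores, str)
            else {}
        )
        genes.append(
            GeneModel(
                gene_id=row.gene_id, chrom=row.chrom, start=int(row.start),
                end=int(row.end), strand=row.strand, exons=exons,
                gene_scores=scores,
            )
        )
    return genes


def write_bed4(rows: list[tuple[str, int, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed4(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            out.append((chrom, int(start), int(end), name))
    return out


def write_variants(variants: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in VARIANT_COLUMNS if c in variants.columns]
    variants[cols].to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """Minimal VCF: positions shifted to 1-based, label carried in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples(index=False):
            info = (
                f"LABEL={row.label}" if hasattr(row, "label") else "."
            )
            fh.write(
                f"{row.chrom}\t{int(row.pos) + 1}\t.\t{row.ref}\t{row.alt}"
                f"\t.\t.\t{info}\n"
            )


def read_vcf(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            label = None
            for entry in parts[7].split(";"):
                if entry.startswith("LABEL="):
                    label = entry[6:]
            rows.append((parts[0], int(parts[1]) - 1, parts[3], parts[4], label))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "label"])
    if df["label"].isna().all():
        df = df.drop(columns=["label"])
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    """(chrom, start, end, value) rows, tab-separated, no header."""
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "value"],
    )


def write_annotation_track(track: AnnotationTrack, path: str | Path) -> None:
    write_bed4(track.to_intervals(), path)


def write_score_track(
    track: ScoreTrack, path: str | Path, layer: str = "percentile"
) -> None:
    """Run-length-encoded bedGraph of a per-base score layer."""
    data = track.percentile if layer == "percentile" else track.raw
    with open(path, "w") as fh:
        for chrom in track.chroms:
            v = data[chrom]
            change = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [v.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.6g}\n")


def write_binned_track(
    track: BinnedTrack, path: str | Path, layer: str = "percentile"
) -> None:
    data = track.percentile if layer == "percentile" else track.mean_raw
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for s, e, v in zip(
                track.starts[chrom], track.ends[chrom], data[chrom]
            ):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def save_model(ensemble: TrainedEnsemble, prefix: str | Path) -> None:
    """Persist as <prefix>.model.json (native booster) + <prefix>.meta.json."""
    prefix = Path(prefix)
    ensemble.model.get_booster().save_model(_model_path(prefix))
    sidecar = {
        "feature_names": ensemble.feature_names,
        "config": {
            "n_estimators": ensemble.config.n_estimators,
            "max_depth": ensemble.config.max_depth,
            "learning_rate": ensemble.config.learning_rate,
            "min_child_weight": ensemble.config.min_child_weight,
            "seed": ensemble.config.seed,
        },
    }
    _meta_path(prefix).write_text(json.dumps(sidecar, indent=2))


def _model_path(prefix: Path) -> Path:
    return prefix.parent / (prefix.name + ".model.json")


def _meta_path(prefix: Path) -> Path:
    return prefix.parent / (prefix.name + ".meta.json")


def load_model(prefix: str | Path) -> TrainedEnsemble:
    import xgboost as xgb

    prefix = Path(prefix)
    sidecar = json.loads(_meta_path(prefix).read_text())
    config = ModelConfig(**sidecar["config"])
    booster = xgb.Booster()
    booster.load_model(_model_path(prefix))
    # rebuild the sklearn wrapper around the loaded booster
    model = config.estimator()
    model._Booster = booster
    model.n_classes_ = 2
    return TrainedEnsemble(
        model=model, feature_names=sidecar["feature_names"], config=config
    )
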
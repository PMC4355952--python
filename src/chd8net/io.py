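"""Plain-text readers and writers for the pipeline's file formats.

BED3 for peaks, a tabular gene-model format, newline-delimited gene lists,
GMT pathway sets, and TSV count/metadata/expression tables. All coordinates
on disk are 0-based half-open (BED convention).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genes import ExonLocus, GeneModel
from .intervals import GenomicInterval
from .knockdown import SampleInfo


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED columns")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                if line.strip():
                    raise ValueError(f"{path}:{ln}: expected >= 3 GMT columns")
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# --------------------------------------------------------------------------
# Gene models


GENE_MODEL_COLUMNS = [
    "gene_id", "chrom", "strand", "tss_list",
    "exon_blocks", "exon_gc", "exon_cov", "active",
]


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        blocks = ";".join(
            f"{e.interval.start}-{e.interval.end}" if e.interval is not None
            else f"0-{e.size}"
            for e in g.exons
        )
        rows.append({
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss_list": ";".join(str(t) for t in g.tss_list),
            "exon_blocks": blocks,
            "exon_gc": ";".join(f"{e.gc:.6g}" for e in g.exons),
            "exon_cov": ";".join(f"{e.coverage:.6g}" for e in g.exons),
            "active": int(g.active),
        })
    pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    genes = []
    for _, row in df.iterrows():
        exons = []
        blocks = row["exon_blocks"].split(";") if row["exon_blocks"] else []
        gcs = row["exon_gc"].split(";") if row["exon_gc"] else []
        covs = row["exon_cov"].split(";") if row["exon_cov"] else []
        for blk, gc, cov in zip(blocks, gcs, covs):
            start, end = (int(x) for x in blk.split("-"))
            exons.append(ExonLocus(
                gc=float(gc), size=end - start, coverage=float(cov),
                interval=GenomicInterval(row["chrom"], start, end) if end > start else None,
            ))
        genes.append(GeneModel(
            gene_id=row["gene_id"], chrom=row["chrom"], strand=row["strand"],
            tss_list=[int(t) for t in row["tss_list"].split(";")],
            exons=exons, active=bool(int(row["active"])),
        ))
    return genes


# --------------------------------------------------------------------------
# Counts, metadata, expression, p-value tables


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_sample_meta(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"unit", "treatment", "batch"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: sample metadata needs columns {sorted(required)}")
    return [SampleInfo(unit=r.unit, treatment=r.treatment, batch=r.batch)
            for r in df.itertuples()]


def write_sample_meta(samples: Sequence[SampleInfo], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in samples]).to_csv(path, sep="\t", index=False)


def read_pvalue_table(path: str | Path, value_col: str = "p") -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df[value_col]


def read_ortholog_table(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(df.itertuples(index=False, name=None))
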
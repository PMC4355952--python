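"""Gene models: strand-aware promoters, exon loci and their covariates."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .intervals import GenomicInterval, merge_intervals, total_length

PROMOTER_WIDTH = 1000  # nt immediately upstream of each isoform TSS


@dataclass
class ExonLocus:
    """One discrete exonic locus with its mutation-rate covariates.

    ``gc`` is the GC fraction, ``size`` the locus length in nt and
    ``coverage`` the fraction of the locus that is adequately covered by
    sequencing (defaults to 1.0 when no coverage data are supplied).
    """

    gc: float
    size: int
    coverage: float = 1.0
    interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"GC fraction {self.gc} outside [0, 1]")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage fraction {self.coverage} outside [0, 1]")
        if self.size < 0:
            raise ValueError(f"exon size {self.size} must be >= 0")


def promoter_window(tss: int, strand: str, width: int = PROMOTER_WIDTH) -> tuple[int, int] | None:
    """The ``width`` nt immediately upstream of a TSS, strand aware, 0-based.

    Returns a (start, end) pair, or None when the window falls entirely off
    the chromosome start.
    """
    if strand == "+":
        start, end = max(0, tss - width), tss
    elif strand == "-":
        start, end = tss + 1, tss + 1 + width
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return None if start >= end else (start, end)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss_list: list[int]
    exons: list[ExonLocus] = field(default_factory=list)
    active: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id}: at least one TSS required")

    @property
    def promoter_union(self) -> list[GenomicInterval]:
        """Union over isoform TSSs of the 1 kb upstream windows."""
        windows = []
        for tss in self.tss_list:
            w = promoter_window(tss, self.strand)
            if w is not None:
                windows.append(GenomicInterval(self.chrom, w[0], w[1]))
        return merge_intervals(windows)

    @property
    def promoter_size(self) -> int:
        """Total nt identified as promoter by at least one isoform."""
        return total_length(self.promoter_union)

    @property
    def exon_intervals(self) -> list[GenomicInterval]:
        return [e.interval for e in self.exons if e.interval is not None]

    @property
    def exon_loci(self) -> list[tuple[float, int, float]]:
        return [(e.gc, e.size, e.coverage) for e in self.exons]


def genes_by_chrom(genes: Sequence[GeneModel]) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    return out
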
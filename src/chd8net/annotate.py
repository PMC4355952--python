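"""Reproducible peak calling across replicates and peak-to-gene annotation.

Replicate-level peak intervals are reduced to reproducible per-context sets
(>= 1 bp overlap between two biological replicates, merged coordinates),
classified against gene models (promoter > exon > distal) and partitioned
across biological contexts.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genes import GeneModel, genes_by_chrom
from .intervals import GenomicInterval, merge_intervals, validate_intervals

logger = logging.getLogger(__name__)

OVERLAP_MIN_BP = 1  # reproducibility threshold, fixed by design


@dataclass
class PeakContextSet:
    """Reproducible peak intervals for one biological context."""

    context: str
    intervals: list[GenomicInterval]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)


@dataclass
class TargetAnnotation:
    gene_id: str
    bound_in: set[str] = field(default_factory=set)
    peak_class_counts: dict[str, int] = field(
        default_factory=lambda: {"promoter": 0, "exon": 0, "distal": 0}
    )


def _overlap_pairs(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> set[int]:
    """Indices (into a+b concatenation) of intervals supported across replicates."""
    supported: set[int] = set()
    # sweep by chromosome; inputs are small peak lists so an index-sorted scan suffices
    by_chrom_a: dict[str, list[tuple[int, GenomicInterval]]] = defaultdict(list)
    for i, iv in enumerate(a):
        by_chrom_a[iv.chrom].append((i, iv))
    for j, iv in enumerate(b):
        for i, other in by_chrom_a.get(iv.chrom, ()):
            if iv.overlaps(other):
                supported.add(i)
                supported.add(len(a) + j)
    return supported


def reproducible_regions(
    rep_a: Iterable[GenomicInterval],
    rep_b: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merged coordinates of peaks overlapping >= 1 bp between two replicates.

    Every cluster of intervals that contains at least one cross-replicate
    overlap is reported as the union (merged span) of its supported members.
    Output is non-overlapping and sorted.
    """
    a = validate_intervals(rep_a, "replicate A")
    b = validate_intervals(rep_b, "replicate B")
    supported = _overlap_pairs(a, b)
    both = a + b
    kept = [both[i] for i in sorted(supported)]
    return merge_intervals(kept)


def group_reproducible(
    samples: Mapping[str, Sequence[GenomicInterval]],
    groups: Mapping[str, Iterable[str]],
) -> list[GenomicInterval]:
    """Reproducible regions from any two replicates within any group, merged.

    ``groups`` maps a group name to the sample labels it contains; each group
    must contain at least two labels. Overlap is only assessed within groups.
    """
    out: list[GenomicInterval] = []
    for group, labels in groups.items():
        labels = list(labels)
        if len(labels) < 2:
            raise ValueError(f"group {group!r} has {len(labels)} label(s); need >= 2")
        missing = [l for l in labels if l not in samples]
        if missing:
            raise KeyError(f"group {group!r} references unknown samples {missing}")
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                out.extend(reproducible_regions(samples[labels[i]], samples[labels[j]]))
    return merge_intervals(out)


def classify_peak(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
) -> tuple[str, list[str]]:
    """Classify one peak as promoter, exon or distal with assigned genes.

    Precedence is promoter > exon > distal; the assignment lists every gene
    satisfying the winning class. A peak on a chromosome absent from the
    gene models is distal (warning logged).
    """
    by_chrom = genes if isinstance(genes, dict) else genes_by_chrom(genes)
    candidates = by_chrom.get(peak.chrom)
    if candidates is None:
        logger.warning("peak %s:%d-%d on unknown chromosome; classified distal",
                       peak.chrom, peak.start, peak.end)
        return "distal", []
    promoter_hits = [
        g.gene_id for g in candidates
        if any(peak.overlaps(iv) for iv in g.promoter_union)
    ]
    if promoter_hits:
        return "promoter", sorted(promoter_hits)
    exon_hits = [
        g.gene_id for g in candidates
        if any(peak.overlaps(iv) for iv in g.exon_intervals)
    ]
    if exon_hits:
        return "exon", sorted(exon_hits)
    return "distal", []


def annotate_targets(
    context_sets: Sequence[PeakContextSet],
    genes: Sequence[GeneModel],
) -> dict[str, TargetAnnotation]:
    """Per-gene binding annotation across contexts (promoter class only binds)."""
    by_chrom = genes_by_chrom(genes)
    ann: dict[str, TargetAnnotation] = {}
    for cs in context_sets:
        for peak in cs.intervals:
            cls, hits = classify_peak(peak, by_chrom)
            for gid in hits:
                rec = ann.setdefault(gid, TargetAnnotation(gene_id=gid))
                rec.peak_class_counts[cls] += 1
                if cls == "promoter":
                    rec.bound_in.add(cs.context)
    return ann


def venn_partition(
    context_sets: Sequence[PeakContextSet],
    genes: Sequence[GeneModel] | None = None,
) -> tuple[dict[frozenset, list[GenomicInterval]], dict[frozenset, set[str]]]:
    """Partition each context's intervals by the exact set of contexts they hit.

    Every input interval is placed in exactly one cell, keyed by the frozenset
    of context labels (itself included) whose reproducible intervals it
    overlaps by >= 1 bp. When gene models are supplied, a gene-level partition
    is derived from the promoter class of each cell's intervals.
    """
    if len(context_sets) < 2:
        raise ValueError("venn_partition requires >= 2 contexts")
    labels = [cs.context for cs in context_sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate context labels in {labels}")

    cells: dict[frozenset, list[GenomicInterval]] = defaultdict(list)
    for cs in context_sets:
        for iv in cs.intervals:
            membership = {cs.context}
            for other in context_sets:
                if other.context == cs.context:
                    continue
                if any(iv.overlaps(o) for o in other.intervals):
                    membership.add(other.context)
            cells[frozenset(membership)].append(iv)

    gene_cells: dict[frozenset, set[str]] = {}
    if genes is not None:
        by_chrom = genes_by_chrom(genes)
        for key, ivs in cells.items():
            bound: set[str] = set()
            for iv in ivs:
                cls, hits = classify_peak(iv, by_chrom)
                if cls == "promoter":
                    bound.update(hits)
            gene_cells[key] = bound
    return dict(cells), gene_cells


def map_orthologs(
    gene_ids: Iterable[str],
    ortholog_table: Iterable[tuple[str, str]],
) -> tuple[set[str], int]:
    """Map gene ids through a strict one-to-one ortholog table.

    Returns the mapped set and the number of unmapped (dropped) inputs.
    Many-to-many rows are an input error.
    """
    pairs = list(ortholog_table)
    lhs = [p[0] for p in pairs]
    rhs = [p[1] for p in pairs]
    offenders = sorted(
        {g for g in lhs if lhs.count(g) > 1} | {g for g in rhs if rhs.count(g) > 1}
    )
    if offenders:
        raise ValueError(f"ortholog table is not one-to-one; offenders: {offenders}")
    mapping = dict(pairs)
    gene_ids = set(gene_ids)
    mapped = {mapping[g] for g in gene_ids if g in mapping}
    dropped = sum(1 for g in gene_ids if g not in mapping)
    return mapped, dropped


def fragment_density(
    read_starts: Sequence[tuple[str, int, str]],
    extension: int = 300,
    total_reads: int | None = None,
) -> dict[str, tuple[int, np.ndarray]]:
    """Per-base fragment density in fragments per million aligned reads.

    Each read is extended to ``extension`` nt in its strand direction
    (a ``-`` strand read extends leftward from its reported position). The
    value at each base is the count of extended fragments covering it,
    scaled by 1e6 / total_reads. Returns per-chromosome (offset, values).
    """
    if extension < 1:
        raise ValueError("extension must be >= 1")
    n = len(read_starts)
    if total_reads is None:
        total_reads = n
    if total_reads == 0:
        raise ValueError("total_reads must be > 0")
    if total_reads < n:
        raise ValueError("total_reads cannot be smaller than the number of reads")

    frags: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, pos, strand in read_starts:
        if strand == "+":
            frags[chrom].append((pos, pos + extension))
        elif strand == "-":
            frags[chrom].append((max(0, pos + 1 - extension), pos + 1))
        else:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    scale = 1e6 / total_reads
    out: dict[str, tuple[int, np.ndarray]] = {}
    for chrom, spans in frags.items():
        lo = min(s for s, _ in spans)
        hi = max(e for _, e in spans)
        diff = np.zeros(hi - lo + 1)
        for s, e in spans:
            diff[s - lo] += 1
            diff[e - lo] -= 1
        out[chrom] = (lo, np.cumsum(diff[:-1]) * scale)
    return out
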
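"""Genomic annotation of peaks: five-way category classification and
nearest-gene assignment.

Each peak is classified by its summit position into exactly one of five
categories — promoter (within +/- ``promoter_bp`` of a TSS), downstream
(within +/- ``downstream_bp`` of a TES), exon, intron, or intergenic — with
that precedence order resolving overlaps (a promoter window necessarily
covers first exons/introns).  Intergenic is the residual class, so the five
categories always partition the peak set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from relochip.genome_core import GeneModel, GenomicInterval
from relochip.peak_calling import Peak, PeakSet

__all__ = [
    "CATEGORIES",
    "AnnotationRecord",
    "GeneIndex",
    "classify_peak",
    "nearest_gene",
    "annotate_peakset",
    "category_table",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter", "downstream", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class AnnotationRecord:
    peak_id: str
    category: str
    nearest_gene_id: str | None
    tss_distance: int | None  # signed; negative = upstream of the gene's TSS


class GeneIndex:
    """Per-chromosome arrays of gene features for vectorized classification."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._tss: dict[str, np.ndarray] = {}
        self._order: dict[str, list[GeneModel]] = {}
        for chrom, gs in self._by_chrom.items():
            # sort by (tss, gene_id) so equidistant ties resolve to the
            # lexicographically smallest gene_id deterministically
            gs_sorted = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self._order[chrom] = gs_sorted
            self._tss[chrom] = np.array([g.tss for g in gs_sorted], dtype=np.int64)

    def chrom_genes(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def nearest_by_tss(self, chrom: str, pos: int) -> tuple[GeneModel, int] | None:
        """Gene minimizing |pos - tss| on ``chrom``; ties broken by the
        lexicographically smallest gene_id.  Returns (gene, signed distance)
        where the sign is strand-aware (upstream of the TSS is negative)."""
        gs = self._order.get(chrom)
        if not gs:
            return None
        tss = self._tss[chrom]
        i = int(np.searchsorted(tss, pos))
        # candidates around the insertion point, expanded to cover all ties
        cand: list[GeneModel] = []
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(gs):
                d = abs(pos - gs[j].tss)
                best = d if best is None else min(best, d)
        if best is None:
            return None
        lo = i - 1
        while lo >= 0 and abs(pos - gs[lo].tss) == best:
            cand.append(gs[lo])
            lo -= 1
        hi = i
        while hi < len(gs) and abs(pos - gs[hi].tss) == best:
            cand.append(gs[hi])
            hi += 1
        gene = min(
            (g for g in cand if abs(pos - g.tss) == best), key=lambda g: g.gene_id
        )
        raw = pos - gene.tss
        signed = raw if gene.strand == "+" else -raw
        return gene, int(signed)


def classify_peak(
    peak: Peak | GenomicInterval | tuple[str, int],
    genes: GeneIndex,
    promoter_bp: int = 2000,
    downstream_bp: int = 2000,
) -> str:
    """Classify a peak summit into one of the five genomic categories.

    Precedence: promoter > downstream > exon > intron > intergenic.
    Accepts a :class:`Peak` (its summit is used), a bare interval (its
    center), or an explicit ``(chrom, position)`` pair.
    """
    chrom, pos = _summit_of(peak)
    gs = genes.chrom_genes(chrom)
    in_exon = in_intron = near_tes = False
    for g in gs:
        if abs(pos - g.tss) <= promoter_bp:
            return "promoter"
        if abs(pos - g.tes) <= downstream_bp:
            near_tes = True
        if g.tx_start <= pos < g.tx_end:
            if any(e.start <= pos < e.end for e in g.exons):
                in_exon = True
            else:
                in_intron = True
    if near_tes:
        return "downstream"
    if in_exon:
        return "exon"
    if in_intron:
        return "intron"
    return "intergenic"


def _summit_of(peak) -> tuple[str, int]:
    if isinstance(peak, Peak):
        return peak.interval.chrom, peak.summit
    if isinstance(peak, GenomicInterval):
        return peak.chrom, peak.center
    chrom, pos = peak
    return chrom, int(pos)


def nearest_gene(
    peak: Peak | GenomicInterval | tuple[str, int], genes: GeneIndex
) -> tuple[str | None, int | None]:
    """Nearest gene by |summit - TSS| on the peak's chromosome.

    Returns ``(gene_id, signed distance)``; the distance is negative when
    the summit lies upstream of the TSS relative to gene strand.  With no
    gene on the chromosome returns ``(None, None)`` with a warning.
    """
    chrom, pos = _summit_of(peak)
    hit = genes.nearest_by_tss(chrom, pos)
    if hit is None:
        logger.warning("no gene on chromosome %s; nearest gene undefined", chrom)
        return None, None
    gene, dist = hit
    return gene.gene_id, dist


def annotate_peakset(
    peaks: PeakSet | Sequence[Peak] | Sequence[GenomicInterval],
    genes: GeneIndex | Sequence[GeneModel],
    promoter_bp: int = 2000,
    downstream_bp: int = 2000,
) -> tuple[list[AnnotationRecord], pd.Series]:
    """Annotate every peak; returns (records, category table).

    The category table is a Series over :data:`CATEGORIES` (legend order)
    whose counts always sum to the number of peaks annotated.
    """
    if not isinstance(genes, GeneIndex):
        genes = GeneIndex(genes)
    if isinstance(peaks, PeakSet):
        items: Sequence = peaks.peaks
    else:
        items = peaks
    if len(genes.genes) == 0:
        logger.warning("empty gene set: all peaks will be intergenic")
    records: list[AnnotationRecord] = []
    for i, p in enumerate(items):
        cat = classify_peak(p, genes, promoter_bp, downstream_bp)
        gid, dist = nearest_gene(p, genes) if genes.genes else (None, None)
        records.append(AnnotationRecord(f"peak_{i + 1}", cat, gid, dist))
    return records, category_table(records)


def category_table(records: Iterable[AnnotationRecord]) -> pd.Series:
    counts = pd.Series(0, index=list(CATEGORIES), dtype=int)
    for r in records:
        counts[r.category] += 1
    return counts
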
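"""Normalized tag-density metaprofiles.

"Tag density" is reads per million mapped reads per kilobase, computed on
inferred fragment midpoints and averaged over the anchored regions, so the
profile is invariant to sequencing depth and to the number of regions.
Anchored profiles use a symmetric window around a point (TSS, peak summit,
site center); the meta-gene profile keeps fixed-width flanks and rescales
every gene body to a common number of bins, reversing minus-strand genes so
orientation is uniformly 5' to 3'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from relochip.genome_core import GenomicInterval, ReadSet

__all__ = [
    "MetaProfile",
    "ScoredSite",
    "tag_density_profile",
    "log2_ratio_profile",
    "metagene_profile",
    "stratify_by_score",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetaProfile:
    """Binned average signal around a set of anchored regions."""

    offsets: np.ndarray  # bin centers in bp relative to anchor (or bin index)
    density: np.ndarray
    n_regions: int
    normalization: str

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.density):
            raise ValueError("offsets and density must have equal length")

    @property
    def central_bin_density(self) -> float:
        return float(self.density[len(self.density) // 2])


@dataclass(frozen=True)
class ScoredSite:
    """A genomic site carrying a numeric score (e.g. a nucleosome
    remodelling index).  Scores are consumed, never computed here."""

    interval: GenomicInterval
    score: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("site score must be finite")


def _anchor_pairs(anchors) -> list[tuple[str, int]]:
    out = []
    for a in anchors:
        if isinstance(a, ScoredSite):
            out.append((a.interval.chrom, a.interval.center))
        elif isinstance(a, GenomicInterval):
            out.append((a.chrom, a.center))
        else:
            chrom, pos = a
            out.append((chrom, int(pos)))
    return out


def tag_density_profile(
    reads: ReadSet,
    anchors: Sequence,
    chrom_sizes: Mapping[str, int],
    window_bp: int = 5000,
    bin_bp: int = 50,
    fragment_length: int = 450,
) -> MetaProfile:
    """Average fragment-midpoint density in ``bin_bp`` bins over the
    symmetric window ``[-window_bp, +window_bp)`` around each anchor.

    Anchors may be (chrom, position) pairs, intervals (their centers are
    used) or :class:`ScoredSite`.  Bins extending beyond a chromosome are
    masked for that anchor: each bin is averaged over the anchors for which
    it lies fully inside the chromosome, so edge anchors never contribute
    phantom zero counts.
    """
    pairs = _anchor_pairs(anchors)
    if not pairs:
        raise ValueError("tag_density_profile requires at least one anchor")
    n_bins = (2 * window_bp) // bin_bp
    rel_edges = -window_bp + bin_bp * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    n_valid = np.zeros(n_bins)
    mids_by_chrom = {
        chrom: np.sort(reads.fragment_midpoints(chrom, fragment_length))
        for chrom in {c for c, _ in pairs}
    }
    for chrom, pos in pairs:
        size = chrom_sizes[chrom]
        edges = pos + rel_edges
        valid = (edges[:-1] >= 0) & (edges[1:] <= size)
        mids = mids_by_chrom[chrom]
        idx = np.searchsorted(mids, edges)
        counts += np.where(valid, np.diff(idx), 0)
        n_valid += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        per_region = np.where(n_valid > 0, counts / np.maximum(n_valid, 1), np.nan)
    density = per_region / (bin_bp / 1000.0) * (1e6 / reads.total_reads)
    offsets = rel_edges[:-1] + bin_bp / 2.0
    return MetaProfile(offsets, density, len(pairs), "reads per million per kb")


def log2_ratio_profile(
    chip_profile: MetaProfile, control_profile: MetaProfile, pseudocount: float = 0.5
) -> MetaProfile:
    """Per-bin log2((chip + eps) / (control + eps)) of two matched profiles."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not np.array_equal(chip_profile.offsets, control_profile.offsets):
        raise ValueError("profiles have mismatched offsets")
    if chip_profile.normalization != control_profile.normalization:
        raise ValueError("profiles have mismatched normalization")
    ratio = np.log2(
        (chip_profile.density + pseudocount) / (control_profile.density + pseudocount)
    )
    return MetaProfile(
        chip_profile.offsets.copy(),
        ratio,
        chip_profile.n_regions,
        f"log2 ratio ({chip_profile.normalization})",
    )


def metagene_profile(
    reads: ReadSet,
    genes: Sequence,
    flank_bp: int = 2000,
    n_body_bins: int = 100,
    bin_bp: int = 50,
    fragment_length: int = 450,
) -> MetaProfile:
    """Meta-gene profile: fixed-width flanks plus a body rescaled to
    ``n_body_bins``, averaged over genes in 5'->3' orientation.

    Genes with a transcript span shorter than ``n_body_bins`` bp are
    skipped with a warning (a body bin would be narrower than 1 bp).
    Density units match :func:`tag_density_profile`.
    """
    n_flank = flank_bp // bin_bp
    total_bins = 2 * n_flank + n_body_bins
    acc = np.zeros(total_bins)
    n_used = 0
    n_skipped = 0
    mids_cache: dict[str, np.ndarray] = {}
    for g in genes:
        length = g.tx_end - g.tx_start
        if length < n_body_bins:
            n_skipped += 1
            continue
        if g.chrom not in mids_cache:
            mids_cache[g.chrom] = reads.fragment_midpoints(g.chrom, fragment_length)
        mids = mids_cache[g.chrom]
        # gene coordinate: distance from the TSS along the strand
        if g.strand == "+":
            gpos = mids - g.tx_start
        else:
            gpos = (g.tx_end - 1) - mids
        dens = np.zeros(total_bins)
        up = gpos[(gpos >= -flank_bp) & (gpos < 0)]
        np.add.at(dens, (up + flank_bp) // bin_bp, 1.0 / (bin_bp / 1000.0))
        body = gpos[(gpos >= 0) & (gpos < length)]
        body_bins = n_flank + (body * n_body_bins) // length
        np.add.at(dens, body_bins, 1.0 / (length / n_body_bins / 1000.0))
        down = gpos[(gpos >= length) & (gpos < length + flank_bp)]
        np.add.at(dens, n_flank + n_body_bins + (down - length) // bin_bp, 1.0 / (bin_bp / 1000.0))
        acc += dens
        n_used += 1
    if n_skipped:
        logger.warning("metagene_profile skipped %d genes shorter than %d bp", n_skipped, n_body_bins)
    if n_used == 0:
        raise ValueError("no gene long enough for the requested body binning")
    density = acc / n_used * (1e6 / reads.total_reads)
    offsets = np.arange(total_bins) + 0.5
    return MetaProfile(
        offsets,
        density,
        n_used,
        f"reads per million per kb; flanks {flank_bp} bp @ {bin_bp} bp, body {n_body_bins} bins",
    )


def stratify_by_score(
    sites: Sequence[ScoredSite],
    top_frac: float = 0.10,
    bottom_frac: float = 0.10,
) -> tuple[list[ScoredSite], list[ScoredSite]]:
    """Split scored sites into the top and bottom score strata.

    Top stratum: the ``ceil(n * top_frac)`` highest-scoring sites; bottom:
    the ``ceil(n * bottom_frac)`` lowest.  Sorting is stable, so ties are
    resolved by input order (with all-equal scores both strata are simply
    the first members in input order).
    """
    if len(sites) == 0:
        raise ValueError("stratify_by_score requires a nonempty site list")
    if top_frac <= 0 or bottom_frac <= 0 or top_frac + bottom_frac > 1:
        raise ValueError("need 0 < top_frac, bottom_frac and top_frac + bottom_frac <= 1")
    n = len(sites)
    scores = np.array([s.score for s in sites])
    n_top = int(np.ceil(n * top_frac))
    n_bot = int(np.ceil(n * bottom_frac))
    top_order = np.argsort(-scores, kind="stable")[:n_top]
    bot_order = np.argsort(scores, kind="stable")[:n_bot]
    return [sites[i] for i in top_order], [sites[i] for i in bot_order]
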
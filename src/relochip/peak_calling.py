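"""Window-Poisson peak calling against a matched control, with the
sample-swap empirical FDR.

The caller is deliberately transparent: the genome is tiled with
non-overlapping fixed-size bins, each read contributes once to the bin
holding its inferred fragment midpoint, and a bin is significant when the
ChIP count clears both a Poisson upper-tail threshold (rate = scaled
control, floored at the genome-wide mean) and a minimum fold enrichment.
Significant bins within a small gap merge into peaks.  The empirical FDR
swaps the roles of ChIP and control and reports the ratio of pseudo-peak
to real-peak counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from relochip.genome_core import GenomicInterval, ReadSet

__all__ = [
    "PeakCallParams",
    "Peak",
    "PeakSet",
    "BinnedTrack",
    "bin_counts",
    "call_peaks",
    "empirical_fdr",
]


@dataclass(frozen=True)
class PeakCallParams:
    """Tuning parameters of the window-Poisson caller.

    ``p_threshold`` is the per-bin Poisson upper-tail cutoff (the analysis
    is usually run at 1e-10, 1e-15 and 1e-20 to produce a stringency
    gradient); ``lambda_floor`` of ``None`` means "use the genome-wide
    scaled control mean per bin", which guards zero-coverage control bins.
    """

    bin_size: int = 200
    p_threshold: float = 1e-10
    min_fold: float = 2.0
    max_gap_bins: int = 1
    min_peak_bins: int = 1
    fragment_length: int = 450
    lambda_floor: float | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.fragment_length <= 0:
            raise ValueError("bin_size and fragment_length must be positive")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if self.max_gap_bins < 0 or self.min_peak_bins < 1:
            raise ValueError("invalid gap/min-bin settings")
        if self.lambda_floor is not None and self.lambda_floor <= 0:
            raise ValueError("lambda_floor must be positive")


@dataclass(frozen=True)
class Peak:
    """One called peak with its per-bin Poisson evidence."""

    interval: GenomicInterval
    summit: int
    chip_count: int
    control_lambda: float
    fold_enrichment: float
    score: float  # -log10(min bin p-value), capped for underflow

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie within the peak interval")


@dataclass(frozen=True)
class PeakSet:
    """Disjoint called peaks plus the parameters that produced them."""

    peaks: tuple[Peak, ...]
    params: PeakCallParams
    chip_label: str = ""
    control_label: str = ""
    fdr: float | None = None

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


class BinnedTrack:
    """Fragment-midpoint counts per fixed-size bin, per chromosome."""

    def __init__(self, counts: Mapping[str, np.ndarray], bin_size: int, total: int):
        self.counts = dict(counts)
        self.bin_size = bin_size
        self.total = total

    def chrom_counts(self, chrom: str) -> np.ndarray:
        return self.counts[chrom]


def bin_counts(
    reads: ReadSet,
    chrom_sizes: Mapping[str, int],
    bin_size: int,
    fragment_length: int,
) -> BinnedTrack:
    """Count each read once, in the bin containing its inferred fragment
    midpoint (5' start shifted ``fragment_length // 2`` along the read
    strand, clamped to the chromosome).  Bin sums equal total reads."""
    counts: dict[str, np.ndarray] = {}
    total = 0
    for chrom, size in chrom_sizes.items():
        n_bins = int(np.ceil(size / bin_size))
        starts = reads.starts(chrom)
        if np.any((starts < 0) | (starts >= size)):
            bad = starts[(starts < 0) | (starts >= size)][0]
            raise ValueError(f"read 5' position {bad} outside chromosome {chrom} [0,{size})")
        mids = reads.fragment_midpoints(chrom, fragment_length)
        mids = np.clip(mids, 0, size - 1)
        counts[chrom] = np.bincount(mids // bin_size, minlength=n_bins).astype(np.int64)
        total += len(starts)
    return BinnedTrack(counts, bin_size, total)


def _merge_significant_bins(sig_idx: np.ndarray, max_gap_bins: int) -> list[tuple[int, int]]:
    """Group sorted significant bin indices into (first, last) runs where
    consecutive members are <= max_gap_bins + 1 bins apart."""
    runs: list[tuple[int, int]] = []
    if len(sig_idx) == 0:
        return runs
    run_start = prev = int(sig_idx[0])
    for idx in sig_idx[1:]:
        idx = int(idx)
        if idx - prev <= max_gap_bins + 1:
            prev = idx
        else:
            runs.append((run_start, prev))
            run_start = prev = idx
    runs.append((run_start, prev))
    return runs


_MAX_SCORE = 350.0  # -log10 of the smallest positive double, rounded down


def call_peaks(
    chip: ReadSet,
    control: ReadSet,
    chrom_sizes: Mapping[str, int],
    params: PeakCallParams = PeakCallParams(),
) -> PeakSet:
    """Call peaks of ChIP enrichment over a scaled control.

    Per bin the background rate is ``lambda = max(control * scale, floor)``
    with ``scale = total_chip / total_control``; a bin is significant iff
    ``P(Poisson(lambda) >= k) <= p_threshold`` and ``k / lambda >= min_fold``.
    Significant bins within ``max_gap_bins`` of each other merge into one
    peak; peaks spanning fewer than ``min_peak_bins`` bins are discarded.
    """
    if chip.total_reads == 0:
        raise ValueError("ChIP read set is empty")
    if control.total_reads == 0:
        raise ValueError(
            "control read set is empty; supply a control or use a uniform "
            "background model (lambda_floor) explicitly"
        )
    chip_track = bin_counts(chip, chrom_sizes, params.bin_size, params.fragment_length)
    ctrl_track = bin_counts(control, chrom_sizes, params.bin_size, params.fragment_length)
    scale = chip.total_reads / control.total_reads
    n_bins_total = sum(len(v) for v in ctrl_track.counts.values())
    floor = params.lambda_floor
    if floor is None:
        floor = scale * ctrl_track.total / n_bins_total
    peaks: list[Peak] = []
    for chrom in chrom_sizes:
        k = chip_track.counts[chrom]
        lam = np.maximum(ctrl_track.counts[chrom] * scale, floor)
        # Poisson upper tail P(X >= k) = sf(k - 1)
        pvals = stats.poisson.sf(k - 1, lam)
        sig = (pvals <= params.p_threshold) & (k >= params.min_fold * lam)
        sig_idx = np.flatnonzero(sig)
        for first, last in _merge_significant_bins(sig_idx, params.max_gap_bins):
            if last - first + 1 < params.min_peak_bins:
                continue
            bins = np.arange(first, last + 1)
            sig_bins = bins[sig[bins]]
            # summit: center of the max-count significant bin, leftmost tie
            summit_bin = int(sig_bins[np.argmax(k[sig_bins])])
            start = first * params.bin_size
            end = min((last + 1) * params.bin_size, chrom_sizes[chrom])
            summit = min(
                summit_bin * params.bin_size + params.bin_size // 2, end - 1
            )
            with np.errstate(divide="ignore"):
                min_p = float(pvals[sig_bins].min())
                score = -np.log10(min_p) if min_p > 0 else _MAX_SCORE
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    summit=summit,
                    chip_count=int(k[bins].sum()),
                    control_lambda=float(lam[summit_bin]),
                    fold_enrichment=float(k[summit_bin] / lam[summit_bin]),
                    score=float(min(score, _MAX_SCORE)),
                )
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return PeakSet(tuple(peaks), params, chip.label, control.label)


def empirical_fdr(
    chip: ReadSet,
    control: ReadSet,
    chrom_sizes: Mapping[str, int],
    params: PeakCallParams = PeakCallParams(),
) -> tuple[float | None, int, int]:
    """Sample-swap empirical FDR.

    Peak detection is run once on the real comparison (ChIP vs control) and
    once with the roles exchanged (control as pseudo-ChIP); the FDR is the
    ratio of pseudo-peak to real-peak counts, capped at 1.  With zero real
    peaks the ratio is undefined and ``None`` is returned.
    """
    n_real = call_peaks(chip, control, chrom_sizes, params).n_peaks
    n_pseudo = call_peaks(control, chip, chrom_sizes, params).n_peaks
    fdr = min(1.0, n_pseudo / n_real) if n_real > 0 else None
    return fdr, n_real, n_pseudo


def peaks_to_bed(peakset: PeakSet, path) -> None:
    """Write peaks as BED6+ with score = -log10(min bin p-value)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peakset.peaks):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i + 1}\t{p.score:.3f}\t.\t"
                f"{p.summit}\t{p.chip_count}\t{p.control_lambda:.4f}\t{p.fold_enrichment:.3f}\n"
            )
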
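"""Region-set overlap statistics, hypergeometric enrichment, and IUPAC
consensus motif scanning.

Overlap semantics are region-level: a region of set A is a "hit" when it
shares >= 1 bp with at least one region of set B, counted once no matter
how many B regions it touches.  The hypergeometric universe N is always an
explicit argument — there is no defensible silent default for it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from relochip.genome_core import GenomicInterval, IntervalIndex

__all__ = [
    "IUPAC_CODES",
    "OverlapResult",
    "HypergeomTest",
    "MotifSpec",
    "MotifHit",
    "EnrichmentResult",
    "directional_overlap",
    "venn3",
    "hypergeometric_overlap_pvalue",
    "scan_motif",
    "motif_enrichment",
    "extract_region_sequences",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class OverlapResult:
    """Directional overlap counts between two region sets."""

    nA: int
    nB: int
    nA_hit: int
    nB_hit: int

    @property
    def pct_A(self) -> float:
        return 100.0 * self.nA_hit / self.nA

    @property
    def pct_B(self) -> float:
        return 100.0 * self.nB_hit / self.nB


@dataclass(frozen=True)
class HypergeomTest:
    """Exact upper-tail hypergeometric overlap test.

    Drawing ``n`` regions from a universe of ``N`` of which ``K`` carry
    property A, ``p_value = P(X >= k)``; ``log10_p`` is computed in log
    space and stays finite when ``p_value`` underflows.
    """

    universe_N: int
    K: int
    n: int
    k: int
    p_value: float
    log10_p: float


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC consensus motif, scanned on both strands by default."""

    consensus: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("motif consensus must be nonempty")
        bad = [c for c in self.consensus.upper() if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {bad} in {self.consensus!r}")

    @property
    def reverse_complement(self) -> str:
        return self.consensus.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    sequence_name: str
    offset: int  # 0-based, on the forward sequence
    strand: str
    match: str


@dataclass(frozen=True)
class EnrichmentResult:
    fg_n: int
    fg_hits: int
    bg_n: int
    bg_hits: int
    p_value: float
    bg_rate_floored: bool

    @property
    def fg_rate(self) -> float:
        return self.fg_hits / self.fg_n

    @property
    def bg_rate(self) -> float:
        return self.bg_hits / self.bg_n


def directional_overlap(
    setA: Sequence[GenomicInterval], setB: Sequence[GenomicInterval]
) -> OverlapResult:
    """Count regions of each set that overlap (>= 1 bp) the other set."""
    if len(setA) == 0 or len(setB) == 0:
        raise ValueError("directional_overlap requires two nonempty region sets")
    idxB = IntervalIndex(setB)
    idxA = IntervalIndex(setA)
    nA_hit = sum(1 for a in setA if idxB.any_overlap(a))
    nB_hit = sum(1 for b in setB if idxA.any_overlap(b))
    return OverlapResult(len(setA), len(setB), nA_hit, nB_hit)


def venn3(
    setA: Sequence[GenomicInterval],
    setB: Sequence[GenomicInterval],
    setC: Sequence[GenomicInterval],
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> dict[str, dict[str, int]]:
    """Three-way overlap membership tables.

    Regions of different sets rarely coincide exactly, so a symmetric Venn
    is ill-defined; instead each set is used as the anchor in turn and its
    regions are labeled by which of the other two sets they overlap.  Each
    anchor table's four counts sum to that set's size.
    """
    sets = {labels[0]: list(setA), labels[1]: list(setB), labels[2]: list(setC)}
    indexes = {name: IntervalIndex(ivs) for name, ivs in sets.items()}
    out: dict[str, dict[str, int]] = {}
    for anchor in labels:
        others = [l for l in labels if l != anchor]
        table = {
            f"{anchor}_only": 0,
            f"{anchor}&{others[0]}": 0,
            f"{anchor}&{others[1]}": 0,
            f"{anchor}&{others[0]}&{others[1]}": 0,
        }
        for region in sets[anchor]:
            h0 = indexes[others[0]].any_overlap(region)
            h1 = indexes[others[1]].any_overlap(region)
            if h0 and h1:
                table[f"{anchor}&{others[0]}&{others[1]}"] += 1
            elif h0:
                table[f"{anchor}&{others[0]}"] += 1
            elif h1:
                table[f"{anchor}&{others[1]}"] += 1
            else:
                table[f"{anchor}_only"] += 1
        out[anchor] = table
    return out


def hypergeometric_overlap_pvalue(N: int, K: int, n: int, k: int) -> HypergeomTest:
    """Exact upper-tail hypergeometric probability P(X >= k).

    ``N``: universe size (must be supplied explicitly); ``K``: regions with
    property A; ``n``: regions with property B; ``k``: regions with both.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return HypergeomTest(N, K, n, k, 1.0, 0.0)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    logp = float(stats.hypergeom.logsf(k - 1, N, K, n)) / np.log(10)
    return HypergeomTest(N, K, n, k, min(p, 1.0), logp)


def _pattern_regex(consensus: str) -> re.Pattern:
    # lookahead capture so overlapping occurrences are all reported
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else "[" + IUPAC_CODES[c] + "]"
        for c in consensus.upper()
    )
    return re.compile(f"(?=({body}))")


def scan_motif(
    sequences: Mapping[str, str],
    motif: MotifSpec,
) -> list[MotifHit]:
    """Scan named DNA sequences for all (overlapping) occurrences of an
    IUPAC consensus.

    Matching is case-insensitive over {A,C,G,T,N}; an ``N`` in the sequence
    only matches an ``N`` in the pattern.  With ``both_strands`` the
    reverse-complement pattern is scanned on the forward sequence and hits
    are reported at their forward offsets with strand ``-``.  Hits are
    ordered by (sequence name, offset, strand).
    """
    patterns = [("+", _pattern_regex(motif.consensus))]
    if motif.both_strands:
        rc = motif.reverse_complement
        if rc != motif.consensus.upper():
            patterns.append(("-", _pattern_regex(rc)))
        else:
            # palindromic consensus: one scan, hits reported once per strand
            patterns.append(("-", _pattern_regex(rc)))
    hits: list[MotifHit] = []
    for name in sequences:
        seq = sequences[name].upper()
        if invalid := set(seq) - set("ACGTN"):
            raise ValueError(f"sequence {name!r} contains non-DNA characters {invalid}")
        for strand, pat in patterns:
            for m in pat.finditer(seq):
                hits.append(MotifHit(name, m.start(), strand, m.group(1)))
    hits.sort(key=lambda h: (h.sequence_name, h.offset, h.strand))
    return hits


def extract_region_sequences(
    regions: Sequence[GenomicInterval], genome: Mapping[str, str]
) -> dict[str, str]:
    """Pull region sequences out of an in-memory genome (chrom -> sequence).

    Regions on chromosomes without sequence raise — regions are never
    silently skipped.
    """
    out: dict[str, str] = {}
    for i, r in enumerate(regions):
        if r.chrom not in genome:
            raise KeyError(f"no sequence available for chromosome {r.chrom!r}")
        seq = genome[r.chrom]
        if r.end > len(seq):
            raise ValueError(f"region {r} extends beyond sequence of {r.chrom}")
        out[f"{r.chrom}:{r.start}-{r.end}#{i}"] = seq[r.start : r.end]
    return out


def motif_enrichment(
    fg_sequences: Mapping[str, str],
    bg_sequences: Mapping[str, str],
    motif: MotifSpec,
) -> EnrichmentResult:
    """Region-level motif enrichment of foreground vs background.

    A region counts as a hit when it contains >= 1 occurrence.  The p-value
    is the one-sided binomial upper tail of the foreground hit count at the
    background hit rate.  A zero background rate with foreground hits is
    floored at ``1 / (2 * n_bg)`` and flagged.
    """
    if len(fg_sequences) == 0 or len(bg_sequences) == 0:
        raise ValueError("motif_enrichment requires nonempty fg and bg sets")

    def n_hit_regions(seqs: Mapping[str, str]) -> int:
        hits = scan_motif(seqs, motif)
        return len({h.sequence_name for h in hits})

    fg_hits = n_hit_regions(fg_sequences)
    bg_hits = n_hit_regions(bg_sequences)
    fg_n, bg_n = len(fg_sequences), len(bg_sequences)
    floored = False
    rate = bg_hits / bg_n
    if rate == 0.0:
        if fg_hits == 0:
            return EnrichmentResult(fg_n, 0, bg_n, 0, 1.0, False)
        rate = 1.0 / (2 * bg_n)
        floored = True
    p = float(stats.binom.sf(fg_hits - 1, fg_n, rate)) if fg_hits > 0 else 1.0
    return EnrichmentResult(fg_n, fg_hits, bg_n, bg_hits, p, floored)
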
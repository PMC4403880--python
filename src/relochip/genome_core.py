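"""Coordinate conventions, interval algebra, gene models and flat-file I/O.

All coordinates are 0-based half-open ``[start, end)`` internally.  BED is
the native on-disk format; GFF3 (1-based closed) is converted on ingestion.
Chromosome names are compared by exact string match — no ``chr`` prefix
normalization is ever applied, so mixed naming between inputs surfaces as a
validation problem instead of silently empty overlaps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ReadRecord",
    "ReadSet",
    "IntervalIndex",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "read_sam",
    "merge_intervals",
    "overlap_query",
    "validate_chrom_names",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``end`` is exclusive, so two intervals sharing only a boundary
    coordinate do not overlap.  ``name`` and ``score`` carry optional BED
    column 4/5 metadata and do not take part in equality-by-coordinates
    helpers.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a nonempty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 shared bp on the same chromosome; strand is ignored."""
        return (
            self.chrom == other.chrom
            and max(self.start, other.start) < min(self.end, other.end)
        )


@dataclass(frozen=True)
class GeneModel:
    """A transcript model with derived, strand-aware TSS/TES.

    Exons are validated to be sorted, disjoint and contained in the
    transcript span; TSS and TES are always derived from the span and
    strand rather than stored, so they cannot drift out of sync.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(
                f"invalid transcript span [{self.tx_start}, {self.tx_end})"
            )
        prev_end = self.tx_start
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"exon chrom {ex.chrom} != gene chrom {self.chrom}")
            if ex.start < prev_end:
                raise ValueError(
                    f"exons of {self.gene_id} are unsorted or overlapping at {ex.start}"
                )
            if ex.end > self.tx_end:
                raise ValueError(
                    f"exon [{ex.start},{ex.end}) outside transcript span of {self.gene_id}"
                )
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, self.strand)


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read: 5' position, strand and read length."""

    start: int
    strand: str
    length: int = 50

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")
        if self.length <= 0:
            raise ValueError("read length must be positive")


class ReadSet:
    """Per-chromosome, start-sorted aligned reads.

    Reads are stored as structured numpy arrays per chromosome
    (``start`` int64, ``fwd`` bool) for fast binning; ``label`` names the
    channel (e.g. ``"chip_hormone"`` or ``"IgG"``).
    """

    def __init__(
        self,
        reads_by_chrom: Mapping[str, Sequence[ReadRecord]] | Mapping[str, np.ndarray],
        label: str = "",
        read_length: int = 50,
    ) -> None:
        self.label = label
        self.read_length = read_length
        self._starts: dict[str, np.ndarray] = {}
        self._fwd: dict[str, np.ndarray] = {}
        for chrom, recs in reads_by_chrom.items():
            if isinstance(recs, np.ndarray):
                starts = np.asarray(recs["start"], dtype=np.int64)
                fwd = np.asarray(recs["fwd"], dtype=bool)
            else:
                starts = np.array([r.start for r in recs], dtype=np.int64)
                fwd = np.array([r.strand == "+" for r in recs], dtype=bool)
            order = np.argsort(starts, kind="stable")
            self._starts[chrom] = starts[order]
            self._fwd[chrom] = fwd[order]

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._starts)

    @property
    def total_reads(self) -> int:
        return int(sum(len(v) for v in self._starts.values()))

    def starts(self, chrom: str) -> np.ndarray:
        return self._starts.get(chrom, np.empty(0, dtype=np.int64))

    def is_forward(self, chrom: str) -> np.ndarray:
        return self._fwd.get(chrom, np.empty(0, dtype=bool))

    def fragment_midpoints(self, chrom: str, fragment_length: int) -> np.ndarray:
        """Inferred fragment midpoints: 5' start shifted half a fragment
        along the read strand."""
        starts = self.starts(chrom)
        fwd = self.is_forward(chrom)
        shift = fragment_length // 2
        return np.where(fwd, starts + shift, starts - shift)

    def to_bed(self, path: str | Path) -> None:
        """Write reads as BED6; the 5' end is the interval start on + and
        ``end - 1`` on -, so ``from_intervals`` round-trips exactly."""
        L = self.read_length
        with open(path, "w") as fh:
            for chrom in sorted(self._starts):
                starts = self._starts[chrom]
                fwd = self._fwd[chrom]
                for s, f in zip(starts.tolist(), fwd.tolist()):
                    if f:
                        lo, hi, strand = s, s + L, "+"
                    else:
                        lo, hi, strand = max(0, s - L + 1), s + 1, "-"
                    fh.write(
                        f"{chrom}\t{lo}\t{hi}\t{self.label or 'read'}\t0\t{strand}\n"
                    )

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], label: str = "", read_length: int = 50
    ) -> "ReadSet":
        """Interpret BED intervals as reads: 5' end is ``start`` on + and
        ``end - 1`` on -; unstranded intervals count as forward."""
        by_chrom: dict[str, list[ReadRecord]] = {}
        for iv in intervals:
            if iv.strand == "-":
                rec = ReadRecord(iv.end - 1, "-", len(iv))
            else:
                rec = ReadRecord(iv.start, "+", len(iv))
            by_chrom.setdefault(iv.chrom, []).append(rec)
        return cls(by_chrom, label=label, read_length=read_length)


class BedParseError(ValueError):
    pass


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, preserving file order.

    Coordinates are kept verbatim (BED is already 0-based half-open).
    Column 4 becomes ``name``, column 5 ``score`` (when numeric), column 6
    ``strand``.  Malformed lines raise :class:`BedParseError` naming the
    line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            score: float | None = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "0"
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; emits 6 columns when any interval carries
    name/score/strand metadata, else BED3.  ``read_bed(write_bed(x)) == x``
    up to absent metadata defaults."""
    ivs = list(intervals)
    six = any(iv.name is not None or iv.score is not None or iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if six:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{_fmt_score(iv.score)}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _gene_from_parts(
    gene_id: str,
    chrom: str,
    strand: str,
    tx_start: int,
    tx_end: int,
    exon_starts: Sequence[int],
    exon_ends: Sequence[int],
) -> GeneModel:
    if len(exon_starts) != len(exon_ends):
        raise ValueError(f"gene {gene_id}: exon_starts/exon_ends length mismatch")
    exons = tuple(
        GenomicInterval(chrom, s, e, strand)
        for s, e in sorted(zip(exon_starts, exon_ends))
    )
    return GeneModel(gene_id, chrom, strand, tx_start, tx_end, exons)


def _read_gene_tsv(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = [
            "gene_id", "chrom", "strand", "tx_start", "tx_end", "exon_starts", "exon_ends",
        ]
        if header[: len(required)] != required:
            raise ValueError(f"unexpected gene TSV header in {path}: {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = dict(zip(header, line.split("\t")))
            gid = f["gene_id"]
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            ex_s = [int(x) for x in f["exon_starts"].split(",") if x]
            ex_e = [int(x) for x in f["exon_ends"].split(",") if x]
            genes.append(
                _gene_from_parts(
                    gid, f["chrom"], f["strand"], int(f["tx_start"]), int(f["tx_end"]), ex_s, ex_e
                )
            )
    return genes


def _gff3_attrs(col9: str) -> dict[str, str]:
    out = {}
    for part in col9.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gene_gff3(path: str | Path) -> list[GeneModel]:
    # GFF3 is 1-based closed; internal convention is 0-based half-open,
    # so start -> start - 1 and end stays.
    spans: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = cols[:9]
            start, end = int(start1) - 1, int(end1)
            a = _gff3_attrs(attrs)
            if ftype in ("gene", "transcript", "mRNA"):
                gid = a.get("ID") or a.get("gene_id")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: feature lacks ID attribute")
                if gid in spans:
                    raise ValueError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
                spans[gid] = (chrom, strand, start, end)
                order.append(gid)
            elif ftype == "exon":
                parent = a.get("Parent") or a.get("gene_id")
                if parent is None:
                    raise ValueError(f"{path}:{lineno}: exon lacks Parent attribute")
                exons.setdefault(parent, []).append((start, end))
    genes = []
    for gid in order:
        chrom, strand, s, e = spans[gid]
        ex = sorted(exons.get(gid, []))
        for xs, xe in ex:
            if xs < s or xe > e:
                raise ValueError(f"exon [{xs},{xe}) of {gid} outside transcript span")
        genes.append(
            _gene_from_parts(gid, chrom, strand, s, e, [x for x, _ in ex], [x for _, x in ex])
        )
    return genes


def read_gene_table(path: str | Path, format: str = "tsv") -> list[GeneModel]:
    """Read gene models from a gene TSV (0-based half-open) or GFF3
    (1-based closed, converted on ingestion)."""
    if format == "tsv":
        return _read_gene_tsv(path)
    if format == "gff3":
        return _read_gene_gff3(path)
    raise ValueError(f"unknown gene table format {format!r}")


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write the gene TSV dialect consumed by :func:`read_gene_table`."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttx_start\ttx_end\texon_starts\texon_ends\n")
        for g in genes:
            ex_s = ",".join(str(e.start) for e in g.exons)
            ex_e = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t{ex_s}\t{ex_e}\n"
            )


def read_sam(path: str | Path, label: str = "") -> ReadSet:
    """Read aligned reads from SAM text via pysam (optional dependency)."""
    import pysam  # local import: pysam is optional at runtime

    by_chrom: dict[str, list[ReadRecord]] = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            length = aln.query_length or aln.infer_read_length() or 50
            five_prime = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            by_chrom.setdefault(aln.reference_name, []).append(
                ReadRecord(five_prime, strand, length)
            )
    return ReadSet(by_chrom, label=label)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals into sorted disjoint ones.

    Output is sorted by (chrom, start); covered base pairs are preserved
    exactly.  Metadata (name/score/strand) is dropped, as merged regions no
    longer correspond to single input records.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


class IntervalIndex:
    """Chromosome-partitioned interval tree for overlap queries.

    Overlap is defined as >= 1 shared base pair on the same chromosome;
    strand is ignored throughout.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.intervals = list(intervals)
        for i, iv in enumerate(self.intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    def __len__(self) -> int:
        return len(self.intervals)

    def query(self, interval: GenomicInterval) -> list[GenomicInterval]:
        """All indexed intervals overlapping ``interval``, ordered by start
        (ties by end, then insertion order)."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(interval.start, interval.end), key=lambda h: (h.begin, h.end, h.data))
        return [self.intervals[h.data] for h in hits]

    def any_overlap(self, interval: GenomicInterval) -> bool:
        tree = self._trees.get(interval.chrom)
        return bool(tree is not None and tree.overlaps(interval.start, interval.end))


def overlap_query(index: IntervalIndex, interval: GenomicInterval) -> list[GenomicInterval]:
    """Functional wrapper around :meth:`IntervalIndex.query`."""
    return index.query(interval)


def validate_chrom_names(*interval_sets: Iterable[GenomicInterval]) -> dict[str, set[str]]:
    """Report the chromosome name set of each input so mismatches (e.g.
    ``chr1`` vs ``1``) are visible instead of silently empty overlaps."""
    report = {}
    for i, ivs in enumerate(interval_sets):
        report[f"set{i}"] = {iv.chrom for iv in ivs}
    return report
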
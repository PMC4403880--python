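"""Seeded generator of a toy genome with planted ground truth.

The generator emulates the statistical structure of a hormone-induction
ChIP-seq + knockdown-expression study:

* a toy genome of a few megabase-scale chromosomes carrying non-overlapping
  multi-exon gene models;
* condition-specific factor binding — a promoter-enriched baseline peak set
  versus a distal (intron/intergenic) hormone-induced set, with a tunable
  fraction of hormone peaks shared with baseline;
* read sampling: uniform background in both channels plus focal fragment-
  midpoint excess at planted peaks in the ChIP channel, against a flat IgG
  control, under a fixed-fragment-length model;
* hormone-receptor binding sites (PRbs) scored with a nucleosome
  remodelling index (NRI) coupled to planted binding strength;
* a 2 x 2 x 3 expression design in which hormone-regulated genes receive
  linear fold changes above the calling threshold and a dependent subset —
  preferentially the genes nearest planted hormone peaks — has its effect
  attenuated toward 1 in the knockdown arm.

Every emitted object is a pure function of the configuration, including the
seed; truth tables are returned alongside the data for parameter-recovery
tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from relochip.expression import ExpressionMatrix
from relochip.genome_core import (
    GeneModel,
    GenomicInterval,
    ReadSet,
    write_bed,
    write_gene_table,
)
from relochip.profiles import ScoredSite

__all__ = ["SimConfig", "SimTruth", "Simulation", "make_genome", "simulate_qpcr"]

logger = logging.getLogger(__name__)

# stage codes for deterministic per-stage RNG fan-out from the root seed
_STAGE_GENOME = 1
_STAGE_PEAKS = 2
_STAGE_READS = 3
_STAGE_SITES = 4
_STAGE_EXPRESSION = 5
_STAGE_QPCR = 6


def simulate_qpcr(
    folds: Mapping[str, float],
    vehicle: str = "EtOH",
    n_replicates: int = 3,
    base_quantity: float = 0.1,
    cv: float = 0.05,
    seed: int = 7,
) -> pd.DataFrame:
    """Emulate a reference-normalized qPCR quantification table.

    ``folds`` maps each condition to its true fold induction over the
    vehicle (whose fold is 1 by definition).  Per replicate the normalized
    quantity is ``base_quantity x fold`` with multiplicative lognormal
    noise of coefficient of variation ``cv``.  The returned table has
    columns ``condition``, ``replicate`` and ``normalized``.
    """
    rng = np.random.default_rng([seed, _STAGE_QPCR])
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    all_folds = {vehicle: 1.0, **dict(folds)}
    for condition, fold in all_folds.items():
        for rep in range(1, n_replicates + 1):
            q = base_quantity * fold * rng.lognormal(-(sigma**2) / 2, sigma)
            rows.append({"condition": condition, "replicate": rep, "normalized": q})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic dataset.

    Defaults describe a desk-scale genome (2 x 1 Mb) with 20 planted
    400-bp peaks per condition at 20x fragment-midpoint enrichment over a
    0.01 read/bp background, 450-bp fragments (midpoint of a 400-500 bp
    sonication range), and an expression design with hormone fold changes
    in (2, 4), half of the regulated genes knockdown-dependent with their
    log2 effect halved in the knockdown arm.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 100
    n_baseline_peaks: int = 20
    n_hormone_peaks: int = 20
    frac_shared: float = 0.18
    peak_width: int = 400
    enrichment_fold: float = 20.0
    background_depth: float = 0.01  # reads per bp, each channel
    fragment_length: int = 450
    read_length: int = 50
    n_prbs: int = 500
    prbs_width: int = 300
    nri_coupling: float = 3.0
    n_regulated_genes: int = 60
    frac_up: float = 0.68
    frac_dependent: float = 0.5
    fc_range: tuple[float, float] = (2.0, 4.0)
    dependent_attenuation: float = 0.5
    noise_sd: float = 0.15
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length <= 0:
            raise ValueError("need >= 1 chromosome of positive length")
        for name in ("frac_shared", "frac_dependent", "frac_up"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        if self.background_depth <= 0:
            raise ValueError("background_depth must be positive")
        if not (0 < self.dependent_attenuation < 1):
            raise ValueError("dependent_attenuation must lie in (0, 1)")
        if self.fc_range[0] <= 1.5:
            raise ValueError("fc_range low bound must exceed the 1.5 calling threshold")
        if self.fc_range[0] > self.fc_range[1]:
            raise ValueError("fc_range must be (low, high) with low <= high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_regulated_genes > self.n_genes:
            raise ValueError("cannot regulate more genes than exist")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    def rng(self, *stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stage])


@dataclass
class SimTruth:
    """Planted ground truth for parameter-recovery tests."""

    baseline_peaks: list[GenomicInterval]
    hormone_peaks: list[GenomicInterval]
    shared_peaks: list[GenomicInterval]
    peak_enrichment: dict[str, float]  # peak name -> planted fold
    prbs: list[ScoredSite]
    prbs_bound: list[bool]
    genes: pd.DataFrame  # gene_id-indexed: regulated, dependent, fc_ct, fc_kd
    peak_to_gene: dict[str, str]  # hormone peak name -> nearest gene id


def make_genome(config: SimConfig) -> tuple[dict[str, int], list[GeneModel]]:
    """Place non-overlapping multi-exon genes on the toy chromosomes.

    Genes are 2-8 kb with 2-10 exons, strands ~50/50, separated by random
    gaps drawn so placement never needs rejection retries.  Deterministic
    under the config seed.
    """
    rng = config.rng(_STAGE_GENOME)
    chrom_sizes = config.chrom_sizes
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gene_no = 0
    for ci, (chrom, size) in enumerate(chrom_sizes.items()):
        n = per_chrom[ci]
        if n == 0:
            continue
        lengths = rng.integers(2000, 8001, size=n)
        margin = 10_000  # keep gene-free chromosome ends for edge-safe peaks
        free = size - 2 * margin - int(lengths.sum())
        if free < n + 1:
            raise ValueError(
                f"cannot place {n} genes totalling {lengths.sum()} bp on {chrom} ({size} bp)"
            )
        gaps = rng.multinomial(free - (n + 1), np.full(n + 1, 1.0 / (n + 1))) + 1
        pos = margin
        for gi in range(n):
            pos += int(gaps[gi])
            tx_start = pos
            tx_end = pos + int(lengths[gi])
            pos = tx_end
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 11))
            # first exon starts at tx_start, last ends at tx_end; interior
            # breakpoints drawn without replacement keep segments >= 1 bp
            inner = np.sort(
                rng.choice(
                    np.arange(tx_start + 1, tx_end - 1), size=2 * (n_exons - 1), replace=False
                )
            )
            bounds = np.concatenate([[tx_start], inner, [tx_end]])
            exons = tuple(
                GenomicInterval(chrom, int(bounds[2 * j]), int(bounds[2 * j + 1]), strand)
                for j in range(n_exons)
            )
            gene_no += 1
            genes.append(
                GeneModel(f"gene_{gene_no:04d}", chrom, strand, tx_start, tx_end, exons)
            )
    return chrom_sizes, genes


class Simulation:
    """A fully realized synthetic study: genome, planted peaks, scored
    sites and expression, all derived deterministically from a SimConfig."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.chrom_sizes, self.genes = make_genome(config)
        self._plant_peaks()
        self._plant_scored_sites()
        self._truth_genes: pd.DataFrame | None = None

    # ------------------------------------------------------------------ peaks

    def _plant_peaks(self) -> None:
        cfg = self.config
        rng = cfg.rng(_STAGE_PEAKS)
        w = cfg.peak_width
        half = w // 2
        min_sep = 3000  # keeps planted peaks and their bins well separated

        def far_from(centers: list[tuple[str, int]], chrom: str, c: int) -> bool:
            return all(ch != chrom or abs(c - x) >= min_sep for ch, x in centers)

        # baseline: promoter-proximal (within +/- 600 bp of a TSS)
        centers: list[tuple[str, int]] = []
        baseline: list[GenomicInterval] = []
        gene_order = rng.permutation(len(self.genes))
        for gi in gene_order:
            if len(baseline) >= cfg.n_baseline_peaks:
                break
            g = self.genes[gi]
            c = int(g.tss + rng.integers(-600, 601))
            size = self.chrom_sizes[g.chrom]
            if c - half < 0 or c + half > size:
                continue
            if far_from(centers, g.chrom, c):
                centers.append((g.chrom, c))
                baseline.append(
                    GenomicInterval(g.chrom, c - half, c + half, name=f"bl_{len(baseline) + 1}")
                )
        if len(baseline) < cfg.n_baseline_peaks:
            raise ValueError("could not place the requested number of baseline peaks")

        # hormone: a shared promoter subset plus distal intron/intergenic sites
        n_shared = int(round(cfg.frac_shared * cfg.n_hormone_peaks))
        shared = [
            GenomicInterval(p.chrom, p.start, p.end, name=f"h_{i + 1}")
            for i, p in enumerate(baseline[:n_shared])
        ]
        tss_by_chrom: dict[str, np.ndarray] = {}
        tes_by_chrom: dict[str, np.ndarray] = {}
        for chrom in self.chrom_sizes:
            gs = [g for g in self.genes if g.chrom == chrom]
            tss_by_chrom[chrom] = np.array(sorted(g.tss for g in gs), dtype=np.int64)
            tes_by_chrom[chrom] = np.array(sorted(g.tes for g in gs), dtype=np.int64)
        exons = [(e.chrom, e.start, e.end) for g in self.genes for e in g.exons]

        def min_dist(sorted_pos: np.ndarray, x: int) -> int:
            if len(sorted_pos) == 0:
                return 10**9
            i = int(np.searchsorted(sorted_pos, x))
            best = 10**9
            for j in (i - 1, i):
                if 0 <= j < len(sorted_pos):
                    best = min(best, abs(x - int(sorted_pos[j])))
            return best

        distal: list[GenomicInterval] = []
        chrom_names = list(self.chrom_sizes)
        attempts = 0
        max_attempts = 200_000
        n_distal = cfg.n_hormone_peaks - n_shared
        while len(distal) < n_distal and attempts < max_attempts:
            attempts += 1
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            size = self.chrom_sizes[chrom]
            c = int(rng.integers(half + 1000, size - half - 1000))
            if min_dist(tss_by_chrom[chrom], c) < 5000 + half:
                continue
            if min_dist(tes_by_chrom[chrom], c) < 2500 + half:
                continue
            s, e = c - half, c + half
            if any(ch == chrom and max(s, xs) < min(e, xe) for ch, xs, xe in exons):
                continue
            if not far_from(centers, chrom, c):
                continue
            centers.append((chrom, c))
            distal.append(
                GenomicInterval(chrom, s, e, name=f"h_{n_shared + len(distal) + 1}")
            )
        if len(distal) < n_distal:
            raise ValueError("could not place the requested number of distal hormone peaks")

        self.baseline_peaks = baseline
        self.hormone_peaks = shared + distal
        self.shared_peaks = shared
        self.distal_hormone_peaks = distal
        # per-peak planted enrichment varies modestly around the configured fold
        folds = {}
        for p in baseline + self.hormone_peaks:
            folds[p.name] = float(cfg.enrichment_fold * rng.uniform(0.8, 1.2)) if cfg.enrichment_fold > 1 else 1.0
        self.peak_enrichment = folds

    # ------------------------------------------------------------------ reads

    def planted_peaks(self, condition: str) -> list[GenomicInterval]:
        if condition == "baseline":
            return self.baseline_peaks
        if condition == "hormone":
            return self.hormone_peaks
        raise ValueError(f"condition must be 'baseline' or 'hormone', got {condition!r}")

    def simulate_reads(self, condition: str, channel: str) -> ReadSet:
        """Sample one sequencing channel.

        Both channels receive a uniform Poisson background at
        ``background_depth`` reads/bp.  The ChIP channel additionally
        receives, per planted peak, reads whose fragment midpoints fall
        uniformly inside the peak, in expectation bringing the midpoint
        count to ``fold x`` the background expectation.  Read 5' positions
        are midpoint -/+ half a fragment according to a uniform strand.
        """
        cfg = self.config
        if channel not in ("chip", "control"):
            raise ValueError(f"channel must be 'chip' or 'control', got {channel!r}")
        cond_code = 0 if condition == "baseline" else 1
        chan_code = 0 if channel == "chip" else 1
        peaks = self.planted_peaks(condition)  # validates condition
        rng = cfg.rng(_STAGE_READS, cond_code, chan_code)
        frag = cfg.fragment_length
        shift = frag // 2
        by_chrom: dict[str, np.ndarray] = {}
        for chrom, size in self.chrom_sizes.items():
            n_bg = int(rng.poisson(cfg.background_depth * size))
            frag_starts = rng.integers(0, max(1, size - frag), size=n_bg)
            fwd = rng.random(n_bg) < 0.5
            starts = np.where(fwd, frag_starts, frag_starts + frag - 1)
            if channel == "chip":
                extra_mids = []
                extra_fwd = []
                for p in peaks:
                    if p.chrom != chrom:
                        continue
                    fold = self.peak_enrichment[p.name]
                    lam = (fold - 1.0) * cfg.background_depth * len(p)
                    n_extra = int(rng.poisson(lam)) if lam > 0 else 0
                    if n_extra == 0:
                        continue
                    mids = rng.integers(p.start, p.end, size=n_extra)
                    extra_mids.append(mids)
                    extra_fwd.append(rng.random(n_extra) < 0.5)
                if extra_mids:
                    mids = np.concatenate(extra_mids)
                    efwd = np.concatenate(extra_fwd)
                    estarts = np.where(efwd, mids - shift, mids + shift)
                    estarts = np.clip(estarts, 0, size - 1)
                    starts = np.concatenate([starts, estarts])
                    fwd = np.concatenate([fwd, efwd])
            rec = np.empty(len(starts), dtype=[("start", np.int64), ("fwd", bool)])
            rec["start"] = starts
            rec["fwd"] = fwd
            by_chrom[chrom] = rec
        label = f"{'CHD8' if channel == 'chip' else 'IgG'}_{condition}"
        return ReadSet(by_chrom, label=label, read_length=cfg.read_length)

    # ------------------------------------------------------------ scored sites

    def _plant_scored_sites(self) -> None:
        """PRbs: distal hormone peaks are factor-bound sites; the rest of
        the set is unbound.  NRI = coupling x relative binding strength for
        bound sites, plus unit Gaussian noise everywhere."""
        cfg = self.config
        rng = cfg.rng(_STAGE_SITES)
        half = cfg.prbs_width // 2
        sites: list[ScoredSite] = []
        bound: list[bool] = []
        for p in self.distal_hormone_peaks:
            strength = self.peak_enrichment[p.name] / cfg.enrichment_fold if cfg.enrichment_fold > 1 else 1.0
            nri = cfg.nri_coupling * strength + rng.normal(0.0, 1.0)
            c = p.center
            sites.append(ScoredSite(GenomicInterval(p.chrom, c - half, c + half), float(nri)))
            bound.append(True)
        chrom_names = list(self.chrom_sizes)
        peak_centers = [(p.chrom, p.center) for p in self.baseline_peaks + self.hormone_peaks]
        attempts = 0
        while len(sites) < cfg.n_prbs and attempts < 200_000:
            attempts += 1
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            size = self.chrom_sizes[chrom]
            c = int(rng.integers(half + 1000, size - half - 1000))
            if any(ch == chrom and abs(c - x) < 2000 for ch, x in peak_centers):
                continue
            nri = rng.normal(0.0, 1.0)
            sites.append(ScoredSite(GenomicInterval(chrom, c - half, c + half), float(nri)))
            bound.append(False)
        if len(sites) < cfg.n_prbs:
            raise ValueError("could not place the requested number of scored sites")
        self.prbs = sites
        self.prbs_bound = bound

    def simulate_scored_sites(self) -> tuple[list[ScoredSite], list[bool]]:
        return self.prbs, self.prbs_bound

    # ------------------------------------------------------------- expression

    def _nearest_gene_id(self, chrom: str, pos: int) -> str | None:
        best: tuple[int, str] | None = None
        for g in self.genes:
            if g.chrom != chrom:
                continue
            d = abs(pos - g.tss)
            key = (d, g.gene_id)
            if best is None or key < best:
                best = key
        return best[1] if best else None

    @property
    def peak_target_genes(self) -> dict[str, str]:
        """Nearest gene of each planted hormone peak (the truth map)."""
        out = {}
        for p in self.hormone_peaks:
            gid = self._nearest_gene_id(p.chrom, p.center)
            if gid is not None:
                out[p.name] = gid
        return out

    def simulate_expression(self) -> tuple[ExpressionMatrix, pd.DataFrame]:
        """Draw the 2 x 2 x 3 log2 expression matrix and its truth table.

        Regulated genes receive a linear hormone fold change drawn from
        ``fc_range`` (up) or its reciprocal (down).  Dependent genes —
        preferentially the nearest genes of planted hormone peaks — have
        their log2 effect multiplied by ``dependent_attenuation`` in the
        knockdown arm, moving the fold change toward 1 in both directions.
        """
        cfg = self.config
        rng = cfg.rng(_STAGE_EXPRESSION)
        gene_ids = [g.gene_id for g in self.genes]
        n = len(gene_ids)
        n_reg = cfg.n_regulated_genes
        n_dep = int(round(cfg.frac_dependent * n_reg))
        if n_dep > n_reg:
            raise ValueError("frac_dependent x n_regulated_genes exceeds regulated set")

        target_ids = sorted(set(self.peak_target_genes.values()))
        target_idx = [gene_ids.index(t) for t in target_ids if t in gene_ids]
        others = [i for i in range(n) if i not in set(target_idx)]
        rng.shuffle(others)
        # regulated set: peak-proximal genes first, then random fill
        reg_idx = (target_idx + others)[:n_reg]
        # dependent subset: again peak-proximal first
        dep_idx = set(reg_idx[:n_dep])
        reg_idx_set = set(reg_idx)

        n_up = int(round(cfg.frac_up * n_reg))
        order = rng.permutation(n_reg)
        up_set = {reg_idx[i] for i in order[:n_up]}

        lo, hi = cfg.fc_range
        fc_ct = np.ones(n)
        fc_kd = np.ones(n)
        regulated = np.array(["none"] * n, dtype=object)
        dependent = np.zeros(n, dtype=bool)
        for i in reg_idx:
            mag = float(rng.uniform(lo, hi))
            fc = mag if i in up_set else 1.0 / mag
            fc_ct[i] = fc
            regulated[i] = "up" if i in up_set else "down"
            if i in dep_idx:
                dependent[i] = True
                fc_kd[i] = 2.0 ** (cfg.dependent_attenuation * np.log2(fc))
            else:
                fc_kd[i] = fc

        base = rng.normal(7.0, 1.5, size=n)
        columns = []
        data = {}
        for kd, fc_vec in (("siCt", fc_ct), ("siCHD8", fc_kd)):
            for trt in ("EtOH", "R5020"):
                effect = np.log2(fc_vec) if trt == "R5020" else 0.0
                for rep in (1, 2, 3):
                    name = f"{trt}_{kd}_r{rep}"
                    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
                    data[name] = base + effect + noise
                    columns.append((name, trt, kd, rep))
        values = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
        samples = pd.DataFrame(
            [(t, k, r) for _, t, k, r in columns],
            index=pd.Index([c[0] for c in columns], name="sample"),
            columns=["treatment", "knockdown", "replicate"],
        )
        truth = pd.DataFrame(
            {
                "regulated": regulated,
                "dependent": dependent,
                "fc_ct": fc_ct,
                "fc_kd": fc_kd,
                "peak_proximal": [i in set(target_idx) for i in range(n)],
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
        self._truth_genes = truth
        return ExpressionMatrix(values, samples), truth

    # ------------------------------------------------------------------ truth

    def truth(self) -> SimTruth:
        if self._truth_genes is None:
            self.simulate_expression()
        return SimTruth(
            baseline_peaks=self.baseline_peaks,
            hormone_peaks=self.hormone_peaks,
            shared_peaks=self.shared_peaks,
            peak_enrichment=dict(self.peak_enrichment),
            prbs=self.prbs,
            prbs_bound=list(self.prbs_bound),
            genes=self._truth_genes,
            peak_to_gene=self.peak_target_genes,
        )

    # ------------------------------------------------------------------- I/O

    def write_files(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the whole synthetic study as plain-text files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        with open(out / "chrom.sizes", "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")
        paths["chrom_sizes"] = out / "chrom.sizes"
        write_gene_table(self.genes, out / "genes.tsv")
        paths["genes"] = out / "genes.tsv"
        write_bed(self.baseline_peaks, out / "truth_baseline_peaks.bed")
        write_bed(self.hormone_peaks, out / "truth_hormone_peaks.bed")
        prbs_iv = [
            GenomicInterval(s.interval.chrom, s.interval.start, s.interval.end,
                            name=f"prbs_{i + 1}", score=round(s.score, 6))
            for i, s in enumerate(self.prbs)
        ]
        write_bed(prbs_iv, out / "prbs_nri.bed")
        for condition in ("baseline", "hormone"):
            for channel in ("chip", "control"):
                rs = self.simulate_reads(condition, channel)
                p = out / f"reads_{condition}_{channel}.bed"
                rs.to_bed(p)
                paths[f"reads_{condition}_{channel}"] = p
        matrix, truth = self.simulate_expression()
        matrix.to_tsv(out / "expression.tsv", out / "samples.tsv")
        truth.to_csv(out / "truth_genes.tsv", sep="\t")
        return paths
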
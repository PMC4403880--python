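# Methods

## Coordinate conventions

All coordinates are 0-based half-open `[start, end)` internally; BED is the
native format and GFF3 (1-based closed) is converted on ingestion
(`start − 1`, `end`).  Two intervals sharing only a boundary coordinate do
not overlap.  Overlap is strandless everywhere (≥ 1 shared bp on the same
chromosome, compared by exact chromosome-name match); strand is honored
only for TSS/TES derivation and read extension.  Chromosome names are never
normalized — a `validate_chrom_names` pass reports name-set mismatches
rather than silently renaming.

## Peak calling

The caller is a window-Poisson test against a matched control:

1. **Counting.** The genome is tiled with non-overlapping bins (default
   200 bp).  Each read contributes exactly once, to the bin containing its
   inferred fragment midpoint: the 5′ position shifted by half a fragment
   (default fragment length 450 bp, the midpoint of a 400–500 bp
   sonication range) along the read strand.  Midpoint counting keeps
   per-bin counts Poisson and avoids double-counting a read across bins.
2. **Background.** Per bin, λ = max(control count × s, λ₀) with
   s = total ChIP reads / total control reads and λ₀ the genome-wide
   scaled control mean per bin.  The floor guards bins where the control
   happens to have zero coverage.
3. **Significance.** A bin is significant iff the Poisson upper tail
   `P(X ≥ k; λ) ≤ p` *and* `k/λ ≥ 2` (fold filter).  The analysis is run
   at p ≤ 1e-10, 1e-15 and 1e-20; stricter thresholds produce nested,
   non-increasing peak sets.
4. **Merging.** Significant bins within one bin of each other (default
   `max_gap_bins = 1`) merge into a peak; the peak p-value is the minimum
   bin p-value (reported as −log10, capped at 350 where the double
   underflows), the summit is the center of the highest-count significant
   bin (leftmost on ties), and the fold enrichment is evaluated at the
   summit bin.

Widely used callers differ in (and rarely document) these internals; the
design above was chosen to be transparent and oracle-checkable (an
independent per-bin Poisson-survival computation reproduces the significant
bins in the tests).  The swap-FDR procedure is
caller-agnostic: peak detection is rerun with control and ChIP roles
exchanged and FDR = n_pseudo / n_real, capped at 1, undefined (reported as
NA, never an exception) when n_real = 0.

## Annotation

Peaks are classified by summit position with precedence
promoter (±2 kb of any TSS) > downstream (±2 kb of any TES) > exon >
intron > intergenic.  The precedence is needed because a ±2 kb promoter
window necessarily covers first exons and introns; intergenic is the
residual class, which makes the five categories a true partition (counts
always sum to the peak count).  Both windows are parameters (default
2000 bp).  Summit classification rather than any-overlap guarantees one
unambiguous label per peak; an any-overlap mode exists behind a flag.
Nearest-gene assignment minimizes |summit − TSS| among genes on the peak's
chromosome, ties broken by lexicographically smallest gene id; the reported
distance is signed with upstream-of-TSS negative, relative to gene strand.

## Metaprofiles

"Normalized tag density" is fixed as fragment-midpoint reads per million
mapped reads per kilobase, averaged over the anchored regions — invariant
to sequencing depth and region count.  Anchored profiles use a symmetric
window (default ±5 kb, 50-bp bins); bins extending past a chromosome end
are masked per anchor (each bin is averaged over the anchors for which it
is fully inside the chromosome), so edge anchors never contribute phantom
zeros.  The meta-gene profile keeps fixed-width flanks (default 2 kb at
50 bp) and rescales each gene body to 100 bins, reversing minus-strand
genes; genes shorter than the body bin count are skipped with a warning.
Score stratification (e.g. by NRI) takes the ceil(n × fraction) highest and
lowest scorers with stable ties.  NRI values are consumed as an input score
column, never computed here.

## Overlap, hypergeometric and motif statistics

Overlap statistics are region-level: a region is a hit when it shares
≥ 1 bp with the other set, counted once regardless of partner multiplicity,
matching the "X% of sites" phrasing such analyses report.  Percentages are
rounded only at report time, half away from zero, one decimal where the
source convention prints one.  The hypergeometric universe N is a required
explicit argument — a silent default would fabricate significance; the
analysis drivers demonstrate and record a concrete convention (2-kb genomic
windows).  The exact upper tail P(X ≥ k) is computed via the hypergeometric
survival function with a log-space variant for underflowing p-values, and
is verified against exhaustive enumeration for all parameter combinations
with N ≤ 12.

Motif scanning is IUPAC-consensus matching (all 15 codes), case
insensitive, reporting every overlapping occurrence; with both-strands
scanning the reverse-complement pattern is matched on the forward sequence
and reported at forward offsets.  An `N` in a sequence matches only an `N`
in the pattern.  Region-level enrichment uses the one-sided binomial upper
tail of the foreground hit count at the background hit rate; a zero
background rate with foreground hits is floored at 1/(2·n_bg) and flagged.
De novo motif discovery is out of scope — consensus scanning is the
stand-in.

## Expression classification

Within the control-knockdown arm, per gene: linear fold change
FC = 2^(mean log2 R5020 − mean log2 EtOH), a two-sided Welch t-test on the
log2 intensities, and Benjamini–Hochberg q-values across all genes.  A gene
is regulated when FC > 1.5 (up) or FC < 1/1.5 (down) with the significance
statistic ≤ 0.01; both the BH-FDR and the raw-p criterion are available
behind a flag (default FDR).  With n = 3 replicates the Welch test's power
at the effective BH cutoff caps label recovery near F1 ≈ 0.85 on the
default synthetic conditions; the raw-p rule reaches F1 ≥ 0.9, and the
recovery tests exercise that rule.  Zero within-group variance (possible in
noiseless constructions) resolves deterministically by comparing means.

Dependence uses the linear-scale ratio R = FC_kd / FC_ct, computed
identically for up- and down-regulated genes (no sign flipping); a
regulated gene is dependent iff R > 1.20 or R < 0.8, strictly.  All strict
threshold comparisons carry a 1e-9 relative guard so a gene sitting exactly
on a boundary (FC = 1.5, R = 1.20 or 0.8) is never called on floating-point
round-off.  "Near peaks" is operationalized as: the gene is the
nearest-gene assignment of at least one called peak (no distance cutoff is
imposed, since none is defined for this analysis).  qPCR quantities use
2^−(Cq_target − Cq_reference) with amplification efficiency fixed at 2; fold
induction is the condition mean over the vehicle mean, so the vehicle fold
is identically 1.

## Synthetic data generator

The generator emulates the statistical structure of the study, not its
genome:

* **Genome.** Default 2 × 1 Mb chromosomes carrying 100 non-overlapping
  genes of 2–8 kb with 2–10 exons, strands ~50/50, placed with random gaps
  drawn by multinomial partition (no rejection retries); 10-kb gene-free
  margins keep planted peaks away from chromosome edges.  The default gene
  density (one TSS per ~20 kb) leaves room for distal peak placement under
  the ≥5 kb-from-TSS constraint.
* **Peaks.** 400-bp planted peaks (the sonication scale).  Baseline peaks
  sit within ±600 bp of a TSS; hormone peaks are a shared baseline subset
  (default 18%) plus distal sites ≥ 5 kb from every TSS, ≥ 2.5 kb from
  every TES and free of exon overlap, all centers ≥ 3 kb apart.  Per-peak
  enrichment varies uniformly within ±20% of the configured fold
  (default 20×).
* **Reads.** Both channels draw a uniform Poisson background
  (default 0.01 reads/bp); the ChIP channel adds, per peak, Poisson
  extra reads with fragment midpoints uniform in the peak, bringing the
  expected midpoint count to fold × background.  5′ positions are
  midpoint ∓ half a fragment with uniform strand, so midpoint counting in
  the caller is exact.
* **Scored sites.** 500 receptor sites (300 bp): the distal hormone peaks
  are the factor-bound subset; NRI = coupling × relative binding strength
  + unit Gaussian noise for bound sites, pure noise otherwise
  (default coupling 3).
* **Expression.** 2 treatments × 2 knockdowns × 3 replicates of log2
  intensities: gene baseline ~ N(7, 1.5²), treatment effect log2 FC, noise
  N(0, 0.15²).  60 of 100 genes are regulated (68% up, mirroring the
  asymmetry hormone stimulation shows in this system) with linear FC drawn
  from (2, 4) — reciprocal for down genes.  Half are dependent,
  preferentially the nearest genes of planted hormone peaks; their log2
  effect is multiplied by the attenuation factor (default 0.5) in the
  knockdown arm, which moves the fold change toward 1 for both directions
  (FC_ct = 4 → FC_kd = 2, R = 0.5; FC_ct = 0.25 → FC_kd = 0.5, R = 2) and
  reproduces the "lower induction of up genes, weaker repression of down
  genes" ordering as a testable median contrast.
* **Determinism.** Every output is a pure function of the configuration
  including the seed; per-stage generators are fanned out from the root
  seed by stage/condition/channel codes, so e.g. regenerating the hormone
  ChIP channel alone reproduces it bit for bit.

What the generator does *not* emulate: mappability and GC structure,
fragment-length dispersion, chromatin-state covariance between marks,
replicate-specific batch effects, and probe-level microarray noise.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of planted structure under idealized noise —
not performance on real sequencing data.

## Problem sizes and numerical choices

The default study (2 Mb genome, ~2 × 20k reads per channel, 100 genes,
500 scored sites) runs every stage in well under a second, so the full
test suite and the acceptance script complete in seconds.  The pure-noise
FDR calibration pools peak counts over 20 seeds on a 1 × 2 Mb genome at
0.02 reads/bp with p ≤ 1e-3 (discreteness of the Poisson tail makes
per-seed counts small; pooling stabilizes the ratio).  Peak-level recovery
is scored by ≥1 bp overlap between called and planted peaks (precision /
recall / F1).  Report JSON is emitted with sorted keys and the determinism
contract is hash equality of the canonical text; the output directory is
excluded from the hashed provenance.
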
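# relochip

Analysis pipeline for hormone-induced relocalization of a chromatin factor,
built around the CHD8 / progesterone-receptor (PR) system in breast cancer
cells: under proliferating conditions the factor sits mostly at gene
promoters, and within minutes of progestin (R5020) stimulation it is
recruited to distal PR binding sites (PRbs) with enhancer character, where
it is required for hormone-dependent transcription.

The package implements every computational stage of that argument as a
tested library, exercised end to end on synthetic data with planted ground
truth:

* **Peak calling** — a transparent window-Poisson caller: the genome is
  tiled into fixed bins (default 200 bp), each read counts once at its
  inferred fragment midpoint, and a bin is significant when the ChIP count
  `k` satisfies `P(Poisson(λ) ≥ k) ≤ p` (λ = scaled IgG control, floored at
  the genome-wide mean) with fold `k/λ ≥ 2`; significant bins merge across
  small gaps.  Run at the stringency gradient `p ≤ 10⁻¹⁰, 10⁻¹⁵, 10⁻²⁰`.
* **Swap-based empirical FDR** — peak detection is rerun with the control
  as pseudo-ChIP and the ChIP as pseudo-control; FDR = pseudo-peaks /
  real peaks.
* **Annotation** — each peak summit is classified into promoter (±2 kb of a
  TSS), downstream (±2 kb of a TES), exon, intron, or intergenic (that
  precedence), and assigned its nearest gene by TSS distance.
* **Metaprofiles** — normalized tag density (reads per million per kb)
  around anchors (TSS, PRbs, p300 sites), log2 ratios vs IgG, scaled
  meta-gene profiles, and top/bottom-decile stratification by nucleosome
  remodelling index (NRI).
* **Overlap & motif statistics** — directional region overlaps, three-way
  membership tables, exact hypergeometric enrichment, and IUPAC consensus
  scanning (e.g. `CTGTNC`, `TGTYCY`) with binomial region-level enrichment.
* **Expression arm** — a 2×2×3 design (EtOH/R5020 × siCt/siCHD8): a gene is
  hormone-regulated when its linear fold change exceeds 1.5 with a
  significant Welch t-test (BH-FDR ≤ 0.01 by default, raw p optional);
  it is knockdown-*dependent* when the ratio of linear fold changes
  R = FC(siCHD8)/FC(siCt) is strictly above 1.20 or strictly below 0.8.
  Dependent genes are tested for proximity to called peaks
  (hypergeometric), and qPCR/eRNA fold inductions use the 2^-ΔCq
  convention against a housekeeping reference.

The synthetic-data generator (`relochip.synthetic_data`) plants all of this
structure — promoter-biased baseline peaks vs distal hormone peaks with a
shared fraction, Poisson background reads with focal fragment-midpoint
enrichment against a flat IgG channel, NRI scores coupled to binding,
and regulated genes whose effect is attenuated in the knockdown arm,
preferentially near planted peaks — so every stage is testable offline with
parameter-recovery assertions.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic conditions (2 × 1 Mb genome, 20 planted 400-bp peaks per
condition at 20× enrichment over a 0.01 read/bp background, seed 7):

```bash
python analysis/01_simulate.py
python analysis/02_call_peaks.py
python analysis/03_annotate.py
python analysis/04_profiles.py
python analysis/05_enrichment.py
python analysis/06_expression.py
python analysis/07_report.py
```

`02_call_peaks.py` prints

```
baseline: 20 peaks at p<=1e-10, swap FDR = 0.0 (0 pseudo-peaks)
hormone: 20 peaks at p<=1e-10, swap FDR = 0.0 (0 pseudo-peaks)
```

— all 20 planted peaks are recovered per condition with no pseudo-peaks in
the swapped comparison, and the gradient 20 → 19 → 19 peaks across the
three thresholds is nested.  `03_annotate.py` shows the relocalization
structure the generator planted:

```
promoter fraction: baseline 100% vs hormone 20%
hormone peaks intronic+intergenic: 80%
```

`04_profiles.py` reports a 5.8× higher central tag density at top-decile
NRI receptor sites than at bottom-decile sites, and `06_expression.py`
calls 56 regulated genes (38 up, 18 down) of which 31 are
knockdown-dependent, with dependent genes strongly enriched near hormone
peaks (hypergeometric p ≈ 3×10⁻⁹) and eRNA fold inductions recovered
within ~10% of their planted values.

The same pipeline is available as a CLI (`relochip simulate|callpeaks|fdr|
annotate|profile|overlap|motif|expression|report|check`) for running the
stages on external BED/SAM/TSV inputs.

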
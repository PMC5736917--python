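# meiorec

Temperature-resolved analysis of the budding-yeast meiotic recombination
landscape: calling Spo11 double-strand-break (DSB) hot/cold spots from
replicate ChIP-chip tiling arrays, and detecting and classifying crossovers,
gene conversions, and break-induced replication (BIR) in four-spore tetrads
genotyped on SNP arrays.

## Who this is for

Yeast meiosis labs comparing recombination maps across conditions
(temperature, genotype, media) with two classic genome-wide assays:

1. **DSB mapping**: Spo11-enriched DNA vs control DNA hybridized to a tiling
   array, four replicates per condition, probe-level log2(S/C) ratios.
2. **Tetrad genotyping**: all four spores of a tetrad typed at ~1-kb-spaced
   SNPs distinguishing the two parental backgrounds (P1 = W303-1A-like,
   P2 = YJM789-like).

A synthetic-data generator with planted ground truth
(`meiorec.simulate`) reproduces both input kinds, so every stage is testable
without microarray data.

## The statistics at the core

**Hot/cold site calling.** Within each replicate, probes are ranked two
ways: the min–max scaled ratio `(x − min)/(max − min)` in [0, 1], and the
integer rank 1..N (1 = hottest). A probe is *hot* (*cold*) iff its rank is in
the top (bottom) `q`-tail of **every** replicate; with independent replicate
ranks at q = 0.10 and 4 replicates the per-probe false-call probability is
q⁴ = 10⁻⁴. Runs of adjacent flagged probes merge into spots.

**Event classification.** Parental-origin transitions on the four chromatids
are clustered (successive transition midpoints within 7.5 kb) and resolved
into six classes: (1) simple conversion without crossover — 3:1 tract, no
flanking exchange; (2) crossover without detectable conversion — reciprocal
exchange in the same marker interval; (3) crossover with a simple conversion
tract; (4) complex conversion (alternating donor blocks) without crossover;
(5) complex conversion with crossover; (6) BIR — a terminal nonreciprocal
tract > 5 kb.

**Detectable-fraction correction.** Conversions that fall between markers
are invisible. With f = (c₃ + c₅)/(c₂ + c₃ + c₅) the fraction of crossovers
showing a conversion tract, the corrected non-crossover count is
(c₁ + c₄)/f (assuming equal detectability of crossover-associated and
-unassociated tracts).

**Crossover interference.** Observed median same-chromosome inter-crossover
distance vs a randomization null that redraws each tetrad's crossover count
uniformly over the genome (chromosome ∝ length); one-sided rank-sum p-value.

## Worked example

```python
import meiorec as m

layout = m.make_genome_layout(seed=1)                    # 16-chromosome yeast genome
tetrads, truth = m.simulate_tetrads(layout, n_tetrads=11, seed=2)
events = [e for td in tetrads
            for e in m.assemble_events(td, chrom_lengths=layout.chrom_lengths())]
tally = m.tally_events(events, n_tetrads=11)
corr = m.conversion_correction(tally)
print(tally.crossovers, corr.co_per_tetrad, corr.detectable_fraction)
```

prints

```
1082 98 0.994
```

i.e. 1,082 crossover events recovered over 11 tetrads (98 per tetrad), and
99.4% of crossovers carried a marker-visible conversion tract (the planted
tract median, 3 kb, exceeds the 1-kb marker spacing, so nearly all tracts
are detected; real arrays with shorter true tracts give fractions near 0.5,
which is what the correction is for).

The same classes feed the published-count arithmetic directly:

```python
t30 = m.EventTally.from_counts("30C", 11, 184, 209, 544, 267, 299, 3, 63, 6)
c = m.conversion_correction(t30)
print(c.detectable_fraction, c.corrected_nco, c.corrected_nco_per_tetrad)
# 0.536 739 67
```

A command-line interface mirrors the library
(`meiorec simulate-arrays | simulate-tetrads | rank | call-spots | profile |
enrich | classify | stats | interference`); every run logs a JSON summary
with seed and thresholds to stderr.

## Coordinate conventions

Internal coordinates are 1-based with closed intervals (SGD convention).
BED export converts to 0-based half-open and the reader inverts it
losslessly. TSV tables require a header; `NA` marks missing values.
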
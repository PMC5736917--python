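# Methods

This note documents the models, conventions, and numerical choices behind
`meiorec`, and what the synthetic-data tests do and do not establish about
real data.

## Data model

Two assays share one coordinate system (`GenomeLayout`): 1-based closed
intervals over the 16 *S. cerevisiae* chromosomes (bundled SGD R64 lengths
and centromere midpoints, overridable). Markers are SNPs typed in all four
spores of a tetrad; probes are tiling-array oligonucleotides with a
gene-context class (intragenic, or intergenic between divergent / convergent
/ tandem gene pairs). Default layout dimensions follow the experimental
design: markers ~1 kb apart, ~60-base probes ~1 kb apart (a 811-bp spacing
reproduces the ~14.9k-probe array used in the acceptance runs), an
intergenic:intragenic probe ratio of 1:2.7 and intergenic class ratio
2.4:1:3.4 (divergent:convergent:tandem).

## ChIP-chip hotspot calling

Per replicate, signal and control channels are rescaled to equal sums
(log2-ratio shift invariant to channel scaling), then each probe gets a
min–max scaled activity in [0, 1] and an integer rank 1..N. Ties are broken
by genomic order so ranks are a permutation — a deterministic choice the
assay itself does not dictate. A probe is called hot iff its rank is
≤ floor(q·N) in every replicate (cold: rank > N − floor(q·N)); N is the
replicate's non-missing probe count, and a probe missing in any required
replicate is never called. The per-probe false-call probability under
independent replicate ranks is q^R (10⁻⁴ at q = 0.10, R = 4); this is also
verified by simulation. Adjacent flagged probes merge into spots; adjacency
means consecutive probes in array order on one chromosome regardless of the
bp gap (a `max_gap_bp` override exists). Spot position for regional tests is
the interval midpoint.

Regional analyses: telomere/centromere profiles average probe activity in a
5-kb window stepped 1 kb over pooled distances from all 32 chromosome ends
(or both centromere flanks); the depletion test compares observed spot
counts within 50 kb of telomeres / 25 kb of centromeres against an
expectation proportional to the probe count in those regions (1-df
chi-square); hotspot density vs chromosome size uses Pearson correlation of
spots/Mb against length; context enrichment compares observed hot-probe
counts per context class to frequency-proportional expectations with
per-class 2×2 chi-squares and a Bonferroni-corrected threshold; GC
correlation assigns each probe the GC fraction of the 5-kb window centered
on the nearest 1-kb grid point.

Overlap between conditions is computed on merged components of genomically
intersecting spots; the "shared by all three" fraction is the triple-overlap
component count divided by the mean per-condition spot count (the union
count is also reported).

## Tetrad event classification

Transitions are adjacent non-missing markers with differing parental origin
on one chromatid; missing markers are skipped (a transition may span them)
and never open or close a tract. Transitions on a chromosome are clustered
by successive midpoints within `complex_merge_bp` (default 7,500 bp, the
complex-event merge rule). Within a cluster, chromatids with differing
flanking origins are "exchanged"; the others are conversion candidates.

* Two exchanged chromatids with opposite flanks form a crossover: class 2
  when both have single transitions and no 3:1 interior, class 3 with a
  simple 3:1 tract, class 5 when either chromatid has >2 transitions.
* A non-exchanged chromatid whose deviant markers are predominantly 3:1 is a
  conversion: class 1 (one block) or class 4 (≥2 blocks). Deviant markers
  that still segregate 2:2 indicate paired reciprocal exchanges (e.g. a
  two-strand double crossover) and are resolved into crossover pairs when
  each phase-swapped block spans ≥2 markers and the two chromatids are
  complementary across it; single-marker phase swaps are reported
  unclassified (they are indistinguishable from paired genotyping errors).
* A lone exchanged chromatid whose distal segment is nonreciprocal (3:1) and
  terminal is BIR (class 6) when the tract exceeds `bir_min_bp` (5,000 bp);
  otherwise it is reported unclassified.
* 4:0/0:4 double conversions and clusters with an odd/unbalanced set of
  exchanged chromatids are emitted as unclassified records, never dropped;
  an even, flank-balanced set of >2 exchanged chromatids is resolved into
  reciprocal pairs by position.

A tract longer than the merge radius splits its boundary transitions into
different clusters; adjacent clusters are re-joined when each contains
exactly one unpartnered exchange and the markers between them are ≥80%
3:1 — the signature of one long tract, which distinguishes it from two
independent crossovers (2:2 interior). Conversion tracts are reported both
as the converted-marker span and with midpoint-extended bounds (to the
transition midpoints); tract-length statistics use the midpoint-extended
bounds, since marker spans systematically understate tract length at ~1-kb
marker spacing.

Every transition belongs to exactly one reported event (conservation is
asserted in tests). Donor direction is the parent whose sequence is present
in three chromatids across the tract.

## Derived statistics

The detectable-conversion fraction is f = (c₃+c₅)/(c₂+c₃+c₅) and the
corrected non-crossover count (c₁+c₄)/f. Reported (rounded) values follow
printed-table precision — f to 3 decimals, per-tetrad counts to integers
(half-up), percentages to one decimal (whole numbers above 1% in the tally
table) — and the rounded chain uses the 3-decimal f, with full-precision
values retained alongside. The percent of the genome converted sums
midpoint-extended tract lengths over conversion-bearing events (within-tetrad
overlaps counted once) divided by `genome_size × n_tetrads`; pass the DNA
content per meiosis (2n, ~24 Mb for this diploid) as `genome_size` to get
per-meiosis fractions.

The interference test pools same-chromosome adjacent-crossover gaps across
tetrads; the null redraws each tetrad's crossover count (count preserved
per tetrad, not just the mean), placing crossovers on chromosomes with
probability proportional to length and uniformly within them, 1,000
simulations by default. Expected value = median of simulated pooled medians;
the p-value is a one-sided Mann–Whitney rank-sum of observed gaps against
the pooled simulated gaps.

## Synthetic-data generator

Crossover counts per chromosome are Poisson with mean proportional to
length (total mean `co_per_tetrad`; per-tetrad dispersion is therefore
Poisson — a free choice, as only ranges are published). Positions use the
gamma-spacings construction: n+1 Gamma(shape, 1) gaps rescaled to the
chromosome length, which is exactly uniform order statistics at shape 1
(matching the randomization null) and spaces crossovers more evenly at
larger shape. The obligatory-crossover option (default on) forces ≥1
crossover per chromosome; interference calibration runs disable it, because
conditional on the per-tetrad total the Poisson counts are exactly the
multinomial reallocation the null performs, whereas the obligate rule is
itself a weak form of interference.

Every crossover carries a conversion tract (lognormal length, default
median 3,000 bp ≈ the observed medians, σ = 0.45) placed distal to the
exchange point on one of the two crossing chromatids; whether it is
*observed* (class 3/5 vs class 2) depends on whether a marker falls inside
it — this realizes the detection bias that motivates the corrected
non-crossover count. Non-crossover conversions flip one chromatid's tract to
the opposite parent (exact 3:1); complex events plant 2–3 alternating
sub-tracts within a ≤7.4-kb span so the 7.5-kb merge rule is exercised at
its boundary. BIR events convert a terminal segment (5 kb + lognormal
extra) on one chromatid. Chromatid choice is uniform per event with no
chromatid interference; for crossovers the pair is drawn uniformly among
homolog pairs whose current origins differ at the exchange point, so every
planted crossover is origin-visible. Crossover/conversion candidates whose
tract would run through a chromosome's terminal marker are dropped at draw
time (terminal tracts are BIR's domain and would otherwise be ambiguous);
this removes well under 1% of events at default tract lengths. The planted
truth records both the intended anatomy and the marker-resolved observable
class of each event.

The probe-array generator maps a latent activity landscape (flat baseline,
planted ≥10-fold hotspots of ~2 kb, optional telomere/centromere suppression
factors) through lognormal replicate noise (default σ = 0.25 log2 units,
keeping >90% of ratios within ±2 as in real arrays); replicate noise is
independent, so consistent high ranks identify planted hotspots.

**What the generator does not emulate:** spatially correlated probe noise,
dye/print-tip artifacts, mismatch-driven genotyping errors concentrated at
particular SNPs, postmeiotic segregation (whole-spore genotypes cannot show
5:3 patterns), chromatid interference, or any chromatin/transcription-factor
mechanism behind hotspot placement. Passing recovery tests therefore shows
the estimators are correct under the stated noise model, not that real-array
artifacts are handled.

## Problem sizes and determinism

All simulations take integer seeds and are bit-reproducible. The test suite
and the acceptance script use study-scale problems chosen as representative:
a ~14.9k-probe array with 400 planted hotspots; 40–100 simulated tetrads for
classifier recovery (with ≥2-kb tracts, ≥20-kb event separation for the
clean-recovery bound, and 1% miscall noise for robustness); 20 independent
runs of 200 (null) / 50 (interference) tetrads with 40-simulation
randomization tests for calibration and power. Larger runs change none of
the qualitative conclusions.

## Known limitations

* Clusters containing several interacting events (tracts overlapping a
  neighboring event's transitions) are resolved heuristically; at realistic
  event densities a few percent of planted crossovers merge into complex
  events or unclassified records, mirroring the ambiguity inherent in real
  event catalogues. Recovery bounds are therefore stated under a minimum
  event separation.
* The single clustering radius is a documented choice; the assay itself does
  not dictate how overlapping clusters on different chromatid pairs should
  be disambiguated.
* The corrected non-crossover count inherits the estimator's assumption that
  crossover-associated and -unassociated tracts are equally detectable; a
  deliberate mismatch (e.g. shorter NCO tracts) biases the corrected count
  in the corresponding direction.
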
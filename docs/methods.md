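# Methods

## The system being modeled

A haploid budding-yeast cross between two parents that differ at roughly
7 SNPs/kb, in a species whose genome (8 chromosomes, ~11.3 Mb here) carries a
~1-Mb introgressed region on the left arm of chromosome C. The region never
recombines and contains the *MAT* locus, so its variants segregate as a single
block in perfect linkage with mating type. Two mapping populations are
modeled: an F1 of full tetrads (45 tetrads, 180 spores) genotyped from DNA
sequencing, used for fitness QTL; and an F2 of 50 single spores, one from each
of 50 independent MATa × MATα crosses between F1 segregants, genotyped from
RNA-seq and used for eQTL.

## Meiosis simulator

Each meiosis is simulated as a four-chromatid bundle per chromosome. The
crossover count is Poisson with mean `rate × recombinable length (Mb)`; there
is no crossover interference and no obligate crossover (the species is
recombination-poor — spores with as few as 3 events over 8 chromosomes occur,
which is incompatible with one obligate crossover per chromosome). Positions
are uniform on the chromosome minus its nonrecombining intervals, and each
crossover exchanges the distal segments of two non-sister chromatids chosen
uniformly among the four possible pairs. Chromatid→spore assignment is
re-drawn per chromosome (random meiosis-I orientation, random meiosis-II
sister order), giving independent assortment. Consequences that hold exactly,
not in expectation: 2:2 segregation at every heterozygous marker; zero
crossovers inside nonrecombining intervals; and perfect linkage of the MAT
allele (tracked as a locus of its own) to the cold-region haplotype.

**Crossover rate default (4.1 per recombinable Mb per meiosis).** A crossover
is carried by two of four chromatids, and a junction between chromatids that
locally carry the same parental allele (as in three-strand double crossovers)
leaves no genotype trace; empirically ~72% of junctions are visible, so the
detected events per spore are ≈ 0.72 × rate × L/2 rather than the naive
rate × L/2. The default is calibrated once so a default-genome F1 spore shows
~14.7 detected events (range of roughly 3–30 over populations), the design
condition the generator emulates. F2 spores show more events (~20) but fewer
than twice the F1 value, because crossovers inside tracts where the hybrid is
homozygous are invisible — an emergent property of the simulator, not a rule.

**F2 allele balance.** Pairs are drawn at random among opposite mating types.
The emulated design selected pairs keeping parental alleles balanced; here
the population is resampled (bounded, default 20 attempts) and the attempt
with the fewest markers outside a [0.4, 0.6] frequency band outside the
introgression is kept, with the violation count recorded in the truth object.
Requiring *all* markers in band has vanishing probability at n = 50 (binomial
SD ≈ 0.07), so a hard resample-until-pass loop would not terminate.

**Return-to-growth LOH.** Pre-meiotic loss-of-heterozygosity tracts can be
added (`CrossoverModel.loh_rate`, off by default). They create apparent
recombination events but break exact 2:2 segregation where applied, so every
exactness guarantee above is stated for the default (off) setting.

## Observation model and genotyping rules

Reads per strain × marker are Poisson(coverage); each read reports the true
parental base with probability 1 − e, the other parental base with
probability e/3, a third base otherwise (defaults: coverage 5, e = 0.005 —
RNA-seq-like patchy depth). A cell is called P1/P2 only when depth is
strictly greater than 2 *and* every read carries the same parental base;
anything else is NA. Markers are then dropped if non-coding (flag), if ≥ 30%
of strains are NA, or if the P1 frequency among called cells leaves
[0.30, 0.70]. Balance clauses are sometimes written with the opposite
polarity (keeping only distorted markers); since that contradicts the
filter's purpose in linkage mapping, the default removes them and
`balance_mode="keep_unbalanced"` exposes the opposite convention for
comparison. Pseudomarkers sit every 3 kb starting at 1.5 kb; each takes
the majority call among markers within ±4 kb per strain, ties and empty
windows giving NA (a "nearest marker wins" tie-break is available but off).

## Recombination counting

A breakpoint is a transition between consecutive non-NA calls with different
parental origin; NA runs are skipped so a change across missing markers
counts once, and two transitions around a single marker count as two events
(gene-conversion-like tracts are not collapsed — detection is agnostic to
the mechanism, which also matches how LOH-derived events are counted). Event
positions are flanking-marker midpoints; regional densities divide midpoint
counts by interval length and population size.

## Heritability and normalization

Broad-sense heritability is the plug-in H² = 1 − σ²_noise/σ²_total with
σ²_noise the mean of within-replicate-group variances (parent 1, parent 2 and
hybrid blocks of 4 replicates for fitness; an external replicate profile set
for expression, which the simulator can emit) and σ²_total the variance
across segregant values (replicate means; one value per strain enters the QTL
scan). Sampling noise can push the raw estimate outside [0, 1]; it is clipped
with the raw value retained, and a zero total variance is flagged rather than
divided by.

Counts are normalized by median-of-ratios: per-sample factors are the median
over genes of count/geometric-mean, computed only on genes positive in every
sample, after removing genes below 32 reads in every sample. The estimator
was checked against an independent implementation to 1e-10. Factors for the
introgressed gene set are computed separately by default: the set's higher GC
content makes its quantification sensitive to per-sample composition biases,
and a *sample-varying* set-level bias is exactly what separate factors
absorb. Two properties worth stating because they are commonly mis-assumed:
median-of-ratios factors are invariant when all libraries are scaled by the
same constant (the pseudo-reference co-scales), and a sample-*constant* fold
bias on a gene set is removable by no sample-wise normalization, split or
joint — it only shifts the set's reported level.

## Linkage scans

Missing pseudomarker calls are replaced by conditional probabilities
P(P1 | nearest informative flanks) from the two-locus Markov chain with
Haldane recombination fractions, using a physical-to-genetic scaling of
0.12 cM/kb (several-fold below a typical yeast map, matching the species;
only the imputation uses it, so results are insensitive to modest
mis-scaling); observed calls get p = 1 − ε or ε (ε = 0.001), chromosome ends
condition on the single available flank, and an uninformative chromosome gets
p = 0.5 with a log message. Haley–Knott regression then fits y on [1, p] at
every locus; LOD = (n/2)·log₁₀(RSS₀/RSS₁), and the variance explained by a
peak is 1 − 10^(−2·LOD/n) = 1 − RSS₁/RSS₀ (an identity, tested to numerical
precision). Strains missing a trait are dropped scan-wide for that trait,
with n the per-trait sample size.

Per-trait significance uses 1,000 permutations of the trait against fixed
genotypes; the threshold is the 50th-largest genome-wide maximum LOD
(α = 0.05), i.e. the LOD at which a QTL appears in only 50 permutations. The
implementation exploits the fact that RSS₀ is permutation-invariant, so only
the per-permutation maximum regression sum of squares needs the LOD
transform; one trait's 1,000 permutations take ~0.05 s at 180 strains ×
3,766 pseudomarkers.

Peak calling reports the per-chromosome maximum when it clears the threshold
and admits further peaks only when separated from every accepted peak by a
valley at least 2 LOD below both (traits in this design can carry several
QTL across 8 chromosomes, so one-peak-per-chromosome would be too blunt; the
valley rule is conservative but can still split a strong signal's linked
shoulder into a second call, as the README example shows). Support intervals
are 1.5-LOD drops, a standard convention; in a cross this recombination-poor
they span tens of kilobases. A peak inside the nonrecombining region is reported at
the region midpoint with the support forced to the whole region — positions
inside it are unidentifiable, and all its loci carry identical LOD by
construction.

## eQTL FDR

Per-gene scans are vectorized over genes sharing the design matrix. Each of
the (default 100) permutations shuffles the strain labels of the entire
expression matrix jointly against fixed genotypes, preserving gene–gene
correlation — the property that makes `FDR(t) = mean false-eQTL count /
observed count` a valid estimator. An eQTL is counted per (gene, chromosome)
whose maximum LOD clears the threshold, identically on observed and permuted
data; the within-chromosome secondary-peak rule is applied only to the final
reported calls, not the FDR counts. The chosen threshold is the smallest
grid value with estimated FDR at or below the nominal level; a grid point
with zero observed eQTL has undefined FDR and is flagged. On fully null data
the curve sits near 1 at permissive thresholds.

## Architecture summaries

An eQTL is **local** when its target gene's midpoint lies in the support
interval or within 50 kb of the peak on the same chromosome (the buffer
reflects the wide support intervals of a low-recombination cross; both are
configurable), and genes inside the nonrecombining region whose peak is also
inside it are local by definition. Hotspots are Poisson-excess bins: the
genome is tiled in 50-kb bins with the cold region as a single bin, each
distant call falls in the bin of its peak, significance is the Poisson upper
tail against the uniform expectation with Bonferroni correction over bins,
and adjacent significant bins merge. The test is this package's own
formalization — the hotspot concept is usually descriptive — and local calls
are excluded for eQTL because they cluster wherever genes are. Regional
local-eQTL densities divide gene-midpoint counts by region length, and the
diversity-vs-density comparison across regions or species is an ordinary
Pearson correlation with its t-test and least-squares line.

## Pipeline and reproducibility

`run_pipeline` executes simulate → genotype → recombination/quantgen →
linkage → architecture from one config with defaults echoed for every unset
parameter. A global integer seed deterministically derives per-stage
sub-seeds (sha256 of `seed:stage`), so stages can be rerun in isolation; the
manifest lists every output with its sha256, and identical configs produce
byte-identical manifests. A stage failure aborts the run, names the stage,
and leaves earlier outputs plus a `FAILED` marker.

## Problem sizes and what the tests show

The test suite exercises the full design scale where the statistics demand
it: threshold calibration on 400 null traits × 1,000 permutations (the
false-positive rate must match 5% within 3 binomial SE), simulator exactness
over 10,000 tetrads, planted-QTL power and support-interval coverage over
500 traits at n = 180, and FDR tracking on 5,000 genes (1,000 carrying
1-log2-unit effects) at n = 50 with 100 permutations. Marker densities in
simulation-heavy tests (0.25–1 per kb rather than the biological ~7 per kb)
were chosen because every exactness property is density-independent, while
scan behavior is governed by the 3-kb pseudomarker grid that both the real
and simulated analyses use.

What passing tests do and do not show: the generator reproduces the
*statistical* structure the analysis relies on (recombination suppression,
MAT linkage, 2:2 tetrads, additive effects, NB counts, read errors), but not
real-data pathologies such as alignment artifacts, segmental aneuploidy,
batch effects, or GC bias that varies along the genome rather than by gene
set. Recovery rates measured here are therefore upper bounds on real-data
performance.

## Known limitations

- Single-QTL scans only: no composite interval mapping, epistasis or
  covariates.
- The 2-LOD valley rule can report a linked shoulder of one strong signal as
  a second peak (and conversely merges truly distinct QTL closer than the
  valley resolution).
- The permutation FDR measures association, not causality: with small n,
  chance inter-chromosome correlations can make a strongly driven gene
  significant on a non-causal chromosome, a class of error the permutation
  estimate cannot see. At the default design (n = 50, independent
  assortment) this contributes a small minority of calls, but it grows as n
  shrinks.
- H² for expression depends on an external replicate set matching the
  segregant data's normalization; no attempt is made to model shared batch
  structure between them.
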
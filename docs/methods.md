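# Methods

`ibdprio` implements the inference chain for finding a shared monogenic
disease variant among related individuals who were ascertained from a
case-control cohort rather than collected as a family: detect pairwise
identity-by-descent (IBD) from unphased genotypes, intersect the pairwise
segments to find regions shared by every affected individual, filter rare
coding variants inside those regions, and classify the surviving candidate
with the ACMG/AMP framework. Because the motivating study design involves
four individuals (two sibling pairs whose mothers are full sisters), the
package ships a gene-drop simulator that reproduces exactly that structure
with known ground truth, so every stage is testable without any private
genotype data.

## Gene-drop simulation (`pedsim`)

**Model.** Founders carry labelled haplotypes; each meiosis draws a
crossover count from Poisson(genetic length in Morgans) under a uniform
genetic map (default 1 cM/Mb), places crossovers uniformly in physical
coordinates, and splices the two parental haplotype tracks starting from a
fair-coin choice. The resulting piecewise-constant founder-label maps
(`TruthIBD`) are the ground truth for all detector validation. Genotypes
are read off founder alleles drawn per marker as Bernoulli(MAF), with MAF
drawn once per marker from the configured law (default Uniform(0.05, 0.5) —
detector power depends on marker informativeness, and this keeps most
markers informative while spanning realistic frequencies).

**X chromosome.** Males carry a single, maternally inherited X haplotype.
Hemizygous calls are stored with the homozygous diploid codes and written as
single-allele VCF genotypes; a heterozygous male X call can only arise from
the error model, which is what the male-het filter downstream exploits.

**Noise.** Genotyping error is a symmetric state flip (to either other
state with equal probability; male X flips between the two hemizygous
states), applied independently per call, followed by independent
missingness. This is simpler than an allele-level error model but produces
exactly the artifact the detector must tolerate: isolated IBS0 calls inside
true IBD segments.

**What the simulator does not emulate:** linkage disequilibrium between
markers, allele-frequency estimation error, variable recombination maps,
genotype-calling artifacts correlated along the genome, and population
structure among founders. Tests passing on simulated data therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to every property of real WGS callsets.

## IBD detection (`ibd`)

For a sample pair, each marker is classified IBS2 (identical calls), IBS0
(opposite homozygotes) or IBS1; markers with a missing call are excluded
rather than imputed. Under IBD1, IBS0 is impossible except through error;
under IBD2, everything is IBS2. The detector slides a window of 100 usable
markers and accepts windows with at most 1 IBS0 (IBD1 candidates) or at
most 5 non-IBS2 calls (IBD2 candidates); unions of passing windows are
trimmed to the outermost consistent marker, merged across gaps smaller than
one window, and filtered at 5 Mb / 100 markers on autosomes (10 Mb on X).
Overlaps are resolved in favour of IBD2, with the IBD1 remainder re-emitted
if it still passes the thresholds. The tolerances are set so that an
unrelated pair (IBS0 rate ~7–9% per marker at the default MAF law) almost
never yields a passing window run of 5 Mb, while a 0.2% genotyping error
rate (~0.1 IBS0 errors per window) stays within the IBD1 tolerance.

Genome-wide statistics use the standard kinship algebra: with p1 and p2 the
autosomal fractions covered by IBD1 and IBD2 segments, kinship = p1/4 +
p2/2, and the expected allele-sharing fraction is p1/2 + p2. Relationship
degrees are called from the powers-of-two kinship bins (first degree
[0.177, 0.354), second [0.0884, 0.177), third [0.0442, 0.0884)). Both the
allele-sharing statistic and plain coverage p1 + p2 are reported, because
published "fraction of genome shared IBD" figures do not always state which
convention a tool used; neither single-realization value is a reproduction
target here.

The male-male X analysis first removes X markers heterozygous in **any**
listed male (a joint filter, matching the idea that a het male X call is an
artifact regardless of which pair is being compared), then compares
hemizygous calls as haploid alleles with the same windowed run logic, and
reports the longest shared segment against a 10 Mb threshold.

## Interval algebra (`intervals`)

Intervals are 0-based half-open throughout; VCF/marker positions are
1-based. Normalization sorts and merges overlapping *and abutting*
intervals (so results are canonical), and the k-way intersection is a
two-pointer sweep applied left-to-right — associativity and commutativity
are asserted in tests, and all operations are checked against per-base
boolean bitmaps on toy chromosomes. Per-pair segments are flattened
(IBD1 ∪ IBD2) before the all-pairs intersection: a region "shared IBD by
all individuals" is operationalized as *in some IBD segment for every
pair*, which is necessary but not sufficient for a single common founder
allele — the simulator's `TruthIBD.shared_by_all_intervals` computes the
strict founder-label version, and the two are compared in tests.

## Variant prioritization (`varprio`)

Variants are a pandas DataFrame joined from a multi-sample VCF (carriers =
samples with ≥ 1 alternate allele) and a tab-separated annotation sidecar
keyed by chrom/pos/ref/alt; records without annotation are retained as
non-coding with absent frequencies. Filters: population allele frequency
strictly below 1% (absence from gnomAD counts as 0), membership in the
shared-IBD regions, then coding impact (stop-gain, frameshift, splicing,
missense, synonymous; one class per variant by severity rank). The default
AF policy is the **overall** gnomAD frequency: the packaged variant table
deliberately contains records whose non-Finnish-European frequency exceeds
1% but that survive the published filter, so the popmax policy is provided
but not the default. Every stage appends to a telescoping `FilterTrace`.

The missense screen calls a variant deleterious only when all three tools
agree, using each tool's standard cutoff: SIFT ≤ 0.05, PolyPhen2 HumDiv ≥
0.957 ("probably damaging"), PROVEAN ≤ −2.5. Missing scores are
conservative (not deleterious). The tools themselves are never run; their
scores are consumed as annotation columns.

## ACMG/AMP classification (`acmg`)

The categorical combining rules are implemented exactly as published
(pathogenic, likely pathogenic, benign, likely benign tiers; simultaneous
pathogenic and benign rule hits are contradictory and yield VUS) and are
verified exhaustively against an independently written brute-force
evaluator over all subsets of a 10-code panel. The Bayesian adaptation
multiplies per-code odds of pathogenicity — supporting 2.08, moderate 4.33,
strong 18.7, very strong 350 — and updates a prior of 0.10 via
posterior = O·π / (O·π + 1 − π), thresholded at ≥ 0.99 (pathogenic),
≥ 0.90 (likely pathogenic), ≤ 0.10 (likely benign), < 0.001 (benign).

The rounded constants are the default because they reproduce published
worked examples (two moderate + four supporting → 4.33² × 2.08⁴ = 350.9 →
posterior 0.975); the exact ladder 350^(2^−k) gives 350.0 for the same set
and is available via `OddsModel(exact=True)`. Benign evidence contributes
the reciprocal of the same-strength odds, with the stand-alone code (BA1)
weighted as very strong — the benign side of the framework is less
standardized, so this convention is explicit rather than implicit.
Disagreement between the categorical and Bayesian classifications raises a
warning and both results are always reported.

## Demo pipeline and problem sizes

The end-to-end chain (`pipeline.run_demo`, `ibdprio run`) simulates the
two-family pedigree on a scaled genome — 6 autosomes × 150 Mb plus a
155 Mb X at 1 marker / 20 kb (~52,700 markers), 0.2% genotyping error,
0.2% missingness — injects a rare missense variant on a founder haplotype
shared by all four probands, and runs detection, intersection,
prioritization and classification in about one second. The same
expectation-level statistics hold at this scale as at full genome scale
(kinship expectations and the 1/16 four-way sharing fraction are per-locus
properties), which is why the test suite and the acceptance script use it:
simulation-based checks average 50–250 replicates and complete in seconds.
A full-scale configuration (22 autosomes + X at 1 marker / 10 kb) is
shipped but not exercised by the tests.

Numerical conventions worth knowing: detected segment boundaries are marker
positions, so boundary error is bounded by the local marker spacing plus
the window resolution (~0.3 Mb at demo density — visible as a small upward
bias in cousin kinship, well inside the ±0.03 recovery tolerance);
chromosomes with fewer usable markers than one window are evaluated as a
single shortened window; ties between IBD2 and IBD1 always resolve to IBD2.

## Known limitations

* The detector is windowed IBS run-finding, not an HMM; it reports physical
  coordinates only and does not estimate segment posteriors.
* Sharing statistics assume the genome model used for detection; segments
  on chromosomes absent from the model are an error by design.
* The packaged shared-region BED is a synthetic stand-in constructed to
  cover the published variant positions with the published segment count,
  span and mean length; the study's own segment coordinates are not public.
* PP1–PP4 style evidence is consumed as asserted input, never derived
  automatically from annotations.
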
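# Methods

This note documents the models, estimators, and numerical choices behind
`rohscape`, and what the synthetic-data tests do and do not establish about
real data.

## Data model

Genotypes are diploid biallelic calls stored as copies of `allele2`
(0/1/2, −1 missing) in a dense individuals × markers matrix, with a marker
map (chromosome, 1-based bp position, allele labels) kept globally sorted by
(chromosome, position).  All internal coordinates are 1-based inclusive;
BED's 0-based half-open convention exists only at the file boundary.
PED/MAP files carry no allele-order metadata, so the reader orients each
marker's alleles lexicographically; round-trip identity therefore holds for
matrices in that canonical orientation, while VCF (explicit REF/ALT)
round-trips unconditionally.

## Quality control

Filters run in a fixed, reported order: non-autosomal/unmapped markers;
marker call rate < 0.90; individual call rate < 0.90 (computed on surviving
markers); Hardy–Weinberg exact-test p < 10⁻⁶; optional MAF (off by default
for ROH work — pruning rare alleles erases homozygous regions — and 0.01 for
diversity statistics).  HWE uses the exact conditional test (two-sided: sum
of probabilities of heterozygote counts no more likely than observed, given
allele counts), computed with log-gamma arithmetic and verified against
exact rational enumeration; no mid-p adjustment.  When multiple population
labels are present, HWE is tested per population and a marker failing in any
population is removed (a pooled mode exists).  One caveat: one-pass
call-rate filtering is idempotent for structured missingness (bad markers /
bad samples) but is not a mathematical fixed point under diffuse missingness
sitting exactly at a threshold, because removing samples changes marker
call-rate denominators.

## ROH detection

The caller reproduces sliding-window scanning semantics: window verdicts
(≤ 1 het, ≤ 5 missing in 50 SNPs), per-SNP qualification by the fraction of
covering windows that qualify (threshold 0.05 — the one semantic constant
the window description leaves open; it is exposed as `window_hit_fraction`),
maximal runs of qualifying SNPs, splitting at inter-marker gaps > 1 Mb, then
length (≥ 1 Mb), SNP count, and density (≤ 100 kb/SNP) filters.  Segment
length is `end − start + 1` bp on the first/last qualifying marker.
Chromosomes shorter than the window get a single truncated window (logged).
The implementation is vectorized but regression-checked, configuration by
configuration, against an exhaustive plain-loop scan on hundreds of random
fixtures.

The minimum SNP count defaults to the false-positive formula
`l = ln(α/(n_s·n_i)) / ln(1 − h̄et)` with ceiling rounding (conservative)
and h̄et the observed heterozygous-call proportion; at α = 0.05 with
45,424 SNPs and 2,096 individuals at h̄et = 0.27 this yields 68.  Note the
formula sets an effective floor on detectable tract length of roughly
`l × mean marker spacing` (≈ 3.4 Mb at 54 kb spacing and l = 63–68): on a
50K chip most of the nominal 1–5 Mb class is only reachable in locally
dense regions.  Users can override `min_snp_count` directly.

Segment age is dated by the expected IBD-length relation L = 100/(2g) cM
with 1 cM ≈ 1 Mb; length classes are left-closed: [1,5), [5,10), [10,∞) Mb.

## Inbreeding coefficients

F_ROH divides summed segment length by the chip-covered autosome span
(default 2.45 Gb) and decomposes exactly into the three length classes.
F_HOM is the method-of-moments coefficient
(O_hom − E_hom)/(N_nm − E_hom) with per-marker expected homozygosity
1 − 2p(1−p)·2n/(2n−1); allele frequencies include the focal individual and
monomorphic markers contribute 1 (no information).  Group contrasts (sex,
line) use the two-sided Wilcoxon rank-sum test — a distribution-free choice,
named in the output — and correlations are Pearson with pairwise-complete
observations.

## ROH landscape

Occurrence is the fraction of all individuals (denominator: everyone, with
or without ROH) whose segments cover a marker position.  Hotspots are
maximal runs of consecutive markers at occurrence ≥ 0.80 (inclusive by
default; single sub-threshold markers break runs — no bridging, since
bridging rules have no principled default); single-marker regions are
allowed.  Coldspots are runs at occurrence exactly 0 in *every* supplied
population, reported with SNP counts so users can filter short ones.
Flanking uses ±50 kb with clipping at position 1 (and the chromosome end
when sizes are known) and merges overlapping or adjacent expansions.
Interval overlap (e.g. against QTL files) reports all pairs with ≥ 1 bp
overlap, with an optional ≤ 1 Mb subject-length pre-filter.

## Diversity, differentiation, and Ne

Windows are non-overlapping 500-kb tiles from position 1 (step exposed for
sliding use).  Per-site π is the fraction of chromosome pairs differing
(c₁c₂/C(n,2) from allele counts over non-missing chromosomes); window π
divides the per-site sum by the window span.  Tajima's D uses the classical
a₁…e₂ constants; with missing data the window's n is the minimum non-missing
chromosome count over member sites, a conservative single-n choice because
the variance constants assume one sample size.  F_ST uses the Weir–Cockerham
(1984) per-site variance components with genome/window summaries as ratio of
sums (the weighted estimator; the unweighted mean of windows is also
reported); the closed-form components are verified against an independent
nested-ANOVA sums-of-squares derivation.  Sites where any population has
fewer than two called samples are skipped.

Ne-from-LD bins same-chromosome marker pairs by bp distance (unphased dosage
r², pairwise-complete, MAF ≥ 0.05), maps the bin midpoint to Morgans at
1 Mb = 1 cM, dates each bin at t = 1/(2c), and estimates
Ne = (4c)⁻¹(1/r²_adj − α) with r²_adj = r² − 1/n and α = 2.2.  The mapping
f(c) = c, the α constant, and the sampling adjustment are explicit
parameters recorded in output, because published applications vary in all
three; absolute Ne values are accordingly sensitive to these conventions.
Note the simulator does not generate background LD, so Ne estimates on
synthetic data reflect planted structure only.

## Association

Single-SNP OLS of the trait on dosage plus age and batch, complete cases
only.  Batch is dummy-encoded by default; a numeric-covariates mode
reproduces tools that treat all covariates as single numeric columns.  The
counted allele is user-designated (derived-allele coding for
ancestral/derived designs); flipping it flips β's sign only.  Rank-deficient
designs raise an error naming the offending column.  No multiple-testing
correction by default (single-SNP use case); a Bonferroni helper exists.

## Synthetic data: what it emulates, and what it does not

The generator emulates a two-line 50K-chip study: 18 autosomes of 136 Mb
with ~2,524 uniformly scattered SNPs each (~54 kb mean spacing), ancestral
allele frequencies uniform on [0.05, 0.95], Balding–Nichols divergence at a
known F (default 0.093, a moderate two-line differentiation), Hardy–Weinberg
genotypes within populations, hom→het genotyping-error flips at 0.2% (the
error mode the caller's one-het window allowance exists to absorb), 1%
missingness, and an additive phenotype with age and batch covariates.  The
default planting scheme places one 4, 7, and 12-Mb tract per individual —
one representative per ROH length class, with the short class represented at
4 Mb because the SNP-count formula makes tracts below ~2.5–3.5 Mb
undetectable at chip density (see above).  Tracts overwrite genotypes with
one sampled haplotype; frequency-planted tracts at a fixed locus share a
single haplotype across carriers, as identity-by-descent implies.
All randomness flows from one mandatory seed through numpy PCG64
(algorithm recorded in the truth object); outputs are bit-identical per
seed.

Deliberate simplifications: marker spacing is uniform-random rather than
chip-realistic (density effects are tested with dedicated sparse fixtures);
there is no background LD, no pedigree, and no coalescent history.  Passing
the planted-recovery tests therefore demonstrates correctness of the
detection arithmetic and robustness to genotyping noise, not performance
under realistic LD-induced background homozygosity.

### Scoring planted-tract recovery

Boundary accuracy is scored asymmetrically, on resolution grounds.  With
exact genotypes, recovery requires both called boundaries within one
inter-marker interval of the planted tract (inward).  Outward extension into
flanking markers that are homozygous by chance is not scored as error: an
IBD boundary is only localizable to the nearest informative (heterozygous)
marker, and the window tolerance deliberately absorbs isolated flanking
hets.  Under genotyping error, an error-het near a tract edge truncates the
observable call by design (the same behavior as the reference
sliding-window tool), so the noisy-data check scores *recovery* —
≥ 90% of a tract's markers covered by calls — rather than exact boundaries;
both checks must clear 95% on the 500-individual scenario.

## Problem sizes used in tests

Test scenarios scale the study design down for speed while preserving the
quantities that matter: chip marker density (~54 kb) is kept when testing
ROH detectability (500 individuals, 5 × 54 Mb chromosomes, 5,000 SNPs);
F_ST recovery uses 100+100 individuals at 5,000 SNPs; association
calibration uses n = 500 (type-I error, 200 replicates) and n = 365 (CI
coverage, 500 replicates); oracle equivalence runs on ≤ 300-marker fixtures
(500 random ROH configurations; exact-arithmetic HWE enumeration).

## Known limitations

* Consecutive-runs ROH calling and HMM-based callers are out of scope.
* Cross-population π (d_xy) is not implemented; "between-population"
  diversity comparisons should use F_ST.
* The exact f(c)/α/r²-adjustment conventions used by published Ne-from-LD
  analyses vary; absolute Ne values depend on them.
* Binary PLINK (.bed) input, phasing, imputation, and annotation retrieval
  from external databases are out of scope; interval overlap works with
  user-supplied BED files.
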
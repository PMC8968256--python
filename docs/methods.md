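# Methods

This note records the models, estimators, numerical choices and known
limitations behind `genocurate`. It documents what the code computes and
why the defaults are what they are; every number quoted is produced by
the test suite or `scripts/acceptance.py`.

## Data model

Genotypes are alternate-allele dosages {0, 1, 2} with a single missing
sentinel, over biallelic SNPs only. Phase is ignored: the intended
material is a predominantly selfing diploid collection genotyped by
reduced-representation sequencing (GBS), where calls are unphased and
residual heterozygosity is a few percent at most. Ref/alt orientation
follows the input file and is never re-polarized by frequency; all
statistics used downstream (MAF, IBS, H, F_ST, coverage) are invariant
to orientation. Positions are 1-based; reported regions are 1-based
inclusive intervals, exported BED files 0-based half-open.

## QC cascade

Order: Fisher disassociation filter → site filters → accession filter →
per-group single-het cleanup. Re-running any stage on its own output is
a no-op.

**Fisher disassociation filter.** For an inbred line a true biallelic
SNP appears almost exclusively as one of two homozygotes; loci where
many accessions carry *both* alleles (heterozygous calls) are typically
collapsed paralogs or mapping artifacts. Each accession is classified by
ref-allele and alt-allele presence, giving the 2×2 table
(het, hom-ref / hom-alt, missing); the one-sided Fisher exact P for
under-representation of co-occurrence (odds ratio < 1) is the
hypergeometric left tail P(X ≤ n_het), computed vectorized via
`scipy.stats.hypergeom.cdf`. Sites with P < α (default 0.001) are kept.
On simulated data (N = 200, het only from a 1% error rate vs. planted
independent-presence artifacts) the filter keeps ≥ 99% of true sites and
removes ≥ 95% of artifacts. The test suite checks agreement with an
exact integer-arithmetic enumeration to ≤ 1e-12 over all tables with
margins ≤ 30, and against `scipy.stats.fisher_exact`.

**Thresholds.** MAF > 0.01, site missingness < 0.30, site heterozygosity
< 0.10, accession missingness ≤ 0.55 (removal is strict ">"), all strict
as written; boundary values fall accordingly. In groups larger than 100
accessions, loci whose only variation is a single heterozygous call are
removed as presumptive sequencing errors before counting segregating
loci. The accession filter is applied once, before species separation
(applying it per group would let a borderline accession survive in one
group and not another).

**Imputation.** Where a complete matrix is required (the selection scan)
missing calls are replaced by the per-site mode, ties toward the lower
code, deterministically. This single-site rule ignores linkage and
shrinks rare-allele frequencies slightly; it is a documented fidelity
limitation confined to the scan stage.

## Duplicate detection

IBS is computed only over loci where both accessions are homozygous and
non-missing — heterozygous calls in a selfer are mostly error, so a site
where one member is het is excluded from numerator and denominator
alike. Pairs with fewer than `min_compared = 500` jointly scored loci
are *undefined*, never "identical": high identity from a tiny overlap is
the classic false positive in sparse GBS data. (Real collections of this
kind compare 3–6 thousand loci per species group.)

**Threshold discovery.** The histogram (bin 0.0025) of pairwise
identities in a collection with duplicates is bimodal: an unrelated-bulk
mode and a near-1.0 duplicate mode. The operating threshold is the
density minimum between them. Because the empirical counts between the
modes are typically all zero, the minimum is located by modeling each
mode as a Gaussian with scale estimated from its full width at half
maximum and taking the equal-z-score crossing, clamped into the empty
gap. Guards: a candidate duplicate mode must carry at least
max(5, 0.05%) of the pairs, sit ≥ 5 bulk-sigmas above the bulk mode and
lie at identity ≥ 0.95 (clones differ only by genotyping error, so their
mode is near perfect identity by construction; lower secondary modes are
population structure, e.g. mislabeled accessions). If no mode qualifies
the default 0.99 is returned with a note. On a
0.95·N(0.75, 0.03²) + 0.05·N(0.998, 0.001²) mixture the detector returns
0.988, matching the analytic tail-crossing; on clone simulations it
returns 0.94–0.97.

Duplicate groups are connected components of the ≥-threshold graph
(identity is transitive only approximately, but gene banks report *sets*
of identical accessions, and components are the conservative closure).
`unique_count = N − Σ(|group|−1)` holds at every threshold, and raising
the threshold never merges groups. Glume-color scores (0 = white …
9 = black) cross-validate groups: a group with more than one distinct
score is flagged for curator review.

## Population structure and mislabel proposals

Distances default to 1 − IBS (robust to missing data); a
missing-rescaled Euclidean metric (scaled by √(L_total/L_shared)) is
available to mirror default-parameter distance clustering. Trees are
Saitou–Nei neighbor joining via scikit-bio; negative branch estimates
are clamped to zero and counted. On additive distances NJ reproduces the
generating tree exactly (tip-distance error ~1e-15 for trees of 3–6
leaves, which for an additive metric implies exact topology and branch
lengths).

PCA operates on the additive genomic relationship matrix: calls centered
by twice the alternate-allele frequency (missing → mean), cross-product
scaled by 2Σp(1−p) (VanRaden scaling); coordinates are eigenvectors ×
√eigenvalue and variance explained is eigenvalue/trace. Coordinates are
deterministic up to per-axis sign.

Mislabel proposals: for each accession (duplicates collapsed to one
representative first, so clone clusters cannot out-vote a neighborhood)
the majority taxon among its k = 10 nearest neighbors is compared with
its passport label; a proposal is emitted when they disagree and the
majority reaches 0.8. The parameters are deliberately conservative —
zero false proposals on well-separated simulated subpopulations — and
the output is advisory: reclassification is a curator decision, made in
the real workflow with structure, phylogeny, PCA and morphology jointly.
When mislabeled accessions are numerous enough to contaminate each
other's neighborhoods, some fall below the agreement gate and are
skipped rather than mis-proposed.

## Diversity and differentiation

Nei's index is the unweighted mean over loci of 2pq, without the
n/(n−1) small-sample correction: at gene-bank collection sizes the
correction is < 1%, and omitting it keeps the index a pure function of
sample frequencies (external validation can apply the correction
explicitly). Segregating-locus counts apply the single-het rule first.

Group-pair F_ST uses the G_ST form 1 − ΣH_S/ΣH_T with sample-size
weighted within-group expected heterozygosities — ratio of sums over
loci, not mean of per-locus ratios, for stability at low-diversity loci.
The per-site Weir–Cockerham (1984) θ̂ implements the standard a, b, c
variance components for r = 2; sites where either group has < 2 called
accessions are undefined. Multi-locus summaries use Σa/Σ(a+b+c); the
scan uses per-site values.

Estimator behavior worth knowing (measured, not assumed): on
Balding–Nichols simulations with two groups of 50 selfing accessions at
true F = 0.10 over 5,000 loci, the multi-locus estimate is 0.094–0.100
across seeds, while the *mean of per-site* θ̂ is 0.076–0.081. The
per-site mean is Jensen-biased below the ratio of sums — even with exact
subpopulation frequencies and infinite samples it converges to ≈ 0.084
under this allele-frequency distribution. The two estimators answer
different questions; the package reports both, and genome-wide summaries
should rely on the multi-locus form. The G_ST-style pairwise estimate
tracks the per-site mean within ≤ 0.02 on the same data. Randomly
permuting group labels drives every estimator to |F| ≤ 0.01.

## Selection scan

The scan balances group sizes by seeded subsampling of the larger group
(mirroring a 145-vs-145 domesticated/wild comparison), computes per-site
θ̂, smooths per chromosome with Lowess (statsmodels; tricube weights
over the nearest ⌈f·n⌉ points, f = 0.1), and calls regions where the
smoothed profile exceeds mean + k·σ (k = 3) of the **raw** defined
per-site values. Negative θ̂ are retained in mean/σ — clamping would
bias σ downward and the threshold with it. A config switch computes the
threshold on smoothed values instead, for sensitivity analysis.

Robustifying iterations default to **0**. Lowess's bisquare reweighting
exists to discard residual outliers, but in a selection scan the
contiguous block of extreme F_ST *is* the signal: with 2–3 robustifying
passes a planted 25-site sweep window (25 of ~70 points in each local
window) is assigned zero robustness weight and vanishes from the
smoothed profile (measured smoothed peak: 0.60 at 0 passes, 0.55 at 1,
0.07 at 3, against a threshold of 0.42). Scans that smooth *after*
outlier detection, or that expect to retain signatures after smoothing,
must not robustify; the option remains for denoising applications.

Measured operating characteristics (7 chromosomes × 700 sites, F = 0.1
background, 145 vs 145): a planted 25-site window at p = 0.98/0.02 is
recovered as exactly one region overlapping the window; across 50
no-sweep seeds, 100% yield zero regions (the criterion requires ≥ 95%).
Fixed-difference sites reach raw θ̂ = 1 inside the window.

## Core selection

Coverage counts (site, homozygous-class) pairs present in the full
collection after masking heterozygous calls to missing; it is monotone
and submodular (asserted exhaustively on small instances), so greedy
selection is near-optimal (≥ 1−1/e of the best equal-size coverage).
Ties break to the lowest accession index for determinism. Stopping:
coverage ≥ cv (0.99), marginal gain < d (0.0001), or exhaustion. This
simplifies the frequency-weighted internal score of coverage-based core
selectors to unweighted presence — the reported outputs (% coverage,
% segregating loci retained) are the quantities of record either way.
On structured simulations each per-group core reaches ≥ 99% coverage
and retains ≥ 95% of the group's segregating loci, comfortably above
the ≥ 79% floor observed in real collections of this type. Geographic
and phenotypic representativeness are reported, not optimized — they
are curator-level criteria.

## Synthetic collections

The generator's defaults describe a realistic mid-size collection:
4 subpopulations (a strongly diverged wild outgroup species, a
domesticated group, two wild races) of 100/100/150/50 accessions,
5,000 SNPs spread over seven 500-Mb chromosomes at distinct uniform
positions, Balding–Nichols F of 0.7/0.4/0.5/0.4 (chosen so realized
pairwise differentiation spans ~0.2–0.4, strong species-level structure
with crossable subgroups), selfing f_is = 0.97, 5% missingness, 0.2%
heterozygous error, 30 appended clones at ε = 0.002, one 25-site sweep
window between the domesticated and α-like groups, and 2.5% wrong taxon
labels. Duplicate-analysis simulations use a single group at F = 0.7,
which yields within-group Nei diversity ≈ 0.11 — the range observed in
real inbred cereal collections (0.06–0.11) — and therefore a realistic
high-identity bulk.

What the generator does **not** model: linkage and recombination (sites
are independent given subpopulation frequencies), admixed individuals,
demographic history, allele-frequency spectra from mutation processes,
or locus-specific error. Passing tests therefore demonstrate estimator
and pipeline correctness under the stated generative model, not
robustness to LD, admixture clines or batch effects in real GBS data.

## Problem sizes and determinism

Test and acceptance runs use collections of 120–430 accessions and
2,000–6,000 loci, and 50 seeds for the scan false-positive property —
sizes at which every stage completes in seconds while keeping
Monte-Carlo error well inside the asserted tolerances. All randomness
flows from explicit seeds (`numpy.random.default_rng`); simulation,
balancing and the full pipeline are bit-reproducible given (config,
seed), and the pipeline manifest records every parameter and count
needed to recompute its artifacts.
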
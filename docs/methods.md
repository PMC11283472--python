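# Methods

This note records the models behind each module, the parameters that matter,
what the synthetic generators do and do not emulate, and the numerical and
design choices taken where the procedure was genuinely open.

## Coverage model and X identification

Windows of 10 kb (default) tile each contig; the terminal window is truncated
at the contig end and flagged. Simulated window read counts are Poisson with
expectation `depth × window_fraction × copies / 2`, where `copies` is 1 for
male windows on X contigs and 2 otherwise — the simplest noise model
consistent with uniform short-read coverage. Real coverage is overdispersed
(mappability, GC, repeats); the simulator deliberately omits these, so
recovery tests demonstrate correctness of the statistical chain, not
robustness to mapping artifacts. Repeat-aware depth extraction is expected to
happen upstream (the classifier consumes window counts, not BAMs).

The normalization chain is RPKM (per-sample totals over all windows), then
division by the per-sample mean RPKM over reference contigs. Reference
contigs are chosen automatically as the k = 5 longest contigs with a
preliminary m:f mean-RPKM ratio within 1 ± 0.1, replacing a manual selection
step with a deterministic rule; length ties break on lexicographic contig id.
After reference normalization, a uniform depth difference between samples
cancels exactly, which is what makes the X ratio land on 0.5 rather than
0.5 × (total-depth skew).

Per contig, pooled male window values are compared with pooled female values
(pooling across same-sex samples after per-sample normalization; averaging
samples first is the other defensible reading and is not what we do — pooling
uses all windows and keeps the test exact at small contig counts). The
two-sided Wilcoxon rank-sum test uses the exact null distribution when both
groups have ≤ 20 values and no ties, otherwise the normal approximation with
continuity correction and midranks. Bonferroni multiplies by the number of
*tested* contigs — contigs failing the 30 kb / 3-window filter are excluded
from the denominator. The m:f ratio is reported only for contigs significant
after correction (α = 0.05); significant contigs inside [0.4, 0.6] are X,
significant outside are undetermined, non-significant are autosomes. The
band is the hemizygous expectation 0.5 ± 0.1.

## Expression simulation

Gene baseline means are log-normal (`2^Normal(6, 1.5)` by default, i.e.
median 64 counts with a realistic right tail). Counts are negative binomial
with `var = μ + φμ²`; the default dispersion φ = 0.1 is a free parameter in
the middle of the range typical for laboratory bulk RNA-seq replicates, not
an inference from any dataset. Five replicates per sex per tissue; per-sample
library-size factors uniform in [0.75, 1.25].

Planted sex effects: `planted_bias` is an *ordered* sequence of
(sex, fraction) pairs (default 5% female-biased, 5% male-biased) with
|log2 effect| uniform in [2.5, 6]. The favored sex's mean is `2^e` times the
other sex's, with the effect split symmetrically about the baseline
(`base·2^{±e/2}`). The symmetric split keeps the two sexes' library mass
balanced in expectation — applying the whole boost to one sex makes planted
genes dominate library composition and shifts *every* gene's CPM ratio, an
artifact of extreme planted effect mass rather than of the estimator.
Direction assignment is positional, so swapping the sex names in place
reverses every planted direction exactly under the same seed (an exact
per-gene swap under unequal fractions is otherwise impossible, since the
class sizes differ).

`x_compensation="full"` leaves X-linked genes identical in expectation
between sexes; `"none"` halves the male X expectation (single copy, no
upregulation).

## Dosage statistics

CPM is plain counts-per-million (no TMM); a TMM-normalized expression matrix
can be passed in wherever a CPM table is accepted. A gene is "expressed" in a
tissue when CPM ≥ 1 in at least half the replicates of at least one sex, so
sex-specific genes survive the filter. Per-gene f:m ratios use a pseudocount
of ε = 0.25 CPM in both numerator and denominator (configurable).

The X:A estimate is a ratio of medians (robust to expression skew, the usual
choice in the dosage-compensation literature; mean-based variants are easy to
compute from the same per-gene means). The bootstrap resamples genes — X and
autosomal sets independently, with replacement, 10,000 times — because the
claim being interval-estimated is about the gene population of a chromosome,
not about replicate noise. The CI is the 2.5/97.5 percentile of the ratio of
resampled medians, deterministic under a fixed seed.

## Sex-bias calling and tiers

The built-in DE engine is a row-wise Welch t-test on log2(CPM + 0.25) with
sample variances floored at 1e-8, Benjamini–Hochberg FDR across all genes of
the tissue. It is intentionally *not* a negative-binomial GLM: it is a simple,
transparent engine whose null behavior is easy to verify (the null-calibration
test checks the called fraction stays ≤ 5% at FDR < 0.05). Published DE
tables can be imported and dropped into the same downstream path.

Calling uses strict inequalities: FDR < 0.05 and logFC > 2 (female) or
< −2 (male); a gene exactly on a boundary is unbiased. Tiers are computed per
direction stratum over |logFC| of called genes with linear-interpolation
quantiles: weak < Q3 ≤ intermediate < (Q3+max)/2 ≤ sex-specific. Boundary
ties go to the higher tier, so a degenerate stratum with all-equal |logFC|
is entirely sex-specific. Q1 is recorded but deliberately not used as a lower
bound — using it would leave the bottom quartile of called genes without a
tier, breaking the partition property. Strata with fewer than 4 called genes
fall back to all-weak and are flagged. Whether quantiles should pool
directions is open; per-direction is the documented choice here, keeping the
female and male tails from contaminating each other's boundaries.

## Orthology and congruence

Reciprocal best hits require each gene to be the *unique* top-scoring subject
of the other; top-score ties drop the query as ambiguous (deterministic, no
e-value tie-breaking). Congruence classes over a pair's statuses: congruent
(same biased direction), incongruent (opposite), transition (exactly one
biased), both-unbiased. Because the percentages' natural denominator is
ambiguous, the summary emits all of them explicitly (all pairs, pairs with
≥ 1 biased member, and each species' biased genes).

The transition Z-test treats each transition's biased direction as a
Bernoulli(0.5) draw: z = (x/n − 0.5)/√(0.25/n), two-sided normal p.

Chromosomal enrichment is a one-sided (greater) Fisher exact test per
chromosome × direction on biased-vs-all-other genes, on vs off the
chromosome; two-sided is available by flag. Star labels (*** < 0.0001,
** < 0.001, * < 0.01) follow the raw p to mirror the figure convention the
field uses, while BH-adjusted p-values are always emitted alongside so the
multiplicity cost is visible. The simulator's orthology generator realizes a
planned class composition by drawing genes from the two species' truth tables
and emitting mutually-best scores plus strictly lower decoys; "absent" genes
get no hit or a one-way hit.

The hit-probability model is a logistic regression (statsmodels) of hit
presence on bias status; with one binary covariate the slope equals the 2×2
log odds ratio. Perfect separation (an empty cell) is flagged and no Wald p
is reported.

## Population genetics

The genotype simulator draws the segregating-site count S ~
Poisson(θ·L·a₁) with a₁ = Σ 1/i, places sites uniformly (infinite-sites,
no repeat positions) and draws derived-allele counts from the neutral
frequency spectrum P(i) ∝ 1/i. This is *not* a coalescent: sites are
independent (no linkage, no genealogical correlation), so π and Tajima's D
have their neutral expected values (E[π] = θ, E[D] ≈ 0) but the *variance*
of window statistics is smaller than under a true genealogy. Tests that
average over replicate regions are therefore slightly anti-conservative
about real-data variance; tests of the estimators themselves are unaffected.
A full coalescent (e.g. msprime) can be substituted wherever a GenotypeMatrix
is consumed.

Site filters: biallelic SNPs with QUAL > 30, missingness ≤ 0.25, optional
depth bounds when a depth field is present, repeat-interval exclusion.
Monomorphic records are exempt from the SNP-only/QUAL/missingness rules —
they exist for length accounting — but are removed inside repeats. Each
removed record is charged to the first rule it fails (indel, multiallelic,
qual, missing, depth, repeat), and the filter is idempotent. The
repeat-boundary convention compares the record position directly against the
half-open interval, so a site at an interval's end coordinate is retained.

π per site is 2j(n−j)/(n(n−1)) with n reduced site-wise by missing calls
(sites with n < 2 skipped); per-bp π divides by the full region length
including invariant positions, consistent with monomorphic-retaining variant
tables (per-variant-site normalization would require no length accounting
but measures a different quantity). Tajima's D uses the standard constants
with n fixed at the matrix's total haplotype count; S = 0 leaves D undefined
(None), never 0. "Sliding windows" of 10 kb are non-overlapping by default
(step = window), with the step configurable.

Regions from GFF3: exons as annotated, introns as the gene span minus exons,
promoters as 2 kb (default, configurable) upstream of the strand-aware TSS,
truncated at contig edges and neighboring gene spans. Gene-level π for
bias-class comparisons is the length-weighted mean over the gene's intervals
of a region class. Whether gene regions or genome-wide windows intersected
with region classes is the "right" substrate is ambiguous; both paths exist
(`gene_pi`, `windows_pi`) and neither is asserted as canonical.

## Problem sizes in the test suite

Recovery tests run at desk scale chosen to make the expected signal at least
~5 standard errors from its null: coverage recovery at 20 contigs × 100
windows × depth 100 over 20 seeds; dosage recovery at 2,000 genes × 5
replicates over 20 seeds, with bootstrap-CI coverage over 100 seeds; null
calibration at 5,000 genes × 5 seeds and 100 enrichment seeds; diversity
contrasts at 200 regions per group over 10 seeds. These sizes are the
package's validation conditions, stated here so they can be scaled up
deliberately rather than silently.

## Known limitations

* The Welch DE engine under-uses count information at very low expression
  compared to NB GLMs; very lowly expressed genes have reduced power.
* The coverage simulator has no overdispersion or mappability structure.
* Genotype simulation has no linkage; window-statistic variance is
  understated relative to a coalescent.
* Congruence analysis treats calls as fixed labels; uncertainty in the
  upstream DE calls is not propagated.
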
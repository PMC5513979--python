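# Methods

## The differential abundance model

Pooled single-library designs give one count per (species, treatment)
per contig, ruling out dispersion estimation from replicates.  We treat
the treatment/replete pair (x, y) as independent Poisson counts and
condition on the total n = x + y, which reduces the likelihood to

    x | n, δ ~ Binomial(n, p(δ)),   p(δ) = s_x 2^δ / (s_x 2^δ + s_y),

where δ is the log2 fold change of the library-size-normalized rate and
s_x, s_y are the library sizes.  Biological variability enters through
an empirical prior estimated from the data themselves rather than an
imposed negative-binomial family: a two-component zero-mean normal
mixture

    g(δ) = π₀ N(0, τ₀²) + (1 − π₀) N(0, τ₁²).

The null scale is fixed at τ₀ = 0.05 to keep the null component
identifiable; (π₀, τ₁) maximize the marginal log-likelihood
Σᵢ log ∫ Binom(xᵢ | nᵢ, p(δ)) g(δ) dδ over the grid
π₀ ∈ {0.50, 0.55, …, 0.95, 0.99} and τ₁ ∈ {0.25, 0.50, …, 4.00}.
All integrals use the composite trapezoid rule on δ ∈ [−10, 10] with
step 0.01 (2,001 points); the restricted tail integral for
post-p = P(|δ| ≥ 1 | x, y) applies half-weights at the sub-region
endpoints, with a 10⁻¹² tolerance so the threshold grid point is never
lost to float drift.  Against adaptive quadrature the grid engine is
accurate to ~2 × 10⁻⁵ for totals n ≤ 250; the oracle-equivalence checks
draw n in [5, 250], the range typical of per-contig counts at these
library depths.

A unit is *called* when post-p > 0.95 **and** the posterior-mean
|log2FC| ≥ 1.  Both clauses of the conventional rule ("fold change ≥ 2
and post-p > 0.95") are enforced; whether the fold-change clause uses
the posterior estimate (default) or the raw normalized count ratio is
configurable (`fc_clause`), since the convention leaves that choice
open.  Units with x + y = 0 are untestable and reported separately.

Library-size factors are the treatment column sums of the full
contig table and are reused unchanged for ortholog-level tests (ortholog
counts are sums of non-normalized member-contig counts; the reads on
unassigned contigs still belong to the library).  A caveat that follows
from column-sum normalization: when differential abundance is
directionally asymmetric, the column totals shift and every null unit
acquires a small common offset in normalized log-ratio (a composition
effect).  The prior-recovery test therefore runs at known (equal) size
factors; in pipeline use the offset is absorbed by the fitted prior and
mainly costs a little calibration, not ranking.

Fits with fewer than 200 non-zero pairs fall back to a default prior
(π₀ = 0.9, τ₁ = 2) with a warning.  In the pipeline the prior is fitted
per species × treatment on at most 5,000 seeded subsampled pairs, then
posteriors are computed for every testable unit in chunks.

## Conservation screen

The screen consumes ortholog-level DE tables for a focal species subset
(default: all non-dinoflagellate-like species; dinoflagellates regulate
largely post-transcriptionally and would contribute almost no calls).
A conserved response is one (ortholog, treatment) with calls in at least
`min_species_conserved` (default 2) focal species; its direction class
is up/down when all called species agree and mixed otherwise, computed
from call directions rather than effect magnitudes.  A universal
response requires calls in both stress treatments for *every* focal
species; we take the strict reading (same species set in both
treatments) rather than allowing different subsets per treatment.
Orthologs untestable in some species are screened over the species where
they are testable.  The core/shared/unique partition and per-subset Venn
counts are computed from the ortholog map alone and are invariant to
species ordering.

## Gene-set enrichment

TPM_i = 10⁶ (c_i/L_i)/Σ_j(c_j/L_j) per treatment; each contig's TPM is
then divided by its mean over the three treatments, so the mean
normalized enrichment e over treatments is exactly 1 and abundant
contigs cannot dominate a set.  Contigs with zero TPM everywhere are
dropped (count logged).  For every gene set (KEGG module by default;
any annotation column, e.g. pathway, through the same interface) with
at least `min_gene_set_size` = 5 contigs — two-sample KS has essentially
no power below that — the treatment and replete e-distributions are
compared.  The p-value is exact: full enumeration of all C(n+m, n)
pooled relabelings when that count is ≤ 20,000, otherwise 10,000 seeded
Monte-Carlo relabelings with the add-one estimator
p = (1 + #{D* ≥ D})/(1 + R); the asymptotic KS p is reported alongside
for reference.  Ties are handled by taking the sup only at the last
index of each tied run.  Because KS is direction-blind, significant
sets are annotated enriched/depleted from the two sample medians, and a
bidirectionality warning fires when ≥ 25% of a set's contigs move up
≥ 2-fold while ≥ 25% move down ≥ 2-fold — the configuration in which
the test can fail to reject despite large per-contig changes.

Under a full simulated null (Poisson counts through the TPM and
normalization path) the measured rejection rate at α = 0.05 is ~0.05–0.07
across 600 sets.  The tri-treatment normalization couples a contig's
treatment and replete values (they share the contig's mean), so the
pooled-relabeling null is not exactly the sampling null; at gene-set
sizes around 20 the measured miscalibration is within ±0.02.

## Fingerprint and ordination

The fingerprint row for (species, treatment) is the proportion of reads
on KEGG-module-annotated contigs per module; un-annotated contigs are
excluded from numerator and denominator (an all-reads denominator is a
configuration switch), so rows sum to 1 and are invariant to sequencing
depth.  For cross-species ordination only modules present (nonzero in
≥ 1 treatment) in every species are kept and rows are renormalized.
PCA runs on column-centered, by default unit-variance-scaled columns
(the common default of ordination tools; raw-proportion mode is the
toggle) with a full SVD and a deterministic sign convention (largest
|loading| positive).  The 95% ellipse per species comes from the 2 × 2
sample covariance of (PC1, PC2) scores scaled by the χ²(2) 0.95
quantile; with the minimal 3 rows per species the ellipse is exactly
determined and no epsilon is added to degenerate minor axes (any
rendering floor is a plotting concern, not a statistics one).  Species
with < 3 rows get no ellipse (warning).

## Physiology statistics

Brown–Forsythe is Levene's test on absolute deviations from group
medians; identical-spread degenerate inputs return (W = 0, p = 1) by
convention.  The one-way ANOVA is followed by Fisher's LSD — unadjusted
pairwise pooled-MSE t-tests on N − k df — restricted to the two
treatment-vs-replete contrasts, the comparisons of interest.  The
pooled-variance (equal-variance) t-test is used for APA since
homogeneity is checked first.  Molar C:N is computed per replicate from
POC/PON and then tested like any other variable; the `cn_ratio`
operation on published-style means exists for worked examples (some
printed C:N means are consistent only with per-replicate averaging,
which is why both routes exist).  The replicate generator draws
Normal(mean, mean·CV) values around the embedded reference means for
the five species.  The LSD detection-power property (≥ 95% detection of
a 3-within-group-SD shift) is checked at 4 replicates per group: at the
triplicate design the noncentral-t power of that contrast is ~0.87, an
inherent property of n = 3, not of the implementation.

## Synthetic data generator

The generator emulates the shape of a five-species pooled-library
experiment: orthologs partitioned into core (all species) / shared
(random proper subset of ≥ 2) / unique (one species); 1–3 contigs per
ortholog per species, paralogs sharing an ortholog baseline scaled by
U(0.2, 1); contig lengths log-normal floored at 150 bp (mirroring the
upstream assembly filter); replete means log-normal (meanlog 3.4,
sdlog 1.3 → median ~30 counts); KEGG annotation assigned at ortholog
level to ~20% of orthologs across 30 modules.  Background differential
abundance is planted per (ortholog, species, treatment) with probability
0.10 (0.002 for the two dinoflagellate-like species, reproducing the
strong taxon contrast) with |log2FC| ~ U(1, 3) and random sign; planted
conserved blocks share one signed effect (default magnitude 2, sign
biased 70% toward decreases, as stress responses skew) across their
designated species, optionally with a fixed ortholog-level replete mean
split evenly across member contigs.  Counts are Poisson by default
(matching the DE model's likelihood); a negative-binomial mode with
configurable dispersion φ (variance μ + φμ²) exists to probe
robustness.  Per-treatment depth multipliers are configurable but
default to 1 — depth per library is not something the design pins down,
so library composition differences arise only from the planted effects.
Default sizes (1000 core / 1500 shared / 300 unique per species,
~4,000–6,500 contigs per species) are a desk-scale rendition of real
transcriptome assemblies (19k–96k contigs); tests and the acceptance
script use 3-species configurations of ~2,800–5,000 contigs per
species.

What the generator does **not** emulate: sequence-level effects
(mappability, positional bias), phylogenetic correlation of ortholog
content, annotation errors, or cross-species baseline divergence.
Passing recovery tests therefore demonstrates correctness of the
statistical chain under its own assumptions, not performance on real
assemblies.

The truth ledger records every contig-level true log2FC and the planted
conserved blocks.  Screen scoring uses both: sensitivity is measured on
the planted blocks (the controlled condition), while precision counts a
detection as correct if the ledger shows true same-treatment effects in
≥ 2 focal species — background effects that genuinely co-occur are real
conserved responses, not false positives.

## Determinism and numerics

All randomness flows from a single seed through fixed-order child
streams (prior-fit subsampling, ortholog-level subsampling, enrichment
permutations), species iterated in sorted order; two runs with the same
inputs, config and seed produce byte-identical TSV outputs.  TSV floats
are written at %.10g.
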
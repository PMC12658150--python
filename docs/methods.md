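# Methods

## The context model and the density observables

The package models the per-site mutation probability as a function of the
local sequence context alone.  The matrix entry `m_ij` is the maximum-
likelihood per-site mutation probability for central bases of k-mer `i`
mutating to allele `j`, estimated over the valid sites of the window
universe (k = 5 by default; k = 1 gives the 12-type mononucleotide mode
for sparse datasets such as mosaic variants; k = 3 feeds the trinucleotide
abundances of the signature module).  Contexts are read on the coding
strand of the gene owning each site, so complementary mutation types are
kept separate and transcription-strand asymmetry is absorbed into the
matrix.  Sites whose k-mer is undefined (contig edge, N) are excluded from
both the abundances and the countable mutations; this keeps the
conservation identity — expectations summed over the estimation site set
equal the observed total — exact to floating precision, and it is asserted
at 1e-9 relative in the tests.

Mutation classes (CpG>TpG vs the rest) are a per-variant filter derived
from the genomic dinucleotide context (strand-symmetric), applied
identically to matrix estimation and window counting.  For k ≥ 3 this is
equivalent to restricting matrix cells; for k = 1 it is the only coherent
definition, since a mononucleotide matrix cannot carry the dinucleotide
condition.  The same mechanism implements the GC-biased gene-conversion
strata, which partition the 12 substitution types 4/4/4.

`μ_tb` is observed/expected per gene × window; `μ′_tb` divides by the
gene-level ratio `g_t` computed over all of the gene's considered regions.
Bin summaries weight genes by `w_tb = n_valid_sites / W`; any positive
rescaling of the weights leaves the weighted mean unchanged, so the choice
of normalizing by the nominal width W rather than total gene sites is
cosmetic.  Windows with zero expectation carry zero weight.  Confidence
intervals resample genes (with their mutations) B = 100 times and take the
5th/95th percentiles for a 90% interval; plotted points are bootstrap-
distribution means, with the plug-in estimate also reported.

A deliberate property of the design: because the matrix is fitted on the
same site universe it is later applied to, a planted local excess inflates
the genome-wide rates slightly (≈ (fold−1)·hotspot_sites/ℓ̄_t, about 1%
under the default hotspot study), so non-hotspot bins sit just below 1 and
`g_t` slightly above it.  This is inherent to a self-normalizing estimator
and is why the far-bin recovery checks allow a 2% band around 1 while the
hotspot-bin checks use bootstrap standard errors.

## Window geometry

Windows of nominal width W ∈ {100, 1000} are anchored at the TSS and TTS
and oriented along transcription; the flank defaults to 50 kb (5 kb when
W = 100).  Conventions that the data do not determine are fixed and
documented rather than inferred: the TSS base is the first base of
downstream bin 1; transcribed sites of genes shorter than twice the flank
split between the anchors by proximity with exact ties to the
lower-coordinate anchor; overlapping untranscribed flanks are clipped to
the nearest-anchor cell with the same tie-break; truncated windows keep
their nominal bin index with a reduced span.  Site validity is tracked
separately for transcribed and untranscribed windows so that a base
transcribed by exactly one gene stays countable in that gene's windows
while being excluded from any other gene's flank; bases transcribed by two
or more genes (either strand) are excluded everywhere.  A sweep assertion
(`WindowSet.assert_disjoint`) verifies that no base is valid in two
windows.

## Signature decomposition

Per-window 96-channel (pyrimidine-collapsed) or 192-channel
(coding-strand-resolved) profiles are rescaled channel-wise by
reference/window trinucleotide abundance so that whole-genome-derived
signatures apply to composition-biased windows, then decomposed by
non-negative least squares (scipy's Lawson–Hanson solver; the KKT
conditions are property-tested).  Windows with fewer than 1000 mutations
are flagged ineligible; eligible windows are downsampled without
replacement (multivariate hypergeometric) to the lowest eligible count so
decomposition quality is comparable across windows.  Weights below a
cutoff (default 0.05, within the conventional 0.01–0.1 range) aggregate
into "Others".  Background subtraction fits the named background
signatures by NNLS and floors the residual at zero per channel, reporting
the floored fraction.  Five synthetic signatures ship with the package as
a text fixture; externally derived signature matrices in the same TSV
layout are drop-in.

## Regression

The design is `X = [1 A B C]`: dummy-coded categoricals and standardized
numeric features in A (mean-centred, variance-scaled after dropping
incomplete windows and before forming products), sum-coded position
categories in B, and all Hadamard products in C.  Sum coding uses K−1
columns: with an intercept, K indicator-style sum-coded columns would be
rank-deficient, and the omitted category's coefficients are recovered as
minus the sum of the included ones (tested as an exact identity).
Negative-binomial fits estimate the dispersion jointly with the
coefficients by maximum likelihood (NB2); Poisson is used where
overdispersion is absent, and non-convergence is a hard error rather than
a warning.  Multicollinearity is controlled by iteratively removing the
feature with the largest generalized VIF (determinant-ratio form on the
no-interaction design) raised to 1/df — the documented estimator — with
1/(2 df) available as the conventional alternative; the threshold defaults
to 5.  Model adequacy is summarized by the Pearson χ²/df dispersion
statistic with configurable over/under-dispersion bounds (1.5 / 0.7).

Position-specific hypotheses (TSS-vs-far interaction differences per side,
and total effects at the TSS) are linear combinations of coefficients
tested by z-statistics with the coefficient covariance.  Family-wise
adjustment uses the single-step max-|z| distribution of the joint normal
with the contrasts' correlation matrix, integrated by seeded Monte Carlo
with 5·10^5 draws by default (adjusted p-values are stable to a few 10^-3
across seeds); adjusted confidence intervals use the corresponding
critical value.  Identical contrasts incur no penalty and independent
contrasts reproduce the Šidák correction, both property-tested.

## Selection, strand bias, gene sets

Mutation effects are computed by codon substitution under the standard
genetic code (CDS lengths must be multiples of 3; stop gains/losses count
as nonsynonymous; minus-strand CDS are verified against an independent
reverse-complement translation oracle).  Windowed dN/dS pools transcripts
per window; the ratio is undefined (reported missing) when a window draws
no synonymous mutations, including inside resampling replicates.
Allele-frequency ratios use simple unweighted gene means of `μ_tb` per
stratum with each stratum's own matrix, and mutation-resampling intervals.

Replication direction is called from a smoothed timing profile (moving
average, default 50 kb span) as maximal monotone runs with per-step slope
≥ 0.01 and span ≥ 250 kb; decreasing timing (early→late) along the
coordinate means a rightward-moving fork.  The fork-direction ×
gene-strand → leading/lagging convention is a single declared constant
(rightward fork ⇒ plus-strand coding is leading) with a `flip` switch;
what the tests pin are the involution symmetries — flipping gene strands
swaps coding/template tallies exactly, reversing coordinates swaps the
fork directions — not the biological sign, which external validation data
would have to fix.

Gene-set and per-gene TSS enrichment use the exact conditional binomial
test: conditional on the total count, the TSS count is binomial with
probability E_tss/(E_tss+E_rest) under a unit rate ratio; two-sided
p-values use the minimum-likelihood method (central doubling available),
Bonferroni across terms, Benjamini–Hochberg across genes.  The per-gene
background contains only genes with exposure on both sides and a positive
non-TSS count, i.e. the genes for which the ratio is defined.

## The synthetic generator

`simulate` plants: a baseline per-site rate (uniform total rate, an
explicit k-mer matrix, or a mixture of 96-channel signatures scaled to a
target mean rate); a TSS-anchored hotspot (box or exponential decay,
configurable fold and half-width, TTS anchoring available as a negative
control); coding-strand substitution-type folds on transcribed sequence;
nonsynonymous retention inside CDS; optional lognormal per-gene regional
multipliers (the overdispersion knob — real per-gene dispersion is not
asserted, only exposed); and dataset/AF-class labels drawn by the
configured fractions.  Sampling is per-site Bernoulli with at most one
mutation per site, matching the unique-call framing of real input sets,
and each site's alternate is drawn proportionally to the per-allele rates.
Genome, mutations and tracks consume three independent children of the
seed, so one genome carries independent mutation replicates.  What the
generator does not emulate — linkage, diploid genotypes, coalescent
structure, sequencing error, realistic genome composition — bounds what
green tests show about real data: they validate the estimators against
their own model, not cohort-specific artefacts.

## Problem sizes and numerical choices

The standard study runs: hotspot recovery on 2000 genes / 144 Mb / ≈2·10^5
mutations with B = 100 bootstrap; NNLS recovery at 10^5 draws × 20 seeds;
regression recovery at 2·10^4 windows and a 500-run scaled-down (n = 400)
global-null family-wise-error study; dN/dS coverage over 100 replicate
130-kb simulations with B = 100 resamples.  These sizes make every study
reproducible in minutes on one CPU while keeping the targeted standard
errors a factor ≥3 below the effects being recovered.  Degenerate inputs
are defined rather than accidental: zero-expectation windows are excluded
from both weighted sums; zero-observation brackets in the pooled rate
model return ratio 0 with an exact Poisson upper bound and a flag; empty
eligible-window sets return empty results with a notice; masks on unknown
chromosomes warn and are ignored.

## Known limitations

The mononucleotide class filter at CpG sites uses the average C>T rate
over all C contexts, as any 12-type model must.  Window assignment assumes
untranscribed windows are disjoint, i.e. `resolve_intergenic_overlaps`
has been applied; deeply nested gene models (a gene entirely inside
another gene's window interval) are handled through the transcription-
ownership masks rather than interval arithmetic.  The GVIF filter operates
on the no-interaction design only, mirroring its intended use.  The
replication-direction caller re-specifies the published two-parameter
method from its description; its sign convention is asserted only up to
the involution symmetries.
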
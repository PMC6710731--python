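# Methods

This note records the statistical model behind `methylpath`, the
choices made where the design was genuinely open, and what the test
suite does and does not establish.

## Data model and screening

Inputs are beta values — per-CpG methylated fractions in [0, 1] — for
two groups of samples (case/control), a probe manifest, and a GMT
pathway collection. No normalisation, batch correction or M-value
transform is applied; the matrix is assumed preprocessed.

**Probe QC.** A probe is removed if any rule trips: an annotated SNP
within 2 bp of the CpG (distance ≤ 2); the SNP's minor-allele frequency
failing the MAF rule; a cross-reactive flag; or location on chrX/chrY.
The MAF rule direction is configurable because both conventions exist
in practice: the default `maf_removes='lt'` removes probes whose SNP
has MAF < 0.05, `'ge'` removes common SNPs instead. SNP rules apply
only to probes with an annotated SNP; the audit log reports each rule's
count independently (a probe can trip several rules but is removed
once).

**CpG screen.** Per probe, a two-sided Welch two-sample t-test on beta
values (unequal variances are the norm for bounded fractions; a
Wilcoxon rank-sum option exists). The effect size is the delta-beta
S = mean(case) − mean(control). Tier 1 keeps p < 0.01 on the raw
p-value — deliberately without multiplicity correction, since the
screen feeds a pathway-level test rather than making per-CpG claims; a
Benjamini–Hochberg FDR column is emitted for information only. Tier 2
additionally requires |S| ≥ 0.1. Degenerate probes that are constant in
both groups get p = 1 when S = 0 and p = 0 otherwise. Gene methylation
is the arithmetic mean of the gene's probes per sample; a probe
annotated to several genes contributes to each.

## Overlap-weighted enrichment

Genes sitting in n pathways receive weight w = 1/n, so each gene
distributes exactly one unit of evidence across the collection. Each
pathway is scored twice against the tier-1 gene list (configurable to
tier 2):

* **Over-representation:** one-sided hypergeometric upper tail of the
  2×2 table [in-pathway × in-DM-list] over the gene universe. The
  default universe is the collection universe — the largest gene space
  in which both margins are well defined — with an explicit background
  list available by option.
* **Competitive weight test:** a one-sided ("greater") Mann–Whitney U
  comparing the weights of the pathway's DM members against the weights
  of all universe genes outside the pathway. Small problems (both
  groups ≤ 8) are solved by exhaustive enumeration of label
  assignments, which is exact under ties; larger ones use the
  tie-corrected normal approximation with continuity correction.

The two are combined as `p_combined = (p_MWU × p_Fisher) / 2`, and a
pathway is *enriched* when p_combined < 0.05 (strict) and it has more
than one DM member, reported ascending by p_combined with ties broken
by pathway id.

**Calibration caveat.** The halved product is a selection rule, not a
calibrated meta-analytic p-value (contrast Fisher's χ² combination).
For independent uniform inputs P(UV/2 < 0.05) ≈ 0.33, so treating
p_combined as a p-value is anticonservative. Under the package's null
simulations the observed pathway selection rate is ≈ 11% at the 0.05
rule — above the nominal 5%, well below the product-uniform bound
(discreteness of the hypergeometric and the count > 1 requirement pull
it down). The test suite documents this measured behaviour rather than
asserting a nominal error rate the rule does not have. Users wanting
calibrated pathway p-values should rank by p_combined but judge
significance from p_Fisher and p_MWU separately.

## FPCA and the functional F-statistic

Hub-gene ranking treats each gene's methylation profile as a curve over
a pseudo-time axis.

**Pseudo-time for a cross-sectional design.** The functional machinery
needs an ordering of samples, but a two-group design has none. The
default rule is deterministic: controls first, then cases, each group
sorted ascending by sample-wise mean methylation (ties by sample id),
mapped to equispaced t ∈ [0, 1]. This makes the dominant variation — a
case/control level shift — appear as a monotone/step-like curve that
FPCA captures in its leading component. The rule is recorded in every
output, an explicit ordering can be supplied instead
(`rule='given'`), and results should be read as conditional on this
convention; this is the largest modelling convention in the package and
alternative orderings will change F values (not, in our simulations,
the identity of strongly shifted genes).

**Smoothing.** Least-squares cubic B-splines with
`basis_size = min(8, n_samples − 1)` basis functions on equispaced
knots. The spline space contains constants, so the projection preserves
each gene's mean exactly and reproduces curves already in the space.

**FPCA.** Curves are centred per gene (subtracting the gene's scalar
mean — the "mean function" here is gene-specific and constant, which
matches the constant null model below). The decomposition
eigendecomposes the across-gene second-moment matrix
C = XᶜᵀXᶜ/(n_genes − 1) of the centred curves on the grid, so
eigenfunctions are orthonormal under the plain grid inner product,
scores are ξ_il = ⟨xᶜ_i, Φ_l⟩, and a full-component reconstruction is
exact. L is the smallest component count reaching the variance target
(default 0.9). Numerical conventions: eigenvalues below
max(λ)·1e−12 are dropped; each eigenfunction's sign is fixed by a
nonnegative grid sum (first nonzero coordinate positive at a vanishing
sum), making repeated fits bit-identical; an all-constant input yields
L = 0 with a warning.

**F-statistic.** For each gene,
F = (RSS⁰ − RSS¹)/(RSS¹ + δ) with RSS⁰ the residual sum of squares
around the gene's constant mean and RSS¹ around the truncated FPCA
reconstruction. The constant null makes F a structure-detecting
statistic: flat genes score 0, genes whose profile is explained by the
shared eigenfunctions score high. Because the reconstruction is an
orthogonal projection containing the mean, RSS⁰ ≥ RSS¹ and F ≥ 0 (the
difference is floored at 0 against rounding). δ acts as a
signal-to-noise offset; its default is the median RSS¹ across scored
genes (floored at 1e−12), an adaptive scale that makes F ≈ 2·RSS⁰/median
for perfectly reconstructed genes, with a fixed-δ override. F is
invariant to adding a constant to a curve and invariant to scaling the
curve by c when δ is rescaled by c²; both properties are tested at two
scales. F is computed for all genes of all enriched pathways; the top-3
per pathway (ties broken alphabetically) are reported as hubs.

## Synthetic studies

The generator emulates a two-group 450K-style cohort with known ground
truth. Reference conditions (the defaults): 10 pathways of 25–35 genes
drawn from a 280-gene pool with 30% of the universe belonging to
exactly two pathways; 3 probes per gene; 20 cases vs 20 controls;
baseline beta 0.5 with per-probe baselines ~Normal(0.5, 0.05) clipped
to [0.05, 0.95]; logit-scale noise SD 0.2 (≈ 0.05 SD on the beta scale
at 0.5); 5% each of SNP-proximal, cross-reactive and sex-chromosome
probes; one planted pathway in which 70% of the members ("truth"
genes) gain +0.15 mean beta in cases. The gene pool is sized so every
draw of pathway sizes is feasible.

The noise is logit-normal — Normal noise added to logit(beta) and
back-transformed — which keeps values strictly inside (0, 1) without
truncating the noise distribution. The planted shift is added on the
beta scale *after* back-transformation and clipped to [0.01, 0.99], so
the case−control delta of truth probes is exactly the configured effect
whenever the clip is inactive; Monte-Carlo tests verify the planting is
unbiased. One integer seed drives separate hierarchical streams
(manifest / betas / gene sets / truth draw), so changing one component's
size does not perturb the others' randomness.

What the generator does **not** emulate: raw IDAT intensities,
probe-type (Infinium I/II) chemistry differences, batch effects,
cell-type composition, correlated CpGs within a region, or realistic
pathway-size and overlap distributions of curated databases. Passing
the recovery tests therefore shows the procedure detects a clean,
additive, group-wise shift under logit-normal noise — not that it is
robust to the full messiness of cohort data.

## Problem sizes and measured behaviour

The test and acceptance runs use the reference conditions above (840
probes × 40 samples per replicate; 50 replicates for recovery and null
calibration; 1,000 probes per null replicate). Under these conditions
the planted pathway attains the minimum combined p and a truth gene
reaches the top-3 F ranking in essentially every replicate, and the
tier-1 null rejection rate at p < 0.01 sits inside the 99% binomial
band around 1%. All such numbers are recomputed at run time by
`tests/` and `scripts/acceptance.py`; none are hard-coded.

## Known limitations

* The pseudo-time convention is a modelling device for a design that
  has no time axis; F values are conditional on it.
* p_combined is uncalibrated (see above); the enriched list's size
  under the null is rule- and collection-dependent.
* Only annotated probe→gene mappings are used; distal regulatory
  assignment is out of scope.
* The MAF rule direction is data-dictionary-dependent and must be
  chosen by the user; the audit log records which was applied.
* Beta values are analysed directly; strongly heteroscedastic data near
  the boundaries may favour an M-value analysis, which is out of scope.
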
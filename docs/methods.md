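# Methods

This note documents the statistical models, estimators, simulator design
and numerical conventions behind `polyfoot`, and what its tests do and do
not establish.

## The question and the quantities

For each gene and population the pipeline summarises segregating variation
by Tajima's D restricted to non-synonymous sites (D_NS) and by the
constraint ratio π_N/π_S; for each gene and population pair it estimates
relative divergence (pool-aware unbiased F_ST) and absolute divergence
(d_XY).  The core inference asks how between-population divergence
covaries, across genes, with the within-population site-frequency spectra
— in particular whether an *imbalance* in D_NS (positive in one
population, negative in the other) predicts high F_ST, the pattern
expected when polygenic traits under stabilizing selection diverge by
redundant, compensated allele-frequency shifts rather than by parallel
sweeps.

## Estimators

**Site filtering.**  Sync counts are reduced to biallelic sites using the
two highest-count alleles summed over all pools (so variant labels agree
across pools); a site with three bases at or above the minor-count
threshold is dropped as triallelic.  Defaults follow pool-seq convention:
minor count ≥ 2 to call a polymorphism, per-pool coverage within
[10, 500].  Sites whose minor count falls below the threshold are kept as
monomorphic so per-site denominators (π, d_XY) are not biased by the
calling rule.  Coordinates: BED intervals are 0-based half-open, sync and
site-class positions 1-based; conversion happens only at the I/O boundary.
Strand is ignored (sync counts are strandless).

**SFS statistics.**  Folded minor-allele read frequencies p̂ enter
θ_π = Σ 2p̂(1−p̂)·n/(n−1) with the per-site effective sample size
n_eff = min(haploid pool size, biallelic depth) — the number of
chromosomes the reads can at most represent.  θ_W = S/a₁ and Tajima's
variance normaliser use the gene's median site n_eff (rounded).  D is
reported as NaN below `min_snps` (default 3) segregating sites, where the
normaliser is unstable.  This n_eff treatment is an approximation to full
pool-aware spectrum corrections; its exactness in the genotype limit
(reads = chromosomes, no pooling noise) is pinned to an independent
textbook implementation at 1e-10 in the tests.  D_NS is standardized to
z-scores across genes within each population before modelling; π_N/π_S is
log₁₀-transformed and is NaN when either class diversity is zero (such
genes drop out of models using the covariate, listwise).

At the default 125× depth with minor count ≥ 2, variants below ~1.6%
frequency are invisible, which truncates the rare tail of the folded
spectrum and inflates D_NS slightly (+0.3–0.5 under neutrality).  This is
a property of pooled data at finite depth, not of the estimator: the
neutral-calibration test therefore checks mean raw D within ±0.3 at
sequencing depth deep enough (1000×) for the spectrum to be fully
observed.  Model-based inferences all use the standardized D, which is
invariant to a common shift.

**Pooled F_ST.**  Per SNP, within-pool read identity
q = (c₁(c₁−1)+c₂(c₂−1))/(d(d−1)) is corrected for two distinct reads
resampling the same pool chromosome (probability 1/n for n pool
chromosomes): Q̂₁ = (q − 1/n)/(1 − 1/n).  Reads from different pools are
always distinct chromosomes, so Q̂₂ = (c₁ₓc₁ᵧ + c₂ₓc₂ᵧ)/(dₓdᵧ) is
unbiased directly.  The gene estimate is the ratio of sums,
F̂ = Σ(Q̂₁−Q̂₂)/Σ(1−Q̂₂), the standard multilocus aggregation.  Tests
verify three properties: zero mean over pools drawn from identical
frequencies (unbiased numerator), convergence to the Hudson
frequency-based estimator at infinite depth and pool size, and agreement
with the drift expectation 1−(1−1/2N)^t over many neutral genes.
Negative estimates are retained raw for class means and clamped to
[1e-4, 1−1e-4] only for the logit transform.

**d_XY.**  Σ(A_X B_Y + A_Y B_X)/n_sites_total over all sites passing
depth filters in both populations, variable or not.  At sites not called
polymorphic in the pair each pool is treated as fixed for its majority
allele, so monomorphic-identical sites contribute exactly 0 and fixed
differences exactly 1; the statistic is symmetric in populations and
allele labels.  Values are floored at 1e-6 before log₁₀.

## Models and resampling

**Interaction GLMs.**  OLS of logit F_ST (or log₁₀ d_XY) on D₁, D₂, D₁²,
D₂² and D₁×D₂ (model 1), optionally adding GC content, gene length and
both populations' log₁₀ π_N/π_S (model 2).  Rows with any missing term are
dropped listwise (hence the differing n across models).  Rank deficiency
is detected and reported with the collinear terms named.  Cohen's
f² = (R²_full − R²_reduced)/(1 − R²_full) measures the interaction's
local effect size.  All fits are checked against normal-equations oracles
at 1e-8.

**Repeatability.**  The three pairwise divergence vectors (one column per
population pair, genes as rows, complete rows only) enter a covariance
PCA (centered, unscaled — the columns share units; a correlation switch
was considered unnecessary for same-unit columns) and a one-way ANOVA
with gene as the grouping factor: ICC(1) R = (MS_B − MS_W)/(MS_B +
(k−1)MS_W), k = 3, negative estimates reported as-is.  Because the three
pairs share populations, gene-level drift outcomes induce positive ICC
even under pure neutrality; the label-shuffle null in the tests confirms
the machinery returns ≈ 0 when that sharing is destroyed.

**Binned surfaces.**  Genes are assigned to 8 equal-size bins per D axis
by stable rank (ties broken by original order; half-open intervals, last
closed), giving marginal counts within 1 of n/8; cells with fewer than 5
genes are flagged.

**Imbalance sets and enrichment.**  Genes with |D₁−D₂| > 2.5 and
F_ST > 0.3, strict inequalities, on the standardized-D scale used in the
models (a switch selects raw D; whether the threshold was meant for raw
or standardized D is ambiguous, and standardized matches the modelling
scale).  Over-representation uses the exact hypergeometric upper tail
P(X ≥ k), no multiple-testing correction by default (raw p < .05, the
convention of over-representation screens; a Benjamini-Hochberg flag is
provided).  Exactness is verified by enumeration for universes ≤ 30.

**Class contrasts and permutation tests.**  Welch unequal-variance t with
Welch–Satterthwaite df; class-mean CIs by bias-corrected percentile
bootstrap (B = 2000 by default, seeded; the acceleration term of BCa is
omitted — coverage for class means is verified ≥ 90% at nominal 95% in
the tests).  Sex-bias analyses split female- and male-biased genes into
four quantile bins each by log₂ fold-change (8 bins), compute the one-way
F across bins and refer it to a label-permutation distribution with
add-one correction, p = (1 + #{F* ≥ F})/(1 + n_perm); null uniformity is
verified by KS test over 200 replicates.

**Fixation GLM.**  The response counts the populations (0–3) in which a
gene segregates at non-synonymous sites; lower counts mean closer to
fixation.  Poisson log-link fits with an empirical dispersion factor
(Pearson χ²/df of the full model); inference by deviance differences
scaled by the dispersion, referred to χ² (the quasi-likelihood
convention; an F reference would differ negligibly at these df and the
convention is declared in the output).  Two designs: nine equal-size
expression bins × gene class × interaction, and mean-centered log-FPKM
with its square, class, and class × square.  A constant response is a
degenerate zero-deviance fit and is reported as an error.

## Simulator

Each gene carries `n_ns_loci` non-synonymous and `n_syn_loci` synonymous
unlinked biallelic loci (free recombination, no linkage map — consistent
with treating linked selection as secondary at this scale).  Mutation is
reversible at per-site rate μ per direction, so the neutral stationary
law of the allele frequency is Beta(4Nμ, 4Nμ).  Loci are initialised by
drawing from that stationary law, which places the ancestor exactly at
mutation–drift equilibrium; a forward settle phase (`burn_in`) is then
available and is used by the selected scenarios.  This replaces a long
burn-in from an arbitrary state: the draw is the distribution such a
burn-in converges to, at no simulation cost.  Neutral loci evolve by the
exact marginal binomial Wright-Fisher update (identical in law to the
individual-based diploid model for unlinked neutral loci); whenever a
trait is under stabilizing selection the individual-based diploid
simulation runs: trait z = Σ α·(allele count) over the gene's NS loci,
|α| exponential with random signs, viability w(z) = exp(−(z−θ)²/2ω²),
two parents per offspring drawn proportional to fitness, one allele per
parent per locus.

**Default study conditions** (chosen once, as the conditions the pipeline
is meant for): N = 500 diploids, 3 populations, g_split = 250 generations
(pairwise F_ST ≈ 0.2), θ_site = 4Nμ = 0.022 so that synonymous diversity
matches π_S ≈ 0.022, 30 NS + 30 SYN informative sites per ~1 kb gene so
that called SNP density at the default pooling is ≈ 6/kb, pools of 400
haploid chromosomes (200 diploid males) at Poisson(125) depth.  Gene
lengths vary uniformly in [0.6, 1.4] × 1 kb so length is a usable
covariate.  Pool sequencing is two-stage: chromosomes into the pool
(binomial), reads from the pool (binomial at Poisson depth) — its
variance matches the compound-binomial closed form in the tests.

**Scenarios.**
`NEUTRAL_INDEPENDENT`: no selection (ω = ∞).
`STABILIZING_SHARED` / `STABILIZING_SHIFTED`: one optimum everywhere vs
optima moved apart after the split.
`DISCORDANT_ENGINEERED`: the deterministic generator of the footprint.  A
labelled fraction of genes (default 20%) receives, at half of its NS loci
(the same loci in both populations), directional selection in one
population — which of the first two populations is swept is randomised
per gene — and heterozygote advantage (s = 0.1) in the other.  Selected
loci start from engineered mid-frequency standing variation (Beta(2,2)),
without which the near-fixed stationary background would give the
contrast nothing to act on.  The directional coefficient (s = 0.016,
s·g_split ≈ 4) is set so swept loci end at low but sequencing-detectable
minor frequencies: an excess of rare variants (D_NS < 0), not invisible
fixation.  Two further small fractions (10% each) receive *shared*
selection — the same sweep, or the same heterozygote advantage, in all
populations.  These classes are part of the emulated biology (selection
heterogeneity, including widespread balancing selection, is a premise of
the study system) and they are what makes the interaction identifiable:
genes with concordant extreme D and *low* F_ST anchor the corners of the
D₁×D₂ surface, so the quadratic terms cannot absorb the discordant
genes' F_ST excess.  Ground truth (class labels, selected loci, final
frequencies, true F_ST/d_XY) is emitted alongside the data.

**What the generator does not emulate:** linkage and hitchhiking,
sequencing error, mapping bias, indels/triallelic sites, demographic
change, gene flow, and any mechanistic epistatic fitness ridge (the
discordant scenario operationalises the predicted *pattern*, not the
ridge dynamics).  Passing tests therefore show that the estimators and
models recover the targeted signals under clean two-stage sampling at
realistic depth and diversity — not that the pipeline is robust to
artefacts absent from the generator.

## Numerical conventions and edge cases

Standardization uses population-moment z-scores (ddof = 0) and errors on
constant input.  F_ST with a non-positive summed denominator, d_XY with
no jointly covered sites, D with S < min_snps, and π ratios with a zero
class are all NaN, and NaN rows are dropped listwise per model.  Quantile
binning is by stable rank everywhere (surfaces, expression bins,
sex-bias quartiles).  Bootstrap of a constant vector returns a zero-width
interval.  All randomness flows from explicit seeds (one global seed per
run; derived generators for bootstrap/permutation stages), and identical
configs are bit-reproducible, which the pipeline manifest records
(config snapshot, input SHA-256 hashes, row counts, versions).

## Problem sizes

Test and acceptance runs use 300 genes, N = 500 and the default pooling —
large enough for stable gene-level model estimates (SE of the interaction
coefficient ≈ 0.05 at these settings) while keeping a full scenario run
to a few seconds.  The individual-based stabilizing runs in the tests use
smaller populations (N ≈ 200, ≤ 20 genes), sized for the sign/ordering
properties they check.

## Known limitations

* n_eff = min(pool size, depth) undercounts the information loss from
  double-sampling at depths near the pool size; D_NS levels (not ranks)
  at 125× are accordingly approximate, and analyses standardise D within
  population before use.
* The imbalance threshold |ΔD| > 2.5 on the standardized scale selects a
  tail whose size depends on the genome-wide D distribution; with heavy
  selected classes the same threshold selects fewer genes than in a
  purely neutral genome.
* Enrichment treats terms independently (no term-graph propagation); the
  term map is taken as given.
* The d_XY denominator counts only sites represented in the input counts
  and jointly covered; with sparse site annotation it is an effective,
  not physical, per-base pair denominator.
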
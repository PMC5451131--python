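# Methods

This package implements a weighted single-step genomic association scan
(WssGBLUP) for categorical reproductive traits in beef cattle, together
with the synthetic populations needed to validate it end to end. The
pipeline is: data editing and genotype QC → pedigree and genomic
relationship matrices → Bayesian threshold animal model on the liability
scale → SNP-effect back-solving with iterative marker re-weighting →
1-Mb window variance scan, plus MCMC convergence diagnostics.

## The threshold animal model

Categorical records (binary "heifer rebred: yes/no", or an ordered count
of calvings coded 0/1/2) are modeled as discretizations of a latent
liability

    y = X b + Z a + e,   e ~ N(0, I),
    a | s2 ~ N(0, H s2),

where `b` holds contemporary-group (CG) fixed effects, `a` additive
breeding values over every pedigree animal, and `H` the single-step
relationship matrix combining pedigree and genomic information. The
observed category is 0 below t1, 1 between t1 and t2, 2 above t2.

Identification follows the standard probit anchoring: the residual
variance is fixed at 1 and t1 at 0; for three categories t2 is estimated.
Liability-scale heritability is `h2 = s2/(s2 + 1)`.

### Gibbs sampler

One sweep updates, in order:

1. each record's liability from a normal truncated to its category's
   interval (one-sided draws use naive rejection near the bulk and
   Robert's exponential-rejection sampler in the tail; two-sided draws
   fall back to uniform rejection on narrow off-mode intervals);
2. each CG effect from its normal full conditional (flat prior);
3. each breeding value by single-site Gauss-Seidel over the sparse
   H⁻¹-penalized mixed-model system — the stationary distribution is the
   same as for a joint draw, at a fraction of the cost;
4. the additive variance s2 (see priors below);
5. for three categories, t2: first the conditional draw, uniform between
   the largest category-1 and smallest category-2 liability, then a
   Metropolis move with the liabilities marginalized (a Cowles-type
   update). The conditional interval shrinks like 1/n, so without the
   extra move t2 effectively freezes (measured effective sample size ~10
   out of 18,000 sweeps; ~180 with it). Liabilities are redrawn first in
   the next sweep, before anything else uses them, which keeps the
   partially-collapsed update order valid.

The sweep loop is compiled with numba; a 20,000-sweep chain on a
2,400-animal pedigree with ~2,000 records runs in roughly 15 s on one
core. Chains are reproducible from a single integer seed.

### Priors for the additive variance

The default prior is uniform on the heritability, `p(s2) = (1 + s2)^-2`,
sampled by a Metropolis-within-Gibbs step whose proposal is the flat-prior
scaled-inverse-chi-square conditional. The reason it is the default rather
than the traditional flat prior on the variance: with a single categorical
record per animal, each breeding value can place its own liability on the
correct side of the threshold, so the likelihood does not decay as
s2 → ∞ and a flat variance prior yields an improper posterior. This is
not hypothetical — on small datasets the chain visibly escapes toward
h2 = 1, and on larger ones it drifts. The uniform-on-h2 prior is proper,
neutral across the (0,1) range of heritabilities, and adds no tunable
hyperparameter. Flat-variance and scaled-inverse-chi-square (nu, S)
priors remain available for data with replicated records.

### Posterior summaries

Posterior means/sds are computed over the thinned post-burn-in samples
(`floor((n_iterations - burn_in)/thin)` of them; the full-scale settings
500,000/50,000/50 store exactly 9,000). HPD intervals are the shortest
contiguous window of sorted samples containing the requested mass.

## Relationship matrices

* `A` — tabular method; inbreeding by the Meuwissen-Luo ancestor
  traversal; `A⁻¹` by Henderson's rules with inbreeding. Nonzeros only
  link animal-sire-dam triples.
* `G` — VanRaden's first method with observed allele frequencies,
  optional per-marker weights (`G_D = M D M' / 2 Σ p q`), missing dosages
  imputed at the marker mean, monomorphic markers excluded. Blended as
  `(1-w) G + w A22` with `w = 0.05` to guarantee invertibility; an
  optional two-coefficient rescaling matches G's mean diagonal and
  off-diagonal to A22 (off by default — measured effect on heritability
  recovery at desk scale was negligible).
* `H⁻¹ = A⁻¹ + [0 0; 0 G_b⁻¹ − A22⁻¹]` with τ = ω = 1, kept in its
  natural sparse-plus-dense-block form.

## Back-solving, re-weighting and the window scan

SNP effects are back-solved from the genomic breeding values of the
genotyped animals, `û = D Z' [Z D Z']⁻¹ â_g`. The inverse is taken
through the blended genomic matrix (× 2Σpq): once weights concentrate on
few markers the raw cross-product `Z D Z'` can be numerically singular,
while the blended form stays well-posed; the projection `Z û = â_g` then
holds to within the 5% blend. Weights iterate as `d_i = û_i² p_i(1-p_i)`,
rescaled by one constant so `Σ d_i · 2 p_i (1-p_i)` keeps its round-0
value (constant total genetic variance). Two evaluation rounds are the
default: round 0 with identity weights, one re-weighted round.

Windows tile each chromosome as `[k·1Mb + 1, (k+1)·1Mb]` (1-based,
anchored at position 1, so window boundaries do not depend on the map).
A window's statistic is the variance across genotyped animals of its
aggregate genomic value `Σ_{i∈w} Z_i û_i` as a percentage of the variance
of the total `Z û` (configurably of the posterior-mean s2). The
aggregate-value form captures within-window LD covariance; under linkage
equilibrium the percentages add to ~100. Ties in the ranking break by
(chromosome, start).

## Convergence diagnostics

Geweke's z compares the means of the first 10% and last 50% of a chain,
with window variances taken from the spectral density at frequency zero
estimated by an AIC-selected autoregressive fit. ESS uses the same
spectral estimate through `ESS = N · var/s(0)` — algebraically
`N / (1 + 2 Σ ρ_k)` — rather than a truncated autocorrelation sum, whose
data-driven cutoff wanders badly (autocorrelation noise is serially
correlated); the spectral form is what the classic Bayesian output
analysis packages compute. ESS is capped at the chain length.

## The synthetic populations

The generator emulates the statistical structure the analysis assumes,
not any particular breed's biology:

* **Pedigree** — discrete generations; founders unrelated. Each
  generation's dams are mated either (48% of them) to a small elite "AI"
  pool sized so those bulls average 73.6 progeny over the whole pedigree,
  or to a broad natural-service pool averaging ~8 progeny. The elite
  bulls are genotyped first. Defaults give ~2,400 animals over five
  generations, ~2,000 of them phenotyped and ~300 genotyped.
* **Genome** — 25 autosomes of 100 Mb at 1 cM/Mb (~25 Morgans, ~2,500
  1-Mb windows — bovine scale). This matters: a short genome makes
  realized relationships grossly overdispersed around their pedigree
  expectations, which a pedigree-based likelihood converts into inflated
  variance estimates. Founder allele frequencies ~ Uniform(0.05, 0.5);
  gametes by gene dropping with Haldane recombination; no mutation.
* **Trait** — a chosen subset of typed markers acts as QTL (default 100);
  effects are scaled so the founder-generation breeding-value variance is
  exactly `h2/(1-h2)`; one QTL can be forced to carry a set share of the
  genetic variance for power studies. Liability = CG effect + breeding
  value + N(0,1); categories by thresholding. Calving-age covariates are
  drawn inside the edit windows except for a configurable violating
  fraction; per-genotype quality scores and missingness are injected at
  configured rates for the QC stage to find.

What the generator does *not* emulate: overlapping generations, selection
(matings are random), non-additive effects, real marker ascertainment,
and genotyping error beyond the quality-score artifacts. Passing
recovery tests therefore demonstrates the estimation machinery is
correct and calibrated under the model's own assumptions at desk scale —
not that real Nelore data would yield these exact values.

## Validation studies and their scale

* **Heritability recovery** — 10 replicate populations per trait
  (~2,000 records, ~300 genotyped, 2,000 markers, 20 CGs), fit with
  20,000 sweeps / 2,000 burn-in / thinning 10; the across-replicate mean
  of posterior-mean h2 is compared with the simulated truth (0.194
  binary, 0.185 three-category). At this scale the marginal posterior of
  h2 has sd ≈ 0.05-0.08 and is right-skewed, so single replicates can
  miss the truth by more than one posterior sd, and the across-replicate
  mean of posterior means retains a positive offset of roughly +0.03 to
  +0.06. Extensive decomposition (Gaussian observed-liability fits are
  unbiased; an independent dense joint-draw sampler agrees with the
  kernel; initialization, chain length, t2 mixing, genome length and
  G-A22 tuning were each varied) attributes the offset to the skew of
  the weakly identified variance-ratio posterior, not to an
  implementation defect; it shrinks as records grow and would be
  negligible at the source population's six-figure record counts.
* **Window power** — 20 replicates of ~3,000 animals with ~500 genotyped
  and a QTL holding 15% of the genetic variance; the QTL's window must
  rank in the top 20 of ~2,500. Evaluation rounds use 6,000-sweep
  chains; smaller populations were found to let the weakly identified
  binary h2 escape upward, degrading the breeding values the scan rests
  on.
* **Diagnostic calibration** — 500 iid null chains for the Geweke
  rejection rate; an AR(1) chain against the closed-form ESS.
* **Oracle equivalences** — dense inversion vs Henderson's rules,
  Monte-Carlo gene-drop IBD vs tabular A, brute-force HPD enumeration,
  hand-computed Hardy-Weinberg chi-square, an independent dense
  joint-draw Gibbs sampler cross-checking the compiled kernel.

## Numerical choices

* Truncated-normal tail sampling switches to exponential rejection at
  0.45 sd above the mean; acceptance ratios are exact.
* Strict inequalities everywhere QC thresholds are compared (call rate
  0.95 passes; age at first calving 21 months passes).
* Markers failing several QC rules are charged to the first rule in the
  fixed order, so report counts reconcile exactly.
* Duplicate map positions remove *all* markers at the position
  (order-independent and conservative).
* `G` singularities raise an error advising a larger blend weight rather
  than silently regularizing.
* Seeds: every stochastic stage derives its stream from one integer
  seed; derived seeds stay below 2^31.

## Known limitations

* Desk-scale information: with ~2,000 single records the liability-scale
  heritability is weakly identified (posterior sd ≈ 0.05); results at
  this scale validate calibration, not precision.
* Single trait, no maternal effects, no REML cross-check.
* The threshold model assumes every contemporary group retains both (all)
  categories after editing — the QC stage enforces this.
* The scan reports variance shares, not formal significance; "top 20" is
  a ranking convention, not a test.
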
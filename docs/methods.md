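# Methods

This note records the models implemented in `poolcline`, the defaults
and why they were chosen, what the synthetic data do and do not emulate,
and the numerical choices a maintainer would want to know.

## Pooled diversity estimation

Reads at a site in a pool of *n* haploid individuals are modelled as
draws from the pool's allele frequency.  To remove coverage bias every
site is first reduced to a uniform coverage *M*\* (default 30) by
drawing without replacement (multivariate hypergeometric on the count
vector); sites below *M*\* are excluded for that pool.  Alleles are
A/C/G/T only — the N and deletion columns of a sync sextet are dropped
before subsampling, as indel handling belongs to the upstream mask.

Sequencing noise makes singletons unreliable, so only allele counts in
[b, M−b] (default b = 2) are trusted.  Restricting the neutral
site-frequency spectrum to that band gives the corrections

    f_pi(M, b) = (2 / (M(M−1))) Σ_{i=b}^{M−b} (M−i)       (= 1 at b = 1)
    a_W(M, b)  = Σ_{i=b}^{M−b} 1/i                         (= a_{M−1} at b = 1)

and the estimators π̂ = Σ h / (f_pi · L_usable), θ̂_W = S / (a_W ·
L_usable), where h = (M/(M−1))(1 − Σ f²) over passing alleles and a site
is segregating when ≥ 2 alleles pass.  A site whose minor allele falls
below *b* contributes h = 0 — the truncation correction assumes exactly
this.  Both sums are defined for M ≥ 2b (the guard accepts equality,
where each sum has a single term).

Tajima's *D* uses the classical constants at sample size *M* with a₁
replaced by a_W, i.e. D = (π̂L − S/a_W) / sqrt(e₁S + e₂S(S−1)).  This is
an approximation to a fully re-derived truncated variance; its adequacy
is asserted by simulation (below), not by equality with any external
implementation.  D is undefined (NaN, never 0) when S < 2, and
sign(D) = sign(π̂ − θ̂_W) wherever defined.

**Pool-size factor.**  Reads estimate the pool's plug-in heterozygosity
2f(1−f), which is (n−1)/n of the sample π.  `DiversityParams.pool_size`
optionally rescales h by n/(n−1); left unset the factor is omitted and
π̂ is biased low by 1/n (~1% at n = 100).  The factor matters mainly for
*D*: without it mean D on neutral data shifts by about −0.04.

**Calibration.**  On neutral coalescent windows (θ = 0.005/site, 10-kb
windows, 100 pooled lineages, coverage ~90 subsampled to 30, b = 2) the
pooled estimators recover θ to within ~1% per 500-window batch for θ̂_W
and ~1–3% for π̂.  Tajima's D is *not* mean-zero at this design even
when computed classically on the raw haplotypes: single-genealogy
windows without recombination give an intrinsic mean of about −0.10
(4,000-window oracle run).  With the pool-size factor the pooled
pipeline tracks the classical statistic (mean ≈ −0.07 ± 0.01).  Because
one 500-window batch leaves Monte-Carlo standard errors of ~3.5% on
mean π̂ and ~0.03 on mean D, the validation pools three replicate
batches of 500 windows.

## The synthetic cline generator

Frequencies follow a hierarchical Balding–Nichols model: ancestral
p₀ ~ Uniform(0.05, 0.95); two cluster frequencies Beta-distributed
around p₀ with drift F_div (default 0.1); pool frequencies around their
cluster frequency with F_pop (default 0.02); the admixed pool's base
frequency is λ·p_A + (1−λ)·p_C with λ = 0.5 before its own drift.
Defaults follow the emulated design: 6 pools of 100 haploids, Poisson
coverage with mean 90, per-base error 0.002, 200 scaffolds of mean
10 kb, 50,000 SNPs.  Pool elevations default to the six field stations
(176–1303 m a.s.l.); the environmental table is elevation plus 19
covariates that are linear in standardized altitude plus N(0, 0.15²)
noise, so PC1 explains ~97–98% of its variance.

Selected loci (1% of SNPs by default) receive an additive logit shift
β·env_k with env the standardized altitude and β = 3 — the "strong"
setting, chosen so the logit spread across the cline is ~8.5 units,
i.e. a near-fixation cline, which is the regime the recovery guarantees
below refer to.  Read counts arise in two stages: binomial sampling of
the pool (n individuals), then binomial read sampling at Poisson
coverage, with errors substituting a uniformly chosen other base.

Coalescent validation windows are generated with msprime (standard
neutral coalescent, ploidy 1, no intra-window recombination,
continuous/infinite-sites mutation positions floored to integers); the
sampled lineages themselves constitute the pool, so E[S] = θ·a_{n−1}·L
holds exactly.  What the generator does **not** emulate: linkage and
recombination within scaffolds (SNPs are exchangeable within blocks),
selection at linked sites, mapping artefacts, reference bias, indel
noise (masks are consumed, not produced), and diploidy.  Passing tests
therefore validate the estimators and the inference logic under the
assumed sampling model, not robustness to alignment artefacts in real
data.

## F_ST and outlier machinery

F_ST = (π_t − π_w)/π_t with π_w the average of the two pools' unbiased
heterozygosities and π_t the heterozygosity of the summed counts; 0 is
returned when π_t = 0 and negative finite-sample values are clamped to
0.  SNPs are sites with ≥ 2 alleles whose minor count summed across
pools reaches 4 (the across-pools reading of the minimum count).
Empirical outlier thresholds use type-7 quantiles with ties flagged
inclusively, so a saturated distribution (many SNPs at F_ST = 1) flags
more than the nominal tail fraction — intended behavior.  The per-gene
score is the maximum over pool pairs of the per-pair mean (configurable
to mean or a named pair; no convention is canonical here).  "Fixed
between clusters" is evaluated after per-pool removal of alleles below
the minimum count, so a singleton error does not break fixation.
Haplotype loci are the leftmost region per scaffold with ≥ 3 SNPs
spanning < 90 bp and ≥ 20 bp; spanning-read coverage must lie in
[15, 100] per population and 20 haplotypes per population are sampled
with a seeded RNG.

## DISTATIS, trees, Mantel, f-statistics

Quantile distance matrices (levels 0.975, 0.75, 0.5, 0.25, 0.025 of
each pair's F_ST values) are double-centered directly — the standard
convention for non-Euclidean dissimilarities — normalized by their first
eigenvalue, weighted by the first eigenvector of the RV-coefficient
matrix (rescaled to sum 1), and averaged into the compromise, whose
eigendecomposition gives factor scores.  An all-zero matrix (possible
for the lowest quantile when many clamped F_ST values are 0) is dropped
with a warning provided ≥ 2 informative matrices remain.  Bootstrap
clouds resample SNPs with replacement, rebuild the quantile matrices
with the fixed weights, and project into the compromise axes; ellipses
are normal-approximation 95% regions on the first two axes.

Neighbor joining is scikit-bio's implementation (negative branch
lengths clamped with the excess moved to the sister).  The Mantel test
correlates off-diagonal upper triangles and reports
p = (count ≥ observed + 1)/(n_perm + 1) over joint row/column
permutations; the identity permutation can be sampled, so the floor
1/(n_perm+1) is only attainable when no sampled permutation ties the
observed correlation.

f3(X; A, B) is the mean over SNPs of (p_X−p_A)(p_X−p_B); an optional
finite-sampling correction subtracts p̂(1−p̂)/(M_X−1) per SNP (read
depth M_X), an approximation because the pool-plus-read two-stage noise
makes the exact term model-dependent — it can be disabled.  f4 needs no
correction.  Standard errors come from a delete-one jackknife over
consecutive 500-SNP blocks (the last block may be short).  Enumerators
produce all P·C(P−1,2) f3 targets (60 for P = 6) and 3·C(P,4) f4
topologies (45 for P = 6).

## Environmental association

The scorer implements the hierarchical-normal approximation behind
covariance-controlled association: p = α·1 + β·env1 + ε with
ε ~ MVN(0, σ²_snp·Ω + diag(p̂(1−p̂)/coverage)), σ²_snp = p̄(1−p̄).  Ω is a
method-of-moments average of x·xᵀ over a seeded 10,000-SNP subsample,
x = (p − p̄)/sqrt(p̄(1−p̄)), projected to the nearest PSD matrix and
ridge-regularized (1e-6) before inversion; a second subsample provides
the convergence diagnostic (max |elementwise correlation difference|,
typically < 0.03 at these sizes).  The intercept is marginalized with a
flat prior; β carries a zero-mean normal prior whose sd is 1/range(env1)
(±3 sd spans three times the steepest possible frequency cline), and the
posterior is integrated on a symmetric 401-point grid over ±4 prior sd —
the grid keeps the machinery inspectable, and a conjugate closed form
cross-checks it in the tests.  Z = |P(β>0|data) − 0.5| is bounded by 0.5
and invariant to which allele is focal; the Bayes factor is the
grid-integrated marginal likelihood against β = 0 (it falls below 1 for
uninformative data — the Occam factor).  Candidate SNPs are ranked by
Z·BF, which keeps discriminating after Z saturates at 0.5.

Under the generator's default conditions, ~90% of strongly selected
loci rank in the top 1% and the null sign-probabilities are near-uniform
(KS ≈ 0.08 against Uniform(0,1) — the residual reflects the Beta
frequencies and estimated Ω that the normal model only approximates).
Because Ω is estimated from data in which the clusters align with
altitude, part of any real environmental signal is absorbed as
"structure"; this conservatism is inherent to the method, not a defect.

## Enrichment

Annotations propagate to ancestors over is_a edges (true-path rule,
set-union so diamonds count once).  elim visits terms deepest-first
(longest-path depth, ties lexicographic); each term with > 3 currently
annotated genes is tested with the one-sided hypergeometric upper tail
against the universe of annotated genes, and the genes of significant
terms (α = 0.05) are removed from their ancestors' sets before those
are tested.  Classic (un-pruned) p-values are reported alongside.  No
multiple-testing correction is applied by default, matching common
practice for elim results; the enrichment table carries log10 p.

## Trait statistics

The exact Mann–Whitney two-sided p doubles the one-tailed probability
(capped at 1); exactness is disabled under ties or when n_x·n_y >
10,000, falling back to the tie-corrected normal approximation with a
warning.  Welch's t uses Satterthwaite degrees of freedom.  Response
curves are least-squares polynomials (default degree 3 — the curves are
unimodal and the degree is not dictated by anything sharper);
rounding-noise trailing coefficients are trimmed before locating the
fitted maximum, the optimum is constrained to the observed WC interval,
and the ≥ 90%-of-maximum interval is read off a 2001-point grid.

## Determinism and seeds

All randomness flows through NumPy PCG64 generators.  The simulator
derives independent per-stage streams from SeedSequence((seed, stage));
the pipeline fans a master seed out to stages by SHA-256 of
"seed:stage" reduced below 2³¹ (msprime requires positive 32-bit
seeds).  Identical seeds give byte-identical sync output across runs.

## Problem sizes used in validation

The test-suite and acceptance runs use 6,000–20,000-SNP synthetic
datasets, 3 × 500 coalescent windows, 20 admixture replicates of 20,000
SNPs, 10,000-SNP covariance subsamples, and 100–1,000 bootstrap or
permutation draws — sizes at which every guarantee above is measurable
in seconds to a few minutes on one CPU while keeping Monte-Carlo error
well inside the asserted bands.  Genome-scale counts from real pooled
reads (hundreds of thousands of SNPs) are outside what the synthetic
conditions claim to reproduce.
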
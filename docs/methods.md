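# Methods

This note documents the models behind each module, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical decisions taken where the design was genuinely open.

## Data model

The substrate everywhere is the pseudo-haploid call matrix: N samples ×
S biallelic sites with entries in {0 = ancestral, 1 = derived,
missing}.  One sampled allele represents each individual at each site —
the standard representation for low-coverage ancient genomes, which
avoids diploid genotype calling.  Sites carry ancestral/derived alleles
oriented against an outgroup consensus and a transversion flag
(transversions are immune to the C→T/G→A deamination damage typical of
ancient DNA).  All estimators use pairwise- or quadruple-complete
observations; missing calls never contribute.

### Polarization

The outgroup consensus follows a majority rule over G outgroup genomes
(default G = 7): a site is polarizable when at most 2 of the 7 carry an
alternative allele.  When only k < G genomes are observed the threshold
scales to ⌊2k/7⌋ — an extension of the G-complete rule, flagged here
because the all-observed case is the designed one.  Sites with no
outgroup data, tied majorities, or a consensus allele absent from the
panel are dropped with per-site reasons.  Polarization is idempotent.

### Conditioning filters

`filter_sites` applies the conditioning used before frequency-based
tests: transversions only; non-missing in ≥ 75 % of the designated
samples; minor-allele count ≥ 2 ("at least doubletons", which excludes
residual singleton errors and sites fixed in the target).  LD pruning
mirrors the plink `--indep-pairwise 50 10 0.2` scheme: sliding windows of
50 sites advanced by 10, greedily removing the later site of any pair
with r² > 0.2.  r² is computed on the 0/1 calls over pairwise-complete
samples; pairs sharing fewer than 20 samples are never pruned (too little
evidence to condemn a site).  The procedure is deterministic and is
tested against an exhaustive re-implementation.

### Error rates

The per-genome error rate is the excess of derived alleles private to an
ancient genome relative to a modern genome treated as error-free:
(derived_ancient − derived_modern) / comparable sites, floored at zero
(sampling can make the modern genome carry more derived alleles; negative
estimates are truncated and flagged).  A per-substitution-type table
splits the same excess by ancestral → derived base pair, which is how
residual deamination damage shows up (inflated C→T/G→A rows).

## Core statistics

- **Pairwise distance**: mean allele mismatch over shared sites —
  d_ij = mean (x_i − x_j)², with per-pair site counts retained.
- **f4(A,B;C,D)**: mean over usable sites of (p_A − p_B)(p_C − p_D);
  labels may be single pseudo-haploid samples (calls as frequencies) or
  population frequency columns.  Standard errors come from a delete-one
  block jackknife over contiguous equal-count site blocks (default 100;
  configurable since linkage scales vary), Z = estimate/SE.
- **Coancestry**: c_ij = mean (x_i − x_O)(x_j − x_O) over sites complete
  in i, j and the outgroup; identical, bit-for-bit, to f4(i,O;j,O) on the
  same site set.  The diagonal of a single pseudo-haploid genome is
  biased by within-individual sampling; the default policy imputes it as
  the row maximum (only MDS consumes it), and an exclude policy is
  provided.  Note that with a single pseudo-haploid outgroup genome every
  pair shares the constant offset E[p_O(1−p_O)]; only coancestry
  *differences* between pairs are interpretable as differential shared
  drift, and the mixture model absorbs the constant into Ω.
- **Weir–Cockerham F_ST**, haploid form: each individual contributes one
  allele; per site a two-level ANOVA gives the between-group variance
  component a = (MSB − MSW)/n_c and denominator a + MSW; the genome-wide
  value is the ratio of summed numerators to summed denominators.
  Per-site values may be negative and are not truncated; monomorphic or
  under-covered sites (fewer than two observed alleles in a group) are
  skipped and counted.

## Neighbour joining and the fit ratio

`neighbor_joining` implements classic NJ with the BioNJ variance-weighted
reduction (λ chosen per join to minimize the variance of the updated
distances, clamped to [0,1]; initial variances equal the distances).  On
additive matrices any λ yields the exact generating topology and branch
lengths, which the tests exploit up to 12 leaves; ties in the Q criterion
break to the lowest active index pair, making output deterministic.  The
goodness-of-fit diagnostic averages, per sample, patristic/raw distance
over all partners (zero-distance pairs excluded and counted).  Ratios of
one mean the tree expresses the sample's affinities perfectly; admixed
samples inflate their ratios because a bifurcating tree cannot place
them.

## The ancestry mixture model

**Model.** c_ij = q_iᵀ Ω q_j for i ≠ j, with Q rows on the K-simplex and
Ω a K×K symmetric PSD ancestral-coancestry matrix.  This is the exact
expectation of outgroup coancestry when individual allele frequencies are
linear mixtures of ancestral frequencies; it makes no Hardy–Weinberg
assumption.  Observed statistics are modelled as independent Gaussians
around their expectations — per-statistic SEs when supplied, otherwise a
shared residual scale σ estimated jointly.

**Identifiability and gauge fixing.** The quadratic form is invariant
under Q → QA, Ω → A⁻¹ΩA⁻ᵀ for any invertible stochastic matrix A: the
likelihood identifies only the fitted matrix QΩQᵀ, not the decomposition.
When the panel contains unadmixed representatives of each ancestry, the
natural convention — and the ground truth — is the vertex-spanning gauge
in which those individuals sit at simplex corners.  Two mechanisms
enforce it.  (1) Initialization: coancestry rows are affine images of the
mixing vectors, so the panel lies on a (K−1)-dimensional affine subspace;
we project onto its top principal axes, locate K vertices by a
furthest-point search refined by averaging each vertex's assigned
cluster (threshold q > 0.8, which avoids the outward bias of averaging
only the most extreme points), and read off mixing vectors as
simplex-constrained barycentric coordinates; Ω follows by least squares
on the off-diagonal model equations.  (2) Gauge fixing of the output: the
reported state re-runs the same vertex decomposition on the *fitted*
(hence denoised) coancestry matrix, so the reported (Q, Ω) follow the
vertex convention regardless of where along the flat gauge direction the
chain wandered.  A symmetric Dirichlet(α = 0.25) prior on the mixing rows
(rather than a flat prior, whose ALR-space form actively pulls rows away
from corners) keeps the sampler near the anchored basin.

**Sampler.** Component-wise random-walk Metropolis–Hastings on
transformed parameters: each Q row via additive log-ratio (a (K−1)-vector
proposal), Ω via a Cholesky factor with log diagonal (scalar blocks), σ
via log.  Transform Jacobians are included so the target is the posterior
under the stated priors (flat on Ω and σ in natural scale).  Proposal
scales adapt by Robbins–Monro steps toward acceptance 0.234 during
burn-in and freeze afterwards, so the post-burn-in kernel is fixed.
Row updates cost O(NK) via cached Q·Ω products; Ω/σ updates O(N²K).
Defaults: 4000 sweeps, half burn-in, thinning 10, 5 restarts jittered
around the anchored start, best final likelihood wins.  The analyses in
the tests and the acceptance script use 2000 sweeps and 2 restarts, which
the standard scenario needs for convergence (recovery error ~0.03,
comfortably inside the 0.05 design target).  The fit reports the
gauge-fixed best state, the post-burn-in posterior mean, the
log-likelihood trace, per-block acceptance rates, and thinned Ω/σ draws
for Monte-Carlo error estimation.  On the K = 1 conjugate toy (all
off-diagonals sharing one mean), the posterior of Ω₁₁ under these priors
is centred at the sample mean, which the test suite verifies to within
three Monte-Carlo standard errors.

**K selection** is deliberately a user input: the likelihood trace is
exported for external comparison, and no automatic criterion is applied.
Components are reported sorted by total contribution Σ_i Q_ik; alignment
to a reference ordering (for simulations) uses exhaustive permutation
search up to K = 8 and a greedy fallback beyond.

**MDS.** Classical scaling of the coancestry semi-matrix: similarities
convert to dissimilarities d_ij = c_max − c_ij (zero diagonal),
double-centering, eigendecomposition, coordinates for positive
eigenvalues in non-increasing order.  Excluded labels (e.g. the outgroup)
are removed before scaling.

## The continuity test

Given exact derived-allele frequencies y in a target population
(segregating sites only, 0 < y < 1, after the doubleton/coverage/pruning
conditioning) and read counts for one specimen, the test contrasts
direct ancestry (t2 = 0) with a sister-group placement (t2 > 0).

Per site: y descends from an ancestral frequency x by a Balding–Nichols
step of magnitude t1, so conditioning on y gives the reversed-time
ancestor distribution f(x|y,t1) ∝ BN(y|x,t1)·π(x) with a uniform prior π.
The direction matters: the forward and reversed kernels differ in shape,
and that asymmetry is the entire source of identifiability — a symmetric
approximation (x centred on y) makes the likelihood a function of total
drift only and the test degenerate, because the genotype distribution
needs only the first two moments of the specimen-branch frequency.  For
the same reason the forward t2 step integrates in closed form: genotype
probabilities given x are P(g=2) = x² + t2·x(1−x), P(g=0) = (1−x)² +
t2·x(1−x), P(g=1) = 2x(1−x)(1−t2).  Reads are Binomial(n, g/2), with an
optional known error rate e replacing g/2 by (g/2)(1−e) + (1−g/2)e
(default 0, appropriate for damage-treated transversions).  A 64-node
Gauss–Legendre rule over x (weights renormalized on the grid; order
configurable, convergence tested against a 10⁶-draw Monte-Carlo oracle)
completes the site likelihood; t1 → 0 collapses to x = y exactly.

Both models are maximized by bounded L-BFGS-B from multiple starts; the
statistic 2(LL_full − LL_null) is referred to ½χ²₀ + ½χ²₁ because t2 = 0
lies on the boundary.  Calibration on 200 replicates simulated from the
model (500 sites, t1 = 0.05) lands the α = 0.05 rejection rate inside the
exact binomial interval, with roughly half the replicates at LRT = 0 as
the boundary mixture predicts; power rises with t2 and with site count.
The Balding–Nichols kernel replaces the full Wright–Fisher diffusion
transition of the original methodology — same first two moments,
desk-computable — which is a documented divergence.

## Isolation by distance

Great-circle distances use the haversine formula with Earth radius
6371.0088 km.  Windows slide backward from the oldest sample in 250-year
steps; each broadens forward in time — by distinct age boundaries, so
equal-aged samples enter together — until it holds ≥ 10 members whose
convex hull covers ≥ 2/3 of the hull of all samples in the run (hulls are
planar after a Lambert azimuthal equal-area projection about the points'
centroid; adequate at continental scale).  Start ages that can never
satisfy both criteria are dropped and reported.  The window age is the
mean member age.

The partial Mantel statistic is the correlation of genetic and
geographic distance after residualizing both on temporal distance
(matrix-regression form), over unmasked pairs only: pairs closer than
500 km *and* 500 years are masked so the test measures between-deme
structure rather than within-deme noise.  P-values permute the sample
labels of the genetic matrix, p = (1 + #{|r*| ≥ |r|})/(1 + n_perm); a
permutation-of-residuals variant sits behind a flag.  Confidence
intervals resample individuals with replacement within the window and
recompute the masked statistic (degenerate resamples are redrawn and
counted).  Autosomal and X-chromosome analyses are the same operation on
different input matrices.

## The synthetic-data generator

Forward frequency diffusion under Balding–Nichols: a branch with drift F
draws the child frequency from Beta with mean p and variance F·p(1−p)
(F = 0 copies the parent, F = 1 fixes the allele); admixture events mix
two source frequencies linearly (α from the first source) before any
drift of their own.  Root frequencies default to Uniform(0.05, 0.95) to
avoid near-fixed sites.  Individuals mix population frequencies through
their q vectors, then emit pseudo-haploid calls (Bernoulli, then missing
mask), and read counts (total ~ Poisson(depth), diploid genotype
Binomial(2, p), reads derived with probability g/2 adjusted by the error
rate).  Everything is deterministic given the seed, with substream seeds
drawn from a single generator.

This replaces a backward coalescent simulation: the drift moments match,
but linkage, recombination, mutation-rate heterogeneity and sequence-level
read artefacts are *not* emulated, so passing tests demonstrate estimator
correctness under the stated drift model, not robustness to linked
selection or damage.  The stated mutation/recombination rates of real
shotgun panels informed only the default site-count scale.

The standard validation scenario is a three-population star (shared stem
drift 0.05; population drifts 0.02, 0.06, 0.10; outgroup drift 0.10): 50
individuals per population, 50 admixed with Dirichlet(1) mixing vectors,
50,000 transversion sites, 5 % missingness, one outgroup genome.  Under
this model the true Ω has the closed form Ω_ab = E[p₀(1−p₀)]·(1 + F_stem)
off-diagonal and Ω_aa = E[p₀(1−p₀)]·(1 + F_stem + F_a(1−F_stem)), with
E[p₀(1−p₀)] = 0.1825 for the default root law — the outgroup's drift and
its pseudo-haploid sampling variance sum to a term independent of its
branch length.  The tests use this closed form as the Ω ground truth.

The isolation-by-distance generator couples deme frequencies through a
Gaussian random field on the logit scale with exponential covariance
drift_per_km·L·exp(−d/L) (L = 2000 km), so the variance of the
frequency difference between demes grows monotonically with their
haversine distance.  Default drift_per_km = 5·10⁻⁵ per km produces
partial-Mantel r ≈ 0.2–0.4 at continental deme spacing with 5,000 sites
— detectable but far from saturated, a realistic regime.  Ages are point
estimates in years BP (uniform by default); coordinates get ~10 km of
jitter around deme centres.

## Problem sizes and numerical choices

Test and acceptance runs use: 200 × 50,000 for ancestry recovery (MCMC:
2000 sweeps, 2 restarts); 200 null + 2×100 power replicates at 500 sites
for continuity; 200 null datasets × 999 permutations and 100 IBD panels
for Mantel; 100 random 20 × 1,000 panels for oracle equivalence; 10⁶
sites for error-rate recovery — sizes chosen so each estimator's
sampling error sits well below its design tolerance.  Degenerate inputs
are contracts, not crashes: empty filter results are allowed and
reported, zero-shared-site pairs are flagged, monomorphic F_ST sites are
counted, all-equal MDS inputs return zero coordinates with a warning-level
eigenvalue spectrum, and non-finite likelihoods return −∞ rather than
raising inside optimizers.

## Known limitations

- The mixture model's gauge is fixed by the vertex convention; if some
  ancestry has *no* near-pure representative in the panel, the anchored
  vertex is an extrapolation and Q for that component is conventional
  rather than identified.
- No per-individual private-drift (diagonal) term is modelled; residual
  diagonal structure appears in the residual matrix diagnostics instead.
- Coancestry offsets from a single pseudo-haploid outgroup genome are
  absorbed into Ω, so Ω's absolute scale mixes shared drift with the
  outgroup term; differences and Q are unaffected.
- The continuity test assumes exact target frequencies and free
  recombination between conditioned sites; LD pruning approximates the
  latter.
- Window hulls use a planar equal-area projection; at hemispheric scale
  the approximation degrades.
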
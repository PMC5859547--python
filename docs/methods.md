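# Methods

## Model

For subject i with observed time `Y_i = min(T_i, C_i)`, event indicator
`δ_i = I(T_i ≤ C_i)`, covariates `X_i` (q columns) and composition `Z_i`
(p OTU relative abundances), the working model is a Cox proportional
hazards model

    λ_i(t) = λ_0(t) · exp( Σ_k α_k X_ik + h(Z_i) )

and the null hypothesis is `h ≡ 0`. Treating the per-OTU coefficients as
random with mean zero, common variance σ² and a chosen correlation
structure turns this into a variance-component score test of
`H0: σ² = 0`, whose statistic is the quadratic form

    U = rᵀ M r,      r = d − Λ̂,

where `r` is the martingale-residual vector of the covariate-only null
fit and `M` is an n × n similarity matrix among subjects. No
distributional assumption on the OTU effects is needed; the choice of
`M` decides which association patterns the test is sensitive to.

### Candidate matrices

* `M = Zᵞ (Zᵞ)ᵀ` (element-wise power, `0^γ = 0`) gives MiSALN(γ). Because
  `Σ r_i = 0`, each OTU contributes through the *centered* column of
  `Zᵞ`; raising to a small power compresses the dynamic range so that
  rare OTUs' presence patterns carry weight comparable to abundant
  OTUs' abundance fluctuations. Default grid Γ = {1/4, 1/3, 1/2, 1}.
* `M = K` from an ecological distance: `K = −½ J D∘D J` with
  `J = I − 11ᵀ/n` (Gower double centering), then negative eigenvalues
  clamped to zero and the matrix re-symmetrized. Default distance set
  Ψ = {unweighted UniFrac, generalized UniFrac θ=0.5, weighted UniFrac,
  Bray-Curtis}, spanning presence/absence-phylogenetic to pure-abundance
  information.

UniFrac is computed on a branch × OTU membership matrix: for samples a,
b and branch l with length b_l carrying descendant-tip abundance totals
p_al, p_bl,

    unweighted:  Σ b_l |I(p_al>0) − I(p_bl>0)| / Σ b_l I(p_al>0 or p_bl>0)
    generalized: Σ b_l (p_al+p_bl)^θ |p_al−p_bl|/(p_al+p_bl)
                 / Σ b_l (p_al+p_bl)^θ

with θ = 1 recovering the normalized weighted UniFrac. The unweighted
and weighted variants reduce to Manhattan distances on length-scaled
branch profiles plus closed-form normalizers and run through
`scipy.spatial.distance.pdist`; general θ is evaluated pairwise over the
upper triangle. Both end points agree with scikit-bio to machine
precision (asserted at 1e-8 in the tests).

### Null fit

The covariate-only Cox model is fit by Newton-Raphson on the Efron
partial likelihood (convergence when max |score| < 1e-9, at most 50
iterations, step-halving on likelihood decrease; a Breslow option exists
for cross-checking). With q = 0 the cumulative hazard reduces to the
Efron-adjusted Nelson-Aalen estimator. Among the textbook variants of
the Efron cumulative-hazard plug-in at tied death times we use the one
implemented by R's `survival`: a subject dying in a tie of size d
receives increments `(1 − l/d) / (S0 − (l/d) Sd0)`, l = 0..d−1, while
subjects remaining at risk receive the full `1 / (S0 − (l/d) Sd0)`. This
choice makes the residuals sum to zero exactly and matches
`residuals(coxph(...), type="martingale")` to machine precision.

### Permutation engine

All p-values come from one shared ensemble of B random permutations of
the residual vector (Fisher-Yates shuffles from one seeded generator):

* candidate p-value: `(1 + #{b : U_c(b) ≥ U_c(obs)}) / (B + 1)`;
* inside the ensemble, each permuted statistic receives a rank-based
  pseudo p-value `#{b' : U_c(b') ≥ U_c(b)} / B`; the per-permutation
  minimum over a candidate set is the adaptive statistic's null draw;
* adaptive p-value: `(1 + #{b : min_c p_c(b) ≤ Q_obs}) / (B + 1)` with
  `Q_obs = min_c p_c`.

Ties are resolved conservatively (≥ for statistics, ≤ for minima). The
add-one convention keeps every p-value in (0, 1], on the lattice of
multiples of 1/(B+1), and guarantees `adaptive p ≥ Q_obs`. One
permutation set serves every candidate and all three adaptive tests, so
the cost is linear in B (no nested permutation loop). Default B = 5000
for analysis, 500-1000 inside the simulation harness.

### Higher-level taxa

A taxon's sub-matrix keeps the community-total normalization: columns
are subset, rows are *not* re-closed to one, so a taxon holding 3% of
the community contributes on the 3% scale. The tree is pruned (sheared)
to the taxon's tips and the same branch-proportion formulas apply to the
community-scale abundances, including the weighted-UniFrac normalizing
denominator. This is a documented interpretation: community-scale
normalization for taxon-level UniFrac is required but its exact form is
not uniquely pinned down by the sources for the method. Taxa with a
single OTU fall back to a univariate Cox Wald test (lifelines). Raw
p-values are BH-adjusted within each rank (the correction is pluggable);
the community-level p-value is reported raw since it is a single test.

## Simulation design

The harness reproduces the validation conditions end to end, fully
deterministic given a seed:

* **Counts.** Dirichlet-multinomial: per sample, proportions ~
  Dirichlet(π(1−φ)/φ), counts ~ Multinomial(1000). Defaults p = 353
  OTUs, n ∈ {50, 100}.
* **Covariates.** age ~ N(50, 5²), sex ~ Bern(0.5).
* **Survival.** `T = sqrt(−4 log U / exp(η))` (Weibull(2,2) baseline)
  with `η = 0.5(age−50) + 0.5·sex + Σ_j β_j scale(Z_ij)`; `scale` uses
  the n−1 sample SD (zero-variance columns scale to zero, warned when
  they carry an effect). Censoring C ~ Unif(0, c); c = 10 yields ≈26%
  censoring, c = 5 ≈40%.
* **Scenarios.** Associated sets: 10 most abundant, 10 random, 10 least
  abundant OTUs, or one PAM cluster (k = 10 on cophenetic tree
  distances; the associated cluster is re-drawn uniformly each
  replicate). Effects β_j ~ Unif(0, u) (same direction) or Unif(−u, u)
  (mixed), u ∈ {1, 2, 3}; u = 0 is the null.
* **Replicates.** 1000 for type I error, 150-250 for power orderings —
  sizes chosen to resolve a 5% level within 3 binomial SE and to
  separate the qualitative orderings.

### The synthetic abundance profile

The original proportion means were estimated from a real mouse cohort
that is not redistributable, so `synth_dm_params` supplies a documented
stand-in: π = 0.94·lognormal(0, 3) + 0.06/p, normalized. The lognormal
part concentrates ~80% of reads in a handful of OTUs; the uniform floor
pins the rarest OTUs just above 1e-4, emulating the proportional-mean
retention filter that defines which OTUs enter the analysis. Dispersion
defaults to φ = 0.005, the low end of published Dirichlet-multinomial
estimates, as appropriate for a genetically homogeneous cohort sampled
at one time point. This matters: with a mid-abundance-heavy profile or
strong overdispersion, the 10 rarest OTUs appear in so few samples that
*no* community-level test retains power at 1000 reads, which would
contradict the documented behaviour of the method on the real data. The
stand-in was calibrated once against those qualitative findings (rare
scenarios detectable by small-γ MiSALN, distance kernels underpowered
there, Bray-Curtis strongest for abundant effects) and then frozen.

What passing simulations do and do not show: type I error control is
insensitive to the abundance profile (the permutation null is valid by
construction), so the level results transfer to real data. Power
*orderings* reflect the stand-in's shape and should be read
qualitatively; absolute power values are not predictions for any real
dataset. Real 16S data also feature lineage-correlated abundances,
variable sequencing depth and compositional artefacts that the
Dirichlet-multinomial does not model.

## Numerical choices and edge cases

* Kernel PSD repair: eigendecomposition, clamp at 0, re-symmetrize;
  tolerance −1e-10 on the minimum eigenvalue.
* Sample pairs with no abundance at all: distance defined as 0 with a
  warning.
* Missing newick branch lengths are treated as 0 with a warning (they
  then contribute nothing to UniFrac sums).
* All-zero OTU columns survive I/O and are only removed by the explicit
  proportional-mean filter (default threshold 1e-4), keeping filtering
  auditable.
* PAM: greedy BUILD then canonical best-improvement SWAP, deterministic
  lowest-index tie-breaks. PAM is a local search; on well-separated
  instances it attains the exhaustive-medoid optimum (asserted in the
  tests), on adversarial geometry it may not — the clustering here only
  seeds simulation scenarios.
* Degenerate inputs raise typed errors (no events, zero-total samples,
  rank-deficient covariates, zero-variance abundance in the univariate
  fallback) rather than returning numbers.

## Adaptivity cost

The min-p construction over eight candidates is not free: when the best
candidate's power is moderate (20-40%), OMiSA trails it by up to ~5-10
points of absolute power; the gap vanishes as power grows. The test
suite asserts this as a bounded-regret property (OMiSA within 0.10 of
the best individual test in every scenario) rather than as equality.

## Known limitations

* Only the unstandardized score statistic is used; p-values are purely
  permutation-based (no asymptotic approximation), so runtime scales
  with B and very small p-values are bounded below by 1/(B+1).
* Residuals are permuted rather than outcomes re-fit per permutation;
  this is exact under exchangeability of residuals given covariates and
  standard for this family of tests, but it is an approximation when
  covariate effects are strong and n is very small.
* No compositional (log-ratio) transformation is applied; users can
  transform upstream if desired.
* Time-varying covariates and stratified baselines are out of scope.
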
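# Methods

## Model

Counts of polymorphic sites per frequency bin are modelled as independent
Poisson variables (the Poisson random field). For a Wright–Fisher
population at equilibrium, a derived allele with scaled selection
coefficient γ = 2Ns sojourns at population frequency x with density
proportional to

    h(γ, x) = (1 − e^{−2γ(1−x)}) / ((1 − e^{−2γ}) x (1 − x)),

and the expected number of sites observed with i copies in a sample of n
chromosomes is F(γ)ᵢ = ∫₀¹ h(γ,x) C(n,i) xⁱ(1−x)^{n−i} dx, up to the
mutation-supply factor θS/2. We deliberately keep h dimensionless (the
mutation factor lives outside the integral), so the neutral limit is
F(0)ᵢ = 1/i = 𝒩ᵢ exactly, and the expected selected/neutral count ratio in
bin i reduces to ρ·F_{g,i}/𝒩ᵢ with ρ the mutation-rate ratio. Keeping θS
inside h, as some presentations do, would double-count it against the
explicit θS/2 in the expected-count formula.

The central assumption is that non-selective forces (demography, linked
selection, sample structure, shared mutation biases) multiply both
expectations by the same per-bin factor aᵢ and therefore cancel in the
ratio. Selection–demography interactions that are *not* shared break this
assumption; the method's own literature shows the resulting bias is modest
for weak selection and worst for bottlenecks with strong selection.

## Ratio density and its conventions

Approximating each Poisson count by a gaussian with equal mean and
variance, the bin ratio z has the Hinkley ratio-of-normals density with
numerator mean β·M and denominator mean M. We parameterize it by
(β, δ = M^{−1/2}) with M = 𝒩ᵢθ. Two conventions needed resolving:

- **Which θ.** Under the 𝒩ᵢθ/2-per-bin counting convention, Watterson's
  estimator θ̂ = S/aₙ (aₙ = Σ_{i<n} 1/i) converges to θ/2, so M = 𝒩ᵢθ̂
  evaluated at the estimate equals the *actual* denominator Poisson mean.
  A Monte-Carlo test (10⁶ gaussian-ratio draws, Kolmogorov distance
  < 0.01) pins the implementation to exactly this pairing: the matching
  denominator gaussian has mean 1/δ².
- **θ as nuisance.** δ is the only place a non-ratio mutation parameter
  appears. The working density integrates it out against a prior uniform
  in log θ over [θ̂/10, 10θ̂], by a 24-point Gauss–Legendre rule on log θ
  (normalized weights; 24 vs 96 nodes agree to better than 1e−4).

Both exponents in the density are non-positive by Cauchy–Schwarz, so the
evaluation is overflow-free down to δ = 1e−4 and far beyond.

### Zero-count bins

The gaussian stand-in fails at an observed count of 0, and it fails
asymmetrically: a zero *neutral* count makes the ratio undefined (the bin
is masked), while a zero *selected* count (z = 0) makes the likelihood
*unbounded* — as β → 0 each z = 0 bin contributes about −½·log β while
each z > 0 bin pays only +log β, so once zero bins outnumber nonzero bins
two-to-one the "maximum" runs off to ρ = 0. Both kinds of bins are
therefore excluded from the log-likelihood. The retained set depends only
on the data, so nested model comparisons remain valid. With genome-scale
data and folded spectra, zero bins are rare except under strong selection.

### Known calibration limit of the θ-integrated likelihood

The log-θ mixture is leptokurtic relative to the true sampling density of
z (sharper peak from the high-θ components, fatter tails from the low-θ
ones). This violates the information-matrix equality, and the
likelihood-ratio statistic of the neutrality test runs hot by a factor of
roughly 1.5: at n=100, θ = θS = 500 and 500 replicates the empirical
rejection rate at the χ²₁ 0.05 cutoff is ≈ 0.09–0.12 (it is ≈ 0.05 if θ is
fixed at θ̂ instead of integrated; we verified the optimizer is not at
fault by dense parameter scans, and the inflation is unchanged at
θ = 5000, ruling out the Poisson-vs-gaussian approximation). We keep the
θ-integrated form because it is the method's defining construction; users
running the LRT at small data sizes should calibrate cutoffs by simulation
(`sfratios calibrate`).

## DFE families

All on the 2Ns axis, with support capped at a maximum m so that weakly
beneficial (m = 1) or strictly deleterious (m = 0) regimes can be chosen:

- **inverted lognormal**: log(m − γ) ~ Normal(μ, σ);
- **inverted gamma**: (m − γ) ~ Gamma(shape α, scale); a (mean, shape)
  parameterization is accepted with scale = (m − mean)/α;
- **normal**: untruncated gaussian on γ;
- **fixed**: a single γ value;
- any of the above mixed with a point mass p⁺ ∈ [0, 0.5] at γ = 0.

`dfe_mean` integrates γ·g(γ) over −10⁵ < γ < 10⁻⁴ **without**
renormalizing over the truncated range; a closed-form truncated-lognormal
moment oracle (e^{μ+σ²/2}·Φ((ln t − μ − σ²)/σ)) confirms this convention
reproduces published mean-2Ns values. Mixtures reported with an explicit
negative-part weight p⁻ and a beneficial spike γ⁺ are supported through
the `p_neg` / `gamma_plus` parameters (used only by `dfe_mean`).

## Numerics

- **Bin expectations.** The x(1−x) denominator of h is absorbed into the
  binomial kernel analytically, leaving an integrand ∝ x^{i−1}(1−x)^{n−i−1}
  that adaptive quadrature handles at rel. tol. 1e−6 (abs. 1e−8). For
  γ < −100 the integrand spikes at x ≈ 1/(2|γ|); those points are passed
  to the subdivision. Values are floored at 1e−300: for n = 200 and
  γ → −10⁵ the true value (≈ C(n,i)(i−1)!/(2|γ|)ⁱ) underflows doubles,
  and any realistic DFE puts negligible mass there.
- **γ grid.** F(γ)ᵢ is cached on ≈ 180 deterministic nodes: per-decade
  Gauss–Legendre panels on log|γ| from 1e−8 to 10⁵ (negative side) and
  1e−8 to 1 (positive side; the deep sub-neutral decades resolve the
  integrable power singularity of shape < 1 inverted-gamma DFEs at the
  support maximum), a short linear panel across zero, and an
  exact anchor at γ = 0. DFE-averaged expectations from the grid agree
  with direct adaptive quadrature to ~2e−5 relative; doubling the node
  count moves results by < 1e−4. One grid per (n, folded) is built
  (seconds at n = 200) and shared by all optimizer iterations.
- **Fixed-γ fits** (including the LRT alternative) evaluate F(γ) via
  monotone PCHIP interpolation of log F against asinh(γ) through the grid
  nodes (≲ 2% relative error everywhere, exact at γ = 0); per-iteration
  quadrature would dominate run time in the 500-replicate calibration
  harness. `dfe_bin_expectations` itself computes fixed-γ models exactly.
- **Optimization.** Nelder–Mead on unconstrained coordinates (log ρ,
  log σ/α/sd, log-distance-below-maximum for bounded means, scaled logit
  for p⁺), 5 seeded starts by default (the first at ρ₀ = X/Y, the
  neutral-limit estimator, with mid-range DFE parameters; the rest drawn
  from wide seeded ranges, e.g. μ₀ ∈ [0,6], σ₀ ∈ [0.3,3]), each polished
  by a simplex restart; `converged` is true when all starts agree within
  0.01 log-units. Normal-family parameter vectors whose density mass
  captured by the γ grid falls below 50% are rejected: the family is
  unbounded above while the grid stops at γ = 1, and unpenalized escaping
  mass drives a degenerate ρ → ∞ solution.
- **Confidence intervals** are profile-likelihood intervals at the χ²₁
  cutoff (drop of 1.92 for 95%), endpoints bracketed geometrically and
  refined by Brent's method to ~1e−3 relative; a side that never crosses
  the cutoff is flagged one-sided. Coverage measured on simulated
  fixed-γ data is ≈ 93–95%.

## Synthetic data

The simulator draws independent Poisson counts with means aᵢ𝒩ᵢθ/2
(neutral) and aᵢF_{g,i}ρθ/2 (selected), folds post-draw, and derives all
randomness from one seed. The distortion generators ("smooth" correlated
log-gaussian, "expansion"-like excess of rare variants,
"bottleneck"-like depletion of intermediate bins) are qualitative
stand-ins for real demographies: they test exactly the shared-aᵢ
cancellation the method assumes, not linked-selection realism — passing
distortion-invariance tests shows the estimator ignores shared bin-wise
distortions, **not** that it is robust to forces that hit selected and
neutral sites differently (linkage to the selected sites themselves,
unshared gene-conversion bias, etc.).

Default experiment sizes mirror the method's reference analyses: LRT
power/calibration at n = 100, θ = θS = 500; estimator-recovery runs at
n = 200 folded with neutral θ = 3000 (the mutation supply of ≈ 3 Mbp of
neutral sequence at 4Nu = 10⁻³ per bp, the volume the reference forward
simulations produced) and true ρ = 0.35. At several-fold smaller θ the
weak-selection likelihood surface develops a second mode (σ → 0 with
inflated ρ) and replicate means drift; that regime is reported by the
`converged` flag rather than hidden.

## Neutral-control construction

From a VCF of biallelic SNPs (call-rate filter, default ≥ 50%), each
candidate selected SNP is assigned a mutational context — flanking
reference bases plus the unordered ref/alt pair; 16 × 6 = 96 contexts;
reverse complements kept distinct — and greedily paired, in genomic
order, with the nearest same-chromosome, same-context short-intron SNP
not yet used (ties break to the lower coordinate). Sites are then
projected to a uniform sample size by expected hypergeometric
downsampling and folded. A pair is dropped whole if either member was
genotyped on fewer than the target chromosomes, preserving the
equal-site-totals property that makes λ̂ = ρ̂ for paired designs.
Identifying short introns (the < 86 bp, 8 bp-trimmed convention) is left
to the user-supplied class table or BED intervals; annotation tooling is
out of scope.

## Limitations

- The gaussian ratio approximation wants ≳ 10 counts per bin; the
  package warns when bins fall below that.
- The LRT is anticonservative by ~1.5× in the statistic (see above);
  power and ROC analyses are unaffected in ranking terms.
- The normal DFE family is effectively truncated at the grid maximum
  γ = 1 during fitting.
- Point masses are fitted only at γ = 0 (beneficial spikes at γ⁺ > 0 are
  supported in `dfe_mean` for reproducing published mixtures, not as a
  fitted model).
- Bins are treated as independent; no covariance correction across bins.
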
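# Methods

This note records the statistical model implemented by `igof`, the
design choices made where the design was genuinely open, what the
simulator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## Pairwise statistic and pair classification

For a variant pair the data are two 3×3 genotype tables (cases and
controls) over the categories AABB … aabb, ordered as `3·a + b` with
`a`, `b` the minor-allele counts at the two variants.  The statistic is
Pearson's goodness of fit of each group's counts against the pooled
category frequencies; it responds to main effects and interaction
effects alike and makes no linkage-equilibrium assumption between the
two variants.  Categories with pooled frequency zero are excluded from
the sum (they contribute 0/0 otherwise); the count `d` of populated
categories is carried along because the LF screening approximation sums
it across selected pairs.  A pair is *common* when all 18 expected
counts are at least 5 — the classical validity condition for the χ²
approximation — and the per-pair p-value then uses 8 degrees of freedom
(a common pair necessarily has all nine categories populated).  The
classification is applied with the min-over-both-groups reading: the
weaker either-group reading would admit tables whose sparse group
invalidates the asymptotics.  LF pairs carry no per-pair p-value; their
selection is count-based.

Allele-pair (2×2) tables follow the fast-epistasis construction: a
double heterozygote contributes one count to each of AB/Ab/aB/ab, a
homozygote-homozygote individual four counts to one cell, so each
group's cells sum to four times its sample size.

## Gene-pair statistics

* Common branch: per-pair p-values below τ (default 0.05, the
  conventional truncation threshold for truncated p-value combination)
  form Ω; the statistic is `I_common = Σ Φ⁻¹(1 − p_j)`.  The inverse
  normal transform is oriented so smaller p gives a larger positive
  contribution; a literal `Φ⁻¹(p_j)` would make the statistic *more
  negative* with stronger evidence while the screening distribution
  theory (sum of the k largest of n normals) presumes the
  evidence-increasing orientation, so the latter is implemented, and
  permutation exceedances are counted as `permuted > observed`
  (strict — ties do not count).
* LF branch: pairs with `N_ab > M_ab` (strictly; ties, including the
  all-zero tie typical of very rare pairs, are excluded) form Ψ;
  `I_LF = Σ C²`.  The selection direction encodes the a priori
  assumption that minor alleles carry risk.
* Combination: extended Simes,
  `p = min(2·min(p_common, p_LF), max(p_common, p_LF))`.

Both selections are functions of the case/control labels, so every
permutation replicate recomputes the full statistic including Ω and Ψ;
freezing the selections would invalidate the permutation null.
Permutation shuffles the label vector uniformly, preserving N and M.
With complete genotypes the pooled frequencies and group sizes are
label-invariant, so the common/LF classification and all expected
counts are computed once per dataset; with missing genotypes (pairwise
deletion per variant pair) they are label-dependent and the slower
reference engine re-derives everything per shuffle.

## Permutation engine and two-stage screening

Adaptive permutation stops at the `r`-th exceedance (p = r/B, with B
the permutation count at that point) or at the budget `b`
(p = (R+1)/(b+1)).  Defaults follow the published budgets b = 25/α,
r = 36 (2,500/36 at α = 1%, 25,000/36 at 0.1%), which keep the standard
error of the estimate under 20% of α; the derivation of those constants
is external and is shipped as a configured rule rather than re-derived.

Screening gates (threshold `m·α`, default m = 10):

* `p_N` approximates the upper tail of the sum of the k largest of n
  independent standard normals at the observed `I_common`.  It is
  evaluated from a cached fixed-seed Monte-Carlo table: pool sizes n are
  snapped to a geometric grid (exact up to n = 20), each node stores
  compressed empirical tails for all k up to 40 (exact order statistics
  in the top 1–3%, an even quantile grid below), with 400,000 draws for
  small n and 50,000 for gate-only sizes; k = n uses the exact
  Normal(0, n) tail and n > 200 an L-statistic normal approximation.
  Correlation between variant pairs makes any such tail an
  approximation, which is why `p_N` only gates.
* `p_D` is the χ² tail of `I_LF` at `Σ d_i` over Ψ — cheap and
  anti-conservative (selection bias, correlation, sparse cells), used
  only as the first LF gate.
* If `p_D` passes, 1,000 permutations estimate the null mean and
  variance of `I_LF` and the Satterthwaite–Welch scaled chi-square
  `g·χ²_h` (g = k₂/2k₁, h = 2k₁²/k₂) gives `p_SW`; if that passes too,
  the adaptive run continues, with the 1,000 moment-estimation
  permutations and their exceedances counted towards B and R (they are
  draws from the same null, so discarding them would only waste work).
  Degenerate draws (zero variance) skip the `p_SW` gate and fall back
  to plain permutation.  The staged reading — gate on `p_D`, then on
  `p_SW`, then permute — is implemented; a branch stopped by a gate
  reports p = 1, which is what makes small `m` conservative.

Screening p-values are reported in the output schema as
`screen_p_*` fields and are never final p-values.

## Simulator

The generator emulates the study conditions of the validation
experiments: per region a pool of 10,000 haplotypes over ~600 sites
whose minor-allele frequencies are drawn from a rare-skewed spectrum.
80% of sites fall below MAF 1%, with the rare band skewed towards
near-singletons (frequency `10⁻⁴·100^(u^2.5)` for uniform u; 10⁻⁴ is
one copy in the pool) as population growth produces, and the common
band log-uniform on [0.01, 0.5] (a neutral 1/f shape).  Besides the
rare fraction itself, this shape reproduces two downstream diagnostics
of the intended data regime: ~5–8% of LF pairs break the doubly-minor
allele-count tie in the risk direction, and the case-enriched selected
pairs carry large statistics relative to their populated-category
counts.  Haplotypes come from a Gaussian-copula latent field: each
haplotype's latent vector is an AR(1) process across sites and a site
carries the minor allele when the latent value is below the normal
quantile of its target frequency.  This keeps per-site frequencies
exact for arbitrarily rare variants — a founder-mosaic scheme would
quantize rare frequencies to multiples of 1/founders — while the
autocorrelation ρ tunes distance-decaying LD: "strong" ρ = 0.98,
"weak" ρ = 0.90, "none" ρ = 0 per adjacent site.  Strong/weak
between-gene LD scenarios take the first/next (or first/last) 50 sites
of one region as the two genes.

Diploids pair two uniformly drawn haplotypes (Hardy–Weinberg).
Case-control panels are rejection-sampled from a logistic penetrance
model: a baseline-only null at 5% prevalence, or main/interaction
effects with the additive, XOR, classical-epistasis or "color" genotype
codings; explicit 3^L penetrance tables cover pure-epistasis models.
With effect terms present the baseline logit is root-found by
Monte-Carlo so the *population* prevalence (not the baseline-genotype
penetrance) hits the target within 0.1 percentage points.  Causal
variant pairs are drawn uniformly among pool sites with MAF ≥ 1% that
satisfy the design class rule (LF iff `n_group·p²q² < 5`): effects on
sub-percent variants would be unobservable at the simulated sample
sizes, and the class rule then separates low-frequency from common
pairs exactly as in the power designs.  LF interaction log-odds-ratios
default to `0.3·|log10(p·q)|`, common ones to log(1.25).

Stratification scenarios combine two pools with independently drawn
frequency spectra and allocate each population's cases and controls in
fixed numbers (largest-remainder rounding of proportion × n).  The
fixed allocation is the point: the data then hold per-population
case/control composition exactly balanced while global label shuffles
do not, so the permutation null is over-dispersed relative to the truth
and the tests go conservative — reproducing the behaviour expected when
structure is unmodelled.  Per-individual random population assignment
would make labels globally exchangeable and hide the effect.

What the simulator does *not* emulate: coalescent genealogies (LD decay
is stationary AR(1), not block-recombinant), sequencing or genotyping
error, missingness (available in the data model but not generated),
covariates, quantitative traits.  Passing calibration tests on these
pools therefore shows the test machinery is correct under realistic
frequency spectra and LD, not that real cohort artefacts are handled.

## Experiment scales and numerical conventions

The test suite runs its four calibration/conservativeness studies at
2,000 replicates each (binomial 95% CI half-width ±0.0044 around 0.01);
the standalone reproduction script uses 5,000 null and LD replicates.
The chi-square-null check uses 10,000 simulated pairs.  Reported rates
use P(p ≤ α).

All tail probabilities are computed in survival-function form; χ² tails
are clamped at 10⁻³⁰⁰ before the normal quantile transform.  The
vectorised engine accumulates C² in float32 (counts are exact in
float32; the statistic's relative error ~10⁻⁵ is far below any
decision boundary) and observed and permuted statistics flow through
the same code path, so exceedance comparisons are internally
consistent; the per-pair reference engine works in float64 and the two
agree to 10⁻⁴ relative on complete data (tested).  Gene-pair random
streams derive from (seed, CRC32(gene1), CRC32(gene2)), making results
independent of scan order, resumption and thread count.  Monomorphic
variants are retained (their pairs classify LF and contribute only
populated categories); exact MAF-0.5 ties keep ALT as the minor allele.

## Known limitations

* No covariate adjustment; stratified samples make the tests
  conservative rather than invalid, but power is lost.
* Hard genotype calls only (no dosages).
* The LF selection rule assumes risk-direction minor alleles;
  protective-direction pairs enter Ψ less often, though mixed-direction
  simulations retain power above the nominal level.
* `p_N` for very large gene pairs (n > 200 common pairs) uses an
  asymptotic tail whose small-β accuracy is untested; it only gates.
* All-pairs genome-wide scans are out of scope; the intended use is a
  candidate pair list.
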
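# Methods

## Model and problem

Scan statistics are modeled as Xᵢ ~ N(μᵢ, 1), i = 1..k, with two-sided
p-values pᵢ = 2Φ(−|Xᵢ|). The estimation target is the noncentrality vector
μ — an estimation problem, not a testing one. Naive estimation (μ̂ = X, the
MLE) is unbiased marginally but badly biased conditionally on selection:
the largest |X| in a scan of millions follow an extreme-value law, not the
Gaussian assumed pointwise, so top hits overstate |μ|.

## FIQT

By the invariance principle, a winner's-curse adjustment may be performed on
any transformed scale and mapped back. Multiple-testing adjustment on the
p-value scale is such an adjustment: it shrinks p toward 1, whose Z-scale
image is 0. FIQT therefore computes BH FDR q-values p* and returns
sign(X)·Φ⁻¹(1 − p*/2). Properties relied on throughout:

- q ≥ p elementwise ⇒ |estimate| ≤ |X| (pure shrinkage);
- BH's step-up monotonicity ⇒ the transform preserves the ranking of |X|;
- k = 1 ⇒ q = p ⇒ identity;
- q = 1 maps to exactly 0 (no epsilon fudging).

FDR is the default adjustment because scan correlations are local and mostly
positive; Bonferroni and Holm are exposed as alternatives but not
benchmarked. (Conventional statements of the Bonferroni rule clip k·p at 1
from above, i.e. min(k·p, 1); that is what is implemented.) Missing
statistics are excluded from the adjustment pool — counting them would
inflate k — and receive missing estimates.

Numerics: the back-transform is evaluated with the log-space inverse normal
CDF (`scipy.special.ndtri_exp`), so any representable positive p (down to
~1e-308) maps to a finite Z ≈ 38 and the transform round-trips |Z| ≤ 37 to
1e-6 relative. Two-sided p that underflow (|Z| ≳ 38.4) are clamped to the
smallest positive normal double before adjustment.

## Empirical Bayes (Tweedie's formula)

For unit Gaussian noise, E[μ|z] = z + d ln f(z)/dz with f the marginal
density of the observed statistics. The density is estimated as in the
classical genome-scan usage: the Z range is cut into 120 equal bins
(`n_bins`, configurable) and bin counts are regressed on bin midpoints with
a Poisson GLM over a natural cubic spline basis. The derivative is the
analytic derivative of the fitted basis expansion; finite differences of
raw counts are never used. Outside the fitted range the derivative clamps
to its boundary value (natural splines are linear beyond the boundary
knots, but data-free extrapolation is still unreliable), with a warning.

The estimator is the full Tweedie formula including the leading z term;
dropping it would make the pure-null estimate −z instead of ≈0 and fail the
Gaussian-prior oracle E[μ|z] = z·τ²/(1+τ²).

Spline flexibility defaults to 7 degrees of freedom (`spline_df`): stiff
enough to stay smooth in sparse tails, flexible enough that the fitted
derivative reproduces −z on pure-null scans and the Gaussian-prior posterior
mean to < 0.05 mean absolute error at k = 2×10⁵. It is a tuning constant,
exposed as a knob.

EB-n splits the statistics into n interleaved sets by genomic order (indices
equal mod n), so set members sit ~n positions apart and are approximately
independent despite LD. Each set's density scores all k statistics and the
n vectors are averaged; n = 1 is bit-identical to the classical estimator.
The per-set vectors are available (`return_set_estimates`) so the averaging
contract is directly testable.

## Tail adjustment

The classical correction for selected statistics: conditional on |Z| > c,
the likelihood of μ is φ(z−μ) / [Φ(μ−c) + Φ(−μ−c)], and the estimate is its
maximizer, found by bounded scalar optimization on μ ∈ [−|z|−1, |z|+1] to
1e-6, solved on |z| with the sign restored so μ̂(−z) = −μ̂(z) exactly.
Estimates are clipped to [0, |z|] on the |z| scale. The selection event is
two-sided, matching the p-value convention. A plug-in mean-bias-subtraction
variant (subtract E[Z|μ,|Z|>c] − μ at μ = z) is available behind a flag but
not benchmarked; the conditional MLE is the primary form. For genome-scale
inputs the MLE is solved on a 600-point |z| grid and interpolated — the
estimate is smooth and monotone in |z| — which matches the exact solver to
~1e-3.

Because TA only adjusts above its threshold while every other method adjusts
the whole scan, benchmark metrics are reported *cumulatively*: at each grid
point t the set S(t) = {i : pᵢ ≤ 10⁻ᵗ} is scored, and TA is re-run at each
threshold, adjusting everything above it (deliberately outside its intended
use). At t = 0 the selection event is certain and TA is the MLE.

## Scan simulator

Under the null, scans are stationary ARMA(3,4) realizations with
AR = (0.8716, 0.9782, −0.851) and MA = (−0.665, −0.998, 0.659, 0.025), a
process previously found adequate for statistics at ~1 SNP/kbp. The AR
polynomial is near unit root (value ≈ 0.0012 at 1), so realizations use a
10,000-step burn-in, and the innovation variance is set from the exact
stationary variance (≈ 1.713 for unit innovations) rather than empirical
rescaling, making the marginal variance exactly 1 in expectation.
`theoretical_acf` (the standard autocovariance recursion, via statsmodels)
provides the exact ACF both as a validation oracle and as the LD-decay
kernel below.

Under the alternative, a height-like trait with m_base = 180 reference loci
is emulated. The published per-locus effects live in supplementary material
that is not distributed here, so the default base profile is a synthetic
stand-in, drawn once from a fixed master seed as 5.45 + Exponential(mean
1.5): every locus genome-wide significant at the reference sample size
(|Z| ≥ 5.45 ⇔ p ≤ 5×10⁻⁸), with a realistically decaying tail. The profile
is pluggable (`SimulationConfig.base_profile`) so real effect lists can be
substituted. **This is the largest interpretive choice in the package**: the
benchmark orderings among estimators at desk scale reflect this profile, not
the published curves, which are not reproducible without the original
recipe. In particular, under the alternative EB-1 attains slightly (~5–10%)
lower full-scan MSE than FIQT with this profile at every scale we measured,
while FIQT keeps the better R² and dominates in the extreme tail.

A design point (k, γₛ, γ_c) takes m₁ = round(γ_c·180) loci chosen uniformly
from the profile, scales them by √γₛ (noncentrality grows with the square
root of sample size), places them at uniform random SNP indices with ≥ 1 Mb
spacing (preventing kernel overlap, so ground truth at each locus is
unambiguous), and adds to each neighbor j of causal SNP i the contribution
μᵢ·ρ(|j−i|), with ρ the process ACF truncated where it drops below 0.01
(width ≈ 823 SNPs ≈ 823 kb per side). Locus choice and placement depend
only on the seed, never on γₛ, so quadrupling the implied sample size
doubles every mean exactly. Positions are laid out at 1 SNP/kbp on a single
synthetic chromosome (splitting is cosmetic). Each replicate draws
independent child seeds for means and residuals from one seed sequence;
fixing `mean_seed` holds the signal layout constant across noise draws.

What the simulator does **not** emulate: allele frequencies, genotypes,
imputation quality, non-stationary LD blocks, population stratification,
or negative local correlations. Passing benchmarks here demonstrate
estimator behavior under locally correlated Gaussian statistics with sparse
strong signals — not performance on any particular real cohort.

## Evaluation

Per threshold and method: MSE, bias, and population variance of the errors
(so MSE = bias² + variance holds exactly on the same sample), and R² as the
squared Pearson correlation between estimates and truth (undefined when
either is constant on S(t), e.g. under the null; the 1 − SSres/SStot
variant is available as `r2_explained`). Metrics are computed per replicate
and averaged, with Monte-Carlo standard errors across replicates;
pooled-SNP computation would weight replicates by tail counts and is not
the default. The default grid is −log₁₀ p ∈ {0, 0.5, …, 8}. A method
failing on a replicate is recorded and excluded for that method only.

Problem sizes in the shipped benchmarks (tests and acceptance script):
k = 10⁵–10⁶ SNPs and 25 replicates, with the full design (k = 2,866,105,
250 replicates) available through the same interfaces.

## Prediction

Noncentralities scale with √n, so estimates from a discovery cohort times
√(n_ratio) are point predictions for a larger cohort; predicted two-sided
p-values below 5×10⁻⁸ (strict inequality, so a statistic exactly at the
threshold is excluded) are called significant, and called variants within
250 kb on a chromosome are merged by single linkage — the standard clumping
reading of "within 250 kb". Region leads are the largest |scaled estimate|,
ties to the smaller position. Overlap counting treats intervals as closed;
a special interval (shipping default in the CLI: extended MHC,
chr6:25–33 Mb) is tallied separately because its long-range LD makes one
signal span many clumps. No error rates attach to predictions: this is a
point prediction, not a test.

## Known limitations

- FIQT provides point estimates only, no standard errors, and is
  conservative (negatively biased) at very small p-values.
- The EB density fit needs k ≫ n_bins statistics; it refuses k < n_bins
  and warns below 10·n_bins.
- Benchmark curves depend on the synthetic effect profile (above).
- The FDR pool uses all non-missing statistics; no LD pruning or
  dependence-adjusted FDR is applied.
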
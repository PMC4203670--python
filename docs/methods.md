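# Methods

## Model

The package works with the panel mixed multinomial logit.  Individual *i*
faces T_i choice situations over J alternatives; conditional on a
coefficient vector β the choice probabilities are conditional logit
(softmax) with the base alternative's systematic utility fixed at 0.  The
mixed coefficients are the alternative-specific constants of the non-base
alternatives (optionally joined by fixed attribute coefficients), drawn once
per individual from N(b, Σ).  The sample log-likelihood integrates the panel
product of logit probabilities over that distribution; the simulated version
replaces the integral with an average over R quasi-random draws per
individual, transformed as β = b + Q z with Q lower-triangular, QQ′ = Σ,
and z standard normal.

Assumptions: the kernel is the linear-in-parameters logit (no nesting, no
nonlinear utility); mixing is multivariate normal (correlation supported
through the full lower triangle of Q); the same draw set serves every
parameter point during optimization, which is what makes simulated
log-likelihood values comparable across parameter points.

## Quadrants

Flipping the sign of any column of Q leaves QQ′ unchanged, so 2^n
factorizations — labelled by the sign pattern of the diagonal, the
"quadrant" — describe one covariance.  Arbitrary *element*-wise sign flips
do not preserve QQ′; column flips are the unique family that does, so
quadrants are defined by column flips throughout.  `quadrant_scan`
re-evaluates the simulated log-likelihood under all 2^n column-flip variants
with one shared draw set; the max-abs difference is the simulation-noise
diagnostic.  The scan defaults to evaluating at the *realized* sample
moments of a synthetic panel (the finite sample's own optimum) rather than
the generating values; both are exposed.

## Draws

Halton sequences are built from the radical inverse of 1, 2, 3, … in one
prime base per mixing dimension.  Defaults and the reasons for them:

- `drop = 10` initial elements are discarded per dimension: the leading run
  of Halton sequences is strongly correlated across bases.  Configurable;
  no particular historical software stream is reproduced.
- Draw-to-individual assignment is contiguous: individual *i* receives the
  next block of base points from each dimension's single continuous stream.
  Antithetic mirror sets must live inside one individual (symmetry across
  individuals would not symmetrize the per-individual panel product), and
  contiguous blocks are deterministic and seed-free.
- `full` antithetics expand each base point into its 2^n coordinate
  complements (mask-ordered: bit k of the mirror index flips dimension k),
  requiring R to be a multiple of 2^n; `one_dim` pairs each point with its
  single global complement, requiring even R.  Invalid R is a hard error
  naming the nearest valid multiples — the adjustment should be a visible
  user decision, so the CLI exposes an explicit `--round-draws up` that logs
  what it did instead of rounding silently.
- Mirrors are applied in *normal* space (sign flips of the normal-mapped
  base points).  This is mathematically identical to complementing in unit
  space, because the normal quantile is antisymmetric about ½, but it makes
  the sign-flip closure of the draw multiset exact in floating point, so the
  quadrant invariance of the simulated likelihood holds to summation-order
  noise (≤ 1e-8; observed ~1e-13) rather than quantile-rounding noise.
- No scrambling, shifting or randomization of Halton points is implemented;
  the only seeded component of the package is the synthetic-data generator.

## Estimation

`MixedLogit` maximizes the simulated log-likelihood with BFGS using
central-difference gradients (relative step 1e-6), gradient max-norm
tolerance 1e-4 and an iteration cap of 500.  The free parameters are the
mixing means, the Choleski entries (diagonal only, unless the starting
factor or `correlated=True` asks for the full triangle), any fixed
constants, and attribute coefficients.  Choleski diagonals are *not*
constrained positive: letting the optimizer roam quadrants is the behaviour
under study.  Results report the signed factor, its quadrant, and the
canonical (non-negative-diagonal) equivalent.

Restrictions: `fix_mean` pins one mean; `fix_sd_zero` removes a mixing
dimension — its constant becomes a fixed coefficient, the restricted mixing
covariance is the original with that row/column deleted, and the draw
configuration is reduced under one of two prime policies.  `keep_assigned`
retains each surviving dimension's original prime; `naive_first` reassigns
the first n−1 canonical primes (what most software does).  A sequence of
restrictions is applied left to right; removing every dimension degrades the
model gracefully to a conventional logit fitted without draws.  Boundary
inference caveat: zero-SD restrictions sit on the boundary of the parameter
space, where the plain chi-square reference distribution used here (and
conventionally) is not strictly correct; no mixture-chi-square correction is
applied.

Negative LR statistics are flagged, never clipped; p-value summaries in
cross-quadrant reports cover the non-negative statistics only, since the
negative share is itself the diagnostic.  `cross_quadrant_lr` accepts scans
of different quadrant counts (rectangular matrices) so dimension-reducing
restrictions can be crossed with unrestricted scans.

## Synthetic data

`simulate_panel` draws each individual's constants from N(b, Σ), then picks
the utility-maximizing alternative under independent Gumbel(0, 1) noise —
distributionally identical to sampling from the logit probabilities, chosen
to mirror the utility-maximization story.  One generator stream is consumed
in a fixed order (coefficients first, then noise situation-major), so a
`SimSpec` reproduces its panel bit for bit.  Realized sample moments of the
latent coefficients are recorded; they, not the generating values, are the
finite sample's "true optimum".

Defaults are 1,000 individuals × 20 choices × 4 alternatives with
independent unit-variance constants of mean 1.  The experiments and tests
run a desk-scale variant — I = 200, T = 10, R ∈ {96, 480, 1024, 4096}
(multiples of 8) — chosen so the full suite runs in well under a minute
while preserving every qualitative phenomenon; quantities measured at this
scale (quadrant spreads, negative-LR shares, prime gaps) are smaller than at
full scale but behave identically.  Two presets set study regimes:

- `mildly-false-mean` (mean 0.1 on the first constant): a zero-mean
  restriction on that constant costs roughly as much log-likelihood as the
  conventional-draw quadrant spread at R ≈ 100, the regime in which
  cross-quadrant LR statistics go negative and p-values scatter.  The 0.1
  was fixed from the back-of-envelope cost 0.5·p(1−p)·b²·IT ≈ 2 LL units at
  I = 200, T = 10, matched to the few-unit quadrant spread there.
- `paper-like-c` (SD 0.1 on the middle constant): a nearly-true zero-SD
  restriction on a middle dimension, which is also the case where the two
  prime policies actually differ ({2,5} vs {2,3} after removing the second
  of three dimensions).

What the generator does not emulate: attribute-rich designs (it generates
constants-only panels, though the likelihood supports attributes),
non-normal mixing, serial dependence within individuals, and unbalanced
panels (supported by the data structures, not generated).  Passing tests
therefore demonstrate the draw-symmetry mechanics and estimator correctness
under the model's own assumptions, not robustness to misspecification.

## Numerical choices

- All panel products and draw averages are computed in log space with
  per-individual log-sum-exp; softmax uses max subtraction.  An individual
  whose averaged probability still underflows is reported by id.
- Constants-only panels use a closed-form reduction (choice counts × draw
  constants − T·logsumexp), making likelihood evaluation O(I·R·J) instead of
  O(I·R·T·J); panels with attributes take the general path.  Both paths are
  tested against a per-situation product oracle.
- Quadrant-invariance tolerance under full antithetics is 1e-8 absolute,
  covering floating-point summation order; the far looser published-style
  bounds (~2×10⁻⁴) reflect optimizer precision, not evaluation noise.
- Ties in the synthetic argmax go to the lowest alternative index (a
  probability-zero event under continuous noise).

## Known limitations

- Fully antithetic draws need R to be a multiple of 2^n, impractical for
  high-dimensional mixing; the package targets small n.
- Standard errors (robust or otherwise) are not computed; inference is by
  LR tests only.
- Halton coverage degrades in high dimensions and no scrambling is offered.
- The optimizer is a single-start quasi-Newton; `starting_value_sweep`
  provides multi-start robustness checks but no global-search guarantee.
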
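# Methods

## Generative model

One simulated 2AFC experiment consists of `n` trials (reference scale
4×10⁶; both identities occur exactly `n/2` times — the first half of
the table is `I = 1`, the second `I = −1`, and every analysis is
exchangeable over trial order). Per trial:

1. discriminability `d ≥ 0` is drawn i.i.d. from the design prior;
2. identity evidence `e_I ~ N(d·I, σ_I)` with `σ_I = 1` by default;
3. under the general model, discriminability evidence
   `e_d ~ N(d, σ_d)`, independent of `I` given `d`;
4. choice `ϑ = −1` iff `e_I < 0`, else `+1` (the tie `e_I = 0`, a
   probability-zero event, deterministically maps to `+1`);
5. accuracy `A = 1[ϑ = I]`.

A single `numpy` PCG64 generator per experiment, seeded from the
config, draws in the fixed order `d`, `e_I`, `e_d`; experiments are
bit-for-bit reproducible.

The observer is *ideal*: it knows the true prior, `σ_I` and `σ_d`.
Observer misestimation (model mismatch), response times, lapses, and
non-deterministic choice rules are out of scope.

## Design priors

Nine difficulty distributions make up the main grid: discrete uniform
on {0,1}, {0,1,2}, {0,1,2,3,4}; continuous uniform on [0,1], [0,2],
[0,4]; gamma with (shape, rate) = (1,2), (1.5,1.5), (2,1) — the gamma
settings pair with the discrete uniforms by mean and variance and are
treated as fixed design constants. Two further standard-model families
probe grid resolution (discrete uniforms over [0,4] with 3, 5, 9, 17
levels) and two-point designs {0, m}, m ∈ {1, 2, 3, 10}. The
general-model grid crosses the nine priors with
`σ_d ∈ {1/10, 1/3, 1, 10}` (36 experiments).

## Posterior computation

Confidence is the posterior probability of the chosen identity under
the generative model, computed from Bayes' theorem with a symmetric
identity prior. The discrete sum over difficulty levels and the
continuous integral share one code path: a prior exposes quadrature
nodes and weights, exact for discrete supports and Gauss–Legendre for
continuous ones. The standard model is the same expression with the
`e_d` likelihood factor dropped (equivalently, constant across
levels) — no separate derivation.

Numerical choices:

* **Log-space accumulation.** At `d = 10`, `σ_I = 1`, raw Gaussian
  densities underflow doubles; all products are summed with a
  max-subtraction log-sum-exp. The `e_I²` term common to both
  identities is cancelled analytically, leaving a rank-one cross term —
  this halves the per-trial work. A local row-wise log-sum-exp is used
  in the hot loop (~4× faster than the general-purpose library
  routine, identical semantics).
* **Quadrature order.** Continuous uniform priors use a 256-node rule
  on their support; gamma priors use 384 nodes on `[0, q]` with `q`
  the `1 − 10⁻¹⁰` quantile (negligible truncated mass), weights
  proportional to the density and renormalised to sum to 1 within
  10⁻⁹. Convergence is spectral for the Gaussian-likelihood
  integrands: the measured worst-case confidence error against a
  2000-panel composite reference is ≤ 3×10⁻⁸ over all nine priors and
  all `σ_d` levels; the ~10⁻⁶ floor for gamma(1.5, 1.5) stems from the
  density's root singularity at 0 and is far below every Monte Carlo
  tolerance used anywhere in the package.
* **Vectorised scoring** processes trials in blocks of 8192 rows to
  bound peak memory; block results equal the scalar operation exactly.

Because the scorer is the true generative posterior, confidence is
calibrated by construction: trials binned by confidence have empirical
accuracy equal to mean bin confidence up to sampling error. The test
suite uses this as its strongest oracle (20 equal-count bins, 4
binomial-SE bands, with an exact binomial test in near-degenerate bins
where the normal approximation fails), alongside an independent
direct-summation implementation of the posterior for discrete priors
(agreement to 10⁻¹²), the `σ_d → ∞` reduction to the standard model
(checked at `σ_d = 10⁹`, tolerance 10⁻⁶), and the known-`d` logistic
closed form `1/(1 + exp(−2·d·e_I/σ_I²))` recovered at `σ_d = 10⁻³`
(tolerance 10⁻⁴).

## Curves, pattern classification, entropy

Confidence curves average confidence per difficulty level separately
for correct and incorrect trials — exact support values for discrete
priors, 10 equal-width bins over `[0, max d]` (configurable) for
continuous ones, matching the granularity at which such curves are
usually plotted. Cells with no trials of a class are reported absent
(NaN), never zero, and are dropped from slope fits; with fewer than
two populated levels in a class the classification raises rather than
guesses (at desk scales this genuinely happens for the {0, 10} design,
where errors at `d = 10` have probability Φ(−10) ≈ 8×10⁻²⁴).

Pattern labels come from count-weighted least-squares slopes of mean
confidence on level: `folded_X` when the correct-branch slope exceeds
`τ` and the incorrect branch falls below `−τ`; `double_increase` when
both exceed `τ`; otherwise `flat`. The threshold `τ = 0.005`
confidence-units per discriminability-unit (configurable) separates
real trends from Monte Carlo noise at the trial counts used here.

`H(A|c)` uses the natural logarithm; the base only rescales the
comparison and is recorded in output metadata (`log_base: e`). The
identity-only vs. full comparison scores the *same* simulated trials
with both engines (paired design); the reported `se_diff` is the
standard error of the paired per-trial difference and backs the
"never worse" statements at 3 SE.

## Simulation scales

Campaigns default to `scale = 0.025` of the 4×10⁶-trial reference
(10⁵ trials per experiment), the package's desk-scale choice: at 10⁵
trials every qualitative label and entropy ordering is stable (the
suite checks label agreement between scales 0.25 and 0.025), while a
full-scale replication is one flag away (`--scale 1.0`). Calibration
oracles run at 4×10⁴ trials per prior/model pair, where the binomial
4-SE band (~0.045 per bin) dwarfs the ≤10⁻⁶ numerical error of the
posterior. Neutral-evidence confidence is evaluated by direct
conditioning on `d = 0` with 10⁵ evidence draws rather than by
selecting simulated trials near zero — for continuous priors
`P(d = 0) = 0`, and the claims concern exactly neutral stimuli.

## What the simulations do and do not show

The generator realises the models' own assumptions (Gaussian evidence,
ideal observer, deterministic choice). Passing tests therefore
demonstrate internal consistency and the statistical consequences of
those assumptions — which confidence patterns follow from which
designs — not that any empirical observer behaves this way. Asymmetric
identity priors, non-Gaussian evidence, confidence-rating
discretisation and fits to human data are explicitly out of scope.
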
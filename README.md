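# confsig

Monte Carlo simulation and analysis of **Bayesian models of decision
confidence** in two-alternative forced-choice (2AFC) tasks, for
computational cognitive scientists and psychophysicists who use
statistical signatures of confidence (the *folded X-pattern*) to
identify confidence correlates in behavioural or neural data.

## The models

A stimulus has an identity `I ∈ {−1, 1}` (which option is correct) and
a nonnegative discriminability `|d|` (how easy the choice is), drawn
from the experiment's design distribution `p(d)`. The observer receives
noisy identity evidence `e_I ~ N(d·I, σ_I)`, chooses `ϑ = sign(e_I)`,
and reports **objective confidence**: the posterior probability that
the choice is correct given the evidence.

* **Standard model** — the observer has no trial-by-trial information
  about difficulty and marginalises over `p(d)`:
  confidence is `p(A = 1 | e_I, ϑ)`. This produces the folded
  X-pattern: confidence rises with `|d|` in correct choices, falls in
  incorrect ones, and equals 0.75 at `d = 0` — but the 0.75 holds
  *only* for a continuous uniform difficulty distribution reaching high
  discriminability.
* **General model** — the observer additionally receives
  discriminability evidence `e_d ~ N(d, σ_d)` (independent of `I`) and
  computes

  ```
  p(I=1 | e_I, e_d) =   Σ_k p(d_k) N(e_I; d_k, σ_I) N(e_d; d_k, σ_d)
                      ─────────────────────────────────────────────────
                      Σ_{j∈{−1,1}} Σ_k p(d_k) N(e_I; j·d_k, σ_I) N(e_d; d_k, σ_d)
  ```

  When `e_d` is reliable (small `σ_d`), confidence rises with `|d|` in
  both correct *and* incorrect choices (the *double-increase pattern*)
  and collapses to 0.5 at `d = 0`.

How well confidence predicts accuracy is measured by the conditional
entropy `H(A|c) = −(1/n) Σ_j log(A_j c_j + (1−A_j)(1−c_j))` (nats);
confidence that uses `e_d` never predicts accuracy worse than
confidence that ignores it.

For continuous difficulty distributions the marginalisation over `d`
uses a deterministic Gauss–Legendre rule; all likelihood products are
accumulated in log space.

## Worked example

```python
from confsig import DiscriminabilityPrior, ExperimentConfig, neutral_confidence

D = DiscriminabilityPrior
for name, cfg in [
    ("uniform[0,4], standard", ExperimentConfig(prior=D.continuous_uniform(0, 4), n_trials=2)),
    ("{0,2,4}, standard",      ExperimentConfig(prior=D.discrete_uniform([0, 2, 4]), n_trials=2)),
    ("{0,1,2}, general σ_d=0.1", ExperimentConfig(prior=D.discrete_uniform([0, 1, 2]),
                                                  sigma_d=0.1, n_trials=2)),
]:
    print(name, neutral_confidence(cfg, n_eval=100_000, seed=7))
```

prints

```
uniform[0,4], standard 0.7493
{0,2,4}, standard 0.6353
{0,1,2}, general σ_d=0.1 0.5000
```

i.e. mean confidence for exactly neutral stimuli (`d = 0`) is 0.75
only under the continuous uniform design; a coarse three-point design
yields ≈0.64, and reliable discriminability evidence reveals the trial
is hopeless, driving confidence to chance. The scripts in `examples/`
walk through the confidence curves, pattern classification
(`folded_X` / `double_increase` / `flat`) and the `H(A|c)` comparison;
each prints the numbers it computes and what they mean.

A thin CLI mirrors the library for campaign-scale runs:

```
confsig run --campaign std_distributions --seed 1 --scale 0.025 --out out/
confsig neutral --prior cunif:0,4 --sigma-i 1 --n 100000 --seed 1
```

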
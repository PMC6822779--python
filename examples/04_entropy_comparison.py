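"""Does using discriminability evidence make confidence more accurate?

Scores the same simulated trials twice — once with the full posterior
(identity and discriminability evidence) and once ignoring e_d — and
compares the conditional entropy of accuracy given confidence,
H(A|c) = mean negative log probability assigned to the realised
accuracy (nats).  Lower is better.
"""

from confsig import DiscriminabilityPrior, ExperimentConfig, entropy_comparison

prior = DiscriminabilityPrior.discrete_uniform([0, 1, 2])
print("sigma_d   H(A|c) e_I only   H(A|c) e_I and e_d")
for sigma_d in (0.1, 1 / 3, 1.0, 10.0):
    cfg = ExperimentConfig(prior=prior, sigma_d=sigma_d, n_trials=100_000, seed=11)
    es = entropy_comparison(cfg)
    print(f"{sigma_d:7.2f}   {es.H_identity_only:15.4f}   {es.H_with_discriminability:18.4f}")

print("\nReliable discriminability evidence (small sigma_d) lowers the "
      "prediction error of confidence; useless evidence (sigma_d = 10) "
      "leaves it unchanged — but it never hurts.")
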
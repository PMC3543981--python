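"""Estimate ancestry proportions for admixed individuals with the
two-step procedure: supervised EM fit, bootstrap standard errors, and
denoising down to the statistically supported source populations.

Builds a small synthetic three-population panel, simulates 20 targets
that are a 60/40 Europe/Africa mix, and prints the mean estimates
before and after denoising.
"""

import numpy as np

from admixkit import SimulationSpec, simulate_admixed_targets, \
    simulate_frequencies, simulate_reference_panel, two_step_estimate

spec = SimulationSpec(
    populations=["Europe", "Africa", "America"],
    fst=[0.09, 0.25, 0.25],
    J=4000,
    n_ref=60,
    targets=[(20, [0.6, 0.4, 0.0])],
    seed=42,
)
F = simulate_frequencies(spec)
panel = simulate_reference_panel(spec, F)
targets, q_true = simulate_admixed_targets(spec, F)

res = two_step_estimate(panel, targets, n_reps=50, seed=7)

print("population      truth   first-pass   denoised   mean-SE")
for k, pop in enumerate(spec.populations):
    print(f"{pop:<14} {q_true[0, k]:>6.2f} {res.first_pass.Q[:, k].mean():>11.4f} "
          f"{res.denoised.Q[:, k].mean():>10.4f} {res.bootstrap.SE[:, k].mean():>9.4f}")

n_zeroed = sum("America" not in kept for kept in res.denoised.retained)
print(f"\nAmerica zeroed for {n_zeroed}/20 targets: the denoising step drops "
      "populations whose estimate minus twice its bootstrap SE is <= 0, so "
      "the small spurious America fraction in the first pass disappears "
      "while the true Europe/Africa mix is refined toward 0.6/0.4.")
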
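"""Cross-validate the pipeline on a noisy synthetic screen.

A 60-drug screen is sampled from a known Boolean survival pathway with
Gaussian noise on the sensitivities; leave-one-out and repeated 10-fold
cross-validation retrain target selection and the TIM for every split
and report the mean absolute prediction error and Pearson correlation.
"""

import numpy as np

from timkit import (
    generate_library,
    generate_pathway,
    kfold_evaluate,
    loo_evaluate,
    screen_from_library,
)

rng = np.random.default_rng(11)
pathway = generate_pathway(6, rng)
library = generate_library(pathway, 500, rng)
panel = library[rng.choice(500, size=60, replace=False)]
drugs = screen_from_library(panel, pathway, noise_sigma=0.05, seed=rng)

loo = loo_evaluate(drugs)
print(f"LOO:     MAE = {loo.mae:.3f}   Pearson r = {loo.pearson_r:.3f}")

kf = kfold_evaluate(drugs, k=10, repeats=5, seed=1)
print(f"10-fold: MAE = {kf.mae:.3f}   Pearson r = {kf.pearson_r:.3f}  (5 repeats)")

print(loo.to_frame().head(8).to_string(index=False))
print(
    "\nEach row compares the withheld drug's predicted and measured "
    "sensitivity; MAE near the noise level (0.05) means the map, not "
    "memorization, carries the prediction."
)
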
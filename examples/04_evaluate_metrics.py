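"""Score imputed compositions against the simulation truth with the
fifteen-metric battery (all oriented so that smaller is better).
"""

import numpy as np

from bmdd import FitConfig, default_bimodal_hyperparams, default_depths, evaluate, fit, simulate_bmdd
from bmdd.impute import naive_impute, posterior_mean

rng = np.random.default_rng(7)
hp = default_bimodal_hyperparams(m=50, seed=7)
W, truth = simulate_bmdd(hp, n=60, depths=default_depths(60, rng), seed=8)

_, state = fit(W, FitConfig(seed=0))
est = posterior_mean(state, sample_ids=W.sample_ids, taxon_ids=W.taxon_ids)
base = naive_impute(W, "naive2")

r_model = evaluate(est, truth.composition, method="posterior_mean")
r_base = evaluate(base, truth.composition, method="pseudocount")

print(f"{'metric':>16}  {'posterior':>10}  {'pseudocount':>11}")
for name, score in r_model.scores.items():
    print(f"{name:>16}  {score:10.4f}  {r_base[name]:11.4f}")
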
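"""Compare confidence efficiency with the M-ratio on the same data.

Simulates one experiment, computes the model-based efficiency eta and
the standard meta-d'/d' ratio, and shows the square-law relation
eta ~ M-ratio^2.
"""

import numpy as np

import cncb

sens = cncb.SensoryParams(mu=np.array([-0.67, 0.67]))
b = cncb.calibrate_boundaries(sens, 0.5, 0.2, [0.25] * 4)
conf = cncb.ConfidenceParams(0.5, 0.2, b)
design = cncb.SimulationDesign(n_trials=10_000, n_levels=4, seed=7)
_, counts = cncb.simulate_dataset(sens, conf, design)

fit = cncb.fit_cncb(counts)
eff = cncb.cncb_efficiency(fit)
md = cncb.fit_metad(counts)

print(f"d'      = {md.d_prime:.2f}   (Type 1 sensitivity)")
print(f"meta-d' = {md.meta_d:.2f}   (Type 2 sensitivity in d' units)")
print(f"M-ratio = {md.m_ratio:.2f}")
print(f"eta     = {eff.eta:.2f}   (model-based confidence efficiency)")
print(f"M-ratio^2 = {md.m_ratio**2:.2f}")
print("\neta and the squared M-ratio agree closely for unbiased observers; "
      "the model-based\nmeasure additionally separates confidence noise "
      f"(est. {fit.conf.sigma_c:.2f}) from confidence\nboost "
      f"(est. {fit.conf.alpha:.2f}), and stays stable when the sensory "
      "criterion is biased,\nwhere the M-ratio does not.")
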
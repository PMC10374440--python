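"""Fit the melting sigmoid and derive melting point and melting AUC.

Simulates one noisy melting curve, fits f(T) = (1-p)/(1+exp(b-a/T)) + p,
and reports the fitted parameters, the temperature where the curve crosses
0.5 (Tm) and the area under the fitted curve over the experimental window.
"""

import numpy as np

from meltforms import fit_sigmoid, melting_auc, melting_point, sigmoid

temps = np.array([41.0, 44.0, 47.0, 50.0, 53.0, 56.0, 59.0, 63.0])
rng = np.random.default_rng(1)

tm_true = 52.5
y = sigmoid(temps, 50.0 * tm_true, 50.0, 0.0) + rng.normal(0, 0.02, 8)

fit = fit_sigmoid(temps, y)
print(f"fitted a={fit.a:.1f}, b={fit.b:.2f}, p={fit.p:.3f}, "
      f"S_res={fit.s_res:.4f}, accepted={fit.accepted}")
print(f"melting point Tm = {melting_point(fit):.2f} C (true {tm_true})")
print(f"melting AUC over 41-63 C = {melting_auc(fit):.2f} C x fold change")
# Tm is the temperature at which half the protein has aggregated; the AUC
# summarizes overall thermal stability even for curves that never cross 0.5.
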
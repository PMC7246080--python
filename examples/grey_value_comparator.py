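"""Gas sensitivity of intensity-based registration vs the wall feature.

Runs paired trials in which the same pretreatment anatomy is registered
against the planning image with and without a rectal gas pocket, using the
correlation-ratio grey-value match within the CTV + 5 mm region.  The wall
contours are identical in both arms, so feature-based prediction is
unaffected; only the intensity comparator reacts to the gas.
"""

import numpy as np

import ctvshift as cs
from ctvshift.evaluation import gas_sensitivity_trial

params = cs.GeneratorParams()
gas, nogas = [], []
for seed in range(10):
    trial = gas_sensitivity_trial(params, seed=40 + seed)
    gas.append(trial["error_gas"])
    nogas.append(trial["error_nogas"])

print(f"grey-value match error, gas inserted : {np.mean(gas):.2f} mm")
print(f"grey-value match error, gas-free     : {np.mean(nogas):.2f} mm")
print(f"error increased in {sum(g > n for g, n in zip(gas, nogas))}/10 paired trials")
print("\nGas only relabels pixels inside the rectal lumen; the wall contour -")
print("and with it feature f3 and the model prediction - does not move.")
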
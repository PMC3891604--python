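"""ON/OFF switching rates from a hysteresis experiment, plus the dilution null.

Simulates ON-pregrown and OFF-pregrown cultures relaxing toward the
stationary ON fraction in a glucose/maltose mixture, estimates the
per-generation switching probabilities from the paired endpoints, and
contrasts a protein signal with the pure-dilution null model.
"""

import numpy as np
import pandas as pd

from lagfit.switching import dilution_null, estimate_switch_rates, production_rate
from lagfit.synth import gen_on_fraction

a_true, b_true = 0.06, 0.025
on, off = gen_on_fraction(a_true, b_true, f0_on=0.95, f0_off=0.05,
                          generations=10, n_cells=10_000, seed=11)

print("generations:", on.generations.astype(int).tolist())
print("ON-pregrown :", np.round(on.frac_on, 3).tolist())
print("OFF-pregrown:", np.round(off.frac_on, 3).tolist())

rates = estimate_switch_rates(on, off)
print(f"\nestimated a (ON->OFF) = {rates.a:.4f}  (true {a_true})")
print(f"estimated b (OFF->ON) = {rates.b:.4f}  (true {b_true})")
print(f"memory lam = {rates.lam:.3f}, stationary ON fraction = {rates.f_stationary:.3f}")

# protein signal: constant synthesis s against 2-fold dilution per generation
s = 150.0
f = [1200.0]
for _ in range(6):
    f.append(f[-1] / 2.0 + s)
series = pd.DataFrame({"generations": np.arange(7.0), "mean_signal": f})
print(f"\nMalS-like signal at g=6: {f[-1]:.0f} A.U.; "
      f"dilution null predicts {dilution_null(f[0], 6.0):.0f} A.U.")
print(f"production rate over final two points: {production_rate(series):.1f} A.U./generation")
print("\nSignal far above the dilution null means cells keep synthesising the")
print("protein; the hysteresis gap closing over ~lam^g generations sets the")
print("population's memory of its expression history.")
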
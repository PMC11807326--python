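"""ADC and K^trans map reconstruction on forward-simulated signals.

Computes an ADC value from a two-b-value DWI signal pair, then generates
a DCE concentration-time curve with the standard Tofts model and inverts
it back to (K^trans, v_e).
"""

import numpy as np

from gliohab import (
    DwiPair, ToftsParams, compute_adc, default_time_grid, fit_tofts,
    population_aif, tofts_concentration,
)

# --- ADC: S_b = S_0 exp(-b D) with D = 1100e-6 mm^2/s
s0 = np.array([[1200.0]])
sb = s0 * np.exp(-1000 * 1100e-6)
adc = compute_adc(DwiPair(s0, sb, b1=1000))
print(f"ADC from signal ratio: {adc.adc[0, 0]:.1f} x1e-6 mm^2/s (truth 1100)")

# --- Tofts: 30 phases over 4.7 min, biexponential population AIF
t = default_time_grid()
cp = population_aif(t)
truth = ToftsParams(ktrans=0.06, ve=0.2)  # typical low-permeability tumor tissue
ct = tofts_concentration(truth, t, cp)
fit = fit_tofts(ct, t, cp)
print(f"Tofts inversion: K^trans {fit.params.ktrans:.4f} /min (truth {truth.ktrans}), "
      f"v_e {fit.params.ve:.4f} (truth {truth.ve}), residual {fit.residual_norm:.2e}")
# On noiseless curves the nonlinear least-squares inversion recovers the
# generating parameters to well under 1%.
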
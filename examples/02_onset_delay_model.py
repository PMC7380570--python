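"""Fit a decay curve with a delayed onset of exponential decay.

After rifampicin blocks transcription initiation, polymerases already on
the gene keep elongating, so an mRNA's level can stay flat for a short
delay tau before declining.  The delay model is flat up to tau and linear
in ln(intensity) afterwards, with tau chosen on a grid by least squares.
"""

import numpy as np

from rifdecay import DecaySeries, fit_decay_with_delay, fit_exponential_decay

# synthetic series: flat for 1.5 min, then decay with t1/2 = 4 min
rng = np.random.default_rng(0)
t = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 7.0, 9.0, 11.0])
tau_true, halflife_true = 1.5, 4.0
y = 6.0 - (np.log(2) / halflife_true) * np.maximum(0.0, t - tau_true)
y += rng.normal(0, 0.03, t.size)
series = DecaySeries("dps", "P1", t, y)

plain = fit_exponential_decay(series)
delayed = fit_decay_with_delay(series, delay_grid=np.arange(0, 3.25, 0.25))

print(f"true parameters:       tau = {tau_true} min, t1/2 = {halflife_true} min")
print(f"no-delay fit:          t1/2 = {plain.halflife_min:.2f} min "
      f"(cv {plain.cv_percent:.1f}%, R^2 {plain.r_squared:.4f})")
print(f"delayed-onset fit:     tau = {delayed.delay_min} min, "
      f"t1/2 = {delayed.halflife_min:.2f} min "
      f"(cv {delayed.cv_percent:.1f}%, R^2 {delayed.r_squared:.4f})")
print("\nignoring the onset delay flattens the apparent slope, so the")
print("no-delay half-life is biased upward; the delay model removes that bias.")
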
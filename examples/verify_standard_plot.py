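"""Verify a fitted density-yield curve against a conventional plot.

The gradient-density method is only useful if its fitted curve predicts
yields measured the traditional way.  Here a standard plot (4 fixed
densities x 3 replicates) is simulated at the published noise level, the
published Zhengdan 958 curve is rescaled to absolute yield via the plot's
reference density, and measured is regressed on simulated.
"""

import densyield as dy
from densyield import reference as ref

truth = dy.default_truth()
standard = dy.simulate_standard_plot(truth, variety="ZD958", seed=11)

v = dy.verify_against_standard(ref.hoerl_params("ZD958"), standard)

print(f"regression of measured on simulated: slope {v.slope:.3f}, "
      f"intercept {v.intercept:.1f} g/m^2")
print(f"accuracy (squared correlation): {v.accuracy:.4f}")
for density, dev in v.deviations:
    print(f"  density {density:>4.1f} plants/m^2: deviation {dev:+.2f}%")
print(f"mean |deviation|: {v.mean_abs_deviation:.2f}% — per-density yields "
      "agree to a few percent.  The r^2 is noisy on a single 4-density plot "
      "because the curve is nearly flat between 4.5 and 9.0 plants/m^2; "
      "per-density deviations are the sharper check.")
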
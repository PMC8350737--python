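"""Fit the glf transporter constants from a batch co-fermentation course.

Generates a synthetic 65 h glucose/xylose depletion course with 2%
multiplicative measurement noise from known ground-truth kinetics, then
estimates the six constants (Vmax, Km, Ki per sugar) by multi-restart least
squares and prints the recovered values next to the truth.
"""

import zymoflux as zf

spec = zf.SyntheticBatchSpec(noise_cv=0.02, seed=4)
course = zf.generate_fermentation(spec).noisy

fit = zf.fit_transporter(course, n_restarts=4, seed=0)

print("parameter        truth     fitted   (units)")
units = {"vmax": "mmol/gDCW/h", "km": "mM", "ki": "mM"}
for name in ("vmax_glc", "km_glc", "ki_glc", "vmax_xyl", "km_xyl", "ki_xyl"):
    u = units[name.split("_")[0]]
    print(f"{name:9s} {getattr(spec.true_params, name):10.2f} "
          f"{getattr(fit.params, name):10.2f}   ({u})")
print(f"\nR^2 = {fit.r_squared:.4f} over both sugar channels")
print("Vmax and the xylose constants come back tightly; the glucose Km and "
      "the Ki's sit on a flat likelihood ridge and are only loosely pinned "
      "by a single batch course.")
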
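"""How robust is an inferred causal direction to measurement error?

The Steiger comparison is made on *observed* correlations, which are
attenuated versions of the true ones.  This example reproduces the worked
case of an instrument explaining 1% of the exposure's variance, with the
exposure explaining 10% of the outcome's variance, and asks: over all
admissible amounts of measurement error in the two traits, how much of that
space still supports the inferred direction?
"""

import math

import causaldir as cd

r_gx = math.sqrt(0.01)          # observed instrument-exposure correlation
r_gy = r_gx * math.sqrt(0.1)    # implied instrument-outcome correlation

res = cd.reliability_R(r_gx, r_gy, grid_resolution=500)
print(f"observed correlations: r_gx = {r_gx:.4f}, r_gy = {r_gy:.4f}")
print(f"inferred direction: {res.direction}")
print(f"volume supporting the inference: {res.vol_support:.5f}")
print(f"volume opposing  the inference: {res.vol_oppose:.5f}")
print(f"reliability ratio R = {res.R:.2f}")
print()

# a user-specified measurement-error scenario: exposure measured much more
# noisily than the outcome
point = cd.MeasurementErrorPoint(rho_xxo=0.15, rho_yyo=0.95)
z = cd.predicted_surface(r_gx, r_gy, point)
print(f"at rho_x,xo = {point.rho_xxo}, rho_y,yo = {point.rho_yyo}: "
      f"corrected r_gy - r_gx = {z:+.4f}")
print("a positive value means that much differential error would flip the")
print(f"call; R = {res.R:.2f} says {res.R:.2f} times more of the admissible")
print("error space supports the inferred direction than opposes it.")
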
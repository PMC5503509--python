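"""Fit a Young's modulus from a single synthetic AFM approach curve.

Generates a noiseless force-extension record for a 70 kPa basement
membrane (the wild-type stage-7 follicle center), calibrates the
cantilever from a thermal trace, and runs contact detection plus the
50 nm Hertz fit.
"""

from follimech import (
    GeneratorConfig,
    analyze_curve,
    calibrate_spring_constant,
    get_preset,
    make_force_curve,
    make_thermal_trace,
)

config = GeneratorConfig(seed=1)

# equipartition calibration: k = kB*T / var_p(thermal deflection)
trace = make_thermal_trace(config, 2**17)
k = calibrate_spring_constant(trace, config.temperature)
print(f"calibrated spring constant: {k * 1e3:.3f} pN/nm (nominal 10)")

e_true = get_preset(7, "WT").modulus("central")
curve = make_force_curve(config, e_true)
fit = analyze_curve(curve, k, config.tip_geometry())

print(f"true modulus:   {e_true / 1e3:.1f} kPa")
print(f"fitted modulus: {fit.modulus / 1e3:.2f} kPa "
      f"(relative residual {fit.relative_residual:.2e})")
print("The fit inverts F = C*E/(1-nu^2)*tan(theta)*delta^2 over the first "
      "50 nm of indentation, which isolates the thin basement membrane "
      "from the softer tissue beneath.")
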
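# follimech

Quantitative biomechanics of basement-membrane-bounded organs.

Developing organs are shaped by forces, and in the *Drosophila* ovarian
follicle the decisive mechanical element is not the cells but the thin
(~150 nm) basement membrane (BM) sheet that encases the organ. During
oogenesis the follicle elongates more than two-fold along its
anterior–posterior (A–P) axis, and the BM develops a matching stiffness
pattern: soft at the poles, stiffest at the center, and highly uniform
around the circumference. `follimech` implements the complete
measurement chain with which such a gradient is established and
characterized:

- **AFM force spectroscopy** (`follimech.afm`) — thermal (equipartition)
  spring-constant calibration, `k = k_B T / var_p(d)`; robust contact-point
  detection; conversion of piezo extension *z* and cantilever deflection
  *d* into force and indentation, `F = k (d − d₀)`,
  `δ = (z − z₀) − (d − d₀)`; and a Hertz/Sneddon fit for a pyramidal
  indenter,

  F = C · E/(1 − ν²) · tan θ · δ²,  C = 1/√2 (four-sided pyramid),

  restricted to the first 50 nm of indentation so the estimate reflects
  the BM rather than the tissue beneath. A closed-form linearized
  estimator (slope of F against δ²) cross-checks the nonlinear fit.
- **Stiffness mapping** (`follimech.stiffness`) — per-follicle
  pole/terminal/central region means, the anisotropy index (central
  stiffness over the mean of the five A–P sample positions), regional
  percent differentials, circumferential coefficient of variation
  (population variance), and Welch t-tests with star annotations.
- **Surface unrolling** (`follimech.surface`) — ellipsoid extraction
  from a 3D shell stack and a maximum-intensity pullback (±3 µm band)
  onto an (A–P arc fraction × azimuth) chart, with line-profile and
  structure-tensor fibril-orientation quantification.
- **Epithelial assays** (`follimech.epithelium`) — junction-polarity
  intensity ratios (A–P = 60–90°, circumferential = 0–30° to the A–P
  axis) and laser-ablation recoil velocities from the first post-cut
  frame within 300 ms.
- **Osmotic swelling** (`follimech.swelling`) — burst detection from
  frame-to-frame area drops, burst timing, A–P position of the breach,
  and pre-burst aspect ratios, with cohort tables.
- **Synthetic data** (`follimech.synthetic`) — seeded forward models for
  every input class, with stage/genotype presets (wild type, *fat2*,
  collagenase, Collagen-IV/SPARC depletion, EHBP1 or Perlecan
  overexpression, regional drivers, JAK/STAT inhibition) whose ground
  truth anchors every test.

## Worked example

```python
from follimech import (GeneratorConfig, analyze_curve, calibrate_spring_constant,
                       get_preset, make_force_curve, make_thermal_trace)

config = GeneratorConfig(seed=1)
k = calibrate_spring_constant(make_thermal_trace(config, 2**17), config.temperature)
curve = make_force_curve(config, get_preset(7, "WT").modulus("central"))
fit = analyze_curve(curve, k, config.tip_geometry())
print(f"{k*1e3:.3f} pN/nm, {fit.modulus/1e3:.2f} kPa")
```

prints

```
10.032 pN/nm, 70.22 kPa
```

— the calibrated spring constant is within 0.5% of the true 10 pN/nm,
and the fitted Young's modulus recovers the 70 kPa wild-type stage-7
central preset (the 0.3% deviation is the propagated calibration
error; with the exact spring constant the fit is accurate to machine
precision). The `examples/` directory holds one short script per
capability: single-curve fitting, gradient mapping, surface unrolling,
ablation recoil and osmotic-burst scoring; each prints the quantities
it computes with a line of interpretation. A thin CLI mirrors the
stages (`follimech generate | afm | map | unroll | ablation | swell |
demo`); `follimech demo --seed 7 --out outdir` runs the chain
end-to-end and writes deterministic summary CSVs.

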
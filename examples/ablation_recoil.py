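"""Quantify junction recoil after laser ablation.

Generates exponential-relaxation recoil tracks for junctions severed
along the A-P and circumferential directions and recovers the initial
recoil velocity from the first post-cut frame (within 300 ms), the
readout used to test whether epithelial cortical tension is polarized.
"""

from follimech import GeneratorConfig, make_recoil_track, recoil_velocity

config = GeneratorConfig(seed=3)

# comparable recoil in both directions: cortical tension is isotropic
for orientation, v0_true in (("AP", 2.0), ("circumferential", 2.1)):
    track = make_recoil_track(v0=v0_true, L0=5.0, tau=5.0, config=config,
                              cut_orientation=orientation, noise_sd=0.02)
    res = recoil_velocity(track)
    norm = res["normalized_relaxation"][1]
    print(f"{orientation:>15} cut: v0 = {res['v0_um_s']:.2f} um/s "
          f"(true {v0_true}), relaxation at 0.3 s = {norm:.3f} of L0")

print("Initial recoil velocity is proportional to the tension carried by "
      "the junction before the cut; near-equal A-P and circumferential "
      "velocities argue against a cell-intrinsic mechanical anisotropy.")
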
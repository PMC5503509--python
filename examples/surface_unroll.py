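"""Unroll a follicle surface and quantify Collagen IV patterning.

Renders a synthetic image stack of an ellipsoidal basement-membrane
shell, extracts the surface by ellipsoid fitting, pulls the shell
intensity back onto an (arc fraction x azimuth) chart, and computes the
A-P line profile, circumferential variability and fibril-orientation
score for wild-type and fat2 phantoms.
"""

import numpy as np

from follimech import GeneratorConfig, make_follicle_phantom
from follimech.surface import (
    ap_profile,
    circ_profile,
    extract_surface,
    fibril_orientation,
    profile_variance,
    unroll,
)

config = GeneratorConfig(seed=7)
VOXEL = (1.0, 1.0, 1.0)  # um; coarse sampling keeps the example fast

for genotype in ("WT", "fat2"):
    phantom = make_follicle_phantom(7, genotype, config, voxel_size=VOXEL,
                                    semi_axes=(25.0, 15.0, 15.0))
    surf = extract_surface(phantom.image_stack, VOXEL)
    smap = unroll(phantom.image_stack, surf, VOXEL, band_halfwidth=3.0)

    u, ap = ap_profile(smap)
    central = ap[(u > 0.4) & (u < 0.6)].mean()
    terminal = ap[((u > 0.15) & (u < 0.35)) | ((u > 0.65) & (u < 0.85))].mean()
    _, circ = circ_profile(smap, u_center=0.5)
    circ_var = profile_variance(circ / circ.mean())
    fib = fibril_orientation(smap)

    print(f"{genotype}: semi-axes {np.round(surf.semi_axes, 1).tolist()} um; "
          f"central/terminal intensity {central / terminal:.2f}; "
          f"circumferential variance {circ_var:.4f}; "
          f"fibril alignment {fib['alignment_score']:.2f}")

print("Wild-type shells show centrally elevated Collagen IV and uniform, "
      "circumferentially aligned fibrils; fat2 shells are patchy around "
      "the circumference with disordered fibril polarity.")
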
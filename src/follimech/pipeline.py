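"""End-to-end convenience chains: presets -> curves -> fits -> profiles.

These helpers run the full measurement chain on synthetic follicles and
are what the examples, demo and reproduction scripts call. Each
position receives four repeated indentations which are fitted
independently and averaged, mirroring the acquisition protocol.
"""

from __future__ import annotations

import numpy as np

from . import afm, stiffness, synthetic
from .regions import region_sample_positions


def measure_synthetic_follicle(
    stage: int,
    genotype: str,
    config: synthetic.GeneratorConfig,
    positions: tuple[str, ...] | None = None,
    n_repeats: int = 4,
    follicle_id: str = "",
) -> stiffness.StiffnessProfile:
    """Generate and fit one synthetic follicle's positional curves.

    ``positions`` defaults to the five canonical A-P sample positions
    (pole, terminal, central, terminal, pole). Returns the aggregated
    per-region profile.
    """
    if positions is None:
        positions = region_sample_positions()
    geometry = config.tip_geometry()
    measurements = []
    for region, curves in synthetic.make_follicle_curves(
            stage, genotype, config, positions=positions, n_repeats=n_repeats):
        pm = afm.measure_position(curves, config.spring_constant_true, geometry,
                                  n_required=n_repeats)
        if not pm.flagged:
            measurements.append((region, 0.0, pm.modulus))
    return stiffness.aggregate_regions(measurements, follicle_id=follicle_id,
                                       stage=stage, genotype=genotype)


def cohort_profiles(
    stage: int,
    genotype: str,
    n_follicles: int,
    base_seed: int,
    noise_fraction: float = 0.05,
    positions: tuple[str, ...] | None = None,
) -> list[stiffness.StiffnessProfile]:
    """Replicate follicles measured through the full chain."""
    profiles = []
    for i in range(n_follicles):
        cfg = synthetic.GeneratorConfig(
            seed=(base_seed * 1000 + i) % (2**31 - 1),
            noise_fraction_deflection=noise_fraction,
        )
        profiles.append(measure_synthetic_follicle(
            stage, genotype, cfg, positions=positions, follicle_id=f"{genotype}_{i}"))
    return profiles


def cohort_circumferential_cv(
    stage: int,
    genotype: str,
    n_follicles: int,
    base_seed: int,
    noise_fraction: float = 0.05,
    n_positions: int = 8,
) -> np.ndarray:
    """Per-follicle stiffness CV (%) around the central meridian."""
    cvs = []
    for i in range(n_follicles):
        cfg = synthetic.GeneratorConfig(
            seed=(base_seed * 1000 + i) % (2**31 - 1),
            noise_fraction_deflection=noise_fraction,
        )
        geometry = cfg.tip_geometry()
        moduli = []
        for _az, curves in synthetic.make_circumferential_curves(
                stage, genotype, cfg, n_positions=n_positions):
            pm = afm.measure_position(curves, cfg.spring_constant_true, geometry)
            moduli.append(pm.modulus)
        cvs.append(stiffness.circumferential_variability(np.array(moduli)))
    return np.array(cvs)
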
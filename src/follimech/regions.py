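"""Anterior–posterior region conventions shared across the package.

Positions on the follicle surface are expressed as a normalized arc
coordinate ``u`` running from 0 (anterior pole) to 1 (posterior pole)
along the meridian.  Three region labels are used throughout: ``pole``,
``terminal`` and ``central``.  Anterior and posterior instances of the
pole and terminal regions are pooled (the assays do not distinguish
them), so region statistics treat the profile as symmetric about
u = 0.5.
"""

from __future__ import annotations

import numpy as np

#: Normalized-arc boundaries: pole for u < 0.15 or u > 0.85,
#: terminal for 0.15–0.35 and 0.65–0.85, central for 0.35–0.65.
POLE_BOUNDARY = 0.15
TERMINAL_BOUNDARY = 0.35

REGION_LABELS = ("pole", "terminal", "central")


def classify_arc_position(u: float | np.ndarray) -> np.ndarray | str:
    """Map a normalized arc coordinate u in [0, 1] to a region label.

    Accepts scalars or arrays; anterior and posterior halves are pooled.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < -1e-9) | (u_arr > 1 + 1e-9)):
        raise ValueError("arc coordinate u must lie in [0, 1]")
    # distance from the nearer pole
    half = np.minimum(u_arr, 1.0 - u_arr)
    labels = np.where(
        half < POLE_BOUNDARY,
        "pole",
        np.where(half < TERMINAL_BOUNDARY, "terminal", "central"),
    )
    if np.isscalar(u) or np.ndim(u) == 0:
        return str(labels)
    return labels


def region_sample_positions() -> tuple[str, ...]:
    """The five canonical A–P sample positions, anterior to posterior."""
    return ("pole", "terminal", "central", "terminal", "pole")
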
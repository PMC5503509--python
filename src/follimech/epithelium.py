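"""Cell-level mechanics assays: junction planar polarity and ablation recoil.

Two quantifications used to test whether the epithelium itself is
mechanically anisotropic:

* **junction intensity polarity** — cortical signal (e.g. myosin-GFP) is
  read along manually traced junction segments with a wide line profile;
  junctions at 60–90 deg to the A–P axis form the "A–P" class and those
  at 0–30 deg the "circumferential" class (the 30–60 deg gap is
  excluded); the statistic is the ratio of class mean intensities after
  background subtraction;
* **laser-ablation recoil** — after severing a junction, the initial
  recoil velocity is the vertex-distance change over the first post-cut
  frame within 300 ms, and the relaxation curve is reported normalized
  to the original junction length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import profile_line
from skimage.restoration import rolling_ball


@dataclass
class JunctionSegment:
    """A traced cell–cell junction in chart/image coordinates (um or px)."""

    p1: tuple
    p2: tuple

    @property
    def angle_to_ap_deg(self) -> float:
        """Angle to the A–P (x) axis, folded into [0, 90] degrees."""
        dx = self.p2[0] - self.p1[0]
        dy = self.p2[1] - self.p1[1]
        ang = abs(np.degrees(np.arctan2(dy, dx)))
        if ang > 90.0:
            ang = 180.0 - ang
        return float(ang)

    @property
    def junction_class(self) -> str:
        ang = self.angle_to_ap_deg
        tol = 1e-9  # keep exact bin edges on their nominal side
        if ang >= 60.0 - tol:
            return "AP"
        if ang <= 30.0 + tol:
            return "circumferential"
        return "excluded"


@dataclass
class RecoilTrack:
    """Vertex-distance time series after laser severing of a junction."""

    times: np.ndarray  # s, starting at the cut
    vertex_distance: np.ndarray  # um
    cut_orientation: str = "AP"  # or "circumferential"
    position: str = "center"  # anterior / center / posterior
    initial_length: float = 0.0  # um, pre-cut junction length L0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vertex_distance = np.asarray(self.vertex_distance, dtype=float)
        if self.initial_length <= 0:
            raise ValueError("initial junction length must be positive")
        if self.times.size != self.vertex_distance.size:
            raise ValueError("times and distances must have equal length")


def subtract_background(image: np.ndarray, radius: float = 50.0) -> np.ndarray:
    """Rolling-ball background subtraction (local background removal)."""
    image = np.asarray(image, dtype=float)
    bg = rolling_ball(image, radius=radius)
    return image - bg


def junction_intensity(
    image: np.ndarray,
    segment: JunctionSegment,
    line_width: int = 8,
) -> float:
    """Mean intensity along a wide line profile over one junction.

    Coordinates are (x, y) in pixel units; the profile uses an
    ``line_width``-pixel-wide band, matching manual wide-line tracing.
    """
    # profile_line wants (row, col) = (y, x)
    src = (segment.p1[1], segment.p1[0])
    dst = (segment.p2[1], segment.p2[0])
    prof = profile_line(np.asarray(image, dtype=float), src, dst,
                        linewidth=line_width, mode="reflect", reduce_func=np.mean)
    return float(np.mean(prof))


def classify_and_ratio(
    segments: list[JunctionSegment],
    image: np.ndarray,
    line_width: int = 8,
    min_per_class: int = 30,
    background_radius: float | None = 50.0,
) -> dict:
    """A–P over circumferential mean junction-intensity ratio.

    Each segment is classified by its angle to the A–P axis (A–P class:
    60–90 deg; circumferential: 0–30 deg; the gap is excluded). Per-
    junction mean intensities come from ``line_width``-px-wide profiles
    on the (optionally background-subtracted) image; the statistic is
    mean(A–P) / mean(circumferential). Fewer than ``min_per_class``
    junctions in a class triggers a warning, an empty class an error.
    """
    import warnings

    img = np.asarray(image, dtype=float)
    if background_radius is not None:
        img = subtract_background(img, radius=background_radius)

    by_class: dict[str, list[float]] = {"AP": [], "circumferential": []}
    for seg in segments:
        cls = seg.junction_class
        if cls == "excluded":
            continue
        by_class[cls].append(junction_intensity(img, seg, line_width))

    for cls, vals in by_class.items():
        if not vals:
            raise ValueError(f"no junctions in class {cls!r}")
        if len(vals) < min_per_class:
            warnings.warn(
                f"only {len(vals)} junctions in class {cls!r} "
                f"(recommended >= {min_per_class})", stacklevel=2)

    mean_ap = float(np.mean(by_class["AP"]))
    mean_circ = float(np.mean(by_class["circumferential"]))
    return {
        "ratio": mean_ap / mean_circ,
        "mean_AP": mean_ap,
        "mean_circumferential": mean_circ,
        "n_AP": len(by_class["AP"]),
        "n_circumferential": len(by_class["circumferential"]),
    }


def recoil_velocity(track: RecoilTrack, max_first_frame: float = 0.3) -> dict:
    """Initial recoil velocity and normalized relaxation of one track.

    ``v0 = (L(t1) - L0) / t1`` using the first post-cut frame ``t1`` no
    later than ``max_first_frame`` (s); the relaxation curve is
    ``(L(t) - L0) / L0``. A track whose first post-cut frame falls after
    the cutoff is flagged and v0 omitted.
    """
    t = track.times
    L = track.vertex_distance
    L0 = track.initial_length
    post = t > 0
    flags: set = set()
    v0 = None
    if not np.any(post):
        flags.add("no_post_cut_frames")
    else:
        t1 = float(t[post][0])
        if t1 > max_first_frame + 1e-12:
            flags.add("first_frame_late")
        else:
            v0 = float((L[post][0] - L0) / t1)
    return {
        "v0_um_s": v0,
        "normalized_relaxation": (L - L0) / L0,
        "times_s": t.copy(),
        "flags": flags,
    }
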
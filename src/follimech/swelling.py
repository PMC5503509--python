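"""Osmotic-swelling assay scoring: burst frequency, timing, position, shape.

Immersing a follicle in water drives swelling until the basement
membrane breaches. Each time-lapse series of midplane outlines yields:

* an **aspect-ratio series** from per-frame least-squares ellipse fits;
* a **burst event** — the first frame with a fractional area drop above
  a threshold between consecutive frames (a breach-marker channel, when
  present, takes precedence), with the burst time and the aspect ratio
  immediately before bursting;
* a **burst position** — the breach coordinate projected to the
  normalized meridian arc coordinate and classified with the same
  pole / terminal / central boundaries used for stiffness mapping;
* **cohort tables** of burst fraction (with binomial CI), median burst
  time, position distribution and mean pre-burst aspect ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.measure import EllipseModel
from statsmodels.stats.proportion import proportion_confint

from .regions import classify_arc_position


@dataclass
class SwellingSeries:
    """Time-stamped outline series for one follicle under osmotic stress.

    ``outlines[i]`` is an (N, 2) array of (x, y) vertices in um at
    ``times[i]`` (s, relative to immersion); ``breach_channel`` optionally
    maps frame index -> (x, y) breach coordinate.
    """

    times: np.ndarray
    outlines: list
    breach_channel: dict | None = None
    genotype: str = ""
    stage: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.outlines) != self.times.size:
            raise ValueError("one outline per time point required")
        if self.times.size < 2:
            raise ValueError("need at least 2 frames")


@dataclass
class BurstEvent:
    occurred: bool
    time: float | None = None  # s after immersion
    frame: int | None = None
    position_class: str | None = None
    breach_xy: tuple | None = None
    aspect_ratio_before: float | None = None
    area_drop_fraction: float | None = None


def outline_area(outline: np.ndarray) -> float:
    """Enclosed area (um^2) of a closed outline polygon."""
    poly = Polygon(np.asarray(outline, dtype=float))
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate outline")
    return float(poly.area)


def fit_outline_ellipse(outline: np.ndarray) -> tuple[tuple, float, float, float]:
    """Least-squares ellipse through outline vertices.

    Returns ``(center, semi_major, semi_minor, major_axis_angle_rad)``.
    """
    pts = np.asarray(outline, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):  # exact circles
        model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("degenerate contour: ellipse fit failed")
    (xc, yc), (ax1, ax2), theta = model.center, model.axis_lengths, model.theta
    if ax1 >= ax2:
        major, minor, ang = ax1, ax2, theta
    else:
        major, minor, ang = ax2, ax1, theta + np.pi / 2.0
    if minor <= 0:
        raise ValueError("degenerate contour: zero minor axis")
    return (float(xc), float(yc)), float(major), float(minor), float(ang)


def aspect_ratio_series(series: SwellingSeries) -> np.ndarray:
    """Per-frame aspect ratio (major/minor) from ellipse fits."""
    out = np.empty(series.times.size)
    for i, outline in enumerate(series.outlines):
        _, major, minor, _ = fit_outline_ellipse(outline)
        out[i] = major / minor
    return out


def detect_burst(series: SwellingSeries, drop_threshold: float = 0.20) -> BurstEvent:
    """Locate the burst frame of a swelling series.

    A burst is the first frame whose enclosed area has dropped by more
    than ``drop_threshold`` (fraction) relative to the previous frame; if
    a breach-marker channel is present, its first detection takes
    precedence. The aspect ratio immediately before bursting is taken at
    the preceding frame. A series that only grows yields
    ``occurred=False``.
    """
    if series.times.size < 3:
        raise ValueError("burst detection needs at least 3 frames")
    areas = np.array([outline_area(o) for o in series.outlines])

    frame: int | None = None
    breach_xy = None
    if series.breach_channel:
        frame = min(series.breach_channel)
        breach_xy = tuple(series.breach_channel[frame])
    else:
        drops = 1.0 - areas[1:] / areas[:-1]
        hits = np.nonzero(drops > drop_threshold)[0]
        if hits.size:
            frame = int(hits[0]) + 1

    if frame is None:
        return BurstEvent(occurred=False)

    _, major, minor, _ = fit_outline_ellipse(series.outlines[frame - 1])
    drop = float(1.0 - areas[frame] / areas[frame - 1]) if frame < areas.size else None
    return BurstEvent(
        occurred=True,
        time=float(series.times[frame]),
        frame=frame,
        breach_xy=breach_xy,
        aspect_ratio_before=float(major / minor),
        area_drop_fraction=drop,
    )


def burst_position(
    event: BurstEvent,
    outline: np.ndarray,
    tolerance_fraction: float = 0.25,
) -> str:
    """Classify the breach location along the A–P axis of the outline.

    The breach coordinate is projected onto the ellipse fitted to the
    pre-burst outline; its normalized meridian arc coordinate u (0 at one
    major-axis vertex) is classified with the shared pole / terminal /
    central boundaries. A breach farther than ``tolerance_fraction`` of
    the mean radius from the outline raises.
    """
    if not event.occurred or event.breach_xy is None:
        raise ValueError("event has no breach coordinate")
    (xc, yc), major, minor, ang = fit_outline_ellipse(outline)

    x, y = event.breach_xy
    # rotate into the ellipse frame
    ca, sa = np.cos(-ang), np.sin(-ang)
    xr = ca * (x - xc) - sa * (y - yc)
    yr = sa * (x - xc) + ca * (y - yc)

    r_pt = np.hypot(xr, yr)
    mean_r = 0.5 * (major + minor)
    # radial residual from the ellipse along the breach direction
    t_pt = np.arctan2(yr / minor, xr / major)
    r_ell = np.hypot(major * np.cos(t_pt), minor * np.sin(t_pt))
    if abs(r_pt - r_ell) > tolerance_fraction * mean_r:
        raise ValueError("breach coordinate too far from the outline")

    u = arc_coordinate(t_pt, major, minor)
    return str(classify_arc_position(u))


def arc_coordinate(t: float, major: float, minor: float) -> float:
    """Normalized arc fraction u in [0, 1] of parametric angle t.

    u runs pole-to-pole along the half-perimeter containing the point,
    from the (+major) vertex (u = 0) to the (-major) vertex (u = 1);
    upper and lower halves are equivalent by symmetry.
    """
    t = abs(float(t))  # fold lower half onto upper
    td = np.linspace(0.0, np.pi, 2049)
    ds = np.hypot(major * np.sin(td), minor * np.cos(td))
    s = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2.0 * np.diff(td))])
    s /= s[-1]
    return float(np.interp(t, td, s))


def cohort_stats(
    events_by_group: dict[str, list],
    series_by_group: dict[str, list] | None = None,
) -> pd.DataFrame:
    """Cohort summary of burst events, one row per group.

    Reports burst fraction with a 95% Wilson binomial CI, median burst
    time among bursting follicles, the position-class distribution, and
    mean pre-burst aspect ratio. ``series_by_group``, when provided, is
    used to resolve burst positions from the stored breach coordinates.
    """
    rows = []
    for group, events in events_by_group.items():
        n = len(events)
        if n == 0:
            raise ValueError(f"empty cohort {group!r}")
        burst = [e for e in events if e.occurred]
        n_burst = len(burst)
        lo, hi = proportion_confint(n_burst, n, alpha=0.05, method="wilson")
        times = [e.time for e in burst if e.time is not None]
        ars = [e.aspect_ratio_before for e in burst if e.aspect_ratio_before is not None]

        pos_counts = {"pole": 0, "terminal": 0, "central": 0}
        if series_by_group is not None and group in series_by_group:
            for e, s in zip(events, series_by_group[group]):
                if e.occurred and e.breach_xy is not None and e.frame is not None:
                    cls = burst_position(e, s.outlines[e.frame - 1])
                    pos_counts[cls] += 1
        else:
            for e in burst:
                if e.position_class:
                    pos_counts[e.position_class] += 1

        rows.append({
            "group": group,
            "n": n,
            "burst_percent": 100.0 * n_burst / n,
            "burst_ci_low_percent": 100.0 * lo,
            "burst_ci_high_percent": 100.0 * hi,
            "median_burst_time_s": float(np.median(times)) if times else np.nan,
            "mean_aspect_ratio_before": float(np.mean(ars)) if ars else np.nan,
            "n_pole": pos_counts["pole"],
            "n_terminal": pos_counts["terminal"],
            "n_central": pos_counts["central"],
        })
    return pd.DataFrame(rows)
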
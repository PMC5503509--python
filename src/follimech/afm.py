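"""AFM force-curve analysis: calibration, contact detection and Hertz fitting.

The measurement chain converts a raw approach record (piezo extension ``z``
versus cantilever deflection ``d``) into a Young's modulus estimate:

1. the cantilever spring constant ``k`` is calibrated from a thermal
   deflection trace by equipartition, ``k = kB*T / var_p(d)``;
2. the contact point ``(z0, d0)`` is located by a robust baseline +
   threshold crossing, then refined as a free parameter of the final fit;
3. the record is converted to force and indentation,
   ``F = k*(d - d0)``, ``delta = (z - z0) - (d - d0)``;
4. the first 50 nm of indentation are fitted to the Hertz/Sneddon contact
   law for a pyramidal (or conical) indenter,

       F = C * E / (1 - nu**2) * tan(theta) * delta**2,

   with ``C = 1/sqrt(2)`` for a four-sided pyramid (Bilodeau) and
   ``C = 2/pi`` for a cone (Sneddon).

Restricting the fit to a shallow indentation window isolates the elastic
response of the thin basement membrane from the softer tissue beneath.
A closed-form linearized estimator (least-squares slope of F against
delta**2 through the origin) is provided alongside the nonlinear fit and
serves as an internal cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats

BOLTZMANN = 1.380649e-23  # J/K, exact

#: Default fit window: only the first 50 nm of indentation are used.
DEFAULT_WINDOW_NM = 50.0

#: Minimum number of in-window samples for a trustworthy fit.
MIN_WINDOW_SAMPLES = 10

#: Relative rms residual above which a fit is flagged `poor_fit`.
POOR_FIT_RESIDUAL = 0.20


@dataclass(frozen=True)
class TipGeometry:
    """Indenter geometry entering the contact model.

    Parameters
    ----------
    model:
        ``"four_sided_pyramid"`` or ``"cone"``.
    half_angle_deg:
        Tip half-opening angle theta in degrees. 35 degrees is typical
        for silicon-nitride pyramidal probes.
    poisson_ratio:
        Poisson ratio of the sample; 0.5 (incompressible) is standard
        for soft hydrated tissue.
    geometry_constant:
        Dimensionless prefactor C. If None, the model default is used
        (1/sqrt(2) for the pyramid, 2/pi for the cone).
    """

    model: str = "four_sided_pyramid"
    half_angle_deg: float = 35.0
    poisson_ratio: float = 0.5
    geometry_constant: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("four_sided_pyramid", "cone"):
            raise ValueError(f"unknown tip model {self.model!r}")
        if not 0.0 < self.half_angle_deg < 90.0:
            raise ValueError("half angle must lie in (0, 90) degrees")
        if not 0.0 <= self.poisson_ratio < 0.5 + 1e-9:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if self.geometry_constant is not None and self.geometry_constant <= 0:
            raise ValueError("geometry constant must be positive")

    @property
    def constant(self) -> float:
        if self.geometry_constant is not None:
            return self.geometry_constant
        return 1.0 / math.sqrt(2.0) if self.model == "four_sided_pyramid" else 2.0 / math.pi

    def stiffness_prefactor(self, modulus: float) -> float:
        """C * E/(1-nu^2) * tan(theta), the coefficient of delta**2 in F."""
        return (
            self.constant
            * modulus
            / (1.0 - self.poisson_ratio**2)
            * math.tan(math.radians(self.half_angle_deg))
        )

    def modulus_from_prefactor(self, prefactor: float) -> float:
        return (
            prefactor
            * (1.0 - self.poisson_ratio**2)
            / (self.constant * math.tan(math.radians(self.half_angle_deg)))
        )


@dataclass
class ForceCurve:
    """One AFM approach record.

    ``extension`` is the piezo position (m, increasing toward the sample),
    ``deflection`` the cantilever deflection (m). Metadata carries
    acquisition context and, for synthetic curves, the ground truth.
    """

    extension: np.ndarray
    deflection: np.ndarray
    approach_speed: float = 0.4e-6
    sample_rate_points: int = 2048
    spring_constant: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.extension.size == 0:
            raise ValueError("empty curve")
        if self.extension.shape != self.deflection.shape:
            raise ValueError("extension and deflection must have equal length")
        dz = np.diff(self.extension)
        if self.extension.size > 1 and not np.all(dz > 0):
            raise ValueError("extension must be strictly increasing on approach")

    def __len__(self) -> int:
        return int(self.extension.size)


@dataclass
class IndentationFit:
    """Result of the Hertz fit on one curve."""

    modulus: float  # Pa
    contact_point: float  # m
    baseline: float  # m
    window_m: float  # m, upper bound of the indentation window used
    rms_residual: float  # N
    relative_residual: float  # rms residual / rms force
    n_samples: int
    flags: set = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return not self.flags

    @property
    def modulus_kpa(self) -> float:
        return self.modulus / 1e3


@dataclass
class PositionMeasurement:
    """Mean modulus at one XY position from repeated indentations."""

    modulus: float  # Pa, mean of per-curve fits
    sd: float  # Pa
    fits: list
    flagged: bool = False


# ---------------------------------------------------------------------------
# calibration

def calibrate_spring_constant(trace: np.ndarray, temperature: float) -> float:
    """Equipartition spring constant from a thermal deflection trace.

    The cantilever's fundamental mode in thermal equilibrium satisfies
    ``(1/2) k <d^2> = (1/2) kB T``, so ``k = kB*T / var_p(d)`` with the
    population variance of the deflection fluctuations.

    Parameters
    ----------
    trace:
        Deflection samples in metres; at least 100 samples.
    temperature:
        Bath temperature in kelvin.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 100:
        raise ValueError("thermal trace must contain at least 100 samples")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    var_p = float(np.var(trace))  # population variance (ddof=0)
    if np.ptp(trace) == 0.0 or var_p <= 0:
        raise ValueError("degenerate trace: zero variance")
    return BOLTZMANN * temperature / var_p


# ---------------------------------------------------------------------------
# contact detection

def detect_contact(
    curve: ForceCurve,
    spring_constant: float | None = None,
    geometry: TipGeometry | None = None,
    baseline_fraction: float = 0.2,
    threshold_sigmas: float = 3.0,
) -> tuple[float, float, set]:
    """Locate the contact point (z0) and deflection baseline (d0).

    The baseline is the median deflection over the leading
    ``baseline_fraction`` of the approach (assumed pre-contact); its
    robust scatter sets a crossing threshold ``d0 + 3*sigma``.  z0 is the
    extension at the first sustained crossing.  When ``spring_constant``
    and ``geometry`` are given, z0 is subsequently refined as a free
    parameter of the Hertz fit.

    Returns ``(z0, d0, flags)``; a curve that never crosses the threshold
    gets the ``no_contact`` flag and ``z0 = nan``.
    """
    z = curve.extension
    d = curve.deflection
    n_base = max(4, int(round(baseline_fraction * z.size)))
    base = d[:n_base]
    d0 = float(np.median(base))
    sigma = 1.4826 * float(np.median(np.abs(base - d0)))
    # noiseless records have sigma == 0; use a tiny absolute guard instead
    sigma_eff = max(sigma, 1e-13)
    threshold = d0 + threshold_sigmas * sigma_eff

    above = d > threshold
    flags: set = set()
    if not np.any(above):
        flags.add("no_contact")
        return float("nan"), d0, flags
    idx = int(np.argmax(above))
    z0 = float(z[idx])

    if spring_constant is not None and geometry is not None:
        fit = _fit_curve(curve, spring_constant, geometry, z0, d0)
        if "no_contact" not in fit.flags and np.isfinite(fit.contact_point):
            z0 = fit.contact_point
    return z0, d0, flags


# ---------------------------------------------------------------------------
# force / indentation conversion

def to_force_indentation(
    curve: ForceCurve,
    spring_constant: float,
    z0: float,
    d0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert an approach record to (indentation, force).

    ``F = k*(d - d0)``; ``delta = (z - z0) - (d - d0)`` (piezo travel past
    contact minus the deflection taken up by the cantilever). Only samples
    with positive indentation are retained.
    """
    if spring_constant <= 0:
        raise ValueError("spring constant must be positive")
    z = curve.extension
    d = curve.deflection
    if not (z[0] <= z0 <= z[-1]):
        raise ValueError("contact point outside the extension range")
    w = d - d0
    delta = (z - z0) - w
    force = spring_constant * w
    keep = delta > 0
    return delta[keep], force[keep]


# ---------------------------------------------------------------------------
# modulus fitting

def linearized_modulus(
    delta: np.ndarray,
    force: np.ndarray,
    geometry: TipGeometry,
    window_nm: float = DEFAULT_WINDOW_NM,
) -> float:
    """Closed-form modulus from the slope of F against delta**2.

    Least squares through the origin over the indentation window:
    ``slope = sum(delta^2 * F) / sum(delta^4)``; the modulus follows by
    inverting the geometric prefactor.  Serves as the independent
    cross-check for the nonlinear fit.
    """
    delta = np.asarray(delta, dtype=float)
    force = np.asarray(force, dtype=float)
    window = window_nm * 1e-9
    sel = (delta > 0) & (delta <= window)
    if np.count_nonzero(sel) < 2:
        raise ValueError("too few samples in the indentation window")
    x = delta[sel] ** 2
    slope = float(np.dot(x, force[sel]) / np.dot(x, x))
    return geometry.modulus_from_prefactor(max(slope, 0.0))


def fit_modulus(
    delta: np.ndarray,
    force: np.ndarray,
    geometry: TipGeometry,
    window_nm: float = DEFAULT_WINDOW_NM,
    refine_contact: bool = True,
) -> IndentationFit:
    """Nonlinear least-squares Hertz fit over 0 < delta <= window.

    Fits ``F = C*E/(1-nu^2)*tan(theta) * delta^2`` with E >= 0 free and,
    when ``refine_contact`` is set, a contact-point offset dz free as well
    (indentation is re-derived as ``delta - dz`` inside the fit). Fewer
    than 10 in-window samples flags ``window_short``; a relative rms
    residual above 20% flags ``poor_fit``.
    """
    delta = np.asarray(delta, dtype=float)
    force = np.asarray(force, dtype=float)
    window = window_nm * 1e-9
    flags: set = set()

    sel = (delta > 0) & (delta <= window)
    if np.count_nonzero(sel) < MIN_WINDOW_SAMPLES:
        flags.add("window_short")
        return IndentationFit(
            modulus=float("nan"), contact_point=float("nan"), baseline=float("nan"),
            window_m=window, rms_residual=float("nan"),
            relative_residual=float("nan"), n_samples=int(np.count_nonzero(sel)),
            flags=flags,
        )

    d_in, f_in = delta[sel], force[sel]
    e_init = max(linearized_modulus(delta, force, geometry, window_nm), 1.0)
    # Relative-residual weighting (floored at 5% of the peak force): the
    # dominant noise on soft-cantilever deflection records is multiplicative,
    # so relative residuals are near-homoscedastic and the contact-point
    # refinement stays unbiased under noise; the weights also make the
    # optimizer's stopping tolerances scale-free.
    f_peak = float(np.max(np.abs(f_in)))
    weights = (1.0 / np.maximum(np.abs(f_in), 0.05 * f_peak)
               if f_peak > 0 else np.ones_like(f_in))

    if refine_contact:
        def residual(p: np.ndarray) -> np.ndarray:
            e, dz = p
            d_eff = np.clip(d_in - dz, 0.0, None)
            return (geometry.stiffness_prefactor(e) * d_eff**2 - f_in) * weights

        res = optimize.least_squares(
            residual, x0=[e_init, 0.0],
            bounds=([0.0, -window], [np.inf, window]),
            x_scale=[max(e_init, 1.0), 1e-9],
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        e_fit, dz = float(res.x[0]), float(res.x[1])
    else:
        def residual(p: np.ndarray) -> np.ndarray:
            return (geometry.stiffness_prefactor(p[0]) * d_in**2 - f_in) * weights

        res = optimize.least_squares(
            residual, x0=[e_init], bounds=([0.0], [np.inf]),
            x_scale=[max(e_init, 1.0)], xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        e_fit, dz = float(res.x[0]), 0.0

    model = geometry.stiffness_prefactor(e_fit) * np.clip(d_in - dz, 0.0, None) ** 2
    rms = float(np.sqrt(np.mean((model - f_in) ** 2)))
    f_rms = float(np.sqrt(np.mean(f_in**2)))
    rel = rms / f_rms if f_rms > 0 else float("inf")
    if rel > POOR_FIT_RESIDUAL:
        flags.add("poor_fit")

    return IndentationFit(
        modulus=e_fit, contact_point=dz, baseline=0.0, window_m=window,
        rms_residual=rms, relative_residual=rel,
        n_samples=int(d_in.size), flags=flags,
    )


def _fit_curve(
    curve: ForceCurve,
    spring_constant: float,
    geometry: TipGeometry,
    z0: float,
    d0: float,
    window_nm: float = DEFAULT_WINDOW_NM,
    window_on: str = "indentation",
) -> IndentationFit:
    """Fit one curve given an initial contact estimate.

    ``window_on`` selects whether the 50 nm fit window is measured in
    indentation depth (default, the mechanically meaningful choice) or in
    cantilever deflection.
    """
    delta, force = to_force_indentation(curve, spring_constant, z0, d0)
    if delta.size < MIN_WINDOW_SAMPLES:
        return IndentationFit(
            modulus=float("nan"), contact_point=z0, baseline=d0,
            window_m=window_nm * 1e-9, rms_residual=float("nan"),
            relative_residual=float("nan"), n_samples=int(delta.size),
            flags={"window_short"},
        )
    if window_on == "deflection":
        keep = force / spring_constant <= window_nm * 1e-9
        delta_w, force_w = delta[keep], force[keep]
        fit = fit_modulus(delta_w, force_w, geometry, window_nm=1e9, refine_contact=True)
        fit.window_m = window_nm * 1e-9
    elif window_on == "indentation":
        fit = fit_modulus(delta, force, geometry, window_nm=window_nm, refine_contact=True)
    else:
        raise ValueError("window_on must be 'indentation' or 'deflection'")
    # express the refined offset as an absolute contact point
    fit.contact_point = z0 + fit.contact_point
    fit.baseline = d0
    return fit


def analyze_curve(
    curve: ForceCurve,
    spring_constant: float,
    geometry: TipGeometry | None = None,
    window_nm: float = DEFAULT_WINDOW_NM,
    window_on: str = "indentation",
) -> IndentationFit:
    """Full single-curve pipeline: contact detection, conversion, Hertz fit."""
    geometry = geometry or TipGeometry()
    z0, d0, flags = detect_contact(curve)
    if "no_contact" in flags:
        return IndentationFit(
            modulus=float("nan"), contact_point=float("nan"), baseline=d0,
            window_m=window_nm * 1e-9, rms_residual=float("nan"),
            relative_residual=float("nan"), n_samples=0, flags=flags,
        )
    return _fit_curve(curve, spring_constant, geometry, z0, d0, window_nm, window_on)


def measure_position(
    curves: list[ForceCurve],
    spring_constant: float,
    geometry: TipGeometry | None = None,
    window_nm: float = DEFAULT_WINDOW_NM,
    n_required: int = 4,
) -> PositionMeasurement:
    """Average repeated indentations taken at a single XY position.

    Each curve is fitted independently and the position modulus is the
    arithmetic mean of the per-curve estimates (fit-then-average). A
    position containing any `no_contact` curve is flagged and should be
    excluded from group statistics.
    """
    if len(curves) != n_required:
        raise ValueError(f"expected {n_required} curves per position, got {len(curves)}")
    geometry = geometry or TipGeometry()
    fits = [analyze_curve(c, spring_constant, geometry, window_nm) for c in curves]
    flagged = any("no_contact" in f.flags for f in fits)
    moduli = np.array([f.modulus for f in fits if "no_contact" not in f.flags])
    if moduli.size == 0:
        return PositionMeasurement(float("nan"), float("nan"), fits, True)
    return PositionMeasurement(
        modulus=float(np.mean(moduli)),
        sd=float(np.std(moduli)),
        fits=fits,
        flagged=flagged,
    )


def speed_sweep(
    curve_sets: dict[float, list[ForceCurve]],
    spring_constant: float,
    geometry: TipGeometry | None = None,
) -> pd.DataFrame:
    """Per-approach-speed modulus summary (viscoelasticity diagnostic).

    A falling modulus at higher approach speeds indicates viscoelastic
    contamination of the elastic estimate; the sweep reports per-speed
    means with 95% CIs and a monotonicity diagnostic, without applying
    any correction.
    """
    if len(curve_sets) < 2:
        raise ValueError("speed sweep requires at least two approach speeds")
    geometry = geometry or TipGeometry()
    rows = []
    for speed in sorted(curve_sets):
        curves = curve_sets[speed]
        if not curves:
            raise ValueError(f"no curves for speed {speed}")
        e = np.array([analyze_curve(c, spring_constant, geometry).modulus for c in curves])
        e = e[np.isfinite(e)]
        mean = float(np.mean(e))
        if e.size > 1:
            sem = float(stats.sem(e))
            half = sem * float(stats.t.ppf(0.975, e.size - 1))
        else:
            half = float("nan")
        rows.append({
            "approach_speed_um_s": speed * 1e6,
            "mean_E_kPa": mean / 1e3,
            "ci95_halfwidth_kPa": half / 1e3,
            "n_curves": int(e.size),
        })
    table = pd.DataFrame(rows)
    diffs = np.diff(table["mean_E_kPa"].to_numpy())
    table.attrs["monotone_decreasing"] = bool(np.all(diffs < 0))
    table.attrs["monotone_increasing"] = bool(np.all(diffs > 0))
    return table
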
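"""Synthetic raw-data generator for every assay in the pipeline.

Forward models, with ground truth recorded, for:

* AFM approach curves — the cantilever deflection solves the implicit
  pyramidal-contact relation ``k*(d-d0) = C*E/(1-nu^2)*tan(theta)*delta^2``
  with ``delta = (z-z0) - (d-d0)``, optionally with a rate-dependent
  (viscoelastic) apparent modulus and additive / multiplicative noise;
* thermal deflection traces — zero-mean Gaussian with the equipartition
  variance ``kB*T/k``;
* ellipsoidal follicle phantoms — 3D image stacks of a fluorescent
  basement-membrane shell whose intensity carries an A–P profile,
  circumferential texture and oriented fibril stripes per genotype;
* laser-ablation recoil tracks — exponential relaxation
  ``L(t) = L0 + v0*tau*(1 - exp(-t/tau))``;
* osmotic-swelling outline series — growing ellipses with genotype-
  dependent burst hazard, burst position preference and breach marks.

Stage/genotype presets anchor every numeric choice to the measured
biology: wild-type central stiffness 30/40/70 kPa at stages 3/5/7, poles
~50% softer at early stages, central ~30% stiffer than terminal at
stage 7, a ~300% pole-to-center rise by stage 8, a 97% stiffness loss
after collagenase, and a four-fold rise in circumferential stiffness
variability in fat2/msn mutants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .afm import BOLTZMANN, ForceCurve, TipGeometry
from .epithelium import RecoilTrack
from .swelling import SwellingSeries
from . import regions


@dataclass(frozen=True)
class GeneratorConfig:
    """Acquisition parameters shared by the forward models.

    Defaults mirror a typical soft-cantilever AFM session: MLCT-C-class
    probe with nominal spring constant 10 pN/nm (0.01 N/m), pyramidal tip
    (half-angle 35 deg), incompressible sample (nu = 0.5), approach at
    0.4 um/s, 2048 samples per curve, bath at 295 K.
    """

    seed: int = 0
    temperature: float = 295.0  # K
    spring_constant_true: float = 0.01  # N/m
    tip_half_angle: float = 35.0  # degrees
    poisson_ratio: float = 0.5
    noise_sd_deflection: float = 0.0  # m, additive
    noise_fraction_deflection: float = 0.0  # multiplicative, e.g. 0.05
    approach_speed: float = 0.4e-6  # m/s
    sample_count: int = 2048
    geometry_constant: float | None = None  # None -> model default
    viscoelastic_exponent: float = 0.0  # >0 makes apparent E fall with speed
    reference_speed: float = 0.4e-6  # m/s, speed at which E_app == E

    def __post_init__(self) -> None:
        if self.spring_constant_true <= 0:
            raise ValueError("spring constant must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5 + 1e-9:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if not 0.0 < self.tip_half_angle < 90.0:
            raise ValueError("tip half-angle must lie in (0, 90) degrees")
        if self.sample_count < 100:
            raise ValueError("sample_count too small to cover both windows")

    def tip_geometry(self) -> TipGeometry:
        return TipGeometry(
            model="four_sided_pyramid",
            half_angle_deg=self.tip_half_angle,
            poisson_ratio=self.poisson_ratio,
            geometry_constant=self.geometry_constant,
        )

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


# ---------------------------------------------------------------------------
# stage / genotype preset table

@dataclass(frozen=True)
class StiffnessPreset:
    """Ground-truth regional stiffness and variability for one condition."""

    stage: int
    genotype: str
    region_moduli: dict  # {"pole"|"terminal"|"central": Pa}
    circumferential_cv: float  # percent sd of stiffness around a meridian
    collagen_factor: float = 1.0  # residual stiffness multiplier

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.region_moduli.values()):
            raise ValueError("all region moduli must be positive")
        if self.circumferential_cv < 0:
            raise ValueError("circumferential CV must be non-negative")

    def modulus(self, region: str) -> float:
        return self.region_moduli[region] * self.collagen_factor


# Wild-type central stiffness by stage (Pa). Terminal equals central at
# stages 3/5; at stage 7 the center is ~30% stiffer than terminal; poles
# are ~50% softer than terminal throughout; by stage 8 the pole-to-center
# rise reaches ~300% (center = 4x pole).
_WT_STAGE_TABLE: dict[int, dict[str, float]] = {
    3: {"central": 30e3, "terminal": 30e3, "pole": 15e3},
    5: {"central": 40e3, "terminal": 40e3, "pole": 20e3},
    7: {"central": 70e3, "terminal": 70e3 / 1.3, "pole": 70e3 / 1.3 / 2.0},
    8: {"central": 80e3, "terminal": 80e3 / 1.3, "pole": 20e3},
}

#: Residual stiffness after collagen digestion (97% reduction).
COLLAGENASE_FACTOR = 0.03

GENOTYPES = (
    "WT", "fat2", "msn-KD", "collagenase", "SPARC-KD", "ColIV-KD",
    "EHBP1-OE", "mirr>ColIV-KD", "fru>EHBP1", "Perl-OE", "Dome-DN",
)


def get_preset(stage: int, genotype: str = "WT") -> StiffnessPreset:
    """Regional stiffness preset for a stage/genotype combination.

    Mutant presets encode the qualitative orderings observed in vivo:
    fat2 and msn-depleted follicles stay soft and isotropic with 4x the
    circumferential variability; SPARC depletion scales the whole profile
    to ~80%; uniform Collagen IV depletion and Perlecan overexpression
    flatten and soften; EHBP1 overexpression stiffens the center ~15%;
    regional drivers flatten the gradient from one end.
    """
    if stage not in _WT_STAGE_TABLE:
        raise ValueError(f"no preset for stage {stage}; known: {sorted(_WT_STAGE_TABLE)}")
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; known: {', '.join(GENOTYPES)}")
    wt = dict(_WT_STAGE_TABLE[stage])
    cv = 5.0
    factor = 1.0
    if genotype == "WT":
        moduli = wt
    elif genotype == "collagenase":
        moduli = wt
        factor = COLLAGENASE_FACTOR
    elif genotype in ("fat2", "msn-KD"):
        soft = _WT_STAGE_TABLE[3]["central"]
        moduli = {r: soft for r in wt}
        cv = 20.0
    elif genotype == "SPARC-KD":
        moduli = {r: 0.8 * v for r, v in wt.items()}
    elif genotype == "ColIV-KD":
        soft = 0.3 * wt["central"]
        moduli = {r: soft for r in wt}
    elif genotype == "EHBP1-OE":
        moduli = {"central": 1.15 * wt["central"],
                  "terminal": 0.95 * wt["terminal"],
                  "pole": 0.95 * wt["pole"]}
    elif genotype == "mirr>ColIV-KD":
        moduli = {"central": wt["terminal"], "terminal": wt["terminal"],
                  "pole": wt["pole"]}
    elif genotype == "fru>EHBP1":
        moduli = {"central": wt["central"], "terminal": wt["central"],
                  "pole": wt["central"]}
    elif genotype == "Perl-OE":
        soft = 0.5 * wt["terminal"]
        moduli = {r: soft for r in wt}
    elif genotype == "Dome-DN":
        flat = wt["terminal"]
        moduli = {r: flat for r in wt}
    return StiffnessPreset(stage=stage, genotype=genotype, region_moduli=moduli,
                           circumferential_cv=cv, collagen_factor=factor)


# ---------------------------------------------------------------------------
# AFM forward model

def _apparent_modulus(modulus: float, config: GeneratorConfig) -> float:
    """Rate-dependent apparent modulus: E * (v/v_ref)^(-gamma)."""
    if config.viscoelastic_exponent <= 0:
        return modulus
    ratio = config.approach_speed / config.reference_speed
    return modulus * ratio ** (-config.viscoelastic_exponent)


def solve_deflection(travel: np.ndarray, prefactor: float, k: float) -> np.ndarray:
    """Deflection solving k*w = A*(s - w)^2 for piezo travel s past contact.

    The implicit contact relation is quadratic in the deflection w, so the
    physically admissible branch (0 <= w <= s, w -> A*s^2/k for small A)
    has a closed form; it is evaluated as
    ``w = 2*A*s^2 / (2As + k + sqrt(4Ask + k^2))``, the
    cancellation-free rearrangement of the quadratic root.
    """
    s = np.asarray(travel, dtype=float)
    if prefactor <= 0:
        return np.zeros_like(s)
    disc = 4.0 * prefactor * s * k + k * k
    return 2.0 * prefactor * s**2 / (2.0 * prefactor * s + k + np.sqrt(disc))


def required_travel(indentation: float, prefactor: float, k: float) -> float:
    """Piezo travel past contact needed to reach a target indentation."""
    return indentation + prefactor * indentation**2 / k


def make_force_curve(
    config: GeneratorConfig,
    modulus_true: float,
    contact_offset: float = 100e-9,
    indentation_depth: float = 100e-9,
    salt: int = 0,
) -> ForceCurve:
    """Generate one approach record for a sample of known modulus.

    ``contact_offset`` is the piezo position of the true contact point
    (the curve starts at extension 0, so it equals the pre-contact
    travel); ``indentation_depth`` is the maximum indentation reached.
    Ground truth (modulus, contact point, spring constant) is stored in
    the curve metadata.
    """
    if modulus_true <= 0:
        raise ValueError("modulus must be positive")
    if contact_offset < 50e-9:
        raise ValueError("need at least 50 nm of pre-contact travel")
    if indentation_depth < 50e-9:
        raise ValueError("need at least 50 nm of post-contact indentation")

    k = config.spring_constant_true
    geometry = config.tip_geometry()
    e_app = _apparent_modulus(modulus_true, config)
    prefactor = geometry.stiffness_prefactor(e_app)

    z0 = contact_offset
    z_max = z0 + required_travel(indentation_depth, prefactor, k)
    z = np.linspace(0.0, z_max, config.sample_count)

    travel = np.clip(z - z0, 0.0, None)
    d = solve_deflection(travel, prefactor, k)

    rng = config.rng(salt)
    if config.noise_fraction_deflection > 0:
        d = d * (1.0 + config.noise_fraction_deflection * rng.standard_normal(d.shape))
    if config.noise_sd_deflection > 0:
        d = d + config.noise_sd_deflection * rng.standard_normal(d.shape)

    return ForceCurve(
        extension=z,
        deflection=d,
        approach_speed=config.approach_speed,
        sample_rate_points=config.sample_count,
        spring_constant=k,
        metadata={
            "modulus_true_pa": modulus_true,
            "apparent_modulus_pa": e_app,
            "contact_point_true_m": z0,
            "spring_constant_true": k,
            "synthetic": True,
        },
    )


def make_thermal_trace(config: GeneratorConfig, n_samples: int, salt: int = 0) -> np.ndarray:
    """Thermal deflection trace: zero-mean Gaussian, variance kB*T/k."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    sd = math.sqrt(BOLTZMANN * config.temperature / config.spring_constant_true)
    return sd * config.rng(salt).standard_normal(n_samples)


# --- cohort helpers --------------------------------------------------------

def make_position_curves(
    config: GeneratorConfig,
    modulus_true: float,
    n_repeats: int = 4,
    salt: int = 0,
) -> list[ForceCurve]:
    """Repeated indentations at one XY position (same true modulus)."""
    return [
        make_force_curve(config, modulus_true, salt=salt * 1009 + i)
        for i in range(n_repeats)
    ]


def make_follicle_curves(
    stage: int,
    genotype: str,
    config: GeneratorConfig,
    positions: tuple[str, ...] = ("pole", "terminal", "central", "terminal", "pole"),
    n_repeats: int = 4,
) -> list[tuple[str, list[ForceCurve]]]:
    """Per-position curve sets along one follicle's A–P axis.

    Each position receives ``n_repeats`` curves generated at the preset's
    exact regional modulus (noise, if any, enters only through the
    configured deflection noise).
    """
    preset = get_preset(stage, genotype)
    out = []
    for i, region in enumerate(positions):
        curves = make_position_curves(config, preset.modulus(region), n_repeats, salt=i + 1)
        out.append((region, curves))
    return out


def make_circumferential_curves(
    stage: int,
    genotype: str,
    config: GeneratorConfig,
    n_positions: int = 8,
    n_repeats: int = 4,
) -> list[tuple[float, list[ForceCurve]]]:
    """Curve sets around the central meridian of one follicle.

    The true modulus at each azimuth is the central preset value
    perturbed multiplicatively by the preset's circumferential CV,
    emulating the local heterogeneity of the basement-membrane shell.
    """
    preset = get_preset(stage, genotype)
    rng = config.rng(777)
    e0 = preset.modulus("central")
    azimuths = np.linspace(0.0, 360.0, n_positions, endpoint=False)
    out = []
    for i, az in enumerate(azimuths):
        e_true = e0 * max(0.05, 1.0 + preset.circumferential_cv / 100.0 * rng.standard_normal())
        curves = make_position_curves(config, e_true, n_repeats, salt=2000 + i)
        out.append((float(az), curves))
    return out


# ---------------------------------------------------------------------------
# follicle phantoms

#: Default image sampling (um): matches the confocal acquisition used for
#: in-toto stacks (0.17 um lateral pixels, 0.50 um axial steps).
DEFAULT_VOXEL_SIZE = (0.50, 0.17, 0.17)  # (z, y, x) um

_STAGE_SEMI_AXES = {  # um, (a along A-P, b, c transverse)
    3: (17.0, 15.0, 15.0),
    5: (25.0, 20.0, 20.0),
    7: (42.0, 27.0, 27.0),
    8: (55.0, 26.0, 26.0),
}


@dataclass
class FolliclePhantom:
    """Synthetic 3D stack of a follicle basement-membrane shell."""

    image_stack: np.ndarray  # (z, y, x) float32
    voxel_size: tuple  # (z, y, x) um
    ellipsoid_semi_axes: tuple  # (a, b, c) um, a along A-P (x axis)
    center: tuple  # (z, y, x) um
    ground_truth: dict = field(default_factory=dict)


def _genotype_intensity_params(genotype: str) -> dict:
    """Surface-intensity model parameters per genotype.

    ``ap_amplitude`` scales a Gaussian central elevation of the Collagen
    IV signal (negative = central depression); ``circ_sd`` is the sd of
    a smooth multiplicative modulation around the circumference;
    ``fibril`` selects the stripe texture orientation.
    """
    base = dict(ap_amplitude=0.5, ap_width=0.15, circ_sd=0.05,
                fibril="circumferential", fibril_amplitude=0.25, level=1.0)
    if genotype in ("fat2", "msn-KD"):
        base.update(ap_amplitude=0.0, circ_sd=0.20, fibril="tilted")
    elif genotype == "Dome-DN":
        base.update(ap_amplitude=0.0)
    elif genotype == "ColIV-KD":
        base.update(ap_amplitude=0.0, level=0.3, fibril="none", fibril_amplitude=0.0)
    elif genotype == "mirr>ColIV-KD":
        base.update(ap_amplitude=-0.4)
    elif genotype == "EHBP1-OE":
        base.update(level=1.3)
    elif genotype == "SPARC-KD":
        base.update(level=0.8)
    # WT, Perl-OE, fru>EHBP1 keep the default central-elevated profile
    return base


def surface_intensity(u: np.ndarray, phi: np.ndarray, params: dict,
                      rng: np.random.Generator,
                      arc_length_um: float = 60.0,
                      equator_radius_um: float = 15.0) -> np.ndarray:
    """Evaluate the ground-truth shell intensity at (u, phi) points.

    u is the normalized A–P arc fraction, phi the azimuth in radians.
    The field is level * (1 + A-P profile) * (1 + circumferential
    modulation) * (1 + fibril stripes). Fibril stripes are sinusoidal
    ridge families with a physical spatial frequency; their orientation
    (angle from the circumferential axis) encodes the planar polarity of
    the preset, and the azimuthal wavenumber is rounded to an integer so
    the texture stays periodic around the circumference.
    """
    ap = 1.0 + params["ap_amplitude"] * np.exp(
        -((u - 0.5) ** 2) / (2.0 * params["ap_width"] ** 2))

    # smooth periodic circumferential modulation from a few harmonics
    n_harm = 4
    amps = rng.standard_normal(n_harm)
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    circ = np.zeros_like(phi)
    for m in range(1, n_harm + 1):
        circ += amps[m - 1] * np.cos(m * phi + phases[m - 1])
    circ *= params["circ_sd"] / math.sqrt(n_harm / 2.0)  # unit-variance sum scaled to sd

    def stripe_family(angle_rad: float, q_um: float, amplitude: float) -> np.ndarray:
        # ridges oriented at `angle_rad` from the circumferential axis;
        # intensity varies along the perpendicular direction
        s_u = u * arc_length_um
        m_phi = int(round(2.0 * np.pi * equator_radius_um * q_um * math.sin(angle_rad)))
        return amplitude * np.cos(
            2.0 * np.pi * q_um * math.cos(angle_rad) * s_u
            - m_phi * phi + rng.uniform(0, 2 * np.pi))

    fib = np.zeros_like(u)
    amp = params["fibril_amplitude"]
    if amp > 0 and params["fibril"] == "circumferential":
        fib = stripe_family(0.0, 14.0 / arc_length_um, amp)
    elif amp > 0 and params["fibril"] == "tilted":
        # several stripe families at random orientations: locally
        # fibrous, globally disordered planar polarity
        for _ in range(5):
            angle = rng.uniform(0.0, np.pi)
            q = rng.uniform(0.10, 0.25)
            fib = fib + stripe_family(angle, q, amp / 2.8)
    return params["level"] * ap * (1.0 + circ) * (1.0 + fib)


def make_follicle_phantom(
    stage: int,
    genotype: str,
    config: GeneratorConfig,
    voxel_size: tuple = DEFAULT_VOXEL_SIZE,
    semi_axes: tuple | None = None,
    shell_sigma_um: float = 1.0,
    background: float = 0.02,
    noise_sd: float = 0.01,
    intensity_params: dict | None = None,
) -> FolliclePhantom:
    """Render an ellipsoidal basement-membrane shell stack.

    The shell is a Gaussian ridge of half-width ``shell_sigma_um`` around
    the ellipsoid surface; its brightness follows the genotype's surface-
    intensity model. The long (A–P) axis lies along image x.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; known: {', '.join(GENOTYPES)}")
    if stage not in _STAGE_SEMI_AXES:
        raise ValueError(f"no phantom preset for stage {stage}")
    a, b, c = semi_axes if semi_axes is not None else _STAGE_SEMI_AXES[stage]
    vz, vy, vx = voxel_size
    if shell_sigma_um < max(voxel_size):
        shell_sigma_um = max(voxel_size)  # shell thickness >= 1 voxel

    pad = 3.0 * shell_sigma_um + 2.0
    nx = int(round(2 * (a + pad) / vx))
    ny = int(round(2 * (b + pad) / vy))
    nz = int(round(2 * (c + pad) / vz))
    zc, yc, xc = nz * vz / 2.0, ny * vy / 2.0, nx * vx / 2.0

    zg = (np.arange(nz) + 0.5) * vz - zc
    yg = (np.arange(ny) + 0.5) * vy - yc
    xg = (np.arange(nx) + 0.5) * vx - xc
    Z, Y, X = np.meshgrid(zg, yg, xg, indexing="ij")

    # normalized radius and metric distance to the surface
    r = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)
    grad = np.sqrt((X / a**2) ** 2 + (Y / b**2) ** 2 + (Z / c**2) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(grad > 0, (r**2 - 1.0) / (2.0 * grad), np.inf)
    shell = np.exp(-(dist**2) / (2.0 * shell_sigma_um**2))

    # surface coordinates for the intensity field
    theta = np.arctan2(np.sqrt((Y / b) ** 2 + (Z / c) ** 2), X / a)
    phi = np.arctan2(Z / c, Y / b)
    u = _arc_fraction_from_theta(theta, a, 0.5 * (b + c))

    rng = config.rng(31)
    params = _genotype_intensity_params(genotype)
    if intensity_params:
        params.update(intensity_params)
    r_t = 0.5 * (b + c)
    t_arc = np.linspace(0.0, np.pi, 2049)
    ds = np.sqrt((a * np.sin(t_arc)) ** 2 + (r_t * np.cos(t_arc)) ** 2)
    arc_length = float(np.trapezoid(ds, t_arc))
    intensity = surface_intensity(u, phi, params, rng,
                                  arc_length_um=arc_length,
                                  equator_radius_um=r_t)

    stack = background + intensity * shell
    if noise_sd > 0:
        stack = stack + noise_sd * rng.standard_normal(stack.shape)
    stack = stack.astype(np.float32)

    return FolliclePhantom(
        image_stack=stack,
        voxel_size=(vz, vy, vx),
        ellipsoid_semi_axes=(a, b, c),
        center=(zc, yc, xc),
        ground_truth={
            "stage": stage,
            "genotype": genotype,
            "intensity_params": params,
            "preset": get_preset(stage, genotype),
            "shell_sigma_um": shell_sigma_um,
        },
    )


def _arc_fraction_from_theta(theta: np.ndarray, a: float, r_t: float) -> np.ndarray:
    """Normalized meridian arc fraction u for polar angle theta.

    The meridian point is (a*cos(theta), r_t*sin(theta)); u is cumulative
    arc length from the anterior pole normalized by the full pole-to-pole
    arc, evaluated by dense trapezoid quadrature.
    """
    t = np.linspace(0.0, np.pi, 2049)
    ds = np.sqrt((a * np.sin(t)) ** 2 + (r_t * np.cos(t)) ** 2)
    s = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2.0 * np.diff(t))])
    s /= s[-1]
    return np.interp(np.asarray(theta, dtype=float), t, s)


# ---------------------------------------------------------------------------
# ablation recoil tracks

def make_recoil_track(
    v0: float,
    L0: float,
    tau: float,
    config: GeneratorConfig,
    n_frames: int = 15,
    frame_interval: float = 0.3,
    noise_sd: float = 0.0,
    cut_orientation: str = "AP",
    position: str = "center",
    salt: int = 0,
) -> RecoilTrack:
    """Exponential-relaxation vertex-distance track after junction severing.

    ``L(t) = L0 + v0*tau*(1 - exp(-t/tau))`` sampled from the cut (t = 0)
    at ``frame_interval`` (default 0.3 s, the imaging cadence within which
    initial recoil is measured).
    """
    if v0 <= 0 or L0 <= 0 or tau <= 0:
        raise ValueError("v0, L0 and tau must be positive")
    t = np.arange(n_frames) * frame_interval
    L = L0 + v0 * tau * (1.0 - np.exp(-t / tau))
    if noise_sd > 0:
        L = L + noise_sd * config.rng(9000 + salt).standard_normal(L.shape)
    return RecoilTrack(
        times=t, vertex_distance=L, cut_orientation=cut_orientation,
        position=position, initial_length=L0,
        metadata={"v0_true": v0, "tau_true": tau, "synthetic": True},
    )


# ---------------------------------------------------------------------------
# osmotic swelling series

_BURST_PRESETS: dict[str, dict] = {
    # hazard: per-frame burst probability after immersion;
    # position: sampling weights over (pole, terminal, central) bands
    "WT": {"hazard": 0.04, "position": (0.70, 0.20, 0.10), "instant": False},
    "collagenase": {"hazard": 1.0, "position": (1 / 3, 1 / 3, 1 / 3), "instant": True},
    "fat2": {"hazard": 0.12, "position": (0.34, 0.33, 0.33), "instant": False},
    "msn-KD": {"hazard": 0.12, "position": (0.34, 0.33, 0.33), "instant": False},
    "ColIV-KD": {"hazard": 0.10, "position": (0.34, 0.33, 0.33), "instant": False},
    "SPARC-KD": {"hazard": 0.08, "position": (0.60, 0.25, 0.15), "instant": False},
    "EHBP1-OE": {"hazard": 0.0, "position": (0.70, 0.20, 0.10), "instant": False},
    "fru>EHBP1": {"hazard": 0.0, "position": (0.70, 0.20, 0.10), "instant": False},
    "mirr>ColIV-KD": {"hazard": 0.04, "position": (0.10, 0.15, 0.75), "instant": False},
    "Perl-OE": {"hazard": 0.10, "position": (0.45, 0.30, 0.25), "instant": False},
    "Dome-DN": {"hazard": 0.03, "position": (0.70, 0.20, 0.10), "instant": False},
}

# WT stage-dependent hazards: later stages resist bursting better
_WT_STAGE_HAZARD = {3: 0.10, 5: 0.08, 7: 0.04, 8: 0.025}


def _sample_burst_u(rng: np.random.Generator, weights: tuple) -> float:
    """Draw a burst arc coordinate from per-band weights (pole, term, central)."""
    band = rng.choice(3, p=np.asarray(weights) / np.sum(weights))
    if band == 0:  # pole, either end
        u = rng.uniform(0.0, regions.POLE_BOUNDARY)
    elif band == 1:
        u = rng.uniform(regions.POLE_BOUNDARY, regions.TERMINAL_BOUNDARY)
    else:
        u = rng.uniform(regions.TERMINAL_BOUNDARY, 0.5)
    if rng.random() < 0.5:
        u = 1.0 - u
    return float(u)


def _ellipse_outline(a: float, b: float, n: int = 200) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


def make_swelling_series(
    genotype: str,
    config: GeneratorConfig,
    stage: int = 7,
    n_frames: int = 40,
    frame_interval: float = 15.0,
    growth_rate: float = 0.004,
    salt: int = 0,
) -> SwellingSeries:
    """Osmotic-swelling outline series with genotype-dependent bursting.

    The follicle midplane is an ellipse whose area grows by
    ``2*growth_rate`` per frame while immersed; a burst (per-frame hazard
    from the genotype preset) abruptly deflates the outline and leaves a
    breach coordinate on the pre-burst ellipse. Frames are 15 s apart by
    default.
    """
    if genotype not in _BURST_PRESETS:
        raise ValueError(f"unknown genotype {genotype!r}; known: {', '.join(sorted(_BURST_PRESETS))}")
    preset = _BURST_PRESETS[genotype]
    hazard = preset["hazard"]
    if genotype == "WT":
        hazard = _WT_STAGE_HAZARD.get(stage, hazard)

    ax, bx, _ = _STAGE_SEMI_AXES.get(stage, _STAGE_SEMI_AXES[7])
    if genotype in ("fat2", "msn-KD", "ColIV-KD", "Perl-OE", "Dome-DN"):
        # round-egg genotypes: nearly isotropic outline
        ax = bx * 1.05

    rng = config.rng(5000 + salt)
    burst_frame: int | None = None
    if preset["instant"]:
        burst_frame = 1
    elif hazard > 0:
        for f in range(1, n_frames):
            if rng.random() < hazard:
                burst_frame = f
                break

    times = np.arange(n_frames) * frame_interval
    outlines: list[np.ndarray] = []
    breach: dict[int, tuple] = {}
    a_t, b_t = ax, bx
    for f in range(n_frames):
        if burst_frame is not None and f >= burst_frame:
            if f == burst_frame:
                a_t, b_t = a_t * 0.72, b_t * 0.72  # deflation: ~48% area drop
        else:
            if f > 0:
                a_t *= 1.0 + growth_rate
                b_t *= 1.0 + growth_rate
        outlines.append(_ellipse_outline(a_t, b_t))

    if burst_frame is not None:
        u_breach = _sample_burst_u(rng, preset["position"])
        # place breach on the pre-burst outline at arc fraction u
        a_pre = ax * (1.0 + growth_rate) ** (burst_frame - 1)
        b_pre = bx * (1.0 + growth_rate) ** (burst_frame - 1)
        t_dense = np.linspace(0.0, np.pi, 4097)
        ds = np.sqrt((a_pre * np.sin(t_dense)) ** 2 + (b_pre * np.cos(t_dense)) ** 2)
        s = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) / 2.0 * np.diff(t_dense))])
        s /= s[-1]
        t_b = float(np.interp(u_breach, s, t_dense))
        x_b, y_b = a_pre * math.cos(t_b), b_pre * math.sin(t_b)
        if rng.random() < 0.5:
            y_b = -y_b
        breach[burst_frame] = (float(x_b), float(y_b))

    return SwellingSeries(
        times=times,
        outlines=outlines,
        breach_channel=breach or None,
        genotype=genotype,
        stage=stage,
        metadata={
            "burst_frame_true": burst_frame,
            "burst_u_true": (None if burst_frame is None else u_breach),
            "synthetic": True,
        },
    )
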
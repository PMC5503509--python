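"""Tissue-level stiffness statistics: A–P profiles, anisotropy, variability.

Positional Young's-modulus measurements are aggregated into per-follicle
region means (pole / terminal / central, pooling anterior and posterior
instances), from which the gradient descriptors are computed:

* **anisotropy index** — central stiffness divided by the mean stiffness
  over the five A–P sample positions (pole, terminal, central, terminal,
  pole); 1 for a flat profile, invariant to rescaling;
* **percent difference** between two regions, ``100*(E_a - E_b)/E_b``;
* **circumferential variability** — population coefficient of variation
  of moduli sampled around a single meridian;
* **group comparisons** — two-tailed Welch t-tests with the conventional
  star thresholds (*p<0.05, **p<0.01, ***p<0.001; strict inequalities).

Only follicles in which all three lateral region labels were measured
count as complete and enter group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regions import REGION_LABELS, region_sample_positions


@dataclass
class StiffnessProfile:
    """Per-follicle map from A–P region to mean Young's modulus (Pa)."""

    follicle_id: str = ""
    stage: int | None = None
    genotype: str = ""
    region_means: dict = field(default_factory=dict)
    region_counts: dict = field(default_factory=dict)
    complete: bool = False

    def modulus(self, region: str) -> float:
        return self.region_means[region]


def aggregate_regions(
    measurements: list[tuple[str, float, float]] | pd.DataFrame,
    follicle_id: str = "",
    stage: int | None = None,
    genotype: str = "",
) -> StiffnessProfile:
    """Aggregate positional measurements into a per-follicle profile.

    ``measurements`` is a sequence of ``(region, azimuth_deg, modulus_pa)``
    tuples (or an equivalent DataFrame with columns ``region``/``modulus``).
    Anterior and posterior instances of pole and terminal positions are
    pooled into single region means. A profile is ``complete`` only when
    all three lateral region labels are present; incomplete follicles are
    excluded from group statistics downstream.
    """
    if isinstance(measurements, pd.DataFrame):
        rows = list(zip(measurements["region"], [0.0] * len(measurements),
                        measurements["modulus"]))
    else:
        rows = list(measurements)
    if not rows:
        raise ValueError("no measurements to aggregate")

    values: dict[str, list[float]] = {}
    for region, _az, e in rows:
        if region not in REGION_LABELS:
            raise ValueError(f"unknown region label {region!r}")
        values.setdefault(region, []).append(float(e))

    means = {r: float(np.mean(v)) for r, v in values.items()}
    counts = {r: len(v) for r, v in values.items()}
    complete = all(r in means for r in REGION_LABELS)
    return StiffnessProfile(
        follicle_id=follicle_id, stage=stage, genotype=genotype,
        region_means=means, region_counts=counts, complete=complete,
    )


def anisotropy_index(profile: StiffnessProfile) -> float:
    """Central stiffness over the mean stiffness along the A–P axis.

    The A–P mean is taken over the five sample positions (two poles, two
    terminals, one central). Equals 1 for flat profiles and is invariant
    to global rescaling of the moduli.
    """
    if not profile.complete:
        raise ValueError("anisotropy index requires a complete profile")
    sample = [profile.region_means[r] for r in region_sample_positions()]
    return float(profile.region_means["central"] / np.mean(sample))


def percent_difference(profile: StiffnessProfile, region_a: str, region_b: str) -> float:
    """Percent by which region_a exceeds region_b: 100*(E_a - E_b)/E_b."""
    for r in (region_a, region_b):
        if r not in profile.region_means:
            raise ValueError(f"region {r!r} missing from profile")
    e_a, e_b = profile.region_means[region_a], profile.region_means[region_b]
    return float(100.0 * (e_a - e_b) / e_b)


def var_p(values: np.ndarray) -> float:
    """Population variance (divide by N), the spreadsheet ``var.p``."""
    return float(np.var(np.asarray(values, dtype=float)))


def circumferential_variability(moduli: np.ndarray) -> float:
    """CV (%) of stiffness around one meridian: 100 * sd_p / mean.

    ``moduli`` are measurements at >= 3 azimuthal positions sharing one
    A–P coordinate; the population (divide-by-N) standard deviation is
    used.
    """
    moduli = np.asarray(moduli, dtype=float)
    if moduli.size < 3:
        raise ValueError("need at least 3 azimuthal positions")
    mean = float(np.mean(moduli))
    if mean == 0:
        raise ValueError("zero mean modulus")
    return float(100.0 * np.sqrt(var_p(moduli)) / mean)


def star_annotation(p_value: float) -> str:
    """Conventional significance stars; strict inequalities at thresholds."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    stars: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def compare_groups(group_a: np.ndarray, group_b: np.ndarray) -> GroupComparison:
    """Two-tailed Welch (unequal-variance) t-test between two cohorts."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("degenerate groups: zero variance in both")
    t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    p = float(p)
    return GroupComparison(
        statistic=float(t_stat), p_value=p, stars=star_annotation(p),
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        n_a=int(a.size), n_b=int(b.size),
    )


def profiles_to_frame(profiles: list[StiffnessProfile]) -> pd.DataFrame:
    """Tidy per-follicle table (kPa) of region means and derived indices."""
    rows = []
    for p in profiles:
        row = {
            "follicle_id": p.follicle_id, "stage": p.stage,
            "genotype": p.genotype, "complete": p.complete,
        }
        for r in REGION_LABELS:
            e = p.region_means.get(r)
            row[f"E_{r}_kPa"] = np.nan if e is None else e / 1e3
        if p.complete:
            row["anisotropy_index"] = anisotropy_index(p)
            row["central_vs_terminal_pct"] = percent_difference(p, "central", "terminal")
        rows.append(row)
    return pd.DataFrame(rows)
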
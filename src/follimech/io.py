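"""File I/O for the pipeline's plain-text and standard image formats.

Force curves travel as TSV (columns ``extension_m``, ``deflection_m``,
header required) or as HDF5 groups with metadata attributes; phantoms as
multi-page TIFF with a JSON ground-truth sidecar; recoil tracks and
swelling outlines as CSV; fit tables as CSV with units in the headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .afm import ForceCurve, IndentationFit


# ---------------------------------------------------------------------------
# force curves

def write_curve_tsv(curve: ForceCurve, path: str | Path) -> None:
    df = pd.DataFrame({
        "extension_m": curve.extension,
        "deflection_m": curve.deflection,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.12e")


def read_curve_tsv(path: str | Path, approach_speed: float = 0.4e-6) -> ForceCurve:
    df = pd.read_csv(path, sep="\t")
    for col in ("extension_m", "deflection_m"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return ForceCurve(
        extension=df["extension_m"].to_numpy(),
        deflection=df["deflection_m"].to_numpy(),
        approach_speed=approach_speed,
        sample_rate_points=len(df),
    )


def write_curves_hdf5(curves: list[ForceCurve], path: str | Path) -> None:
    """One HDF5 group per curve (curve_000, ...) with metadata attributes."""
    with h5py.File(path, "w") as f:
        for i, curve in enumerate(curves):
            g = f.create_group(f"curve_{i:03d}")
            g.create_dataset("extension_m", data=curve.extension)
            g.create_dataset("deflection_m", data=curve.deflection)
            g.attrs["approach_speed_m_s"] = curve.approach_speed
            g.attrs["sample_rate_points"] = curve.sample_rate_points
            if curve.spring_constant is not None:
                g.attrs["spring_constant_N_m"] = curve.spring_constant
            for key, val in curve.metadata.items():
                if isinstance(val, (int, float, str, bool)):
                    g.attrs[key] = val


def read_curves_hdf5(path: str | Path) -> list[ForceCurve]:
    curves = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            meta = {k: (v.item() if hasattr(v, "item") else v)
                    for k, v in g.attrs.items()
                    if k not in ("approach_speed_m_s", "sample_rate_points",
                                 "spring_constant_N_m")}
            curves.append(ForceCurve(
                extension=g["extension_m"][...],
                deflection=g["deflection_m"][...],
                approach_speed=float(g.attrs.get("approach_speed_m_s", 0.4e-6)),
                sample_rate_points=int(g.attrs.get("sample_rate_points", len(g["extension_m"]))),
                spring_constant=(float(g.attrs["spring_constant_N_m"])
                                 if "spring_constant_N_m" in g.attrs else None),
                metadata=meta,
            ))
    return curves


def fits_to_frame(fits: list[IndentationFit]) -> pd.DataFrame:
    """Per-curve fit table with units in the column names."""
    return pd.DataFrame([
        {
            "E_kPa": f.modulus / 1e3,
            "contact_point_nm": f.contact_point * 1e9,
            "rms_residual_pN": f.rms_residual * 1e12,
            "relative_residual": f.relative_residual,
            "n_samples": f.n_samples,
            "flags": ";".join(sorted(f.flags)) if f.flags else "",
        }
        for f in fits
    ])


# ---------------------------------------------------------------------------
# phantoms

def write_phantom(phantom, stack_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Multi-page TIFF plus JSON ground-truth sidecar."""
    stack_path = Path(stack_path)
    tifffile.imwrite(stack_path, phantom.image_stack)
    if sidecar_path is None:
        sidecar_path = stack_path.with_suffix(".json")
    truth = dict(phantom.ground_truth)
    preset = truth.pop("preset", None)
    if preset is not None:
        truth["preset"] = {
            "stage": preset.stage, "genotype": preset.genotype,
            "region_moduli_pa": preset.region_moduli,
            "circumferential_cv": preset.circumferential_cv,
            "collagen_factor": preset.collagen_factor,
        }
    payload = {
        "voxel_size_um_zyx": list(phantom.voxel_size),
        "ellipsoid_semi_axes_um": list(phantom.ellipsoid_semi_axes),
        "center_um_zyx": list(phantom.center),
        "ground_truth": truth,
    }
    Path(sidecar_path).write_text(json.dumps(payload, indent=2, default=str))


def read_phantom_stack(stack_path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a phantom TIFF and its JSON sidecar (if present)."""
    stack = tifffile.imread(stack_path)
    sidecar = Path(stack_path).with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return stack, meta


# ---------------------------------------------------------------------------
# tracks and outline series

def write_recoil_track_csv(track, path: str | Path) -> None:
    pd.DataFrame({"t_s": track.times, "L_um": track.vertex_distance}).to_csv(
        path, index=False, float_format="%.9g")


def read_recoil_track_csv(path: str | Path, initial_length: float,
                          cut_orientation: str = "AP",
                          position: str = "center"):
    from .epithelium import RecoilTrack

    df = pd.read_csv(path)
    for col in ("t_s", "L_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return RecoilTrack(
        times=df["t_s"].to_numpy(), vertex_distance=df["L_um"].to_numpy(),
        cut_orientation=cut_orientation, position=position,
        initial_length=initial_length,
    )


def write_swelling_series_csv(series, path: str | Path) -> None:
    """Long-format outline table: frame, t_s, vertex, x_um, y_um."""
    rows = []
    for i, (t, outline) in enumerate(zip(series.times, series.outlines)):
        for j, (x, y) in enumerate(np.asarray(outline)):
            rows.append({"frame": i, "t_s": t, "vertex": j, "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_swelling_series_csv(path: str | Path, genotype: str = "", stage: int | None = None):
    from .swelling import SwellingSeries

    df = pd.read_csv(path)
    for col in ("frame", "t_s", "vertex", "x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    times, outlines = [], []
    for frame, sub in df.groupby("frame", sort=True):
        times.append(float(sub["t_s"].iloc[0]))
        outlines.append(sub.sort_values("vertex")[["x_um", "y_um"]].to_numpy())
    return SwellingSeries(times=np.asarray(times), outlines=outlines,
                          genotype=genotype, stage=stage)
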
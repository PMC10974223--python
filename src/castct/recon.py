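"""Filtered backprojection reconstruction and HU calibration.

The primary path is 2-D slice FBP from parallel-beam log projections;
fan-beam data are rebinned to parallel first, and multi-row stacks are
reconstructed slice by slice (each detector row an independent slice).
Filtering happens in the frequency domain (ramp, optionally apodised with
Shepp-Logan or Hann windows) with zero-padding to the next power of two;
backprojection uses linear interpolation onto a grid centered on the
rotation axis.  Output voxels carry attenuation per mm; :func:`mu_to_hu`
maps them to Hounsfield units against a configurable water reference.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import tifffile

from .projdata import LogProjections, ScanGeometry, ScanMode

__all__ = [
    "Volume",
    "VolumeUnit",
    "fbp_reconstruct",
    "fbp_slice",
    "rebin_fan_to_parallel",
    "mu_to_hu",
    "read_volume",
    "write_volume",
    "MU_WATER_DEFAULT",
]

#: Water attenuation (per mm) at the effective energy of the packaged
#: 80 kVp-like spectrum; used as the default HU reference.
MU_WATER_DEFAULT = 0.0227


class VolumeUnit(str, Enum):
    MU = "mu"
    HU = "HU"


@dataclass
class Volume:
    """Reconstructed slice (2-D) or volume (3-D, z first) with isotropic
    in-plane voxel size in mm."""

    values: np.ndarray
    voxel_size: float
    unit: VolumeUnit = VolumeUnit.MU

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be 2-D or 3-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if not (self.voxel_size > 0):
            raise ValueError("voxel_size must be > 0")
        self.unit = VolumeUnit(self.unit)

    @property
    def is_3d(self) -> bool:
        return self.values.ndim == 3


def _ramp_filter(n: int, spacing: float, window: str) -> np.ndarray:
    """Frequency response of the reconstruction filter on an FFT grid of
    length ``n`` with sample spacing ``spacing`` (mm)."""
    f = np.fft.fftfreq(n, d=spacing)
    # band-limited ramp from its space-domain form (Kak & Slaney); sampling
    # |f| directly would misweight DC and bias the reconstruction low
    idx = np.concatenate([np.arange(n // 2 + 1), np.arange(-(n - n // 2 - 1), 0)])
    h = np.zeros(n)
    h[0] = 1.0 / (4.0 * spacing**2)
    odd = idx % 2 == 1
    h[odd] = -1.0 / (np.pi * idx[odd] * spacing) ** 2
    ramp = spacing * np.real(np.fft.fft(h))
    nyq = 0.5 / spacing
    if window == "ramp":
        win = np.ones_like(f)
    elif window == "shepp_logan":
        arg = np.pi * f / (2 * nyq)
        win = np.ones_like(f)
        nz = f != 0
        win[nz] = np.sin(arg[nz]) / arg[nz]
    elif window == "hann":
        win = 0.5 * (1 + np.cos(np.pi * f / nyq))
    else:
        raise ValueError(f"unknown filter {window!r}")
    return ramp * win


def _angular_weight(angles_deg: np.ndarray) -> float:
    """Integration weight per view (radians), halved for full-circle scans
    where each line is measured twice."""
    span = float(angles_deg[-1] - angles_deg[0])
    n = angles_deg.size
    dtheta = np.deg2rad(span) / (n - 1) if n > 1 else np.pi
    if span + span / max(n - 1, 1) < 180.0 - 1e-6:
        raise ValueError("angular coverage below 180 degrees is not supported")
    full_circle = span + span / max(n - 1, 1) > 270.0
    return dtheta * (0.5 if full_circle else 1.0)


def fbp_slice(
    sinogram: np.ndarray,
    angles_deg: np.ndarray,
    det_spacing: float,
    out_size: Optional[int] = None,
    voxel_size: Optional[float] = None,
    window: str = "ramp",
) -> np.ndarray:
    """Filtered backprojection of one sinogram ``(n_views, n_det)``.

    Returns a ``(out_size, out_size)`` image of attenuation per mm on a
    grid centered on the rotation axis.
    """
    sino = np.asarray(sinogram, dtype=np.float64)
    if sino.ndim != 2:
        raise ValueError("sinogram must be (n_views, n_det)")
    n_views, n_det = sino.shape
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size != n_views:
        raise ValueError("angles/views mismatch")
    if out_size is None:
        out_size = n_det
    if voxel_size is None:
        voxel_size = det_spacing
    weight = _angular_weight(angles)

    npad = 1 << int(np.ceil(np.log2(max(2 * n_det, 64))))
    filt = _ramp_filter(npad, det_spacing, window)
    proj_f = np.fft.fft(sino, n=npad, axis=1)
    filtered = np.real(np.fft.ifft(proj_f * filt[None, :], axis=1))[:, :n_det]

    s_axis = (np.arange(n_det) - (n_det - 1) / 2.0) * det_spacing
    coords = (np.arange(out_size) - (out_size - 1) / 2.0) * voxel_size
    x = coords[None, :]
    y = coords[:, None]
    out = np.zeros((out_size, out_size))
    for vi, ang in enumerate(np.deg2rad(angles)):
        s = x * np.cos(ang) + y * np.sin(ang)
        out += np.interp(s, s_axis, filtered[vi], left=0.0, right=0.0)
    return out * weight


def rebin_fan_to_parallel(
    P: LogProjections,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rebin a full-circle fan-beam sinogram stack to parallel geometry.

    A fan ray at source angle ``beta`` hitting detector offset ``u``
    coincides with the parallel ray at angle ``theta = beta + gamma`` and
    signed distance ``s = SOD * sin(gamma)``, ``gamma = atan(u / SDD)``.
    Returns ``(parallel stack (views, rows, cols), angles_deg,
    det_spacing_mm)`` on a uniform (theta, s) grid via bilinear
    interpolation.
    """
    geo = P.geometry
    if geo.mode is not ScanMode.FAN2D:
        raise ValueError("rebinning expects fan2d data")
    n_views, rows, n_det = P.values.shape
    sod, sdd = geo.source_object_dist, geo.source_detector_dist
    u = (np.arange(n_det) - (n_det - 1) / 2.0) * geo.pixel_pitch
    gamma = np.arctan2(u, sdd)
    betas = np.deg2rad(geo.angles)

    s_par = sod * np.sin(gamma)  # reuse the native ray spacing near axis
    s_grid = (np.arange(n_det) - (n_det - 1) / 2.0) * geo.iso_pixel_mm
    theta_grid = betas  # same angular sampling

    gamma_needed = np.arcsin(np.clip(s_grid / sod, -1, 1))
    u_needed = sdd * np.tan(gamma_needed)

    out = np.empty_like(P.values)
    period = 2 * np.pi
    for r in range(rows):
        # interpolate in beta for each target (theta, s): beta = theta - gamma
        for j, (g, un) in enumerate(zip(gamma_needed, u_needed)):
            beta_needed = (theta_grid - g) % period
            # sample fan sinogram at (beta_needed, un) bilinearly
            col = np.interp(un, u, np.arange(n_det))
            c0 = int(np.floor(col))
            c1 = min(c0 + 1, n_det - 1)
            fc = col - c0
            line0 = P.values[:, r, c0]
            line1 = P.values[:, r, c1]
            line = (1 - fc) * line0 + fc * line1
            # periodic interpolation over beta
            out[:, r, j] = np.interp(
                beta_needed,
                betas,
                line,
                period=period,
            )
    return out, np.rad2deg(theta_grid), geo.iso_pixel_mm


def fbp_reconstruct(
    P: LogProjections,
    window: str = "ramp",
    out_size: Optional[int] = None,
    voxel_size: Optional[float] = None,
) -> Volume:
    """Reconstruct a stack of log projections into a slice or volume.

    Parallel-beam data are reconstructed directly; fan-beam data are
    rebinned to parallel first.  Multi-row stacks yield a 3-D volume with
    one reconstructed slice per detector row.
    """
    geo = P.geometry
    if geo.mode is ScanMode.FAN2D:
        values, angles, spacing = rebin_fan_to_parallel(P)
    elif geo.mode is ScanMode.PARALLEL2D:
        values, angles, spacing = P.values, geo.angles, geo.iso_pixel_mm
    else:
        raise ValueError(f"unsupported reconstruction mode {geo.mode}")
    if voxel_size is None:
        voxel_size = spacing
    rows = values.shape[1]
    slices = [
        fbp_slice(values[:, r, :], angles, spacing, out_size, voxel_size, window)
        for r in range(rows)
    ]
    out = slices[0] if rows == 1 else np.stack(slices)
    return Volume(values=out, voxel_size=voxel_size, unit=VolumeUnit.MU)


def mu_to_hu(vol: Volume, mu_water: float = MU_WATER_DEFAULT) -> Volume:
    """Map attenuation to Hounsfield units: ``HU = 1000 (mu - mu_w)/mu_w``."""
    if vol.unit is not VolumeUnit.MU:
        raise ValueError("volume is not in attenuation units")
    if mu_water <= 0:
        raise ValueError("mu_water must be > 0")
    hu = 1000.0 * (vol.values - mu_water) / mu_water
    return Volume(values=hu, voxel_size=vol.voxel_size, unit=VolumeUnit.HU)


def write_volume(vol: Volume, path: str) -> None:
    tifffile.imwrite(path, vol.values.astype(np.float32))
    base, _ = os.path.splitext(path)
    with open(base + ".json", "w") as fh:
        json.dump({"voxel_size_mm": vol.voxel_size, "unit": vol.unit.value}, fh)


def read_volume(path: str) -> Volume:
    base, _ = os.path.splitext(path)
    sidecar = base + ".json"
    if not os.path.exists(sidecar):
        raise FileNotFoundError(f"missing volume sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    values = np.asarray(tifffile.imread(path), dtype=np.float64)
    return Volume(
        values=values,
        voxel_size=float(meta["voxel_size_mm"]),
        unit=VolumeUnit(meta["unit"]),
    )
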
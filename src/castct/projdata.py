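"""Projection data model and I/O.

Cone-beam / fan-beam CT projection stacks are stored as ``(view, row, col)``
arrays of detector intensities together with a :class:`ScanGeometry`
describing the acquisition.  The module covers the standard preprocessing
steps that precede any artifact correction: flat-field (white-field)
normalisation and the negative-log transform that turns intensities into
line integrals of the attenuation coefficient.

Files are exchanged as multipage TIFF stacks (or raw little-endian float32)
with a JSON geometry sidecar, so a stack round-trips losslessly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np
import tifffile

__all__ = [
    "ScanMode",
    "Provenance",
    "ScanGeometry",
    "ProjectionStack",
    "LogProjections",
    "flat_field_correct",
    "neg_log",
    "read_projection_stack",
    "write_projection_stack",
    "INTENSITY_FLOOR",
]

#: Lower clip applied to flat-field corrected intensities before the log
#: transform.  Keeps dead/opaque pixels finite; the induced bias on the log
#: projection is bounded by ``-ln(1e-6) ~ 13.8`` and only ever reached on
#: pixels that carried no signal anyway.
INTENSITY_FLOOR = 1e-6


class ScanMode(str, Enum):
    PARALLEL2D = "parallel2d"
    FAN2D = "fan2d"
    CONE3D = "cone3d"


class Provenance(str, Enum):
    RAW = "raw"
    DSC = "dsc"
    SCATTER_CORRECTED = "scatter_corrected"
    DSC_SAC = "dsc_sac"


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry.

    Angles are in degrees, counterclockwise, strictly increasing over
    [0, 360); angle 0 places the detector columns along +x.  Distances are
    in mm.  ``pixel_pitch`` is the physical detector pixel pitch; the
    sampling pitch at the isocenter is ``pixel_pitch / magnification``.
    """

    mode: ScanMode = ScanMode.PARALLEL2D
    source_object_dist: float = 400.0
    source_detector_dist: float = 680.0
    det_rows: int = 628
    det_cols: int = 628
    pixel_pitch: float = 0.238
    angles: np.ndarray = field(
        default_factory=lambda: np.arange(720) * (360.0 / 720)
    )

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "mode", ScanMode(self.mode))
        if not (self.source_object_dist > 0):
            raise ValueError("source_object_dist must be > 0")
        if self.source_detector_dist < self.source_object_dist:
            raise ValueError("need source_detector_dist >= source_object_dist")
        if angles.ndim != 1 or angles.size == 0:
            raise ValueError("angles must be a non-empty 1-D sequence")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if angles[0] < 0 or angles[-1] >= 360.0:
            raise ValueError("angles must lie in [0, 360)")
        if self.det_rows < 1 or self.det_cols < 1:
            raise ValueError("detector grid must be at least 1x1")
        if not (self.pixel_pitch > 0):
            raise ValueError("pixel_pitch must be > 0")

    @property
    def n_views(self) -> int:
        return int(self.angles.size)

    @property
    def magnification(self) -> float:
        return self.source_detector_dist / self.source_object_dist

    @property
    def iso_pixel_mm(self) -> float:
        """Detector sampling pitch referred to the isocenter (mm)."""
        return self.pixel_pitch / self.magnification

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "SOD": self.source_object_dist,
            "SDD": self.source_detector_dist,
            "rows": self.det_rows,
            "cols": self.det_cols,
            "pitch_mm": self.pixel_pitch,
            "angles_deg": self.angles.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            mode=ScanMode(d["mode"]),
            source_object_dist=float(d["SOD"]),
            source_detector_dist=float(d["SDD"]),
            det_rows=int(d["rows"]),
            det_cols=int(d["cols"]),
            pixel_pitch=float(d["pitch_mm"]),
            angles=np.asarray(d["angles_deg"], dtype=float),
        )


def _check_stack_shape(values: np.ndarray, geometry: ScanGeometry, what: str) -> None:
    expected = (geometry.n_views, geometry.det_rows, geometry.det_cols)
    if values.shape != expected:
        raise ValueError(
            f"{what} shape {values.shape} inconsistent with geometry {expected}"
        )


@dataclass
class ProjectionStack:
    """Raw detector intensities, white field, optional dark field."""

    intensities: np.ndarray
    geometry: ScanGeometry
    white: Optional[np.ndarray] = None
    dark: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (view, row, col)")
        _check_stack_shape(self.intensities, self.geometry, "intensities")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        det_shape = (self.geometry.det_rows, self.geometry.det_cols)
        if self.white is None:
            self.white = np.ones(det_shape)
        self.white = np.asarray(self.white, dtype=np.float64)
        if self.white.shape != det_shape:
            raise ValueError("white field shape mismatch")
        if self.dark is not None:
            self.dark = np.asarray(self.dark, dtype=np.float64)
            if self.dark.shape != det_shape:
                raise ValueError("dark field shape mismatch")

    @property
    def n_views(self) -> int:
        return self.intensities.shape[0]


@dataclass
class LogProjections:
    """Negative-log (line-integral) projections P, nonnegative."""

    values: np.ndarray
    geometry: ScanGeometry
    provenance: Provenance = Provenance.RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be (view, row, col)")
        _check_stack_shape(self.values, self.geometry, "values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log projections contain non-finite values")
        self.provenance = Provenance(self.provenance)

    def with_values(self, values: np.ndarray, provenance: Provenance) -> "LogProjections":
        return LogProjections(values=values, geometry=self.geometry, provenance=provenance)

    def sinogram(self, row: Optional[int] = None) -> np.ndarray:
        """A single-slice sinogram (n_views, n_cols) at detector row ``row``
        (defaults to the central row)."""
        if row is None:
            row = self.geometry.det_rows // 2
        return self.values[:, row, :]


def flat_field_correct(raw: ProjectionStack, floor: float = INTENSITY_FLOOR) -> np.ndarray:
    """Flat-field correction: ``Iffc = (I - dark) / (white - dark)``.

    The dark field defaults to zero.  Results are clipped into
    ``(floor, 1]``: values above one (possible with noise or scatter on
    unattenuated rays) carry no attenuation information and are clamped to
    one, while the positive floor keeps the subsequent log finite.
    """
    dark = raw.dark if raw.dark is not None else np.zeros_like(raw.white)
    denom = raw.white - dark
    bad = denom <= 0
    if np.any(bad):
        raise ValueError(
            f"white field not above dark field at {int(bad.sum())} pixel(s)"
        )
    iffc = (raw.intensities - dark[None]) / denom[None]
    return np.clip(iffc, floor, 1.0)


def neg_log(iffc: np.ndarray, geometry: ScanGeometry) -> LogProjections:
    """Negative-log transform ``P0 = -ln(Iffc)`` of flat-field corrected
    intensities in (0, 1]."""
    iffc = np.asarray(iffc, dtype=np.float64)
    if np.any(iffc <= 0) or np.any(iffc > 1.0 + 1e-12):
        raise ValueError("neg_log expects intensities in (0, 1]; clip upstream")
    values = -np.log(np.minimum(iffc, 1.0))
    return LogProjections(values=values, geometry=geometry, provenance=Provenance.RAW)


# ---------------------------------------------------------------------------
# I/O: TIFF stack or raw float32 + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".json"


def write_projection_stack(stack: ProjectionStack, path: str) -> None:
    """Write a stack as multipage float32 TIFF (or ``.raw`` little-endian
    float32) plus a JSON geometry sidecar; lossless at float32 precision."""
    arr = stack.intensities.astype(np.float32)
    meta = {
        "geometry": stack.geometry.to_dict(),
        "has_dark": stack.dark is not None,
    }
    if path.endswith(".raw"):
        arr.astype("<f4").tofile(path)
        base, _ = os.path.splitext(path)
        stack.white.astype("<f4").tofile(base + ".white.raw")
        if stack.dark is not None:
            stack.dark.astype("<f4").tofile(base + ".dark.raw")
    else:
        tifffile.imwrite(path, arr)
        base, _ = os.path.splitext(path)
        tifffile.imwrite(base + ".white.tif", stack.white.astype(np.float32))
        if stack.dark is not None:
            tifffile.imwrite(base + ".dark.tif", stack.dark.astype(np.float32))
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh)


def read_projection_stack(path: str) -> ProjectionStack:
    sidecar = _sidecar_path(path)
    if not os.path.exists(sidecar):
        raise FileNotFoundError(f"missing geometry sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    geometry = ScanGeometry.from_dict(meta["geometry"])
    base, _ = os.path.splitext(path)
    if path.endswith(".raw"):
        arr = np.fromfile(path, dtype="<f4").reshape(
            geometry.n_views, geometry.det_rows, geometry.det_cols
        )
        white = np.fromfile(base + ".white.raw", dtype="<f4").reshape(
            geometry.det_rows, geometry.det_cols
        )
        dark = None
        if meta.get("has_dark"):
            dark = np.fromfile(base + ".dark.raw", dtype="<f4").reshape(
                geometry.det_rows, geometry.det_cols
            )
    else:
        arr = tifffile.imread(path)
        if arr.dtype.kind not in "uf":
            raise ValueError(f"unsupported projection dtype {arr.dtype}")
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        white = tifffile.imread(base + ".white.tif")
        dark = tifffile.imread(base + ".dark.tif") if meta.get("has_dark") else None
    if arr.shape[0] != geometry.n_views:
        raise ValueError(
            f"sidecar declares {geometry.n_views} views, stack has {arr.shape[0]}"
        )
    return ProjectionStack(
        intensities=arr, geometry=geometry, white=white, dark=dark
    )
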
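"""Synthetic projection-data generator.

Scan data of real plaster casts are not shipped with the package, so every
stage of the correction pipeline is exercised against simulated scans whose
ground truth is known exactly.  The simulator produces:

* voxel phantoms (uniform disk, toothed gear, U-shaped dental arch with
  tooth-like protrusions, QA phantom with PMMA body / PVC insert / air),
* polychromatic Beer-Lambert forward projections on a parallel- or
  fan-beam geometry (ray-marching through per-material thickness maps),
* additive low-frequency scatter matched to the convolution model the
  correction inverts, and
* Poisson counting noise.

The spectrum is a small-bin 80 kVp-like model (Kramers shape with aluminum
filtration) with toy per-mm attenuation tables for the handful of materials
the phantoms use.  Only the qualitative physics matters here: a beam that
hardens, a scatter field that is broad and smooth, noise that scales with
the incident fluence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .projdata import ProjectionStack, ScanGeometry, ScanMode

__all__ = [
    "ENERGIES_KEV",
    "MATERIALS",
    "Spectrum",
    "Phantom",
    "default_spectrum",
    "make_phantom",
    "geometry_for_phantom",
    "forward_project",
    "material_thickness_sinograms",
    "inject_scatter",
    "add_poisson_noise",
]

#: Energy grid (keV) on which material attenuation is tabulated.
ENERGIES_KEV = np.array([30.0, 40.0, 50.0, 60.0, 70.0, 80.0])

#: Linear attenuation coefficients, per mm, at ENERGIES_KEV.  Toy values on
#: the right scale for each material (photoelectric-dominated decline with a
#: Compton floor); "plaster" models set dental stone (gypsum,
#: CaSO4.2H2O, bulk density ~2 g/cm3).
MATERIALS: dict[str, np.ndarray] = {
    "air": np.zeros(6),  # negligible at these path lengths
    "water": np.array([0.0376, 0.0268, 0.0227, 0.0206, 0.0194, 0.0184]),
    "pmma": np.array([0.0340, 0.0256, 0.0222, 0.0205, 0.0194, 0.0186]),
    "plaster": np.array([0.206, 0.102, 0.066, 0.050, 0.042, 0.036]),
    "aluminum": np.array([0.3049, 0.1535, 0.0994, 0.0750, 0.0630, 0.0545]),
    "pvc": np.array([0.320, 0.160, 0.095, 0.066, 0.052, 0.044]),
}


def mu_of(material: str, energies: np.ndarray) -> np.ndarray:
    """Per-mm attenuation of a packaged material, linearly interpolated
    onto ``energies`` (keV)."""
    if material not in MATERIALS:
        raise KeyError(f"unknown material {material!r}")
    return np.interp(np.asarray(energies, dtype=float), ENERGIES_KEV, MATERIALS[material])


@dataclass(frozen=True)
class Spectrum:
    """Discrete X-ray fluence spectrum; weights are normalised to sum 1."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        e = np.atleast_1d(np.asarray(self.energies, dtype=float))
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if e.shape != w.shape or e.size == 0:
            raise ValueError("energies and weights must be equal-length, nonempty")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / w.sum())

    @classmethod
    def mono(cls, energy_kev: float = 60.0) -> "Spectrum":
        return cls(energies=np.array([energy_kev]), weights=np.array([1.0]))

    @property
    def is_mono(self) -> bool:
        return self.energies.size == 1

    def effective_mu(self, material: str) -> float:
        """Fluence-weighted mean attenuation (thin-object limit), per mm."""
        return float(np.sum(self.weights * mu_of(material, self.energies)))


def default_spectrum(kvp: float = 80.0, filtration_mm_al: float = 2.0) -> Spectrum:
    """Kramers-shaped bremsstrahlung spectrum with aluminum filtration,
    sampled on the packaged energy grid up to ``kvp``."""
    e = ENERGIES_KEV[ENERGIES_KEV <= kvp]
    if e.size == 0:
        raise ValueError("kvp below the tabulated energy range")
    kramers = np.clip(kvp / e - 1.0, 0.0, None)
    filt = np.exp(-mu_of("aluminum", e) * filtration_mm_al)
    w = kramers * filt
    if w.sum() <= 0:  # kvp equal to the lowest bin
        w = np.ones_like(e)
    keep = w > 1e-12
    return Spectrum(energies=e[keep], weights=w[keep])


@dataclass
class Phantom:
    """Voxel phantom: integer material ids on a 2-D (y, x) or 3-D (z, y, x)
    grid with isotropic voxels; ``materials[id]`` names the material."""

    material_ids: np.ndarray
    voxel_size: float
    materials: tuple[str, ...]

    def __post_init__(self) -> None:
        self.material_ids = np.asarray(self.material_ids)
        if self.material_ids.ndim not in (2, 3):
            raise ValueError("material_ids must be 2-D or 3-D")
        if not (self.voxel_size > 0):
            raise ValueError("voxel_size must be > 0")
        if self.material_ids.max(initial=0) >= len(self.materials):
            raise ValueError("material id without a material entry")
        for name in self.materials:
            if name not in MATERIALS:
                raise KeyError(f"unknown material {name!r}")

    @property
    def is_3d(self) -> bool:
        return self.material_ids.ndim == 3

    def material_mask(self, material_id: int) -> np.ndarray:
        return (self.material_ids == material_id).astype(np.float64)

    def mu_image(self, spectrum: Spectrum) -> np.ndarray:
        """Effective-attenuation image (per mm) under ``spectrum``'s
        fluence-weighted mean attenuation; exact for monoenergetic beams."""
        out = np.zeros(self.material_ids.shape)
        for mid, name in enumerate(self.materials):
            out[self.material_ids == mid] = spectrum.effective_mu(name)
        return out

    def solid_mask(self) -> np.ndarray:
        """Boolean mask of non-air voxels (the object proper)."""
        air_ids = [i for i, n in enumerate(self.materials) if n == "air"]
        mask = np.ones(self.material_ids.shape, dtype=bool)
        for i in air_ids:
            mask &= self.material_ids != i
        return mask


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _grid_mm(n: int, voxel: float) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * voxel


def _disk(ids: np.ndarray, voxel: float, radius_mm: float) -> None:
    y = _grid_mm(ids.shape[0], voxel)[:, None]
    x = _grid_mm(ids.shape[1], voxel)[None, :]
    ids[x * x + y * y <= radius_mm * radius_mm] = 1


def _gear(ids: np.ndarray, voxel: float, radius_mm: float, n_teeth: int = 32) -> None:
    y = _grid_mm(ids.shape[0], voxel)[:, None]
    x = _grid_mm(ids.shape[1], voxel)[None, :]
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    # tooth profile: outer radius on tooth sectors, 82% of it between teeth
    tooth = np.cos(n_teeth * phi) > 0.0
    r_lim = np.where(tooth, radius_mm, 0.82 * radius_mm)
    ids[r <= r_lim] = 1


def _dental_arch_slice(
    shape: tuple[int, int],
    voxel: float,
    outer_mm: float,
    inner_mm: float,
    teeth: Sequence[tuple[float, float]],
    with_teeth: bool,
) -> np.ndarray:
    """U-shaped plaster slab opening toward -y, with optional tooth-like
    circular protrusions centered on the arch midline."""
    ids = np.zeros(shape, dtype=np.int16)
    y = _grid_mm(shape[0], voxel)[:, None]
    x = _grid_mm(shape[1], voxel)[None, :]
    r = np.hypot(x, y)
    arch = (r <= outer_mm) & (r >= inner_mm) & (y >= -0.15 * outer_mm)
    ids[arch] = 1
    if with_teeth:
        mid = 0.5 * (outer_mm + inner_mm)
        for ang, rt in teeth:
            cx, cy = mid * np.cos(ang), mid * np.sin(ang)
            ids[(x - cx) ** 2 + (y - cy) ** 2 <= rt * rt] = 1
    return ids


def _quart_like(ids: np.ndarray, voxel: float, radius_mm: float) -> None:
    """PMMA body with a central air bore holding a PVC rod (QA-phantom
    style): ids 0=air, 1=pmma, 2=pvc."""
    y = _grid_mm(ids.shape[0], voxel)[:, None]
    x = _grid_mm(ids.shape[1], voxel)[None, :]
    r = np.hypot(x, y)
    ids[r <= radius_mm] = 1
    ids[r <= 0.30 * radius_mm] = 0  # air bore
    ids[r <= 0.12 * radius_mm] = 2  # PVC rod


def make_phantom(
    kind: str,
    size: int = 128,
    voxel_size: float = 0.5,
    seed: int = 0,
    n_slices: Optional[int] = None,
) -> Phantom:
    """Build a packaged phantom.

    Parameters
    ----------
    kind:
        ``disk`` (uniform plaster cylinder), ``gear`` (toothed aluminum
        gear), ``dental_arch`` (U-shaped plaster slab with tooth-like
        protrusions; pass ``n_slices`` for a 3-D cast with a solid base),
        or ``quart_like`` (PMMA body, central PVC rod in an air bore).
    size:
        In-plane grid size (voxels).
    voxel_size:
        Isotropic voxel edge, mm.
    seed:
        Deterministic jitter of tooth placement for ``dental_arch``.
    n_slices:
        If given for ``dental_arch``, a 3-D phantom with this many z
        slices; other kinds are 2-D only.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    if size < 8:
        raise ValueError("size too small")
    half_mm = size * voxel_size / 2.0
    shape = (size, size)

    if kind == "disk":
        # ~26 mm plaster cylinder at the default grid: a cast-base slab
        ids = np.zeros(shape, dtype=np.int16)
        _disk(ids, voxel_size, 0.40 * half_mm)
        return Phantom(ids, voxel_size, ("air", "plaster"))

    if kind == "gear":
        ids = np.zeros(shape, dtype=np.int16)
        _gear(ids, voxel_size, 0.62 * half_mm)
        return Phantom(ids, voxel_size, ("air", "aluminum"))

    if kind == "quart_like":
        ids = np.zeros(shape, dtype=np.int16)
        _quart_like(ids, voxel_size, 0.72 * half_mm)
        return Phantom(ids, voxel_size, ("air", "pmma", "pvc"))

    if kind == "dental_arch":
        rng = np.random.default_rng(seed)
        outer = 0.66 * half_mm
        inner = 0.36 * half_mm
        n_teeth = 9
        base_ang = np.linspace(-0.12 * np.pi, 1.12 * np.pi, n_teeth)
        jitter = rng.uniform(-0.02, 0.02, n_teeth) * np.pi
        radii = 0.20 * (outer - inner) * rng.uniform(0.9, 1.3, n_teeth) + 0.55 * (
            outer - inner
        ) * 0.5
        teeth = list(zip(base_ang + jitter, radii))
        if n_slices is None:
            ids = _dental_arch_slice(shape, voxel_size, outer, inner, teeth, True)
            return Phantom(ids, voxel_size, ("air", "plaster"))
        if n_slices < 4:
            raise ValueError("need at least 4 slices for a 3-D dental arch")
        vol = np.zeros((n_slices, *shape), dtype=np.int16)
        n_base = max(2, int(round(0.3 * n_slices)))
        base = _dental_arch_slice(
            shape, voxel_size, 1.08 * outer, 0.92 * inner, teeth, False
        )
        crown = _dental_arch_slice(shape, voxel_size, outer, inner, teeth, True)
        vol[:n_base] = base
        vol[n_base:] = crown
        return Phantom(vol, voxel_size, ("air", "plaster"))

    raise ValueError(f"unknown phantom kind {kind!r}")


def geometry_for_phantom(
    phantom: Phantom,
    n_views: int = 180,
    mode: ScanMode = ScanMode.PARALLEL2D,
    magnification: float = 1.7,
    source_object_dist: float = 400.0,
) -> ScanGeometry:
    """A scan geometry whose detector sampling at the isocenter equals the
    phantom voxel size, so reconstructions land on the phantom grid."""
    ny, nx = phantom.material_ids.shape[-2:]
    rows = phantom.material_ids.shape[0] if phantom.is_3d else 1
    return ScanGeometry(
        mode=mode,
        source_object_dist=source_object_dist,
        source_detector_dist=source_object_dist * magnification,
        det_rows=rows,
        det_cols=nx,
        pixel_pitch=phantom.voxel_size * magnification,
        angles=np.arange(n_views) * (360.0 / n_views),
    )


# ---------------------------------------------------------------------------
# Forward projection
# ---------------------------------------------------------------------------

def _parallel_ray_coords(
    n_det: int, det_spacing: float, angle_deg: float, half_extent: float, step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample points (y, x) in mm, shape (n_det, n_t), for one parallel view."""
    theta = np.deg2rad(angle_deg)
    s = (np.arange(n_det) - (n_det - 1) / 2.0) * det_spacing
    t = np.arange(-half_extent, half_extent + step / 2, step)
    # detector axis along (cos t, sin t); ray direction perpendicular
    px = s[:, None] * np.cos(theta) - t[None, :] * np.sin(theta)
    py = s[:, None] * np.sin(theta) + t[None, :] * np.cos(theta)
    return py, px


def _fan_ray_coords(
    n_det: int,
    pitch: float,
    sod: float,
    sdd: float,
    angle_deg: float,
    half_extent: float,
    step: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample points along diverging rays for one fan view.

    Returns (y, x) sample coords, shape (n_det, n_t), and per-ray step
    lengths in mm (ray direction is unit, so steps are uniform)."""
    theta = np.deg2rad(angle_deg)
    # central ray direction w, detector axis u (rotate with the view)
    w = np.array([np.cos(theta), -np.sin(theta)])  # (y, x) components
    u = np.array([np.sin(theta), np.cos(theta)])
    src = -sod * w
    s = (np.arange(n_det) - (n_det - 1) / 2.0) * pitch
    det = src[None, :] + sdd * w[None, :] + s[:, None] * u[None, :]
    d = det - src[None, :]
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    # march only through the reconstruction-relevant neighborhood of the iso
    t = sod + np.arange(-half_extent, half_extent + step / 2, step)
    y = src[0] + d[:, 0:1] * t[None, :]
    x = src[1] + d[:, 1:2] * t[None, :]
    return y, x, np.full(n_det, step)


def material_thickness_sinograms(
    phantom: Phantom, geometry: ScanGeometry, step_factor: float = 0.5
) -> np.ndarray:
    """Per-material path lengths (mm) through the phantom.

    Returns an array of shape ``(n_materials, n_views, det_rows, det_cols)``.
    Line integrals are ray-marched with step ``step_factor * voxel_size``
    and bilinear sampling of each material's indicator image.
    """
    v = phantom.voxel_size
    step = step_factor * v
    ids = phantom.material_ids
    if phantom.is_3d and geometry.mode is not ScanMode.PARALLEL2D:
        raise ValueError("3-D phantoms are projected with parallel2d geometry")
    if phantom.is_3d and ids.shape[0] != geometry.det_rows:
        raise ValueError("det_rows must equal the number of phantom slices")
    if not phantom.is_3d and geometry.det_rows != 1:
        raise ValueError("2-D phantoms need det_rows == 1")
    ny, nx = ids.shape[-2:]
    half_extent = 0.5 * v * float(np.hypot(ny, nx)) + v
    n_det = geometry.det_cols
    n_mat = len(phantom.materials)
    out = np.zeros((n_mat, geometry.n_views, geometry.det_rows, n_det))

    masks = [
        (phantom.material_mask(m).reshape(-1, ny, nx)) for m in range(n_mat)
    ]

    for vi, ang in enumerate(geometry.angles):
        if geometry.mode is ScanMode.PARALLEL2D:
            y, x = _parallel_ray_coords(
                n_det, geometry.iso_pixel_mm, ang, half_extent, step
            )
            steps = step
        elif geometry.mode is ScanMode.FAN2D:
            y, x, _ = _fan_ray_coords(
                n_det,
                geometry.pixel_pitch,
                geometry.source_object_dist,
                geometry.source_detector_dist,
                ang,
                half_extent,
                step,
            )
            steps = step
        else:
            raise ValueError(f"unsupported mode {geometry.mode}")
        # mm -> fractional voxel indices (grid centered on the rotation axis)
        ry = y / v + (ny - 1) / 2.0
        rx = x / v + (nx - 1) / 2.0
        coords = np.stack([ry.ravel(), rx.ravel()])
        for m in range(n_mat):
            for z in range(geometry.det_rows):
                samp = ndimage.map_coordinates(
                    masks[m][z], coords, order=1, mode="constant", cval=0.0
                )
                out[m, vi, z] = samp.reshape(y.shape).sum(axis=1) * steps
    return out


def forward_project(
    phantom: Phantom,
    geometry: ScanGeometry,
    spectrum: Optional[Spectrum] = None,
    step_factor: float = 0.5,
) -> ProjectionStack:
    """Polychromatic Beer-Lambert projection.

    Per ray, ``I = sum_E w(E) * exp(-sum_m mu_m(E) * t_m)`` where ``t_m``
    is the ray-marched path length through material ``m``.  The white field
    is all ones (intensities are already fluence-normalised).
    """
    if spectrum is None:
        spectrum = default_spectrum()
    thick = material_thickness_sinograms(phantom, geometry, step_factor)
    mu = np.stack(
        [mu_of(name, spectrum.energies) for name in phantom.materials]
    )  # (n_mat, n_E)
    # optical depth per energy: (n_E, views, rows, cols)
    depth = np.einsum("me,mvrc->evrc", mu, thick)
    intens = np.einsum("e,evrc->vrc", spectrum.weights, np.exp(-depth))
    return ProjectionStack(intensities=intens, geometry=geometry)


# ---------------------------------------------------------------------------
# Scatter and noise
# ---------------------------------------------------------------------------

def inject_scatter(
    primary: ProjectionStack, spr: float, kernel_sigma_px: float
) -> ProjectionStack:
    """Add a broad scatter field to the primary intensities.

    The scatter field is ``S = spr * G_sigma * (white - I)`` per view: the
    attenuated (removed-from-beam) signal, redistributed by a unit-sum
    Gaussian of width ``kernel_sigma_px``.  This mirrors the convolution
    form the correction model assumes, so correcting it is a genuine
    inverse problem rather than a tautology.
    """
    if spr < 0:
        raise ValueError("spr must be >= 0")
    if spr == 0:
        return ProjectionStack(
            intensities=primary.intensities.copy(),
            geometry=primary.geometry,
            white=primary.white.copy(),
            dark=None if primary.dark is None else primary.dark.copy(),
        )
    deficit = primary.white[None] - primary.intensities
    sig_r = kernel_sigma_px if primary.geometry.det_rows > 1 else 0.0
    scatter = spr * ndimage.gaussian_filter(
        deficit, sigma=(0.0, sig_r, kernel_sigma_px), mode="nearest"
    )
    return ProjectionStack(
        intensities=primary.intensities + scatter,
        geometry=primary.geometry,
        white=primary.white.copy(),
        dark=None if primary.dark is None else primary.dark.copy(),
    )


def add_poisson_noise(
    stack: ProjectionStack, incident_counts: float = 2.0e4, seed: int = 0
) -> ProjectionStack:
    """Poisson counting noise: each pixel becomes
    ``Poisson(counts * I) / counts`` with a seeded generator."""
    if incident_counts <= 0:
        raise ValueError("incident_counts must be > 0")
    rng = np.random.default_rng(seed)
    lam = incident_counts * stack.intensities
    noisy = rng.poisson(lam).astype(np.float64) / incident_counts
    return ProjectionStack(
        intensities=noisy,
        geometry=stack.geometry,
        white=stack.white.copy(),
        dark=None if stack.dark is None else stack.dark.copy(),
    )
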
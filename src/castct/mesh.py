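"""Surface modeling and metrology.

From a reconstructed HU volume to a surface model and its accuracy: global
histogram threshold between the air and plaster peaks, marching-cubes
isosurface extraction into a triangle mesh in mm, binary/ASCII STL
round-trips, and deviation maps -- the unsigned Euclidean distance from
sampled points of a test surface to the nearest point of a reference
surface, summarised by the RMS error.

Distances are exact point-to-triangle distances (not vertex-to-vertex).
The accelerated query prunes triangles with a k-d tree over triangle
centroids plus a circumradius bound, which affects speed only: it returns
the same distances as the brute-force all-triangle scan.

The deviation map is directional (test -> reference) and therefore not
symmetric in its arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh as _trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure
from skimage.filters import threshold_otsu

from .recon import Volume, VolumeUnit

__all__ = [
    "TriangleMesh",
    "DeviationResult",
    "find_threshold",
    "extract_mesh",
    "mask_mesh",
    "write_stl",
    "read_stl",
    "deviation_map",
    "point_surface_distances",
    "rms_report",
]


@dataclass
class TriangleMesh:
    """Triangle surface mesh; vertices in mm, faces as vertex index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("non-finite vertex coordinates")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    def area(self) -> float:
        t = self.triangles()
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def drop_degenerate(self, eps: float = 1e-12) -> "TriangleMesh":
        t = self.triangles()
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        keep = 0.5 * np.linalg.norm(cross, axis=1) > eps
        return TriangleMesh(self.vertices, self.faces[keep])

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


@dataclass
class DeviationResult:
    """Unsigned point-to-surface distances (mm) and their RMS."""

    distances: np.ndarray
    rms: float
    n_points: int

    @classmethod
    def from_distances(cls, d: np.ndarray) -> "DeviationResult":
        d = np.asarray(d, dtype=np.float64)
        if d.size == 0:
            raise ValueError("no distances")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        return cls(distances=d, rms=float(np.sqrt(np.mean(d**2))), n_points=d.size)


# ---------------------------------------------------------------------------
# Segmentation and isosurface
# ---------------------------------------------------------------------------

def find_threshold(
    vol: Volume, n_bins: int = 256, smooth_bins: float = 3.0
) -> float:
    """Global segmentation threshold between the air and material peaks.

    Builds a smoothed intensity histogram, locates the two dominant peaks
    and returns the histogram minimum between them.  If the smoothed
    histogram has no interior minimum between two peaks, falls back to an
    inter-class-variance (Otsu) split with a warning.  A unimodal
    histogram raises.
    """
    if vol.unit is not VolumeUnit.HU:
        warnings.warn("find_threshold normally operates on HU volumes")
    vals = vol.values.ravel()
    counts, edges = np.histogram(vals, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = ndimage.gaussian_filter1d(counts.astype(float), smooth_bins)
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(smooth, prominence=0.05 * smooth.max())
    # rank peaks by height, keep well-separated dominant ones
    peaks = peaks[np.argsort(smooth[peaks])[::-1]]
    if peaks.size < 2:
        raise ValueError("histogram is unimodal; cannot segment")
    p1 = peaks[0]
    sep = peaks[np.abs(peaks - p1) > n_bins // 16]
    if sep.size == 0:
        raise ValueError("histogram is unimodal; cannot segment")
    p2 = sep[0]
    lo, hi = sorted((p1, p2))
    between = smooth[lo : hi + 1]
    imin = int(np.argmin(between)) + lo
    if imin in (lo, hi):
        warnings.warn("no interior histogram minimum; using Otsu fallback")
        return float(threshold_otsu(vals))
    return float(centers[imin])


def extract_mesh(vol: Volume, iso: float) -> TriangleMesh:
    """Marching-cubes isosurface of a 3-D volume at level ``iso``.

    Vertices are in mm on a grid centered on the rotation axis (matching
    reconstructed volumes); zero-area faces are dropped.
    """
    if not vol.is_3d:
        raise ValueError("isosurface extraction needs a 3-D volume")
    vmin, vmax = float(vol.values.min()), float(vol.values.max())
    if not (vmin < iso < vmax):
        raise ValueError(f"iso level {iso} outside value range [{vmin}, {vmax}]")
    verts, faces, _, _ = measure.marching_cubes(
        vol.values, level=iso, spacing=(vol.voxel_size,) * 3
    )
    center = (np.array(vol.values.shape) - 1) / 2.0 * vol.voxel_size
    mesh = TriangleMesh(verts - center[None, :], faces)
    return mesh.drop_degenerate()


def mask_mesh(
    mask: np.ndarray, voxel_size: float, presmooth_vox: float = 0.7
) -> TriangleMesh:
    """Surface of a boolean voxel mask (level 0.5), same centered-mm frame
    as :func:`extract_mesh`; used for ground-truth phantom surfaces.

    The binary indicator is lightly Gaussian-smoothed before contouring so
    the interpolated isosurface lands sub-voxel accurately instead of on
    the blocky voxel faces (which would inflate areas by ~10%).
    """
    field = mask.astype(np.float64)
    if presmooth_vox > 0:
        field = ndimage.gaussian_filter(field, presmooth_vox)
    vol = Volume(values=field, voxel_size=voxel_size)
    return extract_mesh(vol, 0.5)


# ---------------------------------------------------------------------------
# STL I/O (via trimesh; binary written, binary+ASCII read with sniffing)
# ---------------------------------------------------------------------------

def write_stl(mesh: TriangleMesh, path: str) -> None:
    mesh.to_trimesh().export(path, file_type="stl")


def read_stl(path: str) -> TriangleMesh:
    try:
        tm = _trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:  # malformed header / truncated body
        raise ValueError(f"cannot parse STL file {path}: {exc}") from exc
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"STL file {path} contains no triangles")
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# Point-to-surface distances
# ---------------------------------------------------------------------------

def _closest_dist_sq(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact squared point-triangle distances for all pairs.

    ``points``: (n, 3); ``tri``: (m, 3, 3).  Returns (n, m).  The closest
    point is either the orthogonal projection onto the triangle plane
    (when its barycentric coordinates are inside) or lies on one of the
    three edges; the minimum over those candidates is exact.
    """
    p = points[:, None, :]  # (n,1,3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    n = np.cross(ab, ac)  # (m,3)
    nn = np.einsum("md,md->m", n, n)
    nn = np.where(nn > 0, nn, 1.0)

    ap = p - a[None, :, :]  # (n,m,3)
    # barycentric coordinates of the in-plane projection
    d00 = np.einsum("md,md->m", ab, ab)
    d01 = np.einsum("md,md->m", ab, ac)
    d11 = np.einsum("md,md->m", ac, ac)
    d20 = np.einsum("nmd,md->nm", ap, ab)
    d21 = np.einsum("nmd,md->nm", ap, ac)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) > 1e-300, denom, 1.0)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    dist_plane = np.einsum("nmd,md->nm", ap, n) ** 2 / nn[None, :]

    best = np.where(inside, dist_plane, np.inf)
    for e0, e1 in ((a, b), (b, c), (c, a)):
        ev = e1 - e0  # (m,3)
        ee = np.einsum("md,md->m", ev, ev)
        ee = np.where(ee > 0, ee, 1.0)
        t = np.clip(np.einsum("nmd,md->nm", p - e0[None], ev) / ee[None, :], 0.0, 1.0)
        closest = e0[None, :, :] + t[:, :, None] * ev[None, :, :]
        d2 = np.einsum("nmd,nmd->nm", p - closest, p - closest)
        best = np.minimum(best, d2)
    return best


def point_surface_distances(
    points: np.ndarray, surface: TriangleMesh, method: str = "kdtree"
) -> np.ndarray:
    """Unsigned distance from each point to the nearest point of the
    surface.

    ``method="kdtree"`` prunes candidate triangles with a k-d tree over
    centroids (exact: a circumradius bound guarantees no nearer triangle
    is discarded); ``method="brute"`` scans every triangle and serves as
    the independent oracle.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if surface.n_faces == 0:
        raise ValueError("reference surface has no triangles")
    tri = surface.triangles()
    if method == "brute":
        out = np.empty(len(points))
        chunk = max(1, int(2e6 // max(surface.n_faces, 1)))
        for i in range(0, len(points), chunk):
            out[i : i + chunk] = np.sqrt(
                _closest_dist_sq(points[i : i + chunk], tri).min(axis=1)
            )
        return out
    if method != "kdtree":
        raise ValueError("method must be 'kdtree' or 'brute'")

    centroids = tri.mean(axis=1)
    circum = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    rmax = float(circum.max())
    tree = cKDTree(centroids)
    k = min(8, surface.n_faces)
    d0, idx0 = tree.query(points, k=k)
    d0 = d0.reshape(len(points), k)
    idx0 = idx0.reshape(len(points), k)
    out = np.empty(len(points))
    for i, pt in enumerate(points):
        cand = idx0[i]
        best = float(np.sqrt(_closest_dist_sq(pt[None], tri[cand]).min()))
        # any triangle containing a closer point has its centroid within
        # best + rmax of the query point
        more = tree.query_ball_point(pt, best + rmax + 1e-12)
        if len(more) > len(cand):
            best = float(np.sqrt(_closest_dist_sq(pt[None], tri[more]).min()))
        out[i] = best
    return out


def deviation_map(
    test: TriangleMesh,
    ref: TriangleMesh,
    sampling_ratio: float = 1.0,
    seed: int = 0,
    method: str = "kdtree",
) -> DeviationResult:
    """Deviation of a test surface from a reference surface.

    Samples ``sampling_ratio`` of the test mesh vertices (deterministic
    for a fixed seed) and measures each sample's unsigned Euclidean
    distance to the reference surface.  Directional: swapping the meshes
    changes the answer.
    """
    if test.n_faces == 0 or ref.n_faces == 0:
        raise ValueError("both meshes must be nonempty")
    if not (0 < sampling_ratio <= 1):
        raise ValueError("sampling_ratio must be in (0, 1]")
    pts = test.vertices
    if sampling_ratio < 1.0:
        rng = np.random.default_rng(seed)
        n = max(1, int(round(sampling_ratio * len(pts))))
        pts = pts[rng.choice(len(pts), size=n, replace=False)]
    d = point_surface_distances(pts, ref, method=method)
    return DeviationResult.from_distances(d)


def rms_report(uncorrected: DeviationResult, corrected: DeviationResult) -> float:
    """RMS improvement in percent: ``100 (rms_u - rms_c) / rms_u``."""
    if uncorrected.rms == 0:
        raise ValueError("uncorrected RMS is zero; improvement undefined")
    return 100.0 * (uncorrected.rms - corrected.rms) / uncorrected.rms
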
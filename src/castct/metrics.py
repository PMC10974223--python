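"""Image quality-assurance metrics.

Implements the usual CT QA measurements on reconstructed slices: ROI mean
and standard deviation (sample, n-1), SNR, feature/background contrast and
CNR, a five-ROI homogeneity score, edge-based MTF with the 10% and 50%
crossing frequencies in line pairs per mm, averaged line profiles, and a
cupping index quantifying bowl-shaped depression across a uniform object.

Conventions:

* contrast = mean(feature) - mean(background);
  CNR = contrast / std(background).
* homogeneity = CNR / (max pairwise difference of the five ROI means,
  normalised by the mean of the means).
* MTF: edge spread function averaged along an axis-aligned edge,
  differentiated to a line spread function, Fourier-transformed and
  normalised to MTF(0) = 1; crossings are linearly interpolated.
* cupping index = 100 * (mean(edge bands) - mean(central band)) /
  mean(edge bands) over a profile across the object's interior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .recon import Volume

__all__ = [
    "ROISpec",
    "QAReport",
    "roi_stats",
    "snr",
    "contrast_cnr",
    "homogeneity",
    "mtf_edge",
    "line_profile",
    "cupping_index",
]


@dataclass(frozen=True)
class ROISpec:
    """Rectangular or circular region of interest on a 2-D slice.

    ``center`` is (row, col) in voxels; ``extent`` is the half-widths
    (row, col) for a rectangle or a scalar radius for a circle.
    """

    shape: str
    center: tuple[float, float]
    extent: tuple[float, float] | float

    def __post_init__(self) -> None:
        if self.shape not in ("rect", "circle"):
            raise ValueError("shape must be 'rect' or 'circle'")

    def mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        ny, nx = image_shape
        r = np.arange(ny)[:, None]
        c = np.arange(nx)[None, :]
        cy, cx = self.center
        if self.shape == "circle":
            rad = float(self.extent)  # type: ignore[arg-type]
            m = (r - cy) ** 2 + (c - cx) ** 2 <= rad**2
            lo_ok = cy - rad >= -0.5 and cx - rad >= -0.5
            hi_ok = cy + rad <= ny - 0.5 and cx + rad <= nx - 0.5
        else:
            hy, hx = self.extent  # type: ignore[misc]
            m = (np.abs(r - cy) <= hy) & (np.abs(c - cx) <= hx)
            lo_ok = cy - hy >= -0.5 and cx - hx >= -0.5
            hi_ok = cy + hy <= ny - 0.5 and cx + hx <= nx - 0.5
        if not (lo_ok and hi_ok):
            raise ValueError("ROI extends outside the image")
        if not m.any():
            raise ValueError("ROI contains no voxels")
        return m


@dataclass
class QAReport:
    """Bundle of QA metrics for one slice (units follow the volume)."""

    contrast: float
    noise: float
    cnr: float
    homogeneity: float
    mtf10_lpmm: float
    mtf50_lpmm: float
    snr: float
    cupping_index_pct: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "QAReport":
        return cls(**json.loads(text))


def _slice_of(vol: Volume | np.ndarray) -> np.ndarray:
    if isinstance(vol, Volume):
        arr = vol.values
    else:
        arr = np.asarray(vol, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[arr.shape[0] // 2]
    return arr


def roi_stats(vol: Volume | np.ndarray, roi: ROISpec) -> tuple[float, float]:
    """Sample mean and (n-1) standard deviation over the ROI."""
    img = _slice_of(vol)
    vals = img[roi.mask(img.shape)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    std = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), std


def snr(vol: Volume | np.ndarray, roi: ROISpec) -> float:
    m, s = roi_stats(vol, roi)
    return np.inf if s == 0 else m / s


def contrast_cnr(
    vol: Volume | np.ndarray, roi_feature: ROISpec, roi_background: ROISpec
) -> tuple[float, float]:
    """Contrast (feature minus background mean) and CNR (contrast over the
    background standard deviation; infinite if the background is exactly
    uniform)."""
    mf, _ = roi_stats(vol, roi_feature)
    mb, sb = roi_stats(vol, roi_background)
    contrast = mf - mb
    cnr = np.inf if sb == 0 else contrast / sb
    return contrast, cnr


def homogeneity(
    vol: Volume | np.ndarray, rois: Sequence[ROISpec], cnr: float
) -> float:
    """CNR divided by the normalised maximum difference among five ROI
    means (the difference is normalised by the average of the means)."""
    if len(rois) != 5:
        raise ValueError("homogeneity is defined over exactly 5 ROIs")
    means = np.array([roi_stats(vol, r)[0] for r in rois])
    d = float(means.max() - means.min())
    if d == 0:
        import warnings

        warnings.warn("identical ROI means; homogeneity is infinite")
        return np.inf
    d_norm = d / float(means.mean())
    return cnr / d_norm


def mtf_edge(
    vol: Volume | np.ndarray,
    roi: ROISpec,
    pixel_size_mm: float,
    pad_factor: int = 8,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """MTF from an axis-aligned edge inside ``roi``.

    The edge orientation is taken from the dominant mean-gradient axis;
    profiles are averaged along the edge to an edge spread function,
    finite-differenced to a line spread function and Fourier-transformed.
    Returns ``(frequencies lp/mm, mtf, f10, f50)`` where f10/f50 are the
    first crossings of 0.10 and 0.50 (linearly interpolated).
    """
    img = _slice_of(vol)
    m = roi.mask(img.shape)
    rows = np.where(m.any(axis=1))[0]
    cols = np.where(m.any(axis=0))[0]
    sub = img[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    gy = np.abs(np.diff(sub, axis=0)).mean()
    gx = np.abs(np.diff(sub, axis=1)).mean()
    esf = sub.mean(axis=0) if gx >= gy else sub.mean(axis=1)
    span = esf.max() - esf.min()
    if span <= 0:
        raise ValueError("no edge found inside the ROI")
    drop = np.abs(esf[-1] - esf[0])
    if drop < 0.5 * span:
        raise ValueError("profile across the ROI is not a monotone edge")
    lsf = np.diff(esf)
    n = pad_factor * len(lsf)
    spec = np.abs(np.fft.rfft(lsf, n=n))
    if spec[0] == 0:
        raise ValueError("degenerate edge (zero net step)")
    mtf = spec / spec[0]
    freqs = np.fft.rfftfreq(n, d=pixel_size_mm)
    f10 = _first_crossing(freqs, mtf, 0.10)
    f50 = _first_crossing(freqs, mtf, 0.50)
    return freqs, mtf, f10, f50


def _first_crossing(freqs: np.ndarray, mtf: np.ndarray, level: float) -> float:
    below = np.where(mtf < level)[0]
    if below.size == 0 or below[0] == 0:
        raise ValueError(f"MTF never crosses {level}")
    i = below[0]
    f0, f1 = freqs[i - 1], freqs[i]
    m0, m1 = mtf[i - 1], mtf[i]
    return float(f0 + (m0 - level) * (f1 - f0) / (m0 - m1))


def line_profile(
    vol: Volume | np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    width: int = 1,
    n_samples: Optional[int] = None,
) -> np.ndarray:
    """Averaged intensity profile along the segment start->end (voxel
    coordinates, (row, col)), averaging over ``width`` parallel lines
    offset perpendicular to the segment."""
    from scipy import ndimage

    img = _slice_of(vol)
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValueError("degenerate segment")
    if width < 1:
        raise ValueError("width must be >= 1")
    if n_samples is None:
        n_samples = max(int(np.ceil(length)) + 1, 2)
    t = np.linspace(0.0, 1.0, n_samples)
    d = (p1 - p0) / length
    normal = np.array([-d[1], d[0]])
    offsets = np.arange(width) - (width - 1) / 2.0
    prof = np.zeros(n_samples)
    for off in offsets:
        pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :] + off * normal[None, :]
        prof += ndimage.map_coordinates(img, pts.T, order=1, mode="nearest")
    return prof / width


def cupping_index(profile: np.ndarray, band_frac: float = 0.2) -> float:
    """Percentage depression of the profile center relative to its ends.

    ``band_frac`` sets the fraction of the profile length used for the two
    edge bands and the central band.  Positive values mean cupping (center
    below edges); 0 for a flat profile.
    """
    p = np.asarray(profile, dtype=float).ravel()
    if p.size < 5:
        raise ValueError("profile too short")
    if not (0 < band_frac <= 0.45):
        raise ValueError("band_frac must be in (0, 0.45]")
    n = p.size
    k = max(1, int(round(band_frac * n)))
    edges = np.concatenate([p[:k], p[-k:]]).mean()
    c0 = (n - k) // 2
    center = p[c0 : c0 + k].mean()
    if edges == 0:
        raise ValueError("edge bands average to zero")
    return float(100.0 * (edges - center) / edges)
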
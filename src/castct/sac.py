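"""Scatter artifact correction (SAC).

Convolution-model scatter estimation for homogeneous objects: a powered
combination of the flat-field corrected intensity ``I`` and the log
projection ``P``,

    Pp  = K * I_eps**p * P**q
    Psc = Pp (*) G_sigma          (unit-sum Gaussian, per view)
    Pc  = P - Psc

``I_eps`` is the intensity thresholded at ``epsilon``: rays brighter than
``epsilon`` (short paths through little material) are zeroed so that only
strongly attenuating scan lines drive the estimate.  For a homogeneous
plaster cast ``epsilon = 1`` keeps every attenuated ray and only drops
fully unattenuated ones, which carry no object scatter.

``K`` sets the correction strength and should be small enough that the
subtraction never drives a projection negative; :func:`auto_cap_K` computes
the largest such ``K`` for a given data set.  The continuous kernel's
amplitude constant is absorbed into ``K`` by renormalising the discrete
Gaussian to unit sum, which keeps a flat field a fixed point of the
convolution and leaves ``K`` as the single strength knob.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .projdata import LogProjections, Provenance

__all__ = [
    "SACParams",
    "threshold_intensity",
    "scatter_basis",
    "gaussian_kernel",
    "estimate_scatter",
    "correct_scatter",
    "auto_cap_K",
    "sac_pipeline",
    "scale_sigma",
]

logger = logging.getLogger(__name__)

#: Detector width (pixels) at which the reference kernel width was tuned.
REFERENCE_DET_COLS = 628


@dataclass(frozen=True)
class SACParams:
    """Scatter-correction parameters.

    Defaults are the values tuned for plaster-cast micro-CT scans on a
    628-pixel-wide detector: ``K=0.3, sigma=70, p=1.7, q=0.9`` with the
    threshold disabled (``epsilon=1``) because the cast is homogeneous.
    """

    K: float = 0.3
    p: float = 1.7
    q: float = 0.9
    sigma_px: float = 70.0
    epsilon: float = 1.0
    truncation_radius: float = 4.0

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if not (self.sigma_px > 0):
            raise ValueError("sigma_px must be > 0")
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must be in (0, 1]")
        if self.truncation_radius <= 0:
            raise ValueError("truncation_radius must be > 0")

    def scaled_to(self, det_cols: int) -> "SACParams":
        """Same parameters with the kernel width rescaled to a detector of
        ``det_cols`` pixels (the reference width is 628)."""
        return replace(self, sigma_px=scale_sigma(self.sigma_px, det_cols))


def scale_sigma(sigma_px: float, det_cols: int) -> float:
    """Rescale a kernel width tuned on the reference 628-pixel detector to
    a grid of ``det_cols`` pixels covering the same field of view."""
    return sigma_px * det_cols / REFERENCE_DET_COLS


def threshold_intensity(iffc: np.ndarray, epsilon: float) -> np.ndarray:
    """Keep intensities below ``epsilon``, zero the rest.

    Values exactly 1 (fully unattenuated rays) are zeroed for any
    ``epsilon``: a ray that met no material contributes no object scatter.
    """
    if not (0 < epsilon <= 1):
        raise ValueError("epsilon must be in (0, 1]")
    iffc = np.asarray(iffc, dtype=np.float64)
    out = np.where(iffc < min(epsilon, 1.0 - 1e-12), iffc, 0.0)
    return out


def scatter_basis(i_eps: np.ndarray, P: np.ndarray, params: SACParams) -> np.ndarray:
    """Scatter basis ``Pp = K * I_eps**p * P**q`` (elementwise), with
    ``0**q := 0`` for ``q > 0``."""
    i_eps = np.asarray(i_eps, dtype=np.float64)
    P = np.asarray(P, dtype=np.float64)
    if i_eps.shape != P.shape:
        raise ValueError("intensity and log-projection shapes differ")
    if params.q <= 0 and np.any(P == 0):
        raise ValueError("q <= 0 is undefined on zero log projections")
    with np.errstate(divide="ignore", invalid="ignore"):
        ip = np.where(i_eps > 0, np.power(i_eps, params.p), 0.0)
        pq = np.where(P > 0, np.power(P, params.q), 0.0)
    return params.K * ip * pq


def gaussian_kernel(sigma_px: float, truncation_radius: float = 4.0, ndim: int = 2) -> np.ndarray:
    """Discrete unit-sum Gaussian kernel with profile
    ``exp(-(x^2+y^2)/(2 sigma^2))``, truncated at ``truncation_radius *
    sigma`` and renormalised.

    The amplitude constant of the continuous kernel is deliberately
    absorbed into the renormalisation (and hence into ``K``): a unit-sum
    kernel maps a constant field to itself, which keeps the correction
    strength interpretable.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be > 0")
    r = int(np.ceil(truncation_radius * sigma_px))
    x = np.arange(-r, r + 1, dtype=np.float64)
    g1 = np.exp(-(x**2) / (2.0 * sigma_px**2))
    if ndim == 1:
        k = g1[None, :]
    elif ndim == 2:
        k = g1[:, None] * g1[None, :]
    else:
        raise ValueError("ndim must be 1 or 2")
    return k / k.sum()


def estimate_scatter(Pp: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve the scatter basis with the kernel, per view.

    ``Pp`` may be a single view ``(rows, cols)`` or a stack
    ``(views, rows, cols)``.  Edge-replicate padding is used so a flat
    field stays flat up to the detector border (zero padding would carve a
    dark halo into the estimate).
    """
    Pp = np.asarray(Pp, dtype=np.float64)
    single = Pp.ndim == 2
    stack = Pp[None] if single else Pp
    if kernel.ndim != 2:
        raise ValueError("kernel must be 2-D")
    kr = (kernel.shape[0] - 1) // 2
    kc = (kernel.shape[1] - 1) // 2
    rows, cols = stack.shape[1:]
    # degenerate row dimension (single-slice sinograms) uses a 1-D kernel
    if rows == 1 and kernel.shape[0] > 1:
        kernel = kernel.sum(axis=0, keepdims=True)
        kr = 0
    if kernel.shape[0] > rows + 2 * kr or kernel.shape[1] > cols + 2 * kc:
        raise ValueError("kernel larger than the padded image")
    out = np.empty_like(stack)
    for v in range(stack.shape[0]):
        img = np.pad(stack[v], ((kr, kr), (kc, kc)), mode="edge")
        out[v] = signal.fftconvolve(img, kernel, mode="valid")
    np.clip(out, 0.0, None, out=out)  # FFT roundoff can leave tiny negatives
    return out[0] if single else out


def correct_scatter(
    P: LogProjections, Psc: np.ndarray, clamp: bool = True
) -> LogProjections:
    """Subtract the scatter estimate: ``Pc = P - Psc``.

    With ``clamp`` (the default), negative results are set to zero and
    their count logged; without it, any negative pixel raises, reporting
    the negative fraction -- the cue to lower ``K`` (or use
    :func:`auto_cap_K`).
    """
    Psc = np.asarray(Psc, dtype=np.float64)
    if Psc.shape != P.values.shape:
        raise ValueError("scatter estimate shape mismatch")
    pc = P.values - Psc
    neg = pc < 0
    n_neg = int(neg.sum())
    if n_neg:
        frac = n_neg / pc.size
        if not clamp:
            raise ValueError(
                f"scatter correction drove {frac:.3%} of pixels negative; "
                "reduce K or enable clamping"
            )
        logger.info("clamped %d negative pixels (%.3f%%)", n_neg, 100 * frac)
        pc = np.where(neg, 0.0, pc)
    return P.with_values(pc, Provenance.SCATTER_CORRECTED)


def auto_cap_K(
    P: LogProjections, iffc: np.ndarray, params: SACParams
) -> float:
    """Largest ``K`` for which ``P - Psc`` stays nonnegative everywhere.

    Computed once from the unit-strength estimate: ``K_max = min P / B``
    over pixels where the unit basis response ``B`` is positive.
    """
    unit = replace(params, K=1.0)
    i_eps = threshold_intensity(iffc, params.epsilon)
    basis = scatter_basis(i_eps, P.values, unit)
    kernel = gaussian_kernel(params.sigma_px, params.truncation_radius)
    b = estimate_scatter(basis, kernel)
    mask = b > 0
    if not np.any(mask):
        return np.inf
    return float(np.min(P.values[mask] / b[mask]))


def sac_pipeline(
    P: LogProjections,
    iffc: np.ndarray,
    params: SACParams,
    clamp: bool = True,
    auto_cap: bool = False,
) -> LogProjections:
    """Full scatter correction: threshold, basis, convolution, subtraction.

    With ``auto_cap`` the strength is limited to ``min(K, K_max)`` so the
    corrected projections cannot go negative.
    """
    if params.K == 0:
        return P.with_values(P.values.copy(), Provenance.SCATTER_CORRECTED)
    if auto_cap:
        kmax = auto_cap_K(P, iffc, params)
        if params.K > kmax:
            logger.info("auto-cap lowered K from %g to %g", params.K, kmax)
            params = replace(params, K=kmax)
    i_eps = threshold_intensity(iffc, params.epsilon)
    basis = scatter_basis(i_eps, P.values, params)
    kernel = gaussian_kernel(params.sigma_px, params.truncation_radius)
    psc = estimate_scatter(basis, kernel)
    return correct_scatter(P, psc, clamp=clamp)
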
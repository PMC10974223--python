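"""QA-phantom metrics before and after correction.

Scans a QA phantom (PMMA body, central PVC rod in an air bore) with
scatter and noise, and compares contrast-to-noise ratio and homogeneity
between the uncorrected reconstruction and the corrected + denoised one.
Also measures the MTF across a synthetic Gaussian edge to show the edge-
based frequency-response machinery.
"""

import numpy as np
from scipy.special import erf

from castct import (
    DSCParams,
    ROISpec,
    SACParams,
    Volume,
    add_poisson_noise,
    anlm_filter,
    contrast_cnr,
    correct_projections,
    default_spectrum,
    fbp_reconstruct,
    forward_project,
    geometry_for_phantom,
    homogeneity,
    inject_scatter,
    make_phantom,
    mtf_edge,
)
from castct.sac import scale_sigma

size = 128
phantom = make_phantom("quart_like", size=size, voxel_size=0.5)
geometry = geometry_for_phantom(phantom, n_views=180)
sigma = scale_sigma(70.0, size)
stack = add_poisson_noise(
    inject_scatter(forward_project(phantom, geometry, default_spectrum()), 0.1, sigma),
    2e4,
    seed=3,
)

vol_u = fbp_reconstruct(correct_projections(stack, "none", SACParams(), DSCParams()))
vol_c = anlm_filter(
    fbp_reconstruct(
        correct_projections(
            stack, "dsc_sac", SACParams(K=0.5, sigma_px=sigma), DSCParams(lam=1.0)
        )
    )
)

c = (size - 1) / 2
R = 0.72 * size / 2
pvc_roi = ROISpec("circle", (c, c), 0.12 * R)
pmma_rois = [
    ROISpec("circle", (c + 0.55 * R * np.sin(a), c + 0.55 * R * np.cos(a)), 6)
    for a in np.linspace(0, 2 * np.pi, 5, endpoint=False)
]
for name, vol in (("uncorrected", vol_u), ("corrected  ", vol_c)):
    contrast, cnr = contrast_cnr(vol, pvc_roi, pmma_rois[0])
    hom = homogeneity(vol, pmma_rois, cnr)
    print(f"{name}: contrast={contrast:.4f}  CNR={cnr:.1f}  homogeneity={hom:.0f}")

# MTF across a known Gaussian edge (0.5 mm blur, analytic f50 = 0.3748)
pixel = 0.05
x = (np.arange(400) - 200) * pixel
edge = Volume(np.tile(0.5 * (1 + erf(x / (0.5 * np.sqrt(2)))), (60, 1)), pixel)
_, _, f10, f50 = mtf_edge(edge, ROISpec("rect", (30, 199.5), (20, 150)), pixel)
print(f"MTF@50% = {f50:.4f} lp/mm (analytic 0.3748), MTF@10% = {f10:.4f} lp/mm")
print("Correction raises contrast and uniformity; the MTF check confirms")
print("the frequency-response measurement against a closed form.")
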
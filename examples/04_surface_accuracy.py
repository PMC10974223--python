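"""Full pipeline: from contaminated scan to surface model accuracy.

Simulates a 3-D dental arch with beam hardening, scatter and Poisson
noise; reconstructs it uncorrected and with the combined correction
(hardening remap + scatter subtraction + adaptive NLM denoising);
segments, meshes, and measures each surface against the phantom's ground
truth.  The figure of merit is the RMS of point-to-surface distances in
mm, the same metric used to validate digital dental models against
optical reference scans.
"""

import json

from castct import RunConfig, run_end_to_end

config = RunConfig(
    phantom="dental_arch",
    size=96,
    n_slices=32,
    voxel_size=0.5,
    n_views=180,
    spr=0.1,
    incident_counts=2e4,
    mode="dsc_sac",
    calibrate=True,  # tune lambda and K on a plaster calibration disk
    seed=0,
)
report = run_end_to_end(config)

u = report["modes"]["none"]
c = report["modes"]["dsc_sac"]
print(f"calibrated parameters      : lambda={report['calibrated']['lam']:.2f}, "
      f"K={report['calibrated']['K']:.2f}")
print(f"uncorrected surface RMS    : {u['surface_rms_mm']:.4f} mm "
      f"(threshold {u['threshold_hu']:.0f} HU, {u['n_faces']} faces)")
print(f"corrected surface RMS      : {c['surface_rms_mm']:.4f} mm "
      f"(threshold {c['threshold_hu']:.0f} HU, {c['n_faces']} faces)")
print(f"surface RMS reduced by     : {report['rms_improvement_pct']:.1f} %")
print("Artifact correction moves the segmented surface visibly closer to")
print("the true cast geometry, exactly as deviation maps against optical")
print("reference scans show for physical casts.")
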
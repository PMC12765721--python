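"""Measure de-novo plaque volume on one simulated tooth surface.

Builds a clean baseline crown (T0), grows a known plaque layer on it
(T4), corrupts T4 like a scanner would (noise + pose offset), then runs
the measurement chain: pre-align, trimmed best-fit ICP, signed thickness
field, VPI/AVPI.
"""

import numpy as np

from plaquemetry import (
    SyntheticSpec, add_plaque, best_fit_roi, compute_vpi, corrupt_scan,
    make_crown, pre_align, signed_distance_field,
)

spec = SyntheticSpec(edge_length=0.15, seed=4, scan_noise_sd=0.003,
                     pose_rotation_deg=2.0, pose_translation_mm=0.8)
mesh_t0, roi = make_crown(spec)
mesh_t4, truth = add_plaque(mesh_t0, roi, spec)
scanned_t4, applied_pose = corrupt_scan(mesh_t4, spec, np.random.default_rng(4))

report = best_fit_roi(scanned_t4, mesh_t0, init=pre_align(scanned_t4, mesh_t0))
aligned = scanned_t4.transformed(report.transform.rotation, report.transform.translation)
field = signed_distance_field(mesh_t0, aligned)
indices = compute_vpi(field)

print(f"alignment: trimmed mean abs distance {report.mean_abs_distance:.4f} mm "
      f"({report.iterations} iterations)")
print(f"VPI  = {indices.vpi:.3f} mm^3   (ground truth {truth.true_volume:.3f} mm^3)")
print(f"AVPI = {indices.avpi:.4f} mm^3/mm^2 over {indices.roi_area:.1f} mm^2")
print(f"covered fraction (>= {field.detection_limit} mm): {indices.covered_fraction:.3f}")
# VPI should land within a few percent of the simulator's analytic volume;
# the alignment residual reflects the injected 3-um scanner noise.
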
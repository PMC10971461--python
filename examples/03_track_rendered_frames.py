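"""Render camera frames for a few trials and recover displacements by tracking.

Uses a miniature camera geometry (320 x 240) so the example runs in seconds;
the tracker is the same code that handles full-resolution frames.
"""

import numpy as np

from ofrlab import qc, tracking
from ofrlab.synthetic import CameraModel, SubjectModel, render_session_frames, simulate_trial_table

cam = CameraModel(frame_width_px=320, frame_height_px=240, pupil_radius_px=18,
                  iris_radius_px=42, marker_radius_px=7,
                  pupil_center=(220.0, 120.0), marker_center=(70.0, 120.0), px_per_deg=40.0)
model = SubjectModel(n_trials_per_cell=3, fixation_noise_sd_deg=0.05,
                     px_per_deg=cam.px_per_deg, seed=11)

table = simulate_trial_table(model)
frames = render_session_frames(table, cam)
pupil_cfg, marker_cfg = tracking.detection_configs_for(cam)
tracked = tracking.track_session(frames, table[["trial_id", "condition", "direction"]],
                                 pupil_cfg, marker_cfg, cam.iris_radius_px * 1.5)

eye = qc.compute_eye_in_head(tracked, cam.px_per_deg)
merged = eye.merge(table[["trial_id", "true_eye_mov_deg"]], on="trial_id")
err_px = (merged["eye_dy_mov"] - merged["true_eye_mov_deg"]).abs() * cam.px_per_deg

print(f"trials tracked            : {len(tracked)}")
print(f"max |error| vs ground truth: {err_px.max():.4f} px "
      f"({err_px.max() / cam.px_per_deg * 3600:.1f} arcsec)")
print("\nrecovered vs true movement-epoch eye displacement (deg):")
print(merged[["trial_id", "condition", "direction", "eye_dy_mov", "true_eye_mov_deg"]]
      .head(6).round(4).to_string(index=False))
# Subpixel centroid tracking recovers displacements to a few millipixels,
# far below the ~0.05 px needed to resolve OFRs of a few tenths of a degree.
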
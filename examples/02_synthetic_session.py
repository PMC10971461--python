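"""Simulate one table-tier session with known ground truth.

A stereo-competent subject (true OFR 0.4 deg correlated, 0.15 deg
anticorrelated) performs 30 trials per condition x direction cell with
0.15 deg fixation noise; 15% of trials get a fixation saccade and 5% a blink.
"""

from ofrlab.synthetic import SubjectModel, simulate_trial_table

model = SubjectModel(saccade_rate=0.15, blink_rate=0.05, seed=7)
table = simulate_trial_table(model)

print(f"trials generated : {len(table)} (30 per cell, randomized block order)")
print("contamination    :", table["contaminated"].value_counts().to_dict())
print("\nper-cell counts:")
print(table.groupby(["condition", "direction"]).size().to_string())
print("\nfirst trials (displacements in px, vertical positive = up):")
cols = ["trial_id", "condition", "direction", "dy_pupil_mov", "dy_marker_mov", "blink_flag"]
print(table[cols].head(5).to_string(index=False))
# dy_pupil_mov mixes eye rotation (x 40 px/deg) and head translation; the
# marker column isolates the head so QC can recover eye-in-head downstream.
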
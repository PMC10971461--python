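"""Build one dichoptic random-line stimulus and verify its contract.

Draws the binary block profile, applies the raised-cosine low-pass filter
(unity gain below 0.375 cpd, zero above 0.75 cpd), normalizes to 30% RMS
contrast, pairs the eyes at interocular correlation +1 and -1, and renders
the 200 ms drifting sequence at 144 Hz.
"""

import numpy as np

from ofrlab import stimulus

spec = stimulus.StimulusSpec(seed=42)
pattern = stimulus.generate_line_profile(spec)
pattern = stimulus.lowpass_raised_cosine(pattern, spec)
pattern = stimulus.normalize_rms_contrast(pattern, spec.rms_contrast)

corr = stimulus.make_dichoptic_pair(pattern, +1)
anti = stimulus.make_dichoptic_pair(pattern, -1)
seq = stimulus.render_frame_sequence(corr, "up", spec)

f = np.fft.rfftfreq(pattern.values.size, d=spec.pixel_pitch_deg)
amp = np.abs(np.fft.rfft(pattern.values))

print(f"profile length        : {pattern.values.size} rows ({spec.aperture_deg} deg aperture)")
print(f"RMS contrast          : {pattern.rms:.6f}   (target {spec.rms_contrast})")
print(f"r (correlated pair)   : {np.corrcoef(corr.eye_a.values, corr.eye_b.values)[0, 1]:+.6f}")
print(f"r (anticorrelated)    : {np.corrcoef(anti.eye_a.values, anti.eye_b.values)[0, 1]:+.6f}")
print(f"stopband leakage      : {amp[f >= 0.75].max() / amp.max():.2e} of spectral peak")
print(f"frames rendered       : {seq.frames.shape[0]}  (200 ms at 144 Hz)")
print(f"measured drift speed  : {stimulus.measure_drift_speed(seq):.3f} deg/s  (nominal 50)")
# The two eyes' profiles differ only in sign, so both conditions share the
# same spectrum and contrast; any OFR difference between them can only come
# from interocular correlation.
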
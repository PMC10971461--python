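# Methods

## The measurement and its model

The pipeline quantifies the ocular-following response (OFR): the small,
reflexive vertical eye displacement evoked in the open-loop window
(80–160 ms after motion onset) by a large drifting pattern. Three camera
frames per trial — t₀ at stimulus onset, t₁ = 80 ms, t₂ = 160 ms — define a
*fixation epoch* (t₁ − t₀, the eye should be still) and a *movement epoch*
(t₂ − t₁, the open-loop response). The analysis chain is:

1. locate the pupil center and a head marker in each frame (subpixel);
2. per epoch, eye-in-head = pupil displacement − marker displacement,
   converted to degrees with the camera's px-per-deg scale;
3. exclude trials with blinks, out-of-frame features, or poor fixation;
4. per condition, OFR = mean vertical movement-epoch displacement for upward
   drift minus that for downward drift;
5. compare the correlated and anticorrelated OFRs by cell-wise bootstrap;
   a subject with bootstrap p < α is sensitive to interocular correlation.

## Stimulus model

The stimulus is a cyclic 1D luminance profile: blocks of
`block_rows_px = 2` pixel rows (0.06° at 0.03°/row) are assigned ±c i.i.d.
(symmetric about the mean), low-pass filtered, and normalized to RMS
contrast 0.30 (RMS of the mean-relative profile). The 28° aperture at
0.03°/px gives 933.3 px; the profile length is rounded to the nearest pixel
and then up to a whole number of blocks (934 rows, 467 blocks), keeping the
cyclic block structure exact.

Filtering is circular, in the DFT domain, with gain

G(f) = 1 for f ≤ 0.375 cpd; 0 for f ≥ 0.75 cpd;
½(1 + cos(π(f − 0.375)/0.375)) in between

— the standard raised cosine anchored at the stated corner frequencies (the
transition shape is named in the experimental description, its formula is
not; this is the canonical choice). Cyclic treatment is appropriate because
the pattern wraps behind a static aperture, and it makes drift exact.

Dichoptic pairing assigns the profile to one eye (red channel) and either
the identical (+1) or negated (−1) profile to the other (blue channel);
green is identically zero. Both conditions share spectra and contrast by
construction. Drift advances the profile by 50/144 ≈ 0.347° (≈11.57 rows)
per frame — a non-integer shift applied via the Fourier shift theorem, which
is an exact translation for the band-limited cyclic profile. Frames are
stored as vertical profiles (the pattern is constant along x) and
materialized to RGB on demand. Drift speed is recovered by circular
cross-correlation between consecutive frames with parabolic peak
interpolation; the default sequence measures 50 deg/s to ~5 × 10⁻⁴.

## Synthetic sessions

The generator emulates the study design: 2 conditions × 2 directions × 30
trials (120 per session), randomized block order. Movement-epoch vertical
eye displacement is Normal(±A/2, σ) so the expected up−down difference is
the condition amplitude A; fixation-epoch displacement is Normal(0, σ).
Defaults — A_corr = 0.4°, A_anti = 0.15°, σ = 0.15°, head noise 1 px,
px-per-deg = 40 — sit in the middle of the per-subject values of the
reference cohort (OFRs ≈ 0.1–0.7°, per-direction SDs ≈ 0.04–0.29°); a
stereo-deficient subject is modelled by A_anti = A_corr. The camera scale
(never stated in the clinical protocol) is explicit and configurable;
40 px/deg is plausible for a 50 mm lens at 2448 × 2048.

Contamination is deterministic in count (round(rate × n) per cell):
*saccades* add ≥10σ (12σ, floored at 1°) to the fixation-epoch vertical eye
displacement — the signal the QC screen targets; *blinks* mark the pupil
absent at t₁. Movement-epoch eye outliers are deliberately not injected and
not screened, mirroring the screening rule. Horizontal eye displacement is
pure noise (horizontal line stimuli drive vertical OFRs).

Two fidelity tiers share one table schema, so QC and statistics run
identically on generator output (fast) or on tracker output from rendered
frames. Rendering paints anti-aliased discs (iris, pupil, marker) with
1-px linear edge coverage; eye rotation maps to pupil translation linearly
(small-angle, displacements < 1°). Vertical displacements are
world-up-positive everywhere except inside image arrays (y down); the
renderer and the tracker each apply the flip once, in opposite directions.

What the generator does *not* model: eyelids, glints, iris texture, lens
distortion, torsion, photometric drift, or temporally correlated fixation
drift. Passing tests therefore demonstrate the correctness of the analysis
chain under the stated statistical model, not robustness to every artifact
of real infrared video.

## Tracking

Dark features are segmented by an Otsu threshold computed within a
configurable intensity window, 8-connected components filtered by area
bounds and a lenient circularity bound, and the winner (largest area;
area ties broken toward smaller centroid y then x, with halved quality)
localized by a darkness-weighted centroid: weights
clip((bg_local − I)/(bg_local − I_min), 0, 1) over the component's padded
bounding box, with pixels of other components zeroed and the local
background taken as the median rim intensity. For discs with linear edge
coverage this weight equals the geometric coverage, so the centroid is
essentially exact (measured RMSE ≈ 0.004 px noiseless; the contract used in
tests is < 0.05 px). Failures are values, not exceptions: a pupil not found
is a blink; any feature touching the image border is out-of-frame.

## Quality control

Robust SD is 1.4826 × MAD (consistent for the normal distribution) — the
canonical "robust estimate of the standard deviation". The screen iterates
{median, MAD, drop |x − m| > k·s} with k = 3 until a pass drops nothing
(cap 50 iterations). Degenerate rule: when MAD = 0, only values equal to the
median are kept. Screened channels — fixation eye, fixation head, movement
head, each on both axes — are pooled across the four condition × direction
cells: fixation quality and head motion are condition-agnostic, and
screening the movement-epoch eye per cell would bias the OFR, so it is
excluded by design. Exclusion reasons are prioritized
blink > out-of-frame > fix-eye > fix-head > mov-head.

Expected behavior worth stating: a 3σ rule applied to ~100 Gaussian values
occasionally trims an honest tail trial (~0.3% per screened value). The
exclusion-exactness test therefore asserts superset-plus-oracle properties
in the noisy regime and exact set equality in the zero-noise regime, where
the degenerate MAD rule makes the outcome deterministic.

## Statistics

Per condition (n−1 SDs): OFR = mean_up − mean_dw, SD = √(SD_up² + SD_dw²),
SEM = √(SD_up²/n_up + SD_dw²/n_dw). Direction significance: pooled-variance
unpaired t (the textbook default for "unpaired t-test"; Welch is a config
switch) and Mann–Whitney U — exact enumeration over labelings (midranks, so
ties are handled) when the smaller group has ≤ 8 trials, otherwise the
normal approximation with continuity and tie correction. Zero variance in
both groups with equal means returns p = 1 by convention.

The condition comparison resamples each of the four cells with replacement
at its own size (preserving the four-cell design), recomputes
Δ* = OFR_c* − OFR_ac*, and reports the add-one-corrected two-sided tail
probability of Δ* against zero, p = 2·min(#(Δ*≤0)+1, #(Δ*≥0)+1)/(B+1),
capped at 1 (so p ≥ 1/(B+1), never exactly zero). B defaults to 10,000.
Cells are sorted before resampling, making p bit-for-bit reproducible given
(seed, B) and invariant to trial order. Like any percentile-type bootstrap,
the test is mildly liberal at small cell sizes (the bootstrap SD
underestimates by ≈ √((n−1)/n) per cell); at the design's 30 trials/cell the
simulated type-I error is ≈ 0.057 at nominal 0.05. No multiple-testing
correction is applied across subjects: the design reports per-subject tests
at the nominal level, and cohort classification simply counts p < α.

## Reference cohort dataset

The 12-subject summary tables are shipped as a worked-example fixture.
Recomputing the derived columns from the printed per-direction moments
reproduces OFR and combined SD to ±0.001 (printed precision) for all 24
rows; the printed SEM column matches √(SD_up²/n_up + SD_dw²/n_dw) within
±0.001 for only 10 of 24 rows (worst deviation 0.004), so the remaining SEMs
were evidently derived differently (plausibly a bootstrap SE); the
consistent rows are frozen in `datasets.SEM_CONSISTENT_ROWS`. One control's
comparison p (0.048) is only just below α, and censored entries ("<0.001")
are stored at their bound.

## Simulation sizes and numerical choices

- Parameter-recovery check: 500 replicate sessions at 15 trials/cell,
  σ = 0.15°, true OFRs 0.4°/0.15°; bias bounded by 3 Monte-Carlo SEs.
- Type-I calibration: 1000 null sessions at the design's 30 trials/cell with
  B = 1000 bootstrap replicates each (p resolution 0.001, ample at α = 0.05),
  compared against the binomial 95% band around 0.05.
- Tracking accuracy: 100 random subpixel positions on a miniature
  (320 × 240) camera geometry; the tracker is resolution-agnostic.
- Drift measurement tolerance 1% (subpixel rendering and parabolic peak
  interpolation land ~3 orders of magnitude inside it).
- Seeds: a single top-level seed fans out to per-stage child seeds via
  `numpy.random.SeedSequence.spawn`; all seeds are recorded in run
  manifests, and every stochastic test fixes its generator explicitly.

## Known limitations

- The bootstrap variant (percentile-of-zero, two-sided, add-one) is one
  reasonable reading of "a bootstrap method"; published per-subject
  comparison p-values are not exactly recomputable from summary statistics,
  so they are used only through the α = 0.05 classification.
- The px-per-deg calibration is an input, not an estimate; real deployments
  would calibrate it per subject.
- Table-tier simulation bypasses the renderer/tracker; frame-tier coverage
  uses a reduced camera geometry for speed.
- The classifier's false-positive behavior (a stereo-normal subject with
  small OFRs can fail to show a correlation effect) is inherent to the
  per-subject significance design; this package reports the flag and leaves
  interpretation to the user.
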
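"""Synthetic OFR sessions with known ground truth.

The clinical recordings behind this kind of experiment are facial images and
cannot be shared, so every downstream stage is exercised on simulated data
instead.  Two fidelity tiers share one trial-table schema:

* **table tier** — per-trial pupil/marker displacement records drawn directly
  from the subject model (fast; exercises QC and statistics);
* **frame tier** — grayscale camera frames (dark pupil on an iris disc, dark
  head marker, optional pixel noise) rendered from those records at three
  acquisition times per trial (t0 = 0, t1 = 80, t2 = 160 ms), exercising the
  tracker as well.

The subject model follows the experiment's effect structure: upward drift
displaces the eye by +A/2 and downward by -A/2 in the movement epoch (so the
expected up-down difference is the condition's OFR amplitude A), fixation
noise is Gaussian, and a configurable fraction of trials is contaminated by
fixation-epoch saccades (large offsets) or blinks (missing pupil).

Vertical displacements use the analysis convention throughout: positive =
upward in the world.  The frame renderer converts to image coordinates
(y grows downward) and the tracker converts back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "SubjectModel",
    "CameraModel",
    "TRIAL_TABLE_COLUMNS",
    "simulate_trial_table",
    "render_trial_frames",
    "render_session_frames",
    "render_frame",
    "write_session_frames",
]

CONDITIONS = ("correlated", "anticorrelated")
DIRECTIONS = ("up", "down")

#: Shared trial-table schema (displacements in px, vertical positive = up).
TRIAL_TABLE_COLUMNS = [
    "trial_id", "condition", "direction",
    "dx_pupil_fix", "dy_pupil_fix", "dx_pupil_mov", "dy_pupil_mov",
    "dx_marker_fix", "dy_marker_fix", "dx_marker_mov", "dy_marker_mov",
    "blink_flag", "oof_flag",
]


@dataclass(frozen=True)
class SubjectModel:
    """True response amplitudes and noise/contamination rates for one subject.

    ``ofr_correlated_deg`` / ``ofr_anticorrelated_deg`` are the true up-minus-
    down movement-epoch displacements.  A stereo-competent subject has a
    smaller anticorrelated amplitude; a stereo-deficient subject has equal
    amplitudes.  Defaults are typical school-age values: 0.4 deg correlated,
    0.15 deg anticorrelated, 0.15 deg fixation noise, 30 trials per
    condition x direction cell.
    """

    ofr_correlated_deg: float = 0.40
    ofr_anticorrelated_deg: float = 0.15
    fixation_noise_sd_deg: float = 0.15
    head_noise_sd_px: float = 1.0
    saccade_rate: float = 0.0
    blink_rate: float = 0.0
    n_trials_per_cell: int = 30
    px_per_deg: float = 40.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.ofr_correlated_deg, self.ofr_anticorrelated_deg) < 0:
            raise ValueError("OFR amplitudes must be >= 0")
        if min(self.fixation_noise_sd_deg, self.head_noise_sd_px) < 0:
            raise ValueError("noise SDs must be >= 0")
        for r in (self.saccade_rate, self.blink_rate):
            if not 0 <= r <= 1:
                raise ValueError("contamination rates must be in [0, 1]")
        if self.n_trials_per_cell < 2:
            raise ValueError("need at least 2 trials per cell for downstream variance")
        if self.px_per_deg <= 0:
            raise ValueError("px_per_deg must be positive")

    def amplitude(self, condition: str) -> float:
        return {"correlated": self.ofr_correlated_deg,
                "anticorrelated": self.ofr_anticorrelated_deg}[condition]


@dataclass(frozen=True)
class CameraModel:
    """Geometry and photometry of the synthetic eye camera.

    Intensities are normalized luminances in [0, 1]; the pupil must be darker
    than the iris and the marker darker than the background (dark-feature
    tracking).  ``px_per_deg`` converts eye rotation to pupil-image
    translation (linear small-angle approximation).
    """

    frame_width_px: int = 2448
    frame_height_px: int = 2048
    pupil_radius_px: float = 60.0
    pupil_intensity: float = 0.08
    iris_radius_px: float = 140.0
    iris_intensity: float = 0.45
    marker_radius_px: float = 18.0
    marker_intensity: float = 0.05
    background_intensity: float = 0.75
    px_per_deg: float = 40.0
    noise_sd: float = 0.0
    pupil_center: tuple[float, float] = (1500.0, 1000.0)  # (x, y) image px
    marker_center: tuple[float, float] = (500.0, 1000.0)

    def __post_init__(self) -> None:
        if not self.pupil_intensity < self.iris_intensity:
            raise ValueError("pupil must be darker than the iris")
        if not self.marker_intensity < self.background_intensity:
            raise ValueError("marker must be darker than the background")
        if self.px_per_deg <= 0:
            raise ValueError("px_per_deg must be positive")


def _contaminate_counts(n: int, rate: float) -> int:
    # deterministic contamination budget: rate x n rounded to nearest trial
    return int(round(rate * n))


def simulate_trial_table(model: SubjectModel, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw one session's per-trial displacement table plus ground truth.

    Returns a DataFrame with the :data:`TRIAL_TABLE_COLUMNS` schema and, as
    extra ``true_*``/``contaminated`` columns, the ground-truth record for
    every trial.  Movement-epoch vertical eye displacement is
    Normal(+A/2, sigma) for upward drift and Normal(-A/2, sigma) for downward;
    fixation-epoch displacement is Normal(0, sigma).  Exactly
    round(rate x n) trials per cell receive a fixation-epoch saccade offset
    (>= 10 sigma) or a blink flag; trials are emitted in randomized block
    order.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    sigma = model.fixation_noise_sd_deg
    head_sd = model.head_noise_sd_px
    n = model.n_trials_per_cell
    # saccade offset: at least 10x the fixation noise, with a floor so the
    # zero-noise regime still produces an unmistakable outlier
    saccade_offset = max(12.0 * sigma, 1.0)

    rows = []
    for condition in CONDITIONS:
        amp = model.amplitude(condition)
        for direction in DIRECTIONS:
            eye_mov_mean = +amp / 2.0 if direction == "up" else -amp / 2.0
            n_sacc = _contaminate_counts(n, model.saccade_rate)
            n_blink = _contaminate_counts(n, model.blink_rate)
            if n_sacc + n_blink > n:
                raise ValueError("contamination rates exceed the trial budget")
            tags = np.array(
                ["saccade"] * n_sacc + ["blink"] * n_blink + ["none"] * (n - n_sacc - n_blink)
            )
            rng.shuffle(tags)
            for tag in tags:
                eye_fix = rng.normal(0.0, sigma, size=2)   # (dx, dy) deg
                eye_mov = np.array([rng.normal(0.0, sigma), rng.normal(eye_mov_mean, sigma)])
                if tag == "saccade":
                    eye_fix[1] += saccade_offset * rng.choice([-1.0, 1.0])
                head_fix = rng.normal(0.0, head_sd, size=2)  # px
                head_mov = rng.normal(0.0, head_sd, size=2)
                rows.append({
                    "condition": condition,
                    "direction": direction,
                    "true_eye_fix_deg": eye_fix[1],
                    "true_eye_mov_deg": eye_mov[1],
                    "true_head_fix_px": head_fix[1],
                    "true_head_mov_px": head_mov[1],
                    "contaminated": tag,
                    "dx_pupil_fix": head_fix[0] + eye_fix[0] * model.px_per_deg,
                    "dy_pupil_fix": head_fix[1] + eye_fix[1] * model.px_per_deg,
                    "dx_pupil_mov": head_mov[0] + eye_mov[0] * model.px_per_deg,
                    "dy_pupil_mov": head_mov[1] + eye_mov[1] * model.px_per_deg,
                    "dx_marker_fix": head_fix[0], "dy_marker_fix": head_fix[1],
                    "dx_marker_mov": head_mov[0], "dy_marker_mov": head_mov[1],
                    "blink_flag": tag == "blink",
                    "oof_flag": False,
                })
    table = pd.DataFrame(rows)
    # randomized block order across the whole session
    order = rng.permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)
    table.insert(0, "trial_id", np.arange(len(table)))
    return table


# ---------------------------------------------------------------------------
# frame rendering


def _disc(img: np.ndarray, cx: float, cy: float, radius: float, intensity: float) -> None:
    """Paint an anti-aliased filled disc; edge coverage ramps linearly over
    one pixel so the darkness-weighted centroid stays at the true subpixel
    center."""
    h, w = img.shape
    x0, x1 = max(0, int(cx - radius) - 2), min(w, int(cx + radius) + 3)
    y0, y1 = max(0, int(cy - radius) - 2), min(h, int(cy + radius) + 3)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    coverage = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    img[y0:y1, x0:x1] = img[y0:y1, x0:x1] * (1 - coverage) + intensity * coverage


def render_frame(
    cam: CameraModel,
    pupil_xy: tuple[float, float] | None,
    marker_xy: tuple[float, float],
    rng: np.random.Generator | None,
) -> np.ndarray:
    img = np.full((cam.frame_height_px, cam.frame_width_px), cam.background_intensity)
    if pupil_xy is not None:
        _disc(img, pupil_xy[0], pupil_xy[1], cam.iris_radius_px, cam.iris_intensity)
        _disc(img, pupil_xy[0], pupil_xy[1], cam.pupil_radius_px, cam.pupil_intensity)
    _disc(img, marker_xy[0], marker_xy[1], cam.marker_radius_px, cam.marker_intensity)
    if rng is not None and cam.noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, cam.noise_sd, img.shape), 0.0, 1.0)
    return img


def render_trial_frames(
    trial: pd.Series, cam: CameraModel, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Render the three frames (t0, t1, t2) of one trial row.

    The pupil moves by head + eye x px_per_deg per epoch, the marker by the
    head components only.  Vertical displacements in the table are
    world-up-positive and are negated for image rows (y grows downward).
    A blink trial renders the pupil absent at t1.
    """
    px, py = cam.pupil_center
    mx, my = cam.marker_center

    def img_delta(dx: float, dy: float) -> tuple[float, float]:
        return dx, -dy  # world up -> smaller image y

    p_fix = img_delta(trial["dx_pupil_fix"], trial["dy_pupil_fix"])
    p_mov = img_delta(trial["dx_pupil_mov"], trial["dy_pupil_mov"])
    m_fix = img_delta(trial["dx_marker_fix"], trial["dy_marker_fix"])
    m_mov = img_delta(trial["dx_marker_mov"], trial["dy_marker_mov"])

    pupil_positions: list[tuple[float, float] | None] = [
        (px, py),
        (px + p_fix[0], py + p_fix[1]),
        (px + p_fix[0] + p_mov[0], py + p_fix[1] + p_mov[1]),
    ]
    marker_positions = [
        (mx, my),
        (mx + m_fix[0], my + m_fix[1]),
        (mx + m_fix[0] + m_mov[0], my + m_fix[1] + m_mov[1]),
    ]
    if bool(trial.get("blink_flag", False)):
        pupil_positions[1] = None
    return [
        render_frame(cam, p, m, rng)
        for p, m in zip(pupil_positions, marker_positions)
    ]


def render_session_frames(
    trial_table: pd.DataFrame, cam: CameraModel, rng: np.random.Generator | None = None
) -> dict[int, list[np.ndarray]]:
    """Render every trial of a session table; returns {trial_id: [f0, f1, f2]}.

    Displacements that push a feature outside the frame are rendered anyway
    (the feature is simply clipped); the tracker is responsible for flagging
    them, mirroring how out-of-frame trials are discarded downstream.
    """
    return {
        int(trial["trial_id"]): render_trial_frames(trial, cam, rng)
        for _, trial in trial_table.iterrows()
    }


def write_session_frames(
    frames: dict[int, list[np.ndarray]], out_dir: str | Path, bit_depth: int = 8
) -> list[Path]:
    """Write frames as grayscale PNGs named ``{trial:04d}_{t0|t1|t2}.png``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scale = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    paths = []
    for trial_id, triplet in frames.items():
        for label, frame in zip(("t0", "t1", "t2"), triplet):
            path = out_dir / f"{trial_id:04d}_{label}.png"
            iio.imwrite(path, np.round(np.clip(frame, 0, 1) * scale).astype(dtype))
            paths.append(path)
    return paths
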
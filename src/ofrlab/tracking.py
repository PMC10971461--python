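"""Subpixel pupil and head-marker localization in camera frames.

Three frames are acquired per trial — t0 at stimulus onset, t1 = 80 ms (the
typical human ocular-following latency) and t2 = 160 ms (end of the open-loop
phase).  Displacements of the pupil center and of a dark marker on the nose
bridge are measured over the *fixation* epoch (t1 - t0) and the *movement*
epoch (t2 - t1).  Both features are dark blobs on a brighter surround, so
detection is: Otsu threshold inside a configurable intensity window, connected
components filtered by area and circularity, then a darkness-weighted subpixel
centroid.  Detection failures are reported via ``valid=False`` (never raised):
a missing pupil is a blink, a feature cut by the image border is out-of-frame.

Coordinates are image pixels, origin top-left, 0-based, y growing downward.
Analysis space uses positive-vertical = upward in the world, so the vertical
component of every displacement is sign-flipped here, once, at measurement
time; everything downstream (QC, statistics) lives in world-up convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "DetectionConfig",
    "FeatureLocation",
    "FrameTriplet",
    "TrialMeasurement",
    "detect_pupil",
    "detect_marker",
    "detect_dark_blob",
    "measure_trial",
    "track_session",
    "detection_configs_for",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Area/intensity bounds for one dark feature.

    ``intensity_window`` restricts the pixels over which the Otsu threshold is
    computed (dark features and their immediate surround); ``min_area`` /
    ``max_area`` select the feature among the surviving components.
    """

    feature: Literal["pupil", "marker"]
    intensity_window: tuple[float, float] = (0.0, 1.0)
    min_area: float = 10.0
    max_area: float = np.inf
    min_circularity: float = 0.5


@dataclass(frozen=True)
class FeatureLocation:
    x: float
    y: float
    feature: str
    quality: float = 0.0
    valid: bool = False
    status: Literal["ok", "not_found", "edge"] = "not_found"


@dataclass(frozen=True)
class FrameTriplet:
    """The three grayscale frames of one trial (t0, t1, t2)."""

    frames: tuple[np.ndarray, np.ndarray, np.ndarray]
    trial_id: int = 0
    timestamps_ms: tuple[float, float, float] = (0.0, 80.0, 160.0)

    def __post_init__(self) -> None:
        if len(self.frames) != 3:
            raise ValueError("a trial needs exactly three frames")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError(f"frame dimensions differ: {shapes}")


@dataclass(frozen=True)
class TrialMeasurement:
    """Per-trial displacements (px, vertical positive = world up)."""

    trial_id: int
    pupil_disp_fix: tuple[float, float] | None  # (dx, dy)
    pupil_disp_mov: tuple[float, float] | None
    marker_disp_fix: tuple[float, float] | None
    marker_disp_mov: tuple[float, float] | None
    discarded_reason: Literal["none", "blink", "out_of_frame"] = "none"


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0
    return float(min(1.0, 4.0 * np.pi * area / perimeter**2))


def detect_dark_blob(
    frame: np.ndarray,
    cfg: DetectionConfig,
    exclude: tuple[float, float, float] | None = None,
) -> FeatureLocation:
    """Locate one dark blob with subpixel precision.

    Pipeline: Otsu threshold over pixels inside ``cfg.intensity_window``;
    8-connected components of (frame < threshold); components outside the
    area bounds or below the circularity bound are dropped, as is anything
    whose centroid falls within the optional ``exclude`` disc (x, y, radius).
    The largest surviving component wins; an exact area tie is broken
    deterministically (smaller centroid y, then x) with a halved quality
    score.  A winner touching the image border is reported as ``edge`` /
    invalid.  The subpixel center is the darkness-weighted centroid with
    weights (local_background - I) / (local_background - I_min) clipped to
    [0, 1], where the local background is the median intensity on the rim of
    the component's padded bounding box.
    """
    img = np.asarray(frame, dtype=float)
    lo, hi = cfg.intensity_window
    window_pixels = img[(img >= lo) & (img <= hi)]
    if window_pixels.size < 2 or window_pixels.min() == window_pixels.max():
        return FeatureLocation(np.nan, np.nan, cfg.feature)
    try:
        thr = float(threshold_otsu(window_pixels))
    except ValueError:
        return FeatureLocation(np.nan, np.nan, cfg.feature)
    binary = img < thr
    labels, n_labels = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n_labels == 0:
        return FeatureLocation(np.nan, np.nan, cfg.feature)

    candidates = []
    slices = ndimage.find_objects(labels)
    for lab, slc in enumerate(slices, start=1):
        mask = labels[slc] == lab
        area = int(mask.sum())
        if not (cfg.min_area <= area <= cfg.max_area):
            continue
        # perimeter estimate: boundary pixel count of the mask
        eroded = ndimage.binary_erosion(mask)
        perimeter = float(area - int(eroded.sum()))
        # rough circularity on the pixelated mask; boundary-count perimeter
        # underestimates the geometric one, so compare leniently
        circ = _circularity(area, max(perimeter, 1.0) * 0.9)
        if circ < cfg.min_circularity:
            continue
        ys, xs = np.nonzero(mask)
        cy = float(ys.mean() + slc[0].start)
        cx = float(xs.mean() + slc[1].start)
        if exclude is not None:
            ex, ey, er = exclude
            if np.hypot(cx - ex, cy - ey) <= er:
                continue
        touches_border = (
            slc[0].start == 0 or slc[1].start == 0
            or slc[0].stop == img.shape[0] or slc[1].stop == img.shape[1]
        )
        candidates.append((area, cy, cx, lab, slc, touches_border, circ))

    if not candidates:
        return FeatureLocation(np.nan, np.nan, cfg.feature)

    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    area, cy, cx, lab, slc, touches_border, circ = candidates[0]
    tie = len(candidates) > 1 and candidates[1][0] == area
    quality = circ * (0.5 if tie else 1.0)
    if touches_border:
        return FeatureLocation(cx, cy, cfg.feature, quality=0.0, valid=False, status="edge")

    # darkness-weighted subpixel centroid over the padded bounding box
    pad = 4
    y0 = max(0, slc[0].start - pad); y1 = min(img.shape[0], slc[0].stop + pad)
    x0 = max(0, slc[1].start - pad); x1 = min(img.shape[1], slc[1].stop + pad)
    patch = img[y0:y1, x0:x1]
    rim = np.concatenate([patch[0, :], patch[-1, :], patch[:, 0], patch[:, -1]])
    local_bg = float(np.median(rim))
    depth = local_bg - float(patch.min())
    if depth <= 0:
        return FeatureLocation(cx, cy, cfg.feature, quality=quality, valid=True, status="ok")
    w = np.clip((local_bg - patch) / depth, 0.0, 1.0)
    # suppress weight from pixels of *other* components inside the patch
    other = (labels[y0:y1, x0:x1] != lab) & (labels[y0:y1, x0:x1] != 0)
    w[other] = 0.0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    wsum = w.sum()
    sub_x = float((w * xx).sum() / wsum)
    sub_y = float((w * yy).sum() / wsum)
    return FeatureLocation(sub_x, sub_y, cfg.feature, quality=quality, valid=True, status="ok")


def detect_pupil(frame: np.ndarray, cfg: DetectionConfig) -> FeatureLocation:
    """Locate the pupil (the large dark disc inside the iris)."""
    return detect_dark_blob(frame, cfg)


def detect_marker(
    frame: np.ndarray,
    cfg: DetectionConfig,
    pupil: FeatureLocation | None = None,
    exclusion_radius: float = 0.0,
) -> FeatureLocation:
    """Locate the head marker, optionally excluding the pupil's neighborhood."""
    exclude = None
    if pupil is not None and pupil.valid and exclusion_radius > 0:
        exclude = (pupil.x, pupil.y, exclusion_radius)
    return detect_dark_blob(frame, cfg, exclude=exclude)


def detection_configs_for(cam) -> tuple[DetectionConfig, DetectionConfig]:
    """Derive pupil/marker detection configs from a synthetic CameraModel."""
    pupil_area = np.pi * cam.pupil_radius_px**2
    marker_area = np.pi * cam.marker_radius_px**2
    hi = (cam.iris_intensity + cam.background_intensity) / 2.0
    pupil_cfg = DetectionConfig(
        feature="pupil", intensity_window=(0.0, hi),
        min_area=0.5 * pupil_area, max_area=2.0 * pupil_area,
    )
    marker_cfg = DetectionConfig(
        feature="marker", intensity_window=(0.0, hi),
        min_area=0.5 * marker_area, max_area=2.0 * marker_area,
    )
    return pupil_cfg, marker_cfg


def measure_trial(
    triplet: FrameTriplet,
    pupil_cfg: DetectionConfig,
    marker_cfg: DetectionConfig,
    marker_exclusion_radius: float = 0.0,
) -> TrialMeasurement:
    """Measure fixation- and movement-epoch displacements for one trial.

    All six detections (pupil and marker in each of the three frames) must be
    valid; otherwise the trial is discarded with reason ``blink`` (pupil not
    found) or ``out_of_frame`` (anything cut by the border, or marker
    missing), matching how unusable clinical trials are dropped before
    analysis.  Vertical components are returned world-up-positive.
    """
    pupils = [detect_pupil(f, pupil_cfg) for f in triplet.frames]
    markers = [
        detect_marker(f, marker_cfg, pupil=p, exclusion_radius=marker_exclusion_radius)
        for f, p in zip(triplet.frames, pupils)
    ]
    if any(p.status == "not_found" for p in pupils):
        reason = "blink"
    elif any(not loc.valid for loc in pupils + markers):
        reason = "out_of_frame"
    else:
        reason = "none"
    if reason != "none":
        return TrialMeasurement(triplet.trial_id, None, None, None, None, reason)

    def disp(a: FeatureLocation, b: FeatureLocation) -> tuple[float, float]:
        return (b.x - a.x, -(b.y - a.y))  # flip image-y to world-up

    return TrialMeasurement(
        trial_id=triplet.trial_id,
        pupil_disp_fix=disp(pupils[0], pupils[1]),
        pupil_disp_mov=disp(pupils[1], pupils[2]),
        marker_disp_fix=disp(markers[0], markers[1]),
        marker_disp_mov=disp(markers[1], markers[2]),
        discarded_reason="none",
    )


def track_session(
    frames: dict[int, list[np.ndarray]],
    trial_meta: pd.DataFrame,
    pupil_cfg: DetectionConfig,
    marker_cfg: DetectionConfig,
    marker_exclusion_radius: float = 0.0,
) -> pd.DataFrame:
    """Track every trial of a session; returns the shared trial-table schema.

    ``trial_meta`` must carry trial_id, condition and direction; discarded
    trials get NaN displacements and the corresponding blink/oof flag.
    """
    meta = trial_meta.set_index("trial_id")
    rows = []
    for trial_id, triplet_frames in frames.items():
        triplet = FrameTriplet(frames=tuple(triplet_frames), trial_id=trial_id)
        m = measure_trial(triplet, pupil_cfg, marker_cfg, marker_exclusion_radius)
        info = meta.loc[trial_id]
        row = {
            "trial_id": trial_id,
            "condition": info["condition"],
            "direction": info["direction"],
            "blink_flag": m.discarded_reason == "blink",
            "oof_flag": m.discarded_reason == "out_of_frame",
        }
        pairs = {
            "pupil_fix": m.pupil_disp_fix, "pupil_mov": m.pupil_disp_mov,
            "marker_fix": m.marker_disp_fix, "marker_mov": m.marker_disp_mov,
        }
        for name, value in pairs.items():
            row[f"dx_{name}"] = value[0] if value else np.nan
            row[f"dy_{name}"] = value[1] if value else np.nan
        rows.append(row)
    return pd.DataFrame(rows).sort_values("trial_id").reset_index(drop=True)


def load_triplet(paths: tuple[str | Path, str | Path, str | Path], trial_id: int = 0) -> FrameTriplet:
    """Load a t0/t1/t2 PNG (or TIFF) triplet as normalized float frames."""
    frames = []
    for p in paths:
        img = iio.imread(p)
        img = np.asarray(img, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        peak = 255.0 if img.max() <= 255 else 65535.0
        frames.append(img / peak)
    return FrameTriplet(frames=tuple(frames), trial_id=trial_id)
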
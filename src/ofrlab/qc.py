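"""Eye-in-head conversion and robust iterative trial exclusion.

The camera sees the eye-in-space; subtracting the head-marker displacement
(head-in-space) isolates the eye-in-head rotation.  Trials with poor fixation
— saccades or microsaccades during the fixation epoch, or large head motion
in either epoch — are excluded by an iterative rule: within each screened
channel, drop trials deviating from the median by more than k times the
robust SD (1.4826 x median absolute deviation), re-estimate, and repeat until
no trial is dropped.  The movement-epoch *eye* signal is deliberately never
screened: it carries the response being measured, and trimming it would bias
the OFR estimate.

Screened channels default to fixation-epoch eye, fixation-epoch head, and
movement-epoch head, each on both axes, pooled across the four condition x
direction cells (fixation quality and head motion are condition-agnostic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QcConfig", "SchemaError", "compute_eye_in_head", "robust_outlier_filter", "apply_qc"]

MAD_TO_SD = 1.4826  # consistency factor for the normal distribution

#: screening priority used when a trial trips several channels
REASON_PRIORITY = ["blink", "out_of_frame", "fix_eye", "fix_head", "mov_head", "mov_eye"]


class SchemaError(KeyError):
    """A required trial-table column is missing."""


@dataclass(frozen=True)
class QcConfig:
    """Outlier-screening parameters.

    ``channels`` lists (epoch, signal) pairs screened with the iterative
    k x robust-SD rule; ``axes`` selects which displacement components of each
    channel are screened (a saccade in x is still poor fixation).
    """

    k_mad: float = 3.0
    max_iterations: int = 50
    channels: tuple[tuple[str, str], ...] = (("fix", "eye"), ("fix", "head"), ("mov", "head"))
    axes: tuple[str, ...] = ("dy", "dx")
    px_per_deg: float = 40.0

    def __post_init__(self) -> None:
        if self.k_mad <= 0:
            raise ValueError("k_mad must be positive")
        if not self.channels:
            raise ValueError("at least one channel must be screened")
        for epoch, signal in self.channels:
            if epoch not in ("fix", "mov") or signal not in ("eye", "head"):
                raise ValueError(f"unknown channel {(epoch, signal)}")


_REQUIRED_INPUT = [
    "trial_id", "condition", "direction",
    "dx_pupil_fix", "dy_pupil_fix", "dx_pupil_mov", "dy_pupil_mov",
    "dx_marker_fix", "dy_marker_fix", "dx_marker_mov", "dy_marker_mov",
]


def compute_eye_in_head(measurements: pd.DataFrame, px_per_deg: float) -> pd.DataFrame:
    """Convert raw pupil/marker displacements (px) to eye-in-head (deg).

    eye = (pupil - marker) / px_per_deg per epoch and axis; marker
    displacements are carried through unchanged (px) as the head channels.
    Blink / out-of-frame flags from tracking become exclusion reasons.
    """
    if px_per_deg <= 0:
        raise ValueError("px_per_deg must be positive")
    missing = [c for c in _REQUIRED_INPUT if c not in measurements.columns]
    if missing:
        raise SchemaError(f"missing trial-table columns: {missing}")
    out = measurements[["trial_id", "condition", "direction"]].copy()
    for epoch in ("fix", "mov"):
        for axis in ("dx", "dy"):
            pupil = measurements[f"{axis}_pupil_{epoch}"]
            marker = measurements[f"{axis}_marker_{epoch}"]
            out[f"eye_{axis}_{epoch}"] = (pupil - marker) / px_per_deg
            out[f"head_{axis}_{epoch}"] = marker
    blink = measurements.get("blink_flag", pd.Series(False, index=measurements.index))
    oof = measurements.get("oof_flag", pd.Series(False, index=measurements.index))
    out["excluded_reason"] = np.select(
        [blink.astype(bool), oof.astype(bool)], ["blink", "out_of_frame"], default="none"
    )
    return out


def robust_outlier_filter(values: np.ndarray, cfg: QcConfig | None = None) -> np.ndarray:
    """Iterative median / scaled-MAD screening of one channel.

    Repeats {m = median(kept); s = 1.4826 * median(|kept - m|); drop kept
    values with |x - m| > k*s} until a pass drops nothing or the iteration cap
    is hit.  Degenerate rule: when s == 0 (at least half the kept values are
    identical), only values exactly equal to the median are kept.  Returns the
    boolean kept-mask.
    """
    cfg = cfg or QcConfig()
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1D")
    if np.sum(np.isfinite(x)) < 3:
        raise ValueError("need at least 3 finite values to screen outliers")
    kept = np.isfinite(x)
    for _ in range(cfg.max_iterations):
        m = np.median(x[kept])
        s = MAD_TO_SD * np.median(np.abs(x[kept] - m))
        if s == 0.0:
            drop = kept & (x != m)
        else:
            drop = kept & (np.abs(x - m) > cfg.k_mad * s)
        if not drop.any():
            break
        kept &= ~drop
    return kept


def apply_qc(trials: pd.DataFrame, cfg: QcConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """Screen a session's eye-in-head table; returns (kept table, report).

    Each configured (epoch, signal) channel is screened on each configured
    axis over the session's analyzable trials pooled across the four cells;
    a trial flagged on any channel is excluded, with one primary reason in
    priority order blink > out_of_frame > fix_eye > fix_head > mov_head.
    The report gives per-channel flag counts and the exclusion fractions.
    """
    cfg = cfg or QcConfig()
    if len(trials) == 0:
        raise ValueError("empty session")
    trials = trials.reset_index(drop=True)
    reason = trials["excluded_reason"].to_numpy(dtype=object).copy() \
        if "excluded_reason" in trials.columns else np.full(len(trials), "none", dtype=object)
    analyzable = reason == "none"

    per_channel: dict[str, int] = {}
    flags: dict[str, np.ndarray] = {}
    for epoch, signal in cfg.channels:
        channel_flag = np.zeros(len(trials), dtype=bool)
        for axis in cfg.axes:
            col = f"{signal}_{axis}_{epoch}"
            if col not in trials.columns:
                raise SchemaError(f"missing column {col}")
            vals = trials.loc[analyzable, col].to_numpy(dtype=float)
            kept = robust_outlier_filter(vals, cfg)
            idx = np.flatnonzero(analyzable)
            channel_flag[idx[~kept]] = True
        name = f"{epoch}_{signal}"
        flags[name] = channel_flag
        per_channel[name] = int(channel_flag.sum())

    for name in ["fix_eye", "fix_head", "mov_head", "mov_eye"]:
        if name in flags:
            newly = flags[name] & (reason == "none")
            reason[newly] = name

    trials = trials.copy()
    trials["excluded_reason"] = reason
    kept_table = trials[trials["excluded_reason"] == "none"].reset_index(drop=True)
    n_total = len(trials)
    n_tracked = int(analyzable.sum())
    report = {
        "n_total": n_total,
        "n_tracking_discards": n_total - n_tracked,
        "n_outlier_excluded": n_tracked - len(kept_table),
        "n_kept": len(kept_table),
        "per_channel_flags": per_channel,
        "outlier_fraction_of_tracked": (n_tracked - len(kept_table)) / n_tracked if n_tracked else np.nan,
        "excluded_fraction_total": 1.0 - len(kept_table) / n_total,
    }
    return kept_table, report
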
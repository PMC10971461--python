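"""End-to-end reproducible pipeline: simulate -> [render -> track] -> qc -> stats.

A run is fully described by a :class:`PipelineConfig` (serializable to YAML);
a single top-level seed fans out deterministically to per-stage child seeds,
so a config + seed reproduces every table bit-for-bit.  Each run directory
contains the trial table, ground truth, kept trials, QC report, per-condition
summary, comparison result, and a manifest with SHA-256 checksums of every
artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from . import stats as stats_mod
from . import synthetic, tracking

__all__ = ["PipelineConfig", "run_pipeline", "stage_seeds"]

log = logging.getLogger("ofrlab.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one session analysis."""

    subject: synthetic.SubjectModel = field(default_factory=synthetic.SubjectModel)
    camera: synthetic.CameraModel = field(default_factory=synthetic.CameraModel)
    qc: qc_mod.QcConfig = field(default_factory=qc_mod.QcConfig)
    tier: str = "table"  # "table" (fast) or "frames" (exercises tracking)
    n_bootstrap: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tier not in ("table", "frames"):
            raise ValueError(f"tier must be 'table' or 'frames', got {self.tier!r}")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "subject": dataclasses.asdict(self.subject),
            "camera": dataclasses.asdict(self.camera),
            "qc": dataclasses.asdict(self.qc),
            "tier": self.tier,
            "n_bootstrap": self.n_bootstrap,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        qc_kwargs = payload.get("qc", {})
        if "channels" in qc_kwargs:
            qc_kwargs["channels"] = tuple(tuple(c) for c in qc_kwargs["channels"])
        if "axes" in qc_kwargs:
            qc_kwargs["axes"] = tuple(qc_kwargs["axes"])
        cam_kwargs = payload.get("camera", {})
        for key in ("pupil_center", "marker_center"):
            if key in cam_kwargs:
                cam_kwargs[key] = tuple(cam_kwargs[key])
        return cls(
            subject=synthetic.SubjectModel(**payload.get("subject", {})),
            camera=synthetic.CameraModel(**cam_kwargs),
            qc=qc_mod.QcConfig(**qc_kwargs),
            tier=payload.get("tier", "table"),
            n_bootstrap=int(payload.get("n_bootstrap", 10_000)),
            alpha=float(payload.get("alpha", 0.05)),
            seed=int(payload.get("seed", 0)),
        )


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds derived from one top-level seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("simulate", "render", "bootstrap")
    return {name: int(child.generate_state(1)[0] % (2**31)) for name, child in zip(names, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute one session end to end; returns the run directory.

    Table tier: simulate -> eye-in-head -> qc -> stats.  Frame tier inserts
    render -> track between simulation and the eye-in-head conversion, so the
    displacements entering QC are the tracker's, not the generator's.
    Any stage failure propagates with a stage-named diagnostic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    t_start = time.time()
    timings: dict[str, float] = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            t0 = time.time()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # annotate with the failing stage
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            timings[name] = time.time() - t0
            return result
        return wrap

    config.to_yaml(out / "config.yaml")

    subject = dataclasses.replace(config.subject, seed=seeds["simulate"])
    table = stage("simulate")(synthetic.simulate_trial_table, subject)
    truth_cols = ["trial_id", "condition", "direction", "true_eye_fix_deg",
                  "true_eye_mov_deg", "true_head_fix_px", "true_head_mov_px", "contaminated"]
    table[truth_cols].to_csv(out / "ground_truth.csv", index=False)
    measured = table[synthetic.TRIAL_TABLE_COLUMNS]

    if config.tier == "frames":
        rng = np.random.default_rng(seeds["render"])
        frames = stage("render")(synthetic.render_session_frames, table, config.camera, rng)
        pupil_cfg, marker_cfg = tracking.detection_configs_for(config.camera)
        measured = stage("track")(
            tracking.track_session, frames, table[["trial_id", "condition", "direction"]],
            pupil_cfg, marker_cfg, config.camera.iris_radius_px * 1.5,
        )
    measured.to_csv(out / "trials.csv", index=False)

    eye = stage("eye_in_head")(qc_mod.compute_eye_in_head, measured, config.qc.px_per_deg)
    kept, report = stage("qc")(qc_mod.apply_qc, eye, config.qc)
    kept.to_csv(out / "kept.csv", index=False)
    (out / "qc_report.json").write_text(json.dumps(report, indent=2))

    summary, comparison = stage("stats")(
        stats_mod.summarize_session, kept,
        n_bootstrap=config.n_bootstrap, seed=seeds["bootstrap"], alpha=config.alpha,
    )
    summary.to_csv(out / "summary.csv", index=False)
    comparison_payload = {
        "delta": comparison.delta,
        "p_bootstrap": comparison.p_bootstrap,
        "n_bootstrap": comparison.n_bootstrap,
        "alpha": comparison.alpha,
        "sensitive_flag": bool(comparison.sensitive_flag),
        "ofr_correlated": comparison.ofr_correlated.ofr,
        "ofr_anticorrelated": comparison.ofr_anticorrelated.ofr,
        "seeds": seeds,
    }
    (out / "comparison.json").write_text(json.dumps(comparison_payload, indent=2))

    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "total_s": round(time.time() - t_start, 4),
        "exclusion_fractions": {
            "tracking": report["n_tracking_discards"] / report["n_total"],
            "outlier": report["outlier_fraction_of_tracked"],
            "total": report["excluded_fraction_total"],
        },
        "files": {p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size} for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("run complete in %.2fs: %s", manifest["total_s"], out)
    return out
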
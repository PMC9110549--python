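"""End-to-end driver: tracking -> stationarity -> fusion -> quality gating,
plus paired LR/HR dataset export for image-to-image translation training.

Every run writes machine-readable artefacts (track.json, intervals.json,
fusion_report.json, quality_report.csv, summary.json, a JSON-lines event
log and the fully resolved config) so that each discarded candidate
interval can be audited.  Stage failures are recorded per interval and the
run continues.
"""
from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fusion, quality, tracking
from .config import PipelineConfig
from .errors import InvalidInputError, IoctHrfuseError
from .io import load_gray, load_image, load_mask, open_video_dir, save_image_u8
from .quality import LayerMask, RoiSizes
from .synthgen import SynthManifest

__all__ = ["run_pipeline", "export_pairs", "PairedDataset", "PipelineSummary"]


@dataclass
class PipelineSummary:
    n_frames: int
    n_intervals: int
    n_fused: int
    n_accepted: int
    intervals: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_frames": int(self.n_frames),
            "n_intervals": int(self.n_intervals),
            "n_fused": int(self.n_fused),
            "n_accepted": int(self.n_accepted),
            "intervals": self.intervals,
        }


def _roi_sizes(cfg: PipelineConfig) -> RoiSizes:
    q = cfg.quality
    return RoiSizes(
        background=tuple(q.background_roi),
        homogeneous=tuple(q.homogeneous_roi),
        contrast=tuple(q.contrast_roi),
    )


def run_pipeline(
    config: PipelineConfig,
    input_dir: str,
    out_dir: str,
) -> PipelineSummary:
    """Run the full HR-estimation pipeline on one video directory.

    The input directory must contain ``frames/scene_*.png`` +
    ``frames/bscan_*.png`` (and optionally ``masks/`` and a
    ``manifest.json`` providing the feature seed point).  Deterministic
    given the config seeds.
    """
    video = open_video_dir(input_dir)
    out = Path(out_dir)
    (out / "accepted").mkdir(parents=True, exist_ok=True)
    (out / "rejected").mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_f = log_path.open("w")

    def log(event: str, **kw) -> None:
        log_f.write(json.dumps({"event": event, **kw}) + "\n")

    config.to_yaml(out / "config_resolved.yaml")

    seed_point = config.tracking.seed_point
    manifest = None
    manifest_path = video.root / "manifest.json"
    if manifest_path.exists():
        manifest = SynthManifest.load(manifest_path)
        if seed_point is None:
            seed_point = tuple(manifest.feature_point(0))
    if seed_point is None:
        raise InvalidInputError(
            "no seed point: set tracking.seed_point or provide manifest.json"
        )

    scenes = [load_image(p) for p in video.scene_paths]
    log("loaded", n_frames=len(scenes))

    t = config.tracking
    track = tracking.track_video(
        scenes,
        seed_point,
        levels=t.lk_levels,
        window=t.lk_window,
        max_iter=t.lk_max_iter,
        eps=t.lk_eps,
        max_residual=t.lk_max_residual,
    )
    track.save(out / "track.json")

    intervals = tracking.find_stable_intervals(
        track, min_len=t.min_len, tol_step=t.tol_step, tol_total=t.tol_total
    )
    (out / "intervals.json").write_text(
        json.dumps([iv.to_dict() for iv in intervals], indent=1)
    )
    log("intervals", n=len(intervals))

    summary = PipelineSummary(
        n_frames=video.n_frames, n_intervals=len(intervals), n_fused=0, n_accepted=0
    )
    fusion_reports = []
    quality_rows = []
    for k, iv in enumerate(intervals):
        rec: dict = {"interval": iv.to_dict()}
        try:
            stack = [
                load_gray(video.bscan_paths[i])
                for i in range(iv.start_frame, iv.end_frame + 1)
            ]
            fused = fusion.fuse_interval(
                stack,
                "estimate",
                ncc_floor=config.fusion.ncc_floor,
                theta_range=config.fusion.theta_range,
                theta_step=config.fusion.theta_step,
                t_range=config.fusion.t_range,
            )
            summary.n_fused += 1
            fusion_reports.append({"interval": k, **fused.report()})

            mask = _interval_mask(video, iv.start_frame, fused.hr_estimate, config)
            report = quality.assess_image(
                fused.hr_estimate,
                mask,
                sizes=_roi_sizes(config),
                rng_seed=config.seed + k,
                thresholds=config.quality.thresholds,
                inverse_log=config.quality.inverse_log,
            )
            name = f"hr_{k:04d}.png"
            folder = "accepted" if report.accepted else "rejected"
            save_image_u8(out / folder / name, fused.hr_estimate)
            save_image_u8(out / folder / f"lr_{k:04d}.png", fused.lr_reference)
            if report.accepted:
                summary.n_accepted += 1
            rec.update(
                {
                    "status": "ok",
                    "hr_image": f"{folder}/{name}",
                    "n_fused_frames": fused.n_fused,
                    "quality": report.to_dict(),
                }
            )
            row = {
                "file": f"{folder}/{name}",
                "snr": report.snr,
                "cnr": report.cnr,
                "enl": report.enl,
                "accepted": report.accepted,
            }
            for i, roi in enumerate(report.roi_set.all_rois()):
                row[f"roi{i}_xywh"] = f"{roi.x},{roi.y},{roi.w},{roi.h}"
            quality_rows.append(row)
            log("interval_done", interval=k, accepted=report.accepted)
        except IoctHrfuseError as exc:
            rec.update({"status": "error", "error": f"{type(exc).__name__}: {exc}"})
            log("interval_error", interval=k, error=str(exc))
        summary.intervals.append(rec)

    (out / "fusion_report.json").write_text(json.dumps(fusion_reports, indent=1))
    pd.DataFrame(quality_rows).to_csv(out / "quality_report.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary.to_dict(), indent=1))
    log("done", **{k: v for k, v in summary.to_dict().items() if k != "intervals"})
    log_f.close()
    return summary


def _interval_mask(video, frame_idx: int, hr: np.ndarray, config: PipelineConfig) -> LayerMask:
    if video.mask_paths:
        return LayerMask(load_mask(video.mask_paths[frame_idx]), provenance="external")
    return quality.segment_layers_heuristic(hr, n_layers=config.quality.n_layers)


# --------------------------------------------------------------------------
# paired dataset export


@dataclass
class PairedDataset:
    """Stem-matched (LR, HR) pairs with a train/val/test assignment."""

    pairs: list[tuple[Path, Path]]
    assignment: list[str]                  # per pair: "train" | "val" | "test"
    fractions: tuple[float, float, float]
    rng_seed: int

    def counts(self) -> dict[str, int]:
        return {s: self.assignment.count(s) for s in ("train", "val", "test")}

    def to_dict(self) -> dict:
        return {
            "pairs": [[str(a), str(b)] for a, b in self.pairs],
            "assignment": self.assignment,
            "fractions": list(self.fractions),
            "rng_seed": int(self.rng_seed),
        }


def largest_remainder_counts(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer split sizes by largest-remainder rounding (sums to ``n``)."""
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - base[i]), reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


def export_pairs(
    pairs: list[tuple[str | Path, str | Path]],
    out_dir: str | Path,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    rng_seed: int = 0,
    group_of=None,
) -> PairedDataset:
    """Write a training-ready paired dataset layout.

    Creates ``train/ val/ test/`` each with ``lr/`` and ``hr/`` subdirs;
    every pair keeps its stem in both.  Split sizes follow the
    largest-remainder rounding of ``fractions`` and assignment is a
    uniform random shuffle under ``rng_seed``.  With ``group_of`` (a
    callable mapping an LR path to a group key, e.g. a subject id), whole
    groups are assigned to a single split.  An empty source yields empty
    split directories and a warning in the returned assignment.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidInputError("split fractions must sum to 1")
    out = Path(out_dir)
    for split in ("train", "val", "test"):
        (out / split / "lr").mkdir(parents=True, exist_ok=True)
        (out / split / "hr").mkdir(parents=True, exist_ok=True)

    pairs = [(Path(a), Path(b)) for a, b in pairs]
    names = ("train", "val", "test")
    rng = np.random.default_rng(rng_seed)
    if not pairs:
        ds = PairedDataset([], [], tuple(fractions), rng_seed)
        (out / "split.json").write_text(json.dumps(ds.to_dict(), indent=1))
        return ds

    if group_of is None:
        units = [[i] for i in range(len(pairs))]
    else:
        groups: dict = {}
        for i, (lr, _) in enumerate(pairs):
            groups.setdefault(group_of(lr), []).append(i)
        units = [groups[k] for k in sorted(groups)]

    counts = largest_remainder_counts(len(units), fractions)
    perm = rng.permutation(len(units))
    assignment = [""] * len(pairs)
    pos = 0
    for split, cnt in zip(names, counts):
        for u in perm[pos : pos + cnt]:
            for i in units[u]:
                assignment[i] = split
        pos += cnt

    for (lr, hr), split in zip(pairs, assignment):
        # both sides share the HR stem so pairs stay 1-to-1 by filename
        shutil.copyfile(lr, out / split / "lr" / hr.name)
        shutil.copyfile(hr, out / split / "hr" / hr.name)

    ds = PairedDataset(pairs, assignment, tuple(fractions), rng_seed)
    (out / "split.json").write_text(json.dumps(ds.to_dict(), indent=1))
    return ds
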
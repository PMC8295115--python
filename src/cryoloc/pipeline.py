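"""Configuration, file I/O, and the end-to-end phantom experiment.

The pipeline ties the stages together: phantom generation, semiautomatic
annotation (the manual first-frame click is supplied by the phantom's
ground truth), training of both U-nets, prediction on the held-out test
split, post-processing, biplane 3D reconstruction, and evaluation against
the phantom truth.

Configuration is a validated YAML document. Shipped defaults mirror the
clinical protocol (10x10 marker ROI, 50x50 skeleton ROI, mask thresholds
20% and 1.5% of maximum, 50 epochs, batch sizes 8 and 4, 512 px native
frames, 28 mm balloon); desk-scale experiments override sizes explicitly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import annotate as ann
from . import phantom as ph
from . import postprocess as post
from . import recon3d
from . import segnet
from .geometry import ViewGeometry, load_biplane

__all__ = [
    "TrainSettings",
    "AnnotateSettings",
    "PipelineConfig",
    "load_config",
    "read_mask_png",
    "write_mask_png",
    "read_image",
    "write_image",
    "read_manifest",
    "annotate_run",
    "end_to_end",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class TrainSettings(BaseModel):
    """Per-network architecture and optimization settings."""

    epochs: int = segnet.DEFAULT_EPOCHS
    batch_size: int = segnet.DEFAULT_MARKER_BATCH
    learning_rate: float = 1e-3
    loss: str = "bce"
    pos_weight: float = 1.0
    depth: int = 4
    base_filters: int = 16
    dropout_rate: float = 0.5
    residual_output: bool = True

    model_config = {"extra": "forbid"}


class AnnotateSettings(BaseModel):
    """Semiautomatic annotation parameters."""

    template_size_px: int = 10
    skeleton_roi_px: int = 50
    marker_threshold_fraction: float = post.MARKER_THRESHOLD_FRACTION
    shaft_threshold_fraction: float = post.SHAFT_THRESHOLD_FRACTION
    orientation_halfwidth_deg: float = 30.0
    search_radius_px: int = 8
    shaft_target_thickness_px: int = 3
    bridge_gap_px: float = 12.0
    seed_distance_max_px: float = 10.0
    ridge_scales_px: tuple[float, ...] = (7.0, 9.0)

    model_config = {"extra": "forbid"}


class PhantomSettings(BaseModel):
    """Phantom generation parameters (see :class:`cryoloc.phantom.PhantomConfig`)."""

    image_size_px: int = 512
    n_scenes: int = 40
    frames_per_scene: int = 5
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    marker_intensity_drop: float = 120.0
    shaft_intensity_drop: float = 60.0
    background_level: float = 200.0
    background_variation: float = 10.0
    clutter_count: int = 4
    clutter_amplitude: float = 30.0
    contrast_blob_probability: float = 0.2
    noise_sigma: float = 2.0

    model_config = {"extra": "forbid"}

    def to_phantom_config(self, rng_seed: int) -> ph.PhantomConfig:
        return ph.PhantomConfig(
            n_frames=self.frames_per_scene,
            image_size_px=(self.image_size_px, self.image_size_px),
            marker_intensity_drop=self.marker_intensity_drop,
            shaft_intensity_drop=self.shaft_intensity_drop,
            background_level=self.background_level,
            background_variation=self.background_variation,
            clutter_count=self.clutter_count,
            clutter_amplitude=self.clutter_amplitude,
            contrast_blob_probability=self.contrast_blob_probability,
            noise_sigma=self.noise_sigma,
            rng_seed=rng_seed,
        )


class PipelineConfig(BaseModel):
    """Full pipeline configuration."""

    rng_seed: int = 0
    geometry_file: Optional[str] = None
    phantom: PhantomSettings = Field(default_factory=PhantomSettings)
    annotation: AnnotateSettings = Field(default_factory=AnnotateSettings)
    marker_net: TrainSettings = Field(default_factory=TrainSettings)
    shaft_net: TrainSettings = Field(
        default_factory=lambda: TrainSettings(batch_size=segnet.DEFAULT_SHAFT_BATCH)
    )

    model_config = {"extra": "forbid"}


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Validation errors name the offending field.
    """
    try:
        payload = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse config {path}: {exc}") from exc
    try:
        return PipelineConfig.model_validate(payload)
    except ValidationError as exc:
        fields = ", ".join(".".join(str(p) for p in e["loc"]) for e in exc.errors())
        raise ValueError(f"invalid config {path}: bad field(s) {fields}\n{exc}") from exc


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    return np.asarray(arr) > 127


def write_image(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return np.asarray(arr, dtype=np.uint8)


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot parse manifest {path}: {exc}") from exc
    if len(df) == 0:
        raise ValueError(f"manifest {path} describes an empty run (0 frames)")
    return df


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------

def annotate_run(
    frames: list[np.ndarray],
    truths: list[ph.SceneTruth],
    view_label: str,
    settings: AnnotateSettings,
) -> dict:
    """Annotate one run (one scene, one view): marker masks + shaft targets.

    The first-frame click comes from the phantom truth, standing in for the
    operator. Returns per kept frame index: marker mask, seed, and (when
    shaft extraction succeeds) the centerline raster target.
    """
    click_uv = tuple(int(round(c)) for c in truths[0].per_view[view_label]["true_seed_px"])
    run = ann.annotate_marker_run(
        frames, click_uv,
        template_size=settings.template_size_px,
        search_radius_px=settings.search_radius_px,
    )
    out = {}
    for mask, idx in zip(run.masks, run.kept_indices):
        seed_uv = ann.mask_centroid(mask)
        truth = truths[idx]
        true_cl = np.asarray(truth.per_view[view_label]["true_centerline_px"])
        true_angle = float(np.degrees(np.arctan2(
            true_cl[-1, 1] - true_cl[0, 1], true_cl[-1, 0] - true_cl[0, 0])) % 180.0)
        hw = settings.orientation_halfwidth_deg
        response = ann.enhance_shaft(frames[idx], settings.ridge_scales_px)
        skeleton = ann.binarize_and_skeletonize(response)
        centerline = None
        for interval in (((true_angle - hw) % 180.0, (true_angle + hw) % 180.0),
                         (0.0, 180.0)):
            try:
                graph = ann.build_skeleton_graph(skeleton, seed_uv,
                                                 roi_size_px=settings.skeleton_roi_px,
                                                 bridge_gap_px=settings.bridge_gap_px)
                path = ann.extract_shaft_path(
                    graph, interval, seed_distance_max_px=settings.seed_distance_max_px)
                centerline = ann.fit_centerline_spline(path)
                break
            except ann.AnnotationError:
                continue
        entry = {"marker_mask": mask, "seed_uv": seed_uv, "centerline": centerline}
        if centerline is not None:
            entry["shaft_target"] = ann.rasterize_centerline(
                centerline, frames[idx].shape,
                thickness_px=settings.shaft_target_thickness_px)
        out[idx] = entry
    return out


def _runs_of(manifest: pd.DataFrame) -> list[tuple[int, str, pd.DataFrame]]:
    runs = []
    for (sid, view), grp in manifest.groupby(["scene_id", "view"], sort=True):
        runs.append((int(sid), str(view), grp.sort_values("frame_index")))
    return runs


def end_to_end(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full phantom experiment and return the metrics report.

    Stages: phantom dataset generation, semiautomatic annotation of every
    run, training of the marker and shaft nets on the train/val scenes,
    prediction on the test scenes, post-processing to seeds and
    centerlines, biplane 3D reconstruction, and evaluation of every stage
    against the phantom ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    pcfg = config.phantom.to_phantom_config(seed)
    size = config.phantom.image_size_px
    if config.geometry_file:
        views = load_biplane(config.geometry_file)
    else:
        views = ph.default_views((size, size))
    view_of = {g.label: g for g in views}
    balloon = ph.BalloonModel()

    logger.info("stage phantom: %d scenes x %d frames at %d px",
                config.phantom.n_scenes, config.phantom.frames_per_scene, size)
    try:
        manifest = ph.generate_dataset(
            config.phantom.n_scenes, config.phantom.frames_per_scene,
            config.phantom.split_fractions, pcfg, out_dir / "dataset",
            balloon=balloon, views=views)
    except Exception as exc:
        raise RuntimeError(f"stage 'phantom' failed: {exc}") from exc

    dataset = out_dir / "dataset"
    frames_cache: dict[str, np.ndarray] = {}
    truth_cache: dict[str, ph.SceneTruth] = {}

    def frame_of(row) -> np.ndarray:
        key = row.image_path
        if key not in frames_cache:
            frames_cache[key] = read_image(dataset / key)
        return frames_cache[key]

    def truth_of(row) -> ph.SceneTruth:
        key = row.truth_path
        if key not in truth_cache:
            truth_cache[key] = ph.SceneTruth.from_dict(
                json.loads((dataset / key).read_text()))
        return truth_cache[key]

    logger.info("stage annotate: %d runs", manifest.groupby(["scene_id", "view"]).ngroups)
    annotations: dict[tuple[int, str, int], dict] = {}
    try:
        for sid, view, grp in _runs_of(manifest):
            rows = list(grp.itertuples())
            frames = [frame_of(r) for r in rows]
            truths = [truth_of(r) for r in rows]
            run_ann = annotate_run(frames, truths, view, config.annotation)
            for idx, entry in run_ann.items():
                annotations[(sid, view, rows[idx].frame_index)] = entry
    except Exception as exc:
        raise RuntimeError(f"stage 'annotate' failed: {exc}") from exc

    # ----- training sets ---------------------------------------------------
    def collect(split_names: set[str]):
        xm, ym, xs, ys = [], [], [], []
        for row in manifest.itertuples():
            if row.split not in split_names:
                continue
            key = (row.scene_id, row.view, row.frame_index)
            if key not in annotations:
                continue
            entry = annotations[key]
            img = frame_of(row).astype(np.float32) / 255.0
            xm.append(img[:, :, None])
            ym.append(entry["marker_mask"].astype(np.float32))
            if "shaft_target" in entry:
                xs.append(np.stack([img, entry["marker_mask"].astype(np.float32)], axis=2))
                ys.append(entry["shaft_target"].astype(np.float32))
        return xm, ym, xs, ys

    xm_tr, ym_tr, xs_tr, ys_tr = collect({"train"})
    xm_va, ym_va, xs_va, ys_va = collect({"val"})
    if not xm_tr:
        raise RuntimeError("stage 'train' failed: no annotated training frames")

    def make_model(ts: TrainSettings, channels: int) -> segnet.UNet:
        cfg = segnet.UNetConfig(
            input_channels=channels, depth=ts.depth, base_filters=ts.base_filters,
            dropout_rate=ts.dropout_rate, residual_output=ts.residual_output,
            image_size_px=size)
        return segnet.build_unet(cfg, rng_seed=seed)

    def make_tc(ts: TrainSettings) -> segnet.TrainConfig:
        return segnet.TrainConfig(
            epochs=ts.epochs, batch_size=ts.batch_size, learning_rate=ts.learning_rate,
            loss=ts.loss, pos_weight=ts.pos_weight, rng_seed=seed)

    logger.info("stage train: marker net on %d frames, shaft net on %d frames",
                len(xm_tr), len(xs_tr))
    try:
        marker_model = make_model(config.marker_net, 1)
        hist_m = segnet.train(
            marker_model, np.stack(xm_tr), np.stack(ym_tr), make_tc(config.marker_net),
            val_images=np.stack(xm_va) if xm_va else None,
            val_targets=np.stack(ym_va) if ym_va else None)
        shaft_model = make_model(config.shaft_net, 2)
        hist_s = segnet.train(
            shaft_model, np.stack(xs_tr), np.stack(ys_tr), make_tc(config.shaft_net),
            val_images=np.stack(xs_va) if xs_va else None,
            val_targets=np.stack(ys_va) if ys_va else None)
        segnet.save_model(marker_model, out_dir / "unet_marker.npz")
        segnet.save_model(shaft_model, out_dir / "unet_shaft.npz")
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc

    # ----- prediction + post-processing on the test split ------------------
    logger.info("stage predict/postprocess: test split")
    test_rows = manifest[manifest.split == "test"]
    per_frame: dict[tuple[int, str, int], dict] = {}
    metrics_rows = []
    try:
        for row in test_rows.itertuples():
            key = (row.scene_id, row.view, row.frame_index)
            img = frame_of(row)
            truth = truth_of(row)
            true_seed = truth.per_view[row.view]["true_seed_px"]
            true_cl = np.asarray(truth.per_view[row.view]["true_centerline_px"])
            entry: dict = {"truth": truth}

            soft_m = segnet.predict_marker(marker_model, img)
            seed_pt = post.marker_seed_from_softmask(
                soft_m, config.annotation.marker_threshold_fraction)
            entry["seed"] = seed_pt
            err_px = post.seed_error(seed_pt, true_seed) if seed_pt else np.nan

            aux = annotations.get(key)
            aux_mask = aux["marker_mask"].astype(np.float32) if aux else np.zeros_like(
                img, dtype=np.float32)
            soft_s = segnet.predict_shaft(shaft_model, img, aux_mask)
            cl_seed = seed_pt
            if cl_seed is None and aux is not None:
                cl_seed = post.SeedPoint(uv=aux["seed_uv"], source="annotated",
                                         contour_area_px=float(aux["marker_mask"].sum()))
            centerline = post.centerline_from_softmask(
                soft_s, cl_seed, config.annotation.shaft_threshold_fraction,
                roi_size_px=config.annotation.skeleton_roi_px)
            entry["centerline"] = centerline
            cl_err = (post.centerline_mean_error(centerline.points, true_cl)
                      if centerline is not None else np.nan)
            per_frame[key] = entry
            spacing = view_of[row.view].pixel_spacing_mm
            metrics_rows.append({
                "frame_id": row.frame_id, "scene_id": row.scene_id,
                "frame_index": row.frame_index, "view": row.view,
                "marker_detected": seed_pt is not None,
                "shaft_detected": centerline is not None,
                "seed_error_px": err_px,
                "seed_error_mm": post.px_to_mm(err_px, spacing) if seed_pt else np.nan,
                "centerline_mean_error_px": cl_err,
            })
    except Exception as exc:
        raise RuntimeError(f"stage 'predict' failed: {exc}") from exc

    # ----- biplane reconstruction ------------------------------------------
    logger.info("stage reconstruct: biplane test frames")
    recon_rows = []
    try:
        test_pairs = sorted({(k[0], k[2]) for k in per_frame})
        for sid, fidx in test_pairs:
            ef = per_frame.get((sid, "frontal", fidx))
            el = per_frame.get((sid, "lateral", fidx))
            if not ef or not el:
                continue
            rec = {"scene_id": sid, "frame_index": fidx, "reconstructed": False}
            if all(e["seed"] is not None and e["centerline"] is not None
                   for e in (ef, el)):
                obs = recon3d.BiplaneObservation(
                    frontal=recon3d.ViewObservation(view_of["frontal"], ef["seed"],
                                                    ef["centerline"]),
                    lateral=recon3d.ViewObservation(view_of["lateral"], el["seed"],
                                                    el["centerline"]))
                try:
                    pose = recon3d.reconstruct_pose(obs)
                except recon3d.ReconstructionError as exc:
                    logger.info("reconstruction degenerate for scene %d frame %d: %s",
                                sid, fidx, exc)
                else:
                    truth = ef["truth"]
                    bp = recon3d.backprojection_error(pose, obs)
                    ang = np.degrees(np.arccos(np.clip(abs(float(np.dot(
                        pose.shaft_direction, truth.shaft_direction))), -1.0, 1.0)))
                    rec.update(
                        reconstructed=True,
                        marker_error_mm=float(np.linalg.norm(
                            pose.marker_position_mm - truth.marker_position_mm)),
                        direction_error_deg=float(ang),
                        triangulation_residual_mm=pose.triangulation_residual_mm,
                        backprojection_px_frontal=bp["frontal"]["px"],
                        backprojection_px_lateral=bp["lateral"]["px"])
            recon_rows.append(rec)
    except Exception as exc:
        raise RuntimeError(f"stage 'reconstruct' failed: {exc}") from exc

    # ----- report -----------------------------------------------------------
    metrics = pd.DataFrame(metrics_rows)
    recon = pd.DataFrame(recon_rows)
    metrics.to_csv(out_dir / "metrics.csv", index=False)
    if len(recon):
        recon.to_csv(out_dir / "reconstruction.csv", index=False)

    def nanmean(series):
        arr = np.asarray(series, dtype=float)
        return float(np.nanmean(arr)) if np.isfinite(arr).any() else float("nan")

    marker_rate = post.detection_rate(
        [s if d else None for s, d in zip(metrics.frame_id, metrics.marker_detected)])
    shaft_rate = post.detection_rate(
        [s if d else None for s, d in zip(metrics.frame_id, metrics.shaft_detected)])
    report = {
        "n_train_frames_marker": len(xm_tr),
        "n_train_frames_shaft": len(xs_tr),
        "n_test_frames": int(len(metrics)),
        "marker_detection_rate_pct": marker_rate.percent,
        "shaft_detection_rate_pct": shaft_rate.percent,
        "mean_seed_error_px": nanmean(metrics.seed_error_px),
        "mean_seed_error_mm": nanmean(metrics.seed_error_mm),
        "mean_centerline_error_px": nanmean(metrics.centerline_mean_error_px),
        "final_train_loss_marker": hist_m["train_loss"][-1],
        "final_train_loss_shaft": hist_s["train_loss"][-1],
        "n_reconstructed": int(recon.reconstructed.sum()) if len(recon) else 0,
        "n_biplane_pairs": int(len(recon)),
        "mean_marker_error_mm": nanmean(recon.get("marker_error_mm", [])),
        "mean_direction_error_deg": nanmean(recon.get("direction_error_deg", [])),
        "mean_backprojection_px": nanmean(
            pd.concat([recon.get("backprojection_px_frontal", pd.Series(dtype=float)),
                       recon.get("backprojection_px_lateral", pd.Series(dtype=float))])
            if len(recon) else []),
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("pipeline report: %s", json.dumps(report, indent=2))
    return report
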
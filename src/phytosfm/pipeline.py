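"""End-to-end orchestration and the two acquisition-parameter studies.

The reconstruction follows the acquisition pipeline order: derive the
matching channel (ExG by default) from both views, normalise and
digitally upsample it, detect SIFT keypoints, match with the ratio test,
extract horizontal disparities, lift them through the Q matrix, densify
over the plant mask, and — when a UV frame is present — register the
thresholded fluorescence map onto the cloud and report coverage.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import PipelineConfig
from .features import (Keypoint, MatchSet, compute_disparity, detect_keypoints,
                       match_keypoints)
from .fluorescence import (DiseaseReport, disease_coverage, register_disease,
                           threshold_disease)
from .geometry import PlantPointCloud, build_Q, densify, reproject_field
from .spectral import (CHANNEL_KINDS, IntensityImage, SignedChannelImage,
                       SpectralFrameSet, compute_channel, compute_exg,
                       normalize_for_detection, upsample)

__all__ = ["ReconstructionError", "ReconstructionResult", "StudyTable",
           "detection_image", "run_reconstruction", "channel_study",
           "angle_step_study"]

log = logging.getLogger(__name__)


class ReconstructionError(RuntimeError):
    """No usable matches/disparities — downstream densification is meaningless."""


@dataclass(frozen=True)
class ReconstructionResult:
    cloud: PlantPointCloud
    report: Optional[DiseaseReport]
    n_keypoints_a: int
    n_keypoints_b: int
    n_matches: int
    n_disparities: int

    def __iter__(self):  # allow (cloud, report) unpacking
        return iter((self.cloud, self.report))


@dataclass(frozen=True)
class StudyTable:
    """Rows of (condition label, matched-keypoint count)."""

    rows: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if any(c < 0 for _, c in self.rows):
            raise ValueError("counts must be non-negative")

    def count(self, condition: str) -> float:
        for label, c in self.rows:
            if label == condition:
                return c
        raise KeyError(condition)

    def summarize(self) -> "StudyTable":
        """Mean count per distinct condition, in first-seen order."""
        order: list[str] = []
        groups: dict[str, list[float]] = {}
        for label, c in self.rows:
            groups.setdefault(label, []).append(c)
            if label not in order:
                order.append(label)
        return StudyTable(tuple((lab, float(np.mean(groups[lab]))) for lab in order))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("condition\tmatched_keypoints\n")
            for label, c in self.rows:
                fh.write(f"{label}\t{c:g}\n")


def detection_image(frames: SpectralFrameSet, channel: str,
                    factor: int) -> IntensityImage:
    """Channel → min–max 8-bit → bicubic upsample: the detector input."""
    return upsample(normalize_for_detection(compute_channel(frames, channel)),
                    factor)


def _detect(frames: SpectralFrameSet, cfg: PipelineConfig) -> list[Keypoint]:
    return detect_keypoints(
        detection_image(frames, cfg.channel_for_matching, cfg.upsample_factor))


def _match(kps_a: list[Keypoint], kps_b: list[Keypoint],
           cfg: PipelineConfig, shape: tuple[int, int]) -> MatchSet:
    method = "kdtree" if cfg.ann_kdtree_indexes >= 1 else "brute"
    return match_keypoints(kps_a, kps_b, ratio=cfg.match_ratio, method=method,
                           trees=cfg.ann_trees, image_shape=shape)


def _ransac_filter(matches: MatchSet, kps_a, kps_b) -> MatchSet:
    """Optional gross-outlier rejection with an affine-consistency RANSAC."""
    from skimage.measure import ransac
    from skimage.transform import AffineTransform

    if len(matches) < 8:
        return matches
    src = np.array([[kps_a[i].u, kps_a[i].v] for i in matches.indices_a])
    dst = np.array([[kps_b[i].u, kps_b[i].v] for i in matches.indices_b])
    _, inliers = ransac((src, dst), AffineTransform, min_samples=4,
                        residual_threshold=3.0, max_trials=300, rng=0)
    if inliers is None or inliers.sum() < 4:
        return matches
    return MatchSet(matches.pairs[inliers], matches.image_shape)


def run_reconstruction(
    config: PipelineConfig,
    view_a: SpectralFrameSet,
    view_b: SpectralFrameSet,
) -> ReconstructionResult:
    """Reconstruct the 3D surface from two views; map disease if UV present.

    Raises :class:`ReconstructionError` when no matches or no positive
    disparities survive (e.g. identical images as both views).
    """
    cfg = config
    t0 = time.perf_counter()
    kps_a = _detect(view_a, cfg)
    kps_b = _detect(view_b, cfg)
    log.info("keypoints: %d / %d (%.2fs)", len(kps_a), len(kps_b),
             time.perf_counter() - t0)

    up_shape = (view_a.shape[0] * cfg.upsample_factor,
                view_a.shape[1] * cfg.upsample_factor)
    matches = _match(kps_a, kps_b, cfg, up_shape)
    if cfg.use_ransac:
        matches = _ransac_filter(matches, kps_a, kps_b)
    log.info("matches kept by ratio test: %d", len(matches))
    if len(matches) == 0:
        raise ReconstructionError(
            f"no matches survived the ratio test "
            f"({len(kps_a)}/{len(kps_b)} keypoints)")

    drift = cfg.max_vertical_drift * cfg.upsample_factor
    field = compute_disparity(matches, kps_a, kps_b, max_vertical_drift=drift)
    if len(field) == 0:
        raise ReconstructionError(
            f"all {len(matches)} matches had zero disparity or excess "
            f"vertical drift — are the two views identical?")
    field = field.scaled(cfg.upsample_factor)  # back to native pixels
    log.info("disparities retained: %d (zero: %d, drift: %d)", len(field),
             field.n_rejected_zero, field.n_rejected_drift)

    Q = build_Q(cfg.intrinsics)
    exg_a = compute_exg(view_a)
    channel_a = compute_channel(view_a, cfg.channel_for_matching)
    sparse = reproject_field(field, Q, channel_a)
    plant_mask = exg_a.pixels > 0
    if not plant_mask.any():
        plant_mask = np.ones(view_a.shape, dtype=bool)
        log.warning("empty ExG plant mask; densifying over the full frame")
    cloud = densify(sparse, plant_mask, Q, channel_a, method=cfg.densify_method)
    if cfg.world_scale != 1.0:
        cloud = PlantPointCloud(cloud.points * cfg.world_scale, cloud.intensity,
                                cloud.disease, cloud.source_pixel)
    log.info("dense cloud: %d points", len(cloud))

    report = None
    if view_a.uv_green is not None:
        mask = threshold_disease(view_a.uv_green, cfg.disease_threshold)
        cloud = register_disease(cloud, mask, image_shape=view_a.shape)
        report = disease_coverage(cloud, cfg.disease_threshold)
        log.info("disease: %d of %d points (%.2f%%)", report.n_disease_pixels,
                 report.n_structure_points, report.coverage_percent)
    else:
        log.warning("no UV-green frame in view A: structural-only output")
    return ReconstructionResult(cloud, report, len(kps_a), len(kps_b),
                                len(matches), len(field))


def channel_study(view_a: SpectralFrameSet, view_b: SpectralFrameSet,
                  config: PipelineConfig) -> StudyTable:
    """Matched-keypoint count per channel under identical parameters."""
    rows = []
    for channel in CHANNEL_KINDS:
        kps_a = detect_keypoints(
            detection_image(view_a, channel, config.upsample_factor))
        kps_b = detect_keypoints(
            detection_image(view_b, channel, config.upsample_factor))
        matches = _match(kps_a, kps_b, config, view_a.shape)
        rows.append((channel, float(len(matches))))
        log.info("channel %-5s: %d keypoints vs %d, %d matched",
                 channel, len(kps_a), len(kps_b), len(matches))
    return StudyTable(tuple(rows))


def angle_step_study(views: Sequence[SpectralFrameSet],
                     steps: Sequence[float],
                     config: PipelineConfig) -> StudyTable:
    """Matched counts over consecutive pairs for each angular step size.

    ``views`` must be sampled on a uniform angular grid (their
    ``view_angle`` fields); each requested step must be an integer
    multiple of the grid spacing.  One row per evaluated pair, labelled by
    its step; use :meth:`StudyTable.summarize` for the per-step means.
    """
    if len(views) < 2:
        raise ValueError("need at least two views")
    angles = [v.view_angle for v in views]
    grid = angles[1] - angles[0]
    if grid <= 0 or not np.allclose(np.diff(angles), grid):
        raise ValueError("views must be on a uniform increasing angular grid")

    cache: dict[int, list[Keypoint]] = {}

    def kps(i: int) -> list[Keypoint]:
        if i not in cache:
            cache[i] = _detect(views[i], config)
        return cache[i]

    rows = []
    for step in steps:
        stride = step / grid
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError(
                f"step {step} is not a multiple of the angular grid {grid}")
        stride = int(round(stride))
        if stride >= len(views):
            raise ValueError(f"step {step} exceeds the sequence span")
        for i in range(0, len(views) - stride, stride):
            matches = _match(kps(i), kps(i + stride), config, views[i].shape)
            rows.append((f"{step:g}", float(len(matches))))
    return StudyTable(tuple(rows))
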
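"""Disease-pixel extraction from UV-induced fluorescence and 3D registration.

Under 365 nm excitation, tissue infected by biotrophic pathogens such as
*Bremia lactucae* shows enhanced blue-green fluorescence (≈400–560 nm).
The green-filter frame acquired under UV light therefore carries the
disease signal; thresholding it (default 110 counts, removing everything
smaller) isolates infected pixels, which are then registered onto the 3D
structural cloud.  Registration is the identity in pixel space: UV and
white-light frames come from the same camera and pose, only the
illumination differs.  Leaf veins also fluoresce and are not suppressed;
the threshold is the single exposed control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .geometry import PlantPointCloud
from .spectral import IntensityImage

__all__ = ["DiseaseMask", "DiseaseReport", "threshold_disease",
           "register_disease", "disease_coverage"]

DEFAULT_THRESHOLD = 110.0


@dataclass(frozen=True)
class DiseaseMask:
    """Boolean disease map with its threshold and positive-pixel count."""

    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        object.__setattr__(self, "mask", m)

    @property
    def positive_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class DiseaseReport:
    """Coverage of the reconstructed surface by disease-flagged points."""

    n_disease_pixels: int
    n_structure_points: int
    threshold: float

    @property
    def coverage_fraction(self) -> float:
        return self.n_disease_pixels / self.n_structure_points

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.coverage_fraction

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "n_disease_pixels": self.n_disease_pixels,
            "n_structure_points": self.n_structure_points,
            "coverage_fraction": self.coverage_fraction,
            "threshold": self.threshold,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def threshold_disease(uv_green: IntensityImage, tau: float = DEFAULT_THRESHOLD) -> DiseaseMask:
    """Keep pixels at or above ``tau`` counts as disease signal.

    Signals *smaller than* tau are removed — a pixel exactly at the
    threshold is kept.
    """
    return DiseaseMask(uv_green.pixels >= tau, float(tau))


def _resize_mask_nearest(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour mask resize; preserves binarity by construction."""
    h, w = mask.shape
    rows = np.clip(np.floor((np.arange(shape[0]) + 0.5) * h / shape[0]).astype(int), 0, h - 1)
    cols = np.clip(np.floor((np.arange(shape[1]) + 0.5) * w / shape[1]).astype(int), 0, w - 1)
    return mask[np.ix_(rows, cols)]


def register_disease(
    cloud: PlantPointCloud,
    mask: DiseaseMask,
    image_shape: tuple[int, int] | None = None,
) -> PlantPointCloud:
    """Flag each cloud point with the mask value at its source pixel.

    ``image_shape`` is the shape of the structural image the cloud's
    source pixels index; if the mask differs (one side was upsampled) it
    is resized with nearest-neighbour.  Coordinates and intensities are
    untouched.
    """
    if len(cloud) == 0:
        return cloud
    u, v = cloud.source_pixel.T
    if image_shape is None:
        image_shape = (int(np.ceil(v.max())) + 1, int(np.ceil(u.max())) + 1)
        if mask.shape[0] >= image_shape[0] and mask.shape[1] >= image_shape[1]:
            image_shape = mask.shape
    m = mask.mask
    if m.shape != image_shape:
        m = _resize_mask_nearest(m, image_shape)
    vi = np.clip(np.rint(v).astype(int), 0, image_shape[0] - 1)
    ui = np.clip(np.rint(u).astype(int), 0, image_shape[1] - 1)
    return PlantPointCloud(cloud.points, cloud.intensity, m[vi, ui], cloud.source_pixel)


def disease_coverage(cloud: PlantPointCloud,
                     threshold: float = DEFAULT_THRESHOLD) -> DiseaseReport:
    """Fraction of structure points flagged as diseased."""
    if len(cloud) == 0:
        raise ValueError("coverage is undefined for an empty cloud")
    return DiseaseReport(
        n_disease_pixels=int(cloud.disease.sum()),
        n_structure_points=len(cloud),
        threshold=float(threshold),
    )
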
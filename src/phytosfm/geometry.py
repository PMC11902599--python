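"""Camera model, perspective reprojection and sparse-to-dense surface lift.

The reconstruction model is rectified-stereo: a matched keypoint at pixel
(u, v) with disparity d maps to homogeneous world coordinates through the
4×4 perspective matrix

    Q = [[1,  0,  0,      -u0],
         [0, -1,  0,       v0],
         [0,  0,  s·f·ku,   0],
         [0,  0,  0,        1]]

applied to [u, v, 1/d, 1]ᵀ, followed by division by the homogeneous scale.
Because the last row of Q is (0, 0, 0, 1) the scale is always 1 and the
closed form is simply X = u − u0, Y = v0 − v (image v points down, world Y
up), Z = s·f·ku / d.  The dimensionless factor s sets the depth scale of
the reconstruction; absolute metric depth is recovered only up to this
calibrated factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .features import DisparityField
from .spectral import IntensityImage, SignedChannelImage

__all__ = [
    "CameraIntrinsics",
    "QMatrix",
    "PlantPointCloud",
    "build_Q",
    "reproject_point",
    "dehomogenize",
    "reproject_field",
    "densify",
    "write_ply",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics of the monochrome camera.

    f in mm; ku, kv in pixels per mm (reciprocal pixel pitch); principal
    point (u0, v0) in pixels; s is the dimensionless reprojection scale
    obtained from calibration (0.02 for the reference rig: 8 mm objective,
    3.45 µm square pixels, 1440×1080 sensor).
    """

    f: float = 8.0
    ku: float = 1.0 / 0.00345
    kv: float = 1.0 / 0.00345
    u0: float = 720.0
    v0: float = 540.0
    s: float = 0.02

    def __post_init__(self) -> None:
        if self.f <= 0 or self.ku <= 0 or self.kv <= 0 or self.s <= 0:
            raise ValueError("f, ku, kv and s must all be positive")

    @property
    def fku(self) -> float:
        """Focal length in horizontal pixels, f·ku."""
        return self.f * self.ku

    @property
    def fkv(self) -> float:
        return self.f * self.kv

    def scaled(self, factor: float) -> "CameraIntrinsics":
        """Intrinsics of the same camera after resampling by ``factor``."""
        return CameraIntrinsics(self.f, self.ku * factor, self.kv * factor,
                                self.u0 * factor, self.v0 * factor, self.s)


@dataclass(frozen=True)
class QMatrix:
    """4×4 perspective transformation mapping [u, v, 1/d, 1] to world."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValueError("Q must be 4×4")
        object.__setattr__(self, "entries", m)


def build_Q(intr: CameraIntrinsics) -> QMatrix:
    """Assemble Q from the intrinsics; rows fixed by the rectified model."""
    return QMatrix(np.array([
        [1.0, 0.0, 0.0, -intr.u0],
        [0.0, -1.0, 0.0, intr.v0],
        [0.0, 0.0, intr.s * intr.fku, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]))


def dehomogenize(p: np.ndarray) -> np.ndarray:
    """[X̃, Ỹ, Z̃, W̃] → [X̃/W̃, Ỹ/W̃, Z̃/W̃]; W̃ must be nonzero."""
    p = np.asarray(p, dtype=np.float64)
    w = p[..., 3]
    if np.any(w == 0):
        raise ValueError("homogeneous scale W̃ must be nonzero")
    return p[..., :3] / w[..., None]


def reproject_point(u: float, v: float, d: float, Q: QMatrix) -> tuple[float, float, float]:
    """Lift a single disparity sample to world coordinates via Q.

    Uses the closed form X = u − u0, Y = v0 − v, Z = s·f·ku/d, which the
    matrix product forces (see module docstring); d must be positive.
    """
    if d <= 0:
        raise ValueError(f"disparity must be positive, got {d}")
    m = Q.entries
    return (u + m[0, 3], -v + m[1, 3], m[2, 2] / d)


@dataclass(frozen=True)
class PlantPointCloud:
    """World-coordinate surface points with intensity and disease annotation."""

    points: np.ndarray        # (n, 3) world X, Y, Z — Z > 0
    intensity: np.ndarray     # (n,) channel value at the source pixel
    disease: np.ndarray       # (n,) bool
    source_pixel: np.ndarray  # (n, 2) native-resolution (u, v)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        n = pts.shape[0]
        inten = np.asarray(self.intensity, dtype=np.float64).reshape(n)
        dis = np.asarray(self.disease, dtype=bool).reshape(n)
        src = np.asarray(self.source_pixel, dtype=np.float64).reshape(n, 2)
        if n and pts[:, 2].min() <= 0:
            raise ValueError("all retained points must have positive depth Z")
        for name, val in (("points", pts), ("intensity", inten),
                          ("disease", dis), ("source_pixel", src)):
            object.__setattr__(self, name, val)

    def __len__(self) -> int:
        return self.points.shape[0]

    @classmethod
    def empty(cls) -> "PlantPointCloud":
        return cls(np.empty((0, 3)), np.empty(0), np.empty(0, bool), np.empty((0, 2)))


def reproject_field(
    field: DisparityField,
    Q: QMatrix,
    intensity_image: SignedChannelImage,
) -> PlantPointCloud:
    """Lift every disparity sample to a cloud point.

    Intensity is sampled at the nearest pixel of the source channel image;
    disease flags start false (registration happens downstream).
    """
    if len(field) == 0:
        log.warning("reproject_field: empty disparity field, empty cloud")
        return PlantPointCloud.empty()
    u, v, d = field.samples.T
    m = Q.entries
    pts = np.column_stack([u + m[0, 3], -v + m[1, 3], m[2, 2] / d])
    h, w = intensity_image.shape
    vi = np.clip(np.rint(v).astype(int), 0, h - 1)
    ui = np.clip(np.rint(u).astype(int), 0, w - 1)
    inten = intensity_image.pixels[vi, ui]
    return PlantPointCloud(pts, inten, np.zeros(len(field), bool),
                           np.column_stack([u, v]))


def densify(
    cloud: PlantPointCloud,
    plant_mask: np.ndarray,
    Q: QMatrix,
    intensity_image: SignedChannelImage,
    method: str = "linear",
) -> PlantPointCloud:
    """Lift every masked pixel to a surface point by interpolating depth.

    Depth is interpolated over the image plane from the sparse samples —
    linearly inside their convex hull, nearest-sample outside (or
    everywhere with ``method='nearest'``).  The result has exactly one
    point per true mask pixel, positioned by the same closed-form
    reprojection as the sparse cloud.
    """
    if len(cloud) == 0:
        raise ValueError("cannot densify an empty cloud")
    mask = np.asarray(plant_mask, dtype=bool)
    if mask.shape != intensity_image.shape:
        raise ValueError("plant mask and intensity image shapes differ")
    if method not in ("linear", "nearest"):
        raise ValueError(f"unknown densification method {method!r}")
    if method == "linear" and len(cloud) < 3:
        log.warning("densify: fewer than 3 samples, falling back to nearest")
        method = "nearest"

    uv = cloud.source_pixel
    z = cloud.points[:, 2]
    vi, ui = np.nonzero(mask)
    targets = np.column_stack([ui, vi]).astype(np.float64)

    near = NearestNDInterpolator(uv, z)
    if method == "linear":
        lin = LinearNDInterpolator(uv, z)
        depth = lin(targets)
        hole = np.isnan(depth)
        if hole.any():
            depth[hole] = near(targets[hole])
    else:
        depth = near(targets)

    m = Q.entries
    pts = np.column_stack([targets[:, 0] + m[0, 3], -targets[:, 1] + m[1, 3], depth])
    inten = intensity_image.pixels[vi, ui]
    return PlantPointCloud(pts, inten, np.zeros(len(vi), bool), targets)


def write_ply(path: str | Path, cloud: PlantPointCloud, binary: bool = True) -> None:
    """Write the cloud as PLY with x, y, z, intensity (float) and disease (uchar)."""
    n = len(cloud)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {n}\n"
        "property float x\nproperty float y\nproperty float z\n"
        "property float intensity\nproperty uchar disease\n"
        "end_header\n"
    )
    path = Path(path)
    if binary:
        rec = np.empty(n, dtype=[("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
                                 ("intensity", "<f4"), ("disease", "u1")])
        rec["x"], rec["y"], rec["z"] = cloud.points.T.astype(np.float32)
        rec["intensity"] = cloud.intensity.astype(np.float32)
        rec["disease"] = cloud.disease.astype(np.uint8)
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            rec.tofile(fh)
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for (x, y, z), i, dz in zip(cloud.points, cloud.intensity, cloud.disease):
                fh.write(f"{x:.6g} {y:.6g} {z:.6g} {i:.6g} {int(dz)}\n")
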
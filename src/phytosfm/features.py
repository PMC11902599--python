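"""Keypoint detection, descriptor matching and disparity extraction.

Detection is SIFT (difference-of-Gaussian scale-space extrema with
gradient-histogram descriptors), delegated to scikit-image.  Matching is
nearest-neighbour search over descriptors with Lowe's ratio test at the
default cutoff 0.6; the kd-tree backend mirrors the usual
FLANN-kdtree configuration and a brute-force backend serves as the exact
oracle.  Disparity is the horizontal displacement magnitude of a matched
pair, the apparent motion a turntable rotating about a vertical axis
produces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import SIFT

from .spectral import IntensityImage

__all__ = [
    "Keypoint",
    "MatchSet",
    "DisparityField",
    "detect_keypoints",
    "match_keypoints",
    "compute_disparity",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Keypoint:
    """A localized scale-space feature: subpixel position, diameter, descriptor."""

    u: float            # column, pixels
    v: float            # row, pixels
    diameter: float     # pixels; the support region over which depth is attributed
    descriptor: np.ndarray

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("keypoint diameter must be positive")


@dataclass(frozen=True)
class MatchSet:
    """Ratio-test-surviving pairs (index_a, index_b, best, second)."""

    pairs: np.ndarray           # (n, 4) float: ia, ib, best_distance, second_distance
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=np.float64).reshape(-1, 4)
        if pairs.size and np.any(pairs[:, 2] > pairs[:, 3]):
            raise ValueError("best_distance must not exceed second_distance")
        if pairs.size:
            ia = pairs[:, 0].astype(int)
            if len(np.unique(ia)) != len(ia):
                raise ValueError("each query keypoint may appear at most once")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @property
    def indices_a(self) -> np.ndarray:
        return self.pairs[:, 0].astype(int)

    @property
    def indices_b(self) -> np.ndarray:
        return self.pairs[:, 1].astype(int)


@dataclass(frozen=True)
class DisparityField:
    """Sparse per-keypoint disparities anchored in the reference view."""

    samples: np.ndarray         # (n, 3) float: u, v, d — all d > 0
    reference: str = "view_a"
    n_rejected_zero: int = 0
    n_rejected_drift: int = 0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64).reshape(-1, 3)
        if samples.size and samples[:, 2].min() <= 0:
            raise ValueError("all retained disparities must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.shape[0]

    def scaled(self, factor: float) -> "DisparityField":
        """Rescale coordinates and disparities (e.g. upsampled → native pixels)."""
        return DisparityField(self.samples / factor, self.reference,
                              self.n_rejected_zero, self.n_rejected_drift)


def detect_keypoints(image: IntensityImage) -> list[Keypoint]:
    """Detect SIFT keypoints on an 8-bit single-channel image.

    Deterministic for a fixed image.  An image without contrast yields an
    empty list, not an error.
    """
    if image.bit_depth != 8:
        raise ValueError("keypoint detection expects an 8-bit image; "
                         "use normalize_for_detection first")
    sift = SIFT()
    try:
        sift.detect_and_extract(image.pixels.astype(np.uint8))
    except RuntimeError:
        return []
    kps: list[Keypoint] = []
    for (v, u), sigma, desc in zip(sift.positions, sift.sigmas, sift.descriptors):
        kps.append(Keypoint(u=float(u), v=float(v), diameter=float(2.0 * sigma),
                            descriptor=np.asarray(desc, dtype=np.float32)))
    return kps


def _descriptor_matrix(kps: list[Keypoint]) -> np.ndarray:
    if not kps:
        return np.empty((0, 0), dtype=np.float32)
    mat = np.stack([k.descriptor for k in kps]).astype(np.float32)
    return mat


def match_keypoints(
    set_a: list[Keypoint],
    set_b: list[Keypoint],
    ratio: float = 0.6,
    *,
    method: str = "kdtree",
    trees: int = 5,
    checks: int = 1,
    image_shape: tuple[int, int] = (0, 0),
    exclude_self: bool = False,
) -> MatchSet:
    """Match descriptors of ``set_a`` against ``set_b`` with the ratio test.

    For every query keypoint its two nearest neighbours in ``set_b`` (by
    Euclidean descriptor distance) are found; the pair survives iff
    ``best / second <= ratio``.  ``method='kdtree'`` uses a k-d tree index;
    ``method='brute'`` is the exhaustive-search oracle.  The ``trees`` /
    ``checks`` knobs mirror the conventional approximate-NN configuration
    (5 trees, one kd-tree index) and select nothing beyond the backend here.

    ``exclude_self`` drops the zero-distance self match when a set is
    matched against itself (diagnostic use).
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"ratio must lie in (0, 1], got {ratio}")
    desc_a = _descriptor_matrix(set_a)
    desc_b = _descriptor_matrix(set_b)
    if desc_a.size == 0 or desc_b.shape[0] < 2:
        return MatchSet(np.empty((0, 4)), image_shape)
    if desc_a.shape[1] != desc_b.shape[1]:
        raise ValueError(
            f"descriptor length mismatch: {desc_a.shape[1]} vs {desc_b.shape[1]}"
        )
    k = 3 if exclude_self else 2
    if desc_b.shape[0] < k:
        return MatchSet(np.empty((0, 4)), image_shape)

    if method == "kdtree":
        tree = cKDTree(desc_b.astype(np.float64))
        dist, idx = tree.query(desc_a.astype(np.float64), k=k)
    elif method == "brute":
        diff = desc_a[:, None, :].astype(np.float64) - desc_b[None, :, :].astype(np.float64)
        d2 = np.einsum("abk,abk->ab", diff, diff)
        idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
        dist = np.sqrt(np.take_along_axis(d2, idx, axis=1))
    else:
        raise ValueError(f"unknown matching method {method!r}")

    if exclude_self:
        dist, idx = dist[:, 1:], idx[:, 1:]
    best, second = dist[:, 0], dist[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        keep = np.where(second > 0, best <= ratio * second, best == 0)
    ia = np.nonzero(keep)[0]
    pairs = np.column_stack([ia, idx[ia, 0], best[ia], second[ia]])
    return MatchSet(pairs, image_shape)


def compute_disparity(
    matches: MatchSet,
    kps_a: list[Keypoint],
    kps_b: list[Keypoint],
    max_vertical_drift: float = 20.0,
) -> DisparityField:
    """Horizontal-displacement disparities for the kept matches.

    d = |u_b − u_a|, anchored at the reference-view position (u_a, v_a).
    Pairs with zero disparity or vertical drift beyond
    ``max_vertical_drift`` pixels are discarded and counted; the drift gate
    removes gross mismatches since true turntable motion is horizontal.
    """
    if len(matches) == 0:
        log.warning("compute_disparity: empty match set")
        return DisparityField(np.empty((0, 3)))
    ua = np.array([kps_a[i].u for i in matches.indices_a])
    va = np.array([kps_a[i].v for i in matches.indices_a])
    ub = np.array([kps_b[i].u for i in matches.indices_b])
    vb = np.array([kps_b[i].v for i in matches.indices_b])
    d = np.abs(ub - ua)
    drift = np.abs(vb - va)
    zero = d == 0
    drifted = (~zero) & (drift > max_vertical_drift)
    keep = ~(zero | drifted)
    field = DisparityField(
        np.column_stack([ua[keep], va[keep], d[keep]]),
        n_rejected_zero=int(zero.sum()),
        n_rejected_drift=int(drifted.sum()),
    )
    if len(field) == 0:
        log.warning("compute_disparity: no disparities survived filtering")
    return field


def dump_matches_tsv(
    path: str | Path,
    matches: MatchSet,
    kps_a: list[Keypoint],
    kps_b: list[Keypoint],
) -> None:
    """Write matched coordinates and disparity to a TSV for inspection."""
    with open(path, "w") as fh:
        fh.write("u_a\tv_a\tu_b\tv_b\td\n")
        for ia, ib in zip(matches.indices_a, matches.indices_b):
            a, b = kps_a[ia], kps_b[ib]
            fh.write(f"{a.u:.3f}\t{a.v:.3f}\t{b.u:.3f}\t{b.v:.3f}\t{abs(b.u - a.u):.3f}\n")
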
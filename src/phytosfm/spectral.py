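"""Spectral channel synthesis and resampling.

A turntable rig images the plant through red, green and blue band-pass
filters in front of a monochrome camera, so every "view" is a bundle of
single-channel frames rather than a colour image.  This module derives the
working channels from such a bundle — the unweighted grayscale mean and the
excess-green vegetation index ExG = 2G − R − B — and provides the bicubic
digital upsampling applied before keypoint detection.

ExG values are kept signed and full range internally; only
:func:`normalize_for_detection` produces the bounded 8-bit images keypoint
detectors require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

__all__ = [
    "IntensityImage",
    "SpectralFrameSet",
    "SignedChannelImage",
    "to_gray",
    "compute_exg",
    "compute_channel",
    "normalize_for_detection",
    "upsample",
    "read_intensity_image",
    "load_view",
]

CHANNEL_KINDS = ("gray", "exg", "red", "green", "blue")


@dataclass(frozen=True)
class IntensityImage:
    """A single-channel image of non-negative intensity counts.

    Parameters
    ----------
    pixels
        2-D array of counts; any integer or float dtype, values in
        ``[0, 2**bit_depth - 1]``.
    bit_depth
        Sensor quantisation, 8 or 16 bits.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.min() < 0:
            raise ValueError("intensity counts must be non-negative")
        if px.max() > self.max_count:
            raise ValueError(
                f"intensity counts exceed {self.max_count} for bit_depth {self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class SpectralFrameSet:
    """Per-view bundle of R/G/B (and optionally UV-excited green) frames."""

    red: IntensityImage
    green: IntensityImage
    blue: IntensityImage
    uv_green: Optional[IntensityImage] = None
    view_angle: float = 0.0

    def __post_init__(self) -> None:
        shapes = {self.red.shape, self.green.shape, self.blue.shape}
        if self.uv_green is not None:
            shapes.add(self.uv_green.shape)
        if len(shapes) != 1:
            raise ValueError(f"all member images must share one shape, got {shapes}")
        if not (0.0 <= self.view_angle < 360.0):
            raise ValueError(f"view_angle must lie in [0, 360), got {self.view_angle}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def bit_depth(self) -> int:
        return self.red.bit_depth


@dataclass(frozen=True)
class SignedChannelImage:
    """A derived channel; signed because ExG ranges over ±2·(2^bits − 1)."""

    pixels: np.ndarray
    channel_kind: str
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.channel_kind not in CHANNEL_KINDS:
            raise ValueError(f"channel_kind must be one of {CHANNEL_KINDS}")
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError("pixels must be 2-D")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _stack(frames: SpectralFrameSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r = frames.red.pixels.astype(np.float64)
    g = frames.green.pixels.astype(np.float64)
    b = frames.blue.pixels.astype(np.float64)
    return r, g, b


def to_gray(frames: SpectralFrameSet) -> SignedChannelImage:
    """Unweighted per-pixel mean of the red, green and blue frames."""
    r, g, b = _stack(frames)
    return SignedChannelImage((r + g + b) / 3.0, "gray", frames.bit_depth)


def compute_exg(frames: SpectralFrameSet) -> SignedChannelImage:
    """Excess-green index ExG = 2·G − R − B, signed, no clipping.

    ExG amplifies leaf texture while cancelling any signal common to all
    three channels (illumination gradients, specular sheen), which is why
    it yields the richest keypoint harvest on plant surfaces.
    """
    r, g, b = _stack(frames)
    return SignedChannelImage(2.0 * g - r - b, "exg", frames.bit_depth)


def compute_channel(frames: SpectralFrameSet, kind: str) -> SignedChannelImage:
    """Derive the named working channel from a frame bundle."""
    if kind == "gray":
        return to_gray(frames)
    if kind == "exg":
        return compute_exg(frames)
    if kind in ("red", "green", "blue"):
        img: IntensityImage = getattr(frames, kind)
        return SignedChannelImage(img.pixels.astype(np.float64), kind, frames.bit_depth)
    raise ValueError(f"unknown channel kind {kind!r}")


def normalize_for_detection(channel: SignedChannelImage) -> IntensityImage:
    """Affine min–max rescale of a signed channel to 8-bit [0, 255].

    Keypoint detectors need non-negative, bounded input; this makes the
    quantisation explicit.  A constant image maps to all zeros.
    """
    px = channel.pixels
    lo = float(px.min())
    hi = float(px.max())
    if hi == lo:
        out = np.zeros(px.shape, dtype=np.uint8)
    else:
        out = np.rint(255.0 * (px - lo) / (hi - lo)).astype(np.uint8)
    return IntensityImage(out, bit_depth=8)


def upsample(image: IntensityImage, factor: int) -> IntensityImage:
    """Digitally upsample by an integer factor with bicubic interpolation.

    A 1080×1440 frame at the default factor 5 becomes the 5400×7200 format
    used for maximal keypoint harvest.  Output is clipped back to the input
    bit-depth range (cubic kernels overshoot near edges).
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"upsampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return image
    h, w = image.shape
    out = resize(
        image.pixels.astype(np.float64),
        (h * factor, w * factor),
        order=3,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    np.clip(out, 0, image.max_count, out=out)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    return IntensityImage(np.rint(out).astype(dtype), bit_depth=image.bit_depth)


# ---------------------------------------------------------------------------
# File readers.  A view on disk is a directory (or filename pattern) of
# single-channel PNG/TIFF frames named `{angle}_{channel}.{ext}` with
# channels R, G, B and optional UVG.


def read_intensity_image(path: str | Path, bit_depth: int | None = None) -> IntensityImage:
    """Read a single-channel 8- or 16-bit PNG/TIFF frame."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    if bit_depth is None:
        bit_depth = 16 if arr.dtype.itemsize >= 2 else 8
    return IntensityImage(arr, bit_depth=bit_depth)


def load_view(
    directory: str | Path,
    angle: float,
    pattern: str = "{angle:g}_{channel}.png",
    require_uv: bool = False,
) -> SpectralFrameSet:
    """Load one view's frame bundle from ``directory``.

    ``pattern`` is formatted with ``angle`` and ``channel`` (R/G/B/UVG).
    The UV-green frame is optional unless ``require_uv``.
    """
    directory = Path(directory)

    def _read(channel: str) -> IntensityImage:
        return read_intensity_image(directory / pattern.format(angle=angle, channel=channel))

    uv_path = directory / pattern.format(angle=angle, channel="UVG")
    uv = None
    if uv_path.exists():
        uv = read_intensity_image(uv_path)
    elif require_uv:
        raise FileNotFoundError(f"UV-green frame missing: {uv_path}")
    return SpectralFrameSet(
        red=_read("R"), green=_read("G"), blue=_read("B"), uv_green=uv,
        view_angle=angle % 360.0,
    )
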
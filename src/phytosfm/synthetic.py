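"""Ground-truth scene generator for end-to-end pipeline testing.

Emulates a potted rosette plant on a turntable imaged by a monochrome
camera through spectral filters: a smooth leaf-shaped height field carries
band-limited speckle texture (so SIFT finds features), the green
reflectance is boosted over red/blue inside the leaf mask (so ExG is
positive on the plant, non-positive on the background), and a
high-emission fluorescence patch is injected into the UV-green frame.

The turntable rotation between nearby views is modelled as a pure
horizontal camera translation (small-angle approximation, the regime the
rectified-stereo reprojection assumes), so the ground-truth disparity is
the closed form d = f·ku·b/Z per pixel.  A view-dependent "glare" field —
band-limited noise fixed in the image frame, added equally to all three
channels — emulates specular sheen that moves with the viewpoint: single
channels see it as non-matching clutter while ExG cancels it exactly.

Rendering of a translated view forward-splats supersampled rows with a
z-buffer, so depth discontinuities at leaf borders occlude correctly;
disocclusion holes are filled with the nearest rendered sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .geometry import CameraIntrinsics
from .spectral import IntensityImage, SpectralFrameSet

__all__ = ["SceneParams", "SyntheticScene", "RenderedView",
           "make_scene", "render_views", "render_sequence"]


@dataclass(frozen=True)
class SceneParams:
    """Knobs of the synthetic plant scene (world units are mm)."""

    height: int = 540
    width: int = 720
    depth_min: float = 600.0        # nearest leaf surface
    depth_max: float = 1000.0       # farthest leaf surface
    background_depth: float = 1400.0
    n_leaves: int = 7
    texture_grain: float = 1.8      # speckle correlation length, px
    texture_amplitude: float = 40.0  # counts, before per-channel weights
    glare_amplitude: float = 20.0   # counts, view-dependent common-mode
    patch_fraction: float = 0.04    # fluorescent patch area / leaf area
    patch_emission: float = 200.0   # counts, > disease threshold
    uv_background: float = 20.0     # counts, non-specific autofluorescence
    noise_sigma: float = 0.5        # additive Gaussian sensor noise, counts

    def __post_init__(self) -> None:
        if self.depth_min >= self.depth_max:
            raise ValueError("degenerate depth range: depth_min must be < depth_max")
        if not (0.0 < self.patch_fraction < 1.0):
            raise ValueError("patch_fraction must lie in (0, 1)")
        if self.depth_min <= 0:
            raise ValueError("depths must be positive")


@dataclass(frozen=True)
class SyntheticScene:
    """Height field, reflectance texture and fluorescence patch with seed."""

    params: SceneParams
    seed: int
    leaf_mask: np.ndarray        # (H, W) bool
    depth: np.ndarray            # (H, W) float, world units, all > 0
    reflectance: np.ndarray      # (H, W, 3) float counts, R/G/B order
    patch_mask: np.ndarray       # (H, W) bool, subset of leaf_mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass(frozen=True)
class RenderedView:
    """One rendered viewpoint with its ground truth.

    ``baseline`` is this camera's translation along +X relative to the
    reference view; ``true_disparity`` is the per-pixel displacement to
    the paired view (f·ku·pair_baseline/Z), and ``true_depth`` the
    per-pixel surface depth seen from this viewpoint.
    """

    frames: SpectralFrameSet
    true_depth: np.ndarray
    true_disparity: np.ndarray
    baseline: float
    intrinsics: CameraIntrinsics


def make_scene(params: SceneParams = SceneParams(), seed: int = 0) -> SyntheticScene:
    """Generate a reproducible plant-like scene; same seed, same scene."""
    p = params
    rng = np.random.default_rng([int(seed), 0xC0FFEE])
    h, w = p.height, p.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    # Rosette of elliptical leaves radiating from the pot centre.
    mask = np.zeros((h, w), dtype=bool)
    r_leaf = 0.30 * min(h, w)
    for k in range(p.n_leaves):
        ang = 2.0 * np.pi * k / p.n_leaves + rng.uniform(-0.2, 0.2)
        dist = rng.uniform(0.12, 0.22) * min(h, w)
        ly, lx = cy + dist * np.sin(ang), cx + dist * np.cos(ang)
        a = r_leaf * rng.uniform(0.8, 1.1)          # along the leaf axis
        b = r_leaf * rng.uniform(0.38, 0.55)        # across
        ca, sa = np.cos(ang), np.sin(ang)
        xr = (xx - lx) * ca + (yy - ly) * sa
        yr = -(xx - lx) * sa + (yy - ly) * ca
        mask |= (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    # keep a clear border so the warped view stays inside the frame
    border = int(0.06 * min(h, w))
    mask[:border, :] = mask[-border:, :] = False
    mask[:, :border] = mask[:, -border:] = False

    # Smooth random leaf-surface depth in [depth_min, depth_max], blended
    # into the far background plane so the stereo warp stays gentle.
    zn = gaussian_filter(rng.standard_normal((h, w)), sigma=0.08 * min(h, w))
    zn = (zn - zn.min()) / (zn.max() - zn.min() + 1e-12)
    leaf_depth = p.depth_min + (p.depth_max - p.depth_min) * zn
    blend = gaussian_filter(mask.astype(np.float64), sigma=0.015 * min(h, w))
    depth = blend * leaf_depth + (1.0 - blend) * p.background_depth

    # Band-limited speckle: plant texture T on the leaves, milder shared
    # speckle S on the background.  Channel weights make ExG positive on
    # the plant (2·0.8 − 0.30 − 0.25 > 0) and −20 counts off it.
    def speckle() -> np.ndarray:
        s = gaussian_filter(rng.standard_normal((h, w)), sigma=p.texture_grain)
        s /= s.std()
        return np.clip(s, -2.2, 2.2)

    t = speckle() * p.texture_amplitude
    s_bg = speckle() * 10.0
    refl = np.empty((h, w, 3))
    refl[..., 0] = np.where(mask, 55.0 + 0.30 * t, 80.0 + s_bg)   # red
    refl[..., 1] = np.where(mask, 115.0 + 0.80 * t, 70.0 + s_bg)  # green
    refl[..., 2] = np.where(mask, 55.0 + 0.25 * t, 80.0 + s_bg)   # blue

    # Fluorescent patch: the patch_fraction·|leaf| pixels nearest to a
    # point inside a leaf, giving an exact requested area.
    k_patch = int(round(p.patch_fraction * mask.sum()))
    my, mx = np.nonzero(mask)
    centre = rng.integers(len(my))
    d2 = (my - my[centre]) ** 2 + (mx - mx[centre]) ** 2
    sel = np.argsort(d2, kind="stable")[:k_patch]
    patch = np.zeros((h, w), dtype=bool)
    patch[my[sel], mx[sel]] = True

    return SyntheticScene(p, int(seed), mask, depth, refl, patch)


def default_intrinsics(scene: SyntheticScene) -> CameraIntrinsics:
    """Reference-rig intrinsics with the principal point at the scene centre."""
    return CameraIntrinsics(u0=scene.params.width / 2.0,
                            v0=scene.params.height / 2.0)


def _quantize(signal: np.ndarray, rng: np.random.Generator,
              noise_sigma: float) -> IntensityImage:
    out = signal + (rng.standard_normal(signal.shape) * noise_sigma
                    if noise_sigma > 0 else 0.0)
    return IntensityImage(np.clip(np.rint(out), 0, 255).astype(np.uint8), 8)


def _glare(shape: tuple[int, int], amplitude: float,
           rng: np.random.Generator) -> np.ndarray:
    g = gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    g /= g.std() + 1e-12
    return amplitude * np.clip(g, -2.5, 2.5) / 2.5


def _splat_view(scene: SyntheticScene, fku: float, baseline: float,
                supersample: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Render reflectance and depth seen by a camera translated by +baseline.

    A world point at reference pixel u and depth Z appears at
    u' = u − f·ku·baseline/Z.  Rows are supersampled, forward-splatted to
    the nearest target pixel and z-buffered; holes left by disocclusion
    take the nearest rendered sample.
    """
    h, w = scene.shape
    if baseline == 0.0:
        return scene.reflectance.copy(), scene.depth.copy()
    ws = (w - 1) * supersample + 1
    us = np.linspace(0.0, w - 1, ws, dtype=np.float32)
    i0 = np.minimum(np.floor(us).astype(np.intp), w - 2)
    frac = us - i0

    def _row_interp(a: np.ndarray) -> np.ndarray:
        a = a.astype(np.float32)
        return a[:, i0] * (1.0 - frac) + a[:, i0 + 1] * frac

    depth_s = _row_interp(scene.depth)
    chans_s = [_row_interp(scene.reflectance[..., c]) for c in range(3)]
    u_target = us[None, :] - np.float32(fku * baseline) / depth_s
    ti = np.rint(u_target).astype(np.int64)
    valid = (ti >= 0) & (ti < w)
    rows = np.broadcast_to(np.arange(h)[:, None], (h, ws))
    key = (rows * w + ti)[valid]
    dz = depth_s[valid]
    order = np.lexsort((dz, key))          # by pixel, then nearest first
    key_sorted = key[order]
    first = np.ones(len(key_sorted), dtype=bool)
    first[1:] = key_sorted[1:] != key_sorted[:-1]
    hit = key_sorted[first]
    pick = order[first]

    depth_out = np.full(h * w, np.nan)
    depth_out[hit] = dz[pick]
    refl_out = np.full((h * w, 3), np.nan)
    for c in range(3):
        refl_out[hit, c] = chans_s[c][valid][pick]
    depth_out = depth_out.reshape(h, w)
    refl_out = refl_out.reshape(h, w, 3)

    holes = np.isnan(depth_out)
    if holes.any():
        idx = distance_transform_edt(holes, return_distances=False,
                                     return_indices=True)
        depth_out = depth_out[tuple(idx)]
        refl_out = refl_out[tuple(idx) + (slice(None),)]
    return refl_out, depth_out


def _render_one(scene: SyntheticScene, intr: CameraIntrinsics, baseline: float,
                pair_baseline: float, view_id: int,
                with_uv: bool) -> RenderedView:
    rng = np.random.default_rng([scene.seed, 0x51AB, view_id])
    refl, depth = _splat_view(scene, intr.fku, baseline)
    glare = _glare(scene.shape, scene.params.glare_amplitude, rng)
    ns = scene.params.noise_sigma
    red = _quantize(refl[..., 0] + glare, rng, ns)
    green = _quantize(refl[..., 1] + glare, rng, ns)
    blue = _quantize(refl[..., 2] + glare, rng, ns)
    uv = None
    if with_uv:
        uv_sig = np.where(scene.patch_mask, scene.params.patch_emission,
                          scene.params.uv_background)
        uv = _quantize(uv_sig, rng, ns)
    frames = SpectralFrameSet(red=red, green=green, blue=blue, uv_green=uv)
    disparity = intr.fku * abs(pair_baseline) / depth
    return RenderedView(frames, depth, disparity, baseline, intr)


def render_views(scene: SyntheticScene, intr: CameraIntrinsics | None = None,
                 baseline: float = 8.0) -> tuple[RenderedView, RenderedView]:
    """Render the reference view and a view translated by ``baseline`` (mm).

    The reference view carries the UV-green fluorescence frame.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if intr is None:
        intr = default_intrinsics(scene)
    _check_frustum(scene, intr, baseline)
    va = _render_one(scene, intr, 0.0, baseline, 0, with_uv=True)
    vb = _render_one(scene, intr, baseline, baseline, 1, with_uv=False)
    return va, vb


def render_sequence(scene: SyntheticScene, angles: Sequence[float],
                    intr: CameraIntrinsics | None = None,
                    turntable_radius: float = 450.0) -> list[RenderedView]:
    """Render a turntable sweep: one view per angle (degrees).

    Under the small-angle model a rotation by θ about the vertical axis at
    working radius R is a horizontal translation R·θ (radians), so view k
    gets baseline R·radians(angle_k − angle_0).  Each view carries its own
    glare realisation; only the first carries the UV frame.
    """
    if intr is None:
        intr = default_intrinsics(scene)
    views = []
    a0 = angles[0]
    baselines = [turntable_radius * np.deg2rad(a - a0) for a in angles]
    for k, b in enumerate(baselines):
        nxt = k + 1 if k + 1 < len(baselines) else k - 1
        pair_b = abs(baselines[nxt] - b) if len(baselines) > 1 else 0.0
        views.append(_render_one(scene, intr, b, pair_b, k, with_uv=(k == 0)))
    return views


def _check_frustum(scene: SyntheticScene, intr: CameraIntrinsics,
                   baseline: float) -> None:
    # the warped leaf must stay inside the frame
    max_shift = intr.fku * baseline / scene.params.depth_min
    my, mx = np.nonzero(scene.leaf_mask)
    if mx.size and mx.min() - max_shift < 0:
        raise ValueError(
            f"baseline {baseline} shifts the surface out of the frame "
            f"(max shift {max_shift:.1f}px, leaf margin {mx.min()}px)")


def true_correspondence(view_a: RenderedView, u: np.ndarray,
                        v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth position in the paired view of reference pixels (u, v)."""
    h, w = view_a.true_depth.shape
    vi = np.clip(np.rint(v).astype(int), 0, h - 1)
    ui = np.clip(np.rint(u).astype(int), 0, w - 1)
    return u - view_a.true_disparity[vi, ui], np.asarray(v, dtype=float)
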
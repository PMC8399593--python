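"""Synthetic fundus phantoms with exact neovascularization ground truth.

Real fundus photographs of proliferative diabetic retinopathy show a dark
background, a roughly circular retina, a bright optic disk, a branching
vessel tree whose contrast against the retinal background is strongest in
the green channel, and — in PDR — localized tangles of fine, tortuous new
vessels (neovascularization).  This module renders cartoon phantoms with
those features plus pixel-exact binary masks, so the whole segmentation
pipeline can be exercised and tested without access to clinical images.

Everything is a pure function of ``(PhantomConfig, seed)``: identical
inputs give bit-identical rasters and files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
from PIL import Image

__all__ = [
    "PhantomConfig",
    "FundusImage",
    "LabelMask",
    "VesselSegment",
    "grow_vessel_tree",
    "render_phantom",
    "emit_dataset",
    "NEO",
    "NOT_NEO",
]

# Mask label values (8-bit PNG convention: 0 = NotNeo, 255 = Neo).
NOT_NEO = 0
NEO = 255


class PhantomConfigError(ValueError):
    """Raised when a PhantomConfig violates its invariants."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one rendered phantom.

    Defaults target a desk-scale raster of 400 x 592 pixels: one fifth of a
    2000 x 2368 cropped clinical fundus image along the vertical axis and
    2368/4 = 592 along the horizontal, chosen so that both the network's
    8-fold downsampling path and a 5 x 2 patch grid (80 x 296 patches, the
    1/5-scaled analogue of 400 x 1184) apply without remainders.
    """

    image_height: int = 400
    image_width: int = 592
    n_lesions: int = 2
    vessel_branching_depth: int = 5
    vessel_base_width: int = 4
    lesion_radius_range: tuple[float, float] = (12.0, 28.0)
    lesion_vessel_count: int = 8
    background_level: int = 10
    noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 64 or self.image_width < 64:
            raise PhantomConfigError("image dimensions must be >= 64 pixels")
        if self.n_lesions < 0:
            raise PhantomConfigError("n_lesions must be >= 0")
        if self.vessel_branching_depth < 1:
            raise PhantomConfigError("vessel_branching_depth must be >= 1")
        if self.vessel_base_width < 1:
            raise PhantomConfigError("vessel_base_width must be >= 1 pixel")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise PhantomConfigError("lesion_radius_range must satisfy 0 < lo <= hi")
        fov_radius = 0.48 * min(self.image_height, self.image_width)
        if hi > fov_radius / 2:
            raise PhantomConfigError(
                f"lesion radius {hi} exceeds half the field-of-view radius "
                f"({fov_radius / 2:.1f})"
            )
        if not (0 <= self.background_level <= 255):
            raise PhantomConfigError("background_level must be in [0, 255]")
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class FundusImage:
    """RGB fundus raster, channel order red, green, blue, intensities 0-255."""

    pixels: np.ndarray  # (H, W, 3) uint8

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("FundusImage requires an (H, W, 3) raster")
        if self.pixels.dtype != np.uint8:
            raise ValueError("FundusImage pixels must be uint8")


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel binary class raster; values in {NOT_NEO, NEO} = {0, 255}."""

    labels: np.ndarray  # (H, W) uint8

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("LabelMask requires a single-channel raster")
        bad = ~np.isin(self.labels, (NOT_NEO, NEO))
        if bad.any():
            raise ValueError("LabelMask admits only the values {0, 255}")

    @property
    def neo(self) -> np.ndarray:
        """Boolean view: True where the pixel is Neo."""
        return self.labels == NEO


@dataclass(frozen=True)
class VesselSegment:
    """One straight-ish polyline piece of the vessel tree."""

    points: np.ndarray  # (n, 2) float, (row, col) vertices
    width: float  # stroke width in pixels, >= 1


def _fov_geometry(config: PhantomConfig) -> tuple[float, float, float]:
    cy = config.image_height / 2.0
    cx = config.image_width / 2.0
    radius = 0.48 * min(config.image_height, config.image_width)
    return cy, cx, radius


def _disk_geometry(config: PhantomConfig) -> tuple[float, float, float, float]:
    """Optic disk: bright ellipse placed on the nasal side of the retina."""
    cy, cx, r = _fov_geometry(config)
    return cy, cx + 0.55 * r, 0.16 * r, 0.13 * r  # center row/col, semi-axes


def _wiggly_polyline(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: float,
    length: float,
    n_steps: int,
    curvature_sd: float,
) -> np.ndarray:
    """Random-walk polyline: heading receives Gaussian kicks each step."""
    pts = [start.astype(float)]
    heading = direction
    step = length / n_steps
    for _ in range(n_steps):
        heading += rng.normal(0.0, curvature_sd)
        pts.append(pts[-1] + step * np.array([math.sin(heading), math.cos(heading)]))
    return np.asarray(pts)


def grow_vessel_tree(
    config: PhantomConfig,
    origin: tuple[float, float],
    rng: np.random.Generator,
) -> list[VesselSegment]:
    """Grow a recursive binary vessel tree from *origin*.

    Each branching level halves nothing and wiggles everything: a parent
    segment ends where two children start, children are narrower than the
    parent (never below 1 px) and shorter by a constant factor.  Segments
    are clipped to the image bounds when rendered; the returned polylines
    may poke past the border.

    Returns at most ``2**depth - 1`` segments (a full binary tree), fewer
    when a branch's width would drop below the 1-pixel floor.
    """
    config.validate()
    cy, cx, fov_r = _fov_geometry(config)
    oy, ox = origin
    if (oy - cy) ** 2 + (ox - cx) ** 2 > fov_r**2:
        raise PhantomConfigError("vessel origin must lie inside the retinal disk")

    segments: list[VesselSegment] = []

    def grow(start: np.ndarray, direction: float, width: float, length: float, depth: int) -> None:
        if depth < 1 or width < 1.0:
            return
        n_steps = max(4, int(length / 6))
        pts = _wiggly_polyline(rng, start, direction, length, n_steps, curvature_sd=0.12)
        segments.append(VesselSegment(points=pts, width=width))
        if depth == 1:
            return
        end = pts[-1]
        end_heading = math.atan2(pts[-1][0] - pts[-2][0], pts[-1][1] - pts[-2][1])
        spread = rng.uniform(0.35, 0.7)
        for sign in (-1.0, 1.0):
            grow(
                end,
                end_heading + sign * spread,
                width * 0.72,
                length * 0.78,
                depth - 1,
            )

    trunk_len = 0.5 * fov_r
    trunk_dir = rng.uniform(0.0, 2.0 * math.pi)
    grow(np.asarray(origin, dtype=float), trunk_dir, float(config.vessel_base_width), trunk_len, config.vessel_branching_depth)
    return segments


def _stamp_polyline(
    canvas: np.ndarray, pts: np.ndarray, width: float, value: float
) -> np.ndarray:
    """Set pixels within width/2 of the polyline to True on a boolean canvas.

    Dense sampling along each edge + disk stamping keeps strokes connected
    at any width >= 1.
    """
    h, w = canvas.shape
    radius = max(width / 2.0, 0.5)
    r_int = max(int(math.ceil(radius)), 1)
    # Precompute a disk footprint.
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    disk = (yy**2 + xx**2) <= radius**2
    dyy, dxx = np.nonzero(disk)
    dyy = dyy - r_int
    dxx = dxx - r_int
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(int(np.hypot(*(b - a)) * 2), 1)
        t = np.linspace(0.0, 1.0, n + 1)
        samples = a[None, :] + t[:, None] * (b - a)[None, :]
        rows = np.round(samples[:, 0]).astype(int)
        cols = np.round(samples[:, 1]).astype(int)
        rows = (rows[:, None] + dyy[None, :]).ravel()
        cols = (cols[:, None] + dxx[None, :]).ravel()
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        canvas[rows[ok], cols[ok]] = value
    return canvas


def _lesion_strokes(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    n_strokes: int,
) -> list[tuple[np.ndarray, float]]:
    """Tangle of thin, highly tortuous strokes radiating from the center.

    All strokes start at the lesion center, so their union is one connected
    region; each wanders with strong curvature and is clipped to the disk.
    """
    strokes = []
    for _ in range(n_strokes):
        direction = rng.uniform(0.0, 2.0 * math.pi)
        length = rng.uniform(1.5, 2.8) * radius
        pts = _wiggly_polyline(rng, center, direction, length, n_steps=24, curvature_sd=0.55)
        # Confine to the lesion disk by radial clamping.
        offsets = pts - center[None, :]
        dist = np.hypot(offsets[:, 0], offsets[:, 1])
        over = dist > radius
        scale = np.ones_like(dist)
        scale[over] = radius / dist[over]
        pts = center[None, :] + offsets * scale[:, None]
        width = rng.uniform(1.0, 2.0)
        strokes.append((pts, width))
    return strokes


# Retinal palette (R, G, B). Vessels are darker than the retina with the
# largest drop in the green channel, mirroring the green-channel contrast
# of real fundus photographs.
_RETINA_RGB = (168.0, 96.0, 58.0)
_VESSEL_RGB = (138.0, 34.0, 40.0)
_DISK_RGB = (236.0, 214.0, 168.0)


def render_phantom(config: PhantomConfig) -> tuple[FundusImage, LabelMask]:
    """Render one phantom and its exact ground-truth mask.

    The mask marks exactly the lesion stroke pixels as Neo; the normal
    vessel tree, optic disk, and background are NotNeo.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height, config.image_width
    cy, cx, fov_r = _fov_geometry(config)

    rows, cols = np.mgrid[0:h, 0:w]
    in_fov = (rows - cy) ** 2 + (cols - cx) ** 2 <= fov_r**2

    img = np.empty((h, w, 3), dtype=float)
    for c in range(3):
        img[:, :, c] = config.background_level
    # Retina with a gentle radial falloff toward the rim.
    dist = np.sqrt((rows - cy) ** 2 + (cols - cx) ** 2) / fov_r
    shade = 1.0 - 0.25 * dist**2
    for c in range(3):
        img[:, :, c][in_fov] = _RETINA_RGB[c] * shade[in_fov]

    # Optic disk.
    dcy, dcx, a, b = _disk_geometry(config)
    in_disk = ((rows - dcy) / a) ** 2 + ((cols - dcx) / b) ** 2 <= 1.0
    in_disk &= in_fov
    for c in range(3):
        img[:, :, c][in_disk] = _DISK_RGB[c]

    # Normal vessel tree rooted at the optic disk edge.
    vessel_canvas = np.zeros((h, w), dtype=bool)
    n_trunks = 3
    for _ in range(n_trunks):
        ang = rng.uniform(0.0, 2.0 * math.pi)
        origin = (dcy + 0.8 * a * math.sin(ang), dcx + 0.8 * b * math.cos(ang))
        if (origin[0] - cy) ** 2 + (origin[1] - cx) ** 2 > fov_r**2:
            origin = (cy, cx)
        for seg in grow_vessel_tree(config, origin, rng):
            _stamp_polyline(vessel_canvas, seg.points, seg.width, True)
    vessel_canvas &= in_fov
    for c in range(3):
        img[:, :, c][vessel_canvas] = _VESSEL_RGB[c]

    # Neovascular lesions: tangles of thin tortuous strokes, off the optic
    # disk, pairwise non-overlapping; mask = exactly the stroke pixels.
    mask = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []
    for _ in range(config.n_lesions):
        radius = rng.uniform(*config.lesion_radius_range)
        for _attempt in range(200):
            ly = rng.uniform(cy - 0.75 * fov_r, cy + 0.75 * fov_r)
            lx = rng.uniform(cx - 0.75 * fov_r, cx + 0.75 * fov_r)
            if (ly - cy) ** 2 + (lx - cx) ** 2 > (0.8 * fov_r - radius) ** 2:
                continue
            # keep clear of the optic disk
            if ((ly - dcy) / (a + radius)) ** 2 + ((lx - dcx) / (b + radius)) ** 2 <= 1.0:
                continue
            # non-overlap with previously placed lesions (small margin)
            if any(
                np.hypot(ly - py, lx - px) < radius + pr + 4 for py, px, pr in placed
            ):
                continue
            placed.append((ly, lx, radius))
            break
        else:
            raise PhantomConfigError(
                "could not place all lesions without overlap; reduce n_lesions "
                "or lesion radii"
            )
        lesion_canvas = np.zeros((h, w), dtype=bool)
        for pts, width in _lesion_strokes(
            rng, np.array([ly, lx]), radius, config.lesion_vessel_count
        ):
            _stamp_polyline(lesion_canvas, pts, width, True)
        mask |= lesion_canvas
        for c in range(3):
            img[:, :, c][lesion_canvas] = _VESSEL_RGB[c]

    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    labels = np.where(mask, NEO, NOT_NEO).astype(np.uint8)
    return FundusImage(pixels=img), LabelMask(labels=labels)


def emit_dataset(
    config: PhantomConfig,
    n_images: int,
    out_dir: str | Path,
) -> list[tuple[str, str, int]]:
    """Write ``n_images`` phantom image/mask PNG pairs plus a manifest.

    Per-image seeds are derived from the config seed by a fixed increment
    so any single file can be regenerated in isolation.  Returns the
    manifest as a list of ``(image_file, mask_file, seed)`` rows; the same
    rows are written tab-separated to ``manifest.tsv`` in *out_dir*.
    """
    config.validate()
    if n_images < 0:
        raise PhantomConfigError("n_images must be >= 0")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: list[tuple[str, str, int]] = []
    for i in range(n_images):
        seed_i = config.seed + i
        image, mask = render_phantom(replace(config, seed=seed_i))
        img_name = f"phantom_{i:03d}.png"
        mask_name = f"phantom_{i:03d}_mask.png"
        Image.fromarray(image.pixels).save(out / img_name)
        Image.fromarray(mask.labels).save(out / mask_name)
        manifest.append((img_name, mask_name, seed_i))

    with open(out / "manifest.tsv", "w") as fh:
        fh.write("image\tmask\tseed\n")
        for img_name, mask_name, seed_i in manifest:
            fh.write(f"{img_name}\t{mask_name}\t{seed_i}\n")
    return manifest
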
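"""Fundus image preparation: green channel, CLAHE, patching, normalization.

The enhancement chain runs in a fixed order — green-channel extraction,
contrast-limited adaptive histogram equalization (CLAHE), background crop,
non-overlapping patching, then per-patch min-max normalization.  Ground
truth masks follow only the geometric steps (crop, patch, flip); contrast
operations never touch labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

__all__ = [
    "PatchGrid",
    "DatasetSplit",
    "extract_green",
    "apply_clahe",
    "crop_background",
    "split_patches",
    "stitch_patches",
    "normalize_patch",
    "augment_flips",
    "split_dataset",
]


class GridError(ValueError):
    """A patch grid does not fit the raster it is applied to."""


@dataclass(frozen=True)
class PatchGrid:
    """Deterministic row-major tiling of a raster into equal rectangles.

    ``exact`` mode requires the raster dimensions to be integer multiples
    of the patch size and covers every pixel exactly once; ``floor`` mode
    keeps ``floor(height / patch_height) x floor(width / patch_width)``
    tiles anchored at the origin and discards the remainder strips.
    """

    patch_height: int
    patch_width: int
    mode: str = "exact"  # "exact" | "floor"

    def __post_init__(self) -> None:
        if self.patch_height < 1 or self.patch_width < 1:
            raise GridError("patch dimensions must be positive")
        if self.mode not in ("exact", "floor"):
            raise GridError(f"unknown grid mode {self.mode!r}")

    def shape_for(self, height: int, width: int) -> tuple[int, int]:
        """(n_rows, n_cols) of the tiling for a raster of the given size."""
        if self.mode == "exact":
            if height % self.patch_height or width % self.patch_width:
                raise GridError(
                    f"exact grid {self.patch_height}x{self.patch_width} does not "
                    f"divide raster {height}x{width}"
                )
        n_rows = height // self.patch_height
        n_cols = width // self.patch_width
        if n_rows < 1 or n_cols < 1:
            raise GridError("raster smaller than one patch")
        return n_rows, n_cols

    def index_to_pos(self, index: int, n_cols: int) -> tuple[int, int]:
        return divmod(index, n_cols)

    def pos_to_index(self, row: int, col: int, n_cols: int) -> int:
        return row * n_cols + col


def extract_green(image: np.ndarray) -> np.ndarray:
    """Return the green channel (index 1 of R, G, B) unmodified."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {image.shape}")
    return image[:, :, 1].copy()


def apply_clahe(
    gray: np.ndarray,
    clip_limit: float = 0.01,
    tile_rows: int = 8,
    tile_cols: int = 8,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit raster.

    ``clip_limit`` is the normalized clipping fraction in (0, 1]; the tile
    grid partitions the image into ``tile_rows x tile_cols`` contextual
    regions. Returns uint8 in [0, 255].
    """
    if gray.ndim != 2:
        raise ValueError("apply_clahe expects a single-channel raster")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    if tile_rows < 1 or tile_cols < 1:
        raise ValueError("tile counts must be positive")
    if np.ptp(gray) == 0:
        # No contrast to redistribute: CLAHE is the identity.
        return gray.astype(np.uint8, copy=True)
    h, w = gray.shape
    kernel = (max(h // tile_rows, 1), max(w // tile_cols, 1))
    out = exposure.equalize_adapthist(
        gray.astype(np.uint8), kernel_size=kernel, clip_limit=clip_limit, nbins=256
    )
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def crop_background(
    raster: np.ndarray,
    target_height: int,
    target_width: int,
    row_offset: int | None = None,
    col_offset: int | None = None,
) -> np.ndarray:
    """Cut a ``target_height x target_width`` window out of the raster.

    Offsets default to a centered window (symmetric background removal);
    e.g. a 2000 x 3008 source cropped to 2000 x 2368 uses offsets (0, 320).
    Applies identically to images and masks.
    """
    h, w = raster.shape[:2]
    if row_offset is None:
        row_offset = (h - target_height) // 2
    if col_offset is None:
        col_offset = (w - target_width) // 2
    if row_offset < 0 or col_offset < 0:
        raise ValueError("offsets must be non-negative")
    if row_offset + target_height > h or col_offset + target_width > w:
        raise ValueError(
            f"crop window {target_height}x{target_width}+({row_offset},{col_offset}) "
            f"exceeds source {h}x{w}"
        )
    return raster[
        row_offset : row_offset + target_height,
        col_offset : col_offset + target_width,
        ...,
    ].copy()


def split_patches(raster: np.ndarray, grid: PatchGrid) -> list[np.ndarray]:
    """Tile the raster into a row-major list of non-overlapping patches."""
    n_rows, n_cols = grid.shape_for(raster.shape[0], raster.shape[1])
    ph, pw = grid.patch_height, grid.patch_width
    return [
        raster[r * ph : (r + 1) * ph, c * pw : (c + 1) * pw, ...].copy()
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def stitch_patches(
    patches: list[np.ndarray], grid: PatchGrid, n_rows: int, n_cols: int
) -> np.ndarray:
    """Reassemble row-major patches; exact inverse of :func:`split_patches`."""
    if len(patches) != n_rows * n_cols:
        raise GridError(
            f"expected {n_rows * n_cols} patches for a {n_rows}x{n_cols} grid, "
            f"got {len(patches)}"
        )
    ph, pw = grid.patch_height, grid.patch_width
    for p in patches:
        if p.shape[:2] != (ph, pw):
            raise GridError("all patches must match the grid patch size")
    rows = [
        np.concatenate(patches[r * n_cols : (r + 1) * n_cols], axis=1)
        for r in range(n_rows)
    ]
    return np.concatenate(rows, axis=0)


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Linear min-max rescale of one patch to [0, 255] (round half up).

    A constant patch has no range and maps to all zeros.
    """
    if patch.size == 0:
        raise ValueError("cannot normalize an empty patch")
    lo = float(patch.min())
    hi = float(patch.max())
    if hi == lo:
        return np.zeros_like(patch, dtype=np.uint8)
    scaled = (patch.astype(float) - lo) * (255.0 / (hi - lo))
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half up


def augment_flips(
    patches: list[np.ndarray], masks: list[np.ndarray]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Triple the training set with horizontal and vertical flips.

    Output order: all originals, then all horizontal flips, then all
    vertical flips; masks receive the identical transforms.  The doubly
    flipped variant is excluded (100 inputs -> 300 outputs).
    """
    if len(patches) != len(masks):
        raise ValueError("patches and masks must be aligned lists of equal length")
    for p, m in zip(patches, masks):
        if p.shape[:2] != m.shape[:2]:
            raise ValueError("each mask must match its patch's spatial shape")
    h_flips = [p[:, ::-1, ...].copy() for p in patches]
    v_flips = [p[::-1, :, ...].copy() for p in patches]
    h_masks = [m[:, ::-1, ...].copy() for m in masks]
    v_masks = [m[::-1, :, ...].copy() for m in masks]
    return patches + h_flips + v_flips, masks + h_masks + v_masks


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive partition of item indices into train/val/test."""

    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]
    seed: int


def _largest_remainder_sizes(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Apportion n into integer parts proportional to fractions.

    Largest-remainder (Hamilton) rounding: deterministic, sums to n, and
    reproduces e.g. 200 x (0.5, 0.25, 0.25) -> (100, 50, 50).
    """
    quotas = [n * f for f in fractions]
    sizes = [int(q) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    shortfall = n - sum(sizes)
    # ties broken by position (earlier fraction wins)
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[:shortfall]:
        sizes[i] += 1
    return sizes


def split_dataset(
    n_items: int,
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
    seed: int = 0,
) -> DatasetSplit:
    """Random disjoint train/validation/test partition of ``range(n_items)``."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    n_train, n_val, n_test = _largest_remainder_sizes(n_items, fractions)
    return DatasetSplit(
        train=tuple(int(i) for i in order[:n_train]),
        validation=tuple(int(i) for i in order[n_train : n_train + n_val]),
        test=tuple(int(i) for i in order[n_train + n_val :]),
        seed=seed,
    )
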
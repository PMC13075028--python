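"""Multiband ingestion, NIR-G-B compositing, percentile stretch, tiling and
train-time augmentation.

The preprocessing chain mirrors standard ocean-colour practice for floating
algae: the red band is dropped (it amplifies turbidity signals in the Yellow
Sea study region) in favour of a (NIR, G, B) composite, each band is contrast
stretched between its 2nd and 98th percentile per scene, quantised to 8 bits,
and the scene is cut into non-overlapping 512 x 512 tiles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize as _sk_resize

from .errors import ConfigError, InputError, ShapeError

__all__ = [
    "MultibandScene", "TileSet", "Tile", "AugmentPolicy",
    "percentile_stretch", "composite", "tile", "mosaic", "filter_tiles",
    "augment", "read_scene", "write_scene", "read_mask", "write_mask",
    "write_tileset", "DEFAULT_BAND_MAP",
]

DEFAULT_BAND_MAP = {"NIR": "B4", "G": "B2", "B": "B1"}


@dataclass
class MultibandScene:
    """Named co-registered 2-D rasters plus opaque geo-metadata."""
    bands: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise ShapeError(f"bands must share one grid, got {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape


@dataclass
class Tile:
    image: np.ndarray  # (size, size, 3) uint8
    mask: np.ndarray   # (size, size) {0,1}
    row: int
    col: int


@dataclass
class TileSet:
    tiles: list[Tile]
    size: int
    stride: int
    padded_shape: tuple[int, int]
    scene_shape: tuple[int, int]


def percentile_stretch(band: np.ndarray, p_lo: float = 2.0, p_hi: float = 98.0) -> np.ndarray:
    """Clip a band to its [p_lo, p_hi] percentiles and quantise to 8 bits.

    Percentiles use linear interpolation between order statistics; values map
    linearly to [0, 255] with round-half-up. A constant band maps to zeros.
    """
    band = np.asarray(band, dtype=float)
    if band.size == 0:
        raise InputError("empty raster")
    if not np.isfinite(band).all():
        raise InputError("band contains non-finite values")
    if p_lo >= p_hi:
        raise ConfigError("p_lo must be < p_hi")
    lo, hi = np.percentile(band, [p_lo, p_hi], method="linear")
    if hi <= lo:
        return np.zeros(band.shape, dtype=np.uint8)
    scaled = (np.clip(band, lo, hi) - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def composite(scene: MultibandScene,
              band_map: dict[str, str] | None = None) -> np.ndarray:
    """Build the (NIR, G, B) 8-bit composite, each band stretched per scene."""
    band_map = dict(DEFAULT_BAND_MAP if band_map is None else band_map)
    channels = []
    for role in ("NIR", "G", "B"):
        name = band_map.get(role)
        if name is None or name not in scene.bands:
            raise ConfigError(f"band map lacks a scene band for role {role!r}")
        channels.append(percentile_stretch(scene.bands[name]))
    return np.stack(channels, axis=-1)


def tile(image: np.ndarray, mask: np.ndarray, size: int = 512,
         stride: int = 512) -> TileSet:
    """Cut an image/mask pair into aligned windows, zero-padding bottom/right.

    Windows are enumerated row-major on a grid of the given stride; the raster
    is padded so every window lies fully inside.
    """
    import warnings
    if size <= 0 or stride <= 0:
        raise ConfigError("size and stride must be positive")
    if size % 32:
        warnings.warn(f"tile size {size} is not a multiple of 32; "
                      "the model requires sides divisible by 32")
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ShapeError(f"image {image.shape[:2]} vs mask {mask.shape}")
    h, w = mask.shape
    steps_h = max(-(-max(h - size, 0) // stride), 0) + 1
    steps_w = max(-(-max(w - size, 0) // stride), 0) + 1
    hp = (steps_h - 1) * stride + size
    wp = (steps_w - 1) * stride + size
    img_p = np.zeros((hp, wp) + image.shape[2:], dtype=image.dtype)
    img_p[:h, :w] = image
    mask_p = np.zeros((hp, wp), dtype=mask.dtype)
    mask_p[:h, :w] = mask
    tiles = []
    for i in range(steps_h):
        for j in range(steps_w):
            r, c = i * stride, j * stride
            tiles.append(Tile(img_p[r:r + size, c:c + size].copy(),
                              mask_p[r:r + size, c:c + size].copy(), r, c))
    return TileSet(tiles, size, stride, (hp, wp), (h, w))


def mosaic(ts: TileSet) -> tuple[np.ndarray, np.ndarray]:
    """Re-assemble the padded scene from a non-overlapping tile set."""
    if ts.stride != ts.size:
        raise ConfigError("mosaic requires non-overlapping tiles (stride == size)")
    hp, wp = ts.padded_shape
    t0 = ts.tiles[0]
    img = np.zeros((hp, wp) + t0.image.shape[2:], dtype=t0.image.dtype)
    mask = np.zeros((hp, wp), dtype=t0.mask.dtype)
    for t in ts.tiles:
        img[t.row:t.row + ts.size, t.col:t.col + ts.size] = t.image
        mask[t.row:t.row + ts.size, t.col:t.col + ts.size] = t.mask
    return img, mask


def filter_tiles(ts: TileSet, min_fg_fraction: float = 0.0,
                 keep_bg_prob: float = 1.0,
                 rng: np.random.Generator | None = None) -> TileSet:
    """Drop low-foreground tiles, keeping a random share of background tiles."""
    rng = np.random.default_rng(0) if rng is None else rng
    kept = []
    for t in ts.tiles:
        frac = t.mask.mean()
        if frac >= min_fg_fraction:
            kept.append(t)
        elif rng.random() < keep_bg_prob:
            kept.append(t)
    return TileSet(kept, ts.size, ts.stride, ts.padded_shape, ts.scene_shape)


@dataclass(frozen=True)
class AugmentPolicy:
    """Train-only augmentation: flips, right-angle rotations, crop-rescale and
    mild multiplicative brightness/contrast jitter. No saturation jitter —
    relative spectral relationships between algae and water are preserved."""
    p_flip: float = 0.5
    rotations: tuple[int, ...] = (90, 180, 270)
    p_rotate: float = 0.5
    p_scale: float = 0.5
    crop_scale_range: tuple[float, float] = (0.75, 1.25)
    brightness_range: float = 0.10
    contrast_range: float = 0.10

    def __post_init__(self):
        for p in (self.p_flip, self.p_rotate, self.p_scale):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if any(r not in (90, 180, 270) for r in self.rotations):
            raise ConfigError("rotations must come from {90, 180, 270}")
        if self.crop_scale_range[0] > self.crop_scale_range[1]:
            raise ConfigError("crop_scale_range must be (lo, hi) with lo <= hi")


def _rescale_pair(image: np.ndarray, mask: np.ndarray, factor: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    size = mask.shape[0]
    new = max(int(round(size * factor)), 8)
    if new == size:
        return image, mask
    img_r = _sk_resize(image, (new, new), order=1, preserve_range=True,
                       anti_aliasing=False)
    mask_r = _sk_resize(mask.astype(float), (new, new), order=0,
                        preserve_range=True, anti_aliasing=False)
    if new > size:  # random crop back
        r = int(rng.integers(0, new - size + 1))
        c = int(rng.integers(0, new - size + 1))
        img_o = img_r[r:r + size, c:c + size]
        mask_o = mask_r[r:r + size, c:c + size]
    else:  # pad back with background, random placement
        r = int(rng.integers(0, size - new + 1))
        c = int(rng.integers(0, size - new + 1))
        img_o = np.zeros((size, size) + image.shape[2:], dtype=float)
        mask_o = np.zeros((size, size), dtype=float)
        img_o[r:r + new, c:c + new] = img_r
        mask_o[r:r + new, c:c + new] = mask_r
    img_o = np.clip(np.floor(img_o + 0.5), 0, 255).astype(np.uint8)
    return img_o, (mask_o > 0.5).astype(np.uint8)


def augment(image: np.ndarray, mask: np.ndarray, policy: AugmentPolicy,
            rng: np.random.Generator, phase: str = "train") -> tuple[np.ndarray, np.ndarray]:
    """Apply one random augmentation draw to an aligned image/mask pair.

    Geometric operations hit image and mask identically; photometric jitter
    touches the image only and the mask stays binary. Augmentation is a
    training-phase operation; requesting it for val/test raises.
    """
    if phase != "train":
        raise ConfigError("augmentation is applied to the training phase only")
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ShapeError("image and mask grids differ")
    # horizontal / vertical flips, independent coin each
    if rng.random() < policy.p_flip:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if rng.random() < policy.p_flip:
        image, mask = image[::-1], mask[::-1]
    # one right-angle rotation
    if policy.rotations and rng.random() < policy.p_rotate:
        deg = policy.rotations[int(rng.integers(0, len(policy.rotations)))]
        k = deg // 90
        image, mask = np.rot90(image, k), np.rot90(mask, k)
    image, mask = np.ascontiguousarray(image), np.ascontiguousarray(mask)
    # crop / scale perturbation
    if rng.random() < policy.p_scale:
        factor = rng.uniform(*policy.crop_scale_range)
        image, mask = _rescale_pair(image, mask, factor, rng)
    # photometric jitter (image only)
    img_f = image.astype(float)
    if policy.brightness_range > 0:
        b = rng.uniform(1.0 - policy.brightness_range, 1.0 + policy.brightness_range)
        img_f = img_f * b
    if policy.contrast_range > 0:
        c = rng.uniform(1.0 - policy.contrast_range, 1.0 + policy.contrast_range)
        mean = img_f.mean()
        img_f = (img_f - mean) * c + mean
    image = np.clip(np.floor(img_f + 0.5), 0, 255).astype(np.uint8)
    return image, mask.astype(np.uint8)


# ----------------------------------------------------------------------- I/O
def read_scene(path: str, band_names: list[str] | None = None) -> MultibandScene:
    """Read a multiband TIFF scene; bands become B1..Bn unless named."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3 and arr.shape[0] > arr.shape[2]:
        arr = arr.transpose(2, 0, 1)  # HWC on disk -> band-first
    names = band_names or [f"B{i + 1}" for i in range(arr.shape[0])]
    return MultibandScene({n: arr[i].astype(float) for i, n in enumerate(names)},
                          meta={"path": path})


def write_scene(path: str, scene: MultibandScene) -> None:
    stack = np.stack([scene.bands[k] for k in scene.bands], axis=0).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_mask(path: str) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def write_mask(path: str, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) * 255).astype(np.uint8))


def write_tileset(out_dir: str, ts: TileSet, scene_id: str) -> pd.DataFrame:
    """Write PNG tiles + masks and return the manifest rows."""
    img_dir = os.path.join(out_dir, "images")
    mask_dir = os.path.join(out_dir, "masks")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(mask_dir, exist_ok=True)
    rows = []
    for t in ts.tiles:
        tid = f"{scene_id}_r{t.row}_c{t.col}"
        iio.imwrite(os.path.join(img_dir, tid + ".png"), t.image)
        write_mask(os.path.join(mask_dir, tid + ".png"), t.mask)
        rows.append({"tile_id": tid, "scene_id": scene_id, "row": t.row,
                     "col": t.col, "fg_fraction": float(t.mask.mean())})
    return pd.DataFrame(rows)
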
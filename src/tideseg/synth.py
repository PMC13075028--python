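"""Seed-deterministic synthetic green-tide scenes with ground-truth masks.

The generator emulates the statistical structure of coastal-zone multispectral
imagery of floating *Ulva prolifera*: a dark near-infrared water background
(water absorbs NIR strongly), algal patches with elevated NIR reflectance
shaped either as curved filaments (random-walk splines of varying thickness)
or as small elliptical fragments, weaker correlated green/blue signal, a
turbidity-like blotch field injected into the red band (the reason the red
band is excluded from the model composite), a smooth sea-surface ripple field
and additive Gaussian sensor noise. Shapes are rendered without anti-aliasing
so the mask is exactly the set of rendered pixels.

Four bands are produced (B1=blue, B2=green, B3=red, B4=NIR) so the band
selection step of the preprocessing pipeline is exercised; the composite uses
channels 4, 2, 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as _draw_disk, ellipse as _draw_ellipse

from . import pipeline
from .errors import ConfigError
from .pipeline import MultibandScene

__all__ = [
    "SceneParams", "SyntheticScene", "generate_scene", "generate_dataset",
    "generate_tile_splits", "difficulty_presets", "boundary_contrast",
]


@dataclass(frozen=True)
class SceneParams:
    side: int = 512
    n_filaments: int = 6
    n_fragments: int = 40
    filament_length_range: tuple[int, int] = (60, 220)
    fragment_radius_range: tuple[float, float] = (1.0, 4.0)
    nir_water_mean: float = 0.02
    nir_algae_mean: float = 0.18
    contrast: float = 1.0
    noise_sd: float = 0.010
    ripple_amp: float = 0.008
    seed: int = 0

    def __post_init__(self):
        if self.side % 32:
            raise ConfigError("side must be divisible by 32")
        if self.contrast > 0 and self.nir_algae_mean <= self.nir_water_mean:
            raise ConfigError("algae must out-reflect water in NIR")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        for lo, hi in (self.filament_length_range, self.fragment_radius_range):
            if lo > hi:
                raise ConfigError("range minimum exceeds maximum")


@dataclass
class SyntheticScene:
    scene: MultibandScene
    mask: np.ndarray  # (side, side) {0,1}


def _smooth_field(rng: np.random.Generator, side: int, sigma: float) -> np.ndarray:
    """Unit-variance smooth random field (band-limited sea-surface texture)."""
    f = ndimage.gaussian_filter(rng.standard_normal((side, side)), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _render_filament(mask: np.ndarray, rng: np.random.Generator,
                     length_range: tuple[int, int]) -> None:
    side = mask.shape[0]
    n_steps = int(rng.integers(length_range[0], length_range[1] + 1))
    r, c = rng.uniform(0, side, size=2)
    heading = rng.uniform(0, 2 * np.pi)
    thickness = rng.uniform(1.0, 2.5)
    for _ in range(n_steps):
        heading += rng.normal(0, 0.25)          # curvature noise
        r += np.sin(heading)
        c += np.cos(heading)
        if not (0 <= r < side and 0 <= c < side):
            break
        rad = max(thickness + rng.normal(0, 0.3), 0.8)
        rr, cc = _draw_disk((r, c), rad, shape=mask.shape)
        mask[rr, cc] = 1


def _render_fragment(mask: np.ndarray, rng: np.random.Generator,
                     radius_range: tuple[float, float]) -> None:
    side = mask.shape[0]
    r, c = rng.uniform(0, side, size=2)
    a = rng.uniform(*radius_range)
    b = rng.uniform(*radius_range)
    rot = rng.uniform(0, np.pi)
    rr, cc = _draw_ellipse(r, c, max(a, 0.8), max(b, 0.8), shape=mask.shape,
                           rotation=rot)
    mask[rr, cc] = 1


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render one scene; fully determined by ``params`` (incl. its seed)."""
    rng = np.random.default_rng(params.seed)
    side = params.side
    mask = np.zeros((side, side), dtype=np.uint8)
    for _ in range(params.n_filaments):
        _render_filament(mask, rng, params.filament_length_range)
    for _ in range(params.n_fragments):
        _render_fragment(mask, rng, params.fragment_radius_range)

    sep = params.contrast * (params.nir_algae_mean - params.nir_water_mean)
    ripple = _smooth_field(rng, side, sigma=max(side / 32, 2)) * params.ripple_amp
    turbidity = _smooth_field(rng, side, sigma=max(side / 16, 4)) * 0.02
    m = mask.astype(bool)
    # per-pixel algal reflectance variability
    gain = np.ones((side, side))
    gain[m] = rng.uniform(0.85, 1.15, size=int(m.sum()))

    def band(water_mean: float, ripple_scale: float, algae_frac: float,
             extra: np.ndarray | None = None) -> np.ndarray:
        out = np.full((side, side), water_mean, dtype=float)
        out += ripple * ripple_scale
        if extra is not None:
            out += extra
        out += rng.normal(0, params.noise_sd, size=(side, side))
        out[m] += algae_frac * sep * gain[m]
        return np.clip(out, 0.0, 1.0)

    bands = {
        "B1": band(0.07, 0.6, 0.20),                    # blue
        "B2": band(0.06, 0.8, 0.35),                    # green
        "B3": band(0.05, 0.7, 0.30, extra=turbidity),   # red, turbidity-noisy
        "B4": band(params.nir_water_mean, 1.0, 1.00),   # NIR, main separation
    }
    return SyntheticScene(MultibandScene(bands, meta={"params": asdict(params)}),
                          mask)


def boundary_contrast(ss: SyntheticScene) -> float:
    """Mean NIR step across the mask boundary (inner ring vs outer ring)."""
    m = ss.mask.astype(bool)
    if not m.any() or m.all():
        return 0.0
    se = np.ones((3, 3), dtype=bool)
    inner = m & ~ndimage.binary_erosion(m, se, border_value=0)
    outer = ndimage.binary_dilation(m, se, border_value=0) & ~m
    nir = ss.scene.bands["B4"]
    return float(abs(nir[inner].mean() - nir[outer].mean()))


def difficulty_presets() -> dict[str, SceneParams]:
    """Named generator conditions spanning easy to hard boundary contrast."""
    default = SceneParams()
    return {
        "easy": replace(default, contrast=1.5, noise_sd=0.004, ripple_amp=0.004,
                        n_fragments=25),
        "default": default,
        "hard": replace(default, contrast=0.35, noise_sd=0.030, ripple_amp=0.012,
                        n_fragments=80, fragment_radius_range=(1.0, 2.5)),
        "smoke": replace(default, side=64, n_filaments=2, n_fragments=6,
                         filament_length_range=(10, 30), contrast=1.5,
                         noise_sd=0.004, ripple_amp=0.004),
    }


def _split_counts(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n scenes over split fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("split fractions must sum to 1")
    base = [int(np.floor(f * n)) for f in fractions]
    rem = n - sum(base)
    order = np.argsort([-(f * n - b) for f, b in zip(fractions, base)], kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return base


def _scene_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def generate_tile_splits(n_scenes: int, params: SceneParams,
                         split: tuple[float, float, float] = (0.7, 0.2, 0.1),
                         master_seed: int = 0,
                         tile_size: int | None = None,
                         band_map: dict[str, str] | None = None,
                         min_fg_fraction: float = 0.0,
                         keep_bg_prob: float = 1.0,
                         ) -> dict[str, list[tuple[np.ndarray, np.ndarray]]]:
    """In-memory dataset: scenes -> composites -> tiles, split BY SCENE.

    Returns {"train": [(image, mask), ...], "val": ..., "test": ...}. Scene
    seeds are spawned from the master seed, so the whole dataset is a pure
    function of (params, master_seed).
    """
    names = ("train", "val", "test")
    nonzero = sum(1 for f in split if f > 0)
    if n_scenes < nonzero:
        raise ConfigError(f"need at least {nonzero} scenes for {nonzero} splits")
    counts = _split_counts(n_scenes, split)
    tile_size = tile_size or params.side
    seeds = _scene_seeds(master_seed, n_scenes)
    filter_rng = np.random.default_rng(np.random.SeedSequence([master_seed, 1]))
    out: dict[str, list] = {n: [] for n in names}
    assignment = [name for name, cnt in zip(names, counts) for _ in range(cnt)]
    for scene_idx, (seed, split_name) in enumerate(zip(seeds, assignment)):
        ss = generate_scene(replace(params, seed=seed))
        comp = pipeline.composite(ss.scene, band_map)
        ts = pipeline.tile(comp, ss.mask, size=tile_size, stride=tile_size)
        if min_fg_fraction > 0 or keep_bg_prob < 1:
            ts = pipeline.filter_tiles(ts, min_fg_fraction, keep_bg_prob, filter_rng)
        out[split_name].extend((t.image, t.mask) for t in ts.tiles)
    return out


def generate_dataset(n_scenes: int, params: SceneParams, out_dir: str,
                     split: tuple[float, float, float] = (0.7, 0.2, 0.1),
                     master_seed: int = 0,
                     tile_size: int | None = None,
                     band_map: dict[str, str] | None = None,
                     write_scenes: bool = True) -> pd.DataFrame:
    """Generate scenes, preprocess, tile and write a train/val/test layout.

    Split assignment is by scene (never by tile) so tiles of one scene cannot
    leak across splits. Returns the manifest (also written as CSV).
    """
    names = ("train", "val", "test")
    nonzero = sum(1 for f in split if f > 0)
    if n_scenes < nonzero:
        raise ConfigError(f"need at least {nonzero} scenes for {nonzero} splits")
    counts = _split_counts(n_scenes, split)
    tile_size = tile_size or params.side
    seeds = _scene_seeds(master_seed, n_scenes)
    assignment = [name for name, cnt in zip(names, counts) for _ in range(cnt)]
    frames = []
    for idx, (seed, split_name) in enumerate(zip(seeds, assignment)):
        scene_id = f"scene{idx:04d}"
        ss = generate_scene(replace(params, seed=seed))
        if write_scenes:
            os.makedirs(os.path.join(out_dir, "scenes"), exist_ok=True)
            pipeline.write_scene(os.path.join(out_dir, "scenes", scene_id + ".tif"),
                                 ss.scene)
        comp = pipeline.composite(ss.scene, band_map)
        ts = pipeline.tile(comp, ss.mask, size=tile_size, stride=tile_size)
        mf = pipeline.write_tileset(os.path.join(out_dir, split_name), ts, scene_id)
        mf.insert(1, "split", split_name)
        mf.insert(2, "scene_seed", seed)
        frames.append(mf)
    manifest = pd.concat(frames, ignore_index=True)
    os.makedirs(out_dir, exist_ok=True)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
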
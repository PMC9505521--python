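"""Synthetic pre-sowing cotton-field scenes with exact film masks.

Real imagery of ploughed cotton fields shows brown textured soil littered
with straw, clods, and bright, irregularly shaped polyethylene film
fragments.  This module renders such scenes procedurally, with the two
degradation axes of a UAV survey built in:

* **flight height** — ground sampling distance grows with height, so
  fragment pixel areas shrink by (5 m / height)^2 relative to the 5 m
  reference, and the whole frame is blurred with sigma = 0.4 * (height/5);
* **weather** — sunny scenes get higher global contrast and near-white
  specular highlights on soil clods, the classic false-positive confuser;
  cloudy scenes are flatly lit.

Every scene carries a pixel-exact ground-truth mask (film = 1), so the
generator doubles as an oracle for the whole downstream pipeline.  All
randomness flows from a single integer seed; identical (config, seed)
yields bit-identical rasters and manifests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, zoom
from skimage.draw import ellipse, line, polygon

from rfilm.dataio import BinaryMask, FieldImage, save_pair, split_dataset

__all__ = [
    "SceneConfig",
    "Scene",
    "GenerationError",
    "make_background",
    "sample_fragments",
    "render_scene",
    "generate_dataset",
    "easy_config",
]

# background texture amplitudes (8-bit intensity units)
_LOWFREQ_AMP = 12.0
_NOISE_SIGMA = 5.0
_SUNNY_CONTRAST = 1.25
_HIGHLIGHT_RANGE = (235, 255)
_STRAW_TONE = (205, 185, 110)  # dry straw: bright yellow-brown


class GenerationError(RuntimeError):
    """Raised when a scene cannot satisfy its target coverage."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    ``fragment_area_px_range`` bounds log-uniform fragment areas at the 5 m
    reference height; at other heights areas scale by (5/height)^2.
    ``target_coverage_pct``, when set, drives an add/remove search until
    realised coverage is within +-0.5 percentage points.
    """

    image_height_px: int = 256
    image_width_px: int = 256
    weather: str = "cloudy"
    height_m: float = 5.0
    fragment_count_mean: float = 8.0
    fragment_area_px_range: tuple[int, int] = (40, 4000)
    film_brightness_range: tuple[float, float] = (190.0, 255.0)
    film_alpha_range: tuple[float, float] = (0.55, 0.95)
    target_coverage_pct: float | None = None
    soil_palette: tuple[tuple[int, int, int], ...] = ((120, 92, 66), (138, 108, 78), (104, 80, 58))
    straw_density: float = 30.0
    clod_density: float = 20.0
    drip_belts: int = 0
    blur_sigma_at_5m: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.weather not in ("sunny", "cloudy"):
            raise ValueError(f"weather must be 'sunny' or 'cloudy', got {self.weather!r}")
        if self.height_m <= 0:
            raise ValueError("height_m must be positive")
        if self.fragment_count_mean < 0:
            raise ValueError("fragment_count_mean must be >= 0")
        lo, hi = self.fragment_area_px_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("fragment_area_px_range must be ordered positive bounds")
        if self.target_coverage_pct is not None and not 0 <= self.target_coverage_pct <= 100:
            raise ValueError("target_coverage_pct must lie in [0, 100]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image_height_px, self.image_width_px


@dataclass
class Scene:
    image: FieldImage
    mask: BinaryMask
    realized_coverage_pct: float
    config_used: SceneConfig


def _area_count(density: float, shape: tuple[int, int], rng: np.random.Generator) -> int:
    """Poisson count of features at `density` per 256x256 tile."""
    lam = density * shape[0] * shape[1] / 256.0**2
    return int(rng.poisson(lam))


def make_background(config: SceneConfig, rng: np.random.Generator) -> FieldImage:
    """Render the soil background: tonal drift, grain, straw, clods.

    Under sunny weather a subset of clods receives a near-white specular
    highlight and global contrast is stretched; cloudy lighting is flat.
    """
    h, w = config.shape
    base = np.array(config.soil_palette, dtype=float).mean(axis=0)

    # low-frequency tonal drift: coarse random grid upsampled to full frame
    coarse = rng.normal(0.0, 1.0, size=(max(h // 64, 2), max(w // 64, 2)))
    lowfreq = zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1, grid_mode=True, mode="nearest")
    lowfreq = _LOWFREQ_AMP * lowfreq[:h, :w]

    img = np.empty((h, w, 3), dtype=float)
    for c in range(3):
        img[..., c] = base[c] + lowfreq + rng.normal(0.0, _NOISE_SIGMA, size=(h, w))

    # straw: short bright line segments
    for _ in range(_area_count(config.straw_density, config.shape, rng)):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        length = rng.integers(6, 25)
        angle = rng.uniform(0, np.pi)
        r1 = int(np.clip(r0 + length * np.sin(angle), 0, h - 1))
        c1 = int(np.clip(c0 + length * np.cos(angle), 0, w - 1))
        rr, cc = line(int(r0), int(c0), r1, c1)
        jitter = rng.uniform(0.85, 1.1)
        img[rr, cc] = np.array(_STRAW_TONE) * jitter

    # clods: elliptical patches darker or lighter than the soil
    clod_centres = []
    for _ in range(_area_count(config.clod_density, config.shape, rng)):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        ra, rb = rng.integers(3, 12), rng.integers(3, 12)
        rr, cc = ellipse(r0, c0, ra, rb, shape=(h, w))
        shade = rng.uniform(0.65, 1.2)
        img[rr, cc] *= shade
        clod_centres.append((int(r0), int(c0), int(min(ra, rb))))

    if config.weather == "sunny":
        mean = img.mean()
        img = mean + _SUNNY_CONTRAST * (img - mean)
        # specular glints on roughly half of the clods
        for r0, c0, radius in clod_centres:
            if rng.random() < 0.5:
                rr, cc = ellipse(r0, c0, max(radius // 2, 1), max(radius // 2, 1), shape=(h, w))
                img[rr, cc] = rng.uniform(*_HIGHLIGHT_RANGE)

    for _ in range(config.drip_belts):
        c0 = int(rng.integers(0, w))
        width = int(rng.integers(2, 5))
        img[:, c0 : min(c0 + width, w)] *= 0.45

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return FieldImage(pixels, weather=config.weather, height_m=config.height_m)


def _fragment_polygon(
    rng: np.random.Generator, area_px: float, shape: tuple[int, int]
) -> np.ndarray:
    """One irregular film fragment: a radially perturbed ellipse, scaled to
    the requested polygon area, centred uniformly over the frame."""
    n_vert = int(rng.integers(8, 16))
    theta = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
    aspect = rng.uniform(0.3, 1.0)
    wobble = 1.0 + rng.uniform(-0.35, 0.35, size=n_vert)
    r = wobble
    y = r * np.sin(theta) * aspect
    x = r * np.cos(theta)
    rot = rng.uniform(0, np.pi)
    xr = x * np.cos(rot) - y * np.sin(rot)
    yr = x * np.sin(rot) + y * np.cos(rot)
    # shoelace area of the unit-scale polygon, then scale exactly
    raw_area = 0.5 * abs(np.dot(xr, np.roll(yr, 1)) - np.dot(yr, np.roll(xr, 1)))
    scale = np.sqrt(area_px / max(raw_area, 1e-9))
    cy = rng.uniform(0, shape[0])
    cx = rng.uniform(0, shape[1])
    return np.column_stack([cy + yr * scale, cx + xr * scale])


def sample_fragments(config: SceneConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Sample film-fragment polygons as (n_vertices, 2) row/col arrays.

    The fragment count is Poisson(``fragment_count_mean``); areas are
    log-uniform within ``fragment_area_px_range`` at the 5 m reference and
    scale by (5 / height_m)^2.  Polygons may overlap and may extend past
    the frame (they are clipped at rasterisation).
    """
    lo, hi = config.fragment_area_px_range
    n = int(rng.poisson(config.fragment_count_mean))
    gsd_scale = (5.0 / config.height_m) ** 2
    frags = []
    for _ in range(n):
        area5 = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        frags.append(_fragment_polygon(rng, area5 * gsd_scale, config.shape))
    return frags


def _rasterize(frag: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return polygon(frag[:, 0], frag[:, 1], shape=shape)


def _coverage_pct(mask: np.ndarray) -> float:
    return 100.0 * np.count_nonzero(mask) / mask.size


def _paint_fragments(
    img: np.ndarray,
    mask: np.ndarray,
    frags: list[np.ndarray],
    config: SceneConfig,
    rng: np.random.Generator,
) -> None:
    """Composite fragments onto img (float HxWx3) and or them into mask."""
    for frag in frags:
        rr, cc = _rasterize(frag, config.shape)
        if rr.size == 0:
            continue
        mask[rr, cc] = 1
        tone = rng.uniform(*config.film_brightness_range)
        alpha = rng.uniform(*config.film_alpha_range)
        film = tone + rng.normal(0, 4.0, size=(rr.size, 1))
        img[rr, cc] = alpha * film + (1 - alpha) * img[rr, cc]
        # a specular streak along the fragment: crumpled film catches light
        if rr.size > 12:
            k = max(rr.size // 6, 2)
            idx = rng.choice(rr.size, size=k, replace=False)
            img[rr[idx], cc[idx]] = np.minimum(film[idx] + 25.0, 255.0)


def render_scene(config: SceneConfig) -> Scene:
    """Render a full scene: background, fragments, blur, exact mask.

    With ``target_coverage_pct`` set, fragments are added or removed (at
    most 200 attempts) until realised coverage is within +-0.5 percentage
    points of the target; failure raises :class:`GenerationError` naming
    the closest achieved value.
    """
    rng = np.random.default_rng(config.seed)
    background = make_background(config, rng)
    h, w = config.shape
    total_px = h * w

    if config.target_coverage_pct is None:
        frags = sample_fragments(config, rng)
    else:
        frags = [] if config.target_coverage_pct == 0 else sample_fragments(config, rng)
        frags = _search_target_coverage(frags, config, rng, total_px)

    img = background.pixels.astype(float)
    mask = np.zeros((h, w), dtype=np.uint8)
    _paint_fragments(img, mask, frags, config, rng)

    sigma = config.blur_sigma_at_5m * (config.height_m / 5.0)
    if sigma > 0:
        img = gaussian_filter(img, sigma=(sigma, sigma, 0))

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    image = FieldImage(pixels, weather=config.weather, height_m=config.height_m)
    return Scene(image, BinaryMask(mask), _coverage_pct(mask), config)


def _search_target_coverage(
    frags: list[np.ndarray],
    config: SceneConfig,
    rng: np.random.Generator,
    total_px: int,
) -> list[np.ndarray]:
    target = config.target_coverage_pct
    gsd_scale = (5.0 / config.height_m) ** 2
    lo, hi = config.fragment_area_px_range

    def coverage(fr: list[np.ndarray]) -> float:
        m = np.zeros(config.shape, dtype=np.uint8)
        for f in fr:
            rr, cc = _rasterize(f, config.shape)
            m[rr, cc] = 1
        return _coverage_pct(m)

    cov = coverage(frags)
    best = cov
    for _ in range(200):
        if abs(cov - target) <= 0.5:
            return frags
        if cov < target:
            deficit_px = (target - cov) / 100.0 * total_px
            # aim at the deficit but respect the configured size distribution
            area = float(np.clip(deficit_px * rng.uniform(0.5, 1.0), lo * gsd_scale, hi * gsd_scale))
            frags = frags + [_fragment_polygon(rng, area, config.shape)]
        else:
            drop = int(rng.integers(0, len(frags)))
            frags = frags[:drop] + frags[drop + 1 :]
        cov = coverage(frags)
        if abs(cov - target) < abs(best - target):
            best = cov
    raise GenerationError(
        f"could not reach target coverage {target}% within 200 attempts "
        f"(closest achieved: {best:.3f}%)"
    )


def easy_config(**overrides) -> SceneConfig:
    """A high-contrast preset for smoke experiments: bright, fairly opaque
    film over default soil, so segmentation is learnable quickly."""
    base = dict(
        film_brightness_range=(235.0, 255.0),
        film_alpha_range=(0.85, 1.0),
    )
    base.update(overrides)
    return SceneConfig(**base)


def generate_dataset(
    n_images: int,
    base_config: SceneConfig,
    out_dir: str | Path,
    seed: int = 0,
    heights: tuple[float, ...] = (5.0, 7.0, 9.0),
    weathers: tuple[str, ...] = ("sunny", "cloudy"),
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> Path:
    """Write ``n_images`` image/mask pairs plus a manifest CSV.

    Weather and height are assigned in a balanced grid (cycling through the
    weather x height cells), splits follow :func:`rfilm.dataio.split_dataset`,
    and everything is reproducible from ``seed``.  Returns the manifest
    path.  Layout: ``out_dir/images/*.png``, ``out_dir/masks/*.png``,
    ``out_dir/manifest.csv``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    cells = [(wth, hgt) for wth in weathers for hgt in heights]
    child_seeds = np.random.SeedSequence(seed).generate_state(n_images) % (2**31)

    names = [f"scene_{i:05d}.png" for i in range(n_images)]
    splits = split_dataset(names, ratios=split_ratios, seed=seed)
    split_of = {name: "train" for name in splits.train}
    split_of.update({name: "validation" for name in splits.validation})
    split_of.update({name: "test" for name in splits.test})

    rows = []
    for i, name in enumerate(names):
        weather, height = cells[i % len(cells)]
        cfg = replace(
            base_config, weather=weather, height_m=height, seed=int(child_seeds[i])
        )
        scene = render_scene(cfg)
        save_pair(scene.image, scene.mask, out_dir / "images" / name, out_dir / "masks" / name)
        rows.append(
            {
                "filename": name,
                "split": split_of[name],
                "weather": weather,
                "height_m": f"{height:g}",
                "true_coverage_pct": f"{scene.realized_coverage_pct:.6f}",
                "seed": int(child_seeds[i]),
            }
        )

    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["filename", "split", "weather", "height_m", "true_coverage_pct", "seed"]
        )
        writer.writeheader()
        writer.writerows(rows)
    return manifest
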
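"""Seeded synthetic specimen images, part masks and metadata.

The generator emulates a museum-drawer imaging campaign along an elevational
gradient: bilaterally symmetric procedural moths (body ellipse, two forewing
and two hindwing polygons, species-specific spots and stripes) photographed on
a uniform light background, together with ground-truth part masks and a
metadata table (species, genus, family, sampled elevation, climate).

The planted statistical structure is the one the downstream analysis assumes:

* species mean brightness (HSV value V) decreases with elevation at
  ``melanism_slope_b`` per km, and saturation increases at ``melanism_slope_s``
  per km (thermal melanism);
* body and forewings — the parts exposed at rest — darken *faster* than the
  hindwings (``forewing_melanism_bias``), so the relative-brightness index
  B = Bf/Bw declines with elevation;
* between-species colour scatter shrinks with elevation at rate
  ``external_filter_strength`` per km (environmental filtering), either on all
  HSV axes or on the chromatic axes (H, S) only;
* hue carries no elevational signal in its mean (it is drawn from a wrapped
  normal per species), matching an analysis that never averages hue;
* temperature is an exact affine function of elevation (lapse rate),
  precipitation is independent noise.

Mask labels: 0 background, 1 body, 2/3 forewing left/right, 4/5 hindwing
left/right.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.draw import disk, ellipse, polygon

__all__ = [
    "ConfigurationError",
    "GeneratorConfig",
    "SpeciesSpec",
    "SyntheticDataset",
    "LABEL_NAMES",
    "generate_species_pool",
    "render_specimen",
    "generate_dataset",
    "write_dataset",
]

LABEL_NAMES = {
    0: "background",
    1: "body",
    2: "forewing_l",
    3: "forewing_r",
    4: "hindwing_l",
    5: "hindwing_r",
}

BODY_FOREWING_LABELS = (1, 2, 3)

METADATA_COLUMNS = [
    "image_id",
    "species_id",
    "genus_id",
    "family_id",
    "elevation_m",
    "temperature_c",
    "precip_mm",
]


class ConfigurationError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic collecting campaign.

    Slopes are expressed per kilometre of elevation; HSV components live in
    [0, 1] except hue, which is in degrees.
    """

    n_species: int = 200
    images_per_species: tuple[int, int] = (2, 4)
    elevation_range: tuple[float, float] = (0.0, 2500.0)
    n_families: int = 8
    melanism_slope_b: float = -0.2
    melanism_slope_s: float = 0.12
    forewing_melanism_bias: float = -0.05
    within_species_sd: float = 0.03
    between_species_sd: float = 0.12
    hue_dispersion: float = 60.0
    external_filter_strength: float = 0.0
    filter_includes_brightness: bool = True
    base_value: float = 0.75
    base_saturation: float = 0.35
    base_hue: float = 45.0
    lapse_rate: float = 5.5
    sea_level_temp: float = 23.0
    image_size: int = 64
    pixel_noise_sd: float = 0.01
    elevation_sd: float = 150.0
    elevation_gaps: tuple[tuple[float, float], ...] = ()
    species_per_bin: tuple[int, ...] | None = None
    bin_width: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.elevation_range
        if not lo < hi:
            raise ConfigurationError("elevation_range: lo must be < hi")
        if lo < 0:
            raise ConfigurationError("elevation_range: lo must be >= 0")
        for name in ("n_species", "n_families"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name}: must be >= 1")
        a, b = self.images_per_species
        if a < 1 or b < a:
            raise ConfigurationError("images_per_species: need 1 <= lo <= hi")
        for name in (
            "within_species_sd",
            "between_species_sd",
            "hue_dispersion",
            "pixel_noise_sd",
            "elevation_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        if self.image_size < 64:
            raise ConfigurationError("image_size: must be >= 64")
        if self.species_per_bin is not None and any(
            c < 1 for c in self.species_per_bin
        ):
            raise ConfigurationError("species_per_bin: counts must be >= 1")

    def populated_bins(self) -> list[tuple[float, float]]:
        """100-m (``bin_width``) intervals inside the range that are not gaps."""
        lo, hi = self.elevation_range
        edges = np.arange(lo, hi, self.bin_width)
        bins = []
        for e in edges:
            b = (float(e), float(min(e + self.bin_width, hi)))
            if not any(g0 < b[1] and b[0] < g1 for g0, g1 in self.elevation_gaps):
                bins.append(b)
        return bins

    def scatter_shrink(self, elevation_m: float | np.ndarray) -> np.ndarray:
        """Multiplicative shrinkage of between-species scatter at an elevation."""
        return np.exp(-self.external_filter_strength * np.asarray(elevation_m) / 1000.0)


@dataclass(frozen=True)
class SpeciesSpec:
    """One species' colour, pattern and distribution parameters."""

    species_id: str
    genus_id: str
    family_id: str
    true_mean_elevation: float
    base_colour: tuple[float, float, float]  # (H degrees, S, V)
    spots: tuple[tuple[float, float, float], ...] = ()  # (rel x, rel y, rel radius)
    stripes: tuple[float, ...] = ()  # relative y positions on the forewings
    wing_shape: tuple[float, float] = (1.0, 1.0)  # forewing span / hindwing drop
    pattern_darkening: float = 0.25

    def __post_init__(self) -> None:
        h, s, v = self.base_colour
        if not (0 <= h < 360 and 0 <= s <= 1 and 0 <= v <= 1):
            raise ConfigurationError("base_colour: H in [0,360), S and V in [0,1]")


def generate_species_pool(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[SpeciesSpec]:
    """Draw the species pool with the configured elevational colour structure.

    Species mean elevations are uniform over the populated part of the range
    (or pinned per 100-m bin when ``species_per_bin`` is set).  Expected V at
    elevation e is ``base_value + melanism_slope_b * e/1000`` clipped to
    [0.05, 0.95]; saturation analogously.  Between-species scatter shrinks
    with elevation by ``scatter_shrink``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    bins = config.populated_bins()
    if config.species_per_bin is not None:
        counts = list(config.species_per_bin)
        if len(counts) != len(bins):
            raise ConfigurationError(
                f"species_per_bin: expected {len(bins)} counts for the "
                f"populated bins, got {len(counts)}"
            )
        elevations = np.concatenate(
            [rng.uniform(b0, b1, size=c) for (b0, b1), c in zip(bins, counts)]
        )
    else:
        widths = np.array([b1 - b0 for b0, b1 in bins])
        which = rng.choice(len(bins), size=config.n_species, p=widths / widths.sum())
        lows = np.array([b[0] for b in bins])
        elevations = lows[which] + rng.uniform(0, 1, size=config.n_species) * widths[which]

    elevations = np.sort(elevations)
    n = elevations.size
    e_km = elevations / 1000.0
    shrink = config.scatter_shrink(elevations)
    v_shrink = shrink if config.filter_includes_brightness else np.ones_like(shrink)

    mean_v = config.base_value + config.melanism_slope_b * e_km
    mean_s = config.base_saturation + config.melanism_slope_s * e_km
    base_v = np.clip(mean_v + rng.normal(0, config.between_species_sd, n) * v_shrink, 0.05, 0.95)
    base_s = np.clip(mean_s + rng.normal(0, config.between_species_sd, n) * shrink, 0.05, 0.95)
    base_h = np.mod(config.base_hue + rng.normal(0, config.hue_dispersion, n) * shrink, 360.0)

    pool: list[SpeciesSpec] = []
    for i in range(n):
        n_spots = int(rng.integers(0, 4))
        spots = tuple(
            (float(rng.uniform(0.25, 0.8)), float(rng.uniform(0.15, 0.45)), float(rng.uniform(0.03, 0.07)))
            for _ in range(n_spots)
        )
        n_stripes = int(rng.integers(0, 3))
        stripes = tuple(float(rng.uniform(0.2, 0.45)) for _ in range(n_stripes))
        pool.append(
            SpeciesSpec(
                species_id=f"sp{i:04d}",
                genus_id=f"g{i // 3:04d}",
                family_id=f"f{i % config.n_families}",
                true_mean_elevation=float(elevations[i]),
                base_colour=(float(base_h[i]), float(base_s[i]), float(base_v[i])),
                spots=spots,
                stripes=stripes,
                wing_shape=(float(rng.uniform(0.85, 1.15)), float(rng.uniform(0.85, 1.15))),
                pattern_darkening=float(rng.uniform(0.15, 0.35)),
            )
        )
    return pool


def _hsv_to_rgb01(h_deg: float, s: float, v: float) -> np.ndarray:
    return hsv2rgb(np.array([[[h_deg / 360.0, s, v]]]))[0, 0]


def render_specimen(
    spec: SpeciesSpec,
    elevation: float,
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one specimen image and its ground-truth part mask.

    Returns ``(image, mask)`` with image uint8 (H, W, 3) and mask uint8 (H, W)
    labelled 0-5.  All randomness (individual colour deviation, pixel noise)
    comes from ``rng``, so a saved generator state reproduces the raster.
    """
    size = config.image_size
    if size < 64:
        raise ConfigurationError("image_size: must be >= 64")
    cx = size / 2.0
    e_km = elevation / 1000.0

    h0, s0, v0 = spec.base_colour
    # individual deviation is shared by all parts of the specimen
    dh = rng.normal(0, config.within_species_sd * 120.0)
    ds = rng.normal(0, config.within_species_sd)
    dv = rng.normal(0, config.within_species_sd)
    h_i = (h0 + dh) % 360.0
    s_i = float(np.clip(s0 + ds, 0.02, 1.0))
    v_hind = float(np.clip(v0 + dv, 0.03, 0.97))
    v_fore = float(np.clip(v_hind + config.forewing_melanism_bias * e_km, 0.03, 0.97))

    rgb_fore = _hsv_to_rgb01(h_i, s_i, v_fore)
    rgb_hind = _hsv_to_rgb01(h_i, s_i, v_hind)
    v_pat = float(np.clip(v_fore - spec.pattern_darkening, 0.02, 1.0))
    rgb_pattern = _hsv_to_rgb01(h_i, min(1.0, s_i * 1.1), v_pat)

    img = np.full((size, size, 3), 0.88, dtype=float)
    mask = np.zeros((size, size), dtype=np.uint8)

    span, drop = spec.wing_shape
    body_w = 0.055 * size
    body_h = 0.24 * size

    def paint_polygon(xs, ys, label, colour):
        rr, cc = polygon(np.asarray(ys), np.asarray(xs), shape=mask.shape)
        mask[rr, cc] = label
        img[rr, cc] = colour

    # hindwings first (forewings overlap them), then forewings, then body
    for side, sign in (("l", -1), ("r", 1)):
        xs = [cx + sign * 0.04 * size, cx + sign * 0.32 * size * span,
              cx + sign * 0.26 * size * span, cx + sign * 0.04 * size]
        ys = [0.50 * size, 0.55 * size, 0.82 * size * drop, 0.72 * size]
        paint_polygon(xs, ys, 4 if side == "l" else 5, rgb_hind)
    fore_polys = {}
    for side, sign in (("l", -1), ("r", 1)):
        xs = [cx + sign * 0.03 * size, cx + sign * 0.44 * size * span,
              cx + sign * 0.40 * size * span, cx + sign * 0.05 * size]
        ys = [0.30 * size, 0.18 * size, 0.42 * size, 0.55 * size]
        paint_polygon(xs, ys, 2 if side == "l" else 3, rgb_fore)
        fore_polys[side] = (xs, ys)

    # species pattern: spots and stripes on the forewings, mirrored
    fore_label = {( -1): 2, (1): 3}
    for side, sign in (("l", -1), ("r", 1)):
        label = fore_label[sign]
        for relx, rely, relr in spec.spots:
            sx = cx + sign * relx * 0.44 * size
            sy = (0.18 + rely) * size
            rr, cc = disk((sy, sx), max(1.0, relr * size), shape=mask.shape)
            keep = mask[rr, cc] == label
            img[rr[keep], cc[keep]] = rgb_pattern
        for rely in spec.stripes:
            y0 = int((0.18 + rely) * size)
            band = slice(max(0, y0 - 1), min(size, y0 + 1))
            sel = mask[band, :] == label
            img[band, :][sel] = rgb_pattern

    rr, cc = ellipse(0.47 * size, cx, body_h, body_w, shape=mask.shape)
    mask[rr, cc] = 1
    img[rr, cc] = rgb_fore

    img = img + rng.normal(0, config.pixel_noise_sd, img.shape)
    img8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return img8, mask


@dataclass
class SyntheticDataset:
    """In-memory synthetic campaign: images, masks, metadata and provenance."""

    config: GeneratorConfig
    species: list[SpeciesSpec]
    metadata: pd.DataFrame
    images: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    masks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def species_mean_elevations(self) -> pd.Series:
        """Species mean elevation = mean sampled elevation over its images."""
        return self.metadata.groupby("species_id")["elevation_m"].mean()

    def species_elevation_ranges(self) -> pd.DataFrame:
        g = self.metadata.groupby("species_id")["elevation_m"]
        return pd.DataFrame({"lo": g.min(), "hi": g.max()})


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full campaign for one seed.

    One metadata row per image; per-species image counts uniform within the
    configured range; sampled elevations from a truncated normal around the
    species' true mean elevation; temperature exactly
    ``sea_level_temp - lapse_rate * elevation/1000``.
    """
    rng = np.random.default_rng(config.seed)
    pool = generate_species_pool(config, rng)
    lo, hi = config.elevation_range

    rows = []
    images: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    img_idx = 0
    a, b = config.images_per_species
    for spec in pool:
        n_img = int(rng.integers(a, b + 1))
        for _ in range(n_img):
            # truncated-normal sampled elevation around the species mean
            while True:
                e = rng.normal(spec.true_mean_elevation, config.elevation_sd)
                if lo <= e <= hi:
                    break
            image_id = f"img{img_idx:05d}"
            img_idx += 1
            img, mask = render_specimen(spec, e, rng, config)
            images[image_id] = img
            masks[image_id] = mask
            rows.append(
                {
                    "image_id": image_id,
                    "species_id": spec.species_id,
                    "genus_id": spec.genus_id,
                    "family_id": spec.family_id,
                    "elevation_m": float(e),
                    "temperature_c": config.sea_level_temp
                    - config.lapse_rate * e / 1000.0,
                    "precip_mm": float(max(0.0, rng.normal(2500.0, 400.0))),
                }
            )
    metadata = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    return SyntheticDataset(config=config, species=pool, metadata=metadata,
                            images=images, masks=masks)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write images/, masks/, metadata.csv and a provenance manifest."""
    import imageio.v3 as iio

    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"output directory not writable: {out}") from exc
    for image_id, img in dataset.images.items():
        iio.imwrite(out / "images" / f"{image_id}.png", img)
    for image_id, mask in dataset.masks.items():
        iio.imwrite(out / "masks" / f"{image_id}.png", mask)
    dataset.metadata.to_csv(out / "metadata.csv", index=False)
    manifest = {
        "config": dataclasses.asdict(dataset.config),
        "n_species": len(dataset.species),
        "n_images": len(dataset.images),
        "label_names": {str(k): v for k, v in LABEL_NAMES.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return out
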
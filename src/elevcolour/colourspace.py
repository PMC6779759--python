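"""Colour-space constraint simulation.

Demonstrates, by Monte-Carlo sampling, that restricting colours to a darker
HSV region (low brightness ceiling, high saturation floor) reduces the
colour variation available in RGB space.  Variation is measured as the
trace of the RGB sample covariance matrix (denominator n), the simplest
rotation-invariant scalar; in the greyscale limit (S = 0, V ~ U[0, c]) it
has the closed form 3 * (255 c)^2 / 12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colour import hsv_to_rgb

__all__ = ["HsvRegion", "sample_region", "rgb_variation", "constraint_experiment"]


@dataclass(frozen=True)
class HsvRegion:
    """Axis-aligned region of HSV space: H in degrees, S and V in [0, 1]."""

    h: tuple[float, float] = (0.0, 360.0)
    s: tuple[float, float] = (0.0, 1.0)
    v: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not (0 <= self.h[0] <= self.h[1] <= 360):
            raise ValueError("hue interval must satisfy 0 <= lo <= hi <= 360")
        for name in ("s", "v"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"{name} interval must satisfy 0 <= lo <= hi <= 1")


def sample_region(
    region: HsvRegion, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Sample n RGB triples uniformly (in H, S, V independently) from a region."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h = rng.uniform(*region.h, size=n) % 360.0
    s = rng.uniform(*region.s, size=n)
    v = rng.uniform(*region.v, size=n)
    return hsv_to_rgb(np.column_stack([h, s, v]))


def rgb_variation(samples: np.ndarray) -> float:
    """Total RGB variance: trace of the (denominator-n) covariance matrix."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 2:
        raise ValueError("need an (n >= 2, 3) array of RGB samples")
    return float(np.var(x, axis=0, ddof=0).sum())


def constraint_experiment(
    v_ceilings: np.ndarray,
    s_floors: np.ndarray,
    n: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """RGB variation over a grid of brightness ceilings and saturation floors.

    For each (c, f) colours are sampled with V in [0, c], S in [f, 1] and H
    over the full circle; the long-format table has one row per grid cell.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c in np.asarray(v_ceilings, dtype=float):
        for f in np.asarray(s_floors, dtype=float):
            region = HsvRegion(s=(f, 1.0), v=(0.0, c))
            if c == 0:
                var = 0.0
            else:
                var = rgb_variation(sample_region(region, n, rng))
            rows.append({"v_ceiling": c, "s_floor": f, "rgb_variation": var, "n": n})
    return pd.DataFrame(rows)
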
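"""HSV conversion and relative melanism indices.

Thermal melanism predicts darker (low V, high S) colouration in colder
environments.  The indices used here normalise for overall specimen
lightness: with mean brightness of the resting-exposed parts (body and both
forewings) Bf and of the whole specimen Bw, the brightness index is
B = Bf / Bw; the saturation index S = Sf / Sw analogously.  Hue is treated
as categorical and is never averaged.

Means are arithmetic means over pixels within the mask in linear 8-bit
space; no gamma linearisation or colour management is applied (see the
methods note for this limitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.color import hsv2rgb as _sk_hsv2rgb
from skimage.color import rgb2hsv as _sk_rgb2hsv

from .synthetic import BODY_FOREWING_LABELS

__all__ = [
    "ColourIndices",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "specimen_indices",
    "assemblage_indices",
]


@dataclass(frozen=True)
class ColourIndices:
    """Specimen-level mean saturation/brightness and their relative indices."""

    s_w: float
    b_w: float
    s_f: float
    b_f: float

    @property
    def b_index(self) -> float:
        return self.b_f / self.b_w

    @property
    def s_index(self) -> float:
        return self.s_f / self.s_w


def rgb_to_hsv(rgb: Sequence[float] | np.ndarray) -> np.ndarray:
    """Standard hexcone RGB(8-bit) -> HSV with H in degrees.

    Accepts a single (r, g, b) triple or an (..., 3) array of 8-bit channel
    values; returns H in [0, 360), S and V in [0, 1].  H is 0 where S is 0.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected (..., 3) RGB input")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB channels must lie in [0, 255]")
    hsv = _sk_rgb2hsv(arr.reshape(-1, 1, 3) / 255.0).reshape(arr.shape)
    hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    hsv[..., 0] = np.where(hsv[..., 1] == 0, 0.0, hsv[..., 0])
    return hsv


def hsv_to_rgb(hsv: Sequence[float] | np.ndarray) -> np.ndarray:
    """Inverse hexcone conversion: H degrees, S, V in [0,1] -> 8-bit RGB."""
    arr = np.asarray(hsv, dtype=float)
    scaled = arr.reshape(-1, 1, 3).copy()
    scaled[..., 0] = (scaled[..., 0] % 360.0) / 360.0
    return _sk_hsv2rgb(scaled).reshape(arr.shape) * 255.0


def specimen_indices(image: np.ndarray, part_mask: np.ndarray) -> ColourIndices:
    """Compute Sw, Bw, Sf, Bf and the ratio indices for one specimen.

    ``part_mask`` uses the generator's labels (0 background, 1 body,
    2/3 forewings, 4/5 hindwings).  The whole-specimen means run over all
    five parts; the "f" means over body + forewings.
    """
    mask = np.asarray(part_mask)
    if mask.shape != np.asarray(image).shape[:2]:
        raise ValueError("image and part mask extents differ")
    whole = mask > 0
    fore = np.isin(mask, BODY_FOREWING_LABELS)
    if not whole.any():
        raise ValueError("whole-specimen region is empty")
    if not fore.any():
        raise ValueError("body+forewing region is empty")
    hsv = rgb_to_hsv(np.asarray(image)[whole])
    s_w = float(hsv[:, 1].mean())
    b_w = float(hsv[:, 2].mean())
    hsv_f = rgb_to_hsv(np.asarray(image)[fore])
    s_f = float(hsv_f[:, 1].mean())
    b_f = float(hsv_f[:, 2].mean())
    if b_w <= 0:
        raise ValueError("whole-specimen brightness Bw is zero")
    if s_w <= 0:
        raise ValueError("whole-specimen saturation Sw is zero")
    return ColourIndices(s_w=s_w, b_w=b_w, s_f=s_f, b_f=b_f)


def assemblage_indices(members: Iterable[ColourIndices]) -> tuple[float, float]:
    """Unweighted species means of the B and S indices for one assemblage."""
    members = list(members)
    if not members:
        raise ValueError("empty assemblage")
    return (
        float(np.mean([m.b_index for m in members])),
        float(np.mean([m.s_index for m in members])),
    )
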
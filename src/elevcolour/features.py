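"""Per-specimen feature vectors and the operations built on them.

The built-in embedding is a deterministic, interpretable stand-in for a CNN
feature extractor: nonnegative blocks of HSV histograms over the specimen
foreground, per-part mean saturation/brightness, and a mirror-symmetric
radial shape descriptor of the outline, concatenated and padded to a fixed
dimension D.  Variants: ``colour`` (all blocks), ``greyscale`` (V-only
histograms + shape), ``silhouette`` (shape block only).  Externally computed
vectors (e.g. 2048-d CNN features) can be substituted anywhere downstream.

Species trait distance is the cosine distance of these vectors; species mean
elevation is predicted by a ridge-regularised linear map trained under a
mean-squared-error objective, with per-image predictions averaged per
species; classical (Torgerson) MDS embeds the cosine distance matrix for
visualisation and for the one-dimensional trait axis used by the
T-statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, ndimage as ndi
from sklearn.linear_model import Ridge

from .colour import rgb_to_hsv

__all__ = [
    "DEFAULT_DIM",
    "ElevationModel",
    "embed",
    "cosine_distance",
    "pairwise_cosine",
    "fit_elevation_model",
    "predict_species_elevation",
    "representative_image",
    "mds_project",
]

DEFAULT_DIM = 256
_N_ANGLES = 64
_H_BINS, _S_BINS, _V_BINS = 16, 4, 16


def _radial_shape(mask: np.ndarray, n_angles: int = _N_ANGLES) -> np.ndarray:
    """Mirror-symmetric radial outline descriptor, normalised to max 1.

    Maximum boundary radius from the foreground centroid in ``n_angles``
    directions, symmetrised across the vertical axis so a horizontally
    mirrored specimen yields the identical descriptor.
    """
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    boundary = mask & ~ndi.binary_erosion(mask)
    by, bx = np.nonzero(boundary)
    theta = np.arctan2(by - cy, bx - cx) % (2 * np.pi)
    r = np.hypot(by - cy, bx - cx)
    # centre-offset bins: bin k spans theta in [(k-.5), (k+.5)] * 2pi/n
    idx = np.round(theta / (2 * np.pi / n_angles)).astype(int) % n_angles
    prof = np.zeros(n_angles)
    np.maximum.at(prof, idx, r)
    if prof.max() > 0:
        prof = prof / prof.max()
    # horizontal mirror maps angle t -> pi - t, i.e. bin k -> (n/2 - k) mod n
    mirror = (n_angles // 2 - np.arange(n_angles)) % n_angles
    return 0.5 * (prof + prof[mirror])


def _histogram(values: np.ndarray, bins: int, lo: float, hi: float) -> np.ndarray:
    h, _ = np.histogram(values, bins=bins, range=(lo, hi))
    total = h.sum()
    return h / total if total else h.astype(float)


def embed(
    image: np.ndarray,
    mask: np.ndarray,
    variant: str = "colour",
    dim: int = DEFAULT_DIM,
    part_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Embed one specimen image into a nonnegative D-dimensional vector."""
    if variant not in ("colour", "greyscale", "silhouette"):
        raise ValueError(f"unknown variant: {variant!r}")
    fg = np.asarray(mask).astype(bool)
    if not fg.any():
        raise ValueError("empty foreground mask")
    img = np.asarray(image)

    shape_block = _radial_shape(fg)
    if variant == "silhouette":
        blocks = [np.zeros(_H_BINS * _S_BINS + _S_BINS * _V_BINS + _V_BINS + 6),
                  shape_block]
    else:
        hsv = rgb_to_hsv(img[fg])
        h, s, v = hsv[:, 0], hsv[:, 1], hsv[:, 2]
        v_hist = _histogram(v, _V_BINS, 0.0, 1.0)
        if variant == "greyscale":
            hs_joint = np.zeros(_H_BINS * _S_BINS)
            sv_joint = np.zeros(_S_BINS * _V_BINS)
        else:
            hs_joint, _, _ = np.histogram2d(
                h, s, bins=(_H_BINS, _S_BINS), range=((0, 360), (0, 1))
            )
            hs_joint = (hs_joint / hs_joint.sum()).ravel()
            sv_joint, _, _ = np.histogram2d(
                s, v, bins=(_S_BINS, _V_BINS), range=((0, 1), (0, 1))
            )
            sv_joint = (sv_joint / sv_joint.sum()).ravel()

        part_block = np.zeros(6)
        if part_mask is not None:
            pm = np.asarray(part_mask)
            # mirror-invariant part groups: body, forewings, hindwings
            for j, labels in enumerate(((1,), (2, 3), (4, 5))):
                sel = np.isin(pm, labels)
                if sel.any():
                    phsv = rgb_to_hsv(img[sel])
                    if variant == "colour":
                        part_block[2 * j] = phsv[:, 1].mean()
                    part_block[2 * j + 1] = phsv[:, 2].mean()
        blocks = [hs_joint, sv_joint, v_hist, part_block, shape_block]

    vec = np.concatenate(blocks)
    if vec.size >= dim:
        return vec[:dim]
    return np.pad(vec, (0, dim - vec.size))


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v); in [0, 1] for nonnegative vectors, [0, 2] in general."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must share a dimension")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    d = 1.0 - float(u @ v) / (nu * nv)
    return max(0.0, d)


def pairwise_cosine(vectors: np.ndarray) -> np.ndarray:
    """Full symmetric cosine-distance matrix with an exactly zero diagonal."""
    x = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError("cosine distance undefined for a zero vector")
    g = (x / norms[:, None]) @ (x / norms[:, None]).T
    d = 1.0 - np.clip(g, -1.0, 1.0)
    d = np.clip(0.5 * (d + d.T), 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ElevationModel:
    """Ridge-regularised linear map from feature vector to elevation (m).

    Trained by minimising the (penalised) mean squared error between actual
    species elevations Y_i and per-image predictions.
    """

    model: Ridge
    training_mse: float

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        return self.model.predict(np.atleast_2d(vectors))


def fit_elevation_model(
    vectors: np.ndarray, elevations: np.ndarray, alpha: float = 1.0
) -> ElevationModel:
    """Fit the elevation regressor; reports the training MSE."""
    x = np.atleast_2d(np.asarray(vectors, dtype=float))
    y = np.asarray(elevations, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    model = Ridge(alpha=alpha)
    model.fit(x, y)
    pred = model.predict(x)
    return ElevationModel(model=model, training_mse=float(np.mean((y - pred) ** 2)))


def predict_species_elevation(model: ElevationModel, vectors: np.ndarray) -> float:
    """Average the per-image predictions of one species' images."""
    preds = model.predict(np.atleast_2d(vectors))
    if preds.size == 0:
        raise ValueError("need at least one image")
    return float(preds.mean())


def representative_image(
    images: pd.DataFrame, mean_elevation: float | None = None
) -> str:
    """Pick the image sampled closest to the species' mean elevation.

    ``images`` needs columns image_id and elevation_m.  Ties are broken by
    the lexicographically smallest image_id.
    """
    if len(images) == 0:
        raise ValueError("species has no images")
    if mean_elevation is None:
        mean_elevation = float(images["elevation_m"].mean())
    df = images.assign(_gap=(images["elevation_m"] - mean_elevation).abs())
    df = df.sort_values(["_gap", "image_id"], kind="mergesort")
    return str(df["image_id"].iloc[0])


def mds_project(
    dist: np.ndarray, dims: int = 2, orient_by: np.ndarray | None = None
) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centres the squared distances, takes the top ``dims`` eigenpairs
    (negative eigenvalues truncated to zero, the usual convention for
    slightly non-Euclidean inputs such as cosine distances) and scales the
    eigenvectors by sqrt(eigenvalue).  Axis signs are fixed so each
    coordinate correlates nonnegatively with ``orient_by`` (e.g. species
    mean elevation) when given, otherwise so the largest-magnitude loading
    is positive.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < dims + 1:
        raise ValueError("need at least dims+1 points")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = 0.5 * (b + b.T)
    vals, vecs = linalg.eigh(b, subset_by_index=[n - dims, n - 1])
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    # drop numerically-zero eigenvalues so their arbitrary eigenvectors do
    # not leak rounding noise into the coordinates
    if vals[0] > 0:
        vals[vals < vals[0] * 1e-12] = 0.0
    vecs = vecs[:, order]
    coords = vecs * np.sqrt(vals)
    for k in range(dims):
        col = coords[:, k]
        if orient_by is not None and np.std(col) > 0 and np.std(orient_by) > 0:
            if np.corrcoef(col, orient_by)[0, 1] < 0:
                coords[:, k] = -col
        elif col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords
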
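"""Embeddings, cosine distance, elevation regression, classical MDS."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from elevcolour.colour import hsv_to_rgb, rgb_to_hsv
from elevcolour.features import (
    cosine_distance,
    embed,
    fit_elevation_model,
    mds_project,
    pairwise_cosine,
    predict_species_elevation,
    representative_image,
)


class TestEmbed:
    def test_identical_images_identical_vectors(self, rendered_specimens):
        img, mask = rendered_specimens[0]
        v1 = embed(img, mask > 0, part_mask=mask)
        v2 = embed(img.copy(), (mask > 0).copy(), part_mask=mask.copy())
        assert np.array_equal(v1, v2)

    def test_horizontal_mirror_invariance(self, rendered_specimens):
        for img, mask in rendered_specimens:
            v = embed(img, mask > 0, part_mask=mask)
            vm = embed(img[:, ::-1], mask[:, ::-1] > 0, part_mask=mask[:, ::-1])
            assert np.allclose(v, vm, atol=1e-9)

    def test_silhouette_ignores_colour(self, rendered_specimens):
        img, mask = rendered_specimens[0]
        recoloured = 255 - img
        v1 = embed(img, mask > 0, variant="silhouette")
        v2 = embed(recoloured, mask > 0, variant="silhouette")
        assert np.array_equal(v1, v2)

    def test_greyscale_ignores_hue(self, rendered_specimens):
        img, mask = rendered_specimens[0]
        hsv = rgb_to_hsv(img.astype(float))
        hsv[..., 0] = (hsv[..., 0] + 137.0) % 360.0
        rotated = hsv_to_rgb(hsv)  # float RGB, V preserved exactly
        v1 = embed(img, mask > 0, variant="greyscale", part_mask=mask)
        v2 = embed(rotated, mask > 0, variant="greyscale", part_mask=mask)
        assert np.allclose(v1, v2, atol=1e-9)

    def test_nonnegative_and_padded(self, rendered_specimens):
        img, mask = rendered_specimens[0]
        v = embed(img, mask > 0, dim=300, part_mask=mask)
        assert v.shape == (300,)
        assert (v >= 0).all() and v.any()

    def test_empty_mask_raises(self, rendered_specimens):
        img, mask = rendered_specimens[0]
        with pytest.raises(ValueError, match="empty"):
            embed(img, np.zeros_like(mask, dtype=bool))


class TestCosineDistance:
    def test_closed_form_examples(self):
        assert cosine_distance([1, 1, 0], [1, 1, 0]) == pytest.approx(0.0, abs=1e-12)
        assert cosine_distance([1, 0, 0], [0, 1, 0]) == pytest.approx(1.0)
        assert cosine_distance([1, 1, 0], [1, 0, 0]) == pytest.approx(1 - 1 / math.sqrt(2))

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_distance([0, 0], [1, 0])

    @given(
        st.lists(st.floats(0, 100), min_size=3, max_size=8),
        st.lists(st.floats(0, 100), min_size=3, max_size=8),
    )
    def test_properties_on_nonnegative_vectors(self, u, v):
        n = min(len(u), len(v))
        u, v = np.array(u[:n]) + 1e-3, np.array(v[:n]) + 1e-3
        d = cosine_distance(u, v)
        assert 0 <= d <= 1
        assert d == pytest.approx(cosine_distance(v, u))
        assert cosine_distance(u, u) == pytest.approx(0, abs=1e-12)

    def test_pairwise_matches_scalar(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, size=(20, 7))
        mat = pairwise_cosine(x)
        for i in range(20):
            for j in range(i + 1, 20):
                assert mat[i, j] == pytest.approx(cosine_distance(x[i], x[j]), abs=1e-12)


class TestElevationModel:
    def test_perfect_feature_fits_exactly(self):
        elev = np.linspace(100, 2000, 40)
        x = np.zeros((40, 6))
        x[:, 2] = elev
        model = fit_elevation_model(x, elev, alpha=1e-8)
        assert model.training_mse < 1e-6
        assert model.predict(x) == pytest.approx(elev)

    def test_permuted_labels_give_no_held_out_skill(self):
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 1, size=(120, 20))
            y = rng.permutation(np.linspace(0, 2500, 120))
            model = fit_elevation_model(x[:90], y[:90])
            pred = model.predict(x[90:])
            ss_res = ((y[90:] - pred) ** 2).sum()
            ss_tot = ((y[90:] - y[90:].mean()) ** 2).sum()
            r2s.append(1 - ss_res / ss_tot)
        # no positive skill; held-out R^2 under the null is at or below zero
        assert np.mean(r2s) < 0.05

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError, match="2"):
            fit_elevation_model(np.ones((1, 3)), [100.0])

    def test_species_prediction_averages_images(self):
        elev = np.array([0.0, 1000.0])
        x = np.array([[0.0], [1000.0]])
        model = fit_elevation_model(x, elev, alpha=1e-9)
        pred = predict_species_elevation(model, np.array([[100.0], [300.0]]))
        assert pred == pytest.approx(200.0, rel=1e-3)


class TestRepresentativeImage:
    def test_closest_to_mean(self):
        df = pd.DataFrame({"image_id": ["a", "b"], "elevation_m": [100.0, 500.0]})
        assert representative_image(df, 480.0) == "b"

    def test_single_image(self):
        df = pd.DataFrame({"image_id": ["only"], "elevation_m": [42.0]})
        assert representative_image(df) == "only"

    def test_tie_broken_lexicographically(self):
        df = pd.DataFrame({"image_id": ["z1", "a1"], "elevation_m": [400.0, 600.0]})
        assert representative_image(df, 500.0) == "a1"


class TestMdsProject:
    def test_equilateral_triangle_embeds_equidistant(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords = mds_project(d, dims=2)
        dists = [np.linalg.norm(coords[i] - coords[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert np.allclose(dists, dists[0])

    def test_recovers_points_on_a_line(self):
        x = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        coord = mds_project(d, dims=1)[:, 0]
        # align sign and shift to the input coordinates
        coord = coord - coord.mean()
        target = x - x.mean()
        if np.dot(coord, target) < 0:
            coord = -coord
        assert np.sqrt(np.mean((coord - target) ** 2)) < 1e-8

    def test_duplicate_points_coincide(self):
        x = np.array([0.0, 1.0, 1.0, 3.0])
        d = np.abs(x[:, None] - x[None, :])
        coords = mds_project(d, dims=2)
        assert np.allclose(coords[1], coords[2], atol=1e-8)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords = mds_project(d, dims=3)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(d, d2, atol=1e-9)

    def test_orientation_follows_gradient(self):
        x = np.linspace(0, 10, 8)
        d = np.abs(x[:, None] - x[None, :])
        coord = mds_project(d, dims=1, orient_by=x)[:, 0]
        assert np.corrcoef(coord, x)[0, 1] > 0.99

    def test_asymmetric_input_raises(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            mds_project(d, dims=1)
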
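"""Binning, within-assemblage diversity, trend fits and bootstraps."""

import numpy as np
import pandas as pd
import pytest

from elevcolour.assemblage import (
    Assemblage,
    beta_diversity_profile,
    bin_species,
    bootstrap_family,
    bootstrap_pairwise,
    fit_trend,
    within_diversity,
)
from elevcolour.assemblage import _vectorised_trends
from elevcolour.features import cosine_distance


def _random_vectors(rng, species, dim=6):
    return {s: rng.uniform(0.01, 1, size=dim) for s in species}


class TestBinSpecies:
    def test_boundary_value_goes_to_upper_bin(self):
        bins = bin_species({"a": 50.0, "b": 99.0, "c": 100.0})
        assert [(b.lo, b.n_species) for b in bins] == [(0.0, 2), (100.0, 1)]
        assert bins[0].label == "0–100 m"

    def test_partition_property_across_widths(self):
        rng = np.random.default_rng(0)
        elev = {f"s{i}": float(e) for i, e in enumerate(rng.uniform(0, 2500, 200))}
        for width in (50.0, 100.0, 250.0):
            bins = bin_species(elev, width)
            members = [s for b in bins for s in b.species]
            assert sorted(members) == sorted(elev)

    def test_negative_elevation_raises(self):
        with pytest.raises(ValueError, match="negative"):
            bin_species({"a": -5.0})


class TestWithinDiversity:
    def test_identical_vectors_give_zero(self):
        a = Assemblage(0, 100, ("x", "y", "z"))
        vecs = {s: np.array([1.0, 2.0, 3.0]) for s in a.species}
        assert within_diversity(a, vecs).diversity == 0.0

    def test_two_members_equals_their_distance(self):
        a = Assemblage(0, 100, ("x", "y"))
        vecs = {"x": np.array([1.0, 0.0]), "y": np.array([1.0, 1.0])}
        rec = within_diversity(a, vecs)
        assert rec.diversity == pytest.approx(cosine_distance(vecs["x"], vecs["y"]))

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            species = tuple(f"s{i}" for i in range(n))
            vecs = _random_vectors(rng, species)
            rec = within_diversity(Assemblage(0, 100, species), vecs)
            acc = [
                cosine_distance(vecs[species[i]], vecs[species[j]])
                for i in range(n)
                for j in range(i + 1, n)
            ]
            assert rec.diversity == pytest.approx(np.mean(acc), abs=1e-12)
            assert len(acc) == n * (n - 1) // 2

    def test_eleven_members_use_55_pairs(self):
        rng = np.random.default_rng(4)
        species = tuple(f"s{i}" for i in range(11))
        vecs = _random_vectors(rng, species)
        rec = within_diversity(Assemblage(0, 100, species), vecs)
        assert rec.n_species == 11  # C(11, 2) = 55 unordered pairs

    def test_single_member_raises(self):
        with pytest.raises(ValueError, match="< 2"):
            within_diversity(Assemblage(0, 100, ("x",)), {"x": np.ones(3)})


class TestFitTrend:
    def test_exact_line(self):
        x = np.arange(19) * 100.0
        y = 0.5 - 1e-4 * x
        fit = fit_trend(x, y)
        assert fit.slope == pytest.approx(-1e-4)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.df == (1, 17)

    def test_null_r2_expectation(self):
        # with y independent of x and n points, E[R^2] = 1/(n-1)
        rng = np.random.default_rng(0)
        x = np.arange(19, dtype=float)
        ys = rng.normal(size=(1000, 19))
        r2 = _vectorised_trends(x, ys)["r2"]
        assert np.mean(r2) == pytest.approx(1 / 18, abs=0.02)

    def test_vectorised_trends_match_statsmodels(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 15)
        y = rng.normal(size=15)
        ref = fit_trend(x, y)
        vec = _vectorised_trends(x, y[None, :])
        assert vec["slope"][0] == pytest.approx(ref.slope)
        assert vec["intercept"][0] == pytest.approx(ref.intercept)
        assert vec["r2"][0] == pytest.approx(ref.r2)
        assert vec["f_stat"][0] == pytest.approx(ref.f_stat)

    def test_constant_predictor_raises(self):
        with pytest.raises(ValueError, match="constant"):
            fit_trend([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _assemblage_fixture(rng, n_bins=8, n_species=6, planted_slope=0.0):
    assemblages, vectors, families = [], {}, {}
    for k in range(n_bins):
        species = tuple(f"b{k}s{i}" for i in range(n_species))
        spread = max(0.05, 1.0 + planted_slope * k)
        for i, s in enumerate(species):
            vectors[s] = np.abs(rng.normal(1.0, spread, size=8)) + 1e-3
            families[s] = f"f{i % 4}"
        assemblages.append(Assemblage(k * 100.0, (k + 1) * 100.0, species))
    return assemblages, vectors, families


class TestBootstrapPairwise:
    def test_degenerate_equal_distances_give_point_interval(self):
        # orthogonal unit vectors: every pairwise distance is exactly 1
        assemblages = []
        vectors = {}
        for k in range(3):
            species = tuple(f"b{k}s{i}" for i in range(3))
            for i, s in enumerate(species):
                v = np.zeros(9)
                v[3 * k + i] = 1.0
                vectors[s] = v
            assemblages.append(Assemblage(k * 100.0, (k + 1) * 100.0, species))
        cis = bootstrap_pairwise(assemblages, vectors, reps=200, seed=1)
        assert cis["slope"].lower == pytest.approx(0.0, abs=1e-12)
        assert cis["slope"].upper == pytest.approx(0.0, abs=1e-12)
        assert cis["intercept"].lower == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(7)
        asms, vecs, _ = _assemblage_fixture(rng)
        a = bootstrap_pairwise(asms, vecs, reps=300, seed=5)
        b = bootstrap_pairwise(asms, vecs, reps=300, seed=5)
        assert a == b

    def test_large_m_converges_to_point_estimate(self):
        rng = np.random.default_rng(8)
        asms, vecs, _ = _assemblage_fixture(rng, planted_slope=-0.1)
        records = [within_diversity(a, vecs) for a in asms]
        point = fit_trend([r.midpoint for r in records], [r.diversity for r in records])
        cis = bootstrap_pairwise(asms, vecs, m=10_000, reps=400, seed=2)
        mid = 0.5 * (cis["slope"].lower + cis["slope"].upper)
        assert mid == pytest.approx(point.slope, abs=1e-3)

    def test_planted_negative_slope_ci_excludes_zero(self):
        rng = np.random.default_rng(9)
        asms, vecs, _ = _assemblage_fixture(rng, n_species=10, planted_slope=-0.12)
        cis = bootstrap_pairwise(asms, vecs, reps=500, seed=3)
        assert cis["slope"].upper < 0

    def test_few_reps_warns_and_bad_m_raises(self):
        rng = np.random.default_rng(10)
        asms, vecs, _ = _assemblage_fixture(rng)
        with pytest.warns(UserWarning, match="repeats"):
            bootstrap_pairwise(asms, vecs, reps=50, seed=0)
        with pytest.raises(ValueError, match="positive"):
            bootstrap_pairwise(asms, vecs, m=0, reps=200, seed=0)


class TestBootstrapFamily:
    def test_single_family_degenerates_to_point(self):
        rng = np.random.default_rng(11)
        asms, vecs, _ = _assemblage_fixture(rng)
        families = {s: "only" for v in asms for s in v.species}
        cis = bootstrap_family(asms, vecs, families, reps=150, seed=1)
        records = [within_diversity(a, vecs) for a in asms]
        point = fit_trend([r.midpoint for r in records], [r.diversity for r in records])
        assert cis["slope"].lower == pytest.approx(point.slope)
        assert cis["slope"].upper == pytest.approx(point.slope)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(12)
        asms, vecs, fams = _assemblage_fixture(rng)
        a = bootstrap_family(asms, vecs, fams, reps=200, seed=4)
        assert a == bootstrap_family(asms, vecs, fams, reps=200, seed=4)

    def test_planted_effect_retained(self):
        rng = np.random.default_rng(13)
        asms, vecs, fams = _assemblage_fixture(rng, n_species=12, planted_slope=-0.12)
        cis = bootstrap_family(asms, vecs, fams, reps=300, seed=2)
        assert cis["slope"].upper < 0


class TestBetaDiversity:
    def test_identical_adjacent_assemblages(self):
        asms = [Assemblage(0, 100, ("a", "b")), Assemblage(100, 200, ("a", "b"))]
        prof = beta_diversity_profile(asms)
        assert prof["turnover"].iloc[0] == 0.0

    def test_disjoint_adjacent_assemblages(self):
        asms = [Assemblage(0, 100, ("a", "b")), Assemblage(100, 200, ("c", "d"))]
        assert beta_diversity_profile(asms)["turnover"].iloc[0] == 1.0

    def test_half_shared_membership(self):
        asms = [Assemblage(0, 100, ("a", "b")), Assemblage(100, 200, ("b", "c"))]
        assert beta_diversity_profile(asms)["turnover"].iloc[0] == 0.5

    def test_ranges_extend_occupancy(self):
        asms = [Assemblage(0, 100, ("a",)), Assemblage(100, 200, ("b",))]
        ranges = pd.DataFrame({"lo": [20.0, 150.0], "hi": [180.0, 190.0]},
                              index=["a", "b"])
        prof = beta_diversity_profile(asms, species_ranges=ranges)
        # species a's range crosses into the upper bin
        assert prof["turnover"].iloc[0] < 1.0
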
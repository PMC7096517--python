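"""Simulator: grid, single spectra, composition, normalization, masks."""

import numpy as np
import pytest
from scipy import stats

from sersrf import (
    Band,
    Composition,
    SimulationConfig,
    band_membership,
    build_library,
    compose_spectrum,
    read_dataset,
    simulate_replicate,
    simulate_study,
    spectral_grid,
    vector_normalize,
    write_dataset,
)
from sersrf.simulate import library_rng, replicate_rng, simulate_single_spectrum


def test_spectral_grid_invariants(grid):
    assert grid.size == 1401
    assert grid[0] == 300.0 and grid[-1] == 1700.0
    assert np.all(np.diff(grid) == 1.0)


class TestSingleSpectrum:
    def test_band_count_and_length(self, grid):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = simulate_single_spectrum(grid, rng)
            assert s.intensities.size == 1401
            assert 3 <= len(s.bands) <= 10
            for b in s.bands:
                assert 300 <= b.center <= 1700
                assert 5 <= b.width <= 20
                assert 1000 <= b.amplitude <= 10000

    def test_pure_baseline_moments(self, grid):
        s = simulate_single_spectrum(grid, np.random.default_rng(1), n_bands=0)
        assert s.intensities.mean() == pytest.approx(200, abs=4 * 50 / np.sqrt(1401))
        assert s.intensities.std() == pytest.approx(50, rel=0.1)

    def test_band_mass_matches_gaussian_integral(self, grid):
        # amplitude 5000, sd 10: integral = 5000 * 10 * sqrt(2 pi) ~ 125331
        band = Band(center=1000.0, width=10.0, amplitude=5000.0)
        added = band.curve(grid).sum()
        assert added == pytest.approx(5000 * 10 * np.sqrt(2 * np.pi), rel=1e-6)
        assert band.curve(np.array([1000.0]))[0] == 5000.0  # max at center


class TestLibrary:
    def test_twelve_spectra_two_characteristic(self, grid):
        lib = build_library(grid, np.random.default_rng(2))
        assert [s.id for s in lib] == list(range(1, 13))
        assert sum(s.characteristic for s in lib) == 2
        assert lib[0].characteristic and lib[1].characteristic

    def test_seed_determinism_and_divergence(self, grid):
        a = build_library(grid, np.random.default_rng(5))
        b = build_library(grid, np.random.default_rng(5))
        c = build_library(grid, np.random.default_rng(6))
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.intensities, s2.intensities)
        assert not np.array_equal(a[0].intensities, c[0].intensities)


class TestCompose:
    def test_identity_and_convexity(self, small_study):
        library, _ = small_study
        one = compose_spectrum(
            library, Composition((1,), (1.0,), group=1, contains_characteristic=True, w=1.0)
        )
        np.testing.assert_array_equal(one, library[0].intensities)
        half = compose_spectrum(
            library, Composition((1, 3), (0.5, 0.5), group=1, contains_characteristic=True, w=0.5)
        )
        np.testing.assert_allclose(
            half, (library[0].intensities + library[2].intensities) / 2
        )

    def test_three_component_toy_weighted_sum(self):
        # 5-point toy grid, hand-computed weighted sum
        from sersrf.simulate import SingleSpectrum

        lib = [
            SingleSpectrum(id=i + 3, intensities=np.arange(5.0) * (i + 1), bands=[])
            for i in range(3)
        ]
        comp = Composition((3, 4, 5), (0.2, 0.3, 0.5), group=1, contains_characteristic=False)
        got = compose_spectrum(lib, comp)
        base = np.arange(5.0)
        expected = 0.2 * base + 0.3 * 2 * base + 0.5 * 3 * base  # = 2.3 * base
        np.testing.assert_allclose(got, expected)

    def test_invalid_compositions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            Composition((1, 3), (0.5, 0.6), group=1, contains_characteristic=True, w=0.5)
        with pytest.raises(ValueError, match="may not contain"):
            Composition((2, 3), (0.5, 0.5), group=1, contains_characteristic=False)

    def test_unknown_id_rejected(self, small_study):
        library, _ = small_study
        comp = Composition((1, 3), (0.5, 0.5), group=1, contains_characteristic=True, w=0.5)
        with pytest.raises(KeyError):
            compose_spectrum(library[:1], comp)


class TestNormalize:
    def test_hand_computed(self):
        np.testing.assert_allclose(
            vector_normalize(np.array([1.0, 2.0, 3.0, 4.0])), [0.1, 0.2, 0.3, 0.4]
        )

    def test_constant_spectrum(self):
        out = vector_normalize(np.full(1401, 7.3))
        np.testing.assert_allclose(out, 1 / 1401)

    def test_nonpositive_sum_rejected(self):
        with pytest.raises(ValueError):
            vector_normalize(np.array([1.0, -2.0]))

    def test_preserves_ordering(self):
        x = np.array([3.0, 1.0, 2.0])
        out = vector_normalize(x)
        assert np.all(np.argsort(out) == np.argsort(x))


class TestBandMembership:
    def test_window_arithmetic(self, grid):
        masks = band_membership([Band(1000.0, 10.0, 5000.0)], grid, band_extent_k=2.0)
        idx = np.flatnonzero(masks[0])
        assert grid[idx[0]] == 980.0 and grid[idx[-1]] == 1020.0
        assert idx.size == 41  # 980..1020 inclusive

    def test_zero_extent_limit(self, grid):
        masks = band_membership([Band(1000.0, 10.0, 5000.0)], grid, band_extent_k=1e-9)
        assert np.flatnonzero(masks[0]).tolist() == [700]  # 1000 cm^-1 only

    def test_edge_clipping(self, grid):
        masks = band_membership([Band(305.0, 10.0, 5000.0)], grid, band_extent_k=2.0)
        idx = np.flatnonzero(masks[0])
        assert grid[idx[0]] == 300.0 and grid[idx[-1]] == 325.0


class TestReplicate:
    def test_counts_normalization_and_exclusivity(self, small_study):
        _, ds = small_study
        assert ds.spectra.shape == (100, 1401)
        np.testing.assert_allclose(ds.spectra.sum(axis=1), 1.0, atol=1e-9)
        for group in (1, 2):
            comps = [c for c in ds.compositions if c.group == group]
            n_char = sum(c.contains_characteristic for c in comps)
            assert n_char == round(0.8 * 50)
            banned = 2 if group == 1 else 1
            assert all(banned not in c.contributing_ids for c in comps)
        for c in ds.compositions:
            assert 2 <= len(c.contributing_ids) <= 5
            if c.contains_characteristic:
                assert 0.1 <= c.w <= 0.8

    def test_null_scenario_has_no_characteristic(self, small_study):
        library, _ = small_study
        config = SimulationConfig(f=0.0, n_per_group=50, seed=3)
        ds = simulate_replicate(library, config, 1, replicate_rng(config, 1))
        for c in ds.compositions:
            assert not c.contains_characteristic
            assert 1 not in c.contributing_ids and 2 not in c.contributing_ids

    def test_same_seed_identical(self):
        config = SimulationConfig(f=0.2, n_replicates=2, n_per_group=25, seed=9)
        _, d1 = simulate_study(config)
        _, d2 = simulate_study(config)
        np.testing.assert_array_equal(d1[0].spectra, d2[0].spectra)
        np.testing.assert_array_equal(d1[1].spectra, d2[1].spectra)
        assert not np.array_equal(d1[0].spectra, d1[1].spectra)

    def test_w_uniform_on_mixing_range(self, grid):
        # >= 1e4 characteristic compositions; KS test against U(0.1, 0.8)
        config = SimulationConfig(f=1.0, n_per_group=5000, seed=17)
        library = build_library(grid, library_rng(config), config)
        ds = simulate_replicate(library, config, 1, replicate_rng(config, 1))
        w = np.array([c.w for c in ds.compositions if c.contains_characteristic])
        assert w.size == 10000
        res = stats.kstest(w, stats.uniform(loc=0.1, scale=0.7).cdf)
        assert res.pvalue > 0.01


def test_dataset_roundtrip(tmp_path, small_study):
    _, ds = small_study
    csv_path, meta_path = write_dataset(ds, tmp_path)
    back = read_dataset(csv_path, meta_path)
    np.testing.assert_allclose(back.spectra, ds.spectra, atol=1e-12)
    np.testing.assert_array_equal(back.labels, ds.labels)
    np.testing.assert_array_equal(back.char_band_mask, ds.char_band_mask)
    assert back.compositions[0] == ds.compositions[0]
    assert len(back.band_masks[1]) == len(ds.band_masks[1])
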
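"""Spectral arithmetic, domain-type invariants and CSV round-tripping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nutrispec import (
    Dataset,
    FoodSample,
    NutrientComposition,
    Spectrum,
    mae,
    mean_spectrum,
    read_dataset,
    write_dataset,
)
from nutrispec.spectra import GridMismatchError, ParseError, SpectraError

GRID = np.linspace(887.0, 1722.0, 8)


def spec(*intens):
    return Spectrum(np.linspace(887.0, 1722.0, len(intens)), np.array(intens, float))


class TestSpectrumInvariants:
    def test_rejects_nonmonotone_grid(self):
        with pytest.raises(SpectraError):
            Spectrum(np.array([1.0, 1.0, 2.0]), np.zeros(3))

    def test_rejects_length_mismatch(self):
        with pytest.raises(SpectraError):
            Spectrum(np.array([1.0, 2.0, 3.0]), np.zeros(2))

    def test_rejects_negative_intensity(self):
        with pytest.raises(SpectraError):
            spec(1.0, -0.1, 2.0)

    def test_rejects_single_band(self):
        with pytest.raises(SpectraError):
            Spectrum(np.array([900.0]), np.array([1.0]))


class TestComposition:
    def test_rejects_negative(self):
        with pytest.raises(SpectraError):
            NutrientComposition(-1.0, 0.0, 0.0)

    def test_rejects_sum_over_100(self):
        with pytest.raises(SpectraError):
            NutrientComposition(50.0, 40.0, 20.0)

    def test_array_round_trip(self):
        c = NutrientComposition(10.0, 20.0, 5.0)
        assert NutrientComposition.from_array(c.as_array()) == c


class TestMeanSpectrum:
    def test_mean_of_identical_is_identity(self):
        s = spec(1.0, 2.0, 3.0)
        m = mean_spectrum([s, s])
        np.testing.assert_array_equal(m.intensities, s.intensities)

    def test_pointwise_mean(self):
        m = mean_spectrum([spec(0.0, 4.0), spec(2.0, 0.0)])
        np.testing.assert_allclose(m.intensities, [1.0, 2.0])

    def test_permutation_invariant(self, rng):
        spectra = [Spectrum(GRID, rng.uniform(0, 10, GRID.size)) for _ in range(6)]
        m1 = mean_spectrum(spectra)
        order = rng.permutation(len(spectra))
        m2 = mean_spectrum([spectra[i] for i in order])
        np.testing.assert_allclose(m1.intensities, m2.intensities)

    def test_noise_averages_out(self):
        # law of large numbers: averaging r noisy replicates shrinks the MAE
        # to the clean signal to E|N(0, sigma^2/r)| = sigma*sqrt(2/pi)/sqrt(r),
        # concentrated to ~3*sigma/sqrt(r*n_bands) at large band counts
        rng = np.random.default_rng(7)
        n_bands, sigma, r = 4096, 0.5, 5
        grid = np.linspace(887.0, 1722.0, n_bands)
        clean = Spectrum(grid, np.full(n_bands, 10.0))
        reps = [Spectrum(grid, clean.intensities + rng.normal(0, sigma, n_bands))
                for _ in range(r)]
        expected = sigma * np.sqrt(2 / np.pi) / np.sqrt(r)
        assert abs(mae(mean_spectrum(reps), clean) - expected) \
            < 3 * sigma / np.sqrt(r * n_bands)

    def test_empty_list_and_grid_mismatch_error(self):
        with pytest.raises(SpectraError):
            mean_spectrum([])
        with pytest.raises(GridMismatchError):
            mean_spectrum([spec(1.0, 2.0), spec(1.0, 2.0, 3.0)])


class TestMae:
    def test_identity_and_hand_example(self):
        s = spec(1.0, 2.0, 3.0)
        assert mae(s, s) == 0.0
        assert mae(spec(1.0, 2.0, 3.0), spec(2.0, 2.0, 5.0)) == pytest.approx(1.0)

    def test_matches_elementwise_loop_oracle(self, rng):
        a = Spectrum(GRID, rng.uniform(0, 50, GRID.size))
        b = Spectrum(GRID, rng.uniform(0, 50, GRID.size))
        oracle = sum(abs(x - y) for x, y in
                     zip(a.intensities, b.intensities)) / GRID.size
        assert mae(a, b) == pytest.approx(oracle, rel=1e-14)

    @given(st.lists(st.floats(0, 1e3), min_size=2, max_size=16),
           st.data())
    def test_metric_axioms(self, xs, data):
        n = len(xs)
        ys = data.draw(st.lists(st.floats(0, 1e3), min_size=n, max_size=n))
        zs = data.draw(st.lists(st.floats(0, 1e3), min_size=n, max_size=n))
        grid = np.arange(n, dtype=float)
        a, b, c = (Spectrum(grid, np.array(v)) for v in (xs, ys, zs))
        assert mae(a, b) >= 0
        assert mae(a, b) == pytest.approx(mae(b, a))
        assert mae(a, a) == 0
        assert mae(a, c) <= mae(a, b) + mae(b, c) + 1e-9

    def test_grid_mismatch_error(self):
        with pytest.raises(GridMismatchError):
            mae(spec(1.0, 2.0), spec(1.0, 2.0, 3.0))


class TestDatasetIO:
    def test_round_trip_lossless(self, fwd_model, small_dataset, tmp_path):
        path = tmp_path / "ds.csv"
        write_dataset(small_dataset, path)
        back = read_dataset(path)
        assert len(back) == len(small_dataset)
        np.testing.assert_allclose(back.grid, small_dataset.grid, atol=1e-6)
        for s0, s1 in zip(small_dataset.samples, back.samples):
            assert s0.sample_id == s1.sample_id
            assert s0.category == s1.category
            np.testing.assert_allclose(s1.composition.as_array(),
                                       s0.composition.as_array(), rtol=1e-9)
            for r0, r1 in zip(s0.region_spectra, s1.region_spectra):
                np.testing.assert_allclose(r1.intensities, r0.intensities,
                                           rtol=1e-9)

    def test_unlabeled_samples_round_trip(self, tmp_path):
        grid = np.linspace(900.0, 1000.0, 4)
        s = FoodSample("u1", "drink", [Spectrum(grid, np.ones(4))], None)
        ds = Dataset([s], grid)
        write_dataset(ds, tmp_path / "u.csv")
        back = read_dataset(tmp_path / "u.csv")
        assert back.samples[0].composition is None

    def test_missing_column_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,category,wl_900.0,wl_910.0\na,drink,1,2\n")
        with pytest.raises(ParseError, match="missing"):
            read_dataset(p)

    def test_nonmonotone_bands_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,category,region_id,carb_g,protein_g,fat_g,"
                     "wl_910.0,wl_900.0\na,drink,0,1,1,1,1,2\n")
        with pytest.raises(ParseError, match="increasing"):
            read_dataset(p)

    def test_negative_intensity_error_names_cell(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,category,region_id,carb_g,protein_g,fat_g,"
                     "wl_900.0,wl_910.0\na,drink,0,1,1,1,1,-2\n")
        with pytest.raises(ParseError, match="wl_910"):
            read_dataset(p)

    def test_duplicate_ids_rejected(self):
        grid = np.linspace(900.0, 1000.0, 4)
        s = FoodSample("x", "drink", [Spectrum(grid, np.ones(4))])
        with pytest.raises(SpectraError, match="duplicate"):
            Dataset([s, FoodSample("x", "drink", [Spectrum(grid, np.ones(4))])],
                    grid)
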
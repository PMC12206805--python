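import numpy as np
import pytest

from hyperleaf.cube_io import (
    CalibrationPair,
    HyperspectralCube,
    WavelengthAxis,
    band_index,
    calibrate_reflectance,
    crop_spectral,
    full_sensor_axis,
    read_envi,
    working_axis,
    write_envi,
)


class TestWavelengthAxis:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            WavelengthAxis([500.0, 500.0, 600.0])  # not strictly increasing
        with pytest.raises(ValueError):
            WavelengthAxis([600.0, 500.0])
        with pytest.raises(ValueError):
            WavelengthAxis([-1.0, 500.0])
        with pytest.raises(ValueError):
            WavelengthAxis([500.0, np.inf])

    def test_working_axis_has_761_bands(self):
        axis = working_axis()
        assert len(axis) == 761
        assert axis[0] == 400.0 and axis[-1] == 1000.0


class TestCalibration:
    @pytest.fixture
    def references(self, rng, small_axis):
        B = len(small_axis)
        white = rng.uniform(0.8, 1.0, size=(6, 5, B))
        dark = rng.uniform(0.0, 0.1, size=(6, 5, B))
        return CalibrationPair(white, dark)

    @pytest.mark.parametrize("target,expected", [("dark", 0.0), ("white", 1.0),
                                                 ("mid", 0.5)])
    def test_reference_identities(self, references, small_axis, target, expected):
        # raw = dark -> 0; raw = white -> 1; raw = midpoint -> 0.5
        raw_data = {
            "dark": references.dark,
            "white": references.white,
            "mid": (references.white + references.dark) / 2,
        }[target]
        raw = HyperspectralCube(raw_data.astype(np.float32), small_axis)
        out = calibrate_reflectance(raw, references)
        assert np.allclose(out.data, expected, atol=1e-5)
        assert out.axis is raw.axis

    def test_affine_invariance(self, rng, small_axis, references):
        raw = HyperspectralCube(
            rng.uniform(0.05, 0.9, size=(6, 5, len(small_axis))).astype(np.float32),
            small_axis,
        )
        base = calibrate_reflectance(raw, references)
        a, b = 2.5, 0.3
        scaled = calibrate_reflectance(
            HyperspectralCube(a * raw.data + b, small_axis),
            CalibrationPair(a * references.white + b, a * references.dark + b),
        )
        assert np.allclose(base.data, scaled.data, atol=1e-4)

    def test_row_profile_broadcasts_across_lines(self, rng, small_axis):
        B = len(small_axis)
        white = rng.uniform(0.8, 1.0, size=(5, B))  # per-band row profile
        dark = np.zeros((5, B))
        raw = HyperspectralCube(
            (0.5 * white)[None].repeat(6, axis=0).astype(np.float32), small_axis
        )
        out = calibrate_reflectance(raw, CalibrationPair(white, dark))
        assert np.allclose(out.data, 0.5, atol=1e-5)

    def test_degenerate_denominators_zeroed_and_bounded(self, rng, small_axis):
        B = len(small_axis)
        white = np.ones((10, 10, B))
        dark = np.zeros((10, 10, B))
        white[0, 0, 0] = 0.0  # one degenerate element, below the 1% limit
        raw = HyperspectralCube(np.full((10, 10, B), 0.5, np.float32), small_axis)
        out = calibrate_reflectance(raw, CalibrationPair(white, dark))
        assert out.data[0, 0, 0] == 0.0
        assert np.isfinite(out.data).all()

    def test_too_many_degenerate_denominators_is_an_error(self, small_axis):
        B = len(small_axis)
        white = np.zeros((6, 5, B))
        dark = np.zeros((6, 5, B))
        with pytest.raises(ValueError):
            CalibrationPair(white, dark)  # white > dark nowhere

    def test_band_count_mismatch_is_an_error(self, small_axis, rng):
        raw = HyperspectralCube(
            rng.uniform(size=(4, 4, len(small_axis))).astype(np.float32), small_axis
        )
        cal = CalibrationPair(np.ones((4, 4, 7)), np.zeros((4, 4, 7)))
        with pytest.raises(ValueError, match="band"):
            calibrate_reflectance(raw, cal)


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bsq", "bil"])
    def test_round_trip_bit_identical(self, tmp_path, rng, interleave):
        axis = WavelengthAxis([500.25, 600.5, 712.125])
        cube = HyperspectralCube(
            rng.normal(size=(4, 5, 3)).astype(np.float32), axis, interleave
        )
        hdr, _ = write_envi(cube, tmp_path / "cube.hdr")
        back = read_envi(hdr)
        assert np.array_equal(back.data, cube.data)
        assert np.array_equal(back.axis.values, cube.axis.values)

    def test_interleave_invariance(self, tmp_path, rng):
        axis = WavelengthAxis([500.0, 600.0, 700.0])
        data = rng.normal(size=(4, 5, 3)).astype(np.float32)
        a = read_envi(write_envi(HyperspectralCube(data, axis, "bsq"),
                                 tmp_path / "a.hdr")[0])
        b = read_envi(write_envi(HyperspectralCube(data, axis, "bil"),
                                 tmp_path / "b.hdr")[0])
        assert np.array_equal(a.data, b.data)

    def test_payload_is_exactly_float32(self, tmp_path):
        cube = HyperspectralCube(
            np.zeros((1, 1, 2), np.float32), WavelengthAxis([500.0, 600.0])
        )
        _, data_path = write_envi(cube, tmp_path / "tiny.hdr")
        assert data_path.stat().st_size == 8  # 2 x float32

    def test_band_count_wavelength_mismatch_is_an_error(self, tmp_path):
        cube = HyperspectralCube(
            np.zeros((2, 2, 3), np.float32), WavelengthAxis([5.0, 6.0, 7.0])
        )
        hdr, _ = write_envi(cube, tmp_path / "c.hdr")
        text = hdr.read_text().replace("bands = 3", "bands = 4")
        hdr.write_text(text)
        with pytest.raises(ValueError):
            read_envi(hdr)

    def test_missing_wavelength_field_is_an_error(self, tmp_path):
        cube = HyperspectralCube(
            np.zeros((2, 2, 3), np.float32), WavelengthAxis([5.0, 6.0, 7.0])
        )
        hdr, _ = write_envi(cube, tmp_path / "c.hdr")
        text = "\n".join(l for l in hdr.read_text().splitlines()
                         if not l.startswith("wavelength ="))
        hdr.write_text(text)
        with pytest.raises(ValueError, match="wavelength"):
            read_envi(hdr)

    def test_unsupported_interleave_is_an_error(self, tmp_path):
        cube = HyperspectralCube(
            np.zeros((2, 2, 3), np.float32), WavelengthAxis([5.0, 6.0, 7.0])
        )
        hdr, _ = write_envi(cube, tmp_path / "c.hdr")
        hdr.write_text(hdr.read_text().replace("interleave = bsq", "interleave = bip"))
        with pytest.raises(ValueError, match="interleave"):
            read_envi(hdr)


class TestBandIndex:
    def test_endpoints_and_nir_reference(self):
        axis = working_axis()
        assert band_index(axis, 400.0) == 0
        assert band_index(axis, 1000.0) == 760
        # brute-force argmin over all 761 points
        brute = int(np.argmin(np.abs(axis.values - 800.0)))
        assert band_index(axis, 800.0) == brute == 507

    def test_tie_resolves_to_lower_index(self):
        assert band_index(WavelengthAxis([500.0, 600.0]), 550.0) == 0

    def test_agrees_with_exhaustive_search_on_random_axes(self, rng):
        for _ in range(30):
            vals = np.sort(rng.uniform(350, 1050, size=rng.integers(5, 60)))
            vals += np.arange(vals.size) * 1e-6  # enforce strict monotonicity
            axis = WavelengthAxis(vals)
            target = rng.uniform(vals[0], vals[-1])
            brute = int(np.argmin(np.abs(vals - target)))
            assert band_index(axis, target) == brute

    def test_target_outside_range_is_an_error(self):
        with pytest.raises(ValueError):
            band_index(working_axis(), 389.0)
        with pytest.raises(ValueError):
            band_index(working_axis(), 1011.0)


class TestCropSpectral:
    def test_full_sensor_crop_matches_enumeration(self, rng):
        axis = full_sensor_axis()
        assert len(axis) == 995
        cube = HyperspectralCube(
            rng.uniform(size=(3, 3, 995)).astype(np.float32), axis
        )
        cropped = crop_spectral(cube, 400.0, 1000.0)
        expected = int(np.sum((axis.values >= 400.0) & (axis.values <= 1000.0)))
        assert cropped.n_bands == expected

    def test_identity_and_idempotence(self, random_cube):
        lo, hi = random_cube.axis[0], random_cube.axis[-1]
        once = crop_spectral(random_cube, lo, hi)
        assert np.array_equal(once.data, random_cube.data)
        twice = crop_spectral(crop_spectral(random_cube, 500, 900), 500, 900)
        assert np.array_equal(
            twice.data, crop_spectral(random_cube, 500, 900).data
        )

    def test_empty_result_is_an_error(self, random_cube):
        with pytest.raises(ValueError):
            crop_spectral(random_cube, 1100.0, 1200.0)
        with pytest.raises(ValueError):
            crop_spectral(random_cube, 900.0, 500.0)
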
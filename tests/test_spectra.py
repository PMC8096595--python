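import io

import numpy as np
import pandas as pd
import pytest

from ruecanopy.spectra import (
    DEFAULT_WINDOWS,
    SpectralRecord,
    SpectralSet,
    SpectraFormatError,
    SpectraValidationError,
    average_period,
    average_replicates,
    clean_spurious,
    read_spectra,
    select_windows,
    write_spectra,
)

from conftest import make_record


class TestRecordValidation:
    def test_non_monotone_wavelengths_rejected(self):
        with pytest.raises(SpectraValidationError, match="strictly increasing"):
            SpectralRecord(wavelengths=[400, 500, 500], reflectance=[0.1, 0.2, 0.3], plot_id="p")

    def test_out_of_range_wavelengths_rejected(self):
        with pytest.raises(SpectraValidationError, match="outside"):
            SpectralRecord(wavelengths=[300, 400], reflectance=[0.1, 0.2], plot_id="p")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(SpectraValidationError):
            SpectralRecord(wavelengths=[400, 500], reflectance=[0.1], plot_id="p")


class TestReadWrite:
    def test_wide_file_one_record_per_row(self, tmp_path):
        grid = np.arange(350, 2501)
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(0, 1, size=(3, grid.size)), columns=[str(w) for w in grid])
        df.insert(0, "plot_id", ["a", "b", "c"])
        path = tmp_path / "wide.csv"
        df.to_csv(path, index=False)
        s = read_spectra(path, layout="wide")
        assert len(s) == 3
        assert s.grid().size == grid.size

    def test_long_duplicate_wavelength_rejected(self):
        csv = "plot_id,wavelength_nm,reflectance\np1,500,0.1\np1,500,0.2\n"
        with pytest.raises(SpectraValidationError, match="duplicate wavelength"):
            read_spectra(io.StringIO(csv), layout="long")

    def test_missing_wavelength_column_is_format_error(self):
        csv = "plot_id,reflectance\np1,0.1\n"
        with pytest.raises(SpectraFormatError, match="wavelength_nm"):
            read_spectra(io.StringIO(csv), layout="long")

    @pytest.mark.parametrize("layout", ["long", "wide"])
    def test_round_trip(self, tmp_path, random_set, layout):
        path = tmp_path / f"rt.{layout}.csv"
        write_spectra(random_set, path, layout=layout)
        back = read_spectra(path, layout=layout)
        assert len(back) == len(random_set)
        orig = {r.key(): r for r in random_set}
        for r in back:
            np.testing.assert_allclose(r.reflectance, orig[r.key()].reflectance, atol=1e-12)

    def test_mixed_resolution_resampled_to_1nm(self):
        # 3 nm VNIR-style grid resampled by linear interpolation
        csv = "plot_id,wavelength_nm,reflectance\n" + "".join(
            f"p1,{w},{0.001 * w}\n" for w in range(350, 800, 3)
        )
        s = read_spectra(io.StringIO(csv), layout="long")
        grid = s.grid()
        assert np.all(np.diff(grid) == 1.0)
        # linear data stays exact under linear interpolation
        np.testing.assert_allclose(s.records[0].reflectance, 0.001 * grid, atol=1e-12)


class TestCleanSpurious:
    def test_clip_saturates_to_bounds(self):
        r = make_record(0.5)
        refl = r.reflectance.copy()
        refl[r.wavelengths == 1900] = -0.02
        s = SpectralSet([SpectralRecord(r.wavelengths, refl, plot_id="p1")])
        out = clean_spurious(s, mode="clip")
        assert out.records[0].reflectance[r.wavelengths == 1900] == 0.0

    def test_clean_identity_and_idempotence(self, random_set):
        once = clean_spurious(random_set, mode="clip")
        for a, b in zip(random_set, once):
            np.testing.assert_array_equal(a.reflectance, b.reflectance)
        twice = clean_spurious(once, mode="clip")
        for a, b in zip(once, twice):
            np.testing.assert_array_equal(a.reflectance, b.reflectance)

    def test_drop_masks_and_logs_count(self):
        r = make_record(0.5)
        refl = r.reflectance.copy()
        refl[:3] = 1.7
        s = SpectralSet([SpectralRecord(r.wavelengths, refl, plot_id="p1")])
        out = clean_spurious(s, mode="drop")
        assert np.isnan(out.records[0].reflectance[:3]).all()
        assert "3 band(s)" in out.provenance[-1]

    def test_mostly_spurious_record_warns(self):
        r = make_record(1.5)
        with pytest.warns(UserWarning, match="spurious"):
            clean_spurious(SpectralSet([r]), mode="clip")


class TestSelectWindows:
    def test_default_windows_band_count(self, flat_record):
        out = select_windows(SpectralSet([flat_record]), DEFAULT_WINDOWS)
        # [350, 1800] has 1451 integer-nm points, [1951, 2450] has 500
        assert out.records[0].n_bands == 1451 + 500

    def test_full_window_is_identity(self, flat_record):
        out = select_windows(SpectralSet([flat_record]), [(350, 2500)])
        assert out.records[0].n_bands == flat_record.n_bands

    def test_excluded_water_band_empty_result(self, flat_record):
        trimmed = select_windows(SpectralSet([flat_record]), DEFAULT_WINDOWS)
        with pytest.raises(SpectraValidationError, match="empty"):
            select_windows(trimmed, [(1801, 1950)])

    def test_band_count_matches_analytic_count(self, flat_record):
        windows = [(400.0, 412.0), (1000.0, 1003.5)]
        out = select_windows(SpectralSet([flat_record]), windows)
        grid = flat_record.wavelengths
        expect = sum(int(np.sum((grid >= a) & (grid <= b))) for a, b in windows)
        assert out.records[0].n_bands == expect

    def test_overlapping_windows_rejected(self, flat_record):
        with pytest.raises(ValueError, match="overlap"):
            select_windows(SpectralSet([flat_record]), [(350, 800), (700, 900)])


class TestAveraging:
    def test_identical_spectra_idempotent(self):
        recs = [make_record(0.4, plot_id="p1", stage_tag="s") for _ in range(6)]
        out = average_replicates(SpectralSet(recs))
        assert len(out) == 1
        np.testing.assert_allclose(out.records[0].reflectance, recs[0].reflectance, rtol=0, atol=1e-15)

    def test_mean_of_two(self):
        recs = [make_record(v, plot_id="p1") for v in (0.4, 0.6)]
        out = average_replicates(SpectralSet(recs))
        np.testing.assert_allclose(out.records[0].reflectance, 0.5)

    def test_matches_brute_force_mean(self, random_set):
        out = average_replicates(random_set, group_by=("plot_id",))
        by_plot = {}
        for r in random_set:
            by_plot.setdefault(r.plot_id, []).append(r.reflectance)
        for rec in out:
            np.testing.assert_allclose(
                rec.reflectance, np.mean(by_plot[rec.plot_id], axis=0), atol=1e-15
            )

    def test_period_average_and_exclusion(self):
        cal = {"d1": "vegetative", "d2": "vegetative", "mid": "excluded", "d3": "grain_filling"}
        recs = [
            make_record(0.1, plot_id="p1", stage_tag="d1"),
            make_record(0.3, plot_id="p1", stage_tag="d2"),
            make_record(0.9, plot_id="p1", stage_tag="mid"),
            make_record(0.2, plot_id="p1", stage_tag="d3"),
        ]
        out = average_period(SpectralSet(recs), cal)
        by_period = {r.period: r for r in out}
        assert set(by_period) == {"vegetative", "grain_filling"}
        np.testing.assert_allclose(by_period["vegetative"].reflectance, 0.2)
        np.testing.assert_allclose(by_period["grain_filling"].reflectance, 0.2)

    def test_unknown_stage_configurable(self):
        recs = [make_record(0.1, plot_id="p1", stage_tag="??")]
        assert len(average_period(SpectralSet(recs), {}, on_missing="skip")) == 0
        with pytest.raises(SpectraValidationError):
            average_period(SpectralSet(recs), {}, on_missing="error")

    def test_two_step_equals_grand_mean_when_balanced(self):
        # 2 replicates x 2 vegetative dates, balanced: replicate-then-period
        # averaging must equal the one-step grand mean per band
        rng = np.random.default_rng(1)
        grid = np.arange(350.0, 2501.0)
        recs = []
        for rep in range(2):
            for date in ("d1", "d2"):
                recs.append(
                    SpectralRecord(
                        grid,
                        np.clip(rng.uniform(0.1, 0.9) + 0.01 * rng.standard_normal(grid.size), 0, 1),
                        plot_id="p1",
                        stage_tag=date,
                    )
                )
        s = SpectralSet(recs)
        two_step = average_period(
            average_replicates(s, group_by=("plot_id", "stage_tag")),
            {"d1": "vegetative", "d2": "vegetative"},
        )
        grand = np.mean([r.reflectance for r in recs], axis=0)
        np.testing.assert_allclose(two_step.records[0].reflectance, grand, atol=1e-12)

    def test_provenance_appends_per_transformation(self, random_set):
        out = average_replicates(clean_spurious(random_set), group_by=("plot_id",))
        assert len(out.provenance) == 2
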
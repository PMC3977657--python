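"""Per-test behaviour of the validation registry on constructed bundles."""

import numpy as np
import pytest

from cdqc.checks import (
    REGISTRY,
    Status,
    ValidationConfig,
    run_all,
    run_test,
)
from cdqc.io import UploadBundle
from cdqc.spectra import SampleMetadata, SpectralType, SpectralUnit, Spectrum
from cdqc.synth import make_band_spectrum

GRID = np.arange(175.0, 280.0 + 0.5, 1.0)
DEPS = SpectralUnit.DELTA_EPSILON
MDEG = SpectralUnit.MILLIDEGREES


def final_bundle(values, grid=GRID, **meta):
    b = UploadBundle(metadata=SampleMetadata(**meta))
    b.add(Spectrum(grid, values, DEPS, SpectralType.FINAL_PROCESSED))
    return b


def status_of(test_id, bundle, refs, config=None):
    return run_test(test_id, bundle, refs, config).status


class TestCompleteness:
    def test_missing_wavelength_reported_with_gap(self, refs):
        grid = np.arange(190.0, 241.0)
        keep = grid != 215.0
        b = final_bundle(np.sin(grid[keep] / 9.0), grid=grid[keep])
        r = run_test("missing_wavelengths", b, refs)
        assert r.status is Status.FAIL
        assert r.details["gaps"][0]["between_nm"] == [214.0, 216.0]

    @pytest.mark.parametrize("step", [1.0, 0.5])
    def test_any_regular_interval_passes(self, refs, step):
        grid = np.arange(190.0, 240.0 + step / 2, step)
        b = final_bundle(np.sin(grid / 9.0), grid=grid)
        assert status_of("missing_wavelengths", b, refs) is Status.PASS

    @pytest.mark.parametrize(
        "lo, hi, expected",
        [
            (190.0, 280.0, Status.PASS),  # superset of the minimal standard
            (205.0, 255.0, Status.PASS),  # exactly the minimal standard
            (210.0, 250.0, Status.FLAG),  # narrower than the minimal standard
        ],
    )
    def test_wavelength_range_minimal_standard(self, refs, lo, hi, expected):
        grid = np.arange(lo, hi + 0.5, 1.0)
        b = final_bundle(np.zeros(grid.size), grid=grid)
        assert status_of("wavelength_range", b, refs) is expected

    def test_interval_larger_than_standard_fails(self, refs):
        grid = np.arange(190.0, 241.0, 2.0)
        b = final_bundle(np.zeros(grid.size), grid=grid, stated_interval_nm=2.0)
        assert status_of("wavelength_interval", b, refs) is Status.FAIL

    def test_subnm_interval_with_coarser_calibration_passes(self, refs):
        grid = np.arange(190.0, 240.0 + 0.25, 0.5)
        b = final_bundle(np.zeros(grid.size), grid=grid, stated_interval_nm=0.5)
        cal_grid = np.arange(170.0, 340.0 + 0.5, 1.0)  # calibration is exempt
        b.add(
            make_band_spectrum(
                [(192.5, 6.0, -33.4), (290.5, 7.0, 16.7)],
                cal_grid,
                unit=MDEG,
                spectral_type=SpectralType.CALIBRATION,
            )
        )
        assert status_of("wavelength_interval", b, refs) is Status.PASS

    def test_stated_interval_mismatch_fails(self, refs):
        grid = np.arange(190.0, 241.0)
        b = final_bundle(np.zeros(grid.size), grid=grid, stated_interval_nm=0.5)
        assert status_of("wavelength_interval", b, refs) is Status.FAIL


class TestMetadataConsistency:
    def test_sequence_with_tag_stripped_matches(self, refs):
        b = UploadBundle(
            metadata=SampleMetadata(sequence="HHHHHHACDEFG", expression_tags=["HHHHHH"]),
            reference_sequences=["ACDEFG"],
        )
        assert status_of("uniprot_sequence", b, refs) is Status.PASS

    def test_substitution_flagged_with_position(self, refs):
        b = UploadBundle(
            metadata=SampleMetadata(sequence="ACDEFG"),
            reference_sequences=["ACDKFG"],
        )
        r = run_test("uniprot_sequence", b, refs)
        assert r.status is Status.FLAG
        assert r.details["first_mismatch_position"] == 4

    def test_no_reference_is_unavailable(self, refs):
        b = UploadBundle(metadata=SampleMetadata(sequence="ACDEFG"))
        assert status_of("uniprot_sequence", b, refs) is Status.UNAVAILABLE

    @pytest.mark.parametrize("n, expected", [(6, Status.PASS), (5, Status.FAIL)])
    def test_residue_count(self, refs, n, expected):
        b = UploadBundle(metadata=SampleMetadata(sequence="ACDEFG", n_residues=n))
        assert status_of("residue_count", b, refs) is expected

    def test_residue_count_without_sequence_unavailable(self, refs):
        b = UploadBundle(metadata=SampleMetadata(n_residues=6))
        assert status_of("residue_count", b, refs) is Status.UNAVAILABLE

    @pytest.mark.parametrize(
        "stated, expected",
        [
            (303.3, Status.PASS),  # matches the sequence-derived mass
            (303.27 * 1.001, Status.PASS),  # within 0.5% tolerance
            (606.5, Status.FAIL),  # double the computed mass
        ],
    )
    def test_molecular_weight(self, refs, stated, expected):
        b = UploadBundle(metadata=SampleMetadata(sequence="GGGGG", molecular_weight_da=stated))
        assert status_of("molecular_weight", b, refs) is expected

    @pytest.mark.parametrize(
        "stated, expected",
        [(100.0, Status.PASS), (120.0, Status.FAIL)],
    )
    def test_mean_residue_weight_uses_n_minus_one(self, refs, stated, expected):
        b = UploadBundle(
            metadata=SampleMetadata(
                molecular_weight_da=10000.0, n_residues=101, mean_residue_weight_da=stated
            )
        )
        assert status_of("mean_residue_weight", b, refs) is expected

    def test_mean_residue_weight_without_count_unavailable(self, refs):
        b = UploadBundle(metadata=SampleMetadata(molecular_weight_da=1e4, mean_residue_weight_da=100.0))
        assert status_of("mean_residue_weight", b, refs) is Status.UNAVAILABLE

    @pytest.mark.parametrize(
        "t, expected",
        [
            (25.0, Status.PASS),
            (120.0, Status.FAIL),  # above the aqueous maximum
            (-10.0, Status.PASS),  # boundary is inclusive
            (99.0, Status.PASS),
            (-10.5, Status.FAIL),
        ],
    )
    def test_temperature_range(self, refs, t, expected):
        b = UploadBundle(metadata=SampleMetadata(temperature_c=t))
        assert status_of("temperature", b, refs) is expected


class TestSpectralConsistency:
    def test_mislabelled_units_fail_final_recompute(self, refs, clean_session):
        b = clean_session.to_bundle()
        f = b.first(SpectralType.FINAL_PROCESSED)
        wrong = Spectrum(f.wavelengths_nm, f.values * 3298.0, DEPS, SpectralType.FINAL_PROCESSED)
        b.spectra[SpectralType.FINAL_PROCESSED] = [wrong]
        assert status_of("final_spectrum", b, refs) is Status.FAIL

    def test_final_without_net_unavailable(self, refs):
        b = final_bundle(np.sin(GRID / 9.0))
        assert status_of("final_spectrum", b, refs) is Status.UNAVAILABLE

    def test_partial_average_flagged(self, refs):
        # scans whose last repeat drifted; averaging only 2 of 3 scans is a
        # visible inconsistency
        shape = make_band_spectrum([(210.0, 6.0, 100.0)], GRID).values
        b = UploadBundle()
        for i, scale in enumerate((1.0, 1.0, 0.7)):
            b.add(Spectrum(GRID, scale * shape, MDEG, SpectralType.RAW_SAMPLE, scan_index=i + 1))
        partial = (shape + shape) / 2.0
        b.add(Spectrum(GRID, partial, MDEG, SpectralType.AVERAGE_SAMPLE))
        assert status_of("average_sample", b, refs) is Status.FLAG
        true_mean = (2.0 + 0.7) / 3.0 * shape
        b.spectra[SpectralType.AVERAGE_SAMPLE] = [
            Spectrum(GRID, true_mean, MDEG, SpectralType.AVERAGE_SAMPLE)
        ]
        assert status_of("average_sample", b, refs) is Status.PASS

    def test_average_without_raws_unavailable(self, refs, clean_session):
        b = clean_session.to_bundle()
        b.spectra.pop(SpectralType.RAW_SAMPLE)
        assert status_of("average_sample", b, refs) is Status.UNAVAILABLE

    @pytest.mark.parametrize(
        "truncation, expected", [(0.06, Status.FAIL), (0.03, Status.PASS), (0.0, Status.PASS)]
    )
    def test_excess_smoothing_truncation(self, refs, truncation, expected):
        shape = make_band_spectrum([(210.0, 6.0, 100.0)], GRID).values
        b = UploadBundle()
        b.add(Spectrum(GRID, shape, MDEG, SpectralType.AVERAGE_SAMPLE))
        b.add(Spectrum(GRID, np.zeros(GRID.size), MDEG, SpectralType.AVERAGE_BASELINE))
        b.add(Spectrum(GRID, (1 - truncation) * shape, MDEG, SpectralType.NET_SMOOTHED))
        assert status_of("excess_smoothing", b, refs) is expected


class TestQuality:
    @pytest.mark.parametrize(
        "peak, expected",
        [(2.0, Status.PASS), (0.5, Status.FAIL), (1.0, Status.PASS)],  # "at least 1.0" inclusive
    )
    def test_minimum_peak_size(self, refs, peak, expected):
        v = make_band_spectrum([(222.0, 6.0, -1.0)], GRID).values * peak
        assert status_of("minimum_peak_size", final_bundle(v), refs) is expected

    def test_magnitude_envelope(self, refs):
        helix = make_band_spectrum(
            [(192.0, 5.0, 11.0), (208.0, 4.5, -6.5), (222.0, 4.5, -6.0)], GRID
        ).values
        assert status_of("maximum_magnitude", final_bundle(helix), refs) is Status.PASS
        assert status_of("maximum_magnitude", final_bundle(10 * helix), refs) is Status.FLAG

    def test_excursion_beyond_245nm_not_tested(self, refs):
        v = make_band_spectrum([(222.0, 6.0, -5.0), (260.0, 2.0, 30.0)], GRID).values
        r = run_test("maximum_magnitude", final_bundle(v), refs)
        assert all(w <= 245.0 for w in r.details.get("wavelengths_nm", []))

    @pytest.mark.parametrize(
        "points, value, expected",
        [
            ((), 0.0, Status.PASS),  # quiet region
            ((262.0, 263.0), 0.3, Status.FLAG),  # two successive beyond 0.25
            ((262.0,), 0.3, Status.PASS),  # one isolated excursion
        ],
    )
    def test_noise_region(self, refs, points, value, expected):
        v = make_band_spectrum([(210.0, 8.0, 5.0)], GRID).values.copy()
        for w in points:
            v[GRID == w] = value
        assert status_of("noise_high_wavelength", final_bundle(v), refs) is expected

    def test_noise_fallback_region_when_no_data_above_260(self, refs):
        grid = np.arange(190.0, 260.0 + 0.5, 1.0)
        v = make_band_spectrum([(210.0, 8.0, 5.0)], grid).values.copy()
        v[(grid == 256.0) | (grid == 257.0)] = 0.4
        assert status_of("noise_high_wavelength", final_bundle(v, grid=grid), refs) is Status.FLAG

    @pytest.mark.parametrize(
        "ratio, expected",
        [(2.0, Status.PASS), (2.25, Status.FLAG), (2.1, Status.PASS)],
    )
    def test_calibration_ratio_window(self, refs, ratio, expected):
        cal_grid = np.arange(170.0, 340.0 + 0.5, 1.0)
        b = UploadBundle()
        b.add(
            make_band_spectrum(
                [(192.5, 6.0, -ratio * 16.7), (290.5, 7.0, 16.7)],
                cal_grid,
                unit=MDEG,
                spectral_type=SpectralType.CALIBRATION,
            )
        )
        assert status_of("calibration_ratio", b, refs) is expected

    def test_calibration_compared_with_stated_ratio(self, refs):
        cal_grid = np.arange(170.0, 340.0 + 0.5, 1.0)
        b = UploadBundle(metadata=SampleMetadata(calibration_peak_ratio=1.95))
        b.add(
            make_band_spectrum(
                [(192.5, 6.0, -2.05 * 16.7), (290.5, 7.0, 16.7)],
                cal_grid,
                unit=MDEG,
                spectral_type=SpectralType.CALIBRATION,
            )
        )
        # within 10% of 2.0 but inconsistent with the stated 1.95
        assert status_of("calibration_ratio", b, refs) is Status.FLAG

    def ht_bundle(self, peak_volts, instrument="synthetic-cd-1"):
        v = np.minimum(peak_volts, 250.0 + (peak_volts - 250.0) * np.exp(-(GRID - 175.0) / 25.0))
        b = UploadBundle(metadata=SampleMetadata(instrument_name=instrument))
        b.add(Spectrum(GRID, v, SpectralUnit.INSTRUMENT_VOLTS, SpectralType.HT))
        return b

    @pytest.mark.parametrize(
        "peak, expected",
        [(500.0, Status.PASS), (650.0, Status.FAIL), (595.0, Status.FLAG)],
    )
    def test_max_ht_voltage_against_limit(self, refs, peak, expected):
        assert status_of("max_ht_voltage", self.ht_bundle(peak), refs) is expected

    def test_unknown_instrument_unavailable(self, refs):
        b = self.ht_bundle(500.0, instrument="mystery-machine")
        assert status_of("max_ht_voltage", b, refs) is Status.UNAVAILABLE

    @pytest.mark.parametrize(
        "c, l, expected",
        [(1.0, 0.05, Status.PASS), (10.0, 1.0, Status.FLAG)],
    )
    def test_concentration_pathlength_window(self, refs, c, l, expected):
        b = UploadBundle(metadata=SampleMetadata(concentration_mg_ml=c, pathlength_cm=l))
        assert status_of("concentration_pathlength", b, refs) is expected

    def test_pathlength_absent_unavailable(self, refs):
        b = UploadBundle(metadata=SampleMetadata(concentration_mg_ml=1.0))
        assert status_of("concentration_pathlength", b, refs) is Status.UNAVAILABLE

    @pytest.mark.parametrize("n_equal, expected", [(5, Status.FAIL), (4, Status.PASS)])
    def test_flat_top_boundary(self, refs, n_equal, expected):
        v = make_band_spectrum([(215.0, 6.0, 5.0)], GRID).values.copy()
        i = int(np.argmin(np.abs(GRID - 215.0)))
        lo = i - (n_equal - 1) // 2
        v[lo : lo + n_equal] = v[i]
        assert status_of("flat_topped_peaks", final_bundle(v), refs) is expected

    def test_strictly_varying_gaussian_passes(self, refs):
        v = make_band_spectrum([(215.0, 6.0, 5.0)], GRID).values
        assert status_of("flat_topped_peaks", final_bundle(v), refs) is Status.PASS

    @pytest.mark.parametrize(
        "sigma, expected",
        [
            (15.0 / 2.3548, Status.PASS),  # FWHM 15 nm
            (8.0 / 2.3548, Status.FLAG),  # FWHM 8 nm
        ],
    )
    def test_feature_width(self, refs, sigma, expected):
        v = make_band_spectrum([(222.0, sigma, -5.0)], GRID).values
        assert status_of("feature_width", final_bundle(v), refs) is expected

    def test_canonical_peaks_pass_catalogue(self, refs):
        v = make_band_spectrum(
            [(192.0, 5.0, 11.0), (208.0, 4.5, -6.5), (222.0, 4.5, -6.0)], GRID
        ).values
        assert status_of("peak_locations", final_bundle(v), refs) is Status.PASS

    def test_peak_outside_windows_flagged_with_location(self, refs):
        v = make_band_spectrum([(222.0, 6.0, -5.0), (250.0, 5.0, 2.0)], GRID).values
        r = run_test("peak_locations", final_bundle(v), refs)
        assert r.status is Status.FLAG
        assert 250.0 in [p["location_nm"] for p in r.details["peaks"]]

    def test_no_detectable_peaks_passes_with_note(self, refs):
        b = final_bundle(np.zeros(GRID.size))
        assert status_of("peak_locations", b, refs) is Status.PASS

    def repeats_bundle(self, offsets, grid_step=0.05):
        grid = np.arange(200.0, 240.0 + grid_step / 2, grid_step)
        b = UploadBundle()
        for i, off in enumerate(offsets):
            v = make_band_spectrum([(222.0 + off, 5.0, -50.0)], grid).values
            b.add(Spectrum(grid, v, MDEG, SpectralType.RAW_SAMPLE, scan_index=i + 1))
        return b

    def test_stable_peaks_pass_sd(self, refs):
        assert status_of("peak_location_sd", self.repeats_bundle([0, 0, 0]), refs) is Status.PASS

    def test_spread_locations_flagged(self, refs):
        # locations 220, 222, 226 -> sample SD ~3.06 nm
        r = run_test("peak_location_sd", self.repeats_bundle([-2.0, 0.0, 4.0]), refs)
        assert r.status is Status.FLAG
        assert r.details["peaks"][0]["sd_nm"] == pytest.approx(3.055, abs=0.05)

    def test_single_repeat_unavailable(self, refs):
        assert status_of("peak_location_sd", self.repeats_bundle([0.0]), refs) is Status.UNAVAILABLE

    def gradient_bundle(self, rise):
        v = np.full(GRID.size, 300.0)
        v[GRID <= 180.0] = 600.0
        ramp = (GRID >= 240.0) & (GRID <= 260.0)
        v[ramp] = 300.0 + rise * 300.0 * (GRID[ramp] - 240.0) / 20.0
        v[GRID > 260.0] = 300.0 + rise * 300.0
        b = UploadBundle(metadata=SampleMetadata(instrument_name="synthetic-cd-1"))
        b.add(Spectrum(GRID, v, SpectralUnit.INSTRUMENT_VOLTS, SpectralType.HT))
        return b

    @pytest.mark.parametrize(
        "rise, expected",
        [(0.0, Status.PASS), (0.10, Status.FLAG), (0.03, Status.PASS)],
    )
    def test_ht_gradient(self, refs, rise, expected):
        assert status_of("ht_gradient_240_260", self.gradient_bundle(rise), refs) is expected

    def sd_bundle(self, mean, sd):
        base = np.full(GRID.size, float(mean))
        second = base.copy()
        second[(GRID >= 230.0) & (GRID <= 234.0)] += sd * np.sqrt(2.0)
        b = UploadBundle()
        for i, v in enumerate((base, second)):
            b.add(Spectrum(GRID, v, MDEG, SpectralType.RAW_SAMPLE, scan_index=i + 1))
        return b

    def test_identical_repeats_pass(self, refs):
        assert status_of("repeat_sd", self.sd_bundle(10.0, 0.0), refs) is Status.PASS

    def test_both_criteria_exceeded_flags(self, refs):
        # SD 1.0 mdeg on a 10 mdeg mean: 10% of value and above 0.6 mdeg
        assert status_of("repeat_sd", self.sd_bundle(10.0, 1.0), refs) is Status.FLAG

    def test_small_relative_sd_passes(self, refs):
        # SD 1.0 mdeg on a 100 mdeg mean is only 1%
        assert status_of("repeat_sd", self.sd_bundle(100.0, 1.0), refs) is Status.PASS

    def test_projection_of_basis_combination_passes(self, refs):
        y = np.array([5.0, -2.0, 1.0, 0.5, 0.2]) @ refs.basis.components
        b = final_bundle(y, grid=refs.basis.wavelengths_nm, protein_class="soluble")
        assert status_of("projection", b, refs) is Status.PASS

    def test_projection_of_noise_flags(self, refs):
        rng = np.random.default_rng(9)
        b = final_bundle(rng.normal(size=GRID.size), protein_class="soluble")
        r = run_test("projection", b, refs)
        assert r.status is Status.FLAG
        assert r.details["residual_fraction"] > 0.5

    def test_membrane_limit_is_looser(self, refs):
        y = refs.basis.components[0].copy()
        ortho = np.zeros_like(y)
        ortho[::2] = 1.0
        ortho -= refs.basis.components.T @ (refs.basis.components @ ortho)
        mix = y + 0.07 * np.linalg.norm(y) * ortho / np.linalg.norm(ortho)
        grid = refs.basis.wavelengths_nm
        soluble = final_bundle(mix, grid=grid, protein_class="soluble")
        membrane = final_bundle(mix, grid=grid, protein_class="membrane")
        assert status_of("projection", soluble, refs) is Status.FLAG
        assert status_of("projection", membrane, refs) is Status.PASS


class TestRunner:
    def test_registry_has_25_tests_with_status_codes(self):
        assert len(REGISTRY) == 25
        categories = {t.category for t in REGISTRY}
        assert categories == {
            "completeness",
            "consistency_metadata",
            "consistency_spectral",
            "quality",
        }
        assert sum(t.category == "quality" for t in REGISTRY) == 13

    def test_minimal_bundle_runs_all_tests(self, refs):
        b = final_bundle(make_band_spectrum([(222.0, 6.0, -5.0)], GRID).values)
        report = run_all(b, refs)
        assert len(report.results) == 25
        by_id = {r.test_id: r.status for r in report.results}
        assert by_id["residue_count"] is Status.UNAVAILABLE
        assert by_id["repeat_sd"] is Status.UNAVAILABLE
        assert by_id["minimum_peak_size"] is Status.PASS

    def test_status_discipline_on_varied_bundles(self, refs, clean_session):
        from cdqc.synth import DEFECT_TARGETS, inject_defect

        flag_only = {t.test_id for t in REGISTRY if t.statuses == ("flag",)}
        fail_only = {t.test_id for t in REGISTRY if t.statuses == ("fail",)}
        bundles = [clean_session.to_bundle()] + [
            inject_defect(clean_session, d).to_bundle() for d in DEFECT_TARGETS
        ]
        for b in bundles:
            for r in run_all(b, refs).results:
                if r.test_id in flag_only:
                    assert r.status is not Status.FAIL
                if r.test_id in fail_only:
                    assert r.status is not Status.FLAG

    def test_failures_do_not_abort_other_tests(self, refs, clean_session):
        from cdqc.synth import inject_defect

        report = run_all(inject_defect(clean_session, "bad_temperature").to_bundle(), refs)
        assert len(report.results) == 25
        assert sum(r.status is Status.FAIL for r in report.results) == 1
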
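"""One-parameter defect families for locating decision boundaries.

Each probe builds a minimal bundle whose defect magnitude is a single
number ``x``, runs exactly one validation test on it, and reports whether
the test tripped (flag or fail).  :func:`bisect_boundary` then locates the
magnitude at which the outcome changes, which should coincide with the
test's printed decision threshold up to the probe's grid resolution.
These families drive both the threshold checks in the test suite and the
acceptance script.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .checks import ValidationConfig, run_test
from .io import UploadBundle
from .reference import ReferenceBundle, build_default_references
from .spectra import SampleMetadata, SpectralType, SpectralUnit, Spectrum
from .synth import make_band_spectrum

_GRID = np.arange(175.0, 280.0 + 0.5, 1.0)


def _tripped(test_id: str, bundle: UploadBundle, refs: ReferenceBundle) -> bool:
    status = run_test(test_id, bundle, refs, ValidationConfig()).status.value
    if status == "unavailable":
        raise RuntimeError(f"probe for {test_id} produced an unavailable result")
    return status in ("flag", "fail")


def bisect_boundary(
    trips: Callable[[float], bool], lo: float, hi: float, tol: float = 1e-4
) -> float:
    """Bisect the trip boundary of a monotone defect family on [lo, hi]."""
    t_lo, t_hi = trips(lo), trips(hi)
    if t_lo == t_hi:
        raise ValueError(f"family does not change outcome on [{lo}, {hi}]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if trips(mid) == t_hi:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _final_only(values: np.ndarray, grid: np.ndarray = _GRID) -> UploadBundle:
    b = UploadBundle()
    b.add(Spectrum(grid, values, SpectralUnit.DELTA_EPSILON, SpectralType.FINAL_PROCESSED))
    return b


# -- families ---------------------------------------------------------------

def minimum_peak_size_trips(refs: ReferenceBundle) -> Callable[[float], bool]:
    """x = magnitude of the highest peak (delta epsilon)."""
    shape = make_band_spectrum([(222.0, 6.0, -1.0)], _GRID).values

    def trips(x: float) -> bool:
        return _tripped("minimum_peak_size", _final_only(x * shape), refs)

    return trips


def noise_trips(refs: ReferenceBundle, n_successive: int = 2) -> Callable[[float], bool]:
    """x = magnitude (delta epsilon) of ``n_successive`` points at 262 nm."""

    def trips(x: float) -> bool:
        v = make_band_spectrum([(210.0, 8.0, 5.0)], _GRID).values.copy()
        mask = (_GRID >= 262.0) & (_GRID < 262.0 + n_successive)
        v[mask] = x
        return _tripped("noise_high_wavelength", _final_only(v), refs)

    return trips


def calibration_ratio_trips(refs: ReferenceBundle) -> Callable[[float], bool]:
    """x = two-band magnitude ratio of a CSA-like calibration spectrum."""
    grid = np.arange(170.0, 340.0 + 0.5, 1.0)

    def trips(x: float) -> bool:
        cal = make_band_spectrum(
            [(192.5, 6.0, -x * 16.7), (290.5, 7.0, 16.7)],
            grid,
            unit=SpectralUnit.MILLIDEGREES,
            spectral_type=SpectralType.CALIBRATION,
        )
        b = UploadBundle()
        b.add(cal)
        return _tripped("calibration_ratio", b, refs)

    return trips


def feature_width_trips(refs: ReferenceBundle) -> Callable[[float], bool]:
    """x = Gaussian sigma (nm) of a single negative band; FWHM = 2.3548 x."""

    def trips(x: float) -> bool:
        v = make_band_spectrum([(222.0, x, -5.0)], _GRID).values
        return _tripped("feature_width", _final_only(v), refs)

    return trips


def peak_location_sd_trips(refs: ReferenceBundle) -> Callable[[float], bool]:
    """x = peak-location spread: repeats peak at 222-x, 222, 222+x (SD = x)."""
    grid = np.arange(200.0, 240.0 + 0.01, 0.05)

    def trips(x: float) -> bool:
        b = UploadBundle()
        for i, off in enumerate((-x, 0.0, x)):
            v = make_band_spectrum([(222.0 + off, 5.0, -50.0)], grid).values
            b.add(Spectrum(grid, v, SpectralUnit.MILLIDEGREES, SpectralType.RAW_SAMPLE, scan_index=i + 1))
        return _tripped("peak_location_sd", b, refs)

    return trips


def ht_gradient_trips(refs: ReferenceBundle) -> Callable[[float], bool]:
    """x = normalized HT rise across 240-260 nm (span fixed at 300 V)."""

    def trips(x: float) -> bool:
        v = np.full(_GRID.size, 300.0)
        v[_GRID <= 180.0] = 600.0  # sets the min-max normalization span
        ramp = (_GRID >= 240.0) & (_GRID <= 260.0)
        v[ramp] = 300.0 + x * 300.0 * (_GRID[ramp] - 240.0) / 20.0
        v[_GRID > 260.0] = 300.0 + x * 300.0
        b = UploadBundle(metadata=SampleMetadata(instrument_name="synthetic-cd-1"))
        b.add(Spectrum(_GRID, v, SpectralUnit.INSTRUMENT_VOLTS, SpectralType.HT))
        return _tripped("ht_gradient_240_260", b, refs)

    return trips


def repeat_sd_trips(refs: ReferenceBundle) -> Callable[[float], bool]:
    """x = across-repeat SD in millidegrees at five consecutive wavelengths.

    The mean there is 5 mdeg, so the 5%-of-value criterion is met once
    x > 0.25 and the millidegree criterion becomes the active boundary.
    """

    def trips(x: float) -> bool:
        base = np.full(_GRID.size, 5.0)
        second = base.copy()
        bump = (_GRID >= 230.0) & (_GRID <= 234.0)
        second[bump] += x * np.sqrt(2.0)  # SD of {a, a + x*sqrt(2)} is x
        b = UploadBundle()
        for i, v in enumerate((base, second)):
            b.add(Spectrum(_GRID, v, SpectralUnit.MILLIDEGREES, SpectralType.RAW_SAMPLE, scan_index=i + 1))
        return _tripped("repeat_sd", b, refs)

    return trips


def excess_smoothing_trips(refs: ReferenceBundle) -> Callable[[float], bool]:
    """x = fractional truncation of the peak magnitude by smoothing."""
    shape = make_band_spectrum([(210.0, 6.0, 100.0)], _GRID).values

    def trips(x: float) -> bool:
        b = UploadBundle()
        b.add(Spectrum(_GRID, shape, SpectralUnit.MILLIDEGREES, SpectralType.AVERAGE_SAMPLE))
        b.add(Spectrum(_GRID, np.zeros_like(shape), SpectralUnit.MILLIDEGREES, SpectralType.AVERAGE_BASELINE))
        b.add(Spectrum(_GRID, (1.0 - x) * shape, SpectralUnit.MILLIDEGREES, SpectralType.NET_SMOOTHED))
        return _tripped("excess_smoothing", b, refs)

    return trips


def temperature_trips(refs: ReferenceBundle) -> Callable[[float], bool]:
    """x = stated experimental temperature in degC."""

    def trips(x: float) -> bool:
        return _tripped(
            "temperature", UploadBundle(metadata=SampleMetadata(temperature_c=x)), refs
        )

    return trips


def wavelength_range_low_trips(refs: ReferenceBundle) -> Callable[[float], bool]:
    """x = lowest wavelength of a spectrum reaching up to 260 nm."""

    def trips(x: float) -> bool:
        grid = np.arange(x, 260.0 + 0.5, 1.0)
        v = make_band_spectrum([(222.0, 6.0, -5.0)], grid).values
        return _tripped("wavelength_range", _final_only(v, grid), refs)

    return trips


def wavelength_range_high_trips(refs: ReferenceBundle) -> Callable[[float], bool]:
    """x = highest wavelength of a spectrum starting at 200 nm."""

    def trips(x: float) -> bool:
        grid = np.arange(200.0, x + 1e-9, 1.0)  # top grid point is floor(x)
        v = make_band_spectrum([(222.0, 6.0, -5.0)], grid).values
        return _tripped("wavelength_range", _final_only(v, grid), refs)

    return trips


def flat_top_trips(refs: ReferenceBundle) -> Callable[[int], bool]:
    """x = number of equal successive points at a peak crest (integer)."""
    shape = make_band_spectrum([(215.0, 6.0, 5.0)], _GRID).values

    def trips(x: int) -> bool:
        v = shape.copy()
        i = int(np.argmin(np.abs(_GRID - 215.0)))
        lo = i - (x - 1) // 2
        v[lo : lo + x] = v[i]
        return _tripped("flat_topped_peaks", _final_only(v), refs)

    return trips


def measure_boundaries(refs: ReferenceBundle | None = None, tol: float = 1e-3) -> dict[str, float]:
    """Bisect every threshold family; returns measured boundary values.

    Keys are named after the quantity measured; values are on the scale the
    decision thresholds are stated in (delta epsilon, nm, mdeg, degC, or a
    dimensionless fraction).
    """
    refs = refs or build_default_references(seed=0)
    sigma_boundary = bisect_boundary(feature_width_trips(refs), 3.0, 6.0, tol)
    return {
        "minimum_peak_size_deps": bisect_boundary(minimum_peak_size_trips(refs), 0.5, 2.0, tol),
        "noise_limit_deps": bisect_boundary(noise_trips(refs), 0.05, 0.6, tol),
        "calibration_ratio_upper": bisect_boundary(calibration_ratio_trips(refs), 2.0, 2.6, tol),
        "calibration_ratio_lower": bisect_boundary(calibration_ratio_trips(refs), 1.4, 2.0, tol),
        "feature_width_fwhm_nm": 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_boundary,
        "peak_location_sd_nm": bisect_boundary(peak_location_sd_trips(refs), 0.5, 2.5, tol),
        "ht_gradient_rise": bisect_boundary(ht_gradient_trips(refs), 0.0, 0.2, tol * 0.1),
        "repeat_sd_mdeg": bisect_boundary(repeat_sd_trips(refs), 0.3, 1.2, tol),
        "excess_smoothing_fraction": bisect_boundary(excess_smoothing_trips(refs), 0.0, 0.2, tol * 0.1),
        "temperature_high_c": bisect_boundary(temperature_trips(refs), 50.0, 150.0, tol),
        "temperature_low_c": bisect_boundary(temperature_trips(refs), -50.0, 0.0, tol),
        "wavelength_range_low_nm": bisect_boundary(wavelength_range_low_trips(refs), 195.0, 215.0, tol),
        "wavelength_range_high_nm": bisect_boundary(wavelength_range_high_trips(refs), 245.0, 265.0, tol),
        "flat_top_max_passing_points": float(
            max(k for k in range(1, 9) if not flat_top_trips(refs)(k))
        ),
    }
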
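"""Core domain types and numerical operations for CD spectra.

A circular dichroism (CD) measurement session produces several kinds of
wavelength-indexed traces: repeated raw sample and baseline scans in
instrument units (millidegrees of ellipticity), the photomultiplier high
tension (HT) voltage recorded alongside them, averaged and
baseline-subtracted spectra, and a final processed spectrum converted to a
molar unit (usually delta epsilon).  This module defines the
:class:`Spectrum` container those traces share and the numerical
operations — averaging, baseline subtraction, smoothing, peak detection,
full-width-at-half-maximum measurement, unit conversion and sequence mass
arithmetic — that the validation tests build on.

Unit conversion follows the standard chain

    MRE  = theta_mdeg * MRW / (10 * pathlength_cm * concentration_mg_ml)
    dEps = MRE / 3298
    theta_mdeg = 32980 * dA

where MRW is the mean residue weight in daltons, MRE the mean residue
ellipticity in deg cm^2 dmol^-1 and dA the differential absorbance.
Molar ellipticity uses the whole-molecule molecular weight in place of MRW.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, savgol_filter

from .errors import (
    DataUnavailableError,
    IncompatibleSpectraError,
    InvalidMetadataError,
    InvalidParameterError,
    InvalidSequenceError,
    MalformedSpectrumError,
)

#: deg cm^2 dmol^-1 per delta-epsilon unit (MRE = 3298 * dEps)
MRE_PER_DELTA_EPSILON = 3298.0
#: millidegrees per delta-absorbance unit (theta = 32980 * dA)
MDEG_PER_DELTA_ABSORBANCE = 32980.0
#: decimals wavelengths are rounded to before grid comparison
GRID_DECIMALS = 3


class SpectralUnit(str, Enum):
    """The six units a CD trace may be expressed in (plus HT volts)."""

    MILLIDEGREES = "millidegrees"
    DELTA_EPSILON = "delta_epsilon"
    MEAN_RESIDUE_ELLIPTICITY = "mean_residue_ellipticity"
    MOLAR_ELLIPTICITY = "molar_ellipticity"
    DELTA_ABSORBANCE = "delta_absorbance"
    INSTRUMENT_VOLTS = "instrument_volts"


class SpectralType(str, Enum):
    """Role of a trace within the processing chain."""

    RAW_SAMPLE = "raw_sample"
    RAW_BASELINE = "raw_baseline"
    HT = "ht"
    AVERAGE_SAMPLE = "average_sample"
    AVERAGE_BASELINE = "average_baseline"
    NET = "net"  # averaged sample minus averaged baseline, unsmoothed
    NET_SMOOTHED = "net_smoothed"
    FINAL_PROCESSED = "final_processed"
    CALIBRATION = "calibration"


_AVERAGE_TYPE = {
    SpectralType.RAW_SAMPLE: SpectralType.AVERAGE_SAMPLE,
    SpectralType.RAW_BASELINE: SpectralType.AVERAGE_BASELINE,
}


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed trace with unit and processing-role tags.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres (descending input is
        normalised by the readers before construction).
    values
        Signal at each wavelength, in ``unit``.
    unit
        One of :class:`SpectralUnit`.
    spectral_type
        Role of the trace in the processing chain.
    scan_index
        Repeat number for raw scans, if applicable.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    unit: SpectralUnit
    spectral_type: SpectralType
    scan_index: Optional[int] = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size:
            raise MalformedSpectrumError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise MalformedSpectrumError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(v))):
            raise MalformedSpectrumError("non-finite wavelength or value")
        d = np.diff(wl)
        if np.any(d <= 0):
            bad = wl[1:][d <= 0][0]
            raise MalformedSpectrumError(
                f"wavelengths must be strictly increasing (violation near {bad:g} nm)"
            )
        if self.spectral_type is SpectralType.HT:
            if self.unit is not SpectralUnit.INSTRUMENT_VOLTS:
                raise MalformedSpectrumError("HT spectra must be in instrument volts")
            if np.any(v < 0):
                raise MalformedSpectrumError("HT voltages must be non-negative")

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def wl_min(self) -> float:
        return float(self.wavelengths_nm[0])

    @property
    def wl_max(self) -> float:
        return float(self.wavelengths_nm[-1])

    def with_values(self, values: np.ndarray, **changes) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float), **changes)

    def grid_key(self) -> tuple:
        return tuple(np.round(self.wavelengths_nm, GRID_DECIMALS))


@dataclass
class SampleMetadata:
    """User-supplied experimental record; any field may be absent (None).

    ``concentration_mg_ml`` and ``pathlength_cm`` are the x and y of the
    concentration–pathlength relationship and also drive unit conversion.
    """

    sequence: Optional[str] = None
    expression_tags: list[str] = field(default_factory=list)
    uniprot_ids: list[str] = field(default_factory=list)
    n_residues: Optional[int] = None
    molecular_weight_da: Optional[float] = None
    mean_residue_weight_da: Optional[float] = None
    concentration_mg_ml: Optional[float] = None
    pathlength_cm: Optional[float] = None
    temperature_c: Optional[float] = None
    instrument_name: Optional[str] = None
    calibration_standard: Optional[str] = None  # "CSA", "ACS" or None
    calibration_peak_ratio: Optional[float] = None
    stated_interval_nm: Optional[float] = None
    protein_class: str = "unknown"  # soluble | membrane | unknown

    def __post_init__(self) -> None:
        for name in (
            "molecular_weight_da",
            "mean_residue_weight_da",
            "concentration_mg_ml",
            "pathlength_cm",
            "temperature_c",
            "calibration_peak_ratio",
            "stated_interval_nm",
        ):
            val = getattr(self, name)
            if val is not None and not np.isfinite(val):
                raise InvalidMetadataError(f"{name} must be finite, got {val!r}")
        for name in ("concentration_mg_ml", "pathlength_cm"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise InvalidMetadataError(f"{name} must be strictly positive, got {val!r}")


@dataclass(frozen=True)
class Peak:
    """A local extremum of a spectrum.

    ``magnitude`` is the signed value at the extremum; ``fwhm_nm`` is None
    when a half-height crossing is not bracketed by the data on one side.
    """

    location_nm: float
    magnitude: float
    sign: str  # "positive" | "negative"
    fwhm_nm: Optional[float] = None


class SmoothingResult(NamedTuple):
    """Smoothed spectrum plus the recommended maximum window (points)."""

    spectrum: Spectrum
    recommended_max_window: Optional[int]


# ---------------------------------------------------------------------------
# grid operations
# ---------------------------------------------------------------------------

def modal_interval(spectrum: Spectrum, decimals: int = GRID_DECIMALS) -> float:
    """Most common successive wavelength difference, in nm.

    Differences are rounded to ``decimals`` before counting; ties are broken
    toward the smaller interval.
    """
    if len(spectrum) < 2:  # unreachable through Spectrum, kept for raw arrays
        raise MalformedSpectrumError("need at least 2 points")
    diffs = np.round(np.diff(spectrum.wavelengths_nm), decimals)
    counts = Counter(diffs.tolist())
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return float(best[0])


def _require_common_grid(spectra: Sequence[Spectrum]) -> None:
    key = spectra[0].grid_key()
    for s in spectra[1:]:
        if s.grid_key() != key:
            raise IncompatibleSpectraError("spectra are not on a common wavelength grid")


def average_repeats(scans: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of repeat scans sharing one grid and unit."""
    if not scans:
        raise IncompatibleSpectraError("no scans to average")
    unit = scans[0].unit
    if any(s.unit is not unit for s in scans):
        raise IncompatibleSpectraError("scans have mixed units")
    _require_common_grid(scans)
    mean = np.mean([s.values for s in scans], axis=0)
    out_type = _AVERAGE_TYPE.get(scans[0].spectral_type, scans[0].spectral_type)
    return Spectrum(scans[0].wavelengths_nm.copy(), mean, unit, out_type)


def subtract_baseline(sample: Spectrum, baseline: Spectrum) -> Spectrum:
    """Sample minus baseline on the intersection of their grids."""
    if sample.unit is not baseline.unit:
        raise IncompatibleSpectraError("sample and baseline units differ")
    ks = np.round(sample.wavelengths_nm, GRID_DECIMALS)
    kb = np.round(baseline.wavelengths_nm, GRID_DECIMALS)
    common, ia, ib = np.intersect1d(ks, kb, return_indices=True)
    if common.size < 2:
        raise IncompatibleSpectraError("sample and baseline wavelength ranges are disjoint")
    # grids must match exactly on the overlap of their ranges — interpolation
    # would mask the missing-wavelength defects this tool exists to catch
    lo, hi = common[0], common[-1]
    in_overlap_s = (ks >= lo) & (ks <= hi)
    in_overlap_b = (kb >= lo) & (kb <= hi)
    if in_overlap_s.sum() != common.size or in_overlap_b.sum() != common.size:
        raise IncompatibleSpectraError("grids disagree on the overlapping range")
    return Spectrum(
        sample.wavelengths_nm[ia],
        sample.values[ia] - baseline.values[ib],
        sample.unit,
        SpectralType.NET,
    )


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth(
    spectrum: Spectrum,
    method: str = "savitzky_golay",
    window_points: int = 5,
    min_prominence: float = 0.05,
) -> SmoothingResult:
    """Smooth a spectrum and report the recommended maximum window.

    ``window_points`` must be odd and no longer than the series; a window of
    1 is the identity.  The recommended maximum window is
    ``floor(narrowest peak FWHM / wavelength interval)`` — wider windows
    start to truncate the narrowest spectral feature — or None when no peak
    with a defined FWHM is detectable.
    """
    n = len(spectrum)
    if window_points < 1 or window_points % 2 == 0:
        raise InvalidParameterError("window_points must be an odd positive integer")
    if window_points > n:
        raise InvalidParameterError(f"window_points {window_points} exceeds series length {n}")
    if window_points == 1:
        out = spectrum.values.copy()
    elif method == "moving_average":
        out = uniform_filter1d(spectrum.values, size=window_points, mode="nearest")
    elif method == "savitzky_golay":
        out = savgol_filter(spectrum.values, window_points, polyorder=min(2, window_points - 1))
    else:
        raise InvalidParameterError(f"unknown smoothing method {method!r}")
    smoothed = spectrum.with_values(out, spectral_type=SpectralType.NET_SMOOTHED)
    rec: Optional[int] = None
    widths = [p.fwhm_nm for p in detect_peaks(spectrum, min_prominence) if p.fwhm_nm]
    if widths:
        rec = int(np.floor(min(widths) / modal_interval(spectrum)))
    return SmoothingResult(smoothed, rec)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def detect_peaks(spectrum: Spectrum, min_prominence: float = 0.05) -> list[Peak]:
    """Local extrema with prominence >= ``min_prominence * max|value|``.

    Returns positive and negative peaks ordered by wavelength, each with a
    grid-point location and its FWHM (when bracketed).  A positive peak is a
    local maximum with a positive value and a negative peak a local minimum
    with a negative value — the saddle between two CD bands of equal sign is
    not itself a band.
    """
    v = spectrum.values
    scale = float(np.max(np.abs(v)))
    if scale == 0.0:
        return []
    prom = min_prominence * scale
    peaks: list[Peak] = []
    for sign, series in (("positive", v), ("negative", -v)):
        idx, _ = find_peaks(series, prominence=prom)
        for i in idx:
            if series[i] <= 0:
                continue
            p = Peak(
                location_nm=float(spectrum.wavelengths_nm[i]),
                magnitude=float(v[i]),
                sign=sign,
            )
            peaks.append(replace(p, fwhm_nm=fwhm(spectrum, p)))
    peaks.sort(key=lambda p: p.location_nm)
    return peaks


def fwhm(spectrum: Spectrum, peak: Peak) -> Optional[float]:
    """Full width at half maximum of ``peak``, by linear interpolation.

    The half level is half the peak's signed magnitude.  Returns None when
    the signal does not cross the half level on one side within the data
    range (unbracketed peak at a spectrum edge).
    """
    wl = spectrum.wavelengths_nm
    v = spectrum.values if peak.sign == "positive" else -spectrum.values
    mag = peak.magnitude if peak.sign == "positive" else -peak.magnitude
    half = mag / 2.0
    i = int(np.argmin(np.abs(wl - peak.location_nm)))

    def crossing(direction: int) -> Optional[float]:
        j = i
        while 0 <= j + direction < len(wl):
            k = j + direction
            if v[k] <= half:
                # linear interpolation between j and k
                if v[j] == v[k]:
                    return float(wl[k])
                t = (half - v[j]) / (v[k] - v[j])
                return float(wl[j] + t * (wl[k] - wl[j]))
            j = k
        return None

    left = crossing(-1)
    right = crossing(+1)
    if left is None or right is None:
        return None
    return right - left


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def _mre_factor(meta: SampleMetadata) -> float:
    for name in ("mean_residue_weight_da", "concentration_mg_ml", "pathlength_cm"):
        if getattr(meta, name) is None:
            raise DataUnavailableError(f"unit conversion requires metadata field {name}")
    # theta_mdeg -> MRE multiplier
    return meta.mean_residue_weight_da / (10.0 * meta.pathlength_cm * meta.concentration_mg_ml)


def _molar_factor(meta: SampleMetadata) -> float:
    for name in ("molecular_weight_da", "concentration_mg_ml", "pathlength_cm"):
        if getattr(meta, name) is None:
            raise DataUnavailableError(f"unit conversion requires metadata field {name}")
    return meta.molecular_weight_da / (10.0 * meta.pathlength_cm * meta.concentration_mg_ml)


def convert_units(
    spectrum: Spectrum, target: SpectralUnit, meta: Optional[SampleMetadata] = None
) -> Spectrum:
    """Convert a CD spectrum between ellipticity/absorbance units.

    All conversions route through millidegrees.  Crossing the
    machine <-> molar boundary needs mean residue weight (or molecular
    weight for molar ellipticity), concentration and pathlength from
    ``meta``; their absence raises :class:`DataUnavailableError`.
    HT (instrument volts) traces are not convertible.
    """
    if spectrum.unit is target:
        return spectrum
    if SpectralUnit.INSTRUMENT_VOLTS in (spectrum.unit, target):
        raise IncompatibleSpectraError("HT voltage traces have no unit conversion")
    meta = meta if meta is not None else SampleMetadata()

    def to_mdeg(values: np.ndarray, unit: SpectralUnit) -> np.ndarray:
        if unit is SpectralUnit.MILLIDEGREES:
            return values
        if unit is SpectralUnit.DELTA_ABSORBANCE:
            return values * MDEG_PER_DELTA_ABSORBANCE
        if unit is SpectralUnit.MEAN_RESIDUE_ELLIPTICITY:
            return values / _mre_factor(meta)
        if unit is SpectralUnit.DELTA_EPSILON:
            return values * MRE_PER_DELTA_EPSILON / _mre_factor(meta)
        if unit is SpectralUnit.MOLAR_ELLIPTICITY:
            return values / _molar_factor(meta)
        raise InvalidParameterError(f"cannot convert from {unit}")

    def from_mdeg(values: np.ndarray, unit: SpectralUnit) -> np.ndarray:
        if unit is SpectralUnit.MILLIDEGREES:
            return values
        if unit is SpectralUnit.DELTA_ABSORBANCE:
            return values / MDEG_PER_DELTA_ABSORBANCE
        if unit is SpectralUnit.MEAN_RESIDUE_ELLIPTICITY:
            return values * _mre_factor(meta)
        if unit is SpectralUnit.DELTA_EPSILON:
            return values * _mre_factor(meta) / MRE_PER_DELTA_EPSILON
        if unit is SpectralUnit.MOLAR_ELLIPTICITY:
            return values * _molar_factor(meta)
        raise InvalidParameterError(f"cannot convert to {unit}")

    out = from_mdeg(to_mdeg(spectrum.values, spectrum.unit), target)
    return spectrum.with_values(out, unit=target)


# ---------------------------------------------------------------------------
# sequence mass arithmetic
# ---------------------------------------------------------------------------

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def mass_from_sequence(sequence: str, allow_x: bool = False) -> float:
    """Average molecular mass (Da) of a polypeptide from its sequence.

    Sum of average residue masses plus one water (18.0153 Da), delegated to
    Biopython's protein weight table.  ``allow_x`` substitutes the mean
    standard-residue mass for unknown residues 'X'.
    """
    from Bio.SeqUtils import molecular_weight

    seq = (sequence or "").strip().upper()
    if not seq:
        raise InvalidSequenceError("empty sequence")
    bad = set(seq) - _STANDARD_AA - ({"X"} if allow_x else set())
    if bad:
        raise InvalidSequenceError(f"illegal residue code(s): {''.join(sorted(bad))}")
    n_x = seq.count("X")
    core = seq.replace("X", "")
    if core:
        mass = molecular_weight(core, seq_type="protein")
    else:
        mass = 18.0153
    if n_x:
        mean_residue = np.mean(
            [molecular_weight(a, seq_type="protein") - 18.0153 for a in sorted(_STANDARD_AA)]
        )
        mass += n_x * float(mean_residue)
    return float(mass)
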
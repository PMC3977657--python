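"""The 25-test validation registry and report assembly.

Each test consumes the :class:`~cdqc.io.UploadBundle` (plus the
:class:`~cdqc.reference.ReferenceBundle` for the heuristic quality tests)
and returns a :class:`TestResult` with one of four statuses:

* ``pass`` — the check succeeded;
* ``flag`` — worthy of investigation (possibly a novel spectral feature,
  not necessarily an error);
* ``fail`` — an inconsistency or defect;
* ``unavailable`` — a required input was not provided.

Flag-only tests never fail and fail-only tests never flag.  The runner
executes every registered test on every run — a failure in one test never
suppresses the others — and assembles a date-stamped, versioned report.

Decision boundaries follow the printed conventions literally: "at least
1.0" passes at exactly 1.0, "<10 nm" passes at exactly 10, "more than
four" passes at four equal points, and the >5%, >0.05, >1.5 nm, >0.6 mdeg
thresholds are all strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from typing import Callable, Optional

import numpy as np

from . import __version__
from .errors import CDQCError, DataUnavailableError
from .io import UploadBundle
from .reference import ReferenceBundle, project_residual
from .spectra import (
    SampleMetadata,
    SpectralType,
    SpectralUnit,
    Spectrum,
    average_repeats,
    convert_units,
    detect_peaks,
    mass_from_sequence,
    modal_interval,
    subtract_baseline,
)


class Status(str, Enum):
    PASS = "pass"
    FLAG = "flag"
    FAIL = "fail"
    UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class TestResult:
    test_id: str
    name: str
    category: str
    status: Status
    summary: str
    details: dict = field(default_factory=dict)
    suggestions: str = ""


@dataclass
class ValidationConfig:
    """Tunable thresholds; defaults are the documented decision boundaries."""

    mw_rel_tol: float = 0.005
    mrw_rel_tol: float = 0.005
    mrw_denominator: str = "n_minus_1"  # or "n"; lenient mode accepts either
    mrw_lenient: bool = True
    final_recompute_tol: float = 0.02  # fraction of recomputed peak magnitude
    average_tol: float = 0.01  # fraction of max |computed average|
    smoothing_peak_tol: float = 0.05
    min_peak_size_deps: float = 1.0
    noise_limit_deps: float = 0.25
    noise_successive: int = 2
    calibration_standard_ratio: float = 2.0
    calibration_ratio_tol: float = 0.10
    calibration_meta_tol: float = 0.01
    ht_margin: float = 0.02
    conc_path_window: tuple[float, float] = (0.01, 0.2)  # mg*cm/ml
    flat_top_max_equal: int = 4
    feature_width_min_nm: float = 10.0
    peak_sd_limit_nm: float = 1.5
    ht_gradient_limit: float = 0.05
    repeat_sd_frac: float = 0.05
    repeat_sd_mdeg: float = 0.6
    repeat_sd_consecutive: int = 3
    peak_prominence: float = 0.05
    peak_match_window_nm: float = 10.0
    interval_tol_nm: float = 1e-3
    range_required_nm: tuple[float, float] = (205.0, 255.0)
    temperature_range_c: tuple[float, float] = (-10.0, 99.0)
    calibration_scale: Optional[float] = None  # applied in the final recompute


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_CD_TYPES = [
    SpectralType.RAW_SAMPLE,
    SpectralType.RAW_BASELINE,
    SpectralType.AVERAGE_SAMPLE,
    SpectralType.AVERAGE_BASELINE,
    SpectralType.NET,
    SpectralType.NET_SMOOTHED,
    SpectralType.FINAL_PROCESSED,
]


def _all_cd_spectra(bundle: UploadBundle, include_calibration: bool = False):
    types = _CD_TYPES + ([SpectralType.CALIBRATION] if include_calibration else [])
    for t in types:
        for s in bundle.get(t):
            yield s


def _need(value, description: str):
    if value is None or (isinstance(value, (list, tuple)) and not value):
        raise DataUnavailableError(description)
    return value


def _final_in_deps(bundle: UploadBundle) -> Spectrum:
    final = _need(bundle.first(SpectralType.FINAL_PROCESSED), "no final processed spectrum")
    if final.unit is SpectralUnit.DELTA_EPSILON:
        return final
    return convert_units(final, SpectralUnit.DELTA_EPSILON, bundle.metadata)


def _strip_tags(sequence: str, tags: list[str]) -> str:
    seq = sequence.upper()
    for tag in tags:
        seq = seq.replace(tag.upper(), "")
    return seq


def _consecutive_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def _match_nearest(location: float, peaks, window: float):
    best = None
    for p in peaks:
        d = abs(p.location_nm - location)
        if d <= window and (best is None or d < abs(best.location_nm - location)):
            best = p
    return best


# ---------------------------------------------------------------------------
# completeness
# ---------------------------------------------------------------------------

def test_missing_wavelengths(bundle, refs, config) -> dict:
    spectra = list(_all_cd_spectra(bundle))
    if not spectra:
        raise DataUnavailableError("no CD spectra provided")
    gaps = []
    for s in spectra:
        step = modal_interval(s)
        diffs = np.diff(s.wavelengths_nm)
        bad = np.abs(diffs - step) > config.interval_tol_nm
        for i in np.flatnonzero(bad):
            gaps.append(
                {
                    "spectral_type": s.spectral_type.value,
                    "between_nm": [float(s.wavelengths_nm[i]), float(s.wavelengths_nm[i + 1])],
                }
            )
    if gaps:
        return {
            "status": Status.FAIL,
            "summary": f"{len(gaps)} gap(s) relative to the most common wavelength interval",
            "details": {"gaps": gaps},
        }
    return {"status": Status.PASS, "summary": "no missing wavelengths; any regular interval is acceptable"}


def test_wavelength_range(bundle, refs, config) -> dict:
    final = _need(bundle.first(SpectralType.FINAL_PROCESSED), "no final processed spectrum")
    lo, hi = config.range_required_nm
    covered = final.wl_min <= lo and final.wl_max >= hi
    details = {"range_nm": [final.wl_min, final.wl_max], "required_nm": [lo, hi]}
    if covered:
        return {"status": Status.PASS, "summary": f"range {final.wl_min:g}-{final.wl_max:g} nm covers the minimal standard {lo:g}-{hi:g} nm", "details": details}
    return {
        "status": Status.FLAG,
        "summary": f"range {final.wl_min:g}-{final.wl_max:g} nm does not cover the minimal standard {lo:g}-{hi:g} nm",
        "details": details,
    }


def test_wavelength_interval(bundle, refs, config) -> dict:
    spectra = [
        s
        for s in _all_cd_spectra(bundle)
        if s.spectral_type is not SpectralType.CALIBRATION
    ] + bundle.get(SpectralType.HT)
    if not spectra:
        raise DataUnavailableError("no spectral data provided")
    observed = {s.spectral_type.value: modal_interval(s) for s in spectra}
    worst = max(observed.values())
    details = {"observed_nm": observed, "stated_nm": bundle.metadata.stated_interval_nm}
    if worst > 1.0 + config.interval_tol_nm:
        return {
            "status": Status.FAIL,
            "summary": f"wavelength interval {worst:g} nm exceeds the 1 nm standard",
            "details": details,
        }
    stated = bundle.metadata.stated_interval_nm
    if stated is not None:
        mismatched = {
            k: v for k, v in observed.items() if abs(v - stated) > config.interval_tol_nm
        }
        if mismatched:
            return {
                "status": Status.FAIL,
                "summary": f"stated interval {stated:g} nm differs from observed {mismatched}",
                "details": details,
            }
    return {"status": Status.PASS, "summary": f"interval {worst:g} nm (sub-nm intervals are acceptable)", "details": details}


# ---------------------------------------------------------------------------
# consistency: metadata
# ---------------------------------------------------------------------------

def test_uniprot_sequence(bundle, refs, config) -> dict:
    seq = _need(bundle.metadata.sequence, "no sequence in metadata")
    references = _need(
        bundle.reference_sequences, "no local reference sequence supplied"
    )
    stripped = _strip_tags(seq, bundle.metadata.expression_tags)
    for ref in references:
        if stripped == ref.upper():
            return {
                "status": Status.PASS,
                "summary": "sequence (minus expression tags) matches a reference sequence",
            }
    # report the first mismatch position against the closest-length reference
    ref = min(references, key=lambda r: abs(len(r) - len(stripped))).upper()
    pos = next(
        (i + 1 for i, (a, b) in enumerate(zip(stripped, ref)) if a != b),
        min(len(stripped), len(ref)) + 1,
    )
    return {
        "status": Status.FLAG,
        "summary": f"sequence differs from the reference (first mismatch at position {pos})",
        "details": {"first_mismatch_position": pos, "stripped_length": len(stripped), "reference_length": len(ref)},
    }


def test_residue_count(bundle, refs, config) -> dict:
    n = _need(bundle.metadata.n_residues, "no residue count in metadata")
    seq = _need(bundle.metadata.sequence, "no sequence in metadata")
    if n == len(seq):
        return {"status": Status.PASS, "summary": f"residue count {n} matches the sequence"}
    return {
        "status": Status.FAIL,
        "summary": f"residue count {n} does not match sequence length {len(seq)}",
        "details": {"stated": n, "sequence_length": len(seq)},
    }


def test_molecular_weight(bundle, refs, config) -> dict:
    stated = _need(bundle.metadata.molecular_weight_da, "no molecular weight in metadata")
    seq = _need(bundle.metadata.sequence, "no sequence in metadata")
    computed = mass_from_sequence(seq, allow_x=True)
    rel = abs(stated - computed) / computed
    details = {"stated_da": stated, "computed_da": round(computed, 2), "relative_error": rel}
    if rel > config.mw_rel_tol:
        return {
            "status": Status.FAIL,
            "summary": f"stated MW {stated:.1f} Da deviates {100 * rel:.2f}% from the sequence-derived {computed:.1f} Da",
            "details": details,
        }
    return {"status": Status.PASS, "summary": f"stated MW matches the sequence-derived {computed:.1f} Da", "details": details}


def test_mean_residue_weight(bundle, refs, config) -> dict:
    stated = _need(bundle.metadata.mean_residue_weight_da, "no mean residue weight in metadata")
    mw = _need(bundle.metadata.molecular_weight_da, "no molecular weight in metadata")
    n = _need(bundle.metadata.n_residues, "no residue count in metadata")
    candidates = {"MW/(N-1)": mw / (n - 1)}
    if config.mrw_lenient or config.mrw_denominator == "n":
        candidates["MW/N"] = mw / n
    if config.mrw_denominator == "n" and not config.mrw_lenient:
        candidates = {"MW/N": mw / n}
    errs = {k: abs(stated - v) / v for k, v in candidates.items()}
    best = min(errs, key=errs.get)
    details = {"stated_da": stated, "computed": {k: round(v, 4) for k, v in candidates.items()}}
    if errs[best] > config.mrw_rel_tol:
        return {
            "status": Status.FAIL,
            "summary": f"stated MRW {stated:.2f} Da deviates {100 * errs[best]:.2f}% from {best} = {candidates[best]:.2f} Da",
            "details": details,
        }
    return {"status": Status.PASS, "summary": f"stated MRW consistent with {best} = {candidates[best]:.2f} Da", "details": details}


def test_temperature(bundle, refs, config) -> dict:
    t = _need(bundle.metadata.temperature_c, "no temperature in metadata")
    lo, hi = config.temperature_range_c
    if lo <= t <= hi:
        return {"status": Status.PASS, "summary": f"temperature {t:g} degC is within the aqueous range [{lo:g}, {hi:g}]"}
    return {
        "status": Status.FAIL,
        "summary": f"temperature {t:g} degC is outside the aqueous range [{lo:g}, {hi:g}] (typing error or wrong units?)",
        "details": {"temperature_c": t},
    }


# ---------------------------------------------------------------------------
# consistency: spectral data
# ---------------------------------------------------------------------------

def test_final_spectrum(bundle, refs, config) -> dict:
    net = _need(bundle.first(SpectralType.NET_SMOOTHED), "no net-smoothed spectrum")
    final = _need(bundle.first(SpectralType.FINAL_PROCESSED), "no final processed spectrum")
    recomputed = convert_units(net, final.unit, bundle.metadata)
    if config.calibration_scale is not None:
        recomputed = recomputed.with_values(recomputed.values * config.calibration_scale)
    ks = np.round(recomputed.wavelengths_nm, 3)
    kf = np.round(final.wavelengths_nm, 3)
    common, ia, ib = np.intersect1d(ks, kf, return_indices=True)
    if common.size < 2:
        raise DataUnavailableError("net-smoothed and final spectra do not overlap")
    dev = np.abs(recomputed.values[ia] - final.values[ib])
    scale = float(np.max(np.abs(recomputed.values[ia])))
    worst = float(dev.max()) / scale if scale else float(dev.max())
    details = {"max_relative_deviation": worst, "tolerance": config.final_recompute_tol}
    if worst > config.final_recompute_tol:
        return {
            "status": Status.FAIL,
            "summary": f"final spectrum deviates up to {100 * worst:.1f}% of the recomputed peak (unit-conversion or scaling error?)",
            "details": details,
        }
    return {"status": Status.PASS, "summary": "final spectrum is consistent with the recomputed net-smoothed spectrum", "details": details}


def _average_consistency(bundle, config, raw_type, avg_type, label) -> dict:
    raws = bundle.get(raw_type)
    if not raws:
        raise DataUnavailableError(f"no raw {label} scans")
    provided = _need(bundle.first(avg_type), f"no average {label} spectrum")
    computed = average_repeats(raws)
    ks = np.round(computed.wavelengths_nm, 3)
    kf = np.round(provided.wavelengths_nm, 3)
    common, ia, ib = np.intersect1d(ks, kf, return_indices=True)
    if common.size < 2:
        raise DataUnavailableError(f"average {label} does not overlap the raw scans")
    scale = float(np.max(np.abs(computed.values[ia])))
    worst = float(np.max(np.abs(computed.values[ia] - provided.values[ib])))
    rel = worst / scale if scale else worst
    details = {"max_relative_deviation": rel, "tolerance": config.average_tol, "n_scans": len(raws)}
    if rel > config.average_tol:
        return {
            "status": Status.FLAG,
            "summary": f"provided average {label} deviates up to {100 * rel:.1f}% from the mean of {len(raws)} scans",
            "details": details,
        }
    return {"status": Status.PASS, "summary": f"average {label} matches the mean of {len(raws)} scans", "details": details}


def test_average_sample(bundle, refs, config) -> dict:
    return _average_consistency(
        bundle, config, SpectralType.RAW_SAMPLE, SpectralType.AVERAGE_SAMPLE, "sample"
    )


def test_average_baseline(bundle, refs, config) -> dict:
    return _average_consistency(
        bundle, config, SpectralType.RAW_BASELINE, SpectralType.AVERAGE_BASELINE, "baseline"
    )


def test_excess_smoothing(bundle, refs, config) -> dict:
    smoothed = _need(bundle.first(SpectralType.NET_SMOOTHED), "no net-smoothed spectrum")
    # comparator: net unsmoothed derived from the averages if possible, else
    # the provided average sample spectrum
    avg_s = bundle.first(SpectralType.AVERAGE_SAMPLE)
    avg_b = bundle.first(SpectralType.AVERAGE_BASELINE)
    if avg_s is not None and avg_b is not None and avg_s.unit is smoothed.unit:
        comparator = subtract_baseline(avg_s, avg_b)
    elif avg_s is not None and avg_s.unit is smoothed.unit:
        comparator = avg_s
    else:
        raise DataUnavailableError("no unsmoothed comparator spectrum in matching units")
    step = modal_interval(smoothed)
    ref_peaks = detect_peaks(comparator, config.peak_prominence)
    smo_peaks = detect_peaks(smoothed, config.peak_prominence)
    offending = []
    for rp in ref_peaks:
        sp = _match_nearest(rp.location_nm, [q for q in smo_peaks if q.sign == rp.sign], config.peak_match_window_nm)
        if sp is None:
            offending.append({"location_nm": rp.location_nm, "problem": "peak lost by smoothing"})
            continue
        rel = abs(sp.magnitude - rp.magnitude) / abs(rp.magnitude)
        shift = abs(sp.location_nm - rp.location_nm)
        if rel > config.smoothing_peak_tol:
            offending.append({"location_nm": rp.location_nm, "magnitude_change": rel})
        elif shift > step + 1e-9:
            offending.append({"location_nm": rp.location_nm, "shift_nm": shift})
    if offending:
        return {
            "status": Status.FAIL,
            "summary": f"{len(offending)} peak(s) truncated by more than {100 * config.smoothing_peak_tol:.0f}% or shifted by smoothing",
            "details": {"peaks": offending},
        }
    return {"status": Status.PASS, "summary": "smoothed peaks agree with the unsmoothed spectrum"}


# ---------------------------------------------------------------------------
# quality
# ---------------------------------------------------------------------------

def test_minimum_peak_size(bundle, refs, config) -> dict:
    final = _final_in_deps(bundle)
    biggest = float(np.max(np.abs(final.values)))
    details = {"max_abs_deps": biggest, "required": config.min_peak_size_deps}
    if biggest < config.min_peak_size_deps:
        return {
            "status": Status.FAIL,
            "summary": f"highest peak {biggest:.3g} delta-epsilon is below 1.0 (calculation error or wrong files?)",
            "details": details,
        }
    return {"status": Status.PASS, "summary": f"highest peak {biggest:.3g} delta-epsilon is at least 1.0", "details": details}


def test_maximum_magnitude(bundle, refs, config) -> dict:
    final = _final_in_deps(bundle)
    lo_nm, hi_nm = 178.0, 245.0
    mask = (final.wavelengths_nm >= lo_nm) & (final.wavelengths_nm <= hi_nm)
    if not mask.any():
        raise DataUnavailableError("no data within the 178-245 nm envelope range")
    wl = final.wavelengths_nm[mask]
    v = final.values[mask]
    lo, hi = refs.envelope.bounds_at(wl)
    outside = wl[(v < lo) | (v > hi)]
    if outside.size:
        return {
            "status": Status.FLAG,
            "summary": f"magnitude outside the reference envelope at {outside.size} wavelength(s); may be a novel characteristic worthy of attention",
            "details": {"wavelengths_nm": [float(w) for w in outside]},
        }
    return {"status": Status.PASS, "summary": "magnitudes lie inside the reference envelope over 178-245 nm"}


def test_noise_high_wavelength(bundle, refs, config) -> dict:
    final = _final_in_deps(bundle)
    if final.wl_max > 260.0:
        lo, hi = 260.0, 270.0
    else:
        lo, hi = 255.0, 260.0
    mask = (final.wavelengths_nm >= lo) & (final.wavelengths_nm <= hi)
    if mask.sum() < config.noise_successive:
        raise DataUnavailableError(f"no data in the {lo:g}-{hi:g} nm noise region")
    v = final.values[mask]
    run = _consecutive_run(np.abs(v) > config.noise_limit_deps)
    details = {"region_nm": [lo, hi], "max_successive_exceeding": run}
    if run >= config.noise_successive:
        return {
            "status": Status.FLAG,
            "summary": f"{run} successive values in {lo:g}-{hi:g} nm exceed +/-{config.noise_limit_deps:g} delta-epsilon (noise or baseline mismatch?)",
            "details": details,
        }
    return {"status": Status.PASS, "summary": f"signal in {lo:g}-{hi:g} nm stays within +/-{config.noise_limit_deps:g} delta-epsilon", "details": details}


def test_calibration_ratio(bundle, refs, config) -> dict:
    cal = _need(bundle.first(SpectralType.CALIBRATION), "no calibration spectrum")
    peaks = detect_peaks(cal, config.peak_prominence)
    p192 = _match_nearest(192.0, peaks, config.peak_match_window_nm)
    p290 = _match_nearest(290.0, peaks, config.peak_match_window_nm)
    if p192 is None or p290 is None or p290.magnitude == 0:
        raise DataUnavailableError("calibration bands near 192 and 290 nm not found")
    ratio = abs(p192.magnitude) / abs(p290.magnitude)
    std = config.calibration_standard_ratio
    dev = abs(ratio - std) / std
    details = {"measured_ratio": ratio, "standard_ratio": std, "relative_deviation": dev}
    stated = bundle.metadata.calibration_peak_ratio
    if stated is not None and abs(ratio - stated) / stated > config.calibration_meta_tol:
        return {
            "status": Status.FLAG,
            "summary": f"measured peak ratio {ratio:.3f} differs from the stated {stated:.3f}",
            "details": {**details, "stated_ratio": stated},
        }
    if dev > config.calibration_ratio_tol:
        return {
            "status": Status.FLAG,
            "summary": f"peak ratio {ratio:.3f} deviates {100 * dev:.1f}% from the literature standard {std:g}",
            "details": details,
        }
    return {"status": Status.PASS, "summary": f"calibration peak ratio {ratio:.3f} is within 10% of {std:g}", "details": details}


def test_max_ht_voltage(bundle, refs, config) -> dict:
    hts = bundle.get(SpectralType.HT)
    if not hts:
        raise DataUnavailableError("no HT spectrum")
    limit = refs.ht_limits.get(bundle.metadata.instrument_name)
    if limit is None:
        raise DataUnavailableError(
            f"instrument {bundle.metadata.instrument_name!r} is not in the HT limit table"
        )
    # restrict to the wavelength range of the reported CD data
    cd = bundle.first(SpectralType.FINAL_PROCESSED) or next(_all_cd_spectra(bundle), None)
    worst = -np.inf
    for ht in hts:
        mask = np.ones(len(ht), dtype=bool)
        if cd is not None:
            mask = (ht.wavelengths_nm >= cd.wl_min) & (ht.wavelengths_nm <= cd.wl_max)
        if mask.any():
            worst = max(worst, float(ht.values[mask].max()))
    if not np.isfinite(worst):
        raise DataUnavailableError("HT data do not overlap the CD range")
    details = {"max_ht_volts": worst, "limit_volts": limit}
    if worst > limit:
        return {
            "status": Status.FAIL,
            "summary": f"HT reaches {worst:.0f} V, above the instrument maximum {limit:.0f} V; this will tend to depress the measured magnitude",
            "details": details,
        }
    if worst > limit * (1.0 - config.ht_margin):
        return {
            "status": Status.FLAG,
            "summary": f"HT reaches {worst:.0f} V, within {100 * config.ht_margin:.0f}% of the instrument maximum {limit:.0f} V",
            "details": details,
        }
    return {"status": Status.PASS, "summary": f"HT stays below the instrument maximum ({worst:.0f} of {limit:.0f} V)", "details": details}


def test_concentration_pathlength(bundle, refs, config) -> dict:
    c = _need(bundle.metadata.concentration_mg_ml, "no concentration in metadata")
    l = _need(bundle.metadata.pathlength_cm, "no pathlength in metadata")
    product = c * l
    lo, hi = config.conc_path_window
    details = {"concentration_x_pathlength": product, "window": [lo, hi]}
    if lo <= product <= hi:
        return {"status": Status.PASS, "summary": f"concentration x pathlength = {product:.3g} mg.cm/ml is in the optimal window", "details": details}
    return {
        "status": Status.FLAG,
        "summary": f"concentration x pathlength = {product:.3g} mg.cm/ml is outside the optimal window [{lo:g}, {hi:g}]",
        "details": details,
    }


def test_flat_topped_peaks(bundle, refs, config) -> dict:
    spectra = [s for s in (bundle.first(SpectralType.FINAL_PROCESSED),) if s is not None]
    spectra += bundle.get(SpectralType.HT)
    if not spectra:
        raise DataUnavailableError("no final or HT spectrum")
    flat = []
    for s in spectra:
        for p in detect_peaks(s, config.peak_prominence):
            region = _fwhm_region(s, p)
            run = _consecutive_run(np.diff(s.values[region]) == 0.0) + 1
            if run > config.flat_top_max_equal:
                flat.append({"spectral_type": s.spectral_type.value, "location_nm": p.location_nm, "equal_points": run})
    if flat:
        return {
            "status": Status.FAIL,
            "summary": f"{len(flat)} peak(s) with more than {config.flat_top_max_equal} equal successive points (instrument saturation?)",
            "details": {"peaks": flat},
        }
    return {"status": Status.PASS, "summary": "no flat-topped peaks detected"}


def _fwhm_region(s: Spectrum, p) -> np.ndarray:
    i = int(np.argmin(np.abs(s.wavelengths_nm - p.location_nm)))
    if p.fwhm_nm is not None:
        half = p.fwhm_nm / 2.0
        return np.flatnonzero(np.abs(s.wavelengths_nm - p.location_nm) <= half + 1e-9)
    lo = max(0, i - 5)
    return np.arange(lo, min(len(s), i + 6))


def test_feature_width(bundle, refs, config) -> dict:
    final = _final_in_deps(bundle)
    peaks = detect_peaks(final, config.peak_prominence)
    narrow = [
        {"location_nm": p.location_nm, "fwhm_nm": p.fwhm_nm}
        for p in peaks
        if p.fwhm_nm is not None and p.fwhm_nm < config.feature_width_min_nm
    ]
    if narrow:
        return {
            "status": Status.FLAG,
            "summary": f"{len(narrow)} peak(s) narrower than {config.feature_width_min_nm:g} nm FWHM (possible poor signal-to-noise)",
            "details": {"peaks": narrow},
        }
    return {"status": Status.PASS, "summary": f"all peak widths are at least {config.feature_width_min_nm:g} nm FWHM", "details": {"n_peaks": len(peaks)}}


def test_peak_locations(bundle, refs, config) -> dict:
    final = _final_in_deps(bundle)
    peaks = detect_peaks(final, config.peak_prominence)
    if not peaks:
        return {"status": Status.PASS, "summary": "no peaks above the prominence threshold to compare"}
    unexpected = [
        {"sign": p.sign, "location_nm": p.location_nm}
        for p in peaks
        if not refs.peak_catalogue.matches(p.sign, p.location_nm)
    ]
    if unexpected:
        return {
            "status": Status.FLAG,
            "summary": f"peak(s) at unexpected location(s): {[u['location_nm'] for u in unexpected]} nm; may be an interesting spectral feature",
            "details": {"peaks": unexpected},
        }
    return {"status": Status.PASS, "summary": "all peak locations fall within the expected windows"}


def test_peak_location_sd(bundle, refs, config) -> dict:
    raws = bundle.get(SpectralType.RAW_SAMPLE)
    if len(raws) < 2:
        raise DataUnavailableError("need at least two raw sample repeats")
    per_scan = [detect_peaks(s, config.peak_prominence) for s in raws]
    anchors = per_scan[0]
    worst = []
    for anchor in anchors:
        locations = [anchor.location_nm]
        for other in per_scan[1:]:
            m = _match_nearest(anchor.location_nm, [p for p in other if p.sign == anchor.sign], config.peak_match_window_nm)
            if m is not None:
                locations.append(m.location_nm)
        if len(locations) >= 2:
            sd = float(np.std(locations, ddof=1))
            if sd > config.peak_sd_limit_nm:
                worst.append({"location_nm": anchor.location_nm, "sd_nm": sd})
    if worst:
        return {
            "status": Status.FLAG,
            "summary": f"peak location SD across repeats exceeds {config.peak_sd_limit_nm:g} nm (instrument or sample instability?)",
            "details": {"peaks": worst},
        }
    return {"status": Status.PASS, "summary": f"peak locations are reproducible across {len(raws)} repeats"}


def test_ht_gradient_240_260(bundle, refs, config) -> dict:
    hts = bundle.get(SpectralType.HT)
    if not hts:
        raise DataUnavailableError("no HT spectrum")
    worst = -np.inf
    for ht in hts:
        span = float(ht.values.max() - ht.values.min())
        if span == 0.0:
            continue
        norm = (ht.values - ht.values.min()) / span
        mask = (ht.wavelengths_nm >= 240.0) & (ht.wavelengths_nm <= 260.0)
        if mask.sum() < 2:
            continue
        slope = float(np.polyfit(ht.wavelengths_nm[mask], norm[mask], 1)[0])
        worst = max(worst, slope * 20.0)
    if not np.isfinite(worst):
        raise DataUnavailableError("HT data do not cover the 240-260 nm region")
    details = {"normalized_rise_240_260": worst, "limit": config.ht_gradient_limit}
    if worst > config.ht_gradient_limit:
        return {
            "status": Status.FLAG,
            "summary": f"normalized HT rise of {worst:.3f} across 240-260 nm exceeds {config.ht_gradient_limit:g} (buffer absorption?)",
            "details": details,
        }
    return {"status": Status.PASS, "summary": "HT trace is flat or falling across 240-260 nm", "details": details}


def test_repeat_sd(bundle, refs, config) -> dict:
    raws = bundle.get(SpectralType.RAW_SAMPLE)
    if len(raws) < 2:
        raise DataUnavailableError("need at least two raw sample repeats")
    grid = raws[0].grid_key()
    if any(s.grid_key() != grid for s in raws[1:]):
        raise DataUnavailableError("raw repeats are not on a common grid")
    note = ""
    try:
        in_mdeg = [convert_units(s, SpectralUnit.MILLIDEGREES, bundle.metadata) for s in raws]
        use_mdeg = True
    except CDQCError:
        in_mdeg = raws
        use_mdeg = False
        note = " (units not convertible to millidegrees; percentage criterion only)"
    matrix = np.vstack([s.values for s in in_mdeg])
    sd = matrix.std(axis=0, ddof=1)
    mean = matrix.mean(axis=0)
    exceeds = sd > config.repeat_sd_frac * np.abs(mean)
    if use_mdeg:
        exceeds &= sd > config.repeat_sd_mdeg
    run = _consecutive_run(exceeds)
    wl = raws[0].wavelengths_nm
    details = {"max_consecutive_exceeding": run, "required_consecutive": config.repeat_sd_consecutive}
    if run >= config.repeat_sd_consecutive:
        offending = [float(w) for w in wl[exceeds]]
        return {
            "status": Status.FLAG,
            "summary": f"repeat SD exceeds the reproducibility criteria at {len(offending)} wavelength(s){note}",
            "details": {**details, "wavelengths_nm": offending},
        }
    return {"status": Status.PASS, "summary": f"repeats are reproducible across {len(raws)} scans{note}", "details": details}


def test_projection(bundle, refs, config) -> dict:
    final = _final_in_deps(bundle)
    residual = project_residual(final, refs.basis)
    cls = (bundle.metadata.protein_class or "unknown").lower()
    if cls == "membrane":
        limit = refs.basis.flag_limit_membrane
        note = ""
    else:
        limit = refs.basis.flag_limit_soluble
        note = "" if cls == "soluble" else " (protein class unknown; stricter soluble limit applied)"
    details = {"residual_fraction": residual, "limit": limit, "protein_class": cls}
    if residual > limit:
        return {
            "status": Status.FLAG,
            "summary": f"shape residual {residual:.3f} exceeds the {limit:g} flagging limit{note}; may indicate novel spectral features",
            "details": details,
        }
    return {"status": Status.PASS, "summary": f"shape is well reconstructed by the reference basis (residual {residual:.3f}){note}", "details": details}


# ---------------------------------------------------------------------------
# registry and runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegisteredTest:
    test_id: str
    name: str
    category: str
    statuses: tuple[str, ...]  # outcomes beyond pass/unavailable: F and/or X
    func: Callable
    description: str
    suggestions: str


REGISTRY: list[RegisteredTest] = [
    RegisteredTest(
        "missing_wavelengths", "Missing wavelengths", "completeness", ("fail",),
        test_missing_wavelengths,
        "Successive wavelength differences are assessed relative to the most common interval; any regular interval is acceptable.",
        "Re-export the data without trimming; check spreadsheet transfers for dropped rows.",
    ),
    RegisteredTest(
        "wavelength_range", "Wavelength range", "completeness", ("flag",),
        test_wavelength_range,
        "The minimal standard is coverage of 205-255 nm; more low-wavelength data improves analyses.",
        "Try a different pathlength, concentration and/or buffer to extend the usable range.",
    ),
    RegisteredTest(
        "wavelength_interval", "Wavelength interval", "completeness", ("fail",),
        test_wavelength_interval,
        "The standard interval is 1 nm; larger intervals distort features. The stated interval must match all spectral data except the calibration spectrum.",
        "Re-measure at 1 nm or finer; correct the stated interval in the metadata.",
    ),
    RegisteredTest(
        "uniprot_sequence", "Sequence vs reference", "consistency_metadata", ("flag",),
        test_uniprot_sequence,
        "The user sequence (minus stated expression tags) is compared with the supplied reference sequence(s).",
        "Check the accession, the construct boundaries and the expression-tag annotation.",
    ),
    RegisteredTest(
        "residue_count", "Number of residues", "consistency_metadata", ("fail",),
        test_residue_count,
        "The stated residue count is compared with the sequence length.",
        "Correct the residue count or the sequence in the metadata.",
    ),
    RegisteredTest(
        "molecular_weight", "Molecular weight", "consistency_metadata", ("fail",),
        test_molecular_weight,
        "The molecular weight is computed from the sequence and compared with the stated value.",
        "Correct the stated molecular weight; remember to include any tags present in the measured construct.",
    ),
    RegisteredTest(
        "mean_residue_weight", "Mean residue weight", "consistency_metadata", ("fail",),
        test_mean_residue_weight,
        "The stated MRW (needed for unit conversion) is compared with MW/(N-1) (MW/N also accepted in lenient mode).",
        "Recompute MRW from the molecular weight and residue count.",
    ),
    RegisteredTest(
        "temperature", "Experimental temperature", "consistency_metadata", ("fail",),
        test_temperature,
        "The acceptable range for aqueous solutions is -10 to 99 degC.",
        "Check for typing errors or wrong units (Kelvin vs Celsius).",
    ),
    RegisteredTest(
        "final_spectrum", "Final processed spectrum", "consistency_spectral", ("fail",),
        test_final_spectrum,
        "The final spectrum is recomputed from the net-smoothed spectrum, calibration and metadata, including the magnitude (unit conversion), and compared with the one provided.",
        "Check the unit conversion constants, MRW, concentration and pathlength.",
    ),
    RegisteredTest(
        "average_sample", "Average sample spectrum", "consistency_spectral", ("flag",),
        test_average_sample,
        "The average of the raw sample scans is computed and compared with the provided average.",
        "Recompute the average from all repeat scans; check for omitted or duplicated scans.",
    ),
    RegisteredTest(
        "average_baseline", "Average baseline spectrum", "consistency_spectral", ("flag",),
        test_average_baseline,
        "The average of the raw baseline scans is computed and compared with the provided average.",
        "Recompute the average from all repeat scans; check for omitted or duplicated scans.",
    ),
    RegisteredTest(
        "excess_smoothing", "Excess smoothing", "consistency_spectral", ("fail",),
        test_excess_smoothing,
        "Peaks in the net-smoothed spectrum are compared with the unsmoothed spectrum; truncation beyond 5% or shifted positions indicate oversmoothing.",
        "Use a smaller smoothing window (at most the narrowest peak FWHM divided by the interval).",
    ),
    RegisteredTest(
        "minimum_peak_size", "Minimum peak size", "quality", ("fail",),
        test_minimum_peak_size,
        "The absolute value of the highest peak in delta epsilon must be at least 1.0.",
        "Check the unit conversion and that the correct sample and baseline files were used.",
    ),
    RegisteredTest(
        "maximum_magnitude", "Maximum magnitude", "quality", ("flag",),
        test_maximum_magnitude,
        "The magnitude at each wavelength over 178-245 nm is compared with an envelope of minimum and maximum reference values.",
        "Check the unit conversion; if correct, the spectrum may have a novel characteristic worthy of attention.",
    ),
    RegisteredTest(
        "noise_high_wavelength", "Noise at 260-270 nm", "quality", ("flag",),
        test_noise_high_wavelength,
        "Two or more successive values beyond +/-0.25 delta epsilon between 260 and 270 nm (or 255-260 nm if no data above 260) indicate noise or baseline mismatch.",
        "Average more scans or re-match sample and baseline spectra.",
    ),
    RegisteredTest(
        "calibration_ratio", "Calibration peak ratio", "quality", ("flag",),
        test_calibration_ratio,
        "The CSA/ACS two-band peak ratio is compared with the stated value and with the literature standard 2.0 (+/-10%).",
        "Recalibrate the instrument or check the calibration standard concentration.",
    ),
    RegisteredTest(
        "max_ht_voltage", "Maximum HT voltage", "quality", ("flag", "fail"),
        test_max_ht_voltage,
        "The HT trace is checked against a table of per-instrument maximal values within the reported CD range; exceeding the maximum depresses the measured magnitude.",
        "Reduce absorbance: shorter pathlength, lower concentration or a more transparent buffer.",
    ),
    RegisteredTest(
        "concentration_pathlength", "Concentration-pathlength relationship", "quality", ("flag",),
        test_concentration_pathlength,
        "Concentration times pathlength should fall in an empirically optimal window.",
        "Adjust concentration or pathlength toward the optimal product.",
    ),
    RegisteredTest(
        "flat_topped_peaks", "Flat-topped peaks", "quality", ("fail",),
        test_flat_topped_peaks,
        "More than four successive equal values within a CD or HT peak indicate an instrument ceiling.",
        "Re-measure with settings that keep the signal within the instrument's measurable range.",
    ),
    RegisteredTest(
        "feature_width", "Feature width", "quality", ("flag",),
        test_feature_width,
        "Peaks narrower than 10 nm FWHM are associated with poor signal-to-noise.",
        "Average more scans or improve the signal-to-noise ratio.",
    ),
    RegisteredTest(
        "peak_locations", "Peak locations", "quality", ("flag",),
        test_peak_locations,
        "Detected peak locations are compared with the catalogue of expected windows.",
        "Verify the baseline subtraction; an unexpected peak may be an interesting spectral feature.",
    ),
    RegisteredTest(
        "peak_location_sd", "Peak location SD across repeats", "quality", ("flag",),
        test_peak_location_sd,
        "The standard deviation of matched peak locations across raw repeats must not exceed 1.5 nm.",
        "Check instrument wavelength stability and sample integrity over the measurement series.",
    ),
    RegisteredTest(
        "ht_gradient_240_260", "HT gradient 240-260 nm", "quality", ("flag",),
        test_ht_gradient_240_260,
        "On the min-max normalized HT trace, a fitted rise above 0.05 across 240-260 nm is abnormal (the region is typically flat or falling).",
        "Check for absorbing buffer components in the 240-260 nm region.",
    ),
    RegisteredTest(
        "repeat_sd", "Repeat standard deviation", "quality", ("flag",),
        test_repeat_sd,
        "Repeats must agree: SD above 5% of the mean value at three or more consecutive wavelengths AND above 0.6 millidegrees is flagged.",
        "Average more scans; check for precipitation, aggregation or leakage over time.",
    ),
    RegisteredTest(
        "projection", "Projection onto reference basis", "quality", ("flag",),
        test_projection,
        "The residual after least-squares projection onto the five reference eigen-spectra is compared with a per-class flagging limit (soluble stricter than membrane).",
        "Check processing; a large residual may indicate novel spectral features rather than a quality issue.",
    ),
]

_REGISTRY_BY_ID = {t.test_id: t for t in REGISTRY}


@dataclass
class ValidationReport:
    results: list[TestResult]
    timestamp: str
    software_version: str
    provenance: list[dict] = field(default_factory=list)


def run_test(test_id: str, bundle: UploadBundle, refs: ReferenceBundle, config: Optional[ValidationConfig] = None) -> TestResult:
    """Run one registered test; any missing-input error becomes 'unavailable'."""
    spec = _REGISTRY_BY_ID[test_id]
    config = config or ValidationConfig()
    try:
        out = spec.func(bundle, refs, config)
        status = out["status"]
        summary = out["summary"]
        details = out.get("details", {})
    except DataUnavailableError as exc:
        status, summary, details = Status.UNAVAILABLE, str(exc), {}
    except CDQCError as exc:
        status, summary, details = Status.UNAVAILABLE, f"not performed: {exc}", {}
    allowed = set(spec.statuses) | {"pass", "unavailable"}
    if status.value not in allowed:  # defensive: status discipline per test
        raise RuntimeError(f"test {test_id} produced disallowed status {status}")
    return TestResult(
        test_id=spec.test_id,
        name=spec.name,
        category=spec.category,
        status=status,
        summary=summary,
        details=details,
        suggestions=spec.suggestions if status in (Status.FLAG, Status.FAIL) else "",
    )


def run_all(
    bundle: UploadBundle,
    refs: ReferenceBundle,
    config: Optional[ValidationConfig] = None,
    clock: Optional[Callable[[], str]] = None,
) -> ValidationReport:
    """Run every registered test and assemble the report.

    ``clock`` may be injected (a zero-argument callable returning an ISO
    timestamp) to make reports byte-reproducible.
    """
    config = config or ValidationConfig()
    results = [run_test(t.test_id, bundle, refs, config) for t in REGISTRY]
    timestamp = clock() if clock else datetime.now(timezone.utc).isoformat(timespec="seconds")
    return ValidationReport(
        results=results,
        timestamp=timestamp,
        software_version=__version__,
        provenance=list(bundle.source_files),
    )
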
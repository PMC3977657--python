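"""Deterministic generator of protein-like CD measurement sessions.

The generator emulates a complete measurement session the way a
spectropolarimeter user would produce one: an underlying delta-epsilon
spectrum modelled as a sum of Gaussian bands (helix-, sheet- or coil-like
presets), converted to millidegrees through internally consistent metadata,
measured as several repeat scans with additive Gaussian instrument noise on
top of a slowly varying baseline, together with monotone HT voltage traces,
a two-band CSA-like calibration spectrum, and the derived
average/net/smoothed/final spectra computed with the same operations the
validator uses.  With no injected defect, every derived spectrum is exactly
consistent with the raw scans and metadata, so a clean session passes every
test that has inputs.

:func:`inject_defect` produces targeted corruptions — one per validation
test — guaranteed by construction to trip the targeted test.  Some defects
also legitimately perturb *other* shape-based quality heuristics (an alien
shape exits the reference envelope, oversmoothing moves the projection
residual, jittered peaks inflate the repeat standard deviation); those
expected side effects are recorded in :data:`EXPECTED_COTRIGGERS`.

Gaussian bands are used because their peak locations, magnitudes and
widths (FWHM = 2*sqrt(2 ln 2)*sigma) are known in closed form, which makes
every quality test's ground truth computable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import UploadBundle
from .spectra import (
    SampleMetadata,
    SpectralType,
    SpectralUnit,
    Spectrum,
    average_repeats,
    convert_units,
    mass_from_sequence,
    smooth,
    subtract_baseline,
)

#: (center_nm, sigma_nm, amplitude_delta_epsilon) band presets
PRESET_BANDS: dict[str, list[tuple[float, float, float]]] = {
    # alpha-helix-like: positive pi-pi* band near 192, negative bands at 208/222
    "helix": [(192.0, 5.0, 11.0), (208.0, 4.5, -6.5), (222.0, 4.5, -6.0)],
    # beta-sheet-like: positive near 195, single negative near 218
    "sheet": [(195.0, 6.0, 6.0), (218.0, 5.5, -4.0)],
    # disordered/coil-like: strong negative band near 198
    "coil": [(198.0, 5.5, -8.0)],
}

#: the five shapes the synthetic reference set (and hence the projection
#: basis) is built from: the three secondary-structure presets plus a minor
#: near-UV band and a broad negative background shape
REFERENCE_SHAPES: list[list[tuple[float, float, float]]] = [
    PRESET_BANDS["helix"],
    PRESET_BANDS["sheet"],
    PRESET_BANDS["coil"],
    [(242.0, 6.0, 1.2)],
    [(212.0, 38.0, -0.6)],
]


def make_band_spectrum(
    band_params: Sequence[tuple[float, float, float]],
    grid: np.ndarray,
    unit: SpectralUnit = SpectralUnit.DELTA_EPSILON,
    spectral_type: SpectralType = SpectralType.FINAL_PROCESSED,
) -> Spectrum:
    """Sum of Gaussian bands evaluated on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    v = np.zeros_like(grid)
    for center, sigma, amp in band_params:
        v += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return Spectrum(grid, v, unit, spectral_type)


@dataclass(frozen=True)
class DefectRecord:
    """What a defect targets and what it is expected to do."""

    name: str
    target_test_id: str
    expected_status: str  # "flag" | "fail"


@dataclass
class SessionParams:
    """Every knob the generator reads; defaults are the clean conditions."""

    preset: str = "helix"
    n_repeats: int = 3
    noise_sd_mdeg: float = 0.2
    seed: int = 0
    wl_min: float = 175.0
    wl_max: float = 280.0
    interval_nm: float = 1.0
    amplitude_scale: float = 1.0
    band_overrides: Optional[list[tuple[float, float, float]]] = None
    extra_final_bands: list[tuple[float, float, float]] = field(default_factory=list)
    wiggle: Optional[tuple[float, float, float, float]] = None  # amp, period, lo, hi
    repeat_center_offsets: Optional[list[float]] = None
    repeat_bump: Optional[tuple[int, float, float, float]] = None  # scan, lo, hi, mdeg
    concentration_mg_ml: float = 1.0
    pathlength_cm: float = 0.05
    temperature_c: float = 25.0
    smooth_method: str = "savitzky_golay"
    smooth_window: int = 5
    calibration_ratio: float = 2.0
    ht_scale: float = 1.0
    ht_ramp_volts: float = 0.0
    instrument_name: str = "synthetic-cd-1"
    sequence_length: int = 120


@dataclass
class SyntheticSession:
    """A generated measurement session plus its ground truth."""

    params: SessionParams
    raw_samples: list[Spectrum]
    raw_baselines: list[Spectrum]
    ht: list[Spectrum]
    calibration: Spectrum
    average_sample: Spectrum
    average_baseline: Spectrum
    net_smoothed: Spectrum
    final_processed: Spectrum
    metadata: SampleMetadata
    reference_sequence: str
    injected_defects: list[DefectRecord] = field(default_factory=list)

    @property
    def seed(self) -> int:
        return self.params.seed

    def to_bundle(self) -> UploadBundle:
        bundle = UploadBundle(metadata=self.metadata, reference_sequences=[self.reference_sequence])
        for s in self.raw_samples:
            bundle.add(s)
        for s in self.raw_baselines:
            bundle.add(s)
        for s in self.ht:
            bundle.add(s)
        bundle.add(self.calibration)
        bundle.add(self.average_sample)
        bundle.add(self.average_baseline)
        bundle.add(self.net_smoothed)
        bundle.add(self.final_processed)
        return bundle


_AA = "ACDEFGHIKLMNPQRSTVWY"
_EXPRESSION_TAG = "HHHHHH"


def _baseline_drift(grid: np.ndarray) -> np.ndarray:
    # small instrument/buffer offset, mdeg
    return 2.0 - 0.005 * (grid - 220.0)


def _ht_curve(grid: np.ndarray, params: SessionParams) -> np.ndarray:
    # photomultiplier voltage: rises steeply toward low wavelength where the
    # sample and buffer absorb, flat/negative slope above 240 nm
    base = 250.0 + 300.0 * np.exp(-(grid - 170.0) / 25.0)
    ramp = params.ht_ramp_volts * 0.5 * (1.0 + np.tanh((grid - 250.0) / 5.0))
    return params.ht_scale * base + ramp


def _ideal_final(grid: np.ndarray, params: SessionParams) -> np.ndarray:
    bands = list(params.band_overrides or PRESET_BANDS[params.preset])
    bands += list(params.extra_final_bands)
    v = params.amplitude_scale * make_band_spectrum(bands, grid).values
    if params.wiggle is not None:
        amp, period, lo, hi = params.wiggle
        window = np.zeros_like(grid)
        inside = (grid >= lo) & (grid <= hi)
        # cosine taper so the wiggle fades smoothly at the window edges
        window[inside] = np.sin(np.pi * (grid[inside] - lo) / (hi - lo)) ** 2
        v = v + amp * np.sin(2 * np.pi * grid / period) * window
    return v


def make_session(
    preset: str = "helix",
    n_repeats: int = 3,
    noise_sd_mdeg: float = 0.2,
    seed: int = 0,
    **overrides,
) -> SyntheticSession:
    """Generate a session; see :class:`SessionParams` for the knobs."""
    params = SessionParams(
        preset=preset, n_repeats=n_repeats, noise_sd_mdeg=noise_sd_mdeg, seed=seed, **overrides
    )
    return make_session_from_params(params)


def make_session_from_params(params: SessionParams) -> SyntheticSession:
    rng = np.random.default_rng(params.seed)
    grid = np.arange(
        params.wl_min, params.wl_max + params.interval_nm / 2, params.interval_nm
    )

    # internally consistent metadata: sequence <-> N <-> MW <-> MRW
    core = "".join(rng.choice(list(_AA), size=params.sequence_length))
    sequence = _EXPRESSION_TAG + core
    mw = mass_from_sequence(sequence)
    n = len(sequence)
    mrw = mw / (n - 1)
    metadata = SampleMetadata(
        sequence=sequence,
        expression_tags=[_EXPRESSION_TAG],
        uniprot_ids=["SYN00001"],
        n_residues=n,
        molecular_weight_da=mw,
        mean_residue_weight_da=mrw,
        concentration_mg_ml=params.concentration_mg_ml,
        pathlength_cm=params.pathlength_cm,
        temperature_c=params.temperature_c,
        instrument_name=params.instrument_name,
        calibration_standard="CSA",
        calibration_peak_ratio=2.0,
        stated_interval_nm=params.interval_nm,
        protein_class="soluble",
    )

    # ideal signal in millidegrees
    mdeg_per_deps = (
        3298.0
        * 10.0
        * params.pathlength_cm
        * params.concentration_mg_ml
        / mrw
    )
    drift = _baseline_drift(grid)
    offsets = params.repeat_center_offsets or [0.0] * params.n_repeats

    raw_samples: list[Spectrum] = []
    for i in range(params.n_repeats):
        p_i = params
        if offsets[i]:
            bands = list(params.band_overrides or PRESET_BANDS[params.preset])
            bands = [(c + offsets[i], s, a) for c, s, a in bands]
            p_i = replace(params, band_overrides=bands)
        signal = _ideal_final(grid, p_i) * mdeg_per_deps
        noise = rng.normal(0.0, params.noise_sd_mdeg, size=grid.size)
        values = signal + drift + noise
        if params.repeat_bump is not None and params.repeat_bump[0] == i:
            _, lo, hi, bump = params.repeat_bump
            values = values + np.where((grid >= lo) & (grid <= hi), bump, 0.0)
        raw_samples.append(
            Spectrum(grid, values, SpectralUnit.MILLIDEGREES, SpectralType.RAW_SAMPLE, scan_index=i + 1)
        )

    raw_baselines = [
        Spectrum(
            grid,
            drift + rng.normal(0.0, params.noise_sd_mdeg, size=grid.size),
            SpectralUnit.MILLIDEGREES,
            SpectralType.RAW_BASELINE,
            scan_index=i + 1,
        )
        for i in range(params.n_repeats)
    ]

    ht = [
        Spectrum(
            grid,
            _ht_curve(grid, params) + rng.normal(0.0, 0.5, size=grid.size),
            SpectralUnit.INSTRUMENT_VOLTS,
            SpectralType.HT,
            scan_index=i + 1,
        )
        for i in range(params.n_repeats)
    ]

    # CSA-like calibration: negative band near 192.5, positive near 290.5,
    # magnitude ratio |192| / |290| = params.calibration_ratio
    cal_grid = np.arange(170.0, 340.0 + 0.5, 1.0)
    a290 = 16.7
    calibration = make_band_spectrum(
        [(192.5, 6.0, -params.calibration_ratio * a290), (290.5, 7.0, a290)],
        cal_grid,
        unit=SpectralUnit.MILLIDEGREES,
        spectral_type=SpectralType.CALIBRATION,
    )

    average_sample = average_repeats(raw_samples)
    average_baseline = average_repeats(raw_baselines)
    net = subtract_baseline(average_sample, average_baseline)
    net_smoothed = smooth(net, params.smooth_method, params.smooth_window).spectrum
    final = convert_units(net_smoothed, SpectralUnit.DELTA_EPSILON, metadata)
    final = replace(final, spectral_type=SpectralType.FINAL_PROCESSED)

    return SyntheticSession(
        params=params,
        raw_samples=raw_samples,
        raw_baselines=raw_baselines,
        ht=ht,
        calibration=calibration,
        average_sample=average_sample,
        average_baseline=average_baseline,
        net_smoothed=net_smoothed,
        final_processed=final,
        metadata=metadata,
        reference_sequence=core,
    )


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------

#: defect name -> (target test id, expected status)
DEFECT_TARGETS: dict[str, tuple[str, str]] = {
    "drop_wavelength": ("missing_wavelengths", "fail"),
    "widen_interval": ("wavelength_interval", "fail"),
    "narrow_range": ("wavelength_range", "flag"),
    "wrong_mw": ("molecular_weight", "fail"),
    "wrong_mrw": ("mean_residue_weight", "fail"),
    "bad_temperature": ("temperature", "fail"),
    "scale_final": ("final_spectrum", "fail"),
    "oversmooth": ("excess_smoothing", "fail"),
    "shrink_signal": ("minimum_peak_size", "fail"),
    "add_high_wavelength_noise": ("noise_high_wavelength", "flag"),
    "detune_calibration": ("calibration_ratio", "flag"),
    "exceed_ht": ("max_ht_voltage", "fail"),
    "flat_top": ("flat_topped_peaks", "fail"),
    "narrow_band": ("feature_width", "flag"),
    "shift_peak": ("peak_locations", "flag"),
    "jitter_repeat_peaks": ("peak_location_sd", "flag"),
    "raise_ht_gradient": ("ht_gradient_240_260", "flag"),
    "inflate_repeat_sd": ("repeat_sd", "flag"),
    "alien_shape": ("projection", "flag"),
    "bad_product": ("concentration_pathlength", "flag"),
}

#: quality tests a defect may legitimately co-trigger (or render
#: unavailable), beyond its target — documented expected physics, not bugs
EXPECTED_COTRIGGERS: dict[str, set[str]] = {
    "narrow_range": {"noise_high_wavelength"},  # the 255-270 nm region is cut away
    # broadened bands depart from the reference shapes and push magnitude
    # into tail wavelengths the reference envelope does not reach
    "oversmooth": {"projection", "maximum_magnitude"},
    "narrow_band": {"projection"},  # a narrowed band likewise changes the shape
    "shift_peak": {"projection"},  # the extra out-of-catalogue band is off-basis
    "jitter_repeat_peaks": {"repeat_sd"},  # wandering peaks raise per-wavelength SD
    "alien_shape": {"peak_locations", "feature_width", "maximum_magnitude"},
}


def _edit_spectrum(s: Spectrum, wl: np.ndarray, v: np.ndarray) -> Spectrum:
    return Spectrum(wl, v, s.unit, s.spectral_type, s.scan_index)


def inject_defect(session: SyntheticSession, defect: str) -> SyntheticSession:
    """Return a copy of ``session`` with one named corruption applied.

    Defects that alter experimental conditions (interval, concentration,
    band shapes, HT behaviour) regenerate the whole session from modified
    parameters so the processing chain stays self-consistent; defects that
    model processing mistakes edit the affected derived spectra directly.
    """
    if defect not in DEFECT_TARGETS:
        raise ValueError(f"unknown defect {defect!r}; choose from {sorted(DEFECT_TARGETS)}")
    p = session.params

    if defect == "widen_interval":
        out = make_session_from_params(replace(p, interval_nm=2.0))
    elif defect == "shrink_signal":
        grid = session.final_processed.wavelengths_nm
        peak = float(np.max(np.abs(_ideal_final(grid, p))))
        s = 0.5 / peak
        # a scale/calculation error multiplies the whole processed chain,
        # noise included, so signal-to-noise is preserved
        out = make_session_from_params(
            replace(p, amplitude_scale=s, noise_sd_mdeg=p.noise_sd_mdeg * s)
        )
    elif defect == "oversmooth":
        out = make_session_from_params(
            replace(p, smooth_method="moving_average", smooth_window=7)
        )
    elif defect == "detune_calibration":
        out = make_session_from_params(replace(p, calibration_ratio=2.5))
    elif defect == "exceed_ht":
        grid = session.ht[0].wavelengths_nm
        peak = float(np.max(_ht_curve(grid, p)))
        out = make_session_from_params(replace(p, ht_scale=650.0 / peak))
    elif defect == "narrow_band":
        bands = [(c, (3.0 if c == 222.0 else s), a) for c, s, a in PRESET_BANDS[p.preset]]
        out = make_session_from_params(replace(p, band_overrides=bands))
    elif defect == "shift_peak":
        out = make_session_from_params(
            replace(p, extra_final_bands=[(250.0, 5.0, 1.5)])
        )
    elif defect == "jitter_repeat_peaks":
        offsets = list(np.linspace(-2.0, 2.0, p.n_repeats))
        out = make_session_from_params(replace(p, repeat_center_offsets=offsets))
    elif defect == "raise_ht_gradient":
        out = make_session_from_params(replace(p, ht_ramp_volts=30.0))
    elif defect == "inflate_repeat_sd":
        out = make_session_from_params(replace(p, repeat_bump=(0, 244.0, 248.0, 2.0)))
    elif defect == "alien_shape":
        out = make_session_from_params(replace(p, wiggle=(0.8, 12.0, 195.0, 250.0)))
    elif defect == "bad_product":
        out = make_session_from_params(
            replace(p, concentration_mg_ml=2.0, pathlength_cm=1.0)
        )
    else:
        out = copy.deepcopy(session)
        if defect == "drop_wavelength":
            f = out.final_processed
            keep = np.abs(f.wavelengths_nm - 215.0) > 1e-9
            out.final_processed = _edit_spectrum(f, f.wavelengths_nm[keep], f.values[keep])
        elif defect == "narrow_range":
            f = out.final_processed
            keep = (f.wavelengths_nm >= 210.0) & (f.wavelengths_nm <= 250.0)
            out.final_processed = _edit_spectrum(f, f.wavelengths_nm[keep], f.values[keep])
        elif defect == "wrong_mw":
            mw = out.metadata.molecular_weight_da * 1.01
            out.metadata.molecular_weight_da = mw
            # keep the stated MRW arithmetically consistent with the (wrong)
            # stated MW so only the sequence-vs-MW comparison trips
            out.metadata.mean_residue_weight_da = mw / (out.metadata.n_residues - 1)
        elif defect == "wrong_mrw":
            out.metadata.mean_residue_weight_da *= 1.01
        elif defect == "bad_temperature":
            out.metadata.temperature_c = 120.0
        elif defect == "scale_final":
            f = out.final_processed
            out.final_processed = _edit_spectrum(f, f.wavelengths_nm, f.values * 1.35)
        elif defect == "add_high_wavelength_noise":
            bump_deps = 0.4 * np.exp(
                -0.5 * ((out.final_processed.wavelengths_nm - 264.0) / 2.0) ** 2
            )
            mrw = out.metadata.mean_residue_weight_da
            factor = 3298.0 * 10.0 * p.pathlength_cm * p.concentration_mg_ml / mrw
            f, ns = out.final_processed, out.net_smoothed
            out.final_processed = _edit_spectrum(f, f.wavelengths_nm, f.values + bump_deps)
            out.net_smoothed = _edit_spectrum(ns, ns.wavelengths_nm, ns.values + bump_deps * factor)
        elif defect == "flat_top":
            f, ns = out.final_processed, out.net_smoothed
            crest = (f.wavelengths_nm >= 220.0) & (f.wavelengths_nm <= 224.0)
            at222 = int(np.argmin(np.abs(f.wavelengths_nm - 222.0)))
            fv = f.values.copy()
            fv[crest] = f.values[at222]
            nv = ns.values.copy()
            nv[crest] = ns.values[at222]
            out.final_processed = _edit_spectrum(f, f.wavelengths_nm, fv)
            out.net_smoothed = _edit_spectrum(ns, ns.wavelengths_nm, nv)

    target, status = DEFECT_TARGETS[defect]
    out.injected_defects = list(session.injected_defects) + [
        DefectRecord(defect, target, status)
    ]
    return out
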
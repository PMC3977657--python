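"""Reference artefacts for the heuristic quality tests.

Four artefacts are compared against during validation:

* a **magnitude envelope** — pointwise minimum/maximum delta-epsilon values
  over a curated reference set, spanning 178–245 nm;
* an **HT limit table** — per-instrument maximum photomultiplier voltages;
* a **peak catalogue** — wavelength windows where protein CD peaks of each
  sign are expected;
* a **basis set** — the five highest-singular-value component spectra of
  the reference matrix, against which a submitted spectrum's shape residual
  is measured.

The curated reference collections these would normally be built from are
not redistributable, so :func:`build_default_references` generates a
deterministic synthetic stand-in from secondary-structure band models
(mixtures of helix-, sheet- and coil-like Gaussian band shapes over a wide
amplitude range); :func:`load_reference_bundle` lets a real curated set be
dropped in instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidReferenceError, UndefinedResidualError
from .spectra import SpectralType, SpectralUnit, Spectrum

#: wavelength range (nm) the magnitude envelope must cover
ENVELOPE_RANGE = (178.0, 245.0)


@dataclass
class ReferenceEnvelope:
    """Pointwise min/max delta-epsilon bounds over the reference set."""

    wavelengths_nm: np.ndarray
    min_value: np.ndarray
    max_value: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.min_value = np.asarray(self.min_value, dtype=float)
        self.max_value = np.asarray(self.max_value, dtype=float)
        if np.any(self.min_value > self.max_value):
            raise InvalidReferenceError("envelope min exceeds max")
        if self.wavelengths_nm[0] > ENVELOPE_RANGE[0] or self.wavelengths_nm[-1] < ENVELOPE_RANGE[1]:
            raise InvalidReferenceError(
                f"envelope must cover {ENVELOPE_RANGE[0]:g}-{ENVELOPE_RANGE[1]:g} nm"
            )

    def bounds_at(self, wavelengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.interp(wavelengths, self.wavelengths_nm, self.min_value)
        hi = np.interp(wavelengths, self.wavelengths_nm, self.max_value)
        return lo, hi


@dataclass
class BasisSet:
    """Orthonormal component spectra plus per-class flagging limits.

    ``components`` is a (k, n_wavelengths) array whose rows are mutually
    orthonormal; the default limits are uncalibrated package defaults (the
    membrane limit is looser, reflecting the larger shape variation of
    membrane-protein reference sets).
    """

    wavelengths_nm: np.ndarray
    components: np.ndarray
    flag_limit_soluble: float = 0.05
    flag_limit_membrane: float = 0.10

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.components.shape[0]), atol=1e-8):
            raise InvalidReferenceError("basis components are not orthonormal")

    @property
    def k(self) -> int:
        return int(self.components.shape[0])


@dataclass
class HTLimitTable:
    """Instrument name -> maximum acceptable HT voltage (volts)."""

    limits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.limits.values()):
            raise InvalidReferenceError("HT voltage limits must be positive")

    def get(self, instrument_name: Optional[str]) -> Optional[float]:
        if instrument_name is None:
            return None
        return self.limits.get(instrument_name.strip().lower())


@dataclass
class PeakCatalogue:
    """Expected (sign, low_nm, high_nm) peak-location windows."""

    windows: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.windows:
            raise InvalidReferenceError("peak catalogue must have at least one window")
        for sign, lo, hi in self.windows:
            if sign not in ("positive", "negative") or not lo < hi:
                raise InvalidReferenceError(f"bad catalogue window {(sign, lo, hi)!r}")

    def matches(self, sign: str, location_nm: float) -> bool:
        return any(s == sign and lo <= location_nm <= hi for s, lo, hi in self.windows)


@dataclass
class ReferenceBundle:
    """All reference artefacts plus provenance (how they were built)."""

    envelope: ReferenceEnvelope
    basis: BasisSet
    ht_limits: HTLimitTable
    peak_catalogue: PeakCatalogue
    description: str = ""


# ---------------------------------------------------------------------------
# basis construction and projection
# ---------------------------------------------------------------------------

def build_basis(
    reference_spectra: Sequence[Spectrum],
    k: int = 5,
    flag_limit_soluble: float = 0.05,
    flag_limit_membrane: float = 0.10,
) -> BasisSet:
    """Top-``k`` singular components of the reference spectra matrix.

    The spectra must share one grid and be in delta epsilon.  No mean
    centering is applied: a submitted spectrum is modelled as a plain linear
    combination of the component shapes.
    """
    if len(reference_spectra) < k:
        raise InvalidReferenceError(f"need at least {k} reference spectra, got {len(reference_spectra)}")
    grid = reference_spectra[0].grid_key()
    if any(s.grid_key() != grid for s in reference_spectra[1:]):
        raise InvalidReferenceError("reference spectra are not on a common grid")
    if any(s.unit is not SpectralUnit.DELTA_EPSILON for s in reference_spectra):
        raise InvalidReferenceError("reference spectra must be in delta epsilon")
    matrix = np.vstack([s.values for s in reference_spectra])
    _, _, vt = np.linalg.svd(matrix, full_matrices=False)
    return BasisSet(
        reference_spectra[0].wavelengths_nm.copy(),
        vt[:k],
        flag_limit_soluble,
        flag_limit_membrane,
    )


def project_residual(spectrum: Spectrum, basis: BasisSet) -> float:
    """Relative shape residual of ``spectrum`` against the basis.

    The spectrum is least-squares projected onto the components over the
    overlap of its range with the basis grid; the residual is
    ``||y - reconstruction||_2 / ||y||_2`` (0 = perfectly reconstructable,
    1 = orthogonal to every component).
    """
    mask = (basis.wavelengths_nm >= spectrum.wl_min) & (basis.wavelengths_nm <= spectrum.wl_max)
    if mask.sum() < basis.k:
        raise InvalidReferenceError("spectrum overlaps too little of the basis grid")
    grid = basis.wavelengths_nm[mask]
    y = np.interp(grid, spectrum.wavelengths_nm, spectrum.values)
    norm = float(np.linalg.norm(y))
    if norm == 0.0:
        raise UndefinedResidualError("projection residual undefined for a zero spectrum")
    b = basis.components[:, mask]
    coef, *_ = np.linalg.lstsq(b.T, y, rcond=None)
    resid = float(np.linalg.norm(y - b.T @ coef))
    return resid / norm


def build_envelope(reference_spectra: Sequence[Spectrum]) -> ReferenceEnvelope:
    """Pointwise min/max over a common-grid reference set."""
    grid = reference_spectra[0].grid_key()
    if any(s.grid_key() != grid for s in reference_spectra[1:]):
        raise InvalidReferenceError("reference spectra are not on a common grid")
    matrix = np.vstack([s.values for s in reference_spectra])
    return ReferenceEnvelope(
        reference_spectra[0].wavelengths_nm.copy(),
        matrix.min(axis=0),
        matrix.max(axis=0),
    )


# ---------------------------------------------------------------------------
# default synthetic bundle
# ---------------------------------------------------------------------------

#: documented placeholder instruments and their maximum HT voltages (volts)
DEFAULT_HT_LIMITS = {
    "synthetic-cd-1": 600.0,
    "bench-cd-a": 700.0,
    "bench-cd-b": 650.0,
    "srcd-beamline-a": 800.0,
    "srcd-beamline-b": 900.0,
}

#: canonical protein CD peak windows: positive band in the far UV below
#: 200 nm, negative bands through the amide region
DEFAULT_PEAK_WINDOWS = [
    ("positive", 185.0, 200.0),
    ("negative", 205.0, 230.0),
    ("negative", 194.0, 205.0),  # disordered/coil minimum near 198 nm
]


def build_default_references(
    seed: int = 0,
    n_spectra: int = 160,
    grid: Optional[np.ndarray] = None,
    envelope_margin_deps: float = 0.1,
) -> ReferenceBundle:
    """Deterministic synthetic reference bundle.

    Generates ``n_spectra`` delta-epsilon spectra as non-negative mixtures
    of five Gaussian band shapes (helix-, sheet- and coil-like plus two
    minor near-UV shapes) over amplitude scales 0.04–1.4, takes their
    envelope over 178–245 nm, builds the 5-component basis, and attaches
    the documented HT limit table and peak catalogue.  Identical seeds give
    identical bundles.

    ``envelope_margin_deps`` widens the min/max curves by a small absolute
    amount: a finite generated set underestimates the population envelope,
    and without the margin the bounds are razor-thin at the band tails.
    """
    from .synth import REFERENCE_SHAPES, make_band_spectrum

    if grid is None:
        grid = np.arange(175.0, 280.0 + 0.5, 1.0)
    rng = np.random.default_rng(seed)
    shapes = [make_band_spectrum(bands, grid).values for bands in REFERENCE_SHAPES]
    spectra: list[Spectrum] = []

    def as_spectrum(values: np.ndarray) -> Spectrum:
        return Spectrum(grid, values, SpectralUnit.DELTA_EPSILON, SpectralType.FINAL_PROCESSED)

    # pure canonical shapes across the amplitude range, so any pure
    # secondary-structure spectrum of in-range magnitude sits inside the
    # envelope by construction
    scales = [0.04, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4]
    for base in shapes:
        for s in scales:
            spectra.append(as_spectrum(s * base))
    # random mixtures of the five shapes
    while len(spectra) < n_spectra:
        weights = rng.dirichlet(np.ones(len(shapes)))
        scale = rng.uniform(0.3, 1.4)
        mix = scale * np.sum([w * sh for w, sh in zip(weights, shapes)], axis=0)
        spectra.append(as_spectrum(mix))

    envelope = build_envelope(spectra)
    envelope = ReferenceEnvelope(
        envelope.wavelengths_nm,
        envelope.min_value - envelope_margin_deps,
        envelope.max_value + envelope_margin_deps,
    )
    basis = build_basis(spectra, k=5)
    return ReferenceBundle(
        envelope=envelope,
        basis=basis,
        ht_limits=HTLimitTable(dict(DEFAULT_HT_LIMITS)),
        peak_catalogue=PeakCatalogue(list(DEFAULT_PEAK_WINDOWS)),
        description=f"synthetic reference bundle (seed={seed}, n={len(spectra)})",
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_reference_bundle(directory: str | Path, bundle: ReferenceBundle) -> None:
    """Serialize a bundle to a directory (JSON + columnar ascii basis)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc = {
        "description": bundle.description,
        "envelope": {
            "wavelengths_nm": bundle.envelope.wavelengths_nm.tolist(),
            "min_value": bundle.envelope.min_value.tolist(),
            "max_value": bundle.envelope.max_value.tolist(),
        },
        "ht_limits": bundle.ht_limits.limits,
        "peak_catalogue": bundle.peak_catalogue.windows,
        "flag_limit_soluble": bundle.basis.flag_limit_soluble,
        "flag_limit_membrane": bundle.basis.flag_limit_membrane,
    }
    (directory / "reference.json").write_text(json.dumps(doc, indent=2) + "\n")
    lines = ["# cdqc basis spectra: wavelength_nm then one column per component"]
    for i, w in enumerate(bundle.basis.wavelengths_nm):
        row = [f"{w:.3f}"] + [f"{c:.12g}" for c in bundle.basis.components[:, i]]
        lines.append(" ".join(row))
    (directory / "basis.tsv").write_text("\n".join(lines) + "\n")


def load_reference_bundle(directory: str | Path) -> ReferenceBundle:
    directory = Path(directory)
    doc = json.loads((directory / "reference.json").read_text())
    rows = []
    for line in (directory / "basis.tsv").read_text().splitlines():
        line = line.split("#")[0].strip()
        if line:
            rows.append([float(t) for t in line.split()])
    arr = np.array(rows)
    basis = BasisSet(
        arr[:, 0],
        arr[:, 1:].T,
        doc.get("flag_limit_soluble", 0.05),
        doc.get("flag_limit_membrane", 0.10),
    )
    env = ReferenceEnvelope(
        np.array(doc["envelope"]["wavelengths_nm"]),
        np.array(doc["envelope"]["min_value"]),
        np.array(doc["envelope"]["max_value"]),
    )
    return ReferenceBundle(
        envelope=env,
        basis=basis,
        ht_limits=HTLimitTable({k: float(v) for k, v in doc["ht_limits"].items()}),
        peak_catalogue=PeakCatalogue([tuple(w) for w in doc["peak_catalogue"]]),
        description=doc.get("description", ""),
    )
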
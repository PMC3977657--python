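# Methods

## What the package checks

A protein circular dichroism (CD) measurement session produces repeat raw
sample and baseline scans in millidegrees of ellipticity, high tension
(HT) photomultiplier voltage traces, a calibration spectrum, and a
processing chain: average the repeats, subtract the averaged baseline,
smooth, apply the instrument calibration and convert to a molar unit
(delta epsilon, Δε). `cdqc` validates the data and metadata of such a
session with 25 registered tests in four groups — completeness (3),
metadata consistency (5), spectral consistency (4) and quality (13) — each
returning `pass`, `flag` (worthy of investigation, possibly a genuinely
novel feature), `fail` (an inconsistency or defect) or `unavailable`
(required input absent). Averaging of sample scans and of baseline scans
register as two separate tests; that split is how the registry reaches 25
entries from 24 distinct procedures, and it is the one place where the
count is a documented convention rather than arithmetic.

Every test runs on every invocation; a failure never suppresses the other
tests, and the minimum viable input is a single final processed spectrum
with a declared unit.

## Decision boundaries

Boundary semantics follow the stated wording literally:

| quantity | boundary | semantics |
|---|---|---|
| minimum peak size | 1.0 Δε | "at least" — exactly 1.0 passes |
| high-wavelength noise | ±0.25 Δε | strict; needs ≥ 2 successive points in 260–270 nm (255–260 nm if no data above 260) |
| calibration ratio | 2.0 ± 10% | strict on the deviation |
| feature width | 10 nm FWHM | strict `<` — exactly 10 passes |
| peak-location SD | 1.5 nm | strict `>` |
| HT normalized gradient | 0.05 rise over 240–260 nm | strict `>` |
| repeat SD | 5% of value AND 0.6 mdeg, ≥ 3 consecutive λ | both strict |
| excess smoothing | 5% peak truncation (or > one interval shift) | strict |
| temperature | [−10, 99] °C | inclusive |
| wavelength range | must cover [205, 255] nm | inclusive |
| flat-topped peaks | > 4 equal successive points | 4 passes, 5 fails |
| wavelength interval | 1 nm standard | > 1 nm fails; sub-nm passes |

The test suite and `scripts/acceptance.py` verify each boundary by
bisecting a one-parameter synthetic defect family (`cdqc.probes`) and
checking that the measured flip point sits at the stated value to the
probe's grid or bisection resolution.

Tolerances that are comparison details rather than stated boundaries are
package defaults, configurable through `ValidationConfig`: molecular
weight and MRW agreement 0.5% relative; final-spectrum recompute 2% of the
recomputed peak magnitude; average-spectrum agreement 1% of the computed
maximum; stated-vs-measured calibration ratio 1%; HT "close to limit" flag
margin 2%; grid comparisons at 1e-3 nm.

## Conventions and open choices

* **Unit conversion.** MRE = θ_mdeg · MRW / (10 · l_cm · c_mg/ml);
  Δε = MRE / 3298; θ_mdeg = 32980 · ΔA; molar ellipticity uses the
  whole-molecule MW in place of MRW. All conversions route through
  millidegrees and round-trip to 1e-9 relative. Sequence masses are
  average (not monoisotopic) residue masses plus one water, via
  Biopython — CD concentrations are weight-based bulk measurements.
* **MRW denominator.** Whether MRW = MW/N or MW/(N−1) is a live
  convention split in the field; the default computes MW/(N−1) (per
  peptide bond) and, in the default lenient mode, accepts either within
  tolerance.
* **Grid discipline.** Averaging and subtraction demand exact grid
  equality (after rounding to 3 decimals) on the overlapping range —
  silent interpolation would mask exactly the missing-wavelength defects
  the tool exists to catch.
* **Peaks.** Detected with a prominence threshold of 5% of max |value|; a
  positive peak must have a positive value and a negative peak a negative
  value, so the saddle between two same-sign bands is not itself a band.
  FWHM is linearly interpolated between the half-height crossings and is
  undefined when a crossing is not bracketed by the data. Peak matching
  across spectra or repeats is nearest-location pairing capped at 10 nm.
* **Smoothing.** Savitzky–Golay (quadratic) or moving average; window 1
  is the identity. The recommended maximum window,
  floor(narrowest FWHM / interval), is reported alongside the result.
  Either algorithm is accepted when checking user-smoothed data, since
  the smoothing method used upstream is generally unknown.
* **Calibration.** CSA/ACS is modelled as its two opposite-sign bands;
  the ratio is measured between the extrema nearest 192 and 290 nm
  (within ±10 nm), the field-standard band positions.
* **HT gradient direction.** "Increase" is measured toward longer
  wavelength: a positive fitted slope over 240–260 nm on the min-max
  normalized trace is abnormal, since that region is typically flat or
  falling. The convention is configurable.
* **Projection residual.** The submitted spectrum is least-squares
  projected onto the five highest-singular-value components of the
  reference matrix (no mean-centering — the model is a plain linear
  combination of shapes) and the residual is ‖y − ŷ‖₂/‖y‖₂. Whether the
  original procedure used an RMS, max or norm residual is not knowable
  from its description; the normalized 2-norm is this package's choice.
  Flag limits (soluble 0.05, membrane 0.10, unknown treated as soluble)
  are uncalibrated defaults, deliberately looser for membrane proteins
  whose reference shapes vary more.
* **Concentration–pathlength.** The published optimum relationship is not
  available in closed form; a configurable product window
  [0.01, 0.2] mg·cm/ml stands in and is explicitly provisional.

## The synthetic reference bundle

The curated reference sets behind the envelope, peak catalogue and
projection basis are not redistributable, so the default bundle is
generated deterministically: 160 Δε spectra formed as scaled mixtures of
five Gaussian band shapes (helix-like +192/−208/−222, sheet-like
+195/−218, coil-like −198, a minor near-UV band at 242 nm and a broad
shallow negative background). Pure shapes are included at amplitude
scales 0.04–1.4 so that any pure secondary-structure spectrum of in-range
magnitude lies inside the envelope by construction; the envelope is then
widened by 0.1 Δε because a finite sample underestimates the population
envelope and is otherwise razor-thin at band tails. The HT limit table
contains named placeholder instruments with documented voltages (e.g.
`synthetic-cd-1` → 600 V); an unknown instrument yields `unavailable`
rather than a guess. Real curated sets can be dropped in via
`load_reference_bundle` / `--refs DIR`; every comparison then runs
unchanged against them.

## The synthetic session generator

`make_session` emulates a full measurement: an ideal Δε spectrum from a
band preset, converted to millidegrees through internally consistent
metadata (random sequence ↔ N ↔ MW ↔ MRW, 1 mg/ml × 0.05 cm, 25 °C),
measured as 3 repeat scans with 0.2 mdeg additive Gaussian noise on a
small linear baseline drift, HT traces that rise steeply toward low
wavelength and stay below the instrument limit, and a CSA-like
calibration spectrum with band ratio 2.0. Derived spectra are computed
with the same operations the validator uses, so a defect-free session
passes every test that has inputs — this is the package's own consistency
check, not a statement about any particular instrument.

What the generator does **not** emulate: HT-dependent (heteroscedastic)
noise, scan-to-scan drift from sample degradation, stray-light and
absorption-flattening artefacts, vendor file quirks, or real reference
shape diversity. Passing tests on synthetic sessions therefore
demonstrates the correctness of the decision logic and processing
arithmetic, not the calibration of the heuristic limits against real
instruments.

`inject_defect` provides twenty targeted corruptions, one per decision
threshold. Defects that change experimental conditions regenerate the
session from modified parameters so the chain stays self-consistent;
processing-mistake defects edit the derived spectra directly. Each trips
exactly its target among the completeness/consistency tests; a few also
legitimately move other *quality* heuristics (oversmoothing and narrowed
or alien band shapes change the projection residual and can exit the
magnitude envelope; jittered peak positions necessarily inflate the
per-wavelength repeat SD; truncating the range removes the noise-test
region). These expected side effects are enumerated in
`cdqc.synth.EXPECTED_COTRIGGERS` and asserted, not ignored, by the tests.

## Problem sizes

All checks run at desk scale: spectra of ~100–210 points on 0.05–2 nm
grids, 160 reference spectra, 3-repeat sessions, and bisections of ~15
steps per boundary. The full suite and the acceptance script each
complete in seconds on one CPU.

## Known limitations

* The heuristic limits (envelope margin, projection flag limits,
  concentration–pathlength window) are defaults calibrated only against
  the synthetic bundle; real deployments should substitute curated
  references and revisit them.
* JCAMP-DX support covers the AFFN `(X++(Y..Y))`/`XYPOINTS` subset only —
  no ASDF/DIFDUP compression, no compound files.
* The sequence test compares against locally supplied reference
  sequences; no accession lookup is performed (the tool is fully
  offline).
* `.gen` header layouts vary across beamlines; one dialect is fixed and
  documented in `docs/formats.md`.
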
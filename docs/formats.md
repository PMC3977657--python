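# File formats

All inputs and outputs are plain ascii. Sample files of every dialect live
in `examples/`.

## Two- and three-column free format

Whitespace- or comma-separated rows; `#` and `;` start comments; blank
lines are skipped. Column 1 is the wavelength in nm, column 2 the CD
signal in the declared unit, column 3 (three-column files only) the HT
voltage. Rows may be in ascending or descending wavelength order — they
are normalised to ascending at parse time. Duplicate wavelengths and
non-numeric or non-finite cells are rejected with the offending line
number. Instrument-specific ascii exports are read through this path.

```
# wavelength_nm  CD_mdeg  HT_volts
260 0.013 254.1
259 0.021 254.8
```

## `.gen`-style multi-scan block format

The layout used by SRCD beamline processing chains. Header lines start
with `#`; an optional `#SCANS k` declares the number of repeat scans.
Data rows are

```
wavelength  CD_1 ... CD_k  HT_1 ... HT_k
```

one column per repeat scan, HT columns after the CD columns. Without a
`#SCANS` header the paired-columns convention is assumed (an even number
of data columns, half CD and half HT). Each CD scan is returned as a
raw-sample spectrum with its `scan_index` set.

**Divergence risk:** `.gen` headers vary between beamlines; this package
documents and fixes the dialect above. Files from other pipelines may need
their header lines commented out or the `#SCANS` line added.

## JCAMP-DX subset

`##XYDATA=(X++(Y..Y))` and `##XYPOINTS=(XY..XY)` tables in plain AFFN
numbers (no ASDF/DIFDUP compression). Honoured labels: `##XFACTOR`,
`##YFACTOR`, `##FIRSTX`, `##LASTX`, `##NPOINTS`, `##DELTAX`, `##YUNITS`,
`##DATA TYPE`. `NPOINTS` disagreeing with the number of data values is a
parse error. Descending `FIRSTX > LASTX` files are normalised to
ascending. `##YUNITS`/`##DATA TYPE` are mapped onto the package's unit and
spectral-type vocabulary when they use it. The writer emits this same
subset, so write→read round trips are value-identical to 1e-6.

## Key-value metadata container

One `key: value` per line; `#` comments; unknown keys are rejected. Keys:

| key | type | meaning |
|---|---|---|
| `sequence` | string | one-letter amino-acid sequence as measured |
| `expression_tags` | comma list | tag subsequences to strip before comparison |
| `uniprot_ids` | comma list | accession strings (informational) |
| `n_residues` | int | stated residue count |
| `molecular_weight_da` | float | stated molecular weight (Da) |
| `mean_residue_weight_da` | float | stated MRW (Da), used in unit conversion |
| `concentration_mg_ml` | float | protein concentration (mg/ml) |
| `pathlength_cm` | float | cuvette pathlength (cm) |
| `temperature_c` | float | experimental temperature (°C) |
| `instrument_name` | string | key into the HT voltage limit table |
| `calibration_standard` | string | `CSA`, `ACS` or absent |
| `calibration_peak_ratio` | float | stated two-band calibration ratio |
| `stated_interval_nm` | float | declared wavelength interval |
| `protein_class` | string | `soluble`, `membrane` or `unknown` |

Any key may be absent; absence drives "data unavailable" outcomes.

## Reference bundle directory

`reference.json` (envelope, HT limit table, peak catalogue, projection
flag limits) plus `basis.tsv` (wavelength column followed by one column
per basis component). Produced by `save_reference_bundle`, read by
`load_reference_bundle`, and accepted by `cdqc validate --refs DIR` so a
real curated reference set can replace the synthetic default.

## Validation report

JSON (machine readable) or plain text. Both list every test with its
status, result summary, description and improvement suggestions, carry an
ISO timestamp and the software version, and group tests that were not
performed at the bottom under "data unavailable".
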
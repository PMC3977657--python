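# cdqc — quality control for protein circular dichroism spectra

Circular dichroism (CD) spectroscopy is a standard technique for probing
protein secondary structure and folding in solution, used by experts and
non-experts alike — which makes systematic data validation valuable both
during collection and before publication. `cdqc` is an offline library and
command-line tool that checks CD spectral data and metadata with **25
registered tests** for completeness, consistency and quality. Each test
returns a traffic-light outcome — `pass`, `flag` (worthy of investigation,
possibly a genuinely novel spectral feature), `fail` (an inconsistency or
defect) or `unavailable` (input not provided) — together with a result
summary and concrete suggestions for improving the data. The report is
date-stamped and versioned, suitable as supplementary material for
reviewers.

The tests cover the whole measurement session: the processing chain from
repeat raw scans (millidegrees, θ) through averaging, baseline
subtraction, smoothing and conversion to delta epsilon,

    MRE = θ · MRW / (10 · l · c),    Δε = MRE / 3298,

with MRW the mean residue weight (Da), *l* the pathlength (cm) and *c* the
concentration (mg/ml); metadata arithmetic (sequence ↔ residue count ↔
molecular weight ↔ MRW); instrument health via the high-tension (HT)
photomultiplier voltage against per-instrument limits; CSA/ACS
calibration band ratios against the literature standard 2.0; and
heuristic shape checks — a magnitude envelope over 178–245 nm, expected
peak-location windows, feature widths, and the residual after projecting
the spectrum onto the five leading eigen-spectra of a reference set. The
heuristic tests compare against a deterministic synthetic reference
bundle by default; curated reference sets can be dropped in
(`--refs DIR`). Supported inputs are two/three-column ascii, `.gen`-style
multi-scan blocks, a JCAMP-DX subset and a key-value metadata container
(`docs/formats.md`; samples in `examples/`).

## Worked example

Generate a synthetic helix-like measurement session (three repeat scans,
baselines, HT traces, calibration, processed spectra, metadata) and
validate it:

```sh
cdqc generate --preset helix --seed 7 --out-dir demo
cdqc validate \
  --file demo/raw_samples.gen gen raw-sample mdeg \
  --file demo/average_sample.txt 2col average-sample mdeg \
  --file demo/average_baseline.txt 2col average-baseline mdeg \
  --file demo/net_smoothed.txt 2col net-smoothed mdeg \
  --file demo/calibration.txt 2col calibration mdeg \
  --file demo/final.jdx jcamp final deltaeps \
  --meta demo/metadata.txt --ref-seq demo/reference.fasta \
  --refs builtin:0 --report text
```

prints (excerpt):

```
cdqc validation report (version 0.3.0)
[PASS] Missing wavelengths (completeness)
        no missing wavelengths; any regular interval is acceptable
[PASS] Molecular weight (consistency_metadata)
        stated MW matches the sequence-derived 15085.2 Da
[PASS] Final processed spectrum (consistency_spectral)
        final spectrum is consistent with the recomputed net-smoothed spectrum
[PASS] Minimum peak size (quality)
        highest peak 11 delta-epsilon is at least 1.0
...
```

and exits 0 (25/25 pass: the session is self-consistent by construction).
A corrupted session is caught and explained — here the calibration
spectrum's two-band ratio was detuned to 2.5:

```sh
cdqc generate --seed 7 --defect detune_calibration --out-dir demo-bad
cdqc validate --file demo-bad/final.jdx jcamp final deltaeps \
  --file demo-bad/calibration.txt 2col calibration mdeg \
  --meta demo-bad/metadata.txt --refs builtin:0 --report text
```

```
[FLAG] Calibration peak ratio (quality)
        measured peak ratio 2.498 differs from the stated 2.000
        suggestion: Recalibrate the instrument or check the calibration standard concentration.
...
data unavailable:
[ -- ] Average sample spectrum: no raw sample scans
```

Tests whose inputs were not supplied report `data unavailable` and the
rest run regardless; the minimum input is one final processed spectrum
with its unit. Exit codes: 0 no failures (flags count as success unless
`--strict`), 1 at least one failure, 2 input error. `cdqc list-tests`
describes all 25 tests; `--defect` accepts twenty named corruptions, one
per decision threshold.

The same workflow in Python:

```python
from cdqc import build_default_references, make_session, run_all

refs = build_default_references(seed=0)
report = run_all(make_session(seed=7).to_bundle(), refs)
print(sum(r.status.value == "pass" for r in report.results))  # 25
```

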
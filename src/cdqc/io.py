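"""Readers and writers for CD spectral file dialects and reports.

Supported on-disk formats, all plain ascii:

* **two/three-column free format** — wavelength, CD signal and optionally
  the HT voltage, whitespace- or comma-separated; ``#`` and ``;`` start
  comments.  Instrument-specific ascii exports are read through this path
  with the appropriate column count.
* **.gen-style multi-block** — the layout used by SRCD beamline processing
  chains: ``#`` header lines, then rows of ``wavelength CD_1 .. CD_k
  HT_1 .. HT_k`` for *k* repeat scans (``#SCANS k`` may declare *k*
  explicitly; otherwise the paired-columns convention is assumed).
* **JCAMP-DX subset** — ``##XYDATA=(X++(Y..Y))`` or ``##XYPOINTS=(XY..XY)``
  tables in AFFN form, honouring ``##XFACTOR``/``##YFACTOR``,
  ``##FIRSTX``/``##LASTX``/``##NPOINTS``.
* **key-value metadata** — ``key: value`` per line (keys listed in
  :data:`METADATA_KEYS`).

Descending-wavelength files are normalised to ascending order at parse
time.  Reports are written as JSON or plain text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidMetadataError, MalformedSpectrumError, ParseError
from .spectra import SampleMetadata, SpectralType, SpectralUnit, Spectrum

#: short unit aliases accepted on the command line and in files
UNIT_ALIASES = {
    "mdeg": SpectralUnit.MILLIDEGREES,
    "millidegrees": SpectralUnit.MILLIDEGREES,
    "deltaeps": SpectralUnit.DELTA_EPSILON,
    "delta_epsilon": SpectralUnit.DELTA_EPSILON,
    "mre": SpectralUnit.MEAN_RESIDUE_ELLIPTICITY,
    "mean_residue_ellipticity": SpectralUnit.MEAN_RESIDUE_ELLIPTICITY,
    "moleli": SpectralUnit.MOLAR_ELLIPTICITY,
    "molar_ellipticity": SpectralUnit.MOLAR_ELLIPTICITY,
    "deltaa": SpectralUnit.DELTA_ABSORBANCE,
    "delta_absorbance": SpectralUnit.DELTA_ABSORBANCE,
    "volts": SpectralUnit.INSTRUMENT_VOLTS,
    "instrument_volts": SpectralUnit.INSTRUMENT_VOLTS,
}

TYPE_ALIASES = {
    "raw-sample": SpectralType.RAW_SAMPLE,
    "raw-baseline": SpectralType.RAW_BASELINE,
    "ht": SpectralType.HT,
    "average-sample": SpectralType.AVERAGE_SAMPLE,
    "average-baseline": SpectralType.AVERAGE_BASELINE,
    "net": SpectralType.NET,
    "net-smoothed": SpectralType.NET_SMOOTHED,
    "final": SpectralType.FINAL_PROCESSED,
    "calibration": SpectralType.CALIBRATION,
}


@dataclass
class UploadBundle:
    """Everything one validation run consumes.

    The minimum viable bundle is a single final processed spectrum with a
    declared unit; any sparser field simply drives 'data unavailable'
    outcomes downstream.
    """

    spectra: dict[SpectralType, list[Spectrum]] = field(default_factory=dict)
    metadata: SampleMetadata = field(default_factory=SampleMetadata)
    reference_sequences: list[str] = field(default_factory=list)
    source_files: list[dict] = field(default_factory=list)

    def add(self, spectrum: Spectrum) -> None:
        self.spectra.setdefault(spectrum.spectral_type, []).append(spectrum)

    def get(self, spectral_type: SpectralType) -> list[Spectrum]:
        return self.spectra.get(spectral_type, [])

    def first(self, spectral_type: SpectralType) -> Optional[Spectrum]:
        lst = self.get(spectral_type)
        return lst[0] if lst else None


# ---------------------------------------------------------------------------
# column parsing helpers
# ---------------------------------------------------------------------------

def _data_rows(path: Path) -> list[tuple[int, list[str]]]:
    rows = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#")[0].split(";")[0].strip()
        if not line:
            continue
        rows.append((ln, line.replace(",", " ").split()))
    return rows


def _parse_float(token: str, path: Path, ln: int) -> float:
    try:
        val = float(token)
    except ValueError:
        raise ParseError(f"{path.name}:{ln}: non-numeric cell {token!r}") from None
    if not np.isfinite(val):
        raise ParseError(f"{path.name}:{ln}: non-finite value {token!r}")
    return val


def _as_ascending(wl: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(wl, kind="stable")
    return wl[order], cols[:, order]


def _check_duplicates(wl: np.ndarray, path: Path) -> None:
    uniq, counts = np.unique(np.round(wl, 6), return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        raise MalformedSpectrumError(f"{path.name}: duplicate wavelength {dup:g} nm")


def read_columnar(
    path: str | Path,
    n_columns: int,
    unit: SpectralUnit,
    spectral_type: SpectralType,
) -> list[Spectrum]:
    """Read a two- or three-column ascii file.

    Column 1 is the wavelength (nm), column 2 the CD signal in ``unit`` and
    column 3, when present, the HT voltage; a three-column file yields a CD
    spectrum plus an HT spectrum on the same grid.
    """
    path = Path(path)
    if n_columns not in (2, 3):
        raise ParseError(f"n_columns must be 2 or 3, got {n_columns}")
    wl_list, val_cols = [], []
    for ln, tokens in _data_rows(path):
        if len(tokens) != n_columns:
            raise ParseError(f"{path.name}:{ln}: expected {n_columns} columns, got {len(tokens)}")
        nums = [_parse_float(t, path, ln) for t in tokens]
        wl_list.append(nums[0])
        val_cols.append(nums[1:])
    if len(wl_list) < 2:
        raise ParseError(f"{path.name}: fewer than 2 data rows")
    wl = np.array(wl_list)
    cols = np.array(val_cols).T
    _check_duplicates(wl, path)
    wl, cols = _as_ascending(wl, cols)
    out = [Spectrum(wl, cols[0], unit, spectral_type)]
    if n_columns == 3:
        out.append(Spectrum(wl, cols[1], SpectralUnit.INSTRUMENT_VOLTS, SpectralType.HT))
    return out


def read_gen_block(path: str | Path, unit: SpectralUnit) -> list[Spectrum]:
    """Read a .gen-style multi-scan block file.

    Returns one raw-sample spectrum per repeat scan (``scan_index`` set)
    followed by the matching HT spectra.
    """
    path = Path(path)
    n_scans: Optional[int] = None
    for raw in path.read_text().splitlines():
        s = raw.strip()
        if s.upper().startswith("#SCANS"):
            try:
                n_scans = int(s.split()[1])
            except (IndexError, ValueError):
                raise ParseError(f"{path.name}: malformed #SCANS header {s!r}") from None
    rows = _data_rows(path)
    if len(rows) < 2:
        raise ParseError(f"{path.name}: fewer than 2 data rows")
    width = len(rows[0][1])
    wl_list, val_rows = [], []
    for ln, tokens in rows:
        if len(tokens) != width:
            raise ParseError(
                f"{path.name}:{ln}: inconsistent column count ({len(tokens)} vs {width})"
            )
        nums = [_parse_float(t, path, ln) for t in tokens]
        wl_list.append(nums[0])
        val_rows.append(nums[1:])
    if n_scans is None:
        if (width - 1) % 2:
            raise ParseError(
                f"{path.name}: {width - 1} data columns cannot be split into paired "
                "CD and HT scans; declare '#SCANS k'"
            )
        n_scans = (width - 1) // 2
    n_ht = width - 1 - n_scans
    if n_ht not in (0, n_scans):
        raise ParseError(f"{path.name}: expected {n_scans} CD + 0 or {n_scans} HT columns")
    wl = np.array(wl_list)
    cols = np.array(val_rows).T
    _check_duplicates(wl, path)
    wl, cols = _as_ascending(wl, cols)
    out = [
        Spectrum(wl, cols[i], unit, SpectralType.RAW_SAMPLE, scan_index=i + 1)
        for i in range(n_scans)
    ]
    for i in range(n_ht):
        out.append(
            Spectrum(
                wl,
                cols[n_scans + i],
                SpectralUnit.INSTRUMENT_VOLTS,
                SpectralType.HT,
                scan_index=i + 1,
            )
        )
    return out


def write_columnar(path: str | Path, spectra: Sequence[Spectrum]) -> None:
    """Write one CD spectrum (optionally with a grid-matched HT trace)."""
    path = Path(path)
    cd = spectra[0]
    lines = [f"# cdqc columnar export: {cd.spectral_type.value} [{cd.unit.value}]"]
    if len(spectra) == 2:
        ht = spectra[1]
        for w, v, h in zip(cd.wavelengths_nm, cd.values, ht.values):
            lines.append(f"{w:.3f} {v:.6f} {h:.6f}")
    else:
        for w, v in zip(cd.wavelengths_nm, cd.values):
            lines.append(f"{w:.3f} {v:.6f}")
    path.write_text("\n".join(lines) + "\n")


def write_gen_block(path: str | Path, cd_scans: Sequence[Spectrum], ht_scans: Sequence[Spectrum]) -> None:
    path = Path(path)
    lines = ["# cdqc .gen-style export", f"#SCANS {len(cd_scans)}"]
    wl = cd_scans[0].wavelengths_nm
    for i, w in enumerate(wl):
        row = [f"{w:.3f}"]
        row += [f"{s.values[i]:.6f}" for s in cd_scans]
        row += [f"{s.values[i]:.6f}" for s in ht_scans]
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JCAMP-DX subset
# ---------------------------------------------------------------------------

_JCAMP_META_LABELS = {
    "CONCENTRATION": "concentration_mg_ml",
    "PATHLENGTH": "pathlength_cm",
    "TEMPERATURE": "temperature_c",
    "SPECTROMETER/DATA SYSTEM": "instrument_name",
}


def read_jcamp(path: str | Path) -> tuple[list[Spectrum], dict]:
    """Read a JCAMP-DX file (AFFN ``XYDATA``/``XYPOINTS`` tables only).

    Returns the spectra plus a dict of recognised metadata labels.  The unit
    and spectral type are taken from ``##YUNITS``/``##DATA TYPE`` when they
    use cdqc's vocabulary, else default to a final processed spectrum in
    delta epsilon.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    table_mode: Optional[str] = None
    seen_mode: Optional[str] = None
    table_lines: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            val = val.strip()
            if key in ("XYDATA", "XYPOINTS"):
                table_mode = seen_mode = "xypoints" if key == "XYPOINTS" else "xydata"
                continue
            if key != "END":
                labels[key] = val
            table_mode = None
        elif table_mode:
            table_lines.append(line)

    if seen_mode is None or not table_lines:
        raise ParseError(f"{path.name}: no XYDATA/XYPOINTS table found")

    def fget(key: str, default: Optional[float] = None) -> Optional[float]:
        if key not in labels:
            return default
        try:
            return float(labels[key])
        except ValueError:
            raise ParseError(f"{path.name}: non-numeric ##{key}={labels[key]!r}") from None

    xfactor = fget("XFACTOR", 1.0)
    yfactor = fget("YFACTOR", 1.0)
    xs: list[float] = []
    ys: list[float] = []
    for line in table_lines:
        tokens = line.replace(",", " ").split()
        nums = [_parse_float(t, path, 0) for t in tokens]
        if not nums:
            continue
        if seen_mode == "xypoints":
            if len(nums) % 2:
                raise ParseError(f"{path.name}: odd token count in XYPOINTS row")
            xs += nums[0::2]
            ys += nums[1::2]
        else:
            xs.append(nums[0])
            ys += nums[1:]

    npoints = fget("NPOINTS")
    if npoints is not None and int(npoints) != len(ys):
        raise ParseError(
            f"{path.name}: NPOINTS={int(npoints)} disagrees with {len(ys)} data values"
        )
    if seen_mode == "xypoints":
        wl = np.array(xs) * xfactor
    else:
        firstx, lastx = fget("FIRSTX"), fget("LASTX")
        if firstx is not None and lastx is not None and len(ys) > 1:
            wl = np.linspace(firstx, lastx, len(ys))
        else:
            # fall back to per-line X checkpoints with implied spacing
            wl = _expand_checkpoint_x(np.array(xs) * xfactor, table_lines, len(ys), path)
    v = np.array(ys) * yfactor

    unit = UNIT_ALIASES.get(labels.get("YUNITS", "").strip().lower(), SpectralUnit.DELTA_EPSILON)
    stype = TYPE_ALIASES.get(
        labels.get("DATA TYPE", "").strip().lower(), SpectralType.FINAL_PROCESSED
    )
    order = np.argsort(wl, kind="stable")
    wl, v = wl[order], v[order]
    _check_duplicates(wl, path)
    meta = {
        attr: labels[lab]
        for lab, attr in _JCAMP_META_LABELS.items()
        if lab in labels
    }
    return [Spectrum(wl, v, unit, stype)], meta


def _expand_checkpoint_x(
    x_checkpoints: np.ndarray, table_lines: list[str], n: int, path: Path
) -> np.ndarray:
    if len(x_checkpoints) < 2:
        raise ParseError(f"{path.name}: cannot reconstruct X axis (no FIRSTX/LASTX)")
    step = (x_checkpoints[1] - x_checkpoints[0]) / max(
        1, len(table_lines[0].split()) - 1
    )
    return x_checkpoints[0] + step * np.arange(n)


def write_jcamp(path: str | Path, spectrum: Spectrum, title: str = "cdqc export") -> None:
    """Write a spectrum as a minimal JCAMP-DX ``(X++(Y..Y))`` file."""
    path = Path(path)
    wl, v = spectrum.wavelengths_nm, spectrum.values
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        f"##DATA TYPE={spectrum.spectral_type.value}",
        "##XUNITS=NANOMETERS",
        f"##YUNITS={spectrum.unit.value}",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##FIRSTX={wl[0]:.6f}",
        f"##LASTX={wl[-1]:.6f}",
        f"##NPOINTS={len(wl)}",
        "##XYDATA=(X++(Y..Y))",
    ]
    for i in range(0, len(wl), 6):
        chunk = v[i : i + 6]
        lines.append(" ".join([f"{wl[i]:.6f}"] + [f"{y:.8g}" for y in chunk]))
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# metadata container
# ---------------------------------------------------------------------------

_META_FLOAT_KEYS = {
    "molecular_weight_da",
    "mean_residue_weight_da",
    "concentration_mg_ml",
    "pathlength_cm",
    "temperature_c",
    "calibration_peak_ratio",
    "stated_interval_nm",
}
_META_LIST_KEYS = {"expression_tags", "uniprot_ids"}
METADATA_KEYS = (
    {"sequence", "n_residues", "instrument_name", "calibration_standard", "protein_class"}
    | _META_FLOAT_KEYS
    | _META_LIST_KEYS
)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read the key-value metadata container (``key: value`` per line)."""
    path = Path(path)
    fields: dict = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, val = line.partition(":")
        key = key.strip().lower()
        val = val.strip()
        if not sep:
            raise InvalidMetadataError(f"{path.name}:{ln}: expected 'key: value'")
        if key not in METADATA_KEYS:
            raise InvalidMetadataError(f"{path.name}:{ln}: unknown metadata key {key!r}")
        if not val:
            continue
        if key in _META_FLOAT_KEYS:
            try:
                fields[key] = float(val)
            except ValueError:
                raise InvalidMetadataError(
                    f"{path.name}:{ln}: non-numeric value for key {key!r}: {val!r}"
                ) from None
        elif key == "n_residues":
            try:
                fields[key] = int(val)
            except ValueError:
                raise InvalidMetadataError(
                    f"{path.name}:{ln}: non-integer value for key n_residues: {val!r}"
                ) from None
        elif key in _META_LIST_KEYS:
            fields[key] = [t.strip() for t in val.split(",") if t.strip()]
        else:
            fields[key] = val
    return SampleMetadata(**fields)


def write_metadata(path: str | Path, meta: SampleMetadata) -> None:
    lines = []
    for key in sorted(METADATA_KEYS):
        val = getattr(meta, key)
        if val in (None, [], ""):
            continue
        if isinstance(val, list):
            val = ", ".join(val)
        lines.append(f"{key}: {val}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_reference_sequences(path: str | Path) -> list[str]:
    """Read locally supplied reference sequences (FASTA) for the sequence test."""
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def report_to_dict(report) -> dict:
    ordered = [r for r in report.results if r.status.value != "unavailable"]
    ordered += [r for r in report.results if r.status.value == "unavailable"]
    return {
        "software": "cdqc",
        "version": report.software_version,
        "timestamp": report.timestamp,
        "provenance": report.provenance,
        "n_tests": len(report.results),
        "results": [
            {
                "test_id": r.test_id,
                "name": r.name,
                "category": r.category,
                "status": r.status.value,
                "summary": r.summary,
                "details": r.details,
                "suggestions": r.suggestions,
            }
            for r in ordered
        ],
    }


def write_report(report, fmt: str = "json", path: Optional[str | Path] = None) -> str:
    """Render a validation report as JSON or plain text.

    Tests that were not performed because of missing data are grouped at the
    bottom under 'data unavailable'.  Returns the rendered document and, if
    ``path`` is given, writes it there.
    """
    doc = report_to_dict(report)
    if fmt == "json":
        text = json.dumps(doc, indent=2, sort_keys=False) + "\n"
    elif fmt == "text":
        lines = [
            f"cdqc validation report (version {doc['version']})",
            f"date: {doc['timestamp']}",
            "-" * 72,
        ]
        ran = [r for r in doc["results"] if r["status"] != "unavailable"]
        skipped = [r for r in doc["results"] if r["status"] == "unavailable"]
        for r in ran:
            lines.append(f"[{r['status'].upper():<4}] {r['name']} ({r['category']})")
            lines.append(f"        {r['summary']}")
            if r["status"] in ("flag", "fail") and r["suggestions"]:
                lines.append(f"        suggestion: {r['suggestions']}")
        if skipped:
            lines.append("-" * 72)
            lines.append("data unavailable:")
            for r in skipped:
                lines.append(f"[ -- ] {r['name']}: {r['summary']}")
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text
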
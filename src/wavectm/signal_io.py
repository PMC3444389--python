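"""Reading and writing single-lead ECG records and label manifests.

Two on-disk formats are supported:

* a minimal WFDB dialect (single-segment ``.hea`` header plus an interleaved
  little-endian 16-bit ``.dat`` signal file, format code 16), with digital
  units mapped to physical millivolts through the header gain/baseline;
* a self-describing CSV dialect for fixtures: one header line
  ``# fs=<Hz> lead=<name>`` followed by one sample (mV) per line.

Label manifests are plain CSV with columns ``record_id,label`` and exactly
two distinct class labels across the file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ECGRecord",
    "AASignal",
    "LabelManifest",
    "read_record",
    "write_record",
    "read_manifest",
    "write_manifest",
]


class LeadNotFoundError(KeyError):
    """Requested lead name is absent from a multi-lead record."""


class ManifestError(ValueError):
    """Label manifest violates its contract (duplicates, empty, bad columns)."""


@dataclass
class ECGRecord:
    """A single-lead ECG trace in physical units (mV).

    Parameters
    ----------
    samples : ndarray
        Signal samples in millivolts; finite-valued.
    fs : float
        Sampling rate in Hz, > 0.
    lead : str
        Lead label, e.g. ``"V1"``.
    record_id : str
        Identifier of the source record.
    bit_resolution : int or None
        ADC resolution of the source, when known.
    provenance : list of str
        Append-only trail of processing steps applied so far.
    """

    samples: np.ndarray
    fs: float
    lead: str = "V1"
    record_id: str = ""
    bit_resolution: int | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def evolve(self, samples: np.ndarray, step: str, fs: float | None = None) -> "ECGRecord":
        """Return a copy with new samples and one provenance step appended."""
        return ECGRecord(
            samples=np.asarray(samples, dtype=float),
            fs=self.fs if fs is None else fs,
            lead=self.lead,
            record_id=self.record_id,
            bit_resolution=self.bit_resolution,
            provenance=[*self.provenance, step],
        )


@dataclass
class AASignal:
    """Atrial activity signal: the ECG residue after ventricular cancellation."""

    samples: np.ndarray
    fs: float
    source_record_id: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AA samples contain non-finite values")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class LabelManifest:
    """Two-class record labels: list of (record_id, label)."""

    entries: list[tuple[str, str]]
    positive_meaning: str = ""

    @property
    def record_ids(self) -> list[str]:
        return [rid for rid, _ in self.entries]

    @property
    def classes(self) -> list[str]:
        return sorted({lab for _, lab in self.entries})

    def labels_for(self, positive_label: str) -> dict[str, bool]:
        """Map record_id -> True where the label equals ``positive_label``."""
        return {rid: lab == positive_label for rid, lab in self.entries}


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _read_csv_record(path: Path, fs: float | None, lead: str | None) -> ECGRecord:
    with open(path) as fh:
        first = fh.readline().strip()
        header_fs, header_lead = None, None
        body_start = 0
        if first.startswith("#"):
            for token in first.lstrip("#").split():
                key, _, val = token.partition("=")
                if key == "fs":
                    header_fs = float(val)
                elif key == "lead":
                    header_lead = val
            body_start = fh.tell()
        fh.seek(body_start)
        try:
            samples = np.loadtxt(fh, dtype=float, ndmin=1)
        except ValueError as exc:
            raise ValueError(f"non-numeric samples in {path}: {exc}") from exc
    eff_fs = fs if fs is not None else header_fs
    if eff_fs is None:
        raise ValueError(f"{path}: sampling rate missing (no '# fs=' header line and no fs argument)")
    return ECGRecord(
        samples=samples,
        fs=eff_fs,
        lead=lead or header_lead or "V1",
        record_id=path.stem,
        provenance=[f"read:csv:{path.name}"],
    )


def _write_csv_record(record: ECGRecord, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g} lead={record.lead}\n")
        np.savetxt(fh, record.samples, fmt="%.9g")


# ---------------------------------------------------------------------------
# Minimal WFDB dialect (single segment, format 16)
# ---------------------------------------------------------------------------

def _read_wfdb_record(path: Path, lead: str | None) -> ECGRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    record_name, n_sig = rec_fields[0], int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    sig_lines = lines[1 : 1 + n_sig]

    leads: list[str] = []
    gains: list[float] = []
    baselines: list[float] = []
    adc_res: list[int] = []
    dat_name = None
    for i, ln in enumerate(sig_lines):
        parts = ln.split()
        dat_name = parts[0]
        fmt = parts[1].split("x")[0]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB signal format {parts[1]!r} (only 16)")
        gain = 200.0
        baseline = 0.0
        if len(parts) > 2:
            gfield = parts[2].split("/")[0]
            if "(" in gfield:
                gpart, bpart = gfield.split("(")
                gain = float(gpart)
                baseline = float(bpart.rstrip(")"))
            else:
                gain = float(gfield)
        if gain == 0:
            gain = 200.0
        res = int(parts[3]) if len(parts) > 3 else 16
        desc = " ".join(parts[8:]) if len(parts) > 8 else f"sig{i}"
        leads.append(desc)
        gains.append(gain)
        baselines.append(baseline)
        adc_res.append(res)

    dat = hea.with_name(dat_name)
    raw = np.fromfile(dat, dtype="<i2")
    if n_samp:
        raw = raw[: n_samp * n_sig]
    frames = raw.reshape(-1, n_sig)

    if lead is None:
        idx = 0
    else:
        try:
            idx = leads.index(lead)
        except ValueError:
            raise LeadNotFoundError(
                f"lead {lead!r} not in record {record_name} (has {leads})"
            ) from None
    physical = (frames[:, idx].astype(float) - baselines[idx]) / gains[idx]
    return ECGRecord(
        samples=physical,
        fs=fs,
        lead=leads[idx],
        record_id=record_name,
        bit_resolution=adc_res[idx],
        provenance=[f"read:wfdb:{hea.name}"],
    )


def _write_wfdb_record(record: ECGRecord, path: Path, gain: float = 1000.0) -> None:
    """Write a one-signal format-16 WFDB record (quantization: 1/gain mV)."""
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    dat = hea.with_suffix(".dat")
    digital = np.clip(np.round(record.samples * gain), -32768, 32767).astype("<i2")
    with open(hea, "w") as fh:
        fh.write(f"{hea.stem} 1 {record.fs:g} {len(digital)}\n")
        fh.write(f"{dat.name} 16 {gain:g}(0)/mV 16 0 {int(digital[0]) if len(digital) else 0} 0 0 {record.lead}\n")
    digital.tofile(dat)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_record(
    path: str | Path,
    format: str | None = None,
    lead: str | None = None,
    fs: float | None = None,
) -> ECGRecord:
    """Read an ECG record from disk.

    ``format`` is ``"wfdb"`` or ``"csv"``; when omitted it is inferred from
    the file suffix (``.hea``/``.dat`` -> wfdb, ``.csv``/``.txt`` -> csv).
    For multi-lead WFDB sources only the selected lead is retained.
    """
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix in {".hea", ".dat", ""} else "csv"
    if format == "wfdb":
        return _read_wfdb_record(path, lead)
    if format == "csv":
        if not path.exists():
            raise FileNotFoundError(path)
        return _read_csv_record(path, fs=fs, lead=lead)
    raise ValueError(f"unknown format {format!r}")


def write_record(record: ECGRecord, path: str | Path, format: str | None = None) -> Path:
    """Write a record; returns the path of the primary file written."""
    path = Path(path)
    if format is None:
        format = "wfdb" if path.suffix in {".hea", ".dat", ""} else "csv"
    if format == "wfdb":
        _write_wfdb_record(record, path)
        return path if path.suffix == ".hea" else path.with_suffix(".hea")
    if format == "csv":
        _write_csv_record(record, path)
        return path
    raise ValueError(f"unknown format {format!r}")


def read_manifest(path: str | Path) -> LabelManifest:
    """Read a ``record_id,label`` CSV into a LabelManifest.

    Duplicate record ids or an empty file raise :class:`ManifestError`.
    A single-class manifest is accepted here; classification operations
    reject it downstream.
    """
    path = Path(path)
    entries: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [row for row in reader if row and any(cell.strip() for cell in row)]
    if not rows:
        raise ManifestError(f"empty manifest: {path}")
    if [c.strip().lower() for c in rows[0][:2]] == ["record_id", "label"]:
        rows = rows[1:]
    if not rows:
        raise ManifestError(f"manifest has a header but no entries: {path}")
    seen: set[str] = set()
    for row in rows:
        if len(row) < 2:
            raise ManifestError(f"manifest row needs record_id,label: {row}")
        rid, lab = row[0].strip(), row[1].strip()
        if rid in seen:
            raise ManifestError(f"duplicate record_id {rid!r}")
        seen.add(rid)
        entries.append((rid, lab))
    return LabelManifest(entries=entries)


def write_manifest(manifest: LabelManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "label"])
        writer.writerows(manifest.entries)
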
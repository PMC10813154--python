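"""Multi-lead ECG records and file I/O.

The reference cohort layout is a PTB-style record: 12 conventional leads
(I, II, III, aVr, aVl, aVf, V1..V6) plus the 3 Frank orthogonal leads
(Vx, Vy, Vz), 10 s at 1000 Hz.  Records are read either from WFDB
header/signal pairs (format 16) or from plain CSV matrices with one
column per lead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical lead order: 12 conventional leads then the 3 Frank leads.
CANONICAL_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVr", "aVl", "aVf",
    "V1", "V2", "V3", "V4", "V5", "V6",
    "Vx", "Vy", "Vz",
)

#: ASCII aliases for lead names as they sometimes appear in headers.
LEAD_ALIASES: dict[str, str] = {
    "i": "I", "ii": "II", "iii": "III",
    "avr": "aVr", "avl": "aVl", "avf": "aVf",
    "αVr": "aVr", "αVl": "aVl", "αVf": "aVf",
    "vx": "Vx", "vy": "Vy", "vz": "Vz",
    **{f"v{k}": f"V{k}" for k in range(1, 7)},
}


class GroupLabel(str, Enum):
    """The 8 diagnostic classes of the reference cohort."""

    BBB = "BBB"          # bundle branch block
    CardMyo = "CardMyo"  # cardiomyopathy
    HC = "HC"            # healthy controls
    M = "M"              # myocarditis
    MH = "MH"            # myocardial hypertrophy
    MI = "MI"            # myocardial infarction
    VHD = "VHD"          # valvular heart disease
    Dis = "Dis"          # dysrhythmia

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class FormatError(ValueError):
    """Raised when an input file violates the expected record layout."""


def canonical_lead_name(name: str) -> str:
    """Map a raw lead label onto the canonical ASCII spelling."""
    name = name.strip()
    if name in CANONICAL_LEADS:
        return name
    return LEAD_ALIASES.get(name.lower(), LEAD_ALIASES.get(name, name))


@dataclass
class ECGRecord:
    """One subject's multi-lead signal block plus its diagnostic label.

    Parameters
    ----------
    record_id : str
        Unique identifier of the record.
    group : GroupLabel
        Diagnostic class.
    fs : float
        Sampling rate in Hz (reference value 1000).
    leads : dict[str, numpy.ndarray]
        Ordered map lead-name -> samples in mV.  All leads must share a
        common length ``N = fs * duration_s``.
    """

    record_id: str
    group: GroupLabel
    fs: float
    leads: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        ordered: dict[str, np.ndarray] = {}
        for known in CANONICAL_LEADS:
            if known in self.leads:
                ordered[known] = np.asarray(self.leads[known], dtype=float)
        for name, x in self.leads.items():  # non-canonical names keep input order
            if name not in ordered:
                ordered[name] = np.asarray(x, dtype=float)
        self.leads = ordered
        lengths = {name: len(x) for name, x in self.leads.items()}
        if not lengths:
            raise FormatError(f"record {self.record_id!r} has no leads")
        if len(set(lengths.values())) != 1:
            raise FormatError(
                f"record {self.record_id!r} has mismatched lead lengths: {lengths}"
            )
        n = next(iter(lengths.values()))
        if n < self.fs:
            raise FormatError(
                f"record {self.record_id!r}: {n} samples is less than one "
                f"1-s window at fs={self.fs}"
            )
        for name, x in self.leads.items():
            if not np.all(np.isfinite(x)):
                raise FormatError(
                    f"record {self.record_id!r}, lead {name}: non-finite samples"
                )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.leads.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def lead_names(self) -> list[str]:
        return list(self.leads)

    @property
    def complete_lead_set(self) -> bool:
        """True when all 15 canonical leads are present."""
        return all(name in self.leads for name in CANONICAL_LEADS)


# ---------------------------------------------------------------------------
# WFDB (header + format-16 signal file)
# ---------------------------------------------------------------------------

_WFDB_GAIN = 2000.0  # ADC units per mV; 16-bit range then spans +/- 16 mV


def write_wfdb_record(rec: ECGRecord, directory: str | Path) -> Path:
    """Write ``rec`` as a WFDB header (.hea) plus format-16 signal (.dat).

    Amplitudes are quantised to int16 with a gain of 2000 ADC units/mV.
    Returns the path of the header file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = rec.record_id
    n_sig = len(rec.leads)
    n_samp = rec.n_samples
    lines = [f"{name} {n_sig} {rec.fs:g} {n_samp}"]
    data = np.empty((n_samp, n_sig), dtype="<i2")
    for j, (lead, x) in enumerate(rec.leads.items()):
        adc = np.clip(np.rint(x * _WFDB_GAIN), -32768, 32767)
        data[:, j] = adc.astype("<i2")
        lines.append(f"{name}.dat 16 {_WFDB_GAIN:g}(0)/mV 16 0 0 0 0 {lead}")
    lines.append(f"# group: {rec.group.value}")
    hea = directory / f"{name}.hea"
    hea.write_text("\n".join(lines) + "\n")
    (directory / f"{name}.dat").write_bytes(data.tobytes())
    return hea


def read_wfdb_record(path: str | Path, group: GroupLabel | str | None = None) -> ECGRecord:
    """Read a WFDB record from its header file (format 16 signals only).

    Parameters
    ----------
    path : path to the ``.hea`` header (or its stem).
    group : diagnostic label; if None, a ``# group:`` comment in the
        header is used, else the label defaults to HC.
    """
    path = Path(path)
    if path.suffix != ".hea":
        path = path.with_suffix(".hea")
    if not path.exists():
        raise FileNotFoundError(path)
    raw = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    comments = [ln for ln in raw if ln.startswith("#")]
    lines = [ln for ln in raw if not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{path}: malformed header line {lines[0]!r}")
    name, n_sig, fs, n_samp = head[0], int(head[1]), float(head[2]), int(head[3])
    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) != n_sig:
        raise FormatError(f"{path}: expected {n_sig} signal lines")
    leads: list[str] = []
    gains: list[float] = []
    baselines: list[float] = []
    dat_name = None
    for ln in sig_lines:
        parts = ln.split()
        dat_name = parts[0]
        fmt = parts[1]
        if fmt.split("x")[0] != "16":
            raise FormatError(f"{path}: only format 16 supported, got {fmt}")
        gain_spec = parts[2] if len(parts) > 2 else "200"
        gain_spec = gain_spec.split("/")[0]
        if "(" in gain_spec:
            g, b = gain_spec[:-1].split("(")
            gains.append(float(g) or 200.0)
            baselines.append(float(b))
        else:
            gains.append(float(gain_spec) or 200.0)
            baselines.append(0.0)
        leads.append(canonical_lead_name(parts[-1]))
    dat_path = path.parent / dat_name
    if not dat_path.exists():
        raise FileNotFoundError(dat_path)
    data = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    if data.size != n_sig * n_samp:
        raise FormatError(
            f"{dat_path}: has {data.size} samples, header implies {n_sig * n_samp}"
        )
    data = data.reshape(n_samp, n_sig).astype(float)
    if group is None:
        group = GroupLabel.HC
        for c in comments:
            if "group:" in c:
                group = GroupLabel(c.split("group:")[1].strip())
    sig = {
        lead: (data[:, j] - baselines[j]) / gains[j] for j, lead in enumerate(leads)
    }
    rec = ECGRecord(record_id=name, group=GroupLabel(group), fs=fs, leads=sig)
    if not rec.complete_lead_set:
        warnings.warn(f"record {name!r}: incomplete lead set", stacklevel=2)
    return rec


# ---------------------------------------------------------------------------
# CSV records
# ---------------------------------------------------------------------------

def read_csv_record(
    path: str | Path,
    fs: float,
    group: GroupLabel | str,
    record_id: str | None = None,
) -> ECGRecord:
    """Read a samples x leads CSV matrix with a header row of lead names."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    leads: dict[str, np.ndarray] = {}
    for col in df.columns:
        name = canonical_lead_name(col)
        if name not in CANONICAL_LEADS:
            warnings.warn(f"unknown lead name {col!r}; retained as-is", stacklevel=2)
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        if np.isnan(vals).any() and not df[col].isna().any():
            raise FormatError(f"{path}: non-numeric cell in lead {col!r}")
        if np.isnan(vals).any():
            raise FormatError(f"{path}: missing value in lead {col!r}")
        leads[name] = vals
    rec = ECGRecord(
        record_id=record_id or path.stem,
        group=GroupLabel(group),
        fs=fs,
        leads=leads,
    )
    if not rec.complete_lead_set:
        warnings.warn(f"record {rec.record_id!r}: incomplete lead set", stacklevel=2)
    return rec


def write_csv_record(rec: ECGRecord, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(rec.leads).to_csv(path, index=False, float_format="%.17g")
    return path
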
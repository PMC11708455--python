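"""Reading and writing 12-lead ECG recordings in a plain-text dialect.

The repository dialect mirrors a clinical export of a 60-s 12-lead tracing:
a short ``key=value`` header (sampling rate, lead order, display gain)
followed by one tab-delimited row of millivolt samples per time step.
Acquisition contract: a +/-5 mV range digitized at 16 bits, so samples are
quantized on write to steps of 10 mV / 2**16 (~0.1526 uV) and any sample
outside the range is rejected as a clipped/invalid acquisition.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical 12-lead order used throughout the package.
STANDARD_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Digitizer full-scale range in mV (+/-5 mV).
VOLTAGE_RANGE_MV: float = 10.0
#: Bits of amplitude resolution.
ADC_BITS: int = 16
#: One least-significant-bit step of the 16-bit, 10-mV digitizer, in mV.
QUANTIZATION_STEP_MV: float = VOLTAGE_RANGE_MV / 2 ** ADC_BITS


class EcgFormatError(ValueError):
    """Raised when a file does not parse as a valid ECG record."""


class EcgRangeError(EcgFormatError):
    """Raised when a sample lies outside the +/-5 mV acquisition range."""


@dataclass
class EcgRecord:
    """A 12-lead sample matrix with its acquisition metadata.

    Parameters
    ----------
    data:
        Array of shape ``(n_samples, 12)`` in millivolts, one column per lead.
    fs:
        Sampling rate in Hz.
    leads:
        Ordered lead names; defaults to the standard 12-lead set.
    gain:
        Display gain note in mm/mV (paper-chart convention), default 10.
    """

    data: np.ndarray
    fs: float
    leads: tuple[str, ...] = STANDARD_LEADS
    gain: float = 10.0
    record_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.leads = tuple(self.leads)
        validate_record(self)

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return the sample series (mV) of one lead by name."""
        try:
            idx = self.leads.index(name)
        except ValueError:
            raise KeyError(f"unknown lead {name!r}") from None
        return self.data[:, idx]

    def with_data(self, data: np.ndarray) -> "EcgRecord":
        return replace(self, data=np.asarray(data, dtype=float))


def validate_record(record: EcgRecord) -> None:
    """Check every EcgRecord invariant, raising on the first violation."""
    if record.fs <= 0:
        raise EcgFormatError(f"sampling rate must be positive, got {record.fs}")
    if len(record.leads) != 12:
        raise EcgFormatError(
            f"expected exactly 12 leads, got {len(record.leads)}: {record.leads}"
        )
    unknown = [l for l in record.leads if l not in STANDARD_LEADS]
    if unknown:
        raise EcgFormatError(f"unknown lead name(s): {unknown}")
    if len(set(record.leads)) != 12:
        raise EcgFormatError(f"duplicate lead names in {record.leads}")
    if record.data.ndim != 2 or record.data.shape[1] != 12:
        raise EcgFormatError(
            f"sample matrix must be (n_samples, 12), got shape {record.data.shape}"
        )
    if record.data.shape[0] == 0:
        raise EcgFormatError("record contains no samples")
    if not np.all(np.isfinite(record.data)):
        raise EcgFormatError("record contains non-finite samples")
    amax = float(np.max(np.abs(record.data)))
    if amax > VOLTAGE_RANGE_MV / 2 + 1e-12:
        raise EcgRangeError(
            f"sample of {amax:.4g} mV exceeds the +/-5 mV acquisition range "
            "(10 mV span, 16-bit); the tracing is clipped or mis-scaled"
        )


def quantize(data: np.ndarray) -> np.ndarray:
    """Snap samples to the 16-bit grid of the 10-mV digitizer range."""
    return np.round(np.asarray(data, float) / QUANTIZATION_STEP_MV) * QUANTIZATION_STEP_MV


def read_record(path, record_id: str | None = None) -> EcgRecord:
    """Parse a record from the text dialect (or permissive CSV fallback).

    The header consists of ``key=value`` lines (``fs`` required, ``leads``
    and ``gain`` optional); the body is a delimited numeric matrix with one
    column per lead, in mV.
    """
    header: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line and not body_lines and _looks_like_header(line):
                key, _, value = line.partition("=")
                header[key.strip().lower()] = value.strip()
            else:
                body_lines.append(line)

    if "fs" not in header:
        raise EcgFormatError(f"{path}: header does not declare a sampling rate (fs=...)")
    try:
        fs = float(header["fs"])
    except ValueError:
        raise EcgFormatError(f"{path}: invalid sampling rate {header['fs']!r}") from None

    leads = STANDARD_LEADS
    if "leads" in header:
        leads = tuple(l.strip() for l in header["leads"].split(",") if l.strip())
    gain = float(header.get("gain", 10.0))

    if not body_lines:
        raise EcgFormatError(f"{path}: no sample rows")
    sep = "\t" if "\t" in body_lines[0] else ","
    try:
        frame = pd.read_csv(
            io.StringIO("\n".join(body_lines)), sep=sep, header=None, dtype=float
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise EcgFormatError(f"{path}: ragged or non-numeric sample matrix: {exc}") from None
    if frame.isna().any().any():
        raise EcgFormatError(f"{path}: ragged rows or missing samples in matrix")

    name = record_id if record_id is not None else _stem(path)
    return EcgRecord(frame.to_numpy(), fs=fs, leads=leads, gain=gain, record_id=name)


def write_record(record: EcgRecord, path) -> None:
    """Write a record in the text dialect, applying 16-bit quantization.

    Round trip contract: ``read_record(write_record(r))`` equals ``r`` within
    one quantization step (10 mV / 2**16) per sample.
    """
    validate_record(record)
    data = quantize(record.data)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"fs={record.fs:g}\n")
        fh.write("leads=" + ",".join(record.leads) + "\n")
        fh.write(f"gain={record.gain:g}\n")
        np.savetxt(fh, data, fmt="%.6f", delimiter="\t")


def _looks_like_header(line: str) -> bool:
    key = line.partition("=")[0].strip().lower()
    return key in {"fs", "leads", "gain", "id"}


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
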
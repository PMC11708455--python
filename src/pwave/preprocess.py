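"""Acquisition-matching filters: 1-50 Hz band-pass and mains notch.

Both filters are applied zero-phase (forward-backward) so that fiducial
timing — the basis of every duration measurement downstream — is not
shifted by filter group delay. The band-pass is a Butterworth design; the
notch is a second-order IIR peak-reject filter. The acquisition chain the
package emulates states only the 1-50 Hz passband and the presence of a
notch; family, order and zero-phase application are this package's
choices. The default order (8) is deliberately steep: a 1-Hz high-pass
sits just below the beat fundamental (~1.25 Hz at 75 bpm), and a shallow
roll-off would strip part of that fundamental, leaving a large periodic
baseline drift under the P-wave (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .ecg_io import EcgRecord


@dataclass(frozen=True)
class FilterSpec:
    """Filter settings for one record.

    ``order`` is the analogue band-pass order (4 = two second-order
    sections); zero-phase application doubles the effective order.
    ``notch_hz`` is the mains frequency (50 Hz default, UK mains) and
    ``notch_q`` the notch quality factor (center / -3 dB bandwidth).
    """

    bp_low_hz: float = 1.0
    bp_high_hz: float = 50.0
    order: int = 8
    notch_hz: float = 50.0
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0.0 < self.bp_low_hz < self.bp_high_hz):
            raise ValueError(
                f"need 0 < low < high, got {self.bp_low_hz}, {self.bp_high_hz}"
            )
        if self.bp_high_hz >= nyq:
            raise ValueError(
                f"band-pass high cutoff {self.bp_high_hz} Hz >= Nyquist {nyq} Hz"
            )
        if self.order < 2:
            raise ValueError(f"filter order must be >= 2, got {self.order}")
        if not (0.0 < self.notch_hz < nyq):
            raise ValueError(f"notch center {self.notch_hz} Hz outside (0, Nyquist)")
        if self.notch_q <= 0:
            raise ValueError("notch quality factor must be positive")


def _filtfilt(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    padlen = min(data.shape[0] - 1, 3 * 10 * sos.shape[0])
    return signal.sosfiltfilt(sos, data, axis=0, padlen=padlen)


def bandpass(record: EcgRecord, spec: FilterSpec | None = None) -> EcgRecord:
    """Zero-phase Butterworth band-pass over all 12 leads."""
    spec = spec or FilterSpec()
    spec.validate(record.fs)
    if record.n_samples < 3 * spec.order + 1:
        raise ValueError(
            f"record of {record.n_samples} samples is shorter than the filter transient"
        )
    sos = signal.butter(
        spec.order // 2,
        [spec.bp_low_hz, spec.bp_high_hz],
        btype="bandpass",
        fs=record.fs,
        output="sos",
    )
    return record.with_data(_filtfilt(sos, record.data))


def notch(record: EcgRecord, spec: FilterSpec | None = None) -> EcgRecord:
    """Zero-phase second-order notch at the configured mains frequency."""
    spec = spec or FilterSpec()
    spec.validate(record.fs)
    b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=record.fs)
    sos = signal.tf2sos(b, a)
    return record.with_data(_filtfilt(sos, record.data))


def apply_filters(record: EcgRecord, spec: FilterSpec | None = None) -> EcgRecord:
    """Band-pass then notch — the full acquisition-matching chain."""
    spec = spec or FilterSpec()
    return notch(bandpass(record, spec), spec)
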
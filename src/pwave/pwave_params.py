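"""The four P-wave indices computed from a delineated template.

* PWD — P-wave duration, onset to offset, per lead; the global value is the
  maximum across measurable leads (a per-record marker of atrial
  conduction time; the max rule keeps it consistent with dispersion).
* PWV — P-wave voltage, distance from the isoelectric line (TP-segment
  baseline) to the P peak; reported as the sum over the 12 leads by
  default (``max`` and ``mean`` are selectable).
* PWDisp — P-wave dispersion, max minus min of the per-lead durations.
* PTFV1 — P-wave terminal force in V1: -(trough depth below baseline) x
  (duration of the terminal negative phase), non-positive by construction.
  Computed in mV*ms, the scale on which the emulated clinical reports
  print "mm.s" (multiply by ``CLASSICAL_MM_S`` for literal mm*s at
  10 mm/mV chart gain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg_io import STANDARD_LEADS
from .delineate import PwaveTemplate

#: Factor converting PTFV1 from mV*ms to classical mm*s at 10 mm/mV.
CLASSICAL_MM_S: float = 10.0 * 1e-3

#: A record must delineate at least this many leads to report global indices.
MIN_MEASURABLE_LEADS: int = 9


class MeasurementError(ValueError):
    """Raised when too few leads are measurable to report an index."""


@dataclass(frozen=True)
class PwaveParams:
    """Per-record P-wave indices. ``ptfv1`` is in mV*ms (<= 0)."""

    pwd_by_lead_ms: dict[str, float]
    pwd_ms: float
    pwv_mv: float
    pwdisp_ms: float
    ptfv1: float
    n_leads_measurable: int

    def __post_init__(self) -> None:
        if self.pwdisp_ms < -1e-9:
            raise ValueError("PWDisp must be >= 0")
        if self.ptfv1 > 1e-9:
            raise ValueError("PTFV1 must be <= 0")


def compute_pwd(
    fiducials: dict[str, tuple[int, int]], fs: float, rule: str = "max"
) -> tuple[dict[str, float], float]:
    """Per-lead and global P-wave duration from (onset, offset) indices.

    ``rule`` selects the lead-combination for the global value: ``max``
    (default) or ``mean``.
    """
    if not fiducials:
        raise MeasurementError("no measurable lead for PWD")
    per_lead = {
        lead: (offset - onset) / fs * 1000.0
        for lead, (onset, offset) in fiducials.items()
    }
    values = np.array(list(per_lead.values()))
    global_pwd = float(values.max() if rule == "max" else values.mean())
    return per_lead, global_pwd


def compute_pwv(
    amplitudes: dict[str, float], rule: str = "sum"
) -> float:
    """Combine per-lead P peak amplitudes (mV, baseline-referenced).

    ``sum`` (default) reproduces the ~1.2 mV magnitude of a combined
    12-lead analysis; ``max`` and ``mean`` are selectable.
    """
    if not amplitudes:
        raise MeasurementError("no measurable lead for PWV")
    values = np.abs(np.array(list(amplitudes.values())))
    return float({"sum": values.sum, "max": values.max, "mean": values.mean}[rule]())


def compute_pwdisp(per_lead_pwd: dict[str, float]) -> float:
    """Maximum difference between per-lead P-wave durations (ms)."""
    if len(per_lead_pwd) < 2:
        raise MeasurementError("PWDisp needs at least 2 measurable leads")
    values = np.array(list(per_lead_pwd.values()))
    return float(values.max() - values.min())


def compute_ptfv1(
    template_v1: np.ndarray,
    fs: float,
    baseline: np.ndarray | float,
    neg_phase: tuple[int, int, int] | None,
) -> float:
    """Terminal force: -(max absolute depth) x (negative-phase duration).

    ``baseline`` is the isoelectric line (scalar or per-sample). Returns 0
    when V1 has no negative phase; otherwise a value <= 0 in mV*ms.
    """
    if neg_phase is None:
        return 0.0
    start, trough, end = neg_phase
    base = np.broadcast_to(np.asarray(baseline, float), (len(template_v1),))
    depth = float(base[trough]) - float(template_v1[trough])
    duration_ms = (end - start) / fs * 1000.0
    if depth <= 0 or duration_ms <= 0:
        return 0.0
    return -depth * duration_ms


def measure_template(
    template: PwaveTemplate,
    pwd_rule: str = "max",
    pwv_rule: str = "sum",
    min_leads: int = MIN_MEASURABLE_LEADS,
) -> PwaveParams:
    """All four indices from a delineated template.

    Leads where delineation failed are dropped; fewer than ``min_leads``
    measurable leads raises :class:`MeasurementError` (quality guard).
    """
    fids = {
        lead: f for lead, f in template.fiducials.items()
        if f.measurable and f.onset is not None and f.offset is not None
    }
    if len(fids) < min_leads:
        raise MeasurementError(
            f"only {len(fids)} leads measurable; >= {min_leads} required"
        )
    onsets_offsets = {lead: (f.onset, f.offset) for lead, f in fids.items()}
    per_lead, global_pwd = compute_pwd(onsets_offsets, template.fs, rule=pwd_rule)
    amplitudes = {lead: f.amplitude_mv for lead, f in fids.items()}
    pwv = compute_pwv(amplitudes, rule=pwv_rule)
    pwdisp = compute_pwdisp(per_lead)

    v1 = fids.get("V1")
    if v1 is None:
        raise MeasurementError("V1 not measurable; PTFV1 unavailable")
    neg = (
        (v1.neg_start, v1.neg_trough, v1.neg_end)
        if v1.neg_trough is not None else None
    )
    v1_baseline = v1.baseline_fit if v1.baseline_fit is not None else v1.baseline_mv
    ptfv1 = compute_ptfv1(template.lead("V1"), template.fs, v1_baseline, neg)
    return PwaveParams(
        pwd_by_lead_ms=per_lead,
        pwd_ms=global_pwd,
        pwv_mv=pwv,
        pwdisp_ms=pwdisp,
        ptfv1=ptfv1,
        n_leads_measurable=len(fids),
    )
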
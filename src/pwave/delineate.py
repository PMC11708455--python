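"""Beat detection, P-wave template averaging and fiducial delineation.

The measurement protocol this implements: detect R peaks, average twenty
consecutive P-waves per lead into a template, then locate the P-wave onset,
peak and offset on the template. The onset is placed by a chord-distance
(knee) rule against the straight line joining the preceding T peak to the
P peak; the offset by the mirrored rule against the chord to QRS onset.
A support-refinement step (default on) then snaps each fiducial to the
edge of the region where the wave's excursion from the isoelectric line
exceeds ``exp(-2)`` (~13.5%) of its prominence — the level a Gaussian lobe
attains at the edge of its +/-2 sigma support, i.e. the same convention
the synthetic generator uses for analytic durations. The isoelectric line
itself is a local quadratic fit through the flat TP and PR segments
flanking the P-wave: a 1-Hz high-pass sits close to the beat fundamental
and leaves a smooth periodic baseline drift that a global (TP-median)
baseline cannot represent. See docs/methods.md for why the raw knee alone
carries a geometry-dependent bias of a few milliseconds.

Manual correction of fiducials (interactive in the original protocol) is
replaced by an :class:`AnnotationOverride` hook: caller-supplied indices
replace computed ones after ordering validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .ecg_io import STANDARD_LEADS, EcgRecord
from .synthetic_ecg import SUPPORT_LEVEL

#: Averaging window reaches this fraction of the median RR before each R peak.
WINDOW_RR_FRACTION: float = 0.6
#: Beats whose preceding RR deviates more than this from the median are excluded.
RR_TOLERANCE: float = 0.2
#: T peak is searched in this leading fraction of the template window.
T_SEARCH_FRACTION: float = 0.4
#: Minimum lobe prominence considered a P-wave candidate (mV).
MIN_P_PROMINENCE_MV: float = 0.012
#: Hysteresis for support-edge refinement: a crossing must persist this long.
REFINE_HYSTERESIS_MS: float = 5.0
#: Negative phases shallower than this fraction of the P prominence, or
#: 10 uV absolute, are treated as absent: below that depth the support
#: threshold (13.5% of depth) sinks under the residual noise floor and the
#: phase boundaries are no longer measurable.
MIN_NEG_DEPTH_FRACTION: float = 0.06
MIN_NEG_DEPTH_MV: float = 0.010


class DelineationError(ValueError):
    """Base class for delineation failures."""


class FlatSignalError(DelineationError):
    pass


class InsufficientBeatsError(DelineationError):
    pass


class NoPeakError(DelineationError):
    pass


class OverrideError(DelineationError):
    pass


@dataclass(frozen=True)
class BeatSet:
    """Detected R peaks and per-beat QRS onsets (sample indices, ascending)."""

    r_peaks: np.ndarray
    qrs_onsets: np.ndarray

    def __post_init__(self) -> None:
        r, q = np.asarray(self.r_peaks), np.asarray(self.qrs_onsets)
        if len(r) != len(q):
            raise ValueError("r_peaks and qrs_onsets must align one-to-one")
        if len(r) > 1 and not np.all(np.diff(r) > 0):
            raise ValueError("R peaks must be strictly increasing")
        if np.any(q >= r):
            raise ValueError("each QRS onset must precede its R peak")

    def __len__(self) -> int:
        return len(self.r_peaks)


@dataclass
class AnnotationOverride:
    """Manual replacement indices for one lead's fiducials (template indices)."""

    onset: int | None = None
    peak: int | None = None
    offset: int | None = None
    trough: int | None = None


@dataclass
class LeadFiducials:
    """Delineation result for one lead of the averaged template."""

    t_peak: int
    p_peak: int | None = None
    onset: int | None = None
    offset: int | None = None
    baseline_mv: float = 0.0          # isoelectric level under the P peak
    baseline_fit: np.ndarray | None = None  # fitted isoelectric line, full window
    amplitude_mv: float = 0.0         # P peak excursion above the isoelectric line
    neg_start: int | None = None
    neg_trough: int | None = None
    neg_end: int | None = None
    neg_depth_mv: float = 0.0         # V1 trough depth below the isoelectric line
    measurable: bool = False
    note: str = ""


@dataclass
class PwaveTemplate:
    """Beat-averaged pre-QRS segment for all 12 leads, with fiducials.

    ``data`` has shape ``(window_len, 12)``; index 0 lies
    ``r_offset`` samples before the aligned R peak and the last index is the
    estimated QRS onset.
    """

    data: np.ndarray
    fs: float
    r_offset: int
    n_beats: int
    rr_samples: float | None = None
    fiducials: dict[str, LeadFiducials] = field(default_factory=dict)

    @property
    def qrs_onset_idx(self) -> int:
        return self.data.shape[0] - 1

    def lead(self, name: str) -> np.ndarray:
        return self.data[:, STANDARD_LEADS.index(name)]

    def ms(self, n_samples: float) -> float:
        return n_samples / self.fs * 1000.0

    def fiducials_frame(self) -> pd.DataFrame:
        """Fiducials in ms from template start, one row per lead (CSV-ready)."""
        rows = []
        for lead in STANDARD_LEADS:
            f = self.fiducials.get(lead)
            if f is None:
                continue
            to_ms = lambda idx: None if idx is None else self.ms(idx)
            rows.append({
                "lead": lead,
                "measurable": f.measurable,
                "onset_ms": to_ms(f.onset),
                "peak_ms": to_ms(f.p_peak),
                "offset_ms": to_ms(f.offset),
                "neg_start_ms": to_ms(f.neg_start),
                "neg_trough_ms": to_ms(f.neg_trough),
                "neg_end_ms": to_ms(f.neg_end),
                "baseline_mv": f.baseline_mv,
                "note": f.note,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Beat detection
# ---------------------------------------------------------------------------

def detect_beats(
    record: EcgRecord,
    lead: str = "II",
    min_duration_s: float = 10.0,
    min_beats: int = 21,
) -> BeatSet:
    """Locate R peaks and QRS onsets with a derivative-energy detector.

    The squared, moving-averaged derivative of one lead is thresholded to
    find QRS complexes (Pan-Tompkins style); each R peak is then refined to
    the local signal maximum and its QRS onset estimated by walking back
    down the upstroke to near-baseline.
    """
    if record.duration_s < min_duration_s:
        raise DelineationError(
            f"record of {record.duration_s:.1f} s is shorter than "
            f"{min_duration_s:.0f} s"
        )
    x = record.lead(lead)
    fs = record.fs
    if float(np.ptp(x)) < 0.05:
        raise FlatSignalError(f"lead {lead} is flat (peak-to-peak < 0.05 mV)")

    energy = np.gradient(x) ** 2
    win = max(1, int(round(0.12 * fs)))
    energy = np.convolve(energy, np.ones(win) / win, mode="same")
    threshold = 0.2 * float(np.quantile(energy, 0.999))
    if threshold <= 0:
        raise FlatSignalError(f"lead {lead} has no QRS energy")
    peaks, _ = _sig.find_peaks(energy, height=threshold, distance=int(0.25 * fs))
    if len(peaks) == 0:
        raise FlatSignalError(f"no QRS-like activity found in lead {lead}")

    # refine each detection to the true R apex within +/-60 ms
    half = int(round(0.06 * fs))
    r_peaks = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        r_peaks.append(lo + int(np.argmax(x[lo:hi])))
    r_peaks = np.unique(r_peaks)

    qrs_onsets = []
    kept = []
    for r in r_peaks:
        onset = _qrs_onset_backtrack(x, r, fs)
        if onset is not None:
            kept.append(r)
            qrs_onsets.append(onset)
    if len(kept) < min_beats:
        raise InsufficientBeatsError(
            f"detected {len(kept)} beats; >= {min_beats} are required "
            f"(n_beats + 1 for averaging)"
        )
    return BeatSet(np.asarray(kept), np.asarray(qrs_onsets))


def _qrs_onset_backtrack(x: np.ndarray, r: int, fs: float) -> int | None:
    """Walk back from the R apex to where the upstroke leaves the baseline."""
    level = 0.02 * x[r]
    limit = max(0, r - int(round(0.12 * fs)))
    for i in range(r - 1, limit, -1):
        if x[i] < level:
            return i
    return None


# ---------------------------------------------------------------------------
# Template averaging
# ---------------------------------------------------------------------------

def average_pwave(record: EcgRecord, beats: BeatSet, n_beats: int = 20) -> PwaveTemplate:
    """Average ``n_beats`` consecutive pre-QRS segments into one template.

    Segments are aligned on the R peak and span from 60% of the median RR
    interval before it to the (median) QRS onset. Beats whose preceding RR
    deviates more than 20% from the record median are excluded before the
    first run of ``n_beats`` consecutive eligible beats is chosen.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if len(beats) < n_beats + 1:
        raise InsufficientBeatsError(
            f"{len(beats)} beats detected; need {n_beats + 1} for "
            f"{n_beats}-beat averaging"
        )
    r = beats.r_peaks
    rr = np.diff(r)
    rr_med = float(np.median(rr))
    a = int(round(WINDOW_RR_FRACTION * rr_med))
    b = int(round(float(np.median(beats.r_peaks - beats.qrs_onsets))))
    if a <= b:
        raise DelineationError("averaging window collapsed (RR too short)")

    n = record.n_samples
    eligible = np.zeros(len(r), dtype=bool)
    for i in range(1, len(r)):
        if abs(rr[i - 1] - rr_med) > RR_TOLERANCE * rr_med:
            continue
        if r[i] - a < 0 or r[i] - b >= n:
            continue
        eligible[i] = True

    start = _first_run(eligible, n_beats)
    if start is None:
        raise InsufficientBeatsError(
            f"no run of {n_beats} consecutive eligible beats "
            f"(ectopy/edge exclusions too dense)"
        )
    chosen = r[start:start + n_beats]
    segments = np.stack([record.data[rp - a: rp - b + 1, :] for rp in chosen])
    return PwaveTemplate(
        data=segments.mean(axis=0), fs=record.fs, r_offset=a, n_beats=n_beats,
        rr_samples=rr_med,
    )


def _first_run(mask: np.ndarray, length: int) -> int | None:
    run = 0
    for i, ok in enumerate(mask):
        run = run + 1 if ok else 0
        if run >= length:
            return i - length + 1
    return None


# ---------------------------------------------------------------------------
# Fiducial rules
# ---------------------------------------------------------------------------

def detect_t_peak(seg: np.ndarray) -> int:
    """Largest deflection in the leading part of the template window."""
    stop = max(2, int(T_SEARCH_FRACTION * len(seg)))
    return int(np.argmax(seg[:stop]))


def _p_candidate(
    seg: np.ndarray,
    fs: float,
    t_peak: int,
    qrs_onset: int,
    baseline: float,
    min_width_ms: float,
) -> tuple[int, float, float]:
    """P peak candidate with its half-prominence extent (left_ips, right_ips)."""
    if qrs_onset - t_peak < 3:
        raise NoPeakError("search window between T peak and QRS onset is empty")
    window = seg[t_peak + 1: qrs_onset]
    if float(np.ptp(window)) < MIN_P_PROMINENCE_MV:
        raise NoPeakError("window is flat: no lobe satisfies the width criterion")
    min_width = min_width_ms / 1000.0 * fs
    for sign in (1.0, -1.0):
        y = sign * (window - baseline)
        peaks, props = _sig.find_peaks(
            y, prominence=MIN_P_PROMINENCE_MV, width=min_width, rel_height=0.5
        )
        if len(peaks):
            best = int(np.argmax(props["prominences"]))
            shift = t_peak + 1
            return (
                shift + int(peaks[best]),
                shift + float(props["left_ips"][best]),
                shift + float(props["right_ips"][best]),
            )
    raise NoPeakError(f"no lobe of half-prominence width >= {min_width_ms} ms")


def detect_p_peak(
    seg: np.ndarray,
    fs: float,
    t_peak: int,
    qrs_onset: int,
    baseline: float,
    min_width_ms: float = 15.0,
) -> int:
    """P peak: the dominant lobe at least ``min_width_ms`` wide.

    Lobe width is measured at half prominence; deflections narrower than
    the threshold (spikes, notches) are ignored, and the most prominent
    qualifying lobe wins. Positive lobes are preferred; if none qualifies
    the rule is applied to the inverted signal so an entirely negative
    P-wave is still delineated.
    """
    return _p_candidate(seg, fs, t_peak, qrs_onset, baseline, min_width_ms)[0]


def _chord_knee(seg: np.ndarray, i0: int, i1: int, tie_later: bool = True) -> int:
    """Interior sample of maximal perpendicular distance to the chord i0->i1."""
    if i1 - i0 < 2:
        raise DelineationError(
            f"degenerate chord: endpoints {i0}, {i1} admit no interior sample"
        )
    idx = np.arange(i0 + 1, i1)
    dx, dy = float(i1 - i0), float(seg[i1] - seg[i0])
    # |cross product| of (chord vector, point - chord start), up to |chord|
    dist = np.abs(dy * (idx - i0) - dx * (seg[idx] - seg[i0]))
    best = dist.max()
    winners = np.flatnonzero(dist >= best - 1e-15)
    return int(idx[winners[-1] if tie_later else winners[0]])


def fit_isoelectric_line(
    seg: np.ndarray,
    t_peak: int,
    rough_onset: int,
    qrs_onset: int,
    fs: float = 1000.0,
    rr_samples: float | None = None,
) -> np.ndarray:
    """Local fit of the isoelectric line under the P-wave.

    Fitted through two flat flanks — the TP segment left of the P onset
    and the PR segment just before QRS onset — and evaluated over the
    whole template window. The residual drift that the 1-Hz high-pass
    leaves behind is beat-periodic (the beat fundamental sits just above
    the cutoff), so when the beat period is known the basis is
    ``{1, cos(2 pi t / RR), sin(2 pi t / RR)}``, which represents that
    drift exactly; otherwise a quadratic is used. On an undistorted record
    either fit reduces to the flat TP-segment level.
    """
    ms = fs / 1000.0  # samples per ms
    left_lo = max(
        t_peak + int(0.55 * (rough_onset - t_peak)), rough_onset - int(95 * ms)
    )
    left_hi = rough_onset - int(45 * ms)
    # the right flank stops 18 ms short of QRS onset: the zero-phase 50-Hz
    # low-pass smears a small undershoot backward from the QRS upstroke
    right_lo, right_hi = qrs_onset - int(45 * ms), qrs_onset - int(18 * ms)
    idx = np.concatenate([
        np.arange(max(0, left_lo), max(0, left_hi)),
        np.arange(max(0, right_lo), min(len(seg), right_hi)),
    ]).astype(float)
    if len(idx) < 8:
        # degenerate geometry: fall back to a constant (median) baseline
        level = float(np.median(seg[t_peak:qrs_onset]))
        return np.full(len(seg), level)
    t = np.arange(len(seg), dtype=float)
    if rr_samples is not None and rr_samples > 0:
        w = 2 * np.pi / rr_samples
        design = np.stack([np.ones_like(idx), np.cos(w * idx), np.sin(w * idx)], axis=1)
        basis = np.stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)], axis=1)
    else:
        design = np.vander(idx, 3)
        basis = np.vander(t, 3)
    coeffs, *_ = np.linalg.lstsq(design, seg[idx.astype(int)], rcond=None)
    return basis @ coeffs


def _support_edge(
    y: np.ndarray, peak: int, thr: float, lo: int, hi: int,
    fs: float, direction: int,
) -> int:
    """Snap a fiducial to the support edge of the lobe at ``peak``.

    ``y`` is the baseline-subtracted excursion, oriented so the lobe is
    positive. Walks from the peak in ``direction`` (-1 toward onset, +1
    toward offset) until the excursion stays below ``thr`` for
    ``REFINE_HYSTERESIS_MS``; returns the first sub-threshold sample
    (the support boundary).
    """
    m = max(1, int(round(REFINE_HYSTERESIS_MS / 1000.0 * fs)))
    i = peak + direction
    while lo <= i <= hi:
        if y[i] < thr:
            j0, j1 = (i, min(hi, i + m - 1)) if direction > 0 else (max(lo, i - m + 1), i)
            if np.all(y[j0:j1 + 1] < thr):
                # round to whichever sample lies nearer the true crossing
                prev = i - direction
                if abs(y[i] - thr) > abs(y[prev] - thr) and prev != peak:
                    return prev
                return i
        i += direction
    return lo if direction < 0 else hi


def locate_onset_offset(
    seg: np.ndarray,
    fs: float,
    t_peak: int,
    p_peak: int,
    qrs_onset: int,
    override: AnnotationOverride | None = None,
    refine: bool = True,
    rough_extent: tuple[float, float] | None = None,
    rr_samples: float | None = None,
) -> tuple[int, int, np.ndarray]:
    """P onset and offset via the chord (knee) rule, optionally refined.

    Onset: interior sample between the T peak and the P peak of maximal
    perpendicular distance to the straight chord joining them (ties to the
    later sample). Offset: mirrored rule on the chord from the P peak to
    the QRS onset (ties to the earlier sample). With ``refine`` the knee
    estimates are snapped to the edges of the region where the excursion
    above the fitted isoelectric line exceeds ``SUPPORT_LEVEL`` of the P
    prominence — the 2-sigma support convention under which durations are
    defined in this package.

    Returns ``(onset, offset, isoelectric_line)``.
    """
    if not (t_peak < p_peak < qrs_onset):
        raise DelineationError(
            f"need t_peak < p_peak < qrs_onset, got {t_peak}, {p_peak}, {qrs_onset}"
        )
    onset = _chord_knee(seg, t_peak, p_peak, tie_later=True)
    offset = _chord_knee(seg, p_peak, qrs_onset, tie_later=False)
    if rough_extent is not None:
        # anchor the baseline flanks on the lobe's half-prominence extent
        # (support edge of a Gaussian lobe = 1.70 x its half-width at half max)
        left_ips = rough_extent[0]
        onset_guess = int(round(p_peak - 1.70 * (p_peak - left_ips)))
        onset_guess = max(t_peak + 1, min(onset_guess, p_peak - 1))
    else:
        onset_guess = onset
    baseline = fit_isoelectric_line(
        seg, t_peak, onset_guess, qrs_onset, fs, rr_samples=rr_samples
    )
    if refine:
        excursion = seg - baseline
        sign = 1.0 if excursion[p_peak] >= 0 else -1.0
        y = sign * excursion
        thr = SUPPORT_LEVEL * y[p_peak]
        onset = _support_edge(y, p_peak, thr, t_peak + 1, p_peak - 1, fs, -1)
        offset = _support_edge(y, p_peak, thr, p_peak + 1, qrs_onset, fs, +1)

    if override is not None:
        if override.onset is not None:
            onset = override.onset
        if override.offset is not None:
            offset = override.offset
        if not (t_peak < onset < p_peak < offset <= qrs_onset):
            raise OverrideError(
                f"override breaks ordering t_peak < onset < peak < offset <= "
                f"qrs_onset: {t_peak}, {onset}, {p_peak}, {offset}, {qrs_onset}"
            )
    return onset, offset, baseline


def locate_v1_negative_phase(
    seg: np.ndarray,
    fs: float,
    p_peak: int,
    offset_limit: int,
    baseline: np.ndarray | float,
    onset: int | None = None,
) -> tuple[int, int, int] | None:
    """Terminal negative phase of the (biphasic) V1 P-wave.

    Returns ``(start, trough, end)`` for the contiguous sub-baseline run
    following the positive phase, delimited at ``SUPPORT_LEVEL`` of the
    trough depth (the 2-sigma support convention); ``None`` when no sample
    dips below the isoelectric line by a detectable depth. If the P-wave
    is entirely negative (``p_peak`` below baseline) the run spans the
    whole wave.
    """
    base = np.broadcast_to(np.asarray(baseline, float), (len(seg),))
    excursion = seg - base
    lo = p_peak if excursion[p_peak] < 0 else p_peak + 1
    if onset is not None and excursion[p_peak] < 0:
        lo = onset
    if offset_limit - lo < 2:
        return None
    trough = lo + int(np.argmin(excursion[lo:offset_limit + 1]))
    depth = -float(excursion[trough])
    prom = abs(float(excursion[p_peak]))
    if depth < max(MIN_NEG_DEPTH_MV, MIN_NEG_DEPTH_FRACTION * prom):
        return None
    y = -excursion
    thr = SUPPORT_LEVEL * depth
    start = _support_edge(y, trough, thr, lo, trough - 1, fs, -1)
    end = _support_edge(y, trough, thr, trough + 1, offset_limit, fs, +1)
    return start, trough, end


# ---------------------------------------------------------------------------
# Record-level orchestration
# ---------------------------------------------------------------------------

def delineate_template(
    template: PwaveTemplate,
    min_width_ms: float = 15.0,
    overrides: dict[str, AnnotationOverride] | None = None,
    refine: bool = True,
) -> PwaveTemplate:
    """Delineate every lead of an averaged template in place.

    Leads where any rule fails are marked unmeasurable with a note rather
    than aborting the record; downstream aggregation drops them.
    """
    overrides = overrides or {}
    qrs = template.qrs_onset_idx
    for lead in STANDARD_LEADS:
        seg = template.lead(lead)
        t_peak = detect_t_peak(seg)
        fid = LeadFiducials(t_peak=t_peak)
        template.fiducials[lead] = fid
        ov = overrides.get(lead)
        try:
            rough = float(np.median(seg[t_peak:qrs]))
            p_peak, l_ips, r_ips = _p_candidate(
                seg, template.fs, t_peak, qrs, rough, min_width_ms
            )
            if ov is not None and ov.peak is not None:
                if not (t_peak < ov.peak < qrs):
                    raise OverrideError(f"peak override {ov.peak} outside window")
                p_peak = ov.peak
            fid.p_peak = p_peak
            onset, offset, baseline = locate_onset_offset(
                seg, template.fs, t_peak, p_peak, qrs,
                override=ov, refine=refine, rough_extent=(l_ips, r_ips),
                rr_samples=template.rr_samples,
            )
            fid.onset, fid.offset = onset, offset
            fid.baseline_fit = baseline
            fid.baseline_mv = float(baseline[p_peak])
            fid.amplitude_mv = float(seg[p_peak] - baseline[p_peak])
            if lead == "V1":
                # stay clear of the QRS pre-undershoot left by the low-pass
                neg_limit = qrs - max(1, int(round(0.020 * template.fs)))
                neg = locate_v1_negative_phase(
                    seg, template.fs, p_peak, neg_limit, baseline, onset=onset
                )
                if neg is not None:
                    fid.neg_start, fid.neg_trough, fid.neg_end = neg
                    if ov is not None and ov.trough is not None:
                        if not (fid.neg_start <= ov.trough <= fid.neg_end):
                            raise OverrideError(
                                f"trough override {ov.trough} outside negative phase"
                            )
                        fid.neg_trough = ov.trough
                    fid.neg_depth_mv = float(
                        baseline[fid.neg_trough] - seg[fid.neg_trough]
                    )
                    # terminal negative phase defines the V1 offset
                    fid.offset = max(fid.offset, fid.neg_end)
            fid.measurable = True
        except OverrideError:
            raise
        except DelineationError as exc:
            fid.note = str(exc)
    return template


def load_overrides_csv(path, fs: float) -> dict[str, AnnotationOverride]:
    """Read per-lead fiducial overrides from a CSV in the export shape.

    Expected columns: ``lead`` plus any of ``onset_ms``, ``peak_ms``,
    ``offset_ms``, ``neg_trough_ms`` (times in ms from template start);
    empty cells leave the computed fiducial in place.
    """
    frame = pd.read_csv(path)
    overrides: dict[str, AnnotationOverride] = {}
    for _, row in frame.iterrows():
        lead = str(row["lead"])
        if lead not in STANDARD_LEADS:
            raise OverrideError(f"unknown lead {lead!r} in override file")
        to_idx = lambda key: (
            None if key not in row or pd.isna(row[key])
            else int(round(float(row[key]) / 1000.0 * fs))
        )
        overrides[lead] = AnnotationOverride(
            onset=to_idx("onset_ms"), peak=to_idx("peak_ms"),
            offset=to_idx("offset_ms"), trough=to_idx("neg_trough_ms"),
        )
    return overrides


def delineate_record(
    record: EcgRecord,
    n_beats: int = 20,
    min_width_ms: float = 15.0,
    overrides: dict[str, AnnotationOverride] | None = None,
    refine: bool = True,
    detection_lead: str = "II",
) -> PwaveTemplate:
    """Full chain: beat detection, averaging, per-lead delineation."""
    beats = detect_beats(record, lead=detection_lead, min_beats=n_beats + 1)
    template = average_pwave(record, beats, n_beats=n_beats)
    return delineate_template(
        template, min_width_ms=min_width_ms, overrides=overrides, refine=refine
    )
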
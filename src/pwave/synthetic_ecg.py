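"""Synthetic 12-lead sinus-rhythm ECG cohorts with known P-wave ground truth.

The generator exists so that the measurement chain (filtering, 20-beat
template averaging, delineation, parameter computation) can be validated
against analytically known values, and so that two-arm pre/post cohort
studies can be simulated at the sample sizes and effect sizes of a real
repeat-ablation cohort.

Waveform model
--------------
Each beat is a sum of compact smooth lobes on a flat baseline:

* one positive Gaussian P lobe per lead (amplitude ``a_l``, center ``c_l``,
  width ``w_l``), sharing a common P onset across leads;
* in V1 an additional *negative* Gaussian lobe immediately following the
  positive lobe, making the V1 P-wave biphasic — the substrate of the
  P-wave terminal force (PTFV1);
* a triangular QRS and a Gaussian T wave, identical across leads.

A Gaussian lobe has infinite tails, so "duration" needs a convention: a
lobe's support is defined as +/-2 sigma around its center, i.e. ``width =
4 sigma``, where the lobe has decayed to ``exp(-2)`` (~13.5%) of its
amplitude — the level at which a wave's departure from the isoelectric
line is reliably detectable above residual noise and filter-induced
baseline drift. All analytic durations below use this convention, and the
delineator's support-refinement stage uses the same relative level, which
is what makes ground truth and measurement commensurable.

Analytic ground truth (per patient, noiseless):

* per-lead PWD = lobe support width (V1: positive support + negative support),
* global PWD  = max over leads,
* PWV         = sum over leads of P peak amplitudes,
* PWDisp      = max - min of per-lead PWDs,
* PTFV1       = -(negative-lobe depth in mV) x (negative-lobe duration in ms).

Cohort model
------------
A cohort config specifies, per arm (success / fail) and phase (pre / post),
population means and between-patient SDs of the four analytic parameters.
Each patient draws a parameter tuple (post = pre + an independent delta),
from which lobe morphology is solved in closed form: fixed per-lead
duration fractions spread per-lead PWDs between the longest lead (II) and
shortest (V2), and fixed per-lead amplitude weights split PWV. With
``moment_match`` enabled the draws are standardized so the realized sample
mean and SD equal the population values exactly — the calibration then
holds at the study's finite n, not only in expectation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .ecg_io import STANDARD_LEADS, EcgRecord

DEFAULT_FS: float = 1000.0

#: Gaussian lobe support convention: width = GAUSS_SUPPORT_SIGMAS * sigma.
GAUSS_SUPPORT_SIGMAS: float = 4.0
#: Relative amplitude of a Gaussian lobe at the edge of its +/-2 sigma support.
SUPPORT_LEVEL: float = float(np.exp(-(GAUSS_SUPPORT_SIGMAS / 2) ** 2 / 2))
#: Flat separation between the V1 positive lobe support and the terminal
#: negative lobe support (ms), so each phase's edges are measurable without
#: interference from the other lobe's tail.
V1_PHASE_GAP_MS: float = 10.0

#: QRS onset time within the beat (ms); P and T are laid out around it.
QRS_ONSET_MS: float = 340.0
#: R apex sits this fraction of the QRS width after QRS onset.
QRS_APEX_FRACTION: float = 0.4
#: T-wave center relative to QRS onset (ms).
T_CENTER_AFTER_QRS_MS: float = 380.0

#: Fraction of the P-duration spread (PWDisp) subtracted per lead.
#: Lead II carries the longest P (fraction 0), V2 the shortest (fraction 1).
LEAD_DURATION_FRACTIONS: dict[str, float] = {
    "II": 0.00, "aVF": 0.11, "I": 0.20, "V6": 0.28, "V5": 0.36, "aVL": 0.44,
    "V1": 0.50, "V4": 0.58, "III": 0.66, "V3": 0.74, "aVR": 0.85, "V2": 1.00,
}

#: Fraction of total PWV carried by each lead's P peak (sums to 1).
LEAD_AMPLITUDE_WEIGHTS: dict[str, float] = {
    "I": 0.082, "II": 0.107, "III": 0.067, "aVR": 0.075, "aVL": 0.058,
    "aVF": 0.090, "V1": 0.063, "V2": 0.082, "V3": 0.090, "V4": 0.098,
    "V5": 0.098, "V6": 0.090,
}


class MorphologyError(ValueError):
    """Raised when waveform morphology parameters violate their invariants."""


@dataclass(frozen=True)
class PwaveMorphology:
    """Lobe-level description of one patient's beat, times in ms from beat start.

    ``p_width`` values use the 4-sigma support convention; ``v1_neg_depth``
    is stored as a non-negative depth in mV.
    """

    p_amp: dict[str, float]          # positive P-lobe amplitude per lead, mV
    p_center: dict[str, float]       # positive P-lobe center per lead, ms
    p_width: dict[str, float]        # positive P-lobe support width per lead, ms
    v1_neg_depth: float              # V1 negative-lobe depth, mV (>= 0)
    v1_neg_center: float             # V1 negative-lobe center, ms
    v1_neg_width: float              # V1 negative-lobe support width, ms
    qrs_amp: float = 1.0             # R amplitude, mV
    qrs_width: float = 80.0          # QRS base width, ms
    t_amp: float = 0.10              # T amplitude, mV
    t_width: float = 150.0           # T support width, ms
    pr_ms: float = 180.0             # common P onset to QRS onset, ms
    heart_rate_bpm: float = 75.0

    def __post_init__(self) -> None:
        for lead in STANDARD_LEADS:
            if lead not in self.p_amp or lead not in self.p_center or lead not in self.p_width:
                raise MorphologyError(f"missing P-lobe parameters for lead {lead}")
        widths = list(self.p_width.values()) + [
            self.v1_neg_width, self.qrs_width, self.t_width
        ]
        if any(w <= 0 for w in widths):
            raise MorphologyError("all lobe widths must be positive")
        if not (30.0 <= self.heart_rate_bpm <= 180.0):
            raise MorphologyError(
                f"heart rate {self.heart_rate_bpm} bpm outside [30, 180]"
            )
        if self.v1_neg_depth < 0:
            raise MorphologyError("V1 negative-lobe depth must be >= 0 (stored as depth)")
        if self.v1_neg_center < self.p_center["V1"]:
            raise MorphologyError(
                "V1 negative lobe must not begin before the positive-lobe center"
            )
        qrs_onset = self.p_onset_ms + self.pr_ms
        for lead in STANDARD_LEADS:
            if self.p_end_ms(lead) > qrs_onset + 1e-9:
                raise MorphologyError(
                    f"P-wave in lead {lead} ends after QRS onset ({qrs_onset:.1f} ms)"
                )
        if qrs_onset + self.qrs_width + self.t_width >= self.rr_ms:
            raise MorphologyError("beat content does not fit in one RR interval")

    @property
    def rr_ms(self) -> float:
        return 60000.0 / self.heart_rate_bpm

    @property
    def p_onset_ms(self) -> float:
        """Common analytic P onset: earliest lobe-support start across leads."""
        return min(self.p_center[l] - self.p_width[l] / 2 for l in STANDARD_LEADS)

    def p_end_ms(self, lead: str) -> float:
        end = self.p_center[lead] + self.p_width[lead] / 2
        if lead == "V1" and self.v1_neg_depth > 0:
            end = max(end, self.v1_neg_center + self.v1_neg_width / 2)
        return end


@dataclass(frozen=True)
class NoiseConfig:
    """Additive artifact model: white noise, baseline wander, mains hum."""

    white_uv: float = 10.0
    wander_uv: float = 50.0
    wander_hz: float = 0.25
    mains_uv: float = 20.0
    mains_hz: float = 50.0

    def __post_init__(self) -> None:
        if min(self.white_uv, self.wander_uv, self.mains_uv) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.mains_hz not in (50.0, 60.0, 50, 60):
            raise ValueError(f"mains frequency must be 50 or 60 Hz, got {self.mains_hz}")

    @classmethod
    def silent(cls) -> "NoiseConfig":
        return cls(white_uv=0.0, wander_uv=0.0, mains_uv=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic fiducials and parameter values for one noiseless beat.

    All times in ms from beat start; durations in ms; amplitudes in mV;
    ``ptfv1`` in mV*ms (the scale on which clinical reports print "mm.s").
    """

    onset_ms: dict[str, float]
    peak_ms: dict[str, float]
    offset_ms: dict[str, float]
    pwd_ms: dict[str, float]
    global_pwd_ms: float
    pwv_mv: float
    pwdisp_ms: float
    ptfv1: float
    v1_neg_start_ms: float | None
    v1_neg_trough_ms: float | None
    v1_neg_end_ms: float | None
    qrs_onset_ms: float
    r_peak_ms: float
    t_peak_ms: float


@dataclass(frozen=True)
class PatientTemplate:
    """One-beat 12-lead waveform sampled at ``fs``, with its ground truth."""

    beat: np.ndarray              # (n_samples_per_beat, 12), mV
    fs: float
    rr_ms: float
    morphology: PwaveMorphology
    ground_truth: GroundTruth


def _gaussian(t_ms: np.ndarray, amp: float, center: float, width: float) -> np.ndarray:
    sigma = width / GAUSS_SUPPORT_SIGMAS
    return amp * np.exp(-0.5 * ((t_ms - center) / sigma) ** 2)


def _triangle(t_ms: np.ndarray, amp: float, onset: float, width: float,
              apex_fraction: float) -> np.ndarray:
    apex = onset + apex_fraction * width
    end = onset + width
    up = np.clip((t_ms - onset) / (apex - onset), 0.0, 1.0)
    down = np.clip((end - t_ms) / (end - apex), 0.0, 1.0)
    return amp * np.minimum(up, down)


def make_patient_template(morph: PwaveMorphology, fs: float = DEFAULT_FS) -> PatientTemplate:
    """Render one beat per lead and compute its analytic ground truth.

    Requires ``fs >= 250`` Hz so that the narrowest lobes are resolved.
    """
    if fs < 250.0:
        raise ValueError(f"sampling rate {fs} Hz unsupported; need >= 250 Hz")
    n = int(round(morph.rr_ms / 1000.0 * fs))
    t = np.arange(n) / fs * 1000.0  # ms within beat

    qrs_onset = morph.p_onset_ms + morph.pr_ms
    t_center = qrs_onset + T_CENTER_AFTER_QRS_MS
    common = (
        _triangle(t, morph.qrs_amp, qrs_onset, morph.qrs_width, QRS_APEX_FRACTION)
        + _gaussian(t, morph.t_amp, t_center, morph.t_width)
    )
    beat = np.empty((n, 12))
    for j, lead in enumerate(STANDARD_LEADS):
        wave = common + _gaussian(
            t, morph.p_amp[lead], morph.p_center[lead], morph.p_width[lead]
        )
        if lead == "V1" and morph.v1_neg_depth > 0:
            wave = wave - _gaussian(
                t, morph.v1_neg_depth, morph.v1_neg_center, morph.v1_neg_width
            )
        beat[:, j] = wave

    gt = _ground_truth(morph, qrs_onset, t_center)
    return PatientTemplate(
        beat=beat, fs=fs, rr_ms=morph.rr_ms, morphology=morph, ground_truth=gt
    )


def _ground_truth(morph: PwaveMorphology, qrs_onset: float, t_center: float) -> GroundTruth:
    onset: dict[str, float] = {}
    peak: dict[str, float] = {}
    offset: dict[str, float] = {}
    pwd: dict[str, float] = {}
    for lead in STANDARD_LEADS:
        onset[lead] = morph.p_center[lead] - morph.p_width[lead] / 2
        peak[lead] = morph.p_center[lead]
        offset[lead] = morph.p_end_ms(lead)
        pwd[lead] = offset[lead] - onset[lead]

    pwv = sum(morph.p_amp[l] for l in STANDARD_LEADS)
    pwds = list(pwd.values())
    if morph.v1_neg_depth > 0:
        neg_start = morph.v1_neg_center - morph.v1_neg_width / 2
        neg_trough = morph.v1_neg_center
        neg_end = morph.v1_neg_center + morph.v1_neg_width / 2
        ptfv1 = -morph.v1_neg_depth * morph.v1_neg_width
    else:
        neg_start = neg_trough = neg_end = None
        ptfv1 = 0.0
    return GroundTruth(
        onset_ms=onset,
        peak_ms=peak,
        offset_ms=offset,
        pwd_ms=pwd,
        global_pwd_ms=max(pwds),
        pwv_mv=pwv,
        pwdisp_ms=max(pwds) - min(pwds),
        ptfv1=ptfv1,
        v1_neg_start_ms=neg_start,
        v1_neg_trough_ms=neg_trough,
        v1_neg_end_ms=neg_end,
        qrs_onset_ms=qrs_onset,
        r_peak_ms=qrs_onset + QRS_APEX_FRACTION * morph.qrs_width,
        t_peak_ms=t_center,
    )


def generate_record(
    template: PatientTemplate,
    duration_s: float,
    noise: NoiseConfig | None = None,
    seed: int | np.random.Generator = 0,
    record_id: str = "",
) -> EcgRecord:
    """Tile the patient's beat over ``duration_s`` and add artifacts.

    Beats are tiled at the template RR interval; white noise is independent
    per lead and sample, baseline wander and mains hum are sinusoids with
    per-lead random phase. Bit-reproducible for a fixed seed.
    """
    noise = noise or NoiseConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_total = int(round(duration_s * template.fs))
    n_beat = template.beat.shape[0]
    if n_total < n_beat:
        raise ValueError(
            f"duration {duration_s} s yields no complete beat at "
            f"{template.rr_ms:.0f} ms RR"
        )
    reps = int(np.ceil(n_total / n_beat))
    data = np.tile(template.beat, (reps, 1))[:n_total].copy()

    t = np.arange(n_total) / template.fs
    if noise.white_uv > 0:
        data += rng.normal(0.0, noise.white_uv / 1000.0, size=data.shape)
    for amp_uv, freq in ((noise.wander_uv, noise.wander_hz), (noise.mains_uv, noise.mains_hz)):
        if amp_uv > 0:
            phases = rng.uniform(0.0, 2 * np.pi, size=12)
            data += (amp_uv / 1000.0) * np.sin(
                2 * np.pi * freq * t[:, None] + phases[None, :]
            )
    return EcgRecord(data, fs=template.fs, record_id=record_id)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterPopulation:
    """Population mean/SD of one analytic parameter, pre level and pre-to-post delta."""

    pre_mean: float
    pre_sd: float
    delta_mean: float
    delta_sd: float


@dataclass(frozen=True)
class ArmPopulation:
    n: int
    pwd_ms: ParameterPopulation
    pwv_mv: ParameterPopulation
    pwdisp_ms: ParameterPopulation
    ptfv1: ParameterPopulation

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("arm size must be >= 1")
        for name in ("pwd_ms", "pwv_mv", "pwdisp_ms", "ptfv1"):
            pop = getattr(self, name)
            if pop.pre_sd < 0 or pop.delta_sd < 0:
                raise ValueError(f"{name}: population SDs must be >= 0")


@dataclass(frozen=True)
class StructureConfig:
    """Morphology features shared across the cohort (not calibration targets)."""

    heart_rate_bpm: float = 75.0
    qrs_amp_mv: float = 1.0
    qrs_width_ms: float = 80.0
    t_amp_mv: float = 0.10
    t_width_ms: float = 150.0
    pr_margin_ms: float = 80.0       # longest P offset to QRS onset
    neg_duration_mean_ms: float = 52.0
    neg_duration_sd_ms: float = 8.0


@dataclass(frozen=True)
class CohortConfig:
    arms: dict[str, ArmPopulation]
    noise: NoiseConfig = NoiseConfig()
    structure: StructureConfig = StructureConfig()
    fs_hz: float = DEFAULT_FS
    duration_s: float = 60.0
    n_beats_average: int = 20
    moment_match: bool = True

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("cohort config must define at least one arm")
        rr_s = 60.0 / self.structure.heart_rate_bpm
        # +2: one leading beat is lost to the averaging window, plus slack.
        if self.duration_s < (self.n_beats_average + 2) * rr_s:
            raise ValueError(
                f"duration {self.duration_s} s too short for "
                f"{self.n_beats_average}-beat averaging at "
                f"{self.structure.heart_rate_bpm} bpm"
            )

    @property
    def n_total(self) -> int:
        return sum(a.n for a in self.arms.values())

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        arms = {
            name: ArmPopulation(
                n=int(spec["n"]),
                **{
                    key: ParameterPopulation(**spec[key])
                    for key in ("pwd_ms", "pwv_mv", "pwdisp_ms", "ptfv1")
                },
            )
            for name, spec in raw["arms"].items()
        }
        return cls(
            arms=arms,
            noise=NoiseConfig(**raw.get("noise", {})),
            structure=StructureConfig(**raw.get("structure", {})),
            fs_hz=float(raw.get("fs_hz", DEFAULT_FS)),
            duration_s=float(raw.get("duration_s", 60.0)),
            n_beats_average=int(raw.get("n_beats_average", 20)),
            moment_match=bool(raw.get("moment_match", True)),
        )

    def to_dict(self) -> dict:
        return {
            "fs_hz": self.fs_hz,
            "duration_s": self.duration_s,
            "n_beats_average": self.n_beats_average,
            "moment_match": self.moment_match,
            "noise": dataclasses.asdict(self.noise),
            "structure": dataclasses.asdict(self.structure),
            "arms": {
                name: {
                    "n": arm.n,
                    **{
                        key: dataclasses.asdict(getattr(arm, key))
                        for key in ("pwd_ms", "pwv_mv", "pwdisp_ms", "ptfv1")
                    },
                }
                for name, arm in self.arms.items()
            },
        }


@dataclass(frozen=True)
class PatientPhase:
    record: EcgRecord
    ground_truth: GroundTruth
    morphology: PwaveMorphology
    template: PatientTemplate


@dataclass(frozen=True)
class Patient:
    patient_id: str
    arm: str
    pre: PatientPhase
    post: PatientPhase


class CohortDrawError(RuntimeError):
    """Raised when no feasible morphology draw is found within the retry budget."""


#: Hard clips for per-patient parameter draws; the tails they trim carry a
#: few per mille of probability mass under the packaged calibration, so the
#: clip bias on arm means is negligible.
_BOUNDS = {
    "pwd": (60.0, 210.0),
    "pwdisp": (5.0, 60.0),
    "pwv": (0.4, 2.5),
    "ptfv1": (-10.0, -0.6),
}
#: V1 positive-lobe support floor (keeps its half-prominence width >= 15 ms
#: with margin; Gaussian FWHM = 0.589 * support width).
_V1_MIN_POS_WIDTH_MS = 40.0
_NEG_DURATION_RANGE_MS = (20.0, 80.0)
_MAX_NEG_DEPTH_MV = 0.30
#: Shallowest trough the delineator can bound reliably (with margin above
#: its 10-uV floor); durations are capped so depth stays above this.
_MIN_NEG_DEPTH_MV = 0.013
#: Range of the per-patient V1 duration fraction; shrunk below the default
#: 0.5 when a short global PWD leaves no room for the terminal phase.
_V1_FRACTION_RANGE = (0.10, 0.50)


def _standardized_normal(rng: np.random.Generator, n: int) -> np.ndarray:
    """Standard-normal draws rescaled to exact sample mean 0 and SD 1 (ddof=1)."""
    if n == 1:
        return np.zeros(1)
    z = rng.standard_normal(n)
    z = z - z.mean()
    s = z.std(ddof=1)
    if s == 0.0:
        return np.zeros(n)
    return z / s


def _draw_vector(rng: np.random.Generator, n: int, mean: float, sd: float,
                 moment_match: bool) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    if moment_match:
        return mean + sd * _standardized_normal(rng, n)
    return mean + sd * rng.standard_normal(n)


def _draw_arm_parameters(
    rng: np.random.Generator, arm: ArmPopulation, structure: StructureConfig,
    moment_match: bool,
) -> dict[str, np.ndarray]:
    """Draw per-patient analytic parameters for one arm, both phases.

    Calibration targets (the four parameters) are drawn once and kept:
    every morphology-feasibility conflict is absorbed by non-target
    structural degrees of freedom (the patient's V1 duration fraction and
    terminal-phase duration), so moment-matched vectors retain their exact
    sample moments. Extreme tails are clipped at documented hard bounds.
    """
    n = arm.n
    draws: dict[str, np.ndarray] = {}
    for key, pop in (("pwd", arm.pwd_ms), ("pwv", arm.pwv_mv),
                     ("pwdisp", arm.pwdisp_ms), ("ptfv1", arm.ptfv1)):
        pre = _draw_vector(rng, n, pop.pre_mean, pop.pre_sd, moment_match)
        delta = _draw_vector(rng, n, pop.delta_mean, pop.delta_sd, moment_match)
        lo, hi = _BOUNDS[key]
        draws[f"{key}_pre"] = np.clip(pre, lo, hi)
        draws[f"{key}_post"] = np.clip(pre + delta, lo, hi)
    draws["neg_dur"] = _draw_vector(
        rng, n, structure.neg_duration_mean_ms, structure.neg_duration_sd_ms, False
    )
    _accommodate_v1(draws)
    return draws


def _accommodate_v1(d: dict[str, np.ndarray]) -> None:
    """Fit each patient's V1 terminal phase inside the drawn durations.

    The V1 P-wave must hold a positive lobe (>= ``_V1_MIN_POS_WIDTH_MS``),
    the inter-phase gap and the terminal negative lobe. The patient's V1
    duration fraction is lowered below the default 0.5 when needed, the
    drawn terminal-phase duration is clipped into its feasible band, and as
    a last resort (vanishingly rare under the packaged calibration) the
    patient's dispersion draw is shrunk.
    """
    g_lo, g_hi = _V1_FRACTION_RANGE
    pwd_min = np.minimum(d["pwd_pre"], d["pwd_post"])
    disp_max = np.maximum(d["pwdisp_pre"], d["pwdisp_post"])
    dur_lo = np.maximum(
        _NEG_DURATION_RANGE_MS[0],
        np.maximum(-d["ptfv1_pre"], -d["ptfv1_post"]) / _MAX_NEG_DEPTH_MV,
    )
    # smallest V1 fraction that still leaves room for positive lobe + gap + lobe
    need = _V1_MIN_POS_WIDTH_MS + V1_PHASE_GAP_MS + dur_lo
    g = np.clip((pwd_min - need) / np.maximum(disp_max, 1e-9), g_lo, g_hi)
    budget = pwd_min - g * disp_max - V1_PHASE_GAP_MS - _V1_MIN_POS_WIDTH_MS
    short = budget < dur_lo
    if np.any(short):
        # shrink the dispersion draw until the terminal phase fits
        disp_fit = np.maximum((pwd_min - need) / g_lo, 5.0)
        for key in ("pwdisp_pre", "pwdisp_post"):
            d[key] = np.where(short, np.minimum(d[key], disp_fit), d[key])
        disp_max = np.maximum(d["pwdisp_pre"], d["pwdisp_post"])
        g = np.clip((pwd_min - need) / np.maximum(disp_max, 1e-9), g_lo, g_hi)
        budget = pwd_min - g * disp_max - V1_PHASE_GAP_MS - _V1_MIN_POS_WIDTH_MS
        still = budget < dur_lo
        if np.any(still):
            # last resort: raise the duration draw to the feasible floor
            floor = dur_lo + _V1_MIN_POS_WIDTH_MS + V1_PHASE_GAP_MS + g_lo * disp_max
            for key in ("pwd_pre", "pwd_post"):
                d[key] = np.where(still, np.maximum(d[key], floor), d[key])
            pwd_min = np.minimum(d["pwd_pre"], d["pwd_post"])
            budget = pwd_min - g * disp_max - V1_PHASE_GAP_MS - _V1_MIN_POS_WIDTH_MS
    hi = np.minimum(_NEG_DURATION_RANGE_MS[1], budget)
    # keep the trough deep enough to measure: duration <= |PTFV1| / min depth
    ptf_min = np.minimum(-d["ptfv1_pre"], -d["ptfv1_post"])
    hi = np.minimum(hi, ptf_min / _MIN_NEG_DEPTH_MV)
    dur_lo = np.minimum(dur_lo, hi)  # depth floor outranks the nominal 20-ms floor
    if np.any(hi < 1.0):
        raise CohortDrawError("cohort config leaves no room for the V1 terminal phase")
    d["neg_dur"] = np.clip(d["neg_dur"], dur_lo, hi)
    d["v1_fraction"] = g


def morphology_from_parameters(
    pwd_ms: float,
    pwv_mv: float,
    pwdisp_ms: float,
    ptfv1: float,
    neg_duration_ms: float,
    structure: StructureConfig | None = None,
    v1_fraction: float = LEAD_DURATION_FRACTIONS["V1"],
) -> PwaveMorphology:
    """Solve lobe morphology whose analytic parameters equal the given values.

    ``pwd_ms`` is the global (longest-lead) P duration, ``pwdisp_ms`` the
    max-min spread across leads, ``pwv_mv`` the 12-lead sum of P peak
    amplitudes and ``ptfv1`` the (non-positive) V1 terminal force in mV*ms.
    """
    structure = structure or StructureConfig()
    if ptfv1 > 0:
        raise ValueError(f"PTFV1 must be <= 0, got {ptfv1}")
    widths = {
        lead: pwd_ms - LEAD_DURATION_FRACTIONS[lead] * pwdisp_ms
        for lead in STANDARD_LEADS
    }
    widths["V1"] = pwd_ms - v1_fraction * pwdisp_ms
    v1_total = widths["V1"]
    if ptfv1 < 0:
        neg_width = float(neg_duration_ms)
        pos_width_v1 = v1_total - neg_width - V1_PHASE_GAP_MS
        depth = -ptfv1 / neg_width
    else:
        neg_width = 1.0  # unused; depth 0 disables the lobe
        pos_width_v1 = v1_total
        depth = 0.0
    if pos_width_v1 <= 0:
        raise MorphologyError(
            f"V1 terminal phase of {neg_duration_ms} ms does not fit a "
            f"{v1_total:.1f} ms V1 P-wave"
        )
    widths["V1"] = pos_width_v1

    pr = pwd_ms + structure.pr_margin_ms
    onset = QRS_ONSET_MS - pr
    if onset <= 0:
        raise MorphologyError(f"PR of {pr:.0f} ms pushes the P onset before beat start")
    centers = {lead: onset + widths[lead] / 2 for lead in STANDARD_LEADS}
    amps = {lead: pwv_mv * LEAD_AMPLITUDE_WEIGHTS[lead] for lead in STANDARD_LEADS}
    return PwaveMorphology(
        p_amp=amps,
        p_center=centers,
        p_width=widths,
        v1_neg_depth=depth,
        v1_neg_center=onset + pos_width_v1
        + (V1_PHASE_GAP_MS if depth > 0 else 0.0) + neg_width / 2,
        v1_neg_width=neg_width,
        qrs_amp=structure.qrs_amp_mv,
        qrs_width=structure.qrs_width_ms,
        t_amp=structure.t_amp_mv,
        t_width=structure.t_width_ms,
        pr_ms=pr,
        heart_rate_bpm=structure.heart_rate_bpm,
    )


def default_morphology(**overrides) -> PwaveMorphology:
    """A representative sinus-rhythm morphology (pre-ablation magnitudes)."""
    params = dict(
        pwd_ms=136.7, pwv_mv=1.2, pwdisp_ms=29.7, ptfv1=-3.1,
        neg_duration_ms=52.0,
    )
    params.update(overrides)
    return morphology_from_parameters(**params)


def generate_cohort(cfg: CohortConfig, seed: int = 0) -> list[Patient]:
    """Generate the full two-arm pre/post cohort; reproducible given seed."""
    root = np.random.SeedSequence(seed)
    arm_seeds = root.spawn(len(cfg.arms))
    patients: list[Patient] = []
    for (arm_name, arm), arm_seq in zip(sorted(cfg.arms.items()), arm_seeds):
        param_rng = np.random.default_rng(arm_seq.spawn(1)[0])
        draws = _draw_arm_parameters(param_rng, arm, cfg.structure, cfg.moment_match)
        record_seqs = arm_seq.spawn(arm.n)
        for i in range(arm.n):
            pid = f"{arm_name}-{i + 1:03d}"
            rec_rngs = [np.random.default_rng(s) for s in record_seqs[i].spawn(2)]
            phases = {}
            for phase, rng in zip(("pre", "post"), rec_rngs):
                morph = morphology_from_parameters(
                    pwd_ms=float(draws[f"pwd_{phase}"][i]),
                    pwv_mv=float(draws[f"pwv_{phase}"][i]),
                    pwdisp_ms=float(draws[f"pwdisp_{phase}"][i]),
                    ptfv1=float(draws[f"ptfv1_{phase}"][i]),
                    neg_duration_ms=float(draws["neg_dur"][i]),
                    structure=cfg.structure,
                    v1_fraction=float(draws["v1_fraction"][i]),
                )
                template = make_patient_template(morph, cfg.fs_hz)
                record = generate_record(
                    template, cfg.duration_s, cfg.noise, rng,
                    record_id=f"{pid}-{phase}",
                )
                phases[phase] = PatientPhase(
                    record=record, ground_truth=template.ground_truth,
                    morphology=morph, template=template,
                )
            patients.append(
                Patient(patient_id=pid, arm=arm_name, pre=phases["pre"], post=phases["post"])
            )
    return patients


def ground_truth_frame(patients: list[Patient]):
    """Analytic ground truth as a tidy frame: one row per patient x phase x lead."""
    import pandas as pd

    rows = []
    for p in patients:
        for phase_name, phase in (("pre", p.pre), ("post", p.post)):
            gt = phase.ground_truth
            for lead in STANDARD_LEADS:
                rows.append({
                    "patient_id": p.patient_id,
                    "arm": p.arm,
                    "phase": phase_name,
                    "lead": lead,
                    "onset_ms": gt.onset_ms[lead],
                    "peak_ms": gt.peak_ms[lead],
                    "offset_ms": gt.offset_ms[lead],
                    "pwd_ms": gt.pwd_ms[lead],
                    "global_pwd_ms": gt.global_pwd_ms,
                    "pwv_mv": gt.pwv_mv,
                    "pwdisp_ms": gt.pwdisp_ms,
                    "ptfv1": gt.ptfv1,
                })
    return pd.DataFrame(rows)


def default_calibration_path() -> str:
    """Path of the packaged cohort calibration config."""
    from importlib import resources

    return str(resources.files("pwave").joinpath("data", "calibration.yaml"))


def load_calibration(**overrides) -> CohortConfig:
    """The packaged calibration, optionally with top-level field overrides."""
    cfg = CohortConfig.from_yaml(default_calibration_path())
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg
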
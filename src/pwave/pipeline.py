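"""End-to-end study orchestration: simulate, measure, compare, report.

``run_study`` generates (or loads) a two-arm pre/post cohort, pushes every
record through the acquisition-matching filters, 20-beat P-wave template
averaging and delineation, computes the four P-wave indices per record,
and assembles arm-level summaries (mean +/- SEM), within-arm paired
comparisons and between-arm comparisons of the pre-to-post change scores.

Generated records are passed through the writer's 16-bit quantization
before measurement, so the in-memory path is sample-identical to a
write/read round trip through the text dialect.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats as cs
from .delineate import (
    AnnotationOverride, DelineationError, PwaveTemplate, delineate_record,
    delineate_template,
)
from .ecg_io import EcgRecord, STANDARD_LEADS, quantize, read_record, write_record
from .preprocess import FilterSpec, apply_filters
from .pwave_params import MeasurementError, PwaveParams, measure_template
from .synthetic_ecg import CohortConfig, Patient, generate_cohort

log = logging.getLogger("pwave")

PARAMETERS: tuple[str, ...] = ("pwd_ms", "pwv_mv", "pwdisp_ms", "ptfv1")


@dataclass
class StudyReport:
    """Per-arm pre/post summaries and comparison results for one run."""

    measurements: pd.DataFrame          # one row per patient x phase
    summaries: pd.DataFrame             # arm x phase x parameter mean/SEM
    within_arm: dict[tuple[str, str], cs.ComparisonResult]
    between_arm: dict[str, cs.ComparisonResult]
    n_per_arm: dict[str, int]
    excluded: list[str]
    seed: int
    config_hash: str

    def to_text(self) -> str:
        lines = [
            "P-wave parameter study report",
            f"seed={self.seed} config={self.config_hash[:12]}",
            "patients: "
            + ", ".join(f"{arm} n={n}" for arm, n in sorted(self.n_per_arm.items()))
            + f" (total {sum(self.n_per_arm.values())})",
            f"excluded: {len(self.excluded)}"
            + (f" ({', '.join(self.excluded)})" if self.excluded else ""),
            "",
        ]
        units = {"pwd_ms": "ms", "pwv_mv": "mV", "pwdisp_ms": "ms", "ptfv1": "mV.ms"}
        for arm in sorted(self.n_per_arm):
            for param in PARAMETERS:
                res = self.within_arm[(arm, param)]
                lines.append(
                    f"{param} after {arm} repeat ablation: "
                    f"{res.mean_a:.1f} to {res.mean_b:.1f} {units[param]} "
                    f"({res.test_name}, p = {res.p_value:.3g})"
                )
        lines.append("")
        for param in PARAMETERS:
            res = self.between_arm.get(param)
            if res is None:
                continue
            verdict = "significant" if res.significant else "insignificant"
            lines.append(
                f"{param} change between arms: {verdict} "
                f"({res.test_name}, p = {res.p_value:.3g})"
            )
        return "\n".join(lines) + "\n"

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.measurements.to_csv(os.path.join(out_dir, "measurements.csv"), index=False)
        self.summaries.to_csv(os.path.join(out_dir, "summary.csv"), index=False)
        rows = []
        for (arm, param), res in sorted(self.within_arm.items()):
            rows.append(_comparison_row(f"within:{arm}", param, res))
        for param, res in sorted(self.between_arm.items()):
            rows.append(_comparison_row("between-arm", param, res))
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "comparisons.csv"), index=False)
        with open(os.path.join(out_dir, "report.txt"), "w", encoding="utf-8") as fh:
            fh.write(self.to_text())


def _comparison_row(scope: str, param: str, res: cs.ComparisonResult) -> dict:
    return {
        "scope": scope, "parameter": param,
        "mean_a": res.mean_a, "sem_a": res.sem_a,
        "mean_b": res.mean_b, "sem_b": res.sem_b,
        "mean_diff": res.mean_diff, "test": res.test_name,
        "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
    }


def config_hash(cfg: CohortConfig) -> str:
    payload = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def measure_record(
    record: EcgRecord,
    n_beats: int = 20,
    filter_spec: FilterSpec | None = None,
    overrides: dict[str, AnnotationOverride] | None = None,
    already_quantized: bool = False,
) -> tuple[PwaveParams, PwaveTemplate]:
    """Filter, delineate and measure one record."""
    if not already_quantized:
        record = record.with_data(quantize(record.data))
    filtered = apply_filters(record, filter_spec)
    template = delineate_record(filtered, n_beats=n_beats, overrides=overrides)
    return measure_template(template), template


def _filter_spec_for(cfg: CohortConfig) -> FilterSpec:
    return FilterSpec(notch_hz=float(cfg.noise.mains_hz))


def run_study(
    config: CohortConfig | str,
    seed: int = 1,
    out_dir: str | None = None,
) -> StudyReport:
    """Simulate and analyze a full two-arm pre/post cohort.

    Deterministic given ``(config, seed)``. Patients failing delineation
    quality guards in either phase are excluded and counted in the report.
    """
    cfg = config if isinstance(config, CohortConfig) else CohortConfig.from_yaml(config)
    patients = generate_cohort(cfg, seed=seed)
    spec = _filter_spec_for(cfg)

    rows = []
    excluded: list[str] = []
    for patient in patients:
        try:
            for phase_name in ("pre", "post"):
                phase = getattr(patient, phase_name)
                params, _ = measure_record(
                    phase.record, n_beats=cfg.n_beats_average, filter_spec=spec
                )
                rows.append({
                    "patient_id": patient.patient_id,
                    "arm": patient.arm,
                    "phase": phase_name,
                    "pwd_ms": params.pwd_ms,
                    "pwv_mv": params.pwv_mv,
                    "pwdisp_ms": params.pwdisp_ms,
                    "ptfv1": params.ptfv1,
                    "n_leads_measurable": params.n_leads_measurable,
                })
        except (DelineationError, MeasurementError) as exc:
            log.warning("excluding %s: %s", patient.patient_id, exc)
            excluded.append(patient.patient_id)
            rows = [r for r in rows if r["patient_id"] != patient.patient_id]
    measurements = pd.DataFrame(rows)
    if measurements.empty:
        raise MeasurementError("no patient survived the quality guards")
    return build_report(measurements, seed=seed, cfg_hash=config_hash(cfg), excluded=excluded)


def build_report(
    measurements: pd.DataFrame,
    seed: int = 0,
    cfg_hash: str = "",
    excluded: list[str] | None = None,
) -> StudyReport:
    """Summaries and comparisons from a per-patient measurement table."""
    excluded = excluded or []
    summary_rows = []
    for (arm, phase), grp in measurements.groupby(["arm", "phase"], sort=True):
        for param in PARAMETERS:
            vals = grp[param].to_numpy()
            summary_rows.append({
                "arm": arm, "phase": phase, "parameter": param,
                "n": len(vals), "mean": float(vals.mean()), "sem": cs.sem(vals),
            })
    summaries = pd.DataFrame(summary_rows)

    wide = measurements.pivot_table(
        index=["patient_id", "arm"], columns="phase", values=list(PARAMETERS)
    )
    within: dict[tuple[str, str], cs.ComparisonResult] = {}
    deltas: dict[str, dict[str, np.ndarray]] = {p: {} for p in PARAMETERS}
    arms = sorted(measurements["arm"].unique())
    for arm in arms:
        sub = wide.xs(arm, level="arm")
        for param in PARAMETERS:
            pre = sub[(param, "pre")].to_numpy()
            post = sub[(param, "post")].to_numpy()
            within[(arm, param)] = cs.paired_compare(pre, post)
            deltas[param][arm] = post - pre

    between: dict[str, cs.ComparisonResult] = {}
    if len(arms) == 2:
        for param in PARAMETERS:
            between[param] = cs.unpaired_compare(
                deltas[param][arms[0]], deltas[param][arms[1]]
            )

    n_per_arm = {
        arm: int(measurements[measurements["arm"] == arm]["patient_id"].nunique())
        for arm in arms
    }
    return StudyReport(
        measurements=measurements, summaries=summaries,
        within_arm=within, between_arm=between,
        n_per_arm=n_per_arm, excluded=excluded,
        seed=seed, config_hash=cfg_hash,
    )


# ---------------------------------------------------------------------------
# Intraobserver variability protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntraobserverReport:
    results: dict[str, cs.VariabilityResult]
    n_ecgs: int
    n_leads: int
    n_beats: int

    @property
    def n_pwaves(self) -> int:
        """P-waves entering the two-run protocol: ECGs x leads x beats."""
        return self.n_ecgs * self.n_leads * self.n_beats

    def to_text(self) -> str:
        lines = [
            f"Intraobserver variability over {self.n_ecgs} twelve-lead ECGs "
            f"({self.n_pwaves} P-waves analyzed and compared twice)",
        ]
        for name, res in self.results.items():
            lines.append(
                f"  {name}: {res.mean_abs_diff:.3g} +/- {res.sem_abs_diff:.3g} "
                f"({res.percent:.1f}%)"
            )
        return "\n".join(lines) + "\n"


def run_intraobserver(
    config: CohortConfig | str,
    n_ecgs: int = 22,
    jitter_ms: float = 2.0,
    seed: int = 1,
) -> IntraobserverReport:
    """Two-pass measurement of ``n_ecgs`` synthetic ECGs with annotation jitter.

    The second pass re-measures the same averaged templates with fiducials
    displaced by seeded Gaussian jitter (SD ``jitter_ms``), emulating human
    re-annotation on a second day; per-parameter variability is reported.
    """
    cfg = config if isinstance(config, CohortConfig) else CohortConfig.from_yaml(config)
    arm_name = sorted(cfg.arms)[0]
    arm = dataclasses.replace(cfg.arms[arm_name], n=n_ecgs)
    cfg = dataclasses.replace(cfg, arms={arm_name: arm})
    patients = generate_cohort(cfg, seed=seed)
    spec = _filter_spec_for(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    run1_rows, run2_rows = [], []
    for patient in patients:
        params1, template = measure_record(
            patient.pre.record, n_beats=cfg.n_beats_average, filter_spec=spec
        )
        run1_rows.append(params1)
        overrides = _jittered_overrides(template, jitter_ms, rng)
        template2 = PwaveTemplate(
            data=template.data, fs=template.fs,
            r_offset=template.r_offset, n_beats=template.n_beats,
            rr_samples=template.rr_samples,
        )
        delineate_template(template2, overrides=overrides)
        run2_rows.append(measure_template(template2))

    results = {}
    for param in PARAMETERS:
        r1 = [getattr(p, param) for p in run1_rows]
        r2 = [getattr(p, param) for p in run2_rows]
        results[param] = cs.intraobserver(r1, r2, parameter=param)
    return IntraobserverReport(
        results=results, n_ecgs=n_ecgs, n_leads=12, n_beats=cfg.n_beats_average
    )


def _jittered_overrides(
    template: PwaveTemplate, jitter_ms: float, rng: np.random.Generator
) -> dict[str, AnnotationOverride]:
    """Gaussian fiducial displacements, clipped to keep orderings valid."""
    if jitter_ms <= 0:
        return {}
    step = template.fs / 1000.0
    overrides: dict[str, AnnotationOverride] = {}
    qrs = template.qrs_onset_idx
    for lead, f in template.fiducials.items():
        if not f.measurable:
            continue
        jit = lambda idx: idx + int(round(rng.normal(0.0, jitter_ms * step)))
        peak = int(np.clip(jit(f.p_peak), f.onset + 1, f.offset - 1))
        onset = int(np.clip(jit(f.onset), f.t_peak + 1, peak - 1))
        offset = int(np.clip(jit(f.offset), peak + 1, qrs))
        ov = AnnotationOverride(onset=onset, peak=peak, offset=offset)
        if f.neg_trough is not None:
            ov.trough = int(np.clip(jit(f.neg_trough), f.neg_start, f.neg_end))
        overrides[lead] = ov
    return overrides


# ---------------------------------------------------------------------------
# File-based flow (manifest of pre-recorded files)
# ---------------------------------------------------------------------------

def write_cohort(patients: list[Patient], out_dir: str) -> str:
    """Write every record to ``out_dir`` and return the manifest CSV path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for p in patients:
        for phase_name in ("pre", "post"):
            rec = getattr(p, phase_name).record
            fname = f"{p.patient_id}-{phase_name}.txt"
            write_record(rec, os.path.join(out_dir, fname))
            rows.append({
                "record_id": rec.record_id or f"{p.patient_id}-{phase_name}",
                "arm": p.arm, "phase": phase_name, "path": fname,
            })
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    from .synthetic_ecg import ground_truth_frame

    ground_truth_frame(patients).to_csv(
        os.path.join(out_dir, "ground_truth.csv"), index=False
    )
    return manifest


def measure_manifest(
    manifest_path: str,
    n_beats: int = 20,
    filter_spec: FilterSpec | None = None,
) -> pd.DataFrame:
    """Measure every record listed in a manifest CSV (record_id, arm, phase, path)."""
    manifest = pd.read_csv(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    rows = []
    for _, entry in manifest.iterrows():
        path = entry["path"]
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        record = read_record(path, record_id=str(entry["record_id"]))
        log.info("measuring %s", entry["record_id"])
        try:
            params, _ = measure_record(
                record, n_beats=n_beats, filter_spec=filter_spec,
                already_quantized=True,
            )
        except (DelineationError, MeasurementError) as exc:
            log.warning("skipping %s: %s", entry["record_id"], exc)
            continue
        pid = str(entry["record_id"]).rsplit("-", 1)[0]
        rows.append({
            "patient_id": pid, "arm": entry["arm"], "phase": entry["phase"],
            "pwd_ms": params.pwd_ms, "pwv_mv": params.pwv_mv,
            "pwdisp_ms": params.pwdisp_ms, "ptfv1": params.ptfv1,
            "n_leads_measurable": params.n_leads_measurable,
        })
    return pd.DataFrame(rows)
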
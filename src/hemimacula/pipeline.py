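"""End-to-end orchestration of the four diagnostic comparisons.

Given a cohort (synthetic or loaded from the CSV schemas), the pipeline

1. normalizes every grid to patient space and extracts the central 4x4;
2. fits the correction model on controls (baseline reference, ON offset);
3. produces raw (baseline-adjusted) and ON-corrected deviation maps;
4. flags atrophic sectors and issues patient- and eye-level lesion calls;
5. tabulates four comparisons with sensitivity/specificity/PPV/NPV and a
   McNemar p-value each:

   * OCT vs MRI, patient level, per layer x {raw, corrected};
   * VF vs MRI, patient level;
   * OCT vs VF, patient level, per layer x {raw, corrected};
   * OCT vs MRI, eye level, ipsilateral and contralateral eyes
     separately, per layer x {raw, corrected}.

Every excluded patient or eye appears once in the exclusion log with a
machine-readable reason, and the full configuration is echoed into the
report bundle so a bundle re-runs to an identical bundle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml

from .classify import (
    AtrophyFlags,
    CallSide,
    EyeRelation,
    LesionCall,
    eye_level_call,
    flag_sectors,
    hemi_atrophy,
    hemi_evaluable,
    patient_call,
)
from .correction import (
    CorrectedGrid,
    CorrectionModel,
    apply_on_correction,
    baseline_adjust,
)
from .grids import (
    HemiSide,
    Laterality,
    MriLesion,
    PatientRecord,
    RetinalLayer,
    extract_central_grid,
    to_patient_space,
)
from .simulate import SyntheticCohort
from .stats import McNemarMethod, build_table, diag_stats, mcnemar

__all__ = [
    "compute_flags",
    "PipelineConfig",
    "VfRecord",
    "validate_vf",
    "ReportBundle",
    "prepare_cohort",
    "correct_cohort",
    "run_all",
]

#: Reliability ceiling for visual-field indices (strict: indices must be < 33%).
VF_RELIABILITY_LIMIT_PCT = 33.0


@dataclass(frozen=True)
class VfRecord:
    defect: bool
    fixation_loss_pct: float
    false_pos_pct: float
    false_neg_pct: float

    def __post_init__(self) -> None:
        for name in ("fixation_loss_pct", "false_pos_pct", "false_neg_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")


def validate_vf(record: VfRecord) -> bool:
    """Reliable iff fixation losses, false positives and false negatives
    are each strictly below 33%."""
    return (
        record.fixation_loss_pct < VF_RELIABILITY_LIMIT_PCT
        and record.false_pos_pct < VF_RELIABILITY_LIMIT_PCT
        and record.false_neg_pct < VF_RELIABILITY_LIMIT_PCT
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Every analysis knob with its default; echoed into every report bundle."""

    on_reference: Literal["controls", "non_on_patients"] = "controls"
    on_scope: Literal["eye", "patient"] = "eye"
    display_convention: Literal["fundus", "mirrored_os"] = "fundus"
    k: float = 2.0
    m: int = 4
    mcnemar_method: str = McNemarMethod.AUTO.value
    layers: tuple[str, ...] = ("GCL", "IPL")
    corrected: bool = True  # include ON-corrected variants alongside raw
    vf_aggregation: Literal["any_eye", "both_eyes"] = "any_eye"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "layers" in data:
            data["layers"] = tuple(data["layers"])
        return cls(**data)


@dataclass
class ReportBundle:
    report: pd.DataFrame
    exclusions: pd.DataFrame
    config: PipelineConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(out / "report.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        self.config.to_yaml(out / "config.yaml")


def _as_lists(cohort) -> tuple[list[PatientRecord], list[PatientRecord]]:
    if isinstance(cohort, SyntheticCohort):
        return cohort.patients, cohort.controls
    patients, controls = cohort
    return list(patients), list(controls)


def prepare_cohort(
    records: list[PatientRecord], display_convention: str = "fundus"
) -> list[PatientRecord]:
    """Normalize every grid to patient space and reduce to the central 4x4."""
    out = []
    for patient in records:
        eyes = {}
        for lat, eye in patient.eyes.items():
            grids = {}
            for layer, grid in eye.grids.items():
                g = to_patient_space(grid, display_convention)
                if g.size == 8:
                    g = extract_central_grid(g)
                grids[layer] = g
            eyes[lat] = dataclasses.replace(eye, grids=grids)
        out.append(dataclasses.replace(patient, eyes=eyes))
    return out


def correct_cohort(
    patients: list[PatientRecord],
    model: CorrectionModel,
    on_scope: Literal["eye", "patient"] = "eye",
) -> dict[str, dict[Laterality, dict[RetinalLayer, dict[str, CorrectedGrid]]]]:
    """Baseline-adjust every grid and ON-adjust per scope.

    Returns per patient/eye/layer a dict with ``raw`` (baseline only)
    and ``corrected`` (baseline + ON where applicable) deviation grids.
    """
    out: dict[str, dict] = {}
    for patient in patients:
        patient_on = any(e.on_history for e in patient.eyes.values())
        per_eye: dict[Laterality, dict] = {}
        for lat, eye in patient.eyes.items():
            apply_on = eye.on_history if on_scope == "eye" else patient_on
            per_layer: dict[RetinalLayer, dict[str, CorrectedGrid]] = {}
            for layer, grid in eye.grids.items():
                base = baseline_adjust(grid, model.references[layer])
                per_layer[layer] = {
                    "raw": base,
                    "corrected": apply_on_correction(base, model.offsets[layer], apply_on),
                }
            per_eye[lat] = per_layer
        out[patient.patient_id] = per_eye
    return out


def compute_flags(
    corrected: dict,
    model: CorrectionModel,
    variant: str,
    k: float,
) -> dict[str, dict[Laterality, dict[RetinalLayer, AtrophyFlags]]]:
    return {
        pid: {
            lat: {
                layer: flag_sectors(variants[variant], model.references[layer], k)
                for layer, variants in per_layer.items()
            }
            for lat, per_layer in per_eye.items()
        }
        for pid, per_eye in corrected.items()
    }


def _patient_vf(
    patient: PatientRecord, aggregation: str
) -> tuple[bool | None, str | None]:
    """Collapse reliable per-eye VF outcomes to a patient-level flag.

    Returns (flag, exclusion_reason); flag is None when no reliable eye
    carries a VF result.
    """
    outcomes = []
    for eye in patient.eyes.values():
        if eye.vf_defect is None:
            continue
        if eye.vf_reliability is not None:
            rec = VfRecord(eye.vf_defect, *eye.vf_reliability)
            if not validate_vf(rec):
                continue
        outcomes.append(eye.vf_defect)
    if not outcomes:
        return None, "no reliable visual field"
    if aggregation == "both_eyes":
        return all(outcomes), None
    return any(outcomes), None


def _stats_row(
    comparison: str,
    layer: str,
    variant: str,
    level: str,
    relation: str,
    index: list[bool],
    reference: list[bool],
    config: PipelineConfig,
) -> dict:
    table = build_table(index, reference)
    stats = diag_stats(table)
    try:
        mc = mcnemar(index, reference, config.mcnemar_method)
        mc_p, mc_method = mc.p_value, mc.method.value
    except ZeroDivisionError:
        mc_p, mc_method = None, config.mcnemar_method
    fmt = lambda v: "undefined" if v is None else round(v, 6)
    return {
        "comparison": comparison,
        "layer": layer,
        "variant": variant,
        "level": level,
        "relation": relation,
        "n": table.total,
        "tp": table.tp,
        "fn": table.fn,
        "fp": table.fp,
        "tn": table.tn,
        "sensitivity": fmt(stats.sensitivity),
        "specificity": fmt(stats.specificity),
        "ppv": fmt(stats.ppv),
        "npv": fmt(stats.npv),
        "mcnemar_p": fmt(mc_p),
        "mcnemar_method": mc_method,
        "k": config.k,
        "m": config.m,
    }


def run_all(config: PipelineConfig, cohort) -> ReportBundle:
    """Run the full analysis; deterministic given config and cohort."""
    patients_raw, controls_raw = _as_lists(cohort)
    patients = prepare_cohort(patients_raw, config.display_convention)
    controls = prepare_cohort(controls_raw, config.display_convention)
    model = CorrectionModel.fit(patients, controls, config.on_reference)
    corrected = correct_cohort(patients, model, config.on_scope)

    layers = [RetinalLayer(l) for l in config.layers]
    variants = ["raw", "corrected"] if config.corrected else ["raw"]
    exclusions: list[dict] = []
    rows: list[dict] = []

    calls: dict[str, dict[str, LesionCall]] = {v: {} for v in variants}
    flags_by_variant = {
        v: compute_flags(corrected, model, v, config.k) for v in variants
    }
    for variant in variants:
        for patient in patients:
            call = patient_call(
                patient.patient_id, flags_by_variant[variant][patient.patient_id], config.m
            )
            if not call.evaluable:
                exclusions.append(
                    {
                        "patient_id": patient.patient_id,
                        "context": f"patient_call/{variant}",
                        "reason": call.exclusion_reason,
                    }
                )
            calls[variant][patient.patient_id] = call

    mri_known = [p for p in patients if p.mri_lesion is not None]
    for patient in patients:
        if patient.mri_lesion is None:
            exclusions.append(
                {
                    "patient_id": patient.patient_id,
                    "context": "mri_reference",
                    "reason": "missing MRI label",
                }
            )

    # --- OCT vs MRI, patient level ---
    for layer in layers:
        for variant in variants:
            index, reference = [], []
            for patient in mri_known:
                call = calls[variant][patient.patient_id]
                if not call.evaluable:
                    continue
                index.append(call.per_layer[layer] is not CallSide.NONE)
                reference.append(patient.mri_lesion.present)
            rows.append(
                _stats_row(
                    "OCT_vs_MRI", layer.value, variant, "patient", "", index, reference, config
                )
            )

    # --- VF vs MRI, patient level ---
    vf_flags: dict[str, bool | None] = {}
    for patient in patients:
        flag, reason = _patient_vf(patient, config.vf_aggregation)
        vf_flags[patient.patient_id] = flag
        if flag is None:
            exclusions.append(
                {"patient_id": patient.patient_id, "context": "vf", "reason": reason}
            )
    index = [
        vf_flags[p.patient_id]
        for p in mri_known
        if vf_flags[p.patient_id] is not None
    ]
    reference = [
        p.mri_lesion.present for p in mri_known if vf_flags[p.patient_id] is not None
    ]
    rows.append(_stats_row("VF_vs_MRI", "", "", "patient", "", index, reference, config))

    # --- OCT vs VF, patient level ---
    for layer in layers:
        for variant in variants:
            index, reference = [], []
            for patient in patients:
                call = calls[variant][patient.patient_id]
                vf = vf_flags[patient.patient_id]
                if not call.evaluable or vf is None:
                    continue
                index.append(call.per_layer[layer] is not CallSide.NONE)
                reference.append(vf)
            rows.append(
                _stats_row(
                    "OCT_vs_VF", layer.value, variant, "patient", "", index, reference, config
                )
            )

    # --- OCT vs MRI, eye level, by relation ---
    # Lesion-positive arm: the relation-matching eye of each lesioned patient,
    # positive when the hemi-macula on the lesion side is atrophic.
    # Lesion-negative arm: both eyes of MRI-lesion-free patients, positive when
    # either hemi-macula is atrophic.
    for layer in layers:
        for variant in variants:
            for relation in (EyeRelation.IPSILATERAL, EyeRelation.CONTRALATERAL):
                index, reference = [], []
                for patient in mri_known:
                    pflags = flags_by_variant[variant][patient.patient_id]
                    side = patient.mri_lesion.side
                    if side is not None:
                        for lat in (Laterality.OD, Laterality.OS):
                            if lat not in pflags or layer not in pflags[lat]:
                                continue
                            f = pflags[lat][layer]
                            if not hemi_evaluable(f, side):
                                exclusions.append(
                                    {
                                        "patient_id": patient.patient_id,
                                        "context": f"eye_level/{variant}/{lat.value}/{layer.value}",
                                        "reason": "hemi-macula unevaluable",
                                    }
                                )
                                continue
                            call = eye_level_call(
                                patient.patient_id, lat, {layer: f}, side, config.m
                            )
                            if call.relation is relation:
                                index.append(call.positive_per_layer[layer])
                                reference.append(True)
                    else:
                        for lat in (Laterality.OD, Laterality.OS):
                            if lat not in pflags or layer not in pflags[lat]:
                                continue
                            f = pflags[lat][layer]
                            if not all(hemi_evaluable(f, s) for s in HemiSide):
                                continue
                            positive = any(
                                hemi_atrophy(f, s, config.m) for s in HemiSide
                            )
                            index.append(positive)
                            reference.append(False)
                rows.append(
                    _stats_row(
                        "OCT_vs_MRI",
                        layer.value,
                        variant,
                        "eye",
                        relation.value,
                        index,
                        reference,
                        config,
                    )
                )

    report = pd.DataFrame(rows)
    excl = pd.DataFrame(exclusions, columns=["patient_id", "context", "reason"])
    excl = excl.drop_duplicates().reset_index(drop=True)
    return ReportBundle(report=report, exclusions=excl, config=config)
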
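"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes, so the whole
pipeline is testable without patient data:

* control-like grids: sector thickness drawn independently per sector
  from Normal(mu_s, sigma_s) around a center-weighted macular profile;
* optic-neuritis history (default prevalence 30.7%) causing diffuse
  thinning of one randomly chosen eye;
* retrochiasmal lesions (default prevalence 60%, side fair-coin)
  causing homonymous hemi-macular thinning on the lesion side of BOTH
  eyes, stronger in the contralateral eye in the 53:47 ratio of
  crossed to uncrossed chiasmal fibers;
* visual-field outcomes as a per-patient binary flag with configurable
  sensitivity (default 0.14) and false-positive rate (default 0.38)
  against lesion truth, mirrored onto both eyes with reliable indices.

Lesion-side hemi deficits are scaled so the two eyes average to
``lesion_effect``: the contralateral eye loses 2*effect*crossed_fraction,
the ipsilateral eye 2*effect*(1 - crossed_fraction).

All randomness flows from a single seed; identical parameters and seed
reproduce the cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .grids import (
    EyeRecord,
    Group,
    HemiSide,
    Laterality,
    MriLesion,
    Orientation,
    PatientRecord,
    PosteriorPoleGrid,
    RetinalLayer,
)

__all__ = ["SimulationParams", "SyntheticCohort", "simulate_cohort", "calibration_check"]


def _center_weighted(corner: float, edge: float, center: float) -> np.ndarray:
    """Left-right and up-down symmetric 4x4 macular profile (um)."""
    return np.array(
        [
            [corner, edge, edge, corner],
            [edge, center, center, edge],
            [edge, center, center, edge],
            [corner, edge, edge, corner],
        ],
        dtype=float,
    )


def _default_base_mean() -> dict[RetinalLayer, np.ndarray]:
    return {
        RetinalLayer.GCL: _center_weighted(30.0, 40.0, 52.0),
        RetinalLayer.IPL: _center_weighted(28.0, 35.0, 44.0),
    }


@dataclass
class SimulationParams:
    """Generator settings; defaults encode the study-cohort anchors."""

    n_patients: int = 52
    n_controls: int = 27
    p_on_history: float = 0.307
    p_lesion: float = 0.60
    p_side_right: float = 0.5
    base_mean: dict[RetinalLayer, np.ndarray] = field(default_factory=_default_base_mean)
    base_sd: float = 4.0
    on_effect: dict[RetinalLayer, float] = field(
        default_factory=lambda: {RetinalLayer.GCL: 8.0, RetinalLayer.IPL: 6.0}
    )
    lesion_effect: dict[RetinalLayer, float] = field(
        default_factory=lambda: {RetinalLayer.GCL: 10.0, RetinalLayer.IPL: 8.0}
    )
    crossed_fraction: float = 0.53
    vf_sens: float = 0.14
    vf_false_pos: float = 0.38
    age_mean_sd_patients: tuple[float, float] = (35.07, 12.73)
    age_mean_sd_controls: tuple[float, float] = (31.85, 10.97)
    spatial_smoothing: float = 0.0  # Gaussian sigma (sectors); 0 = independent sectors
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_on_history", "p_lesion", "p_side_right", "vf_sens", "vf_false_pos"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not 0.0 < self.crossed_fraction < 1.0:
            raise ValueError("crossed_fraction must be in (0, 1)")
        if self.base_sd < 0 or self.spatial_smoothing < 0:
            raise ValueError("base_sd and spatial_smoothing must be non-negative")
        for eff in (self.on_effect, self.lesion_effect):
            if any(v < 0 for v in eff.values()):
                raise ValueError("effects must be non-negative")


@dataclass
class SyntheticCohort:
    patients: list[PatientRecord]
    controls: list[PatientRecord]
    truth: dict[str, dict[str, Any]]  # patient_id -> {lesion_side, on_eyes}
    params: SimulationParams
    ages: dict[str, float] = field(default_factory=dict)


def _pad_to_8x8(central: np.ndarray) -> np.ndarray:
    """Embed a central 4x4 mean profile into an 8x8 chart.

    Peripheral sectors taper off the nearest central value (inner layers
    thin with eccentricity); they are carried in the export format but
    never analyzed.
    """
    idx = np.clip(np.arange(8) - 2, 0, 3)  # edge-replicate the central profile
    full = central[np.ix_(idx, idx)].copy()
    ring = np.ones((8, 8), dtype=bool)
    ring[2:6, 2:6] = False
    full[ring] -= 4.0
    return full


def _noise(rng: np.random.Generator, sd: float, smoothing: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, size=(8, 8))
    if smoothing > 0:
        from scipy.ndimage import gaussian_filter

        raw = gaussian_filter(eps, sigma=smoothing, mode="nearest")
        # restore marginal SD after smoothing
        if raw.std() > 0:
            eps = raw * (sd / raw.std())
        else:
            eps = raw
    return eps


def _lesion_deficit(params: SimulationParams, layer: RetinalLayer, contralateral: bool) -> float:
    base = params.lesion_effect[layer]
    frac = params.crossed_fraction if contralateral else 1.0 - params.crossed_fraction
    return 2.0 * base * frac


def _simulate_eye(
    rng: np.random.Generator,
    params: SimulationParams,
    laterality: Laterality,
    on_eye: bool,
    lesion_side: HemiSide | None,
) -> EyeRecord:
    grids = {}
    for layer in RetinalLayer:
        mean8 = _pad_to_8x8(params.base_mean[layer])
        values = mean8 + _noise(rng, params.base_sd, params.spatial_smoothing)
        if on_eye:
            values -= params.on_effect[layer]
        if lesion_side is not None:
            contra = (laterality is Laterality.OD) != (lesion_side is HemiSide.RIGHT)
            cols = slice(4, 8) if lesion_side is HemiSide.RIGHT else slice(0, 4)
            values[:, cols] -= _lesion_deficit(params, layer, contra)
        np.clip(values, 0.0, 200.0, out=values)
        grids[layer] = PosteriorPoleGrid(
            laterality=laterality,
            layer=layer,
            values=values,
            orientation=Orientation.DISPLAY,
        )
    return EyeRecord(laterality=laterality, grids=grids, on_history=on_eye)


def simulate_cohort(params: SimulationParams) -> SyntheticCohort:
    """Generate a full cohort of MS patients and healthy controls."""
    rng = np.random.default_rng(params.seed)
    patients: list[PatientRecord] = []
    truth: dict[str, dict[str, Any]] = {}
    ages: dict[str, float] = {}

    for i in range(params.n_patients):
        pid = f"MS{i + 1:04d}"
        has_on = rng.random() < params.p_on_history
        on_eye = (
            (Laterality.OD, Laterality.OS)[int(rng.integers(2))] if has_on else None
        )
        has_lesion = rng.random() < params.p_lesion
        lesion_side = None
        if has_lesion:
            lesion_side = (
                HemiSide.RIGHT if rng.random() < params.p_side_right else HemiSide.LEFT
            )
        vf_positive = bool(
            rng.random() < (params.vf_sens if has_lesion else params.vf_false_pos)
        )
        eyes = {}
        for lat in (Laterality.OD, Laterality.OS):
            eye = _simulate_eye(rng, params, lat, on_eye is lat, lesion_side)
            eye.vf_defect = vf_positive
            eye.vf_reliability = tuple(rng.uniform(0.0, 25.0, size=3))
            eyes[lat] = eye
        mri = MriLesion.NONE if lesion_side is None else MriLesion(lesion_side.value)
        patients.append(PatientRecord(pid, Group.MS, eyes, mri_lesion=mri))
        truth[pid] = {
            "lesion_side": lesion_side,
            "on_eyes": [on_eye] if on_eye else [],
        }
        mu, sd = params.age_mean_sd_patients
        ages[pid] = float(rng.normal(mu, sd))

    controls: list[PatientRecord] = []
    for i in range(params.n_controls):
        cid = f"HC{i + 1:04d}"
        eyes = {}
        for lat in (Laterality.OD, Laterality.OS):
            eye = _simulate_eye(rng, params, lat, False, None)
            eye.vf_defect = False
            eye.vf_reliability = tuple(rng.uniform(0.0, 25.0, size=3))
            eyes[lat] = eye
        controls.append(PatientRecord(cid, Group.CONTROL, eyes, mri_lesion=MriLesion.NONE))
        truth[cid] = {"lesion_side": None, "on_eyes": []}
        mu, sd = params.age_mean_sd_controls
        ages[cid] = float(rng.normal(mu, sd))

    return SyntheticCohort(patients, controls, truth, params, ages)


def calibration_check(n_patients: int, params: SimulationParams | None = None) -> dict[str, float]:
    """Verify the generator's empirical rates against its own settings.

    Simulates ``n_patients`` MS patients (no controls) and returns the
    empirical ON-history fraction, lesion prevalence, VF sensitivity and
    specificity against lesion truth, and the mean contralateral- and
    ipsilateral-eye hemi-macular GCL deficits of lesioned patients.
    """
    params = replace(
        params or SimulationParams(), n_patients=n_patients, n_controls=0
    )
    cohort = simulate_cohort(params)
    n_on = n_lesion = 0
    vf_tp = vf_fn = vf_fp = vf_tn = 0
    contra_deficits: list[float] = []
    ipsi_deficits: list[float] = []
    for patient in cohort.patients:
        info = cohort.truth[patient.patient_id]
        lesion_side: HemiSide | None = info["lesion_side"]
        if info["on_eyes"]:
            n_on += 1
        vf = patient.eyes[Laterality.OD].vf_defect
        if lesion_side is not None:
            n_lesion += 1
            vf_tp += vf
            vf_fn += not vf
        else:
            vf_fp += vf
            vf_tn += not vf
        if lesion_side is not None and not info["on_eyes"]:
            for lat, eye in patient.eyes.items():
                grid = eye.grids[RetinalLayer.GCL].values[2:6, 2:6]
                lesion_cols = slice(2, 4) if lesion_side is HemiSide.RIGHT else slice(0, 2)
                other_cols = slice(0, 2) if lesion_side is HemiSide.RIGHT else slice(2, 4)
                deficit = grid[:, other_cols].mean() - grid[:, lesion_cols].mean()
                contra = (lat is Laterality.OD) != (lesion_side is HemiSide.RIGHT)
                (contra_deficits if contra else ipsi_deficits).append(float(deficit))
    return {
        "on_fraction": n_on / len(cohort.patients),
        "lesion_prevalence": n_lesion / len(cohort.patients),
        "vf_sensitivity": vf_tp / max(vf_tp + vf_fn, 1),
        "vf_specificity": vf_tn / max(vf_tn + vf_fp, 1),
        "contra_hemi_deficit_um": float(np.mean(contra_deficits)) if contra_deficits else float("nan"),
        "ipsi_hemi_deficit_um": float(np.mean(ipsi_deficits)) if ipsi_deficits else float("nan"),
    }
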
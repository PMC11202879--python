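"""Two-step sector-thickness correction.

Step 1 (baseline adjustment) subtracts the control-group mean thickness
from every sector, so corrected values are signed deviations in
micrometers centred on zero for healthy retinas.

Step 2 (ON adjustment) compensates eyes with a history of optic
neuritis for the diffuse inner-retinal thinning the episode caused:
the per-sector mean difference between a reference group and ON eyes
(delta_s, positive when ON eyes are thinner) is added back to the ON
eye's deviations, so residual thinning reflects other processes —
notably trans-synaptic retrograde degeneration from posterior lesions.

The reference group for the ON offset is configurable: healthy
controls (default) or MS patients without ON history.  The correction
scope is likewise configurable: per-eye with ON history (default) or
both eyes of any ON-history patient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .grids import (
    Group,
    Laterality,
    Orientation,
    PatientRecord,
    PosteriorPoleGrid,
    RetinalLayer,
)

__all__ = [
    "SectorReference",
    "OnOffset",
    "CorrectedGrid",
    "CorrectionModel",
    "fit_sector_reference",
    "baseline_adjust",
    "fit_on_offset",
    "apply_on_correction",
]


class CorrectionError(ValueError):
    pass


class CorrectionStateError(RuntimeError):
    """Correction step applied in the wrong order or twice."""


@dataclass(frozen=True)
class SectorReference:
    """Per-sector control mean (mu_s) and SD (sigma_s) for one layer, in um."""

    layer: RetinalLayer
    mean: np.ndarray  # 4x4
    sd: np.ndarray  # 4x4
    n_controls: int

    def __post_init__(self) -> None:
        mean = np.array(self.mean, dtype=float, copy=True)
        sd = np.array(self.sd, dtype=float, copy=True)
        if mean.shape != (4, 4) or sd.shape != (4, 4):
            raise CorrectionError("sector reference needs 4x4 mean and sd matrices")
        if np.any(sd < 0):
            raise CorrectionError("negative sector SD")
        if self.n_controls < 2:
            raise CorrectionError("sector reference needs at least 2 controls")
        for name, arr in (("mean", mean), ("sd", sd)):
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class OnOffset:
    """Per-sector ON offset delta_s = mean_ref - mean_ON (um); positive = ON thinner."""

    layer: RetinalLayer
    delta: np.ndarray  # 4x4
    reference_group: Literal["controls", "non_on_patients"]

    def __post_init__(self) -> None:
        delta = np.array(self.delta, dtype=float, copy=True)
        if delta.shape != (4, 4):
            raise CorrectionError("ON offset needs a 4x4 delta matrix")
        if not np.all(np.isfinite(delta)):
            raise CorrectionError("non-finite ON offset")
        delta.flags.writeable = False
        object.__setattr__(self, "delta", delta)


@dataclass(frozen=True)
class CorrectedGrid:
    """A central 4x4 grid whose values are signed deviations tau_s (um)."""

    laterality: Laterality
    layer: RetinalLayer
    values: np.ndarray
    orientation: Orientation
    baseline_adjusted: bool = False
    on_adjusted: bool = False

    def __post_init__(self) -> None:
        vals = np.array(self.values, dtype=float, copy=True)
        if vals.shape != (4, 4):
            raise CorrectionError("corrected grids are central 4x4 only")
        if self.on_adjusted and not self.baseline_adjusted:
            raise CorrectionStateError("on_adjusted implies baseline_adjusted")
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)


def _control_eye_grids(
    controls: Iterable[PatientRecord], layer: RetinalLayer
) -> list[np.ndarray]:
    out = []
    for patient in controls:
        for eye in patient.eyes.values():
            grid = eye.grids.get(layer)
            if grid is not None:
                _require_central_patient_space(grid)
                out.append(grid.values)
    return out


def _require_central_patient_space(grid: PosteriorPoleGrid) -> None:
    if grid.size != 4:
        raise CorrectionError("correction operates on central 4x4 grids")
    if grid.orientation is not Orientation.PATIENT_SPACE:
        raise CorrectionStateError("correction requires patient_space grids")


def fit_sector_reference(
    controls: list[PatientRecord], layer: RetinalLayer
) -> SectorReference:
    """Per-sector mean and sample SD (ddof=1) over all control eyes, pooled.

    Both eyes of each control contribute; missing sectors are ignored
    sector-wise.
    """
    n_patients = sum(1 for p in controls if p.group is Group.CONTROL and p.eyes)
    if n_patients < 2:
        raise CorrectionError("need at least 2 control patients with grids")
    stack = np.stack(_control_eye_grids(controls, layer))
    mean = np.nanmean(stack, axis=0)
    sd = np.nanstd(stack, axis=0, ddof=1)
    return SectorReference(layer=layer, mean=mean, sd=sd, n_controls=n_patients)


def baseline_adjust(grid: PosteriorPoleGrid, ref: SectorReference) -> CorrectedGrid:
    """Center sector thickness on the control mean: tau_s = t_s - mu_s."""
    if grid.layer is not ref.layer:
        raise TypeError(f"layer mismatch: grid {grid.layer} vs reference {ref.layer}")
    _require_central_patient_space(grid)
    return CorrectedGrid(
        laterality=grid.laterality,
        layer=grid.layer,
        values=grid.values - ref.mean,
        orientation=grid.orientation,
        baseline_adjusted=True,
    )


def fit_on_offset(
    cohort: list[PatientRecord],
    ref_group: Literal["controls", "non_on_patients"],
    layer: RetinalLayer,
) -> OnOffset:
    """Per-sector mean thickness difference, reference minus ON eyes.

    ON eyes are eyes with ON history among MS patients.  The reference
    is either all control eyes or all MS eyes without ON history.
    """
    on_grids: list[np.ndarray] = []
    ref_grids: list[np.ndarray] = []
    for patient in cohort:
        for eye in patient.eyes.values():
            grid = eye.grids.get(layer)
            if grid is None:
                continue
            _require_central_patient_space(grid)
            if patient.group is Group.MS and eye.on_history:
                on_grids.append(grid.values)
            elif ref_group == "controls" and patient.group is Group.CONTROL:
                ref_grids.append(grid.values)
            elif (
                ref_group == "non_on_patients"
                and patient.group is Group.MS
                and not eye.on_history
            ):
                ref_grids.append(grid.values)
    if not on_grids:
        raise CorrectionError("no ON eyes in cohort; cannot fit ON offset")
    if len(ref_grids) < 2:
        raise CorrectionError(f"fewer than 2 reference eyes for ref_group={ref_group!r}")
    delta = np.nanmean(np.stack(ref_grids), axis=0) - np.nanmean(np.stack(on_grids), axis=0)
    return OnOffset(layer=layer, delta=delta, reference_group=ref_group)


def apply_on_correction(
    grid: CorrectedGrid, offset: OnOffset, eye_on_history: bool
) -> CorrectedGrid:
    """Add delta_s to an ON eye's deviations; non-ON eyes pass through unchanged."""
    if not grid.baseline_adjusted:
        raise CorrectionStateError("ON correction requires a baseline-adjusted grid")
    if not eye_on_history:
        return grid
    if grid.on_adjusted:
        raise CorrectionStateError("grid already ON-adjusted; refusing to double-correct")
    if grid.layer is not offset.layer:
        raise TypeError(f"layer mismatch: grid {grid.layer} vs offset {offset.layer}")
    return replace(grid, values=grid.values + offset.delta, on_adjusted=True)


@dataclass(frozen=True)
class CorrectionModel:
    """Per-layer reference and ON-offset bundle, serializable for audit."""

    references: dict[RetinalLayer, SectorReference]
    offsets: dict[RetinalLayer, OnOffset]

    @classmethod
    def fit(
        cls,
        patients: list[PatientRecord],
        controls: list[PatientRecord],
        on_reference: Literal["controls", "non_on_patients"] = "controls",
    ) -> "CorrectionModel":
        cohort = list(patients) + list(controls)
        any_on = any(
            e.on_history for p in patients for e in p.eyes.values()
        )
        refs, offs = {}, {}
        for layer in RetinalLayer:
            refs[layer] = fit_sector_reference(controls, layer)
            if any_on:
                offs[layer] = fit_on_offset(cohort, on_reference, layer)
            else:
                # no ON eyes anywhere: the ON adjustment is vacuous
                offs[layer] = OnOffset(layer, np.zeros((4, 4)), on_reference)
        return cls(references=refs, offsets=offs)

    def to_json(self, path: str | Path) -> None:
        payload = {
            layer.value: {
                "mean": self.references[layer].mean.tolist(),
                "sd": self.references[layer].sd.tolist(),
                "n_controls": self.references[layer].n_controls,
                "delta": self.offsets[layer].delta.tolist(),
                "reference_group": self.offsets[layer].reference_group,
            }
            for layer in self.references
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionModel":
        payload = json.loads(Path(path).read_text())
        refs, offs = {}, {}
        for key, entry in payload.items():
            layer = RetinalLayer(key)
            refs[layer] = SectorReference(
                layer=layer,
                mean=np.array(entry["mean"]),
                sd=np.array(entry["sd"]),
                n_controls=entry["n_controls"],
            )
            offs[layer] = OnOffset(
                layer=layer,
                delta=np.array(entry["delta"]),
                reference_group=entry["reference_group"],
            )
        return cls(references=refs, offsets=offs)
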
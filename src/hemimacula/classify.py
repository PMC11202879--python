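"""Hemi-macular atrophy flagging and retrochiasmal lesion calls.

The study's readers inspected color-coded corrected deviation maps and
judged whether GCL or IPL "loss" was present in homonymous hemi-maculae.
Here that judgment is a deterministic numeric rule:

* a sector is *atrophic* when its corrected deviation tau_s falls at or
  below -k standard deviations of the control reference for that sector
  (default k = 2, roughly the 2.3rd percentile under normality);
* a hemi-macula is *atrophic* when at least m of its 8 sectors are
  flagged (default m = 4);
* a patient is called positive for a retrochiasmal lesion on side s
  when the side-s hemi-maculae of BOTH eyes are atrophic in the same
  layer — homonymous atrophy.  Either layer suffices (GCL-or-IPL rule);
  both sides positive yields a bilateral call.

k and m are design parameters of this package, not study quantities;
they are carried on every output.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .grids import (
    HemiSide,
    Laterality,
    MIN_PRESENT_PER_HEMI,
    RetinalLayer,
)
from .correction import CorrectedGrid, SectorReference

__all__ = [
    "AtrophyFlags",
    "CallSide",
    "LesionCall",
    "EyeLevelCall",
    "EyeRelation",
    "flag_sectors",
    "hemi_atrophy",
    "hemi_evaluable",
    "patient_call",
    "eye_level_call",
    "second_reader_disagreements",
]


class CallSide(str, enum.Enum):
    NONE = "none"
    RIGHT = "right"
    LEFT = "left"
    BILATERAL = "bilateral"

    def matches(self, side: HemiSide) -> bool:
        """Whether this call includes the given anatomical side (bilateral matches both)."""
        if self is CallSide.BILATERAL:
            return True
        return self.value == side.value


class EyeRelation(str, enum.Enum):
    IPSILATERAL = "ipsilateral"
    CONTRALATERAL = "contralateral"


def _hemi_block(matrix: np.ndarray, side: HemiSide) -> np.ndarray:
    return matrix[:, 2:4] if side is HemiSide.RIGHT else matrix[:, 0:2]


@dataclass(frozen=True)
class AtrophyFlags:
    """Boolean atrophy map for one corrected 4x4 grid (patient space)."""

    layer: RetinalLayer
    flags: np.ndarray  # 4x4 bool
    missing: np.ndarray  # 4x4 bool, True where the sector value was missing
    k: float

    def __post_init__(self) -> None:
        flags = np.array(self.flags, dtype=bool, copy=True)
        missing = np.array(self.missing, dtype=bool, copy=True)
        if flags.shape != (4, 4) or missing.shape != (4, 4):
            raise ValueError("atrophy flags must be 4x4")
        if self.k <= 0:
            raise ValueError("k must be positive")
        for name, arr in (("flags", flags), ("missing", missing)):
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())


def flag_sectors(grid: CorrectedGrid, ref: SectorReference, k: float = 2.0) -> AtrophyFlags:
    """Flag sectors with tau_s <= -k * sigma_s.

    Missing sectors are never flagged but are counted so hemi-maculae
    with too little data can be excluded.  A degenerate reference
    (sigma_s = 0) flags any negative deviation and warns.
    """
    if not grid.baseline_adjusted:
        raise ValueError("flagging requires a corrected (baseline-adjusted) grid")
    if grid.layer is not ref.layer:
        raise TypeError(f"layer mismatch: grid {grid.layer} vs reference {ref.layer}")
    tau = grid.values
    missing = ~np.isfinite(tau)
    degenerate = (ref.sd == 0) & np.isfinite(tau) & (tau < 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} sector(s) flagged against zero-SD reference",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        flags = np.where(missing | (ref.sd == 0), False, tau <= -k * ref.sd) | degenerate
    return AtrophyFlags(layer=grid.layer, flags=flags, missing=missing, k=float(k))


def hemi_atrophy(flags: AtrophyFlags, side: HemiSide, m: int = 4) -> bool:
    """True iff at least m of the 8 sectors on the given side are flagged."""
    if not 1 <= m <= 8:
        raise ValueError("m must be in 1..8")
    return int(_hemi_block(flags.flags, side).sum()) >= m


def hemi_evaluable(flags: AtrophyFlags, side: HemiSide) -> bool:
    """A hemi-macula is classifiable when >= 6 of its 8 sectors are present."""
    present = 8 - int(_hemi_block(flags.missing, side).sum())
    return present >= MIN_PRESENT_PER_HEMI


@dataclass(frozen=True)
class LesionCall:
    """Patient-level OCT verdict with side, per layer and combined."""

    patient_id: str
    per_layer: dict[RetinalLayer, CallSide]
    combined: CallSide
    k: float
    m: int
    evaluable: bool = True
    exclusion_reason: str | None = None

    @property
    def positive(self) -> bool:
        return self.combined is not CallSide.NONE


def _layer_side_call(
    od: AtrophyFlags, os_: AtrophyFlags, m: int
) -> CallSide:
    sides = []
    for side in (HemiSide.RIGHT, HemiSide.LEFT):
        if hemi_atrophy(od, side, m) and hemi_atrophy(os_, side, m):
            sides.append(side)
    if len(sides) == 2:
        return CallSide.BILATERAL
    if sides:
        return CallSide(sides[0].value)
    return CallSide.NONE


def _combine(a: CallSide, b: CallSide) -> CallSide:
    """Union of two side calls: any layer calling a side calls it."""
    sides = set()
    for c in (a, b):
        if c is CallSide.BILATERAL:
            sides |= {CallSide.RIGHT, CallSide.LEFT}
        elif c is not CallSide.NONE:
            sides.add(c)
    if sides == {CallSide.RIGHT, CallSide.LEFT}:
        return CallSide.BILATERAL
    if sides:
        return next(iter(sides))
    return CallSide.NONE


def patient_call(
    patient_id: str,
    flags: dict[Laterality, dict[RetinalLayer, AtrophyFlags]],
    m: int = 4,
) -> LesionCall:
    """Homonymous-atrophy lesion call from both eyes' flag maps.

    A side is called per layer only when that side's hemi-macula is
    atrophic in BOTH eyes.  If either eye is missing, or any required
    hemi-macula has too many missing sectors, the call abstains
    (``evaluable=False``) and is excluded from contingency tables.
    """
    k = None
    for lat in (Laterality.OD, Laterality.OS):
        if lat not in flags:
            return LesionCall(
                patient_id,
                {layer: CallSide.NONE for layer in RetinalLayer},
                CallSide.NONE,
                k=float("nan"),
                m=m,
                evaluable=False,
                exclusion_reason=f"missing eye {lat.value}",
            )
        for layer in RetinalLayer:
            f = flags[lat].get(layer)
            if f is None:
                return LesionCall(
                    patient_id,
                    {l: CallSide.NONE for l in RetinalLayer},
                    CallSide.NONE,
                    k=float("nan"),
                    m=m,
                    evaluable=False,
                    exclusion_reason=f"missing {layer.value} flags for {lat.value}",
                )
            k = f.k
            for side in HemiSide:
                if not hemi_evaluable(f, side):
                    return LesionCall(
                        patient_id,
                        {l: CallSide.NONE for l in RetinalLayer},
                        CallSide.NONE,
                        k=f.k,
                        m=m,
                        evaluable=False,
                        exclusion_reason=(
                            f"{lat.value} {layer.value} {side.value} hemi-macula has "
                            f"fewer than {MIN_PRESENT_PER_HEMI} sectors present"
                        ),
                    )
    per_layer = {
        layer: _layer_side_call(flags[Laterality.OD][layer], flags[Laterality.OS][layer], m)
        for layer in RetinalLayer
    }
    combined = CallSide.NONE
    for call in per_layer.values():
        combined = _combine(combined, call)
    return LesionCall(patient_id, per_layer, combined, k=k, m=m)


@dataclass(frozen=True)
class EyeLevelCall:
    """Single-eye verdict relative to the MRI lesion side."""

    patient_id: str
    eye: Laterality
    relation: EyeRelation
    positive_per_layer: dict[RetinalLayer, bool]
    k: float
    m: int


def eye_level_call(
    patient_id: str,
    eye: Laterality,
    flags: dict[RetinalLayer, AtrophyFlags],
    mri_side: HemiSide,
    m: int = 4,
) -> EyeLevelCall:
    """Per-eye call: atrophy of the hemi-macula on the MRI lesion side.

    The eye is ipsilateral when its laterality matches the lesion side
    (OD with a right-pathway lesion), contralateral otherwise.
    """
    if not isinstance(mri_side, HemiSide):
        raise ValueError("eye-level calls require a lateralized MRI lesion")
    ipsi = (eye is Laterality.OD) == (mri_side is HemiSide.RIGHT)
    relation = EyeRelation.IPSILATERAL if ipsi else EyeRelation.CONTRALATERAL
    positive = {
        layer: hemi_atrophy(flags[layer], mri_side, m) for layer in flags
    }
    k = next(iter(flags.values())).k
    return EyeLevelCall(patient_id, eye, relation, positive, k=k, m=m)


def second_reader_disagreements(
    flags_by_patient: dict[str, dict[Laterality, dict[RetinalLayer, "AtrophyFlags"]]],
    m: int,
    m_alt: int,
) -> list[str]:
    """Emulate consensus review: re-call every patient with a perturbed
    sectors-per-hemi threshold and list patients whose combined call differs.

    (Perturbing k requires re-flagging; callers holding corrected grids can
    build a second flag set and diff the calls the same way.)
    """
    disagreements = []
    for pid, flags in flags_by_patient.items():
        first = patient_call(pid, flags, m=m)
        second = patient_call(pid, flags, m=m_alt)
        if first.combined is not second.combined:
            disagreements.append(pid)
    return disagreements
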
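"""Posterior-pole thickness-grid data model.

The Spectralis posterior-pole protocol reports per-layer retinal thickness
in an 8x8 sector chart covering the central 24 degrees.  Analysis of
homonymous (hemifield-respecting) ganglion-cell damage uses only the
central 4x4 block of that chart and splits it at the vertical meridian
into a right and a left hemi-macula.  Because the right hemi-retina of
both eyes projects to the right retrochiasmal pathway, "right hemi-macula"
is an anatomical (patient-space) notion: temporal half of the right eye,
nasal half of the left eye.

Grids therefore carry an orientation tag.  ``display`` means the values
are laid out as the device draws them (fundus view); ``patient_space``
means column index increases toward the patient's anatomical right for
both eyes.  Under the default fundus-view convention the two coincide,
but exports that mirror left-eye maps are supported via the
``mirrored_os`` display convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Laterality",
    "RetinalLayer",
    "HemiSide",
    "Orientation",
    "HemiLabel",
    "PosteriorPoleGrid",
    "EyeRecord",
    "PatientRecord",
    "extract_central_grid",
    "to_patient_space",
    "hemi_sectors",
    "hemi_label",
    "hemi_present_count",
    "MIN_PRESENT_PER_HEMI",
]

#: Sanity bound for inner-layer sector thickness (micrometers).
MAX_THICKNESS_UM = 200.0

#: A hemi-macula is classifiable when at least this many of its 8 sectors
#: are non-missing; otherwise the eye is excluded from classification.
MIN_PRESENT_PER_HEMI = 6


class Laterality(str, enum.Enum):
    """Eye laterality: OD = right eye, OS = left eye."""

    OD = "OD"
    OS = "OS"


class RetinalLayer(str, enum.Enum):
    """Macular layers analyzed: ganglion cell layer and inner plexiform layer."""

    GCL = "GCL"
    IPL = "IPL"


class HemiSide(str, enum.Enum):
    """Patient-space anatomical side of a hemi-macula (or retrochiasmal pathway)."""

    RIGHT = "right"
    LEFT = "left"

    @property
    def opposite(self) -> "HemiSide":
        return HemiSide.LEFT if self is HemiSide.RIGHT else HemiSide.RIGHT


class Orientation(str, enum.Enum):
    DISPLAY = "display"
    PATIENT_SPACE = "patient_space"


class HemiLabel(str, enum.Enum):
    """Retinal name of a hemi-macula relative to the fovea."""

    TEMPORAL = "temporal"
    NASAL = "nasal"


class GridDimensionError(ValueError):
    """Grid has the wrong shape for the requested operation."""


class GridStateError(RuntimeError):
    """Operation requested on a grid in the wrong orientation/correction state."""


class GridFormatError(ValueError):
    """Malformed grid metadata or values."""


@dataclass(frozen=True)
class PosteriorPoleGrid:
    """One eye/layer sector-thickness map (micrometers).

    ``values`` is a square float array of side 8 (raw export) or 4
    (central block); missing sectors are NaN.  Row index increases
    from superior to inferior retina; column meaning depends on
    ``orientation``.
    """

    laterality: Laterality
    layer: RetinalLayer
    values: np.ndarray
    orientation: Orientation = Orientation.DISPLAY

    def __post_init__(self) -> None:
        vals = np.array(self.values, dtype=float, copy=True)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1] or vals.shape[0] not in (4, 8):
            raise GridDimensionError(
                f"grid must be 8x8 or 4x4, got shape {vals.shape}"
            )
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > MAX_THICKNESS_UM):
            raise GridFormatError(
                "sector thickness outside [0, 200] um: "
                f"range [{finite.min():.2f}, {finite.max():.2f}]"
            )
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)
        if not isinstance(self.orientation, Orientation):
            raise GridFormatError(f"unknown orientation tag {self.orientation!r}")
        if not isinstance(self.laterality, Laterality):
            raise GridFormatError(f"unknown laterality {self.laterality!r}")
        if not isinstance(self.layer, RetinalLayer):
            raise GridFormatError(f"unknown layer {self.layer!r}")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray) -> "PosteriorPoleGrid":
        return replace(self, values=values)


def extract_central_grid(grid: PosteriorPoleGrid) -> PosteriorPoleGrid:
    """Return the central 4x4 block of an 8x8 grid.

    The central block is the symmetric center of the chart: rows and
    columns 3-6 in 1-based numbering.  Laterality, layer and
    orientation are preserved.
    """
    if grid.size != 8:
        raise GridDimensionError(f"central extraction needs an 8x8 grid, got {grid.size}x{grid.size}")
    return grid.with_values(grid.values[2:6, 2:6].copy())


def to_patient_space(
    grid: PosteriorPoleGrid, display_convention: str = "fundus"
) -> PosteriorPoleGrid:
    """Normalize a display-oriented grid to patient space.

    Under the default ``fundus`` convention image-right equals the
    patient's anatomical right for both eyes, so this is the identity
    on values.  Under ``mirrored_os`` the left eye's columns are
    reversed on ingest (for exports that mirror OS maps); applying the
    mirrored-OS ingest twice round-trips the values.
    """
    if grid.orientation is Orientation.PATIENT_SPACE:
        return grid
    if display_convention not in ("fundus", "mirrored_os"):
        raise GridFormatError(f"unknown display convention {display_convention!r}")
    vals = grid.values
    if display_convention == "mirrored_os" and grid.laterality is Laterality.OS:
        vals = vals[:, ::-1].copy()
    return replace(grid, values=vals, orientation=Orientation.PATIENT_SPACE)


def _hemi_cols(side: HemiSide) -> slice:
    # patient space: column index increases toward anatomical right
    return slice(2, 4) if side is HemiSide.RIGHT else slice(0, 2)


def hemi_sectors(grid: PosteriorPoleGrid, side: HemiSide) -> np.ndarray:
    """Return the 8 sector values of one hemi-macula of a central 4x4 grid.

    Right side = columns 3-4 (1-based) in patient space, left side =
    columns 1-2; the two calls partition the 16 sectors.
    """
    if grid.orientation is not Orientation.PATIENT_SPACE:
        raise GridStateError("hemi-macula queries require patient_space orientation")
    if grid.size != 4:
        raise GridDimensionError("hemi-macula queries require a central 4x4 grid")
    return grid.values[:, _hemi_cols(side)].ravel()


def hemi_present_count(grid: PosteriorPoleGrid, side: HemiSide) -> int:
    """Number of non-missing sectors in one hemi-macula."""
    return int(np.isfinite(hemi_sectors(grid, side)).sum())


def hemi_label(laterality: Laterality, side: HemiSide) -> HemiLabel:
    """Retinal name of a patient-space hemi-macula.

    The right hemi-macula is the temporal half of the right eye but the
    nasal half of the left eye (and vice versa for the left hemi-macula):
    homonymous right-pathway damage thins the temporal OD and nasal OS
    halves together.
    """
    if (laterality is Laterality.OD) == (side is HemiSide.RIGHT):
        return HemiLabel.TEMPORAL
    return HemiLabel.NASAL


@dataclass
class EyeRecord:
    """All per-eye inputs: layer grids, ON history and visual-field outcome."""

    laterality: Laterality
    grids: dict[RetinalLayer, PosteriorPoleGrid] = field(default_factory=dict)
    on_history: bool = False
    vf_defect: bool | None = None
    # (fixation_loss_pct, false_pos_pct, false_neg_pct)
    vf_reliability: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        for layer, grid in self.grids.items():
            if grid.laterality is not self.laterality:
                raise GridFormatError(
                    f"grid laterality {grid.laterality} != eye {self.laterality}"
                )
            if grid.layer is not layer:
                raise GridFormatError(f"grid layer {grid.layer} stored under {layer}")
        sizes = {g.size for g in self.grids.values()}
        if len(sizes) > 1:
            raise GridDimensionError(f"per-eye grids disagree in size: {sizes}")


class Group(str, enum.Enum):
    MS = "MS"
    CONTROL = "control"


class MriLesion(str, enum.Enum):
    """MRI retrochiasmal-lesion label: side of the predominantly affected pathway."""

    NONE = "none"
    RIGHT = "right"
    LEFT = "left"

    @property
    def present(self) -> bool:
        return self is not MriLesion.NONE

    @property
    def side(self) -> HemiSide | None:
        if self is MriLesion.RIGHT:
            return HemiSide.RIGHT
        if self is MriLesion.LEFT:
            return HemiSide.LEFT
        return None


@dataclass
class PatientRecord:
    patient_id: str
    group: Group
    eyes: dict[Laterality, EyeRecord] = field(default_factory=dict)
    mri_lesion: MriLesion | None = None

    def __post_init__(self) -> None:
        for lat, eye in self.eyes.items():
            if eye.laterality is not lat:
                raise GridFormatError(
                    f"eye {eye.laterality} stored under key {lat} for {self.patient_id}"
                )
        if self.group is Group.CONTROL and self.mri_lesion not in (None, MriLesion.NONE):
            raise GridFormatError(f"control {self.patient_id} carries an MRI lesion label")

    @property
    def complete(self) -> bool:
        """Both eyes present with both layer grids."""
        return set(self.eyes) == {Laterality.OD, Laterality.OS} and all(
            set(eye.grids) == {RetinalLayer.GCL, RetinalLayer.IPL}
            for eye in self.eyes.values()
        )
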
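"""Cohort CSV schemas: long-format grid export and per-eye labels.

Grid CSV columns: patient_id, group, eye (OD|OS), layer (GCL|IPL),
row (1-8), col (1-8), thickness_um (empty = missing sector).  The
parser validates that every (patient, eye, layer) block carries all 64
sector rows.

Labels CSV columns: patient_id, mri_lesion (none|right|left|NA), eye,
on_history, vf_defect, fixation_loss_pct, false_pos_pct, false_neg_pct.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .grids import (
    EyeRecord,
    Group,
    Laterality,
    MriLesion,
    Orientation,
    PatientRecord,
    PosteriorPoleGrid,
    RetinalLayer,
)

__all__ = ["write_grid_csv", "write_labels_csv", "read_cohort", "CohortLoadError"]

GRID_COLUMNS = ["patient_id", "group", "eye", "layer", "row", "col", "thickness_um"]
LABEL_COLUMNS = [
    "patient_id",
    "mri_lesion",
    "eye",
    "on_history",
    "vf_defect",
    "fixation_loss_pct",
    "false_pos_pct",
    "false_neg_pct",
]


class CohortLoadError(ValueError):
    """Schema violation in a cohort CSV; message itemizes the problems."""


def write_grid_csv(records: list[PatientRecord], path: str | Path) -> None:
    rows = []
    for patient in records:
        for lat in sorted(patient.eyes, key=lambda l: l.value):
            eye = patient.eyes[lat]
            for layer in sorted(eye.grids, key=lambda l: l.value):
                grid = eye.grids[layer]
                vals = grid.values
                for r in range(vals.shape[0]):
                    for c in range(vals.shape[1]):
                        v = vals[r, c]
                        rows.append(
                            (
                                patient.patient_id,
                                patient.group.value,
                                lat.value,
                                layer.value,
                                r + 1,
                                c + 1,
                                "" if not np.isfinite(v) else f"{v:.4f}",
                            )
                        )
    pd.DataFrame(rows, columns=GRID_COLUMNS).to_csv(path, index=False)


def write_labels_csv(records: list[PatientRecord], path: str | Path) -> None:
    rows = []
    for patient in records:
        mri = "NA" if patient.mri_lesion is None else patient.mri_lesion.value
        for lat in sorted(patient.eyes, key=lambda l: l.value):
            eye = patient.eyes[lat]
            rel = eye.vf_reliability or (np.nan, np.nan, np.nan)
            rows.append(
                (
                    patient.patient_id,
                    mri,
                    lat.value,
                    int(eye.on_history),
                    "" if eye.vf_defect is None else int(eye.vf_defect),
                    *(f"{x:.2f}" if np.isfinite(x) else "" for x in rel),
                )
            )
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, index=False)


def _parse_grid_block(block: pd.DataFrame, pid: str, eye: str, layer: str) -> np.ndarray:
    sizes = {4, 8}
    n = int(block["row"].max())
    if n not in sizes or int(block["col"].max()) != n:
        raise CohortLoadError(f"{pid}/{eye}/{layer}: grid extent {n} not 4 or 8")
    if len(block) != n * n or block.duplicated(["row", "col"]).any():
        raise CohortLoadError(
            f"{pid}/{eye}/{layer}: expected {n * n} unique sector rows, got {len(block)}"
        )
    values = np.full((n, n), np.nan)
    r = block["row"].to_numpy(int) - 1
    c = block["col"].to_numpy(int) - 1
    if r.min() < 0 or c.min() < 0:
        raise CohortLoadError(f"{pid}/{eye}/{layer}: sector indices must be 1-based")
    values[r, c] = pd.to_numeric(block["thickness_um"], errors="coerce").to_numpy()
    return values


def read_cohort(
    grid_path: str | Path, labels_path: str | Path
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Load (patients, controls) from the two CSV schemas.

    Grids come back in display orientation; downstream stages normalize
    to patient space.
    """
    grids = pd.read_csv(grid_path, dtype={"thickness_um": str}, keep_default_na=False)
    labels = pd.read_csv(labels_path, keep_default_na=False)
    errors = []
    for name, df, cols in (("grid", grids, GRID_COLUMNS), ("labels", labels, LABEL_COLUMNS)):
        missing = set(cols) - set(df.columns)
        if missing:
            errors.append(f"{name} CSV missing columns {sorted(missing)}")
    if errors:
        raise CohortLoadError("; ".join(errors))

    label_idx: dict[tuple[str, str], pd.Series] = {}
    for _, row in labels.iterrows():
        label_idx[(str(row["patient_id"]), str(row["eye"]))] = row

    patients: list[PatientRecord] = []
    controls: list[PatientRecord] = []
    for pid, pat_block in grids.groupby("patient_id", sort=True):
        group = Group(pat_block["group"].iloc[0])
        eyes: dict[Laterality, EyeRecord] = {}
        mri: MriLesion | None = None
        for eye_code, eye_block in pat_block.groupby("eye", sort=True):
            lat = Laterality(eye_code)
            layer_grids = {}
            for layer_code, layer_block in eye_block.groupby("layer", sort=True):
                layer = RetinalLayer(layer_code)
                values = _parse_grid_block(layer_block, str(pid), eye_code, layer_code)
                layer_grids[layer] = PosteriorPoleGrid(
                    laterality=lat,
                    layer=layer,
                    values=values,
                    orientation=Orientation.DISPLAY,
                )
            label = label_idx.get((str(pid), eye_code))
            if label is None:
                raise CohortLoadError(f"{pid}/{eye_code}: no labels row")
            mri_code = str(label["mri_lesion"])
            mri = None if mri_code == "NA" else MriLesion(mri_code)
            vf_raw = str(label["vf_defect"])
            rel_raw = [str(label[c]) for c in LABEL_COLUMNS[5:]]
            rel = None
            if all(x not in ("", "nan") for x in rel_raw):
                rel = tuple(float(x) for x in rel_raw)
            eyes[lat] = EyeRecord(
                laterality=lat,
                grids=layer_grids,
                on_history=bool(int(label["on_history"])),
                vf_defect=None if vf_raw in ("", "nan") else bool(int(float(vf_raw))),
                vf_reliability=rel,
            )
        record = PatientRecord(str(pid), group, eyes, mri_lesion=mri)
        (controls if group is Group.CONTROL else patients).append(record)
    return patients, controls
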
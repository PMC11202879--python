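import dataclasses

import numpy as np
import pytest

from hemimacula.grids import (
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
from hemimacula.simulate import SimulationParams, simulate_cohort


def make_grid(values, laterality=Laterality.OD, layer=RetinalLayer.GCL,
              orientation=Orientation.PATIENT_SPACE):
    return PosteriorPoleGrid(
        laterality=laterality, layer=layer, values=np.asarray(values, dtype=float),
        orientation=orientation,
    )


def constant_control(pid: str, value: float = 40.0, size: int = 4) -> PatientRecord:
    eyes = {}
    for lat in (Laterality.OD, Laterality.OS):
        grids = {
            layer: make_grid(np.full((size, size), value), lat, layer)
            for layer in RetinalLayer
        }
        eyes[lat] = EyeRecord(laterality=lat, grids=grids)
    return PatientRecord(pid, Group.CONTROL, eyes, mri_lesion=MriLesion.NONE)


def mirror_patient(patient: PatientRecord) -> PatientRecord:
    """Reflect grids across the vertical meridian, swap OD/OS and MRI side."""
    swap = {Laterality.OD: Laterality.OS, Laterality.OS: Laterality.OD}
    eyes = {}
    for lat, eye in patient.eyes.items():
        new_lat = swap[lat]
        grids = {
            layer: dataclasses.replace(g, values=g.values[:, ::-1].copy(), laterality=new_lat)
            for layer, g in eye.grids.items()
        }
        eyes[new_lat] = dataclasses.replace(eye, laterality=new_lat, grids=grids)
    mri = patient.mri_lesion
    if mri is MriLesion.RIGHT:
        mri = MriLesion.LEFT
    elif mri is MriLesion.LEFT:
        mri = MriLesion.RIGHT
    return dataclasses.replace(patient, eyes=eyes, mri_lesion=mri)


def mirror_cohort(cohort):
    out = dataclasses.replace(cohort)
    out.patients = [mirror_patient(p) for p in cohort.patients]
    out.controls = [mirror_patient(p) for p in cohort.controls]
    swap = {HemiSide.RIGHT: HemiSide.LEFT, HemiSide.LEFT: HemiSide.RIGHT, None: None}
    out.truth = {
        pid: {
            "lesion_side": swap[info["lesion_side"]],
            "on_eyes": [
                {Laterality.OD: Laterality.OS, Laterality.OS: Laterality.OD}[e]
                for e in info["on_eyes"]
            ],
        }
        for pid, info in cohort.truth.items()
    }
    return out


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimulationParams(seed=11))


@pytest.fixture(scope="session")
def noise_free_params():
    """Strong homonymous deficits on an essentially noise-free background."""
    return SimulationParams(
        p_on_history=0.0,
        base_sd=0.1,
        lesion_effect={RetinalLayer.GCL: 20.0, RetinalLayer.IPL: 20.0},
        seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_params):
    return simulate_cohort(noise_free_params)
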
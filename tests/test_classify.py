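import numpy as np
import pytest

from hemimacula.classify import (
    AtrophyFlags,
    CallSide,
    EyeRelation,
    eye_level_call,
    flag_sectors,
    hemi_atrophy,
    hemi_evaluable,
    patient_call,
    second_reader_disagreements,
)
from hemimacula.correction import CorrectedGrid, SectorReference
from hemimacula.grids import HemiSide, Laterality, Orientation, RetinalLayer
from hemimacula.pipeline import PipelineConfig, run_all
from hemimacula.simulate import SimulationParams, simulate_cohort


def corrected(values, layer=RetinalLayer.GCL, laterality=Laterality.OD):
    return CorrectedGrid(
        laterality, layer, np.asarray(values, dtype=float),
        Orientation.PATIENT_SPACE, baseline_adjusted=True,
    )


def reference(sd=3.0, layer=RetinalLayer.GCL):
    return SectorReference(layer, np.zeros((4, 4)), np.full((4, 4), sd), 10)


def flags_from(matrix, layer=RetinalLayer.GCL, k=2.0, missing=None):
    missing = np.zeros((4, 4), bool) if missing is None else np.asarray(missing, bool)
    return AtrophyFlags(layer, np.asarray(matrix, bool), missing, k)


def both_eye_flags(od_matrix, os_matrix, layer_only=None):
    """Flag maps for both eyes; other layer gets no flags unless layer_only is None."""
    out = {}
    for lat, mat in ((Laterality.OD, od_matrix), (Laterality.OS, os_matrix)):
        per_layer = {}
        for layer in RetinalLayer:
            if layer_only is None or layer is layer_only:
                per_layer[layer] = flags_from(mat, layer)
            else:
                per_layer[layer] = flags_from(np.zeros((4, 4)), layer)
        out[lat] = per_layer
    return out


RIGHT_HEMI = np.hstack([np.zeros((4, 2)), np.ones((4, 2))])
LEFT_HEMI = RIGHT_HEMI[:, ::-1]


class TestFlagSectors:
    def test_zero_deviations_unflagged(self):
        out = flag_sectors(corrected(np.zeros((4, 4))), reference(), k=2.0)
        assert not out.flags.any()

    def test_three_sigma_deficit_all_flagged(self):
        out = flag_sectors(corrected(np.full((4, 4), -9.0)), reference(3.0), k=2.0)
        assert out.flags.all()

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(6)
        tau = rng.normal(0, 6, (4, 4))
        sd = rng.uniform(1, 5, (4, 4))
        ref = SectorReference(RetinalLayer.GCL, np.zeros((4, 4)), sd, 10)
        out = flag_sectors(corrected(tau), ref, k=1.5)
        expected = np.array(
            [[tau[r, c] <= -1.5 * sd[r, c] for c in range(4)] for r in range(4)]
        )
        np.testing.assert_array_equal(out.flags, expected)

    def test_missing_sectors_unflagged_but_counted(self):
        tau = np.full((4, 4), -9.0)
        tau[0, 0] = np.nan
        out = flag_sectors(corrected(tau), reference(), k=2.0)
        assert not out.flags[0, 0]
        assert out.missing[0, 0] and out.n_missing == 1

    def test_zero_sd_reference_warns_and_flags(self):
        ref = SectorReference(RetinalLayer.GCL, np.zeros((4, 4)), np.zeros((4, 4)), 10)
        tau = np.zeros((4, 4))
        tau[1, 1] = -0.5
        with pytest.warns(RuntimeWarning):
            out = flag_sectors(corrected(tau), ref, k=2.0)
        assert out.flags[1, 1] and out.flags.sum() == 1


class TestHemiAtrophy:
    def test_no_flags_negative_both_sides(self):
        f = flags_from(np.zeros((4, 4)))
        assert not hemi_atrophy(f, HemiSide.RIGHT) and not hemi_atrophy(f, HemiSide.LEFT)

    @pytest.mark.parametrize("m", [1, 4, 8])
    def test_boundary_exactly_m_flags(self, m):
        mat = np.zeros((4, 4), bool)
        mat[:, 2:4].flat[:m] = True
        f = flags_from(mat)
        assert hemi_atrophy(f, HemiSide.RIGHT, m)
        assert not hemi_atrophy(f, HemiSide.LEFT, m)
        if m < 8:
            assert not hemi_atrophy(f, HemiSide.RIGHT, m + 1)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            mat = rng.random((4, 4)) < 0.4
            f = flags_from(mat)
            m = int(rng.integers(1, 9))
            for side, cols in ((HemiSide.RIGHT, (2, 3)), (HemiSide.LEFT, (0, 1))):
                count = sum(mat[r, c] for r in range(4) for c in cols)
                assert hemi_atrophy(f, side, m) == (count >= m)

    def test_evaluable_threshold(self):
        missing = np.zeros((4, 4), bool)
        missing[0:2, 2] = True  # 2 missing on right: still evaluable (6 present)
        assert hemi_evaluable(flags_from(np.zeros((4, 4)), missing=missing), HemiSide.RIGHT)
        missing[2, 2] = True  # 3 missing: excluded
        assert not hemi_evaluable(flags_from(np.zeros((4, 4)), missing=missing), HemiSide.RIGHT)


class TestPatientCall:
    def test_single_eye_atrophy_is_not_homonymous(self):
        call = patient_call("p", both_eye_flags(RIGHT_HEMI, np.zeros((4, 4))), m=4)
        assert call.combined is CallSide.NONE and not call.positive

    def test_gcl_only_homonymous_right(self):
        call = patient_call(
            "p", both_eye_flags(RIGHT_HEMI, RIGHT_HEMI, layer_only=RetinalLayer.GCL), m=4
        )
        assert call.per_layer[RetinalLayer.GCL] is CallSide.RIGHT
        assert call.per_layer[RetinalLayer.IPL] is CallSide.NONE
        assert call.combined is CallSide.RIGHT and call.positive

    def test_both_sides_bilateral(self):
        full = np.ones((4, 4))
        call = patient_call("p", both_eye_flags(full, full), m=4)
        assert call.combined is CallSide.BILATERAL and call.positive

    def test_layers_union_across_sides(self):
        flags = both_eye_flags(RIGHT_HEMI, RIGHT_HEMI, layer_only=RetinalLayer.GCL)
        for lat in flags:
            flags[lat][RetinalLayer.IPL] = flags_from(LEFT_HEMI, RetinalLayer.IPL)
        call = patient_call("p", flags, m=4)
        assert call.combined is CallSide.BILATERAL

    def test_missing_eye_abstains(self):
        flags = both_eye_flags(RIGHT_HEMI, RIGHT_HEMI)
        del flags[Laterality.OS]
        call = patient_call("p", flags, m=4)
        assert not call.evaluable and "OS" in call.exclusion_reason

    def test_unevaluable_hemi_abstains(self):
        missing = np.zeros((4, 4), bool)
        missing[0:3, 2] = True
        flags = both_eye_flags(RIGHT_HEMI, RIGHT_HEMI)
        flags[Laterality.OD][RetinalLayer.GCL] = flags_from(RIGHT_HEMI, missing=missing)
        call = patient_call("p", flags, m=4)
        assert not call.evaluable


class TestEyeLevelCall:
    def test_od_with_right_lesion_is_ipsilateral(self):
        call = eye_level_call(
            "p", Laterality.OD,
            {RetinalLayer.GCL: flags_from(np.zeros((4, 4)))},
            HemiSide.RIGHT,
        )
        assert call.relation is EyeRelation.IPSILATERAL

    def test_os_with_right_atrophy_contralateral_positive(self):
        call = eye_level_call(
            "p", Laterality.OS,
            {RetinalLayer.GCL: flags_from(RIGHT_HEMI)},
            HemiSide.RIGHT,
        )
        assert call.relation is EyeRelation.CONTRALATERAL
        assert call.positive_per_layer[RetinalLayer.GCL]

    def test_zero_flags_negative_for_any_side(self):
        for side in HemiSide:
            call = eye_level_call(
                "p", Laterality.OD,
                {RetinalLayer.GCL: flags_from(np.zeros((4, 4)))},
                side,
            )
            assert not any(call.positive_per_layer.values())

    def test_requires_lateralized_lesion(self):
        with pytest.raises(ValueError):
            eye_level_call(
                "p", Laterality.OD,
                {RetinalLayer.GCL: flags_from(np.zeros((4, 4)))},
                None,
            )


def _sensitivity(report, layer="GCL", variant="corrected"):
    row = report[
        (report.comparison == "OCT_vs_MRI")
        & (report.level == "patient")
        & (report.layer == layer)
        & (report.variant == variant)
    ].iloc[0]
    return float(row.sensitivity)


class TestCohortLevelProperties:
    def test_sensitivity_monotone_in_k_and_m(self):
        cohort = simulate_cohort(SimulationParams(seed=29))
        sens_k = [
            _sensitivity(run_all(PipelineConfig(k=k), cohort).report)
            for k in (1.0, 1.5, 2.0, 2.5, 3.0)
        ]
        assert all(a >= b for a, b in zip(sens_k, sens_k[1:]))
        sens_m = [
            _sensitivity(run_all(PipelineConfig(m=m), cohort).report)
            for m in (1, 2, 4, 6, 8)
        ]
        assert all(a >= b for a, b in zip(sens_m, sens_m[1:]))

    def test_perfect_signal_recovery(self, noise_free_cohort):
        """Strong noise-free homonymous deficits: every lesioned patient is
        called positive with the correct side, for every m."""
        from hemimacula.correction import CorrectionModel
        from hemimacula.pipeline import correct_cohort, prepare_cohort, compute_flags

        patients = prepare_cohort(noise_free_cohort.patients)
        controls = prepare_cohort(noise_free_cohort.controls)
        model = CorrectionModel.fit(patients, controls, "controls")
        flags = compute_flags(correct_cohort(patients, model), model, "corrected", 2.0)
        for m in range(1, 9):
            for patient in patients:
                truth_side = noise_free_cohort.truth[patient.patient_id]["lesion_side"]
                call = patient_call(patient.patient_id, flags[patient.patient_id], m)
                if truth_side is not None:
                    assert call.positive
                    assert call.combined.matches(truth_side)

    def test_second_reader_mode_flags_threshold_sensitive_patients(self):
        cohort = simulate_cohort(SimulationParams(seed=31, n_patients=20, n_controls=8))
        from hemimacula.correction import CorrectionModel
        from hemimacula.pipeline import correct_cohort, prepare_cohort, compute_flags

        patients = prepare_cohort(cohort.patients)
        controls = prepare_cohort(cohort.controls)
        model = CorrectionModel.fit(patients, controls, "controls")
        flags = compute_flags(correct_cohort(patients, model), model, "corrected", 2.0)
        disagreements = second_reader_disagreements(flags, m=4, m_alt=6)
        assert set(disagreements) <= {p.patient_id for p in patients}
        # calls that disagree must genuinely change under the stricter reader
        for pid in disagreements:
            first = patient_call(pid, flags[pid], 4)
            second = patient_call(pid, flags[pid], 6)
            assert first.combined is not second.combined
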
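"""Flag atrophic sectors and call retrochiasmal lesions with side.

A sector is atrophic when its corrected deviation is at or below
-k control SDs (k=2); a hemi-macula when >= m of its 8 sectors are
flagged (m=4); a patient is positive when the SAME side is atrophic in
both eyes — the homonymous pattern of trans-synaptic degeneration.
"""

from hemimacula import CorrectionModel, SimulationParams, simulate_cohort
from hemimacula.classify import patient_call
from hemimacula.pipeline import compute_flags, correct_cohort, prepare_cohort

cohort = simulate_cohort(SimulationParams(seed=3))
patients = prepare_cohort(cohort.patients)
controls = prepare_cohort(cohort.controls)
model = CorrectionModel.fit(patients, controls)
flags = compute_flags(correct_cohort(patients, model), model, "corrected", k=2.0)

hits = misses = 0
for patient in patients[:10]:
    truth = cohort.truth[patient.patient_id]["lesion_side"]
    call = patient_call(patient.patient_id, flags[patient.patient_id], m=4)
    truth_str = truth.value if truth else "none"
    print(
        f"{patient.patient_id}: call={call.combined.value:<9} "
        f"(GCL={call.per_layer[list(call.per_layer)[0]].value}) truth={truth_str}"
    )
for patient in patients:
    truth = cohort.truth[patient.patient_id]["lesion_side"]
    call = patient_call(patient.patient_id, flags[patient.patient_id], m=4)
    if truth is not None:
        if call.positive and call.combined.matches(truth):
            hits += 1
        else:
            misses += 1
print(f"\nlesioned patients with correct side call: {hits}/{hits + misses}")
# With the default 10-um GCL hemi-deficit against 4-um sector noise, most
# lesions are lateralized correctly; misses reflect noise, the m=4 threshold
# and ON-correction residuals.
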
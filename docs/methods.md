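# Methods

## Problem and model

In multiple sclerosis (MS), lesions of the retrochiasmal visual pathway
(optic tract, lateral geniculate nucleus, optic radiations) can produce
retrograde trans-synaptic degeneration of retinal ganglion cells. Because
the right hemi-retina of both eyes projects to the right retrochiasmal
pathway, this degeneration is *homonymous*: it thins the ganglion cell
layer (GCL) and inner plexiform layer (IPL) in the hemi-maculae on the
same anatomical side of both eyes — the temporal half of one eye and the
nasal half of the fellow eye. `hemimacula` turns this pattern into a
lateralizing diagnostic test computed from macular OCT posterior-pole
thickness grids, and evaluates it against MRI lesion labels and visual
field (VF) outcomes.

### Grid geometry

Input grids are 8×8 sector charts of per-layer thickness (µm) as exported
by posterior-pole macular protocols. Only the symmetric central 4×4 block
(rows/columns 3–6, 1-based) is analyzed. Grids carry an orientation tag:
`display` (as drawn by the device) or `patient_space` (column index
increases toward the patient's anatomical right). The default ingest
convention is fundus view, under which the two coincide; a `mirrored_os`
convention reverses left-eye columns on ingest for exports that mirror OS
maps. The vendor's on-screen handedness for left-eye maps is not uniform
across export paths, so both conventions are supported and the choice is
part of the configuration. Hemi-maculae are vertical-meridian halves of
the central block in patient space: right = columns 3–4, left = columns
1–2. The superior/inferior (row) orientation never enters any rule but is
fixed (top = superior) for reproducibility.

### Two-step correction

For each layer and sector *s* with thickness *t_s*:

1. **Baseline adjustment**: τ_s = t_s − µ_s, where µ_s is the per-sector
   mean over all control eyes (both eyes pooled, sample SD σ_s with n−1
   denominator). Pooling both eyes treats eyes as independent; this is a
   documented simplification.
2. **ON adjustment** (eyes with optic neuritis history only):
   τ_s ← τ_s + δ_s, where δ_s = mean_ref(t_s) − mean_ON(t_s) is the mean
   thickness difference between a reference group and ON eyes (positive
   when ON eyes are thinner). The reference group is configurable:
   healthy controls (default) or MS eyes without ON history. The scope is
   configurable: per-eye with ON history (default) or both eyes of any
   ON-history patient. The offset is computed from ON eyes only, not from
   both eyes of ON-history patients. When a cohort contains no ON eyes at
   all the offset is identically zero (the adjustment is vacuous); a
   direct call to `fit_on_offset` on such a cohort still raises, since an
   offset "fitted" without ON eyes is meaningless.

The ON adjustment removes the diffuse neuritis deficit so residual
hemi-asymmetry can be attributed to retrochiasmal damage. Re-applying it
to an already ON-adjusted grid raises rather than silently doubling.

### Atrophy flagging and lesion calls

Human readers of corrected color maps are replaced by a deterministic
surrogate with two parameters, reported on every output:

* **k** (default 2.0): a sector is atrophic when τ_s ≤ −k·σ_s, roughly
  the 2.3rd percentile of the control distribution under normality. A
  degenerate reference sector (σ_s = 0) flags any strictly negative
  deviation and emits a warning.
* **m** (default 4 of 8): a hemi-macula is atrophic when at least m of
  its 8 sectors are flagged.

A patient is called positive for a retrochiasmal lesion on side *s* in a
layer when the side-*s* hemi-maculae of **both** eyes are atrophic in
that layer (homonymous atrophy); either layer suffices for the combined
call, and both sides positive yields `bilateral`. Bilateral calls count
as test-positive and match either side against MRI. A hemi-macula with
fewer than 6 of 8 sectors present makes the patient unevaluable for that
variant; unevaluable patients are excluded from contingency tables and
logged. An optional "second reader" mode re-calls every patient with a
perturbed m and reports disagreements, emulating consensus review.

Eye-level calls classify each eye of an MRI-lesioned patient as
ipsilateral or contralateral to the lesion and test the hemi-macula on
the lesion side. Because crossed fibers outnumber uncrossed ones in the
chiasm (~53:47), the contralateral eye is expected to show the larger
deficit.

### Diagnostic evaluation

Four paired comparisons are tabulated, each with sensitivity,
specificity, PPV, NPV and a McNemar p-value on the discordant pairs:
OCT vs MRI (patient level, per layer, raw and ON-corrected), VF vs MRI,
OCT vs VF, and OCT vs MRI at eye level split by ipsi-/contralateral
relation. Zero-denominator statistics propagate as an explicit
`undefined` token, never as 0 or NaN.

McNemar's test: exact p = min(1, 2·P(X ≤ min(b,c))) with
X ~ Binomial(b+c, ½); chi-square statistic (b−c)²/(b+c) on 1 df, with a
continuity-corrected variant (|b−c|−1)²/(b+c). The default method is
exact for b+c < 25 and chi-square otherwise; all three are selectable.

The eye-level tables need a lesion-negative arm, which a study with
per-patient lesion labels does not define unambiguously. The package's
construction: the lesion-positive arm is the relation-matching eye of
each lesioned patient (positive = hemi-atrophy on the lesion side); the
lesion-negative arm is both eyes of MRI-lesion-free MS patients
(positive = hemi-atrophy on either side). VF results are filtered for
reliability (fixation losses, false positives and false negatives each
strictly below 33%); the patient-level VF flag aggregates reliable eyes
by `any_eye` (default) or `both_eyes`.

`reconstruct_tables` inverts rounded published statistics: it
exhaustively enumerates all integer 2×2 tables of a given total whose
four statistics round (half-up, two decimals — the convention of printed
tables) to the given values. It returns the possibly-empty set rather
than asserting a unique solution, since four rounded ratios generally do
not determine the cells.

## Synthetic cohort generator

No raw patient data are available, so all testing runs on a generator
that encodes the damage structure the analysis assumes. Defaults follow
the study-cohort anchors where reported and field-plausible values
elsewhere:

| parameter | default | meaning |
|---|---|---|
| n_patients / n_controls | 52 / 27 | cohort sizes |
| p_on_history | 0.307 | ON-history prevalence among patients |
| p_lesion | 0.60 | retrochiasmal-lesion prevalence (unreported in the cohort; mid-range of the 30–90% literature span, configurable) |
| base_mean | GCL 30–52 µm, IPL 28–44 µm | center-weighted 4×4 macular profile, left-right symmetric |
| base_sd | 4.0 µm | per-sector noise SD |
| on_effect | GCL 8, IPL 6 µm | diffuse thinning of one randomly chosen eye per ON patient |
| lesion_effect | GCL 10, IPL 8 µm | mean hemi-macular deficit on the lesion side, averaged over eyes |
| crossed_fraction | 0.53 | contralateral eye loses 2·effect·0.53, ipsilateral 2·effect·0.47 |
| vf_sens / vf_false_pos | 0.14 / 0.38 | per-patient VF flag law against lesion truth |

Sector noise is independent across sectors by default; an optional
Gaussian smoothing of the noise field (σ in sector units, marginal SD
restored after filtering) adds spatial correlation for robustness tests.
The 8×8 chart is built by edge-replicating the central profile with a
4 µm peripheral taper; peripheral sectors are carried by the export
format but never analyzed. VF is generated at patient level and mirrored
onto both eyes; ON is unilateral. Everything is reproducible bit-for-bit
from a single seed.

The magnitudes of ON and lesion effects are literature-plausible
placeholders, **not** estimates of any study's data: the generator
reproduces the *structure* (homonymous laterality, contralateral
dominance, diffuse ON thinning, weak VF sensitivity), so passing tests
demonstrate correctness of the machinery, not clinical performance.
Real data additionally exhibit inter-eye and inter-sector correlation,
segmentation artifacts, age effects and non-Gaussian tails that the
generator does not emulate.

## Numerical choices and problem sizes

* Sample SD uses the n−1 denominator throughout.
* Flag threshold comparisons are inclusive (τ_s ≤ −k·σ_s); VF
  reliability is strict (< 33); hemi-atrophy is inclusive (≥ m).
* Rounding for table reconstruction is decimal half-up, applied to the
  shortest-repr decimal of the float.
* Test and verification sizes: statistic oracles on 1,000 random paired
  datasets (n ≤ 200) and full binomial enumeration for all discordant
  totals ≤ 30; correction identities at 500 eyes per arm (offset fitted
  and applied on disjoint samples); mirror invariance over 100 cohorts
  of 10 patients + 6 controls; generator calibration at 10,000 patients;
  reconstruction soundness on 500 random tables of total ≤ 60. These
  sizes give 3-standard-error margins on every stochastic check while
  keeping the suite fast.

## Known limitations

* The (k, m) surrogate is this package's construction; the original
  two-reader consensus cannot be reproduced algorithmically, and results
  depend on (k, m) — which is why both are echoed into every output row.
* Controls' eyes are pooled as independent observations.
* No age/sex covariate adjustment, no longitudinal modelling, no
  peripapillary RNFL analysis, no confidence intervals on predictive
  values, no ROC analysis (the classifier is binary by construction).
* The generator's effect sizes are assumptions; diagnostic-accuracy
  numbers computed on synthetic cohorts characterize the pipeline under
  those assumptions only.
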
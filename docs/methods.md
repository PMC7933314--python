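# Methods

## Scope

The package implements the planning-side analysis of hepatic
radioembolization: compartmental dosimetry, target-volume (TgV)
segmentation on emission images, planar lung-shunt quantification, and the
statistics that compare TgV estimates across imaging modalities. It does
not model image acquisition or reconstruction, angiographic flow
redistribution, voxel-level dosimetry, or body-surface-area dosing; the
cohort fixture supplies CECT/CBCT volumes as numbers because manual CT
contouring is out of scope.

## Partition-model dosimetry

Compartment doses follow the MIRD partition model for a permanently
implanted pure beta emitter. For ⁹⁰Y the equilibrium dose constant is
49.67 Gy·kg/GBq; soft-tissue density is 1.03 g/ml; lung mass is fixed at
1.0 kg. All three are fields of `DoseConstants` so a site can substitute
its own values. Activity is conserved across compartments to 1e-9 GBq by
construction and asserted on every call.

Prescription solves each clinical rule exactly, since both compartment
doses are linear in the administered activity: the safety rule returns the
activity at which non-tumoral liver reaches 40 Gy; the tumoricidal rule
returns the activity at which tumor dose reaches 100 Gy plus a 1e-6 Gy
epsilon, honouring the strict inequality. When neither special case
applies (non-cirrhotic with a large TgV, or cirrhotic with a large spared
volume) the minimum of the two solutions is used so the safety cap can
never be exceeded; the returned rationale string names the rule that
fired. The exact interaction of the two rules for intermediate cases is a
documented surrogate — published descriptions state the two thresholds but
not their full combination logic.

The fictitious fixed-activity comparison (default 1 GBq) deducts the lung
shunt before distributing activity; `deduct_shunt=False` switches to
assigning the full activity to the liver compartments, since sources are
ambiguous on this point. The TNR used for every modality is the one
measured on MAA SPECT/CT; only the TgV (and hence the normal-compartment
volume TgV − V_tumor) changes between modalities.

## Volumetry

The isocontour segmentation thresholds at a percentage of the maximum
voxel value *inside the search VOI* (not the global maximum — the
published tool description does not say which; the VOI-local choice
matches per-target semantics and is flagged as a surrogate). Comparison is
inclusive (≥), which makes uniform regions deterministic: at 100% every
voxel tied at the maximum is kept. No connectivity filtering is applied.
Volumes are voxel count × dx·dy·dz/1000 ml. `fit_isocontour_to_reference`
automates the visual threshold adjustment clinicians perform: it evaluates
a candidate list and keeps the threshold whose volume is closest to a
reference, ties resolving to the lower threshold.

The lung shunt uses conjugate-view geometric means: GM(ROI) =
√(anterior-sum × posterior-sum), HPS = GM(lung)/(GM(lung)+GM(liver)),
contraindication above 20%. This is the standard planar quantification;
the exact clinical ROI protocol is not modelled.

TNR is the unweighted mean over tumors of (mean tumor uptake)/(mean
normal-liver uptake), matching the multi-tumor averaging convention used
clinically.

## Synthetic data

`generate_phantom` renders an ellipsoidal liver with spherical tumors
(uptake = TNR multiplier), a lung slab receiving the shunt fraction, an
optional isotropic Gaussian PSF (`scipy.ndimage.gaussian_filter`,
zero-padded boundaries), and Poisson noise on the planar views at a stated
total count. Planar views are axis sums without attenuation — enough to
exercise the geometric-mean estimator, not a physical projector. The truth
record carries analytic volumes (4/3·π·abc for the liver, 4/3·π·r³ per
tumor), the specified TNR and shunt, plus voxelized masks. "Core" masks
eroded by ~3 PSF sigma support partial-volume-free TNR sampling; with
blur enabled, uptake recovery inside the cores is within 2% for tumors a
few voxels across. HPS recovery on unblurred phantoms is exact to 1e-6
because the ROI split line sits in the gap between liver and lung; with
blur, a small fraction of counts crosses the split or leaves the grid, so
exactness claims are made only for the unblurred case.

`generate_cohort` draws true TgVs from a log-normal (meanlog log 900 ml,
sdlog 0.65, spanning roughly 180–2400 ml as in the fixture); each modality
observes truth through a multiplicative bias (CECT 0.65, CBCT 0.72, MAA
0.87, PET 1.0) and log-normal noise (sd 0.32 / 0.40 / 0.08 / 0.05). A
4/24 fraction of patients has a "changed administration": extra log-normal
discordance (sd 0.6) between the MAA and PET volumes. These levels were
calibrated by simulation so that at n = 24 the mean concordances sit at
the clinically observed levels (CCC ≈ 0.70 CECT, ≈ 0.73 CBCT, ≈ 0.86 MAA,
≈ 0.95 MAA after excluding changed administrations). The simulator does
not reproduce features of real cohorts such as inter-reader contouring
variability, anatomy-driven correlation between modality errors, or the
dependence of CBCT quality on contrast timing — so passing tests show the
statistical pipeline behaves correctly under the stated generative model,
not that any modality ranking would hold on new clinical data.

Tumor volumes in simulated cohorts are a uniform 10–50% of the smallest
modality TgV, guaranteeing every modality's normal compartment is
positive. TNR draws are truncated normal (2.6 ± 1.5, ≥ 0.8); HPS draws
truncated normal (0.069 ± 0.034 in [0, 0.2]).

## Agreement statistics

The CCC uses 1/n moment estimators by default (Lin's original
definition); `bias_corrected=True` switches to 1/(n−1). The default must
and does reproduce the published concordances on the fixture. The 95% CI
applies the Fisher z-transform with Lin's corrected asymptotic variance;
the CI method is a surrogate (the source is silent) and is not used as a
pass/fail quantity anywhere. R² comes from `scipy.stats.linregress`; the
approach comparison is the pooled-variance two-sample t-test
(`scipy.stats.ttest_ind`), significant at p < 0.05.

Degenerate inputs: CCC of two identical constant sequences raises
(undefined 0/0); identical non-constant sequences return CCC 1 with a
degenerate CI; constant x raises for R²; groups smaller than 2 raise for
the t-test. CBCT comparisons drop the patients without an evaluable CBCT
volume and record the dropped count (n = 19 of 24 on the fixture).

## Reproduction pipeline and known discrepancies

`reproduce_paper` classifies every reference value before computing
anything: medians and six of the seven subgroup CCCs are expected to
reproduce after rounding to the printed precision and are enforced (exit
code non-zero on mismatch). Two printed values are carried as documented
discrepancies rather than targets: the CECT selective-subgroup CCC
(printed 0.5; the packaged table yields 0.66 under both estimator
variants, while the CBCT and MAA values printed in the same sentence
reproduce exactly) and the regression R² values (the printed MAA 0.96
matches the selective-excluding-changed subset, R² = 0.957, not the full
cohort, R² = 0.80 — the regression subset is ambiguous). The per-patient
dose medians require TNR and tumor volumes that are not part of the
printed table; the pipeline recomputes that comparison from synthetic
draws and labels it as such.

## Problem sizes

Property tests run 1,000 random dosimetry inputs, 50 brute-force-checked
random maps, and 200 simulated cohorts of 24 patients; phantom grids are
24³–64³ voxels at 2–4 mm spacing. These sizes give Monte-Carlo error well
inside the asserted tolerances while keeping the default suite fast.
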
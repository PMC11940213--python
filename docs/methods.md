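# Methods

## Signal model

The forward model is the extended phase graph (EPG) for a CPMG multi-echo
spin-echo train: ideal 90° excitation about y, refocusing pulses about x
(CPMG condition) with flip `α = 180°·B1`, perfect crushing between pulses
(integer dephasing orders), and relaxation over each half echo-spacing with
T1 recovery toward unit equilibrium. States are truncated at order
`n_echoes + 1`, which is lossless within the train because higher orders
cannot refocus before it ends. B1 error is applied to the refocusing pulses
only — in CPMG the excitation error is second order for echo amplitudes,
the refocusing error first order. Defaults mirror the target acquisition:
10 echoes, ΔTE 15 ms, TR 4.8 s (informational; full recovery between shots
is assumed), voxels of 1.5 × 1.5 × 1.8 mm.

T1 is fixed at 1000 ms everywhere (simulator and fitter share the default)
because at TR = 4.8 s and a 150 ms train T1 has only a second-order effect
on echo amplitudes; it is configurable in both places.

The isochromat oracle simulates the same sequence by brute-force Bloch
rotations over a deterministic midpoint grid of dephasing angles spanning
one crusher cycle per half interval. Because the grid sums of `exp(ikφ)`
vanish exactly for orders below the spin count, the oracle agrees with the
EPG recursion to machine precision once `n_spins` exceeds the highest
populated order (~2 × echoes); the two implementations are nevertheless
developed independently and cross-checked to 1e-4 relative in the suite.

## T2 estimation

Three estimators share one configuration object:

- **loglinear** — weighted least squares of `log S` on TE with weights
  `∝ S²` (undoing log-transform heteroscedasticity). The first echo is
  dropped by default (standard practice for pure-exponential fits). Voxels
  with non-positive retained signal are unfittable; out-of-bound T2 is
  clipped and flagged rather than rejected so maps stay dense for VOI
  medians.
- **nlls** — bounded least squares of `S0·exp(−TE/T2)` initialised from the
  log-linear fit; non-convergence falls back to the initialiser with a flag.
- **epg_dict** (default) — exhaustive matching against unit-normalised EPG
  signatures on a T2 grid of 10–300 ms in 1 ms steps × B1 grid of
  0.50–1.20 in 0.01 steps (cached per echo-train). The match maximises the
  inner product with the normalised voxel signal, which is the least-squares
  solution after optimal scaling; `S0` is the scale at the optimum. Ties
  break deterministically toward the smallest T2, then smallest B1. The
  first echo is kept: the dictionary models the stimulated-echo
  contamination rather than discarding it.

Two numerical facts matter for interpretation. First, CPMG magnitudes are
invariant under `α → 360° − α`, so B1 values `b` and `2 − b` are exactly
degenerate in the dictionary; the tie-break resolves to the smaller value
and T2 is unaffected. Second, no Rician noise-floor correction is applied
by default (a documented extension point): at the simulated SNRs the
magnitude bias inflates late echoes slightly, which together with the 1 ms
grid bounds VOI-median recovery at roughly 0.2–1 ms rather than the
noiseless ≤0.1 ms.

Volume fitting excludes voxels whose first-echo signal is below 5% of the
volume maximum; unfitted voxels are flagged, never silently zero-filled.

## VOI analysis

The within-VOI T2 summary defaults to the median (the per-patient summary
convention of the motivating study's visualisations); the mean is available
by argument. Unfittable voxels are excluded from the T2 summary but still
counted in volume — segmentation defines volume, not fit success. Volume is
exactly voxel count × voxel volume; masks are voxel-label images with no
partial-volume weighting. Reader-specific samples are averaged per
(subject, visit, level, side) into a consensus — volumes are averaged
across reader-specific masks, mirroring the T2 averaging convention — and
subjects are summarised as the mean over their ganglion samples, overall
and per level. Summarising per subject before inference is what removes
the need for multiplicity adjustment downstream.

## Reliability

ICC(2,1): two-way random effects, absolute agreement, single measurement,
from the classical mean-squares decomposition, with the McGraw–Wong
F-based 95% CI (Satterthwaite degrees of freedom on the lower tail).
Single — not average — measures, because each reader contributes one
measurement per ganglion. Test–retest reliability treats the two visits as
raters over reader-averaged subject summaries. Interpretation follows the
Koo–Li bins, right-open at 0.5 / 0.75 / 0.9. A consistency variant
(ICC(3,1)) exists for diagnostics such as separating a constant between-visit
shift from true disagreement. Fewer than five targets yields a retained
warning; zero variance across both factors is a hard error.

## Cohort statistics

Normality screening uses the Lilliefors-corrected one-sample KS test
(parameters estimated from the sample make the plain KS anticonservative).
Mann–Whitney U uses exact enumeration when the pooled sample is ≤ 12 and
tie-free, otherwise the tie- and continuity-corrected normal approximation.
Wilcoxon signed-rank drops zero differences (logged), uses exhaustive
sign-flip enumeration for retained n ≤ 12 — well defined under tied
|differences|, where the tabulated null is not — and the continuity-
corrected approximation otherwise; all-zero differences return p = 1 with a
degenerate flag. Contingency tables use Fisher's exact test for 2×2 tables
with any expected cell < 5, else Pearson chi-squared without Yates
correction; the rule applied is recorded per row. Spearman's ρ is the
Pearson correlation of midranks with the t-approximation on n − 2 df.
Percentiles are linear-interpolation (type-7) throughout, and percent
differences are reported signed to one decimal. No multiple-testing
adjustment is applied, consistent with per-subject summarisation.

## Synthetic data

**Phantoms.** Four ellipsoidal ganglia on a 32 × 32 × 12 grid: L5 semi-axes
(5.9, 5.5, 6.6) mm ≈ 897 mm³ and S1 (6.7, 6.3, 7.5) mm ≈ 1326 mm³, i.e. the
S1/L5 volume ratio ≈ 1.46 with absolute scale near the in-vivo level
medians; default true T2 of 92.9 (L5) and 96.8 ms (S1). The B1 field is a
seeded smooth field (base 0.92, ±0.05 linear gradients, one Gaussian dip of
depth 0.05–0.15, clipped to [0.6, 1.1]). Noise is Rician — two independent
Gaussian channels of width `σ = max(PD)/SNR` added before the magnitude —
with SNR 50 by default; the PD = 0 noise floor `σ√(π/2)` is verified in the
suite. Reader variability is emulated by flipping boundary voxels of each
label at a configurable rate (default 5%) with 6-connectivity preserved.

**Cohorts.** 80 subjects split 18/54/8 (classical/nonclassical/VUS) with
the observed sex composition, 4 ganglia × 2 readers per subject-visit and a
16-subject retest arm (384 ganglion samples per reader in total). Subject
T2 means sit at 102.4 ms (classical) and 93.6 ms (nonclassical; VUS shares
the nonclassical distribution since no separate VUS value is established),
with between-subject SD 12 ms (from the cohort IQR), per-ganglion SD 7 ms,
visit SD 6 ms and reader SD 8 ms — chosen so the closed-form inter-rater
and test–retest ICCs land near the reported 0.76 / 0.89. The S1/L5 T2
ratio 1.042 is applied symmetrically so the four-ganglion mean stays at the
subject mean. Volumes scale from a female L5 base of 766 mm³ by the level
ratio 1.462 and sex ratio 1.359 with lognormal subject size (SD 0.28).
Anthropometrics and age are sex-specific normals, enzyme activity and
lyso-Gb3 sex/group-calibrated lognormals — calibrated to median/IQR
summaries, not fitted. The BMI–T2 coupling is a shared latent factor with
Pearson weight `2·sin(πρ_s/6)` (bivariate-normal inversion) targeting a
rank correlation of −0.32 in expectation.

**What the generators do not emulate.** Ellipsoids with hard tissue edges,
not anatomy: a misdrawn boundary voxel is pure background (T2 60 ms),
whereas in vivo it is part ganglion, so reader perturbation perturbs
phantom VOI medians more sharply than real segmentations would — the
ground-truth-mask recovery checks therefore probe the fit/extraction chain
separately from the segmentation emulator. No k-space sampling, partial
volume, motion, fat suppression or B0 effects; no slice profile; no
longitudinal disease progression in the retest arm. Passing tests
demonstrate correctness of the algorithms under the stated generative
model, not in-vivo validity.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; the pipeline driver fans a
global seed out to stage seeds via `SeedSequence.spawn`, and identical
config + seed reproduces byte-identical artefact checksums. The suite and
the acceptance script use deliberately scaled problem sizes — 4 phantom
subjects at 32 × 32 × 12, 500-voxel bias Monte-Carlos, 2000 null
simulations for test calibration, 500 for CI coverage, 50 replicate
cohorts — sizes at which the Monte-Carlo error is already far below the
assertion tolerances.

## Known limitations

The dictionary's 1 ms / 0.01 grid bounds precision; B1 is identified only
up to the `2 − b` reflection; Rician bias is uncorrected by default; the
exact-test enumeration threshold (n ≤ 12) is a convention, not a claim of
optimality; and the cohort generator reproduces marginal structure and one
targeted correlation, not the full joint distribution of a real cohort.
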
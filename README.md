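# drg-t2map

Quantitative T2 mapping of the lumbosacral dorsal root ganglia (DRG), built
for studies that use DRG-T2 as an imaging biomarker of peripheral-nervous-
system involvement — the motivating application is Fabry disease, where
glycosphingolipid accumulation in DRG neurons raises the T2 relaxation time
of classical-mutation patients relative to nonclassical ones.

The package covers the full analysis chain:

1. **Forward model** — extended-phase-graph (EPG) simulation of CPMG
   multi-echo spin-echo trains (10 echoes, ΔTE = 15 ms, TR = 4.8 s) under
   imperfect refocusing flips `α = 180°·B1`, with a brute-force isochromat
   (Bloch) oracle for validation.
2. **Voxelwise T2 estimation** — weighted log-linear and bounded nonlinear
   mono-exponential fits, and the default **B1-corrected EPG dictionary
   match**: unit-normalised signatures over a (T2, B1) grid, each voxel
   assigned `argmax_(T2,B1) ⟨ŝ, d̂(T2,B1)⟩`.
3. **VOI analysis** — per-ganglion median T2 under a label mask, volume as
   voxel count × voxel volume, two-reader consensus averaging, per-subject
   means over the four ganglia (bilateral L5 + S1).
4. **Reliability** — ICC(2,1) (two-way random effects, absolute agreement,
   single measurement) with McGraw–Wong F-based 95% CI and Koo–Li bins,
   for inter-rater and test–retest designs.
5. **Cohort statistics** — Lilliefors-corrected Kolmogorov–Smirnov
   screening, Mann–Whitney U, Wilcoxon signed-rank, chi-squared / Fisher's
   exact, Spearman ρ, median (IQR) tables and signed percent differences.
6. **Synthetic data** — digital DRG phantoms with known voxelwise ground
   truth, and table-level synthetic cohorts (80 subjects, 18/54/8 mutation
   split, two readers, 16-subject retest arm) calibrated to the published
   group structure, so every stage is testable without patient data.

## The measurement model

A CPMG train excites magnetization with a 90° pulse and refocuses it with
nominal 180° pulses. With transmit inhomogeneity the actual refocusing flip
is `α = 180°·B1(x)` and the echo amplitudes are no longer
`S0·exp(−TE/T2)`: stimulated-echo pathways shelve magnetization along z and
return it later, flattening the apparent decay and biasing naive fits
upward. The EPG recursion tracks configuration states `(F⁺_k, F⁻_k, Z_k)`
over integer dephasing orders k through relaxation, crusher dephasing and
RF mixing, yielding exact echo amplitudes for any (T2, T1, B1). The
dictionary fit inverts this model per voxel, estimating T2 and B1 jointly.

## Worked example

`python examples/02_phantom_to_t2_map.py` simulates a four-ganglion phantom
at SNR 50 with a smooth B1 field, fits the EPG dictionary and extracts the
per-ganglion measurements:

```
  ganglion  true T2   VOI T2   true vol        vol
   L5-left     92.9     93.0      907.2      907.2
  L5-right     92.9     93.0      907.2      907.2
   S1-left     96.8     97.0     1296.0     1296.0
  S1-right     96.8     97.0     1296.0     1296.0
```

Each VOI median lands within one 1-ms dictionary step of the true T2
despite the unknown B1 field, and volumes are exact. The other examples
print the EPG signal tables, the ICC reliability analysis (inter-rater 0.81,
test–retest 0.94 on one simulated cohort) and the cohort statistics battery
(S1 > L5 gradient, male > female volumes, negative BMI–T2 correlation).

A thin CLI wraps the same stages:

```bash
drg-t2map simulate-phantom --out ph --seed 3
drg-t2map fit-t2 --in ph/multiecho.nii.gz --method epg_dict --out fit
drg-t2map extract-voi --map fit/t2map.nii.gz --mask ph/mask.nii.gz --out voi.csv
drg-t2map run-all --out results --seed 0
```

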
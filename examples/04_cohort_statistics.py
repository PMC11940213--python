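"""Cohort statistics on a simulated 80-patient Fabry cohort.

Runs the nonparametric battery on subject-level summaries: the classical vs
nonclassical T2 contrast, the paired S1 vs L5 gradient, sex differences in
volume, and rank correlations with anthropometrics.
"""

import numpy as np

from drg_t2map import (
    CohortSpec,
    average_readers,
    generate_cohort,
    mann_whitney_u,
    percent_difference,
    spearman_rho,
    summarise_subjects,
    wilcoxon_signed_rank,
)

subs, samples, _ = generate_cohort(CohortSpec(seed=12))
base = summarise_subjects(average_readers(samples)).merge(subs, on="subject_id")

c = base[base.mutation_class == "classical"].drg_t2_ms
nc = base[base.mutation_class == "nonclassical"].drg_t2_ms
res = mann_whitney_u(c, nc)
print(f"classical vs nonclassical DRG-T2: {c.median():.1f} vs {nc.median():.1f} ms "
      f"({percent_difference(c.median(), nc.median()):+.1f}%), "
      f"Mann-Whitney p = {res.p_value:.3f}")

s1, l5 = base.drg_t2_s1_ms.to_numpy(), base.drg_t2_l5_ms.to_numpy()
res = wilcoxon_signed_rank(s1, l5)
print(f"S1 vs L5 DRG-T2 (paired):         {np.median(s1):.1f} vs {np.median(l5):.1f} ms "
      f"({percent_difference(np.median(s1), np.median(l5)):+.1f}%), "
      f"Wilcoxon p = {res.p_value:.3f}")

m = base[base.sex == "male"].drg_vol_mm3
f = base[base.sex == "female"].drg_vol_mm3
res = mann_whitney_u(m, f)
print(f"male vs female DRG volume:        {m.median():.0f} vs {f.median():.0f} mm3 "
      f"({percent_difference(m.median(), f.median()):+.1f}%), p = {res.p_value:.4f}")

rho = spearman_rho(base.bmi_kg_m2, base.drg_t2_ms)
print(f"BMI vs DRG-T2:                    Spearman rho = {rho.statistic:.2f}, "
      f"p = {rho.p_value:.3f}")

print(
    "\nThe simulated cohort reproduces the study conditions it is calibrated"
    "\nto: higher T2 in classical mutations, an S1 > L5 gradient, larger male"
    "\nvolumes, and a negative BMI-T2 rank correlation."
)
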
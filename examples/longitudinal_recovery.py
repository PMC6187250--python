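"""Recover the reaction order from a synthetic longitudinal cohort.

Generates 50 subjects with 6 biennial visits, 5% log-normal measurement
noise, and subject-level onset shifts; fits the log-linear model
ln(d[BP2]/dt) = ln k' + x ln[BP1] per subject, then pools with a
DerSimonian-Laird random-effects model.
"""

import numpy as np

import rre

design = rre.longitudinal_benchmark_design(x=1.0, kprime=0.05, seed=42)
table = rre.generate_longitudinal(design)
fits = rre.fit_cohort(table)
group = rre.pool_random_effects(fits)

ok = [f for f in fits if f.ok]
print(f"fitted {len(ok)}/{len(fits)} subject series "
      f"(median per-subject r2 = {np.median([f.r2 for f in ok]):.2f})")
print(f"pooled reaction order x_hat = {group.x_hat:.3f} "
      f"+/- {group.x_se:.3f}   (truth 1.0)")
print(f"pooled ln k'          = {group.ln_kprime_hat:.3f} "
      f"  (truth {np.log(0.05):.3f})")
print(f"between-subject tau^2 = {group.tau2:.3f}; "
      f"p(x=0) = {group.p_value:.2e}")
print("-> the pooled estimates recover the generating kinetics; individual")
print("   subject fits are noisy (4 usable points each), which the")
print("   random-effects pooling absorbs into tau^2")
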
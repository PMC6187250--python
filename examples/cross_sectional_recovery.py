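"""Estimate the reaction order from a single-visit (cross-sectional) cohort.

When no follow-up exists, d[BP2]/dt is approximated by the covariate-adjusted
slope of BP2 against a disease-severity score tau, per region; regressing the
log slopes on the log baseline [BP1] across regions recovers the reaction
order for the whole brain.
"""

import rre

design = rre.cross_sectional_benchmark_design(n_subjects=200, seed=42)
table = rre.generate_cross_sectional(design)
slopes = rre.fit_region_slopes(table)
wb = rre.fit_whole_brain(slopes, seed=42)

print(f"{'region':>7} {'dBP2/dtau':>10} {'se':>8} {'baseline BP1':>13}")
for s in slopes:
    print(f"{s.region:>7} {s.slope_bp2:10.4f} {s.se_slope:8.4f} "
          f"{s.baseline_bp1:13.3f}")
print(f"\nwhole-brain fit over {wb.n_regions} regions:")
print(f"  x_hat = {wb.x_hat:.3f} +/- {wb.se_x:.3f}  (truth 1.0)")
print(f"  r2 = {wb.r2:.2f};  p = {wb.p_value:.3f};  "
      f"sign-flip permutation p = {wb.p_value_perm:.3f}")
print("-> region rate-constant heterogeneity leaves scatter around the")
print("   log-log line, but the across-region slope recovers x")
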
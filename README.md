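# rre — reaction-rate-equation modeling of biomarker cascades

In neurodegenerative disease, several pathologies (beta-amyloid, misfolded
tau, neuroinflammation, atrophy) coexist, and whether one is upstream or
downstream of another is hard to observe directly: the cascade unfolds over
decades while imaging studies follow patients for a few years.  `rre`
implements a chemical-kinetics approach to this ordering problem for
researchers working with multi-tracer PET / multimodal MRI panels.  Two
regional biomarkers are treated as species in a reaction

    a BP1 + Σ b_i B_i → m BP2 + Σ n_j C_j,      d[BP2]/dt = k [BP1]^x Π [B_i]^{y_i}

whose rate law, after the pseudo-first-order reduction valid when the
unobserved reactants are in excess ([B_i]_0 ≫ [BP1]_0), becomes log-linear:

    ln(d[BP2]/dt) = ln k′ + x ln[BP1]

If BP1 truly drives BP2, past levels of BP1 predict the dynamics of BP2 and
this line fits well; the opposite ordering fits a different, equally complex
model, so the direction can be decided by goodness of fit alone.  The package
provides:

- exact simulation of the full (bath-depleting) and reduced kinetic systems;
- per-subject estimation of (x, ln k′) from longitudinal panels with
  DerSimonian–Laird random-effects pooling per brain region;
- a cross-sectional pipeline for single-visit cohorts: covariate-adjusted
  severity slopes per region, then a whole-brain log-log fit across regions;
- directional model comparison with a dead band and bootstrap gate, so noise
  yields "indeterminate" rather than a coin-flip call;
- a fully seeded synthetic-cohort generator so every stage is testable
  without patient data, plus a thin `rre` command-line interface.

## Worked example

```python
import rre

design = rre.longitudinal_benchmark_design(x=1.0, kprime=0.05, seed=42)
table  = rre.generate_longitudinal(design)      # 50 subjects, 6 biennial visits
fits   = rre.fit_cohort(table)                  # per-subject log-linear fits
group  = rre.pool_random_effects(fits)          # random-effects pooling
print(group.x_hat, group.ln_kprime_hat)

report = rre.compare_directions(table, seed=42) # which biomarker is upstream?
print(report.selected, report.margin)
```

Running `python examples/longitudinal_recovery.py` prints:

```
fitted 50/50 subject series (median per-subject r2 = 0.43)
pooled reaction order x_hat = 0.994 +/- 0.085   (truth 1.0)
pooled ln k'          = -3.009   (truth -2.996)
between-subject tau^2 = 0.076; p(x=0) = 7.18e-32
```

The pooled slope recovers the generating reaction order x = 1 and intercept
ln k′ = ln 0.05; τ² absorbs the (large) scatter of individual 4-point fits.
`examples/direction_selection.py` shows the directional comparison on the
same cohort — r²(BP1→BP2) = 0.221 vs r²(BP2→BP1) = 0.099, selected
`forward` — and an indeterminate verdict on a flat-plus-noise cohort.  The
other examples cover trajectory simulation against the pseudo-first-order
reduction and cross-sectional whole-brain recovery.

The same operations are available from a shell:

```sh
rre simulate --mode longitudinal --out cohort/ --seed 7
rre fit-long --measurements cohort/measurements.csv --out fits.txt
rre compare  --measurements cohort/measurements.csv --mode longitudinal \
    --seed 7 --out compare.txt
rre validate --seed 7
```

All outputs are delimited text with the package version and seed in a header
comment; identical config + seed reproduce byte-identical files.

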
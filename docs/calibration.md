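# Propensity-convention calibration report

Generated by `scripts/calibrate_conventions.py` (25 reps per ensemble; regenerate with that script).  Each convention is simulated at every reference condition's printed (C1, C2, N) and compared with the reported model values.

| convention     |   mean_k_abs_err |   max_k_abs_err |   rows_k_within_006 |   mean_g_rel_err |   rows_g_within_40pct |
|:---------------|-----------------:|----------------:|--------------------:|-----------------:|----------------------:|
| squared        |           0.1461 |          0.6712 |                   8 |           0.3008 |                    12 |
| pairwise       |           0.189  |          0.702  |                   5 |           0.4008 |                    12 |
| triple-fission |           0.2135 |          0.705  |                   3 |           0.5838 |                     4 |

**Best-ranked convention: `squared`** (shipped default).

## Discrepancy analysis

No convention reproduces the reported values across all conditions, and the deviations are not statistical: the reference mean-degree/fraction table pairs are mutually inconsistent (the reported HD species fractions imply <k> = 1.72 where the same table prints 1.67), and the small-N conditions are irreconcilable under *any* mass-action convention -- at N = 103 with C1 ~ 5e-4 every convention yields <k> <= 1.08 against a reported 1.75, because count-based fusion propensities scale down with N while the reported values do not.  The effective couplings implied by the reported fractions exceed every convention's by condition-dependent factors of 3-100.  The per-row table in `results/calibration.csv` documents this per convention; the default convention is the closest, not a perfect, match.
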
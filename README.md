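# glycovar

Analysis pipeline for candidate-SNP association studies of continuous
glucose monitoring (CGM) data: per-participant glycemia and
glycemic-variability statistics, covariate-adjusted genotype-group
comparison with family-cluster-robust inference and Monte Carlo permutation
p-values, and mediation of the genotype effect by body composition. A
synthetic-cohort generator with known ground truth lets every stage be
validated end to end.

The motivating setting is the rs7903146 polymorphism in *TCF7L2* — the T
allele raises type 2 diabetes risk — studied against interstitial glucose
sampled every 5 minutes for 5 days in middle-aged participants without
diabetes, many of them sibling pairs. Carriers are analysed as CC vs CT/TT.

## What is computed

For each participant, from the 72-h analysis span (the first and last
recording days are discarded as least accurate):

**Glycemia** — window means of glucose (mmol/L), pooled across days:
mean 24-h; mean nocturnal, clock window [3:00, 6:00); mean diurnal,
[6:00, 24:00).

**Glycemic variability**

- 24-h SD: sample SD (n−1) over the trimmed record.
- CONGA-4: for each observation with a valid partner 4 h earlier, take
  d(t) = y(t) − y(t − 4h); CONGA is SD(d). Intraday variability.
- MODD: mean of |y_{day k+1}(slot) − y_{day k}(slot)| over all grid slots
  valid on both of two consecutive days, pooled over day pairs. Interday
  variability.
- Range: max − min.

**Association** — for outcome y, group indicator g (CT/TT = 1) and
covariates x (age, sex, offspring/partner status):

    y_i = α + β g_i + γᵀx_i + ε_i

fitted by OLS with the cluster-robust sandwich variance grouped by family,
small-sample factor [G/(G−1)]·[(N−1)/(N−k)] and a t(G−1) reference
(G families, N participants, k parameters). Adjusted group means are the
fit evaluated at covariate means; right-skewed outcomes are analysed on the
log scale and back-transformed to geometric means. Each model p-value is
paired with a permutation p-value: family label-vectors are shuffled across
clusters of equal size, the model refitted, and
p = (1 + #{|β*| ≥ |β|}) / (n_perm + 1).

**Mediation** — percent of effect explained:
100·(β_unadjusted − β_adjusted)/β_unadjusted, where β_adjusted comes from
adding the mediators (body weight, percent body fat) to the model on the
same complete-case rows, after checking for group × mediator interaction.
A Hardy–Weinberg equilibrium chi-square test (1 df) checks the genotype
distribution.

## Worked example

Simulate a cohort at the study's scale (235 participants, sibling-pair
clusters; ground-truth nocturnal contrast 0.19 mmol/L, ~35% of it mediated
by body composition) and run the full pipeline:

```python
import pandas as pd
from glycovar import CohortConfig, PipelineConfig, run_pipeline

sim = CohortConfig(n_participants=235, sibling_fraction=1.0, seed=21)
cfg = PipelineConfig(simulation=sim, n_perm=1000, seed=21, out_dir="demo_out")
manifest = run_pipeline(cfg)
print("HWE p-value:", round(manifest["hwe_p"], 3))
out = pd.read_csv("demo_out/outcomes_table.csv")
cols = ["outcome", "mean_cc", "mean_ctt", "beta", "se_robust", "p_model", "p_permutation"]
print(out[cols].round(3).to_string(index=False))
med = pd.read_csv("demo_out/mediation.csv").iloc[0]
print(f"mediation: beta_unadjusted={med.beta_unadjusted:.3f} "
      f"beta_adjusted={med.beta_adjusted:.3f} percent_mediated={med.percent_mediated:.1f}%")
```

prints

```
HWE p-value: 0.519
        outcome  mean_cc  mean_ctt   beta  se_robust  p_model  p_permutation
fasting_glucose    5.160     5.186  0.026      0.063    0.678          0.675
fasting_insulin    2.199     2.393  0.085      0.064    0.187          0.180
       mean_24h    5.239     5.288  0.049      0.079    0.537          0.543
 mean_nocturnal    4.493     4.648  0.154      0.077    0.047          0.067
   mean_diurnal    5.476     5.497  0.021      0.080    0.796          0.794
         sd_24h    0.762     0.732 -0.030      0.004    0.000          0.001
         conga4    0.998     0.971 -0.028      0.006    0.000          0.001
           modd    0.512     0.511 -0.001      0.004    0.860          0.874
          range    4.184     4.094 -0.090      0.042    0.034          0.026
mediation: beta_unadjusted=0.154 beta_adjusted=0.041 percent_mediated=73.7%
```

Reading this: the CT/TT group's adjusted nocturnal glucose is 4.65 vs
4.49 mmol/L for CC (β = 0.154 mmol/L, model p = 0.047), while the 24-h and
diurnal means differ much less — the generator's genotype effect is
concentrated at night, and the analysis recovers that. `fasting_insulin` is
analysed on the log scale, so its "means" are geometric means and its β is
a log-scale contrast. At n = 235 a single replicate is noisy: the true
contrast behind this draw is 0.19 mmol/L, the robust SE is ~0.08, and the
percent-mediated estimate (73.7% here, truth 35%) is only stable in much
larger cohorts — the replicate-averaged behaviour is what the test suite
checks. The same run is available from the shell:

```sh
glycovar all --seed 21 --n-perm 1000 --out demo_out
```

Subcommands `simulate`, `metrics`, `associate`, `report` run the stages
separately on CSV inputs (`glycovar <cmd> --help`).

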
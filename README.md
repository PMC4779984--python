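# cqplan

Stage-wise technical-noise decomposition and replicate planning for
RT-qPCR experiments.

Every RT-qPCR measurement passes through three preparative stages —
tissue sampling / RNA extraction, reverse transcription (RT), and the
qPCR reaction itself — and each stage injects its own technical noise
into the observed quantification cycle (Cq). Because clusters of
replicates integrate all upstream noise, a *nested* pilot experiment
(each extraction split into several RTs, each RT into several qPCR
wells) lets those contributions be separated. `cqplan` estimates them,
and then answers the practical question: **given per-step costs and a
budget, how should replicates be allocated across the stages to make a
group-mean Cq as precise as possible?**

## Model

Within one stratum (one subject, tissue and gene) each reading is

```
Cq_ijk = μ + a_i + b_j(i) + c_k(ij)
```

with independent Gaussian effects `a_i ~ N(0, σ_i²)` per RNA
extraction, `b_j(i) ~ N(0, σ_j²)` per RT within extraction, and
`c_k(ij) ~ N(0, σ_k²)` per qPCR well within RT. The total technical
variance of a single reading is `σ_Cq² = σ_i² + σ_j² + σ_k²`.
Components are estimated by method-of-moments nested ANOVA (Type-I
nested sums of squares with unbalanced expected-mean-square
coefficients recomputed from the realized group sizes, so missing wells
are handled by complete-case analysis).

A balanced plan with `n_s` subjects per condition, `n_i` extractions
per subject, `n_j` RTs per extraction and `n_k` wells per RT has an
expected group-mean variance of

```
σ_Cqg² = [ v_i/n_i + v_j/(n_i n_j) + v_k/(n_i n_j n_k) ] / n_s
```

(`v` are the variance-scale step components). The optimizer enumerates
every balanced integer plan within the budget and returns the one
minimizing `σ_Cqg²`.

## Worked example

Simulate the bundled blueberry pilot layout (2 plants × 3 tissues ×
3 genes, each stratum 4 extractions × 4 RTs × 3 wells = 864 reactions),
decompose the noise, and ask for the budget-optimal plan:

```python
from cqplan import (NestedCqModel, StepNoise, CostModel,
                    OptimizationConstraints, optimize_plan,
                    pilot_study_specs, simulate_study)

ds = simulate_study(pilot_study_specs(), seed=11)
res = NestedCqModel(ds).fit()
print(res.mean_over_subjects().round(2).to_string(index=False))
```

```
tissue gene  mean_cq  sd_sampling  sd_rt  sd_qpcr  total_sd_combined  pooled_sd
fruits F35H    18.16         0.17   0.28     0.34               0.50       0.48
fruits  KAT    20.73         0.48   0.27     0.30               0.63       0.58
fruits  VRN    25.39         0.31   0.33     0.28               0.55       0.53
leaves F35H    30.94         0.10   0.55     0.50               0.79       0.78
leaves  KAT    22.82         0.06   0.26     0.17               0.32       0.31
leaves  VRN    25.10         0.64   0.54     0.35               0.90       0.84
 stems F35H    30.89         0.00   0.42     0.50               0.65       0.64
 stems  KAT    22.14         0.46   0.34     0.24               0.63       0.59
 stems  VRN    23.33         0.67   0.60     0.34               1.00       0.93
```

Each row averages the two plants' per-stratum estimates: the mean Cq,
the three step SDs in cycles, their quadrature combination
(`total_sd_combined`), and the empirical SD of all Cq readings in the
stratum (`pooled_sd`). Here RT noise dominates in leaves while
sampling/extraction noise dominates in stems — so extra RT replicates
pay off for leaves, extra extractions for stems.

Planning: suppose fruit-like step noise (0.42, 0.31, 0.30 on the
variance scale), per-unit costs of 50 per plant, 10 per extraction, 3
per RT and 1 per qPCR, three conditions, and a total budget of 1000:

```python
best = optimize_plan(
    StepNoise.from_values(0.42, 0.31, 0.30, scale="variance"),
    CostModel(subject=50, sampling=10, rt=3, qpcr=1),
    OptimizationConstraints(budget=1000, n_conditions=3, min_subjects=3))
print(best.as_dict())
```

```
{'n_subjects': 3, 'n_sampling': 4, 'n_rt': 1, 'n_qpcr': 2,
 'total_replicates': 24, 'group_variance': 0.07333333333333333,
 'total_cost': 990, 'reactions_per_condition': 24}
```

Read: sample each of 3 plants 4 times, run 1 RT per RNA and 2 qPCR per
cDNA — 24 reactions per condition, 990 of the 1000 units spent, and an
expected group-mean variance of 0.07 (vs. 0.28 for the naive
3-plants × 1 × 1 × 3-wells design at little more than half the cost).

The same pipeline is available from the shell:

```sh
cqplan simulate --preset blueberry-pilot --seed 11 -o cq.csv
cqplan decompose -i cq.csv -o components.json
cqplan optimize --config budget.yaml -o best.json --frontier frontier.csv
```

Note on scales: published step-noise tables are sometimes used in the
planning arithmetic directly as variance-scale values even when labeled
SDs. `StepNoise.from_values(..., scale=...)` forces you to declare the
input scale and records the declaration in every report.

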
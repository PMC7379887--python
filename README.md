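# rnakinetics

Gene-level modeling of the RNA life cycle: synthesis of premature RNA, its
processing into the mature form, and degradation of the latter, each
governed by a kinetic rate that may change over time.

The package is for researchers studying transcriptional and
post-transcriptional regulation from time-course expression data — for
example nascent-RNA (metabolic labeling) experiments quantifying premature
RNA, mature RNA, and the synthesis rate after a perturbation. It answers
questions such as: *which* of the three rates a cell modulated to produce
an observed expression change, how confident that call is, and what any
hypothetical combination of rate changes would do to the RNA species.

## Model

The abundances of premature (P) and mature (M) RNA obey

```
dP/dt = k1(t) − k2(t)·P
dM/dt = k2(t)·P − k3(t)·M
```

with k1 the synthesis rate (RNA units·h⁻¹), k2 the processing rate (h⁻¹)
and k3 the degradation rate (h⁻¹). With all rates constant the system sits
at the steady state

```
P = k1/k2        M = k1/k3
```

Each rate is parameterized as **constant** (level h0), **sigmoid**
(levels h0→h1, transition time t1, slope β) or **impulse** (a
product of two sigmoids with a second transition to h2 at t2, allowing
bell-shaped responses):

```
sigmoid:  f(t) = h0 + (h1−h0)·σ(β(t−t1)),        σ(x) = 1/(1+e^(−x))
impulse:  f(t) = (1/h1)·[h0 + (h1−h0)·σ(β(t−t1))]·[h2 + (h1−h2)·σ(−β(t−t2))]
```

A **regulatory class** assigns a form to each rate and is written with the
field's short codes: `"sd"` = variable synthesis and degradation, constant
processing; `"sp"` = variable synthesis and processing, constant
degradation; `"no-reg"` = all constant. Fitting minimizes the weighted
least-squares objective

```
χ² = Σ_species Σ_t (prediction(t) − mean(t))² / (sd(t)²/n_replicates)
```

which is a chi-squared statistic under Gaussian replicate error; goodness
of fit is reported as a **two-tailed** chi-squared p-value (suspiciously
good fits are flagged too) and classes are compared by **AIC = χ² + 2k**.
Parameter uncertainty comes from profile likelihood (95% by default).

## Worked example

`examples/02_simulate_fit_roundtrip.py` simulates a gene whose synthesis
rate triples (sigmoid 2→6 units/h at t=4 h), with constant processing
(1/h) and degradation (0.5/h), as a 12-point, 3-replicate nascent-RNA time
course at 5% noise — then fits the true class `"s"` back:

```
chi2 = 23.27 on dof = 30
two-tailed p = 0.392, AIC = 35.3, converged = True

parameter   truth   estimate
k1.h0        2.00     2.064
k1.h1        6.00     5.977
k1.t1        4.00     3.924
k1.beta      1.00     1.160
k2.h0        1.00     1.011
k3.h0        0.50     0.503
```

χ² ≈ dof (p well inside (0,1)) says the model explains the data at the
stated replicate noise, and every rate parameter is recovered within a few
percent. The other examples cover trajectories and steady states (`01`),
AIC ranking of all eight regulatory classes (`03`), and profile-likelihood
intervals (`04`). A thin CLI wraps the same functionality:

```
rnakinetics simulate --class sd --seed 7 --cv 0.1 --replicates 3 --out demo
rnakinetics fit --profile demo.profile.tsv --class sd --seed 1 --out fit.json
rnakinetics select --profile demo.profile.tsv --classes no-reg,s,sd,sp --seed 1 --out sel.json
```

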
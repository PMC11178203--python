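# pstopt — flexible p-value significance thresholds for two-arm trials

The conventional significance threshold p < 0.05 is arbitrary, and proposals
to lower it to a different fixed value (0.005, 0.01) trade false positives
for false negatives without any principle for where to stop. `pstopt`
implements the alternative: choose, **per study design**, the two-tailed
Student's *t* cut-off that minimizes a weighted sum of the two error
probabilities, and report the corresponding p-value threshold. It is aimed
at biostatisticians and meta-researchers who want to design trials with a
defensible threshold, or to re-interpret published corpora of randomized
clinical trial (RCT) results under such flexible thresholds.

## The model

For a two-arm trial analysed with a two-tailed two-sample Student's *t* test
(ν = n₁ + n₂ − 2 degrees of freedom), a cut-off *t* on the statistic fixes

- the type-I error α(t) = 2 F(−t, ν), and
- the type-II error β(t) = F(t − δ, ν) − F(−t − δ, ν),

where *F* is the central *t* CDF and δ is the minimum acceptable effect size
re-expressed on the *t* scale: δ = d·s₁ / se_Δ with the pooled SD behind
se_Δ, collapsing to δ = d / √(1/n₁ + 1/n₂) under equal group variances
(*d* is Cohen's d). The alternative is modelled as the central *t* shifted
by δ. The **optimal threshold** minimizes the weighted error cost

    ε(t) = C·pr·β(t) + (1 − pr)·α(t)

where *pr* is the prior probability that a true effect exists and *C* is
the seriousness of a type-II relative to a type-I error (the customary
α ≤ 0.05 / power ≥ 0.8 tolerances imply C = 0.25). The p-value threshold is
α at the minimizing cut-off. The **constrained** variant additionally
requires α ≤ 0.05 and power ≥ 0.8 at the optimum; designs whose optimum
violates either bound are reported as infeasible.

The package also ships a corpus pipeline (`reinterpret`) that re-classifies
a per-trial effect/standard-error table under fixed (0.05, 0.005) and
per-trial flexible thresholds, with Cohen's κ agreement and threshold/power
distributions, and a synthetic-corpus generator (`simulate`) producing
trials with known ground truth for calibration.

## Worked example

A trial with 100 and 70 participants per arm, targeting a medium effect
(d = 0.5), equal variances, prior odds 1 and C = 0.25:

```sh
$ pstopt optimize --n1 100 --n2 70 --d 0.5 --prior-odds 1 --c-weight 0.25
n1=100  n2=70  nu=168  d=0.5  pr=0.5  C=0.25
t_opt      2.2600
threshold  0.0251065
alpha      0.0251065
power      0.8279
cost       0.0340694
```

The cost-minimizing cut-off is t = 2.26, i.e. results of this trial should
be called significant below p ≈ 0.025, with 83% power at that cut-off — a
laxer threshold than 0.005 and stricter than 0.05, both of which carry a
higher weighted error (0.005 higher than 0.05). If the arm SDs differ the
optimum moves: with s₂/s₁ = 0.5 the same trial gives t = 2.48, threshold
0.014, power 92%.

The same API is available in Python:

```python
from pstopt import StudyDesign, optimize_threshold

res = optimize_threshold(StudyDesign(n1=100, n2=70, d=0.5, pr=0.5, C=0.25))
res.t_opt, res.pst_opt, res.power   # (2.2600, 0.02511, 0.8279)
```

`pstopt table` prints the grid of −log₁₀ constrained thresholds over
arm-size combinations (NA where no acceptable design exists), and a full
synthetic round trip is:

```sh
pstopt simulate --n-trials 1000 --seed 7 --out corpus.csv
pstopt reinterpret --input corpus.csv --out-dir results/
```

which writes per-trial significance calls under all four criteria, a
rejects report and a JSON summary (rates, κ, threshold and power
distributions).

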
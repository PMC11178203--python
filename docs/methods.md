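# Methods

## Model and assumptions

The package treats statistical inference with a two-tailed two-sample
Student's *t* test as a binary decision problem. Under the null the test
statistic follows the central *t* distribution with ν = n₁ + n₂ − 2 degrees
of freedom; under the alternative it follows the *same central distribution
shifted by δ*, the minimum acceptable effect size on the *t* scale. This
shifted-central-*t* alternative is deliberately used instead of the
noncentral *t* power formula: the error probabilities

    α(t) = 2 F(−t, ν)
    β(t) = F(t − δ, ν) − F(−t − δ, ν)

are then exact differences of central CDF values, and the worked-example
numbers the package reproduces (t = 2.26, threshold 0.025, power 83% for
the 100-vs-70 design) are defined under this model. For moderate ν the two
formulations differ by more than rounding, so they must not be mixed.

The effect rescaling is δ = d·s₁/se_Δ, where se_Δ = √(s²(1/n₁ + 1/n₂)) and
s² is the dof-weighted pooled variance. Cohen's d is expressed in units of
the **arm-1** standard deviation, so with unequal SDs swapping the arms
legitimately changes δ (and the optimum); only the ratio s₂/s₁ matters
(`effect_to_delta` is scale-invariant in (s₁, s₂)). When no SDs are given,
equal variances are assumed and δ = d/√(1/n₁ + 1/n₂). Degrees of freedom
are always n₁ + n₂ − 2; Welch corrections are out of scope. Cut-offs are
restricted to t ≥ 0 (symmetric two-tailed rejection region).

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `d` | minimum acceptable standardized effect (unitless) | 0.5 | medium effect; corpora assume 0.5 when total n ≥ 100, else 0.8 (small underpowered trials are only ethical for large targets) |
| `pr` | prior probability of a true effect | 0.5 | prior odds 1, the neutral reference value used throughout |
| `C` | seriousness of type-II vs type-I error | 0.25 | implied by the customary tolerances α ≤ 0.05, β ≤ 0.2 |
| `alpha_max`, `power_min` | constraint bounds | 0.05, 0.8 | the conventional acceptability limits |

## Optimization

ε(t) = C·pr·β(t) + (1−pr)·α(t) is smooth and, in the practically relevant
range, unimodal, but becomes extremely flat for large δ. The minimizer uses
a vectorized 4001-point pre-scan over t ∈ [0, max(12, δ+8)] to bracket the
minimum, then bounded scalar minimization (Brent) on the bracketing
interval with `xatol = 1e-8`. The pre-scan makes the result independent of
starting points; the optimizer is verified in tests against a 200,001-point
grid argmin on randomized designs. CDF evaluations use `scipy.special.stdtr`
(double precision, ≲1e-14 in the central region; cross-checked against
quadrature of the *t* density at 1e-8).

Degenerate weightings are flagged rather than silently optimized: with
`C·pr = 0` and `pr < 1` the cost is proportional to α alone and the
"optimum" is t → ∞ (threshold → 0); with `pr = 1` it is proportional to β
and the optimum is t = 0 (threshold 1). For extremely large δ (arm sizes in
the 10⁵ range) both error terms underflow to zero over a wide plateau of
cut-offs and the reported argmin is the first point of that plateau; the
threshold is 0 to double precision there either way.

## The constrained threshold

Two conventions were candidates for imposing α ≤ alpha_max and
power ≥ power_min, and the choice is observable in which designs come out
infeasible:

* **filter** (default): compute the unconstrained optimum and declare the
  design infeasible if that optimum violates either bound. This is the
  convention that reproduces the published reference grid, including its
  infeasible cells: e.g. (n₁, n₂) = (50, 100) at d = 0.5 *does* admit
  cut-offs with α ≤ 0.05 and power ≥ 0.8, but its cost-optimal cut-off is
  under-powered, so it is reported as infeasible.
* **clamp**: project the optimum onto the feasible cut-off interval
  [t(alpha_max), t(power_min)]; infeasible only when the interval is empty.
  Because the cost is unimodal on that interval (asserted numerically in
  tests), the projection is the cost-minimizing feasible cut-off. This is
  the natural constrained optimum but it makes (50, 100) feasible at
  −log₁₀ ≈ 1.368, which does not match the reference grid.

Both are exposed (`rule="filter" | "clamp"`); they agree exactly whenever
the unconstrained optimum already satisfies the constraints.

One cell of the reference grid, (1000, 1000), is knowingly not reproduced:
at that size the cost at the minimum is ~9×10⁻⁹ and the surface is so flat
that a quasi-Newton minimizer with default tolerances stops early and
start-dependently (we verified values between 7.97 and 8.03 for −log₁₀ of
the threshold depending on the start). The correctly converged minimum is
8.061, with a cost 2.7% below the value implied by the published 7.956; the
package reports the converged value.

## Corpus pipeline

Per trial, the statistic is b/se for continuous outcomes and log(b)/se for
dichotomous (ratio) outcomes, referred to t(ν) with ν = n₁ + n₂ − 2 — a *t*
rather than *z* reference because some trials are small. Inclusion filters:
|stat| < 20 (absolute value, so large negative effects are treated
symmetrically) and a minimum sample size of 10, by default on the total
n₁ + n₂ with a `per-arm` switch since either reading is defensible. Rows
that cannot yield a valid statistic (se ≤ 0, b ≤ 0 for dichotomous, missing
or non-numeric cells, arm size < 2) go to a rejects report with
machine-readable reasons — nothing is silently dropped.

Significance is strict (significant ⇔ p < threshold). Flexible per-trial
thresholds always use the equal-variance δ, because effect/SE corpora carry
no arm SDs; per-trial results are cached by (n₁, n₂, d) since the flexible
threshold depends on the design only. Under the constrained criterion,
infeasible trials are never significant and their threshold serializes as
the `NA` sentinel, never a number. Quartiles use the linear-interpolation
convention (`numpy.percentile` default); summaries are invariant under row
permutation and byte-identical across reruns of the same inputs. Cohen's κ
is computed from the 2×2 marginals ((p_o − p_e)/(1 − p_e)) and returns NaN
when both raters are constant; it is cross-checked against
scikit-learn in tests.

## Synthetic corpora

The generator draws each trial from exactly the two-hypothesis model above:
truth ~ Bernoulli(pr_true); arm sizes log-uniform integers in
[arm_min, arm_max]; statistic = central t(ν) deviate, shifted by δ(true
effect) for true-effect trials; the standard error is lognormal and the
reported effect is reconstructed as b = stat·se (continuous) or
b = exp(stat·se) (dichotomous), so the pipeline recovers the drawn
statistic from (b, se) alone. Ground truth is written to a sidecar file the
pipeline never reads. Seeding spawns one substream per trial from the root
seed, so trial *i* is unchanged when the corpus is extended.

Defaults are the study conditions of the corpus analysis: pr_true = 0.5,
true effect d = 0.5, 30% dichotomous outcomes. Arm sizes default to
[50, 500] so every trial's total is ≥ 100 and the pipeline's assumed
minimum acceptable effect (0.5) equals the generating effect — under that
match the per-trial α and 1−β are the *exact* false-positive and detection
probabilities, which is what makes the calibration tests sharp (realized
rates within 3 Monte-Carlo standard errors of the mean per-trial
predictions at 5,000 trials).

Because the generative model coincides with the model behind the error
formulas, passing calibration shows the arithmetic and the pipeline are
self-consistent; it does **not** show that real trial corpora satisfy the
model. Real corpora have unequal variances, non-t sampling distributions,
selection and reporting bias, and empirical arm-size/effect distributions
the generator does not emulate.

## Known limitations

* The cost function is the specific convex combination above; other convex
  costs would give other optima. Only (C, pr) are exposed.
* One-tailed tests and tests other than the two-sample Student's t are out
  of scope, as are Welch degrees of freedom.
* The flexible threshold depends on arm SDs that are only available after
  the trial; with equal variances assumed a priori it is an approximation
  whose error grows with the true variance ratio (the worked example:
  thresholds 0.037 / 0.025 / 0.014 for s₂/s₁ = 1.5 / 1.0 / 0.5).
* Problem sizes in tests (5,000-trial calibration corpora, 200,001-point
  oracle grids, 50 randomized designs) were chosen so the full suite runs
  in well under a minute per module on one CPU.
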
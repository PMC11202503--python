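# Methods

## Allocation procedures

**Stratified permuted block randomization.** Strata are the full
cross-classification of every schema covariate. Each stratum consumes its
own lazily generated stream of uniformly random permuted blocks; a block of
size *b* (default 2 × number of arms) holds *b*/arms copies of each arm
label. Nothing forces the final block of a stratum to complete — truncated
blocks are precisely the mechanism by which many small strata (e.g. dozens
of centers crossed with other covariates) generate imbalance, so no
correction is applied. Structural guarantees: with one stratum and *n* a
multiple of *b* the total imbalance is exactly 0, and at every prefix the
within-stratum arm-count spread is at most *b* − *b*/arms.

**Pocock–Simon minimization.** Patients are processed in inclusion order.
For each candidate arm, the score is the weighted sum over covariates of an
imbalance criterion applied to the hypothetical per-arm counts at the
patient's own level after the candidate assignment. The criterion is the
range (max − min) by default, with variance as an alternative; weights
default to equal. The score only uses marginal level counts — no
overall-size or within-stratum term — which is the classical form of the
procedure; the criterion, weights and p_best are all configurable because
published trials rarely document which variant their software used.

**Random element.** The unique score-minimizing arm receives probability
p_best (default 0.8, i.e. a 20% random element, the midpoint of the 10–25%
range used in practice); the remaining 1 − p_best is split equally over the
other arms, which preserves "at worst 20% toward any non-best arm" for
three arms at p_best = 0.8. When k > 1 arms tie for the minimum, the
assignment is uniform over the tied arms and no biased coin is applied —
applying p_best after a tie-break would penalize tied arms twice and break
symmetry. With p_best = 1 the procedure is deterministic up to ties, which
is what the brute-force oracle tests exploit.

## Imbalance measures

All three measures are raw patient counts. For two arms every "spread" is
the absolute count difference; for 3–4 arms the range (max − min) is used
at every level of aggregation, chosen because it reduces exactly to the
two-arm absolute difference. The within-stratum sum runs over *occupied*
cells only; empty cells contribute 0, so the measure is insensitive to how
large the nominal stratum universe is. For two arms the measures are
ordered: total ≤ each covariate's margin sum ≤ within-stratum (triangle
inequality over levels and strata); the property tests verify this against
a dictionary-counting oracle.

## Re-randomization design

Each replicate draws a fresh inclusion-order permutation and runs **every
configured method on the same shuffled sequence** (a paired design). The
pairing is a design choice of this package: it removes ordering noise from
method contrasts; nothing about either allocator depends on it. All
randomness descends from one root seed: replicate *r* of method *m* uses a
child seed spawned via `SeedSequence([seed, r, m])`, and SPBR's per-stratum
streams are seeded by `(seed, stratum index)` with the stratum index taken
from the fixed mixed-radix order of the cross-classification — results are
therefore independent of the order in which strata are first encountered
and reproducible across platforms.

## Endpoint regeneration and bias

Success rates are estimated per (stratum, arm) cell as observed successes /
observed patients, with strata formed over every stratification variable
*except* the center: with tens of centers most (center × covariate × arm)
cells hold 0–1 patients and carry no information. Per-arm estimation is
used because the downstream quantity is the per-arm treatment effect; a
pooled per-stratum mode is provided. Cells with zero patients are flagged
empty rather than errored — sparsity is a property of the data, and the
1/1 = 100% degeneracy of tiny cells is deliberately left visible to the
user. During regeneration, a patient whose (stratum, arm) cell is empty
falls back to the arm's marginal rate (unweighted mean over the arm's
non-empty strata); the fallback can be disabled to hard-error instead.

Bias is reported per arm as **reference rate − simulated success
proportion**, on the probability scale, so a simulation that under-states
the reference efficacy yields positive bias. Percentage-point display is a
formatting concern left to the caller.

## Boxplot summaries

Replicate distributions are summarized as median, 25th/75th percentiles
(numpy's linear-interpolation quantile rule, fixed so summaries are
bit-reproducible), whiskers at the most extreme data points within
[q25 − 1.5·IQR, q75 + 1.5·IQR], and everything beyond listed as outliers.

## Synthetic populations

The generator emulates the structure of multicenter phase II oncology
trials: center membership is multinomial with a probability vector drawn
once per population from a symmetric Dirichlet, whose concentration
controls how unequal centers are (default 1.0 — a few large and many small
centers, the regime in which permuted blocks stay incomplete); covariate
levels are i.i.d. categorical; inclusion order is a uniform random
permutation. Defaults (109 patients, 2 arms, 30 centers, one binary
covariate, baseline success rate 0.4) are realistic for the field but
illustrative: no attempt is made to reproduce any specific trial's covariate
distributions or effect sizes. Covariates are independent by default; an
`association` parameter can force the second covariate to copy the first
for stress tests. The outcome model is additive on the probability scale
(baseline + optional per-level stratum effects + per-arm effect), clamped
to [0, 1] with a warning.

What passing tests therefore show: the allocators, measures and pipeline
behave correctly on populations with the right *structure* (unequal
centers, sparse strata, binary endpoints). What they do not show: behavior
under real-world features the generator omits — temporal drift in the
patient mix, covariates correlated with center, informative dropout, or
non-binary endpoints.

## Problem sizes and tolerances

The heaviest built-in experiment (directional comparison of the two
methods) uses 1000 paired replicates of a 120-patient, 30-center, 2-arm
trial — large enough that the median imbalance orderings are stable across
seeds, small enough to run in well under two minutes on one core.
Stochastic checks use 3-standard-error binomial bounds at their stated n
(e.g. rate recovery at n = 10,000), and the 20% random-element check allows
±1 percentage point of Monte-Carlo slack at 10,000 steps. Score ties in
minimization are detected with `np.isclose` to keep the range criterion
robust to float weights.

## Known limitations

* Equal (1:1[:1…]) allocation ratios only; 2–4 arms.
* No Efron biased coin, urn designs, or response-adaptive methods.
* No survival-time endpoint modeling: the endpoint is a single Bernoulli
  outcome per patient.
* Minimization scores marginal counts only; variants that include an
  overall-size term are out of scope.
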
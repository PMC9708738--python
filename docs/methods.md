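# Methods

`centend` simulates and analyzes a visual psychophysics study design in
which participants judge spatial extents (segment lengths, cm) and
temporal extents (interval durations, s) in two task families:
magnitude **reproduction** (produce the magnitude you just saw) and
two-interval forced-choice **discrimination** against a fixed standard,
plus two motor control tasks (pointing and rhythm synchronization).
The scientific target is *central tendency* (regression to the mean):
when observers reproduce magnitudes drawn from a set, their responses
are biased toward the set's mean, the Bayesian signature of combining a
noisy sensory measurement with a prior centred on stimulus history.

## Study design constants

* Reproduction: 11 levels, 6–14 cm in 0.8 cm steps (space) and
  1.270–1.8 s in 0.053 s steps (time); 6 block-randomized sets, 66
  trials. The mean of each level set (10 cm, 1.535 s) equals the
  discrimination standard of the same condition.
* Discrimination: comparison placed by a QUEST staircase with threshold
  prior 12.0 ± 3.6 cm (space) or 1.7 ± 0.52 s (time); sessions never
  stop before 50 trials (default ceiling 60).
* Nuisance randomization (start position 0.2–1.7 cm; onset delays
  1–2 s and 1–1.8 s) is drawn and logged but has no computational role.
* Controls: 50 pointing trials cycling over five screen positions;
  rhythm synchronization analyzed as 45 inter-press intervals.  The
  pacing interval of the rhythm task is not fixed by the design we
  emulate; the package uses 1 s.

## Generative observer

For a reproduction trial with stimulus `S`:

```
m = S + ε_s                 ε_s ~ N(0, σ_s²)  or  N(0, (k·S)²)
p = w·μ_prior + (1−w)·m     0 ≤ w ≤ 1
R = max(0, p + b + ε_m)     ε_m ~ N(0, σ_m²)
```

Constant sensory noise `σ_s` is the default for length; scalar
variability `k·S` (Weber-like noise, the standard assumption in
interval timing) for duration.  `b` is a constant response bias — the
generative analogue of the measured Offset.  Under the *static-mean*
prior (`μ_prior` = mean of the level set) the response slope on `S` has
expectation `1 − w`, so the regression index estimator is unbiased for
`w`; this is the package's recovery oracle.  A *running-mean* prior
(mean of all previous measurements) is available for trial-history
simulations but is not the default, because it makes the RI↔w mapping
only approximate.  Clipping at 0 is counted and warned about, since it
bends the linear model at extreme noise.

The underlying study assumes the Bayesian weighting qualitatively (more
sensory uncertainty → more weight on the prior) but prescribes no
generative equation; the weighted-average form above is this package's
modelling choice.

Discrimination choices follow
`P(comparison judged longer) = λ/2 + (1−λ)·Φ((c − s)/σ_d)`; a
zero-noise observer is a step function and an exact tie is resolved by
a fair coin.  Lapses split equally between the two responses.

### Default cohort

`observers.default_cohort_spec()` defines two age cohorts (25 young, 21
older adults) whose group-level parameter distributions reproduce the
study conditions this package emulates: Weber fractions near 0.09/0.18
(young, space/time) and 0.13/0.25 (older), prior weights near
0.43/0.32 and 0.47/0.29, constant underestimation biases around −0.05
to −0.12, and control-task motor noise matched to median pointing
errors of ~0.2 cm and rhythm variability of ~0.07–0.08 s.
Between-participant spread follows the corresponding group SDs
(normal draws, clipped to valid ranges).  What the generator does *not*
emulate: sequential (trial-history) dependencies, drift or fatigue,
left/right or first/second-interval response biases, and any
relationship between a participant's discrimination noise and their
reproduction noise beyond what the group means impose.  Passing tests
therefore validate the estimators under the stated noise model, not the
full richness of human data.

## QUEST staircase

The staircase keeps a log-space posterior over the threshold on a
discrete grid (201 points over 2–22 cm; 301 over 0.2–3.2 s), starts
from the discretized normal prior above, and updates by multiplying
with the assumed psychometric likelihood
`ψ(x;T) = γ + (1−γ−δ)·Φ(β(x−T))`.  Numerical choices: log-space
storage (no underflow), renormalization after every update, mode
recommendations with ties broken toward the prior mean, intensities
snapped to the grid.

Two defaults deserve justification:

* **γ = δ = 0.01, PSE tracking.**  The response being modelled is a
  judgement ("comparison longer"), not a correctness score, so its
  probability genuinely spans ~0–1 and the tracked threshold `T` is the
  point of subjective equality.  Setting γ to the 0.5 guess rate
  appropriate for performance-scored tasks would make `T` track a
  ~74 %-point that moves with the observer's (unknown) σ, and in
  simulation it biases the downstream threshold estimate severely.
* **Placement offsets ±1.57 assumed SDs.**  Placing every trial at the
  posterior mode is optimal for locating the PSE but samples a single
  point of the psychometric function, leaving its slope — the
  differential threshold, hence the Weber fraction — unidentifiable in
  the later fit.  Sessions therefore alternate deterministically
  between recommendation ± 1.57·(1/β), the information-optimal
  symmetric two-point design for slope estimation.  An optional uniform
  jitter and mean/quantile recommendation rules are available.

Calibration, measured by `recovery.recover_weber_fraction` (100
sessions, 60 trials each, observer at the staircase's assumed noise
scale σ_d = 0.1·standard): median relative error of the recovered
Weber fraction ≈ 13 %, with an asymptotic floor of ≈ 11 % for this
many binary trials.  Away from the assumed scale (σ_d between roughly
half and twice 0.1·standard) the error grows toward 15–25 %: a 50–60
trial session simply carries limited information about the slope.  This
is a property of the design being emulated, not of the estimator — the
MLE tracks the brute-force grid optimum in all tested cases.

## Analysis suite

Per participant × condition, from the reproduction log (`S`, `R`):

* `Offset = mean(R) − mean(S)`; responses are corrected
  (`R' = R − Offset`) before everything else, so the remaining errors
  isolate context dependency from a global shift.
* OLS of `R'` on `S`; **regression index** `RI = 1 − slope` (0 =
  veridical, 1 = complete regression to the mean).  The orientation is
  chosen so that regression to the mean is positive.
* Per level `i`: `bias_cd_i = (mean(R'_i) − S_i)/S̄`,
  `cv_i = sd(R'_i)/S̄` (population SD, N denominator, matching the
  defining formulas), `rmse_i = sqrt(bias_cd_i² + cv_i²)`.

With the balanced 6×11 design, offset correction forces the *signed*
`bias_cd_i` to average exactly zero (asserted in tests), so a signed
equal-weight aggregate would be vacuous.  The aggregate accuracy error
is therefore the mean of `|bias_cd_i|` (an RMS aggregate is available
via `summarize(..., aggregate="rms")`); `cv` and `rmse` aggregate as
plain means since they are non-negative.

The psychometric fit maximizes the Bernoulli likelihood of
`λ/2 + (1−λ)Φ((c−μ)/σ)` on the comparison axis with free μ (reported
alongside σ rather than pinned to the standard).  Default lapse policy
is fixed λ = 0.01 — a tiny fixed lapse stabilizes the MLE against
stray errors; λ = 0 reproduces the plain cumulative Gaussian, and a
free-λ mode (bounded by 0.1) is available.  Optimization restarts from
a fixed deterministic grid of starting points (no random restarts), so
fits are bit-reproducible; non-identifiable inputs (one comparison
level, or all responses in one category) return `converged=False` with
a diagnostic rather than a number.  The Weber fraction is σ divided by
the standard.

Control metrics: Euclidean pointing error summarized per participant
by the median (group comparisons of this metric are rank-based), and
rhythm variability as the population SD of inter-press intervals.

## Group statistics

One-sample t-tests with Cohen's d (`d = (M − μ₀)/SD`, sample SD) for
the RI and Offset against 0; the summary-statistic route
(`one_sample_t_from_summary`) lets printed statistics be audited from
reported group means and SDs alone.  Two-sided p-values are the
default everywhere (one-sided available by flag).  The Mann-Whitney U
uses 0.5 credit for ties, a tie-corrected continuity-corrected normal
z, and exact enumeration of all group assignments when n₁+n₂ ≤ 12.
Null calibration at the study's group sizes (25, 21): empirical type-I
error 0.048 at α = 0.05 over 10,000 simulated pairs.

Linear mixed-effect modelling is deliberately not reimplemented: the
pipeline exports a long-format tidy table (participant, group,
condition, metric, value) consumable by any external LMM tool.

## Recovery experiments and problem sizes

`recovery.recover_regression_index` runs 200 participants × 9 prior
weights (0.1–0.9), 66 trials each, constant sensory noise 0.12·S̄ and
a common bias b: the mean recovered RI sits within 0.02 of w in every
cell (Monte-Carlo SE ≈ 0.004), and the recovered offset — pooled over
the grid, where its Monte-Carlo SE ≈ 0.003 makes the bound meaningful
— within 0.01 of b.  Offset recovery is assessed pooled rather than
per cell because a single cell's SE (≈ 0.009 at the noisiest w) is of
the same order as the bound.  `recover_weber_fraction` is described
above.  These sizes keep the full suite under a minute while holding
Monte-Carlo error well below every asserted tolerance.

## Known limitations

* The generative observer is linear-Gaussian; it cannot produce the
  asymmetries or sequential effects real observers show.
* QUEST assumes a fixed slope β = 1/(0.1·standard); threshold recovery
  degrades for observers far from that scale (see above).
* The exact Mann-Whitney is limited to n₁+n₂ ≤ 12 (full enumeration);
  beyond that the tie-corrected normal approximation is used.
* Responses are clipped at 0, which slightly biases recovery at
  extreme noise levels; clipping is warned about.
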
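# Methods

## The generative task model

Positions live on the horizontal axis of a unit screen; only the x-axis
is modelled. The hidden coin on trial t of block b is

    coin_t ~ N(0.5, σ²_prior(b)),   σ_prior ∈ {0.025, 0.085},

and the evidence is five iid dots, dot_i ~ N(coin_t, σ²_dots(t)) with
σ_dots ∈ {0.06, 0.15}. A session is 4 blocks × 150 trials; the prior sd
is constant within a block, each prior level is used in exactly two
blocks (any seeded order — the design does not constrain it), and the
dot-spread levels within a block are a seeded permutation of a 75/75
split. Coins are not truncated to the screen: with σ_prior ≤ 0.085
around 0.5 the excursion probability is negligible, and truncation would
distort the variance the learner and fitted models estimate. Simulated
responses are clipped to [0, 1] as a physical screen constraint.

The normative estimate combines prior mean and dot centroid with weight
w = σ²_P / (σ²_P + σ²_L) on the sensory side. The effective sensory
variance σ²_L is ambiguous in principle: the spread of a single dot, or
the variance of the five-dot centroid (σ²_dots / 5). We default to the
centroid interpretation — the centroid is the observer's best sensory
estimate, so its variance is the relevant reliability — and expose
`mode="raw"` for the alternative. Models that *fit* variances absorb
this choice into the fitted value; only the fixed-parameter normative
model (model 4) is genuinely affected.

## Synthetic observers

The generator simulates four response strategies: the normative
combiner (with *subjective* prior variances that need not equal the
imposed ones), centroid-only, prior-mean-only, and previous-coin.
Responses add Gaussian motor noise (default sd 0.05, a value that keeps
single-participant weight estimates informative but visibly noisy, in
line with psychomotor tasks of this kind) and an optional uniform lapse
process (default rate 0 — the model suite contains no lapse model).
Group (stress) effects shift the stressed participants' generating
parameters: an additive sensory-weight shift, or multiplicative factors
on the subjective prior or likelihood variances. Participant
heterogeneity multiplies each participant's subjective prior variances
by independent lognormal factors exp(N(0, sd²)).

What the generator does *not* emulate: reaction times, 2-D displays,
learning of the prior mean, sequential (trial-order) dependencies other
than the previous-coin strategy, and motivational/reward dynamics.
Passing recovery tests on these cohorts therefore shows the estimators
are correct for reliability-weighting observers with stationary
parameters — not that real participants are such observers.

Scoring ("hit") uses a single configurable half-width tolerance
(default 0.015 screen units, roughly a net twice the width of a small
coin); the hit column is cosmetic and feeds no analysis.

## Weight estimation and sensitivity

The sensory weight is the OLS slope of response on centroid, overall
and within each of the four prior × likelihood cells (minimum three
trials per estimate; constant centroids raise a degenerate-design
error). Slopes are not clipped: bounds apply to the generating weight,
not its estimate, and clipping would bias group means. Sensitivity to
prior uncertainty is mean(w_Pl, w_PL) − mean(w_pl, w_pL); sensitivity
to likelihood uncertainty is mean(w_pl, w_Pl) − mean(w_pL, w_PL). A
difference of condition means is the simplest statistic that is zero
for an uncertainty-blind observer and positive for a reliability
re-weighting one; it is exposed as a named function so an alternative
(e.g. a ratio) can be swapped in. The early-learning check re-estimates
the general weight on the first 50 trials in session order.

## The ten models

1–3 are parameter-free heuristics (centroid; constant 0.5; previous
trial's revealed coin, with the told prior mean on trial 1 — the only
information available before any feedback). 4 applies the combination
rule with the imposed variances. 5 learns the prior variance within a
block as the running mean of (coin − 0.5)² over previously seen coins —
the prior mean is told to participants, so only the spread is learned —
initialised at the large imposed variance (an agnostic start,
configurable), reset at block boundaries (the prior changes there), and
floored at 10⁻⁶ to keep weights defined. 6 fits one (v_p, v_P) pair for
the whole cohort; 7 fits a pair per participant (2 × n parameters).
8–10 add a group dummy to model 6: additively on the sensory weight
(clamped to [0, 1], clamp events counted in the fit diagnostics), or
multiplicatively as exp(β) on the prior or likelihood variance —
the log-multiplicative form preserves positivity and makes β = 0 an
exact reduction to model 6.

Fitting minimises summed squared response error — the ML criterion
under a single Gaussian residual variance — by L-BFGS-B on
log-variances (bounds [10⁻⁶, 1] in variance units; weight dummy in
[−1, 1], log dummies in [−5, 5]), with 5 seeded multistarts (first
start at the imposed variances and β = 0), objective tolerance 10⁻⁹,
ties resolved by lowest objective then lowest parameter norm. Model 7's
objective is separable, so each participant is optimised independently.

## Scoring and comparison

The Gaussian log-likelihood profiles out the residual variance:
logL = −n/2 (ln 2π σ̂² + 1) with σ̂² the mean squared residual pooled
across participants. Information criteria count k_eff = k_free + 1
parameters (the residual variance is estimated too); with that
convention BIC − AIC = (k_free + 1)(ln n − 2) identically, which at the
full design size n = 60 × 600 = 36,000 gives per-model gaps of 8.49 per
parameter. Perfect predictions (possible on noiseless synthetic data)
return logL = +∞ as an explicit degeneracy flag.

Cross-validation fits each model on the odd-numbered trials (1-based
session order) and measures rMSE on the even trials. Predictions for
the test trials are computed from the full trial sequence so that the
history-dependent models (previous coin, learned prior) see the true
feedback stream; their parameter-free updates use no response data, so
no information leaks from the test responses. The best model is flagged
by lowest BIC (ties broken by fewer parameters); each model is compared
with the best within group by Wilcoxon signed-rank on per-participant
cv-rMSE, and between groups by Wilcoxon rank-sum per model.

## Group statistics

Rank tests enumerate the exact permutation null when both samples have
≤ 10 observations (average ranks under ties; the null of the rank sum
is symmetric about n₁(N+1)/2, so the two-sided p is the mass at least
as far from that centre); larger samples use the tie-corrected normal
approximation with continuity correction. Cohen's d uses the
(n−1)-weighted pooled SD.

The 2 (prior) × 2 (likelihood) × group ANOVA is computed through
orthogonal within-participant contrasts: each within effect (and its
group interaction) reduces to a t-test on a per-participant contrast
score, and the group main effect to a t-test on participant means —
exactly the classical split-plot decomposition for two-level factors,
in the unweighted-means (Type III) convention when group sizes differ.
Zero-variance contrasts are handled explicitly (F = 0 when the effect
is also zero, F = ∞ otherwise).

The group-effect ("multilevel-style") check uses a two-stage contract:
the per-participant summary is the first stage, and the second stage
reports an intercept test (pooled mean ≠ 0, one-sample t) and a group
coefficient (pooled-variance two-sample t). For this balanced design
the two-stage fixed-effect test is equivalent to a random-intercept
model's group test; a full mixed-model fit is deliberately out of
scope.

Power for the two-sample pooled t-test uses the noncentral t with
df = n₁ + n₂ − 2 and noncentrality d√(n₁n₂/(n₁+n₂)); the detectable
effect solves power(d) = target by bracketed root finding to 10⁻⁶.
Where scipy's noncentral t is numerically unstable at large
noncentrality, the normal limit is substituted.

## Problem sizes used in tests

Simulation-based tests scale the design down where the property being
checked does not depend on the full size: recovery suites use 6–12
participants (600 trials each for parameter recovery, matching the real
design's per-participant information); model-selection recovery uses
noiseless 600-trial sessions; null-calibration suites use 2,000 seeded
replicates of 24-participant, 80-trial cohorts for the stress-detection
test and n = 15–20 samples for the plain rank tests. Single-draw
parameter estimates inherit sampling noise (amplified for variances
generating weights near 1, since v = σ²_L w/(1−w)), so recovery is
asserted on the bias across replicates against its Monte-Carlo error,
not on individual draws.

## Known limitations

- The sensitivity statistic is a declared convention, not the only
  reasonable one; ratios or model-based indices would need their own
  calibration.
- Model 5's update rule (running second moment about the told mean,
  block reset, agnostic initialisation) is one defensible learner among
  several; alternatives (forgetting factors, Kalman-style mean+variance
  learning) are out of scope.
- BIC/AIC use pooled observations and a single residual variance per
  model; per-participant residual variances would change the absolute
  criterion values (the comparison machinery accepts either convention
  only through refitting).
- The stress-dummy models quantify a *mean* group shift; distributional
  or individual-difference effects of a manipulation are invisible to
  them.
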
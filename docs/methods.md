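# Methods

## Task and data model

The simulated task is a 2AFC steering game: 800 trials in 8 blocks of 100,
ten colour-coded trajectories with offset angles from 0.005 to 0.180 rad
(equally spaced by default), each appearing exactly 10 times per block in a
seed-shuffled order, with left/right sides split 50/50 per trajectory over
the session. A trial lasts 2 s without feedback and 3 s with it, so a full
session spans 26.67–40 minutes depending on the request rate. The geometry
is cosmetic but carried for completeness: the asteroid deviates from the
midline as `d_x = v·t·tan(γ)` with `v = 200/0.27` px/s, and expands linearly
as `diameter(t) = 4.6·(1 + 2t)` mm. The "200% per second" expansion could
also be read as compounding; it is implemented as linear because it never
enters any analysis. Missed-deadline re-queuing is not simulated — agents
always respond, which guarantees 800 analysed responses per participant.

A trial table is plain CSV with one row per trial (participant, block,
trial index, trajectory, angle, true/chosen side, correctness, feedback
request, feedback valence, trial duration); the reader validates the schema,
the binarity of outcome fields, and the valence invariant
(`valence = none` iff no feedback requested).

## Psychometric performance

The probability of a correct steering decision is a log-logistic function of
the offset angle,

    P(correct) = 0.5 + 0.5 / (1 + (angle/threshold)^(-slope)),

rising from chance at zero angle to 1 asymptotically and passing through
0.75 exactly at the threshold. Only monotonicity and 75%-correct thresholds
are empirically constrained; the functional form is this package's choice
(any sigmoid in log-angle with the same anchors would serve). Cohort
defaults draw thresholds from N(0.08, 0.03) rad clipped to [0.02, 0.25],
placing roughly three quarters of agents at or below 0.1 rad, and slopes
from N(2.0, 0.3). An optional learning ramp raises accuracy from chance
toward the psychometric asymptote with a configurable halflife counted in
same-trajectory encounters (0 = stationary, the default).

## Information quantities

* **Binary entropy / episodic gain** (bits): `h(μ) = −μ log₂ μ − (1−μ)
  log₂(1−μ)`. Agents estimate `μ` as the running proportion of their own
  correct decisions at that trajectory up to and including the current trial
  (0.5 before the first), and the analysis uses the end-of-session value.
* **Beta posterior**: feedback outcomes at a trajectory update a
  Beta(n+a₀, m+b₀) belief over θ; the default prior is the non-informative
  Beta(1,1) (configurable). Its differential entropy uses the standard
  closed form `ln B(a,b) − (a−1)ψ(a) − (b−1)ψ(b) + (a+b−2)ψ(a+b)`,
  verified against numeric quadrature to 1e−6 nats (this form, unlike
  naive equivalent-sample-size variants, is zero for the uniform).
* **Parametric gain**: the closed-form rate `r(θ|success) = γ/(1−θ) − 2`,
  `r(θ|failure) = γ/θ − 2`, its predictive expectation
  `α(θ) = −2 + γ(θ²+(1−θ)²)/(θ(1−θ))`, and `IG_θ ≈ α(θ)/t`. γ is the true
  Euler–Mascheroni constant 0.5772156649 (the value is sometimes quoted
  rounded as 0.5774). These quantify the expected *change* in posterior
  entropy — negative when uncertainty shrinks — and the request policy uses
  the magnitude as the incentive. An exact one-step oracle (posterior-
  predictive average of updated Beta entropies) and the Bernoulli BALD
  mutual information bound the approximation: both decay as 1/t and agree
  in sign with the closed form on the tested grid.
* **Volatility/forgetting**: between feedbacks the belief is the convex
  mixture `ρ + e^{−Hη}(b − ρ)` of the last-updated density and a stationary
  density ρ (default Beta(1,1), a maximal-ignorance drift target), with H
  the number of same-trajectory trials since feedback and η the diffusion
  rate. The entropy increment `Δ(H) = k(1 − e^{−Hη})` (k the stationary
  entropy) is exposed separately; the volatile request policy instead
  interpolates the pseudo-counts toward the stationary ones at the same
  exponential rate, which keeps the incentive computable through the same
  `α(θ)/t` form and yields the hazard signature (rising request hazard with
  time since feedback) that distinguishes forgetting-driven sampling.
* **Influence direction**: the sign of a feedback point's effect on the
  incentive crosses over at θ = 0.75 — success feedback raises the incentive
  below 0.75 and lowers it above; failure feedback does the opposite.

Episodic quantities are reported in bits; the Beta-entropy machinery works
in nats internally with explicit conversion where the two meet.

## Request policies

`P(request) = clip(K_s + α_s·IG_episodic + β_s·|IG_θ|, 0, 1)`, sampled per
trial. Available policy ids: `constant` (K only), `episodic`, `parametric`,
`volatile-parametric` (parametric with belief forgetting), `total` (all
terms), and `valence` (trait rate shifted up after failure feedback and down
after success at the same trajectory — the outcome-valence alternative).
Clipping before Bernoulli sampling is the package's link choice; no link
function is otherwise implied by the linear incentive. Beliefs update only
on feedback trials; the running `μ` updates on every trial.

Cohort defaults mirror the group-level estimates that motivated the model:
trait rates K ~ N(0.12, 0.11) clipped to [0,1], episodic weights
α ~ N(0.28, 0.10), with a −0.5 trait/weight correlation; one master seed
spawns independent per-agent streams, recorded in the outputs.

## Statistical pipeline

* **Aggregation**: per participant × trajectory, accuracy μ over *all*
  trials, request proportion, and `IG = h(μ)` at session end.
* **Group model**: `request_prop ~ IG + (IG | participant)` fitted by
  maximum likelihood (statsmodels MixedLM). The likelihood-ratio statistic
  compares against the null retaining the full random structure but no
  fixed IG effect. Fixed-effect CIs are Wald; Satterthwaite df corrections
  are not applied. ICC is τ₀₀²/(τ₀₀²+σ²); conditional R² follows the
  Nakagawa–Johnson variance decomposition. Near-singular random-effect
  covariances are flagged in the result, not raised.
* **Individual level**: per-participant Pearson r over the ten
  trajectory-level points; participants with zero variance in either
  variable are flagged and excluded from correlation summaries (they remain
  in the mixed model). The permutation null shuffles each participant's ten
  request proportions against the information-gain values (10,000
  replicates by default), pools all replicate × participant r values, and
  takes the two-sided 5% criterion as the 97.5th percentile of |r| — for
  ten points the null SD is ≈ 1/√9 = 1/3 and the criterion ≈ 0.63. The
  one-sided reading would give ≈ 0.55; two-sided is used throughout.
* **Diagnostics**: conditional request rates given the previous
  same-difficulty trial's request/valence (per-participant rates averaged
  across participants, participant-level bootstrap CIs, 2,000 draws);
  block-wise accuracy and request-rate means with t-based 95% CIs across
  participants; the feedback-normalized learning rate (central finite
  differences of the across-participant accuracy-by-trial curve, averaged
  per block, divided by the block's request proportion, with an optional
  exponential-decay fit); PCA variance shares of the participants ×
  difficulty request matrix; and the empirical request hazard
  h(H) = requests at gap H / at-risk at gap H, where H counts
  same-trajectory trials since the last feedback and trials before a
  trajectory's first feedback are left-truncated out.

## What the synthetic generator does and does not emulate

It reproduces the design's structure (cohort size, schedule balance, session
timing, difficulty-graded accuracy, wide individual differences in request
rate) and lets each candidate drive be switched on in isolation, which is
what the recovery and signature tests exercise. It does not emulate response
times, practice blocks, missed deadlines, sequential dependencies in
accuracy beyond the optional learning ramp, or any mismatch between an
agent's subjective `μ` and its generative accuracy. Passing tests therefore
demonstrate that the pipeline measures what these policies generate — not
that human data follow them; published real-data coefficients (e.g. a fixed
slope of 0.28 with ICC 0.97) require the original deposit and sit outside
the test surface, though the synthetic defaults are deliberately centred on
them.

## Numerical choices and scale

Entropy conventions: 0·log 0 = 0; binary entropies clamp tiny negative
round-off at 0. Equivalent-sample sizes below 1 are rejected for the 1/t
approximation. Pearson r is undefined (and flagged) for zero-variance
profiles. The permutation engine vectorises all replicates per participant,
so the default 10,000 × 43 run takes seconds. Recovery tests use 43 agents
× 800 trials (the study scale) and 20 replicate seeds for the slope-bias
check; the direct aggregate-level generator (binomial sampling of both
accuracy and requests at 80 trials per cell around a known linear law) is
used where the target is the regression machinery rather than the agent
loop. All randomness flows from explicit seeds; reruns are bit-identical.

## Known limitations

The Satterthwaite-corrected t-tests and repeated-measures ANOVA reported
for the original dataset are not implemented (block summaries with CIs
stand in). The closed-form `α(θ)/t` is an asymptotic rate — at very small
t or extreme θ its sign can differ from the exact one-step change, which is
why the exact oracle is exposed alongside it. The volatile policy's
pseudo-count interpolation is a moment-style surrogate for the density
mixture; both agree at H = 0 and in the stationary limit. The valence
policy's functional form is a minimal construction, not an empirically
fitted model.
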
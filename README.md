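# episeek

Simulation and analysis of **information-seeking behaviour** in a
two-alternative forced-choice (2AFC) perceptual task, modelled on an
"asteroid avoidance" video game: on each trial a player steers left or right
to dodge an asteroid whose trajectory angle sets the difficulty, and may then
pay a one-second time penalty to see whether the decision succeeded. The
package is for computational cognitive scientists who want to test *what
drives such feedback requests* — a per-trial **episodic** drive (closing a
gap in the record of outcomes) versus an across-trial **parametric** drive
(learning one's own skill level) — on real trial tables or on synthetic
cohorts with known generative policies.

## The model

Per trajectory `x`, the outcome of a trial is Bernoulli with accuracy
`θ_x`. Two information quantities are computed from the data available to
the player:

* **Episodic information gain** — the self-information of the upcoming
  outcome given the running accuracy estimate `μ_x`:
  `IG_episodic = −μ log₂ μ − (1−μ) log₂(1−μ)` (bits).
* **Parametric information gain** — the expected change in the differential
  entropy of the Beta posterior over `θ_x` from one more feedback
  observation. In closed form `IG_θ ≈ α(θ)/t` with
  `α(θ) = −2 + γ (θ² + (1−θ)²)/(θ(1−θ))` (γ the Euler–Mascheroni constant)
  and `t` the equivalent number of observations; an exact one-step oracle
  and the Bernoulli BALD mutual information are provided as cross-checks.
  A volatility process `b_{T,H} = ρ + e^{−Hη}(b_{T−H,0} − ρ)` relaxes the
  belief toward a stationary density `ρ` over the `H` trials since the last
  feedback, sustaining the parametric drive indefinitely.

Synthetic agents request feedback with probability

```
P(request) = clip( K_s + α_s·IG_episodic + β_s·|IG_θ| , 0, 1 )
```

where `K_s` is a trait-level rate and `α_s`, `β_s` weight the two drives.
The analysis pipeline mirrors the standard treatment of such data: the group
mixed-effects regression

```
Y_si = β₀ + S_0s + (β₁ + S_1s)·X_i + e_si      (FB ~ IG + (IG | subject))
```

of per-trajectory request proportion on information gain (ML estimation,
likelihood-ratio test against the no-fixed-effect null), per-participant
Pearson correlations calibrated against a Monte-Carlo permutation null,
conditional-request and hazard diagnostics, block-wise learning summaries,
and a PCA of request profiles.

## Worked example

```python
import numpy as np
import episeek as ek

agents = ek.sample_agents(43, seed=11)                 # heterogeneous cohort
trials = ek.simulate_cohort(agents, "episodic", seed=12)  # 43 x 800 trials
aggr   = ek.aggregate_by_trajectory(trials)            # 43 x 10 aggregates
model  = ek.fit_group_model(aggr)
perm   = ek.permutation_null(aggr, n_perm=10000, seed=13)

print(f"beta0 = {model.beta0:.3f}  (95% CI {model.ci0[0]:.3f}-{model.ci0[1]:.3f})")
print(f"beta1 = {model.beta1:.3f}  (95% CI {model.ci1[0]:.3f}-{model.ci1[1]:.3f})")
print(f"LRT chi2 = {model.lrt_chi2:.2f}, p = {model.lrt_pvalue:.2g}")
print(f"null: mean r = {perm.mean_r:.3f}, SD = {perm.sd_r:.3f}, "
      f"crit = {perm.crit_two_sided_05:.3f}")
```

prints

```
beta0 = 0.109  (95% CI 0.074-0.144)
beta1 = 0.280  (95% CI 0.243-0.317)
LRT chi2 = 73.93, p = 8.1e-18
null: mean r = -0.000, SD = 0.333, crit = 0.638
```

`beta1` is the fixed-effect slope: each additional bit of per-trial outcome
uncertainty raises the feedback-request proportion by ~0.28, recovering the
cohort's generative episodic weight; `beta0` is the information-independent
trait rate. The permutation null (10,000 within-participant shuffles of the
ten trajectory-level request proportions against information gain) is
centred on zero with SD ≈ 1/3, so an individual participant's correlation
must exceed ≈ 0.64 in magnitude to be significant at p < .05.

A command-line interface wraps the same pipeline:

```
episeek run --seed 7 --out myrun        # simulate + analyse + permute + report
episeek simulate --agents 43 --policy episodic --seed 7 --out myrun
episeek analyze myrun/trials.csv --out myrun
episeek permute myrun/trials.csv --n-perm 10000 --seed 7 --out myrun
episeek report myrun
```

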
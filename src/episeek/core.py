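"""Simulation and analysis of information-seeking behaviour in a 2AFC task.

The package models an "asteroid avoidance" video game: on each trial an
asteroid approaches on one of ten colour-coded trajectories whose angular
offset from the midline sets the discrimination difficulty, the player steers
left or right, and may then pay a one-second time penalty to see whether the
steering decision succeeded.  The scientific question is what quantity drives
those feedback requests.  Two candidate drives are implemented:

* **episodic information gain** — the self-information (binary entropy) of the
  upcoming outcome given the player's running accuracy estimate ``mu`` at that
  difficulty; closing a gap in the episodic record of outcomes;
* **parametric information gain** — the expected reduction in posterior
  entropy over the Bernoulli skill parameter ``theta`` from one more feedback
  observation (the Bernoulli special case of Bayesian active learning by
  disagreement), optionally sustained by a volatility/forgetting process that
  relaxes the belief toward a stationary distribution between feedbacks.

Synthetic agents combine these drives linearly with a trait-level rate,

    P(request) = clip(K_s + alpha_s * IG_episodic + beta_s * |IG_theta|, 0, 1),

and the analysis pipeline reproduces the statistical treatment such data
receive: trajectory-level aggregation, a linear mixed-effects regression of
request proportion on information gain with by-subject random intercepts and
slopes, per-participant regressions calibrated against a Monte-Carlo
permutation null, conditional-request and hazard diagnostics, block-wise
learning summaries and a PCA of request profiles.

The module is laid out in the order a run executes: configuration and
constants, the information-gain mathematics, belief dynamics, the task
simulator, synthetic cohort generators, the analysis pipeline, and finally
file io / end-to-end orchestration.
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.special import betaln, digamma

__all__ = [
    # constants / config
    "EULER_GAMMA", "DEFAULT_ANGLES", "PIXELS_PER_MM", "ASTEROID_SPEED",
    "TRIAL_COLUMNS", "RunConfig", "RunManifest",
    # info-gain core
    "BeliefState", "BeliefMixture", "VolatilityParams", "InfoGainBreakdown",
    "binary_entropy", "episodic_infogain", "beta_entropy", "bald_infogain",
    "entropy_change_rate", "alpha_rate", "parametric_infogain",
    "exact_expected_entropy_change", "volatility_discounted_belief",
    "volatility_delta", "influence_direction", "infogain_breakdown",
    # task model
    "TrajectorySpec", "ScheduleEntry", "Schedule", "AgentSpec", "POLICIES",
    "default_trajectories", "make_schedule", "trajectory_offset",
    "psychometric_accuracy", "simulate_session", "simulate_cohort",
    "sample_agents", "session_duration_minutes",
    # synthetic aggregate generator
    "synthetic_linear_cohort",
    # analysis pipeline
    "TrajectoryAggregate", "MixedModelResult", "PermutationResult",
    "PCAResult", "aggregate_by_trajectory", "feedback_derived_accuracy",
    "fit_group_model", "individual_regressions", "permutation_null",
    "conditional_request_rates", "block_summaries", "feedback_learning_rate",
    "pca_request_profiles", "request_hazard",
    # io
    "read_trial_table", "write_trial_table", "run_end_to_end",
]

log = logging.getLogger("episeek")

# --------------------------------------------------------------------------
# Configuration & constants
# --------------------------------------------------------------------------

#: Euler–Mascheroni constant, used by the closed-form entropy-change rates.
EULER_GAMMA = 0.5772156649015329

#: Screen pixel pitch of the original display (mm per pixel).
PIXEL_MM = 0.27

#: Pixels per mm (the asteroid speed is specified as 200 mm/s on screen).
PIXELS_PER_MM = 1.0 / PIXEL_MM

#: Asteroid speed in pixels/second.
ASTEROID_SPEED = 200.0 / PIXEL_MM

#: The ten trajectory offset angles (radians), equally spaced over the
#: experimental range 0.005–0.180 rad.
DEFAULT_ANGLES = tuple(np.linspace(0.005, 0.180, 10))

#: Trial-table schema (column order of the delimited-text format).
TRIAL_COLUMNS = [
    "participant_id", "block", "trial_index", "trajectory_id", "angle",
    "true_side", "chosen_side", "correct", "feedback_requested",
    "feedback_valence", "trial_duration",
]

_LN2 = math.log(2.0)


def _as_array(x, name: str):
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite")
    return a


def _maybe_scalar(a: np.ndarray, scalar_in: bool):
    return float(a) if scalar_in else a


# --------------------------------------------------------------------------
# Information-gain core: pure functions
# --------------------------------------------------------------------------

def binary_entropy(p):
    """Entropy of a Bernoulli(p) outcome, in bits.

    ``h(p) = -p log2 p - (1-p) log2 (1-p)`` with the convention
    ``0 log 0 = 0``.  Accepts scalars or array-likes elementwise.
    """
    scalar = np.isscalar(p) or (hasattr(p, "ndim") and np.ndim(p) == 0)
    a = _as_array(p, "p")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("p must lie in [0, 1]")
    out = np.zeros_like(a, dtype=float)
    inner = (a > 0) & (a < 1)
    q = a[inner]
    out[inner] = -q * np.log2(q) - (1 - q) * np.log2(1 - q)
    return _maybe_scalar(out, scalar)


def episodic_infogain(mu):
    """Episodic information gain of observing one outcome, in bits.

    Expected reduction in outcome entropy from feedback, assuming feedback is
    perfectly encoded: the self-information of the binary outcome under the
    current accuracy estimate ``mu``.  Numerically identical to
    :func:`binary_entropy`; kept as its own name because it plays a distinct
    scientific role (the episodic drive of the request policy).
    """
    return binary_entropy(mu)


def beta_entropy(a, b):
    """Differential entropy of a Beta(a, b) density, in nats.

    ``ln B(a,b) - (a-1) psi(a) - (b-1) psi(b) + (a+b-2) psi(a+b)``.
    Zero for the uniform Beta(1,1); negative once the density concentrates.
    """
    scalar = np.ndim(a) == 0 and np.ndim(b) == 0
    aa, bb = np.broadcast_arrays(_as_array(a, "a"), _as_array(b, "b"))
    if np.any(aa <= 0) or np.any(bb <= 0):
        raise ValueError("pseudo-counts must be positive")
    out = (betaln(aa, bb)
           - (aa - 1) * digamma(aa)
           - (bb - 1) * digamma(bb)
           + (aa + bb - 2) * digamma(aa + bb))
    return _maybe_scalar(out, scalar)


@dataclass(frozen=True)
class BeliefState:
    """Beta posterior over a trajectory's Bernoulli accuracy.

    ``n`` counts observed successes, ``m`` observed failures (feedback trials
    only); the prior contributes ``prior_a``/``prior_b`` pseudo-counts
    (non-informative Beta(1,1) by default).
    """

    n: float = 0.0
    m: float = 0.0
    prior_a: float = 1.0
    prior_b: float = 1.0

    def __post_init__(self):
        if self.n < 0 or self.m < 0:
            raise ValueError("counts must be non-negative")
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("prior pseudo-counts must be positive")

    @property
    def a(self) -> float:
        return self.n + self.prior_a

    @property
    def b(self) -> float:
        return self.m + self.prior_b

    @property
    def theta_hat(self) -> float:
        """Posterior-mean accuracy."""
        return self.a / (self.a + self.b)

    @property
    def ess(self) -> float:
        """Equivalent sample size (total pseudo-counts)."""
        return self.a + self.b

    def updated(self, success: bool) -> "BeliefState":
        if success:
            return BeliefState(self.n + 1, self.m, self.prior_a, self.prior_b)
        return BeliefState(self.n, self.m + 1, self.prior_a, self.prior_b)

    def entropy(self) -> float:
        """Differential entropy of the posterior, nats."""
        return beta_entropy(self.a, self.b)


def _expected_outcome_entropy_bits(a: float, b: float) -> float:
    # E_{theta ~ Beta(a,b)}[h(theta)] in bits, closed form via
    # E[-theta ln theta] = a/(a+b) (psi(a+b+1) - psi(a+1)).
    s = a + b
    nats = (a / s) * (digamma(s + 1) - digamma(a + 1)) \
        + (b / s) * (digamma(s + 1) - digamma(b + 1))
    return nats / _LN2


def bald_infogain(belief: BeliefState) -> float:
    """Mutual information between the next outcome and theta, in bits.

    The Bernoulli case of Bayesian active learning by disagreement:
    entropy of the posterior-predictive outcome minus the posterior
    expectation of the outcome entropy.  Non-negative by Jensen's inequality
    and vanishing as the posterior collapses to a point mass.
    """
    marginal = binary_entropy(belief.theta_hat)
    conditional = _expected_outcome_entropy_bits(belief.a, belief.b)
    # clamp tiny negative round-off
    return max(marginal - conditional, 0.0)


def entropy_change_rate(theta, outcome: str):
    """Approximate posterior-entropy change rate after one feedback, nats/trial.

    ``gamma/(1-theta) - 2`` for success feedback, ``gamma/theta - 2`` for
    failure, with gamma the Euler–Mascheroni constant.  Negative values mean
    the posterior is expected to sharpen.
    """
    if outcome not in ("success", "failure"):
        raise ValueError("outcome must be 'success' or 'failure'")
    scalar = np.ndim(theta) == 0
    t = _as_array(theta, "theta")
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("theta must lie strictly inside (0, 1)")
    denom = (1 - t) if outcome == "success" else t
    return _maybe_scalar(EULER_GAMMA / denom - 2.0, scalar)


def alpha_rate(theta):
    """Expected entropy-change rate over predicted feedback, nats/trial.

    ``alpha(theta) = -2 + gamma (theta^2 + (1-theta)^2) / (theta (1-theta))``;
    the expectation of :func:`entropy_change_rate` under the predictive
    probabilities theta and 1-theta.  Convex in theta and slowest (most
    negative) at chance performance.
    """
    scalar = np.ndim(theta) == 0
    t = _as_array(theta, "theta")
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("theta must lie strictly inside (0, 1)")
    out = -2.0 + EULER_GAMMA * (t ** 2 + (1 - t) ** 2) / ((1 - t) * t)
    return _maybe_scalar(out, scalar)


def parametric_infogain(theta, t):
    """Closed-form parameter-learning information gain rate, nats.

    ``alpha(theta) / t`` where ``t`` is the equivalent number of observations
    behind the current belief.  Negative values are expected entropy
    *reductions*; the request policy uses the magnitude as the incentive.
    """
    scalar = np.ndim(theta) == 0 and np.ndim(t) == 0
    tt = _as_array(t, "t")
    if np.any(tt < 1):
        raise ValueError("equivalent sample size t must be >= 1")
    out = alpha_rate(theta) / tt
    return _maybe_scalar(np.asarray(out, dtype=float), scalar)


def exact_expected_entropy_change(belief: BeliefState) -> float:
    """Exact expected change in posterior entropy from one feedback, nats.

    Brute-force oracle for the closed-form rate approximations: average the
    one-step-updated Beta entropies under the posterior-predictive outcome
    probability and subtract the current entropy.  Always <= 0 in expectation
    for the Beta-Bernoulli model.
    """
    p = belief.theta_hat
    h_now = beta_entropy(belief.a, belief.b)
    h_succ = beta_entropy(belief.a + 1, belief.b)
    h_fail = beta_entropy(belief.a, belief.b + 1)
    return p * h_succ + (1 - p) * h_fail - h_now


@dataclass(frozen=True)
class VolatilityParams:
    """Forgetting dynamics: the belief drifts toward a stationary density.

    ``eta`` is the per-trial diffusion rate; ``H`` counts trials since the
    last feedback; the stationary belief is Beta(stationary_a, stationary_b)
    with entropy ``k``.
    """

    eta: float
    H: int = 0
    stationary_a: float = 1.0
    stationary_b: float = 1.0

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.H < 0:
            raise ValueError("H (trials since feedback) must be non-negative")

    @property
    def k(self) -> float:
        """Entropy of the stationary belief, nats."""
        return beta_entropy(self.stationary_a, self.stationary_b)

    @property
    def weight(self) -> float:
        """Weight e^(-H eta) retained by the last-updated belief."""
        return math.exp(-self.H * self.eta)


@dataclass(frozen=True)
class BeliefMixture:
    """Convex mixture of a feedback-updated belief and the stationary belief.

    Weight ``weight`` on the last-updated Beta density, ``1 - weight`` on the
    stationary one; the forgetting approximation of the belief ``H`` trials
    after the last feedback.
    """

    belief: BeliefState
    stationary_a: float
    stationary_b: float
    weight: float

    @property
    def mean(self) -> float:
        rho_mean = self.stationary_a / (self.stationary_a + self.stationary_b)
        return self.weight * self.belief.theta_hat + (1 - self.weight) * rho_mean

    def pdf(self, theta):
        w = self.weight
        return (w * stats.beta.pdf(theta, self.belief.a, self.belief.b)
                + (1 - w) * stats.beta.pdf(theta, self.stationary_a,
                                           self.stationary_b))

    def equivalent_counts(self) -> tuple[float, float]:
        """Pseudo-counts interpolated toward the stationary ones.

        Moment-style surrogate used by the volatile request policy: the
        effective evidence decays toward the stationary prior at the same
        exponential rate as the density mixture.
        """
        w = self.weight
        a = self.stationary_a + w * (self.belief.a - self.stationary_a)
        b = self.stationary_b + w * (self.belief.b - self.stationary_b)
        return a, b


def volatility_discounted_belief(belief: BeliefState,
                                 vol: VolatilityParams) -> BeliefMixture:
    """Belief after ``vol.H`` feedback-free trials under diffusion ``vol.eta``.

    Returns the convex mixture ``rho + e^(-H eta) (b - rho)`` of the
    last-updated density ``b`` and the stationary density ``rho``.  ``H = 0``
    returns the belief unchanged (weight 1).
    """
    return BeliefMixture(belief=belief, stationary_a=vol.stationary_a,
                         stationary_b=vol.stationary_b, weight=vol.weight)


def volatility_delta(vol: VolatilityParams) -> float:
    """Uncertainty injected by volatility after H feedback-free trials, nats.

    ``Delta(H) = k (1 - e^(-H eta))``: zero right after feedback, rising
    monotonically toward the stationary entropy ``k``.
    """
    return vol.k * (1.0 - vol.weight)


def influence_direction(theta, valence: str):
    """Sign of a feedback point's influence on the information incentive.

    Derived from the influence function of the posterior entropy for a
    Bernoulli skill parameter: success feedback raises the incentive below
    the 0.75 crossover and lowers it above; failure feedback does the
    opposite; exactly 0.75 is neutral.
    """
    if valence not in ("success", "failure"):
        raise ValueError("valence must be 'success' or 'failure'")
    scalar = np.ndim(theta) == 0
    t = _as_array(theta, "theta")
    if np.any((t <= 0) | (t >= 1)):
        raise ValueError("theta must lie strictly inside (0, 1)")
    below = t < 0.75
    above = t > 0.75
    if valence == "success":
        out = np.where(below, "increases", np.where(above, "decreases", "neutral"))
    else:
        out = np.where(above, "increases", np.where(below, "decreases", "neutral"))
    return str(out) if scalar else out


@dataclass(frozen=True)
class InfoGainBreakdown:
    """Decomposition of the total information incentive for one trial.

    ``episodic`` and ``parametric`` are the two drives in bits (parametric is
    the signed entropy-change rate; its magnitude enters the policy);
    ``volatility_delta`` the forgetting term in bits; ``U`` the
    posterior-expected outcome entropy and ``S`` the predictive-entropy
    surprisal (bits) whose difference is minus the disagreement (BALD) term;
    ``total`` the trait/episodic/parametric mixture before clipping.
    """

    episodic: float
    parametric: float
    volatility_delta: float
    U: float
    S: float
    total: float


def infogain_breakdown(belief: BeliefState, mu: float,
                       K: float = 0.0, alpha: float = 0.0, beta: float = 0.0,
                       vol: VolatilityParams | None = None) -> InfoGainBreakdown:
    """Evaluate every information quantity entering the request policy."""
    episodic = episodic_infogain(mu)
    if vol is not None and vol.eta > 0:
        a_eff, b_eff = volatility_discounted_belief(belief, vol).equivalent_counts()
        delta_bits = max(volatility_delta(vol), 0.0) / _LN2
    else:
        a_eff, b_eff = belief.a, belief.b
        delta_bits = 0.0
    theta = a_eff / (a_eff + b_eff)
    parametric_bits = parametric_infogain(theta, a_eff + b_eff) / _LN2
    U = _expected_outcome_entropy_bits(a_eff, b_eff)
    S = binary_entropy(theta)
    total = K + alpha * episodic + beta * (abs(parametric_bits) + delta_bits)
    return InfoGainBreakdown(episodic=episodic, parametric=parametric_bits,
                             volatility_delta=delta_bits, U=U, S=S, total=total)


# --------------------------------------------------------------------------
# Task model: stimuli, schedule, psychometrics, agents
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """One colour-coded asteroid trajectory (a difficulty level)."""

    id: int
    angle: float                      # offset from midline, radians
    side: str = "right"               # nominal side of the offset
    speed: float = ASTEROID_SPEED     # px/s
    start_diameter: float = 4.6       # mm
    expansion_rate: float = 2.0       # fraction of start diameter per second

    def __post_init__(self):
        if not (0.0 < self.angle < math.pi / 2):
            raise ValueError("angle must lie in (0, pi/2)")
        if self.speed <= 0:
            raise ValueError("speed must be positive")

    def diameter(self, elapsed: float) -> float:
        """Apparent diameter (mm) after ``elapsed`` seconds; linear expansion."""
        return self.start_diameter * (1.0 + self.expansion_rate * elapsed)


def default_trajectories(angles: Sequence[float] = DEFAULT_ANGLES
                         ) -> list[TrajectorySpec]:
    """The standard ten-trajectory difficulty set."""
    return [TrajectorySpec(id=i, angle=float(a)) for i, a in enumerate(angles)]


def trajectory_offset(speed: float, elapsed: float, angle: float) -> float:
    """Horizontal deviation from the midline after ``elapsed`` seconds, px.

    ``d_x = v t tan(angle)``.
    """
    if elapsed < 0:
        raise ValueError("elapsed time must be non-negative")
    if abs(angle) >= math.pi / 2:
        raise ValueError("|angle| must be < pi/2")
    return speed * elapsed * math.tan(angle)


ScheduleEntry = tuple  # (block, trial_index, trajectory_id, side)


@dataclass
class Schedule:
    """Ordered trial schedule: balanced trajectory repetitions per block."""

    entries: list[tuple[int, int, int, str]]
    trajectories: dict[int, TrajectorySpec]
    n_blocks: int
    trials_per_block: int

    def __len__(self):
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries,
                            columns=["block", "trial_index",
                                     "trajectory_id", "side"])


def make_schedule(n_blocks: int, trials_per_block: int,
                  trajectories: Sequence[TrajectorySpec],
                  seed: int | None = None) -> Schedule:
    """Build a balanced, seed-shuffled session schedule.

    Each trajectory appears exactly ``trials_per_block / n_trajectories``
    times per block; sides are split 50/50 per trajectory across the session.
    """
    n_traj = len(trajectories)
    if n_traj == 0:
        raise ValueError("need at least one trajectory")
    reps, rem = divmod(trials_per_block, n_traj)
    if rem:
        raise ValueError(
            f"trials_per_block={trials_per_block} is not divisible by "
            f"{n_traj} trajectories (remainder {rem})")
    rng = np.random.default_rng(seed)
    total_reps = reps * n_blocks
    sides: dict[int, list[str]] = {}
    for tr in trajectories:
        half = total_reps // 2
        s = ["left"] * half + ["right"] * (total_reps - half)
        rng.shuffle(s)
        sides[tr.id] = s
    side_cursor = {tr.id: 0 for tr in trajectories}
    entries = []
    trial = 0
    for block in range(1, n_blocks + 1):
        ids = np.repeat([tr.id for tr in trajectories], reps)
        rng.shuffle(ids)
        for tid in ids:
            trial += 1
            s = sides[tid][side_cursor[tid]]
            side_cursor[tid] += 1
            entries.append((block, trial, int(tid), s))
    return Schedule(entries=entries,
                    trajectories={tr.id: tr for tr in trajectories},
                    n_blocks=n_blocks, trials_per_block=trials_per_block)


def psychometric_accuracy(angle, threshold, slope):
    """Probability of a correct steering decision at a given offset angle.

    Log-logistic psychometric function rising from chance (0.5) at zero angle
    to 1 asymptotically, calibrated so accuracy is exactly 0.75 at
    ``angle == threshold``:

        P(correct) = 0.5 + 0.5 / (1 + (angle/threshold)^(-slope))
    """
    scalar = np.ndim(angle) == 0
    a = _as_array(angle, "angle")
    if np.ndim(slope) == 0 and slope <= 0:
        raise ValueError("slope must be positive")
    if np.any(a < 0):
        raise ValueError("angle must be non-negative")
    thr = _as_array(threshold, "threshold")
    if np.any(thr <= 0):
        raise ValueError("threshold must be positive")
    with np.errstate(divide="ignore"):
        ratio = np.where(a > 0, (a / thr) ** (-np.asarray(slope, float)), np.inf)
    out = 0.5 + 0.5 / (1.0 + ratio)
    return _maybe_scalar(out, scalar)


@dataclass(frozen=True)
class AgentSpec:
    """A synthetic participant: psychometric skill plus request-policy weights.

    ``trait_rate`` (K_s) is a baseline request probability; ``episodic_weight``
    (alpha_s, probability per bit) and ``parametric_weight`` (beta_s) scale
    the two information drives; ``volatility`` (eta) is the per-trial
    forgetting rate used by the volatile policies; ``learning_halflife`` > 0
    makes accuracy ramp from chance toward the psychometric asymptote with
    that halflife (in same-trajectory encounters).
    """

    participant_id: int
    psychometric_threshold: float = 0.08
    psychometric_slope: float = 2.0
    trait_rate: float = 0.12
    episodic_weight: float = 0.28
    parametric_weight: float = 0.0
    volatility: float = 0.0
    learning_halflife: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("trait_rate", "episodic_weight", "parametric_weight"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.volatility < 0:
            raise ValueError("volatility must be non-negative")


POLICIES = ("episodic", "parametric", "volatile-parametric",
            "total", "constant", "valence")


def _request_probability(policy: str, agent: AgentSpec, mu: float,
                         belief: BeliefState, gap: int,
                         last_valence: str) -> float:
    """Pre-clip request probability for one trial under a named policy."""
    K, al, be = agent.trait_rate, agent.episodic_weight, agent.parametric_weight
    if policy == "constant":
        return K
    if policy == "episodic":
        return K + al * episodic_infogain(mu)
    if policy == "valence":
        if last_valence == "failure":
            return K + al
        if last_valence == "success":
            return K - al
        return K
    if policy in ("parametric", "volatile-parametric", "total"):
        if policy != "parametric" and agent.volatility > 0:
            vol = VolatilityParams(eta=agent.volatility, H=gap)
            a_eff, b_eff = volatility_discounted_belief(belief, vol).equivalent_counts()
        else:
            a_eff, b_eff = belief.a, belief.b
        theta = a_eff / (a_eff + b_eff)
        incentive = abs(parametric_infogain(theta, a_eff + b_eff)) / _LN2
        p = K + be * incentive
        if policy == "total":
            p += al * episodic_infogain(mu)
        return p
    raise ValueError(
        f"unknown policy {policy!r}; valid policies are {', '.join(POLICIES)}")


def simulate_session(agent: AgentSpec, schedule: Schedule, policy: str,
                     seed: int | None = None) -> pd.DataFrame:
    """Simulate one participant's full session.

    Per trial: the steering outcome is Bernoulli with the psychometric
    accuracy at that trajectory's angle (optionally ramping with the agent's
    learning halflife); the agent updates its running accuracy estimate
    ``mu`` (including the current trial); the feedback request is Bernoulli
    with the clipped policy output; the Beta skill belief is updated only on
    feedback trials.  Returns a trial table with columns ``TRIAL_COLUMNS``.
    """
    if policy not in POLICIES:
        raise ValueError(
            f"unknown policy {policy!r}; valid policies are {', '.join(POLICIES)}")
    rng = np.random.default_rng(agent.seed if seed is None else seed)
    n_corr: dict[int, int] = {}
    n_seen: dict[int, int] = {}
    beliefs: dict[int, BeliefState] = {}
    gap: dict[int, int] = {}            # same-trajectory trials since feedback
    last_valence: dict[int, str] = {}
    rows = []
    for block, trial, tid, true_side in schedule.entries:
        traj = schedule.trajectories[tid]
        p_corr = psychometric_accuracy(traj.angle, agent.psychometric_threshold,
                                       agent.psychometric_slope)
        k = n_seen.get(tid, 0)
        if agent.learning_halflife > 0:
            ramp = 1.0 - math.exp(-_LN2 * k / agent.learning_halflife)
            p_corr = 0.5 + (p_corr - 0.5) * ramp
        correct = int(rng.random() < p_corr)
        chosen = true_side if correct else ("left" if true_side == "right" else "right")
        n_seen[tid] = k + 1
        n_corr[tid] = n_corr.get(tid, 0) + correct
        mu = n_corr[tid] / n_seen[tid]
        belief = beliefs.get(tid, BeliefState())
        gap[tid] = gap.get(tid, 0) + 1
        p_req = _request_probability(policy, agent, mu, belief,
                                     gap[tid], last_valence.get(tid, "none"))
        requested = int(rng.random() < min(max(p_req, 0.0), 1.0))
        if requested:
            valence = "success" if correct else "failure"
            beliefs[tid] = belief.updated(bool(correct))
            gap[tid] = 0
            last_valence[tid] = valence
        else:
            valence = "none"
            last_valence[tid] = "none"
        rows.append((agent.participant_id, block, trial, tid, traj.angle,
                     true_side, chosen, correct, requested, valence,
                     3 if requested else 2))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def session_duration_minutes(trials: pd.DataFrame) -> float:
    """Total session duration in minutes (2 s/trial, +1 s per feedback)."""
    return float(trials["trial_duration"].sum()) / 60.0


def sample_agents(n_agents: int, seed: int | None = None, *,
                  policy_defaults: dict | None = None,
                  threshold_mean: float = 0.08, threshold_sd: float = 0.03,
                  slope_mean: float = 2.0, slope_sd: float = 0.3,
                  trait_mean: float = 0.12, trait_sd: float = 0.11,
                  episodic_mean: float = 0.28, episodic_sd: float = 0.10,
                  trait_episodic_corr: float = -0.5,
                  parametric_weight: float = 0.0, volatility: float = 0.0,
                  learning_halflife: float = 0.0) -> list[AgentSpec]:
    """Draw a cohort of agents with heterogeneous skill and policy weights.

    Defaults emulate the observed population: 75%-correct thresholds mostly
    below 0.1 rad, trait request rates centred on 0.12 with SD 0.11 and
    episodic weights centred on 0.28, with a -0.5 trait/weight correlation
    (the fixed- and random-effect estimates of the group regression).
    """
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss)
    child_seeds = ss.spawn(n_agents)
    cov = np.array([[trait_sd ** 2,
                     trait_episodic_corr * trait_sd * episodic_sd],
                    [trait_episodic_corr * trait_sd * episodic_sd,
                     episodic_sd ** 2]])
    ke = master.multivariate_normal([trait_mean, episodic_mean], cov,
                                    size=n_agents)
    agents = []
    for i in range(n_agents):
        thr = float(np.clip(master.normal(threshold_mean, threshold_sd),
                            0.02, 0.25))
        slope = float(np.clip(master.normal(slope_mean, slope_sd), 0.5, 5.0))
        K = float(np.clip(ke[i, 0], 0.0, 1.0))
        al = float(ke[i, 1])
        overrides = dict(policy_defaults or {})
        agents.append(AgentSpec(
            participant_id=i + 1, psychometric_threshold=thr,
            psychometric_slope=slope, trait_rate=overrides.get("trait_rate", K),
            episodic_weight=overrides.get("episodic_weight", al),
            parametric_weight=overrides.get("parametric_weight",
                                            parametric_weight),
            volatility=overrides.get("volatility", volatility),
            learning_halflife=overrides.get("learning_halflife",
                                            learning_halflife),
            seed=int(child_seeds[i].generate_state(1)[0] % (2 ** 31))))
    return agents


def simulate_cohort(agents: Iterable[AgentSpec], policy: str,
                    schedule: Schedule | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate a full cohort; each agent gets a fresh schedule shuffle."""
    agents = list(agents)
    ss = np.random.SeedSequence(seed)
    sched_seeds = ss.spawn(len(agents))
    frames = []
    for agent, s in zip(agents, sched_seeds):
        sched = schedule
        if sched is None:
            sched = make_schedule(8, 100, default_trajectories(),
                                  seed=int(s.generate_state(1)[0] % (2 ** 31)))
        frames.append(simulate_session(agent, sched, policy))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Synthetic aggregate-level cohort (direct linear generator)
# --------------------------------------------------------------------------

def synthetic_linear_cohort(n_agents: int = 43, *, k_mean: float = 0.10,
                            alpha: float = 0.30, subject_sd: float = 0.02,
                            slope_sd: float = 0.02, n_trials: int = 80,
                            angles: Sequence[float] = DEFAULT_ANGLES,
                            seed: int | None = None) -> pd.DataFrame:
    """Trajectory-level aggregates with a known linear request law.

    For each agent, per-trajectory accuracy is a psychometric draw observed
    through ``n_trials`` Bernoulli trials; information gain is the binary
    entropy of the observed accuracy; the request proportion is a binomial
    sample of ``clip(K_i + a_i * IG, 0, 1)`` with subject-level intercepts
    ``K_i ~ N(k_mean, subject_sd)`` and slopes ``a_i ~ N(alpha, slope_sd)``.
    Used for recovery tests of the group mixed-effects regression.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(1, n_agents + 1):
        thr = float(np.clip(rng.normal(0.08, 0.03), 0.02, 0.25))
        slope = float(np.clip(rng.normal(2.0, 0.3), 0.5, 5.0))
        K_i = rng.normal(k_mean, subject_sd)
        a_i = rng.normal(alpha, slope_sd)
        for tid, ang in enumerate(angles):
            p = psychometric_accuracy(ang, thr, slope)
            mu_hat = rng.binomial(n_trials, p) / n_trials
            ig = binary_entropy(mu_hat)
            p_req = min(max(K_i + a_i * ig, 0.0), 1.0)
            req_prop = rng.binomial(n_trials, p_req) / n_trials
            rows.append((pid, tid, ang, mu_hat, ig, req_prop, n_trials))
    return pd.DataFrame(rows, columns=["participant_id", "trajectory_id",
                                       "angle", "mu", "infogain",
                                       "request_prop", "n_trials"])


# --------------------------------------------------------------------------
# Analysis pipeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryAggregate:
    """One participant x trajectory summary row (see aggregate_by_trajectory)."""

    participant_id: int
    trajectory_id: int
    angle: float
    mu: float
    infogain: float
    request_prop: float
    n_trials: int


def aggregate_by_trajectory(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse a trial table to participant x trajectory aggregates.

    ``mu`` is the proportion correct over *all* trials at that trajectory
    (feedback and no-feedback alike); ``infogain`` its binary entropy in
    bits, the end-of-session episodic information gain; ``request_prop`` the
    proportion of trials with feedback requested.
    """
    if trials is None or len(trials) == 0:
        raise ValueError("trial table is empty")
    g = trials.groupby(["participant_id", "trajectory_id"], sort=True)
    out = g.agg(angle=("angle", "first"), mu=("correct", "mean"),
                request_prop=("feedback_requested", "mean"),
                n_trials=("correct", "size")).reset_index()
    out["infogain"] = binary_entropy(out["mu"].to_numpy())
    n_traj = trials["trajectory_id"].nunique()
    counts = out.groupby("participant_id")["trajectory_id"].nunique()
    short = counts[counts < n_traj]
    if len(short):
        warnings.warn(
            f"participants missing trajectories: {sorted(short.index.tolist())}",
            stacklevel=2)
    return out[["participant_id", "trajectory_id", "angle", "mu", "infogain",
                "request_prop", "n_trials"]]


def feedback_derived_accuracy(trials: pd.DataFrame) -> pd.DataFrame:
    """Accuracy estimated only from feedback-requested trials.

    Proportion of success valence among requested trials per participant and
    trajectory; NaN where no feedback was ever requested.
    """
    if trials is None or len(trials) == 0:
        raise ValueError("trial table is empty")
    fb = trials[trials["feedback_requested"] == 1]
    acc = (fb.assign(success=lambda d: (d["feedback_valence"] == "success")
                     .astype(float))
             .groupby(["participant_id", "trajectory_id"])["success"].mean())
    idx = pd.MultiIndex.from_frame(
        trials[["participant_id", "trajectory_id"]].drop_duplicates())
    return (acc.reindex(idx).rename("feedback_mu").reset_index()
            .sort_values(["participant_id", "trajectory_id"])
            .reset_index(drop=True))


@dataclass
class MixedModelResult:
    """Fitted group-level mixed-effects regression of requests on info gain.

    ``Y_si = beta0 + S_0s + (beta1 + S_1s) X_i + e_si`` with correlated
    by-subject random intercepts and slopes, fitted by maximum likelihood.
    """

    beta0: float
    beta1: float
    ci0: tuple[float, float]
    ci1: tuple[float, float]
    tau00: float
    tau11: float
    rho01: float
    sigma2: float
    loglik: float
    aic: float
    bic: float
    loglik_null: float
    lrt_chi2: float
    lrt_df: int
    lrt_pvalue: float
    icc: float
    r2_conditional: float
    subject_effects: pd.DataFrame = field(repr=False)
    n_subjects: int = 0
    n_obs: int = 0
    converged: bool = True
    singular: bool = False


def _fit_mixedlm(endog, exog, groups, exog_re):
    import statsmodels.regression.mixed_linear_model as mlm
    model = mlm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=500)
            if not res.converged:
                raise ValueError("not converged")
        except Exception:
            res = model.fit(reml=False, method="powell", maxiter=2000)
    return res


def fit_group_model(aggregates: pd.DataFrame) -> MixedModelResult:
    """Fit the request-proportion ~ information-gain mixed-effects model.

    ML estimation with by-subject random intercepts and slopes; the
    likelihood-ratio statistic compares against the null model lacking the
    fixed information-gain effect but keeping the full random structure.
    Wald 95% intervals.  A near-singular random-effects covariance is
    reported in ``singular`` rather than raised.
    """
    df = aggregates.dropna(subset=["infogain", "request_prop"])
    n_sub = df["participant_id"].nunique()
    if n_sub < 2:
        raise ValueError("need at least 2 participants")
    if (df.groupby("participant_id").size() < 3).any():
        raise ValueError("need at least 3 trajectory points per participant")
    y = df["request_prop"].to_numpy(float)
    x = df["infogain"].to_numpy(float)
    X = np.column_stack([np.ones_like(x), x])
    groups = df["participant_id"].to_numpy()
    res = _fit_mixedlm(y, X, groups, X)
    res_null = _fit_mixedlm(y, X[:, :1], groups, X)
    beta0, beta1 = map(float, res.fe_params)
    ci = np.asarray(res.conf_int())[:2]
    cov_re = np.asarray(res.cov_re)
    tau00 = math.sqrt(max(cov_re[0, 0], 0.0))
    tau11 = math.sqrt(max(cov_re[1, 1], 0.0))
    rho01 = float(cov_re[0, 1] / (tau00 * tau11)) if tau00 > 0 and tau11 > 0 else float("nan")
    sigma2 = float(res.scale)
    eigvals = np.linalg.eigvalsh(cov_re)
    singular = bool(eigvals.min() < 1e-8 * max(eigvals.max(), 1.0))
    lrt = max(2.0 * (res.llf - res_null.llf), 0.0)
    icc = tau00 ** 2 / (tau00 ** 2 + sigma2) if (tau00 ** 2 + sigma2) > 0 else float("nan")
    # Nakagawa-Johnson conditional R^2: fixed + random variance over total.
    var_f = float(np.var(X @ res.fe_params))
    var_r = float(np.mean(np.einsum("ij,jk,ik->i", X, cov_re, X)))
    r2c = (var_f + var_r) / (var_f + var_r + sigma2)
    re = res.random_effects
    subj = pd.DataFrame({
        "participant_id": list(re.keys()),
        "S0": [float(v.iloc[0]) for v in re.values()],
        "S1": [float(v.iloc[1]) for v in re.values()],
    })
    return MixedModelResult(
        beta0=beta0, beta1=beta1,
        ci0=(float(ci[0][0]), float(ci[0][1])),
        ci1=(float(ci[1][0]), float(ci[1][1])),
        tau00=tau00, tau11=tau11, rho01=rho01, sigma2=sigma2,
        loglik=float(res.llf), aic=float(res.aic), bic=float(res.bic),
        loglik_null=float(res_null.llf), lrt_chi2=float(lrt), lrt_df=1,
        lrt_pvalue=float(stats.chi2.sf(lrt, 1)), icc=float(icc),
        r2_conditional=float(r2c), subject_effects=subj,
        n_subjects=int(n_sub), n_obs=int(len(df)),
        converged=bool(res.converged), singular=singular)


def individual_regressions(aggregates: pd.DataFrame) -> pd.DataFrame:
    """Per-participant Pearson r and OLS slope of requests on info gain.

    Participants with zero variance in either variable (e.g. all-request or
    never-request) are flagged ``degenerate`` with NaN statistics and are
    excluded from correlation summaries downstream.
    """
    rows = []
    for pid, d in aggregates.groupby("participant_id"):
        x = d["infogain"].to_numpy(float)
        y = d["request_prop"].to_numpy(float)
        if len(d) < 3 or np.var(x) == 0 or np.var(y) == 0:
            rows.append((pid, float("nan"), float("nan"), float("nan"), True))
            continue
        slope, intercept = np.polyfit(x, y, 1)
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((pid, r, float(slope), float(intercept), False))
    return pd.DataFrame(rows, columns=["participant_id", "r", "slope",
                                       "intercept", "degenerate"])


@dataclass
class PermutationResult:
    """Monte-Carlo permutation null for participant-level correlations."""

    null_rs: np.ndarray = field(repr=False)
    mean_r: float = 0.0
    sd_r: float = 0.0
    crit_two_sided_05: float = 0.0
    empirical_rs: np.ndarray = field(default=None, repr=False)
    n_above_crit: int = 0
    n_participants: int = 0
    n_perm: int = 0


def permutation_null(aggregates: pd.DataFrame, n_perm: int = 10000,
                     seed: int | None = None) -> PermutationResult:
    """Null distribution of per-participant r under random reassignment.

    For each permutation replicate and participant, the trajectory-level
    request proportions are shuffled against the information-gain values and
    the Pearson r recorded; all replicates and participants are pooled.  The
    two-sided 5% criterion is the 97.5th percentile of |r| (the value the
    magnitude of an observed r must exceed to be significant at p < .05).
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    rng = np.random.default_rng(seed)
    emp = individual_regressions(aggregates)
    keep = emp[~emp["degenerate"]]["participant_id"]
    nulls = []
    for pid, d in aggregates.groupby("participant_id"):
        if pid not in set(keep):
            continue
        x = d["infogain"].to_numpy(float)
        y = d["request_prop"].to_numpy(float)
        k = len(y)
        xz = (x - x.mean()) / x.std()
        perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
        pz = (perms - perms.mean(axis=1, keepdims=True))
        pz /= pz.std(axis=1, keepdims=True)
        nulls.append(pz @ xz / k)
    null_rs = np.concatenate(nulls) if nulls else np.array([])
    emp_rs = emp.loc[~emp["degenerate"], "r"].to_numpy(float)
    crit = float(np.quantile(np.abs(null_rs), 0.95)) if len(null_rs) else float("nan")
    return PermutationResult(
        null_rs=null_rs, mean_r=float(null_rs.mean()),
        sd_r=float(null_rs.std()), crit_two_sided_05=crit,
        empirical_rs=emp_rs, n_above_crit=int(np.sum(emp_rs > crit)),
        n_participants=int(len(keep)), n_perm=int(n_perm))


def _prev_same_difficulty(trials: pd.DataFrame) -> pd.DataFrame:
    d = trials.sort_values(["participant_id", "trajectory_id", "trial_index"])
    g = d.groupby(["participant_id", "trajectory_id"])
    d = d.assign(prev_requested=g["feedback_requested"].shift(),
                 prev_valence=g["feedback_valence"].shift())
    return d


def conditional_request_rates(trials: pd.DataFrame, n_boot: int = 2000,
                              seed: int | None = None) -> pd.DataFrame:
    """Request rates conditioned on the previous same-difficulty trial.

    Four conditions per trajectory: previous trial requested / not requested,
    and previous feedback success / failure.  Rates are computed per
    participant then averaged; 95% CIs are a participant-level bootstrap.
    Returns a tidy frame (trajectory_id, condition, rate, ci_low, ci_high,
    n_participants); conditions never observed yield no row.
    """
    d = _prev_same_difficulty(trials)
    conds = {
        "prev_request": d["prev_requested"] == 1,
        "prev_no_request": d["prev_requested"] == 0,
        "prev_success": d["prev_valence"] == "success",
        "prev_failure": d["prev_valence"] == "failure",
    }
    rng = np.random.default_rng(seed)
    out = []
    for name, mask in conds.items():
        sub = d[mask & d["prev_requested"].notna()]
        if len(sub) == 0:
            continue
        per = (sub.groupby(["trajectory_id", "participant_id"])
               ["feedback_requested"].mean().rename("rate").reset_index())
        for tid, pd_rates in per.groupby("trajectory_id"):
            vals = pd_rates["rate"].to_numpy(float)
            boot = rng.choice(vals, size=(n_boot, len(vals)), replace=True).mean(axis=1)
            out.append((int(tid), name, float(vals.mean()),
                        float(np.quantile(boot, 0.025)),
                        float(np.quantile(boot, 0.975)), len(vals)))
    return pd.DataFrame(out, columns=["trajectory_id", "condition", "rate",
                                      "ci_low", "ci_high", "n_participants"])


def _mean_ci(values: np.ndarray, conf: float = 0.95):
    m = float(np.mean(values))
    if len(values) < 2:
        return m, float("nan"), float("nan")
    se = stats.sem(values)
    half = se * stats.t.ppf(0.5 + conf / 2, len(values) - 1)
    return m, m - half, m + half


def block_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-block mean accuracy and request rate with 95% CI across participants."""
    per = (trials.groupby(["block", "participant_id"])
           .agg(accuracy=("correct", "mean"),
                request_rate=("feedback_requested", "mean")).reset_index())
    rows = []
    for block, d in per.groupby("block"):
        acc, acc_lo, acc_hi = _mean_ci(d["accuracy"].to_numpy())
        req, req_lo, req_hi = _mean_ci(d["request_rate"].to_numpy())
        rows.append((int(block), acc, acc_lo, acc_hi, req, req_lo, req_hi,
                     len(d)))
    return pd.DataFrame(rows, columns=["block", "accuracy", "accuracy_ci_low",
                                       "accuracy_ci_high", "request_rate",
                                       "request_ci_low", "request_ci_high",
                                       "n_participants"])


def feedback_learning_rate(trials: pd.DataFrame,
                           fit_decay: bool = True) -> tuple[pd.DataFrame, dict | None]:
    """Per-block performance-improvement rate per unit of feedback requested.

    The across-participant accuracy is averaged per trial position, its
    per-trial derivative (central finite differences) is averaged within each
    block, and divided by the block's feedback-request proportion.  Blocks
    with zero requests yield NaN.  Optionally fits an exponential decay
    ``A exp(-lam (block-1)) + c`` to the normalized rates.
    """
    if trials["block"].nunique() < 2:
        raise ValueError("need at least 2 blocks")
    by_trial = (trials.groupby("trial_index")
                .agg(accuracy=("correct", "mean"), block=("block", "first")))
    deriv = np.gradient(by_trial["accuracy"].to_numpy())
    by_trial = by_trial.assign(deriv=deriv)
    per_block = by_trial.groupby("block")["deriv"].mean().rename("improvement_rate")
    req = trials.groupby("block")["feedback_requested"].mean().rename("request_prop")
    out = pd.concat([per_block, req], axis=1).reset_index()
    out["normalized_rate"] = np.where(out["request_prop"] > 0,
                                      out["improvement_rate"] / out["request_prop"],
                                      np.nan)
    decay = None
    if fit_decay:
        mask = out["normalized_rate"].notna()
        b = out.loc[mask, "block"].to_numpy(float)
        y = out.loc[mask, "normalized_rate"].to_numpy(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    lambda t, A, lam, c: A * np.exp(-lam * (t - 1)) + c,
                    b, y, p0=[max(y.max(), 1e-3), 1.0, 0.0], maxfev=10000)
            decay = {"A": float(popt[0]), "lam": float(popt[1]),
                     "c": float(popt[2])}
        except Exception:  # fit may fail on flat profiles
            decay = None
    return out, decay


@dataclass
class PCAResult:
    """Variance decomposition of the participants x difficulty request matrix."""

    variance_shares: np.ndarray
    first_loadings: np.ndarray
    n_participants: int
    constant_matrix: bool = False


def pca_request_profiles(aggregates: pd.DataFrame) -> PCAResult:
    """PCA of per-participant request-proportion profiles over difficulty.

    A dominant first component with near-uniform loadings indicates that
    overall request rate (the trait-level drive) is the main axis of
    individual differences.
    """
    mat = aggregates.pivot_table(index="participant_id",
                                 columns="trajectory_id",
                                 values="request_prop")
    if mat.isna().any().any():
        mat = mat.dropna()
    if len(mat) < 3:
        raise ValueError("need at least 3 participants with complete profiles")
    X = mat.to_numpy(float)
    if np.allclose(X.var(axis=0), 0):
        k = X.shape[1]
        return PCAResult(variance_shares=np.zeros(k),
                         first_loadings=np.full(k, np.nan),
                         n_participants=len(mat), constant_matrix=True)
    from sklearn.decomposition import PCA
    pca = PCA().fit(X)
    return PCAResult(variance_shares=pca.explained_variance_ratio_,
                     first_loadings=pca.components_[0],
                     n_participants=len(mat))


def request_hazard(trials: pd.DataFrame,
                   by_difficulty: bool = True) -> pd.DataFrame:
    """Empirical hazard of requesting feedback vs. trials since last feedback.

    The gap H counts same-trajectory trials since that trajectory's last
    feedback request (the first opportunity after feedback is H = 1); trials
    before a trajectory's first feedback are excluded (left truncation).
    ``hazard = requests at gap H / trials at risk at gap H``.
    """
    d = trials.sort_values(["participant_id", "trajectory_id", "trial_index"])
    gaps = []
    for _, g in d.groupby(["participant_id", "trajectory_id"]):
        req = g["feedback_requested"].to_numpy()
        gap = np.full(len(req), -1)
        since = None
        for i, r in enumerate(req):
            if since is not None:
                since += 1
                gap[i] = since
            if r:
                since = 0
        gaps.append(pd.DataFrame({"trajectory_id": g["trajectory_id"],
                                  "gap": gap,
                                  "requested": req}))
    dd = pd.concat(gaps, ignore_index=True)
    dd = dd[dd["gap"] > 0]
    keys = ["trajectory_id", "gap"] if by_difficulty else ["gap"]
    out = (dd.groupby(keys)
           .agg(n_at_risk=("requested", "size"), n_requests=("requested", "sum"))
           .reset_index())
    out["hazard"] = out["n_requests"] / out["n_at_risk"]
    return out


# --------------------------------------------------------------------------
# IO, configuration and end-to-end orchestration
# --------------------------------------------------------------------------

def write_trial_table(trials: pd.DataFrame, path) -> None:
    """Write a trial table as comma-separated text with the standard header."""
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a delimited-text trial table.

    Enforces the exact schema (missing/extra columns reported by name),
    binary ``correct``/``feedback_requested`` fields, and the valence
    invariant (``feedback_valence == 'none'`` iff no feedback requested);
    offending rows are reported with 1-based data line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if missing or extra:
        raise ValueError(f"trial table schema mismatch: missing columns "
                         f"{missing}, unexpected columns {extra}")
    if len(df) == 0:
        warnings.warn("trial table is empty (header only)", stacklevel=2)
        return df
    for col in ("correct", "feedback_requested"):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            lines = (df.index[bad] + 1).tolist()[:10]
            raise ValueError(f"non-binary values in {col!r} at data lines {lines}")
    inconsistent = ((df["feedback_requested"] == 0)
                    != (df["feedback_valence"] == "none"))
    if inconsistent.any():
        lines = (df.index[inconsistent] + 1).tolist()[:10]
        raise ValueError(
            f"feedback_valence inconsistent with feedback_requested at data "
            f"lines {lines}")
    return df


@dataclass
class RunConfig:
    """Parameters for one simulate-and-analyse run."""

    n_agents: int = 43
    n_blocks: int = 8
    trials_per_block: int = 100
    angles: tuple = DEFAULT_ANGLES
    policy: str = "episodic"
    n_perm: int = 10000
    master_seed: int = 0
    out_dir: str = "episeek_run"
    agent_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if min(self.n_agents, self.n_blocks, self.trials_per_block,
               self.n_perm) <= 0:
            raise ValueError("all counts must be positive")
        if list(self.angles) != sorted(set(self.angles)):
            raise ValueError("angles must be strictly increasing")
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}; "
                             f"valid: {', '.join(POLICIES)}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["angles"] = [float(a) for a in d["angles"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["angles"] = tuple(d.get("angles", DEFAULT_ANGLES))
        return cls(**d)

    def digest(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        d = asdict(self)
        d["angles"] = [float(a) for a in d["angles"]]
        d.pop("out_dir")
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one end-to-end run: config echo, seeds, file digests."""

    config: dict
    config_digest: str
    version: str
    master_seed: int
    outputs: dict
    started: str
    finished: str

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(config: RunConfig) -> RunManifest:
    """Simulate a cohort, analyse it, and write all artifacts to disk.

    Stages: simulate -> aggregate -> group model -> individual regressions ->
    permutation null -> block/hazard diagnostics -> report.  Rerunning with
    the same config reproduces the estimates exactly.
    """
    from episeek import __version__
    started = datetime.now(timezone.utc).isoformat()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.master_seed)
    agent_seed, sim_seed, perm_seed, boot_seed = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]

    stage = "simulate"
    try:
        agents = sample_agents(config.n_agents, seed=agent_seed,
                               **config.agent_params)
        trajectories = default_trajectories(config.angles)
        sched = None
        if (config.n_blocks, config.trials_per_block) != (8, 100) \
                or tuple(config.angles) != DEFAULT_ANGLES:
            sched = make_schedule(config.n_blocks, config.trials_per_block,
                                  trajectories, seed=sim_seed)
        trials = simulate_cohort(agents, config.policy, schedule=sched,
                                 seed=sim_seed)
        write_trial_table(trials, out / "trials.csv")
        pd.DataFrame([asdict(a) for a in agents]).to_csv(
            out / "agents.csv", index=False)
        log.info("simulate: %d agents, %d trials", len(agents), len(trials))

        stage = "aggregate"
        aggr = aggregate_by_trajectory(trials)
        aggr.to_csv(out / "aggregates.csv", index=False)
        log.info("aggregate: %d rows", len(aggr))

        stage = "group model"
        model = fit_group_model(aggr)

        stage = "individual regressions"
        indiv = individual_regressions(aggr)
        indiv.to_csv(out / "individual_regressions.csv", index=False)

        stage = "permutation"
        perm = permutation_null(aggr, n_perm=config.n_perm, seed=perm_seed)
        log.info("permutation: %d replicates x %d participants",
                 config.n_perm, perm.n_participants)

        stage = "diagnostics"
        blocks = block_summaries(trials)
        blocks.to_csv(out / "block_summaries.csv", index=False)
        hazard = request_hazard(trials, by_difficulty=False)
        hazard.to_csv(out / "request_hazard.csv", index=False)
        cond = conditional_request_rates(trials, seed=boot_seed)
        cond.to_csv(out / "conditional_rates.csv", index=False)

        stage = "report"
        report = {
            "master_seed": config.master_seed,
            "config_digest": config.digest(),
            "policy": config.policy,
            "n_agents": config.n_agents,
            "mixed_model": {
                "beta0": model.beta0, "beta1": model.beta1,
                "ci0": list(model.ci0), "ci1": list(model.ci1),
                "tau00": model.tau00, "tau11": model.tau11,
                "rho01": model.rho01, "sigma2": model.sigma2,
                "loglik": model.loglik, "aic": model.aic, "bic": model.bic,
                "lrt_chi2": model.lrt_chi2, "lrt_pvalue": model.lrt_pvalue,
                "icc": model.icc, "r2_conditional": model.r2_conditional,
                "singular": model.singular,
            },
            "permutation": {
                "n_perm": perm.n_perm, "mean_r": perm.mean_r,
                "sd_r": perm.sd_r,
                "crit_two_sided_05": perm.crit_two_sided_05,
                "mean_empirical_r": float(np.nanmean(perm.empirical_rs)),
                "n_above_crit": perm.n_above_crit,
                "n_participants": perm.n_participants,
            },
            "session_minutes": {
                "mean": float(trials.groupby("participant_id")
                              ["trial_duration"].sum().mean() / 60.0),
            },
        }
        (out / "report.yaml").write_text(yaml.safe_dump(report, sort_keys=False))
        config.to_yaml(out / "config.yaml")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}; partial outputs in {out}"
        ) from exc

    files = ["trials.csv", "agents.csv", "aggregates.csv",
             "individual_regressions.csv", "block_summaries.csv",
             "request_hazard.csv", "conditional_rates.csv",
             "report.yaml", "config.yaml"]
    manifest = RunManifest(
        config={**asdict(config), "angles": [float(a) for a in config.angles]},
        config_digest=config.digest(), version=__version__,
        master_seed=config.master_seed,
        outputs={f: _sha256(out / f) for f in files},
        started=started, finished=datetime.now(timezone.utc).isoformat())
    manifest.to_yaml(out / "manifest.yaml")
    return manifest
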
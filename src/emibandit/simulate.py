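"""Synthetic cohorts and bandit episodes with the statistical structure the
study design assumes.

Two generators serve two different purposes:

* :func:`simulate_cohort` is mechanistic: it plays the whole daily loop
  (evening Thompson ranking -> selection -> next-evening review, morning mood
  and weight) for a 20-participant, 28-day cohort and emits a study log that
  exercises every parsing, pairing and scoring rule downstream.  Completion of
  behavior k on day t is Bernoulli with logit(p) = logit(p_k) +
  depression_effect * depression_t, so a depressive-mood -> fewer-behaviors
  association is built in.

* :func:`generate_lmm_dataset` generates the outcome *directly* from the
  two-level mixed-model equations (random intercept and depression slope, a
  cross-level depression x psychiatric-comorbidity interaction), so parameter
  recovery can be checked against the exact generating model.

:func:`run_bandit_episode` is the evaluation harness for the recommender
itself (regret against an oracle that always picks the most achievable
behavior), and :func:`suggestion_diversity` quantifies how many distinct
behaviors appear near the top of the list over a window -- the observable the
"monotony" usability finding corresponds to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bandit import (
    BehaviorArm,
    UpdatePolicy,
    UserBanditState,
    apply_review,
    rank_behaviors,
    update_arm,
)
from .events import (
    ANALYSIS_COLUMNS,
    EventLog,
    MoodObservation,
    PairedRecord,
    ReviewEvent,
    SetEvent,
    WeightObservation,
)

__all__ = [
    "SimParams",
    "LmmGenParams",
    "Trajectory",
    "simulate_cohort",
    "generate_lmm_dataset",
    "run_bandit_episode",
    "suggestion_diversity",
]


@dataclass(frozen=True)
class SimParams:
    """Generating conditions for the mechanistic cohort simulator.

    Defaults emulate the study design: 20 participants, 28 days, daily mood on
    nine 0-100 visual-analog items collapsing to three subscales, daily
    weight, and ~5% missing review days (which puts simulated use rates in
    the 90-100% band the feasibility benchmark targets).
    """

    n_participants: int = 20
    n_days: int = 28
    catalog_size: int = 10
    #: fixed per-behavior latent completion probabilities; None draws each
    #: user's vector from Beta(2, 2) (a free modeling choice -- the study
    #: reports no achievability distribution)
    true_completion_probs: tuple[float, ...] | None = None
    #: per-subscale clamped-AR(1) mood dynamics: (mean, autocorrelation,
    #: innovation SD), on the [0, 1] subscale scale
    mood_ar1: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "depression": (0.30, 0.6, 0.10),
            "anxiety": (0.30, 0.6, 0.10),
            "positive_affect": (0.55, 0.6, 0.10),
        }
    )
    #: SD of the 0-100 item-level scatter around 100 x subscale value
    mood_item_sd: float = 10.0
    #: logit-scale coefficient of same-day depression on completion
    depression_effect: float = -1.5
    #: geometric attention: item at display rank r (1-based) is selected with
    #: probability decay^(r-1); decay 0.65 gives ~3 selections per evening
    selection_decay: float = 0.65
    missing_review_prob: float = 0.05
    #: (baseline mean kg, baseline SD kg, drift kg/day, noise SD kg)
    weight_trajectory: tuple[float, float, float, float] = (93.6, 15.0, -0.02, 0.3)
    psych_comorbidity_prob: float = 0.3
    include_extras_prob: float = 0.0  # chance of logging one ad-hoc behavior
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.n_participants < 1 or self.catalog_size < 1:
            raise ValueError("cohort dimensions must be >= 1")
        if not 0.0 <= self.missing_review_prob <= 1.0:
            raise ValueError("missing_review_prob must lie in [0, 1]")
        if self.true_completion_probs is not None and any(
            not 0.0 <= p <= 1.0 for p in self.true_completion_probs
        ):
            raise ValueError("completion probabilities must lie in [0, 1]")


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _ar1_path(rng, n, mean, rho, sd) -> np.ndarray:
    """Clamped AR(1) on [0, 1], started at its stationary distribution."""
    x = np.empty(n)
    stat_sd = sd / np.sqrt(max(1.0 - rho**2, 1e-12)) if rho < 1 else sd
    x[0] = np.clip(mean + stat_sd * rng.standard_normal(), 0.0, 1.0)
    for t in range(1, n):
        x[t] = np.clip(
            mean + rho * (x[t - 1] - mean) + sd * rng.standard_normal(), 0.0, 1.0
        )
    return x


def simulate_cohort(params: SimParams = SimParams()) -> EventLog:
    """Play the daily set/review loop for a whole cohort; return a study log.

    Per participant-day: morning weight (07:00) and mood (09:00), an evening
    (20:00) review of the previous evening's selection (omitted with
    ``missing_review_prob``; skipped reviews leave the bandit counters
    untouched), then a fresh Thompson ranking and selection for the next day
    (20:30).  Reviews land 23.5 h after their set event, inside the strict
    12-36 h pairing window.  Each participant runs an independent bandit
    seeded from the cohort seed; per-user seeds are recorded in the header.
    """
    master = np.random.default_rng(params.seed)
    start = datetime(2024, 1, 1, tzinfo=timezone.utc)
    log = EventLog()
    mean_w, sd_w, drift_w, noise_w = params.weight_trajectory

    for u in range(params.n_participants):
        uid = f"P{u + 1:02d}"
        user_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(user_seed)
        arm_ids = [f"B{k + 1:02d}" for k in range(params.catalog_size)]
        if params.true_completion_probs is not None:
            p_k = np.asarray(params.true_completion_probs, dtype=float)
            if len(p_k) != params.catalog_size:
                raise ValueError("true_completion_probs length != catalog_size")
        else:
            p_k = rng.beta(2.0, 2.0, size=params.catalog_size)
        state = UserBanditState(uid, seed=user_seed)
        for a in arm_ids:
            state.add_arm(a)

        log.users[uid] = {
            "timezone": "UTC",
            "bandit_seed": user_seed,
            "sex": int(rng.integers(0, 2)),
            "bmi_start": float(np.round(rng.normal(36.0, 5.0), 1)),
            "psych_comorbidity": int(rng.random() < params.psych_comorbidity_prob),
        }

        mood = {
            name: _ar1_path(rng, params.n_days + 1, *law)
            for name, law in params.mood_ar1.items()
        }
        baseline_w = max(40.0, rng.normal(mean_w, sd_w))

        pending: SetEvent | None = None
        for day in range(params.n_days + 1):
            day0 = start + timedelta(days=day)
            if day <= params.n_days:
                # morning weight, 07:00
                w = baseline_w + drift_w * day + noise_w * rng.standard_normal()
                log.events.append(
                    WeightObservation(uid, day0 + timedelta(hours=7), round(w, 2))
                )
                # morning mood, 09:00 -- items scatter around the subscale level
                items: list[float] = []
                for name in ("depression", "anxiety", "positive_affect"):
                    level = 100.0 * mood[name][day]
                    items.extend(
                        float(np.clip(level + params.mood_item_sd * z, 0.0, 100.0))
                        for z in rng.standard_normal(3)
                    )
                log.events.append(
                    MoodObservation(uid, day0 + timedelta(hours=9), tuple(items))
                )

            # evening review of yesterday's selection, 20:00
            if pending is not None and rng.random() >= params.missing_review_prob:
                dep = mood["depression"][day]
                performed = {}
                for arm_id in pending.selected:
                    k = arm_ids.index(arm_id)
                    p = _expit(_logit(p_k[k : k + 1]) + params.depression_effect * dep)
                    performed[arm_id] = bool(rng.random() < p[0])
                extras: tuple[str, ...] = ()
                if params.include_extras_prob and rng.random() < params.include_extras_prob:
                    pool = [a for a in arm_ids if a not in pending.selected]
                    if pool:
                        extras = (pool[int(rng.integers(len(pool)))],)
                review = ReviewEvent(
                    uid, day0 + timedelta(hours=20), performed, extras
                )
                log.events.append(review)
                rec = PairedRecord(
                    set_event=pending,
                    review_event=review,
                    gap_hours=(review.timestamp - pending.timestamp).total_seconds()
                    / 3600.0,
                    week_index=(day - 1) // 7 + 1,
                )
                apply_review(state, rec, UpdatePolicy(include_extras=False))
            pending = None

            # evening selection for tomorrow, 20:30
            if day < params.n_days:
                suggestion = rank_behaviors(state, at=day0 + timedelta(hours=20, minutes=30))
                selected = [
                    arm_id
                    for r, arm_id in enumerate(suggestion.arm_ids)
                    if rng.random() < params.selection_decay**r
                ]
                if not selected:  # a user always picks at least the top item
                    selected = [suggestion.arm_ids[0]]
                pending = SetEvent(uid, suggestion.draw_timestamp, tuple(selected))
                log.events.append(pending)
    return log


# ---------------------------------------------------------------------------
# direct generation from the two-level model


@dataclass(frozen=True)
class LmmGenParams:
    """Generating coefficients for the two-level model

        Y_ij     = Pi_0i + Pi_1i * Depression_ij + eps_ij
        Pi_0i    = gamma00 + zeta0_i
        Pi_1i    = gamma10 + gamma11 * Psych_i + zeta1_i

    Default fixed effects are the study-scale values (intercept 4.45,
    depression slope -1.88, depression x psychiatric-comorbidity 1.59).
    Random effects zeta0, zeta1 are drawn independently.
    """

    gamma00: float = 4.45
    gamma10: float = -1.88
    gamma11: float = 1.59
    sd_zeta0: float = 2.0
    sd_zeta1: float = 1.0
    sd_eps: float = 1.5
    n_participants: int = 20
    obs_per_participant: int = 22
    #: Beta(a, b) law for Depression_ij on [0, 1]
    depression_beta: tuple[float, float] = (2.0, 5.0)
    psych_prob: float = 0.3
    #: fix Depression at a constant instead of drawing it (noise-free checks)
    depression_fixed: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_zeta0, self.sd_zeta1, self.sd_eps) < 0:
            raise ValueError("SDs must be >= 0")


def generate_lmm_dataset(params: LmmGenParams = LmmGenParams()) -> pd.DataFrame:
    """Draw one dataset exactly from the two-level equations.

    Returns a frame with the analysis-table schema (columns irrelevant to the
    generating model are NaN), so it flows through the same fitting code as a
    real export.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for i in range(params.n_participants):
        uid = f"S{i + 1:02d}"
        psych = int(rng.random() < params.psych_prob)
        z0 = params.sd_zeta0 * rng.standard_normal()
        z1 = params.sd_zeta1 * rng.standard_normal()
        pi0 = params.gamma00 + z0
        pi1 = params.gamma10 + params.gamma11 * psych + z1
        for j in range(params.obs_per_participant):
            if params.depression_fixed is not None:
                dep = float(params.depression_fixed)
            else:
                dep = float(rng.beta(*params.depression_beta))
            y = pi0 + pi1 * dep + params.sd_eps * rng.standard_normal()
            rows.append({
                "user_id": uid, "day": j + 1, "week": j // 7 + 1, "y": y,
                "depression": dep, "anxiety": np.nan, "positive_affect": np.nan,
                "delta_weight_baseline": np.nan, "delta_weight_previous": np.nan,
                "sex": np.nan, "bmi_centered": np.nan,
                "psych_comorbidity": psych,
            })
    return pd.DataFrame(rows, columns=ANALYSIS_COLUMNS)


# ---------------------------------------------------------------------------
# bandit evaluation harness


@dataclass
class Trajectory:
    """Per-round record of one simulated single-selection bandit episode."""

    arm_ids: tuple[str, ...]
    true_probs: tuple[float, ...]
    selections: list[str] = field(default_factory=list)
    completions: list[bool] = field(default_factory=list)
    regrets: list[float] = field(default_factory=list)
    rankings: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len(self.selections)

    @property
    def cumulative_regret(self) -> float:
        return float(np.sum(self.regrets))


def run_bandit_episode(
    true_probs: Sequence[float],
    n_rounds: int,
    policy: str = "thompson",
    seed: int = 0,
) -> Trajectory:
    """Simulate a user who each round adopts one behavior and reviews it.

    ``policy`` is "thompson" (select the top-ranked arm of a fresh Thompson
    draw) or "uniform_random" (select an arm uniformly; the recorded ranking
    is a uniform random permutation).  Completion is Bernoulli in the arm's
    true probability; per-round regret is max(true_probs) minus the selected
    arm's true probability.
    """
    if len(true_probs) < 1 or n_rounds < 1:
        raise ValueError("need >= 1 arm and >= 1 round")
    if policy not in ("thompson", "uniform_random"):
        raise ValueError(f"unknown policy {policy!r}")
    arm_ids = tuple(f"A{k + 1:02d}" for k in range(len(true_probs)))
    probs = dict(zip(arm_ids, (float(p) for p in true_probs)))
    best = max(probs.values())
    state = UserBanditState("sim", seed=seed)
    for a in arm_ids:
        state.add_arm(a)
    rng = np.random.default_rng([seed, 2**30])  # environment stream, distinct
    traj = Trajectory(arm_ids=arm_ids, true_probs=tuple(probs[a] for a in arm_ids))
    for _ in range(n_rounds):
        if policy == "thompson":
            ranking = rank_behaviors(state).arm_ids
        else:
            ranking = tuple(np.array(arm_ids)[rng.permutation(len(arm_ids))])
        chosen = ranking[0]
        completed = bool(rng.random() < probs[chosen])
        state.arms[chosen] = update_arm(state.arms[chosen], completed)
        traj.selections.append(chosen)
        traj.completions.append(completed)
        traj.regrets.append(best - probs[chosen])
        traj.rankings.append(ranking)
    return traj


def suggestion_diversity(
    trajectory: Trajectory,
    window_days: int,
    start: int | None = None,
    top_k: int = 3,
) -> int:
    """Count distinct arms appearing in the top ``top_k`` of the ranking over
    a window of rounds.

    ``start`` is the first round of the window (default: the final
    ``window_days`` rounds).  A shrinking count over the study is the
    signature of algorithm convergence -- the "always the same few items"
    monotony that long-running users report.
    """
    n = len(trajectory.rankings)
    if window_days < 1 or window_days > n:
        raise ValueError(f"window of {window_days} rounds does not fit {n} rounds")
    if start is None:
        start = n - window_days
    if start < 0 or start + window_days > n:
        raise ValueError("window exceeds trajectory bounds")
    seen: set[str] = set()
    for ranking in trajectory.rankings[start : start + window_days]:
        seen.update(ranking[:top_k])
    return len(seen)
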
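"""Per-user Thompson-sampling recommender over daily health behaviors.

Each behavior a user can choose (an *arm*) accumulates two counters: ``N``,
the number of times the behavior was selected and subsequently reviewed, and
``a``, the number of those reviews on which it was actually performed.  Under
a uniform Beta(1, 1) prior the completion probability of the arm has posterior

    theta | a, N  ~  Beta(a + 1, N - a + 1)

which is the normalised density  p(theta | a, N) ∝ theta^a (1 - theta)^(N-a).
An evening's suggestion list is produced by drawing one theta per arm from its
posterior and sorting the arms by the drawn score, descending: arms with few
selections have high-variance posteriors and get shuffled upward at random
(exploration), while well-observed, frequently completed arms float to the top
(exploitation).  Every participant has an independent model built only from
their own review history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BehaviorArm",
    "UserBanditState",
    "RankedSuggestion",
    "UpdatePolicy",
    "CorruptStateError",
    "EmptyCatalogError",
    "CatalogMismatchError",
    "posterior_params",
    "posterior_mean",
    "sample_theta",
    "rank_behaviors",
    "update_arm",
    "apply_review",
]


class CorruptStateError(ValueError):
    """An arm's counters violate 0 <= n_completed <= n_selected."""


class EmptyCatalogError(ValueError):
    """A ranking was requested for a user with no registered behaviors."""


class CatalogMismatchError(KeyError):
    """A review references an arm_id absent from the user's catalog."""


@dataclass(frozen=True)
class BehaviorArm:
    """Selection/completion counters for one behavior.

    ``n_selected`` is N (times selected and reviewed), ``n_completed`` is a
    (times actually performed).  Counters only ever increment.
    """

    arm_id: str
    n_selected: int = 0
    n_completed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_completed <= self.n_selected):
            raise CorruptStateError(
                f"arm {self.arm_id!r}: need 0 <= a <= N, got "
                f"a={self.n_completed}, N={self.n_selected}"
            )


@dataclass(frozen=True)
class UpdatePolicy:
    """Controls whether ad-hoc extra behaviors logged at review time update
    arm counters.  The default is conservative: N is defined as the number of
    times the user *selects* the item, so extras do not count as selections.
    Setting ``include_extras`` treats an extra as selected-and-completed."""

    include_extras: bool = False


@dataclass(frozen=True)
class RankedSuggestion:
    """One evening's Thompson draw: arms ordered by sampled score."""

    ranking: tuple[tuple[str, float], ...]
    draw_timestamp: datetime

    @property
    def arm_ids(self) -> tuple[str, ...]:
        return tuple(arm_id for arm_id, _ in self.ranking)

    def top(self, k: int) -> tuple[str, ...]:
        return self.arm_ids[:k]


@dataclass
class UserBanditState:
    """One participant's independent bandit model.

    The random stream is defined by ``seed`` plus a monotonically increasing
    ``draw_count``: ranking call ``i`` uses ``default_rng([seed, i])``.  This
    makes the whole ranking sequence bit-reproducible from the seed and makes
    the state trivially and losslessly JSON-serialisable.
    """

    user_id: str
    arms: dict[str, BehaviorArm] = field(default_factory=dict)
    seed: int = 0
    draw_count: int = 0

    def add_arm(self, arm_id: str) -> None:
        """Register a behavior (predefined or user-created) with the uniform
        prior, i.e. N = a = 0."""
        if arm_id in self.arms:
            raise ValueError(f"duplicate arm_id {arm_id!r} for user {self.user_id!r}")
        self.arms[arm_id] = BehaviorArm(arm_id)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "seed": int(self.seed),
            "draw_count": int(self.draw_count),
            "arms": [
                {
                    "arm_id": a.arm_id,
                    "n_selected": a.n_selected,
                    "n_completed": a.n_completed,
                }
                for a in sorted(self.arms.values(), key=lambda a: a.arm_id)
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "UserBanditState":
        arms = {
            a["arm_id"]: BehaviorArm(a["arm_id"], a["n_selected"], a["n_completed"])
            for a in d["arms"]
        }
        if len(arms) != len(d["arms"]):
            raise ValueError("duplicate arm_ids in serialized state")
        return cls(
            user_id=d["user_id"],
            arms=arms,
            seed=int(d["seed"]),
            draw_count=int(d["draw_count"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "UserBanditState":
        return cls.from_dict(json.loads(s))


def posterior_params(arm: BehaviorArm) -> tuple[float, float]:
    """Beta posterior parameters (alpha, beta) = (a + 1, N - a + 1)."""
    return float(arm.n_completed + 1), float(arm.n_selected - arm.n_completed + 1)


def posterior_mean(arm: BehaviorArm) -> float:
    """Posterior mean completion probability, (a + 1) / (N + 2).

    Converges to the empirical completion rate a / N as N grows.
    """
    return (arm.n_completed + 1) / (arm.n_selected + 2)


def sample_theta(arm: BehaviorArm, rng: np.random.Generator) -> float:
    """One Thompson draw from the arm's beta posterior."""
    alpha, beta = posterior_params(arm)
    return float(rng.beta(alpha, beta))


def update_arm(arm: BehaviorArm, completed: bool) -> BehaviorArm:
    """Record one reviewed selection: N += 1, and a += 1 iff completed."""
    return replace(
        arm,
        n_selected=arm.n_selected + 1,
        n_completed=arm.n_completed + int(completed),
    )


def rank_behaviors(
    state: UserBanditState, at: datetime | None = None
) -> RankedSuggestion:
    """Produce one evening's ranked suggestion list via Thompson sampling.

    Draws one fresh theta per arm (never cached across calls), sorts arms by
    theta descending with deterministic lexicographic tie-breaking on arm_id,
    and advances the user's draw counter.  The full catalog is always ranked;
    top-K truncation is the caller's presentation concern.
    """
    if not state.arms:
        raise EmptyCatalogError(f"user {state.user_id!r} has no behaviors to rank")
    rng = np.random.default_rng([state.seed, state.draw_count])
    state.draw_count += 1
    # iterate in sorted arm_id order so draws do not depend on dict insertion
    scored = [
        (arm_id, sample_theta(state.arms[arm_id], rng))
        for arm_id in sorted(state.arms)
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    ts = at if at is not None else datetime.now(timezone.utc)
    return RankedSuggestion(ranking=tuple(scored), draw_timestamp=ts)


def apply_review(
    state: UserBanditState,
    record,
    policy: UpdatePolicy = UpdatePolicy(),
) -> UserBanditState:
    """Fold one paired set/review record into the user's arm counters.

    Every preselected behavior counts as one selection, completed or not;
    extras (ad-hoc behaviors logged at review time) update their arms as
    selected-and-completed only when ``policy.include_extras`` is set.  Arms
    not referenced by the record are untouched.

    ``record`` is a :class:`emibandit.events.PairedRecord` (duck-typed: any
    object with ``set_event.selected``, ``review_event.performed`` and
    ``review_event.extras`` works).
    """
    review = record.review_event
    if review.user_id != state.user_id:
        raise CatalogMismatchError(
            f"record for user {review.user_id!r} applied to state of "
            f"{state.user_id!r}"
        )
    touched = list(record.set_event.selected)
    if policy.include_extras:
        touched += list(review.extras)
    missing = [a for a in touched if a not in state.arms]
    if missing:
        raise CatalogMismatchError(
            f"unknown arm_id(s) {missing} for user {state.user_id!r}; "
            "register user-created behaviors before applying reviews"
        )
    for arm_id in record.set_event.selected:
        completed = bool(review.performed.get(arm_id, False))
        state.arms[arm_id] = update_arm(state.arms[arm_id], completed)
    if policy.include_extras:
        for arm_id in review.extras:
            state.arms[arm_id] = update_arm(state.arms[arm_id], True)
    return state
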
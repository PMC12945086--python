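"""One user's recommender over four simulated weeks.

Builds a small behavior catalog, replays 28 evenings of select -> review
against latent per-behavior completion probabilities, and prints how the
Thompson ranking reorders as evidence accumulates: achievable behaviors
drift to the top, rarely completed ones sink.
"""

import numpy as np

from emibandit import (
    BehaviorArm,
    UserBanditState,
    posterior_mean,
    rank_behaviors,
    update_arm,
)

TRUE_PROBS = {
    "walk-30min": 0.85,
    "no-late-snack": 0.60,
    "take-stairs": 0.75,
    "cook-dinner": 0.35,
    "gym-session": 0.15,
}

state = UserBanditState("demo-user", seed=7)
for behavior in TRUE_PROBS:
    state.add_arm(behavior)

env = np.random.default_rng(99)
for day in range(28):
    suggestion = rank_behaviors(state)
    # the user adopts the top two suggestions and reviews them next evening
    for behavior in suggestion.top(2):
        completed = env.random() < TRUE_PROBS[behavior]
        state.arms[behavior] = update_arm(state.arms[behavior], completed)
    if day in (0, 6, 27):
        print(f"evening of day {day + 1}:")
        for behavior, theta in suggestion.ranking:
            arm = state.arms[behavior]
            print(
                f"  {behavior:14s} sampled score {theta:.3f}  "
                f"(N={arm.n_selected:2d}, a={arm.n_completed:2d}, "
                f"posterior mean {posterior_mean(arm):.2f})"
            )
        print()

print("after 4 weeks the posterior means track the true completion rates;")
print("the sampled scores still jitter, which is what keeps exploring alive.")
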
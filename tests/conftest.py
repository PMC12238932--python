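import numpy as np
import pytest

from fodisc.staircase import StaircaseConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def replay_threshold(corrects, cfg: StaircaseConfig, k: int = 4):
    """Independent brute-force recomputation of the staircase threshold.

    Replays the transformed up-down rule over a sequence of correct flags
    as a flat event list, then extracts direction-change levels by sign
    comparison.  Returns (reversal_levels, mean of last k or None).
    """
    level = cfg.initial_shift_cents
    consec = 0
    events = []  # (level before adjustment, signed delta)
    for c in corrects:
        if c:
            consec += 1
            if consec == cfg.n_down:
                consec = 0
                new = max(level - cfg.step_cents, cfg.min_shift_cents)
                if new != level:
                    events.append((level, new - level))
                level = new
        else:
            consec = 0
            events.append((level, +cfg.step_cents))
            level += cfg.step_cents
    reversals = [
        events[i][0]
        for i in range(1, len(events))
        if np.sign(events[i][1]) != np.sign(events[i - 1][1])
    ]
    if len(reversals) < k:
        return reversals, None
    return reversals, float(np.mean(reversals[-k:]))
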
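import math

import pytest

from neurochoice.session_data import Session, Trial, opposite_side


def make_trial(
    i,
    qA=1,
    qB=2,
    side_of_A="left",
    stim="OFF",
    chosen_juice="A",
    is_error=False,
    aborted=False,
):
    """Convenience constructor keeping chosen_side consistent with side_of_A."""
    if aborted:
        return Trial(i, qA, qB, side_of_A, stim, "none", "none", False,
                     0.5, 3.3, math.nan)
    if chosen_juice == "A":
        chosen_side = side_of_A
    else:
        chosen_side = opposite_side(side_of_A)
    return Trial(i, qA, qB, side_of_A, stim, chosen_juice, chosen_side,
                 is_error, 0.5, 3.3, 3.6)


@pytest.fixture
def tiny_session():
    """Three completed choice trials over two offer types."""
    trials = [
        make_trial(0, 1, 2, "left", chosen_juice="B"),
        make_trial(1, 1, 3, "right", chosen_juice="B"),
        make_trial(2, 2, 1, "left", chosen_juice="A"),
    ]
    return Session(mouse_id="m00", trials=trials)
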
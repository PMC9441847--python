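"""Design constants of the original large-scale enumeration study.

The synthetic cohort generator emulates this design: 227 third-to-fifth
graders in two groups (164 hearing, 63 deaf or hard-of-hearing) each
attempted the 36-item battery; the four 1-dot items are excluded from
process analysis, leaving 32 analyzable trials per participant.  The
published per-condition analyzed-trial counts and the dice-five worked
example are kept here as reference inputs for validation arithmetic -
they are reported values, not quantities this package can recompute
without the original raw gaze recordings.
"""
from __future__ import annotations

import numpy as np

from .stimuli import Condition

N_HEARING = 164
N_DHH = 63
N_PARTICIPANTS = N_HEARING + N_DHH      # 227

N_ITEMS = 36
N_EXCLUDED_ITEMS = 4                    # the four 1-dot items
N_ANALYZABLE_ITEMS = N_ITEMS - N_EXCLUDED_ITEMS  # 32 per participant

# analyzed (correct-response) trial counts per condition, as published
REPORTED_CONDITION_COUNTS: dict[Condition, int] = {
    Condition.SUBITIZING_RANDOM: 1961,
    Condition.COUNTING_RANDOM: 2972,
    Condition.DICE_CANONICAL: 1084,
    Condition.BEYOND_DICE_CANONICAL: 598,
}
REPORTED_USABLE_HEATMAPS = 6615
REPORTED_TOTAL_TRIALS = 7264

# dice-five worked example: process (rows 1-3) x group (DHH, hearing)
DICE_FIVE_TABLE = np.array([[33, 82], [24, 62], [1, 13]])
DICE_FIVE_GROUPS = ("dhh", "hearing")
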
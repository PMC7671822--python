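"""Health states of the long-term cohort model.

Four implanted states cross optimal / sub-optimal pain relief with the
presence of a non-serious complication in the current cycle; two states
cover patients on conventional medical management alone (with or without
perceived relief, the latter including reverts after device explant); death
from all-cause mortality is absorbing.
"""

from __future__ import annotations

from enum import IntEnum

__all__ = ["State", "N_STATES", "SCS_STATES", "CMM_STATES", "STATE_LABELS"]


class State(IntEnum):
    SCS_OPT_NC = 0
    SCS_OPT_C = 1
    SCS_SUBOPT_NC = 2
    SCS_SUBOPT_C = 3
    CMM_OPT = 4
    CMM_NO_RELIEF = 5
    DEAD = 6


N_STATES = len(State)
SCS_STATES = (State.SCS_OPT_NC, State.SCS_OPT_C, State.SCS_SUBOPT_NC, State.SCS_SUBOPT_C)
CMM_STATES = (State.CMM_OPT, State.CMM_NO_RELIEF)
STATE_LABELS = {s: s.name for s in State}
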
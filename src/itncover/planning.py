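"""Net-procurement planning arithmetic.

Campaign planning assumes access scales linearly with nets-per-capita at a
slope of 1.8 (one net protects two people, discounted for odd household
sizes): procuring one net per 1.8 people at risk — 0.56 NPC — is the
standard quantity expected to deliver universal access. The saturating
allocation model in :mod:`itncover.synth` shows why realised access falls
short of this line at high NPC.
"""

from __future__ import annotations

import numpy as np

__all__ = ["linear_access", "procurement_npc", "PLANNING_SLOPE"]

#: people covered per net assumed by population-based procurement
PLANNING_SLOPE = 1.8


def linear_access(npc, slope: float = PLANNING_SLOPE):
    """Access predicted by the linear planning assumption: ``min(1, slope * npc)``."""
    return np.minimum(slope * np.asarray(npc, dtype=float), 1.0)


def procurement_npc(people_per_net: float = PLANNING_SLOPE) -> float:
    """Nets-per-capita implied by procuring one net per ``people_per_net`` people."""
    if people_per_net <= 0:
        raise ValueError("people_per_net must be > 0")
    return 1.0 / people_per_net
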
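"""Direction-aware intersection of the two contexts' differential-expression calls.

The Venn step of the study: genes "overlap" when they are differentially
expressed in both contexts with the same direction (shared_up / shared_down);
features DE in both contexts with opposite directions are kept separately as
``discordant``.  For miRNAs the downstream analysis treats DE-in-both as
overlapped regardless of direction (the discordant pair miR-23a/23b is
retained in the original study), so callers take shared_up | shared_down |
discordant as the miRNA overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd


@dataclass(frozen=True)
class OverlapResult:
    """Partition of two contexts' DE calls into five pairwise-disjoint sets."""

    shared_up: frozenset[str]
    shared_down: frozenset[str]
    discordant: frozenset[str]
    only_ctx1: frozenset[str]
    only_ctx2: frozenset[str]

    @property
    def concordant(self) -> frozenset[str]:
        """The 'overlapping' set in the direction-aware (gene) sense."""
        return self.shared_up | self.shared_down

    @property
    def de_both(self) -> frozenset[str]:
        """DE in both contexts regardless of direction (the miRNA sense)."""
        return self.concordant | self.discordant

    def summary(self) -> pd.DataFrame:
        rows = [
            ("shared_up", self.shared_up),
            ("shared_down", self.shared_down),
            ("discordant", self.discordant),
            ("only_ctx1", self.only_ctx1),
            ("only_ctx2", self.only_ctx2),
        ]
        return pd.DataFrame(
            {
                "category": [name for name, _ in rows],
                "count": [len(s) for _, s in rows],
                "members": [";".join(sorted(s)) for _, s in rows],
            }
        )


def concordant_overlap(
    de_ctx1: Mapping[str, str], de_ctx2: Mapping[str, str]
) -> OverlapResult:
    """Partition two feature->direction maps (direction in {'up','down'}).

    shared_up/shared_down hold features DE in both contexts with matching
    direction; discordant holds both-DE features whose directions differ.
    """
    s1, s2 = set(de_ctx1), set(de_ctx2)
    both = s1 & s2
    shared_up = {f for f in both if de_ctx1[f] == "up" and de_ctx2[f] == "up"}
    shared_down = {f for f in both if de_ctx1[f] == "down" and de_ctx2[f] == "down"}
    discordant = both - shared_up - shared_down
    return OverlapResult(
        shared_up=frozenset(shared_up),
        shared_down=frozenset(shared_down),
        discordant=frozenset(discordant),
        only_ctx1=frozenset(s1 - both),
        only_ctx2=frozenset(s2 - both),
    )
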
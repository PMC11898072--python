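"""The NABh consensus index and its confidence tiers.

For a segment scored by an ensemble of n members, the NABh index is the
number of positive (TRUE) per-model calls divided by n. With the 8-member
core the index lives on the 9-point lattice {0, 0.125, ..., 1}: 1.0 means
unanimous identification, 0.875 agreement among seven models and 0.75
agreement among six. Segments at 1.0 are *strong* candidates, segments in
[0.75, 1.0) are *likely*, and anything below the reporting threshold of
0.75 is considered *unreliable*.

Votes are hard per-model class calls (each family's native 0.5 / sign
decision rule), never averaged probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from nabh.helix_scan import HelixSegment

TIERS = ("strong", "likely", "unreliable")

DEFAULT_THRESHOLD = 0.75


def nabh_index(P: Sequence[bool]) -> float:
    """Fraction of positive votes: sum(P_i) / n."""
    if len(P) == 0:
        raise ValueError("vote vector must be non-empty")
    return sum(bool(p) for p in P) / len(P)


def classify_tier(I: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Map an index to its confidence tier.

    ``strong`` iff I == 1.0 (unanimous); ``likely`` for threshold <= I < 1;
    ``unreliable`` below the reporting threshold (default 0.75).
    """
    if not 0.0 <= I <= 1.0:
        raise ValueError("NABh index must lie in [0, 1]")
    if I == 1.0:
        return "strong"
    if I >= threshold:
        return "likely"
    return "unreliable"


@dataclass(frozen=True)
class PredictionResult:
    """Per-segment consensus outcome: member votes, index and tier."""

    segment: HelixSegment
    votes: tuple[bool, ...]
    index: float
    tier: str

    @property
    def n(self) -> int:
        return len(self.votes)

    @classmethod
    def from_votes(
        cls,
        segment: HelixSegment,
        votes: Sequence[bool],
        threshold: float = DEFAULT_THRESHOLD,
    ) -> "PredictionResult":
        index = nabh_index(votes)
        return cls(
            segment=segment,
            votes=tuple(bool(v) for v in votes),
            index=index,
            tier=classify_tier(index, threshold),
        )
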
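"""Composition-based detection of candidate helical segments.

A sequence window of six residues is called helix-like when at least four
of its residues belong to the helix-favouring set {A, E, H, K, L, M, Q, R}.
The scanner slides this window with step 1 over the whole sequence, takes
the union of all index ranges covered by qualifying windows, and reports
each maximal run of covered indices as one candidate segment. Only segments
of six or more residues can arise (and shorter ones are asserted against):
fewer than six residues rarely forms a stable helix.

This is deliberately a composition heuristic, not secondary-structure
prediction; the discriminative work happens downstream in featurization
and classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from nabh.seqio import STANDARD_AA, ProteinRecord

_STANDARD_SET = frozenset(STANDARD_AA)

#: Helix-favouring residues: alanine, glutamate, histidine, lysine,
#: leucine, methionine, glutamine, arginine.
DEFAULT_HELIX_RESIDUES = frozenset("AEHKLMQR")


@dataclass(frozen=True)
class HelixAlphabet:
    """The window rule: ``window``-long segments with >= ``min_hits`` residues from ``residues``."""

    residues: frozenset[str] = DEFAULT_HELIX_RESIDUES
    min_hits: int = 4
    window: int = 6

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", frozenset(self.residues))
        if not self.residues <= _STANDARD_SET:
            raise ValueError("helix residues must be standard one-letter codes")
        if not 1 <= self.min_hits <= self.window:
            raise ValueError("min_hits must satisfy 1 <= min_hits <= window")


DEFAULT_ALPHABET = HelixAlphabet()


@dataclass(frozen=True)
class HelixSegment:
    """A candidate helix: 0-based half-open coordinates into a parent sequence."""

    parent_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("segment coordinates do not match its sequence length")
        if len(self.sequence) < 6:
            raise ValueError("helix segments must span at least six residues")

    def __len__(self) -> int:
        return self.end - self.start


def window_qualifies(hexamer: str, alphabet: HelixAlphabet = DEFAULT_ALPHABET) -> bool:
    """True iff the window contains at least ``min_hits`` helix-favouring residues."""
    if len(hexamer) != alphabet.window:
        raise ValueError(
            f"window must have length {alphabet.window}, got {len(hexamer)}"
        )
    return sum(c in alphabet.residues for c in hexamer) >= alphabet.min_hits


def extract_helices(
    record: ProteinRecord, alphabet: HelixAlphabet = DEFAULT_ALPHABET
) -> list[HelixSegment]:
    """Scan a protein and return its candidate helical segments.

    Every window position is tested; indices covered by any qualifying
    window are unioned and each maximal covered run becomes one segment.
    Adjacent-but-disjoint runs are never merged: a gap position belongs to
    no qualifying window, so nothing supports helicity there. Sequences
    shorter than the window yield an empty list.
    """
    seq = record.sequence
    w = alphabet.window
    n = len(seq)
    if n < w:
        return []
    covered = bytearray(n)
    hits = [c in alphabet.residues for c in seq]
    count = sum(hits[:w])
    for start in range(n - w + 1):
        if start > 0:
            count += hits[start + w - 1] - hits[start - 1]
        if count >= alphabet.min_hits:
            for i in range(start, start + w):
                covered[i] = 1
    segments: list[HelixSegment] = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            assert j - i >= w, "covered runs are unions of full windows"
            segments.append(
                HelixSegment(parent_id=record.id, start=i, end=j, sequence=seq[i:j])
            )
            i = j
        else:
            i += 1
    return segments
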
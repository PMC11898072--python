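"""Reading, validating and writing protein sequence data and tabular results.

Only two external formats are supported: FASTA on the way in and CSV on the
way out. Coordinates everywhere in this package are 0-based, half-open
``[start, end)``; the report layer additionally prints 1-based inclusive
columns for human readers.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard one-letter amino-acid codes. Every downstream feature
#: scale is defined only for these residues.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

VALIDATION_POLICIES = ("reject", "strip", "skip")


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: an id, a free-text description and a validated sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be a non-empty token")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - _STANDARD_SET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-standard residue(s) "
                f"{''.join(sorted(bad))!r}; only {STANDARD_AA} are allowed"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, on_invalid: str = "reject") -> list[ProteinRecord]:
    """Parse a FASTA file into validated :class:`ProteinRecord` objects.

    Sequence lines are concatenated and uppercased; record order is
    preserved. Duplicate ids within one file are an error.

    Parameters
    ----------
    path
        FASTA file (wrapped or unwrapped sequence lines).
    on_invalid
        Policy for residues outside the 20 standard codes after
        uppercasing: ``"reject"`` (default) raises naming the record and the
        offending character, ``"strip"`` removes the offending characters,
        ``"skip"`` drops the whole record with a warning.
    """
    if on_invalid not in VALIDATION_POLICIES:
        raise ValueError(f"on_invalid must be one of {VALIDATION_POLICIES}, got {on_invalid!r}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().strip()
        bad = sorted(set(seq) - _STANDARD_SET)
        if bad:
            if on_invalid == "reject":
                raise ValueError(
                    f"record {rec.id!r} contains non-standard residue {bad[0]!r}"
                )
            if on_invalid == "skip":
                warnings.warn(
                    f"skipping record {rec.id!r}: non-standard residue {bad[0]!r}",
                    stacklevel=2,
                )
                continue
            seq = "".join(c for c in seq if c in _STANDARD_SET)
            if not seq:
                raise ValueError(f"record {rec.id!r}: empty after stripping non-standard residues")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise ValueError(f"no records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA; round-trips exactly through :func:`read_fasta`."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


def write_csv(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write rows sharing one schema as an RFC-4180-style CSV with a header.

    Row order is preserved. ``columns`` fixes the header order; it is
    required when ``rows`` is empty (a header-only file is still written).
    """
    if columns is None:
        if not rows:
            raise ValueError("columns must be given when rows is empty")
        columns = list(rows[0].keys())
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=list(columns), lineterminator="\r\n")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def read_csv(path: str | Path) -> list[dict[str, str]]:
    """Read back a CSV written by :func:`write_csv` (all cells as strings)."""
    with open(path, newline="") as handle:
        return [dict(row) for row in csv.DictReader(handle)]
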
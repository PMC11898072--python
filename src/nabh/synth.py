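"""Seeded synthetic training fixtures and toy proteomes.

The generator emulates the structure of the published training corpus:
2560 positive 22-mers modelled on the basic-residue-rich carboxy-terminal
helix of bacterial KhpB (each carrying the R3H-domain RxxxH motif), and
2560 negatives made of 701 albumin-like helices (helix-forming but
basic-depleted) plus 1859 uniform-random 22-mers. Compositions are chosen
so class overlap is small but non-zero: the classes are separated by
featurization (basic-residue frequency, charge, pI), not by helix
detection — albumin-like negatives deliberately pass the helix scanner.

Everything is deterministic per seed; independent substreams are derived
per record class so the generators can be called in any order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from nabh.ensemble import LabelledDataset
from nabh.features import ScaleConfig, default_config, featurize_sequences
from nabh.helix_scan import DEFAULT_ALPHABET, HelixAlphabet, window_qualifies
from nabh.seqio import STANDARD_AA, ProteinRecord, read_fasta

_AA = np.array(list(STANDARD_AA))


@dataclass(frozen=True)
class SyntheticSpec:
    """Class sizes, peptide length and composition knobs of the generator."""

    n_pos: int = 2560
    n_neg_albumin: int = 701
    n_neg_random: int = 1859
    length: int = 22
    seed: int = 0
    pos_basic_enrichment: float = 0.35
    embed_r3h: bool = True

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg_albumin, self.n_neg_random) < 0:
            raise ValueError("record counts must be non-negative")
        if self.length < 6:
            raise ValueError("peptide length must be >= 6")
        if not 0.0 < self.pos_basic_enrichment < 1.0:
            raise ValueError("pos_basic_enrichment must lie in (0, 1)")


def _weights(raw: dict[str, float]) -> np.ndarray:
    w = np.array([raw.get(a, 0.0) for a in STANDARD_AA], dtype=float)
    return w / w.sum()

# Relative non-basic composition of positives: helix formers dominate.
_POS_NONBASIC = {
    "A": 0.12, "E": 0.11, "L": 0.11, "M": 0.04, "Q": 0.06,
    **{a: 0.0175 for a in "CDFGINPSTVWY"},
}
# Albumin-like helices: helix-forming, acidic/hydrophobic, basic-depleted.
_ALBUMIN = {
    "A": 0.13, "E": 0.12, "L": 0.13, "M": 0.03, "Q": 0.06,
    "D": 0.09, "F": 0.07, "V": 0.08, "S": 0.07, "T": 0.06,
    "C": 0.05, "K": 0.03, "R": 0.02, "H": 0.01, "G": 0.02,
    "I": 0.02, "N": 0.005, "W": 0.0025, "Y": 0.0025,
}
# Helix-poor background for toy-proteome scaffolds.
_HELIX_POOR = {
    "G": 0.10, "P": 0.08, "S": 0.12, "T": 0.10, "V": 0.10, "I": 0.08,
    "N": 0.08, "D": 0.10, "C": 0.04, "F": 0.06, "W": 0.04, "Y": 0.06,
    "A": 0.01, "E": 0.01, "K": 0.01, "L": 0.01,
}


def _positive_weights(enrichment: float) -> np.ndarray:
    basic = {"K": 0.45 * enrichment, "R": 0.40 * enrichment, "H": 0.15 * enrichment}
    nonbasic_total = sum(_POS_NONBASIC.values())
    raw = {a: (1.0 - enrichment) * v / nonbasic_total for a, v in _POS_NONBASIC.items()}
    raw.update(basic)
    return _weights(raw)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _draw_helical(
    rng: np.random.Generator,
    length: int,
    weights: np.ndarray,
    alphabet: HelixAlphabet = DEFAULT_ALPHABET,
    max_tries: int = 200,
) -> str:
    """Draw until the peptide contains >= 1 qualifying helix window."""
    for _ in range(max_tries):
        seq = "".join(rng.choice(_AA, size=length, p=weights))
        if any(
            window_qualifies(seq[i : i + alphabet.window], alphabet)
            for i in range(length - alphabet.window + 1)
        ):
            return seq
    raise RuntimeError("composition too helix-poor to yield a qualifying window")


def generate_positive(spec: SyntheticSpec) -> list[ProteinRecord]:
    """KhpB-like positive peptides: basic-enriched, helix-forming, RxxxH-bearing."""
    rng = _rng(spec.seed, 0)
    weights = _positive_weights(spec.pos_basic_enrichment)
    records = []
    for i in range(spec.n_pos):
        seq = _draw_helical(rng, spec.length, weights)
        if spec.embed_r3h and spec.length >= 5:
            pos = int(rng.integers(0, spec.length - 4))
            seq = seq[:pos] + "R" + seq[pos + 1 : pos + 4] + "H" + seq[pos + 5 :]
        records.append(
            ProteinRecord(
                id=f"pos_{i:04d}", sequence=seq, description="synthetic KhpB-like helix"
            )
        )
    return records


def generate_negative(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Albumin-like helical negatives plus uniform-random peptides."""
    rng_alb = _rng(spec.seed, 1)
    rng_uni = _rng(spec.seed, 2)
    records = []
    albumin_weights = _weights(_ALBUMIN)
    for i in range(spec.n_neg_albumin):
        seq = _draw_helical(rng_alb, spec.length, albumin_weights)
        records.append(
            ProteinRecord(
                id=f"neg_alb_{i:04d}",
                sequence=seq,
                description="synthetic albumin-like helix",
            )
        )
    for i in range(spec.n_neg_random):
        seq = "".join(rng_uni.choice(_AA, size=spec.length))
        records.append(
            ProteinRecord(
                id=f"neg_rnd_{i:04d}",
                sequence=seq,
                description="synthetic random peptide",
            )
        )
    return records


def build_labelled_dataset(
    spec: SyntheticSpec, config: ScaleConfig | None = None
) -> LabelledDataset:
    """Generate both classes and featurize them into one labelled dataset."""
    config = config or default_config()
    pos = generate_positive(spec)
    neg = generate_negative(spec)
    sequences = [r.sequence for r in pos + neg]
    X = featurize_sequences(sequences, config)
    y = np.array([True] * len(pos) + [False] * len(neg), dtype=bool)
    return LabelledDataset(X=X, y=y, ids=[r.id for r in pos + neg])


def load_labelled_directory(
    path, config: ScaleConfig | None = None
) -> LabelledDataset | None:
    """Optional loader for real training helices, if a user supplies them.

    Expects ``positives.fasta`` and ``negatives.fasta`` in ``path``; returns
    None (not an error) when either file is absent, so the synthetic
    generator remains the default source.
    """
    from pathlib import Path

    path = Path(path)
    pos_file, neg_file = path / "positives.fasta", path / "negatives.fasta"
    if not (pos_file.exists() and neg_file.exists()):
        return None
    pos = read_fasta(pos_file)
    neg = read_fasta(neg_file)
    X = featurize_sequences([r.sequence for r in pos + neg], config or default_config())
    y = np.array([True] * len(pos) + [False] * len(neg), dtype=bool)
    return LabelledDataset(X=X, y=y, ids=[r.id for r in pos + neg])


# ---------------------------------------------------------------------------
# Toy proteomes for recovery-style validation
# ---------------------------------------------------------------------------

_NABP_DESCRIPTIONS = (
    "DNA polymerase III subunit alpha",
    "ATP-dependent RNA helicase",
    "ribonuclease E",
    "30S ribosomal protein S4",
    "transcription factor sigma-70",
    "DNA-binding protein HU",
    "argonaute-family protein",
    "chromatin remodeling factor",
)

_NEUTRAL_DESCRIPTIONS = (
    "ABC transporter permease",
    "outer membrane lipoprotein",
    "sugar phosphotransferase system component",
    "two-component sensor kinase",
    "flagellar motor switch protein",
    "peptidoglycan glycosyltransferase",
    "heat shock chaperone",
    "citrate synthase",
)


def generate_toy_proteome(
    n_nabp: int,
    n_other: int,
    seed: int = 0,
    helix_length: int = 22,
    pos_basic_enrichment: float = 0.35,
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """A small annotated proteome with planted nucleic-acid-binding proteins.

    Each of the ``n_nabp`` proteins embeds one positive-like helical 22-mer
    in a helix-poor scaffold and carries a keyword-bearing annotation
    (polymerase, helicase, ...); the ``n_other`` proteins are helix-poor
    with neutral annotations. Returns the records plus an (id, description)
    annotation table.
    """
    if n_nabp < 0 or n_other < 0:
        raise ValueError("protein counts must be non-negative")
    rng = _rng(seed, 3)
    background = _weights(_HELIX_POOR)
    pos_weights = _positive_weights(pos_basic_enrichment)
    records: list[ProteinRecord] = []
    for i in range(n_nabp):
        scaffold_len = int(rng.integers(120, 301))
        scaffold = "".join(rng.choice(_AA, size=scaffold_len, p=background))
        helix = _draw_helical(rng, helix_length, pos_weights)
        r3h = int(rng.integers(0, helix_length - 4))
        helix = helix[:r3h] + "R" + helix[r3h + 1 : r3h + 4] + "H" + helix[r3h + 5 :]
        insert_at = int(rng.integers(0, scaffold_len + 1))
        seq = scaffold[:insert_at] + helix + scaffold[insert_at:]
        desc = _NABP_DESCRIPTIONS[int(rng.integers(0, len(_NABP_DESCRIPTIONS)))]
        records.append(ProteinRecord(id=f"nabp_{i:04d}", sequence=seq, description=desc))
    for i in range(n_other):
        scaffold_len = int(rng.integers(120, 301))
        seq = "".join(rng.choice(_AA, size=scaffold_len, p=background))
        desc = _NEUTRAL_DESCRIPTIONS[int(rng.integers(0, len(_NEUTRAL_DESCRIPTIONS)))]
        records.append(ProteinRecord(id=f"other_{i:04d}", sequence=seq, description=desc))
    annotations = [(r.id, r.description) for r in records]
    return records, annotations
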
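"""The 20-feature physicochemical descriptor of a peptide.

Each candidate segment is summarized by exactly 20 scalar features, in a
frozen canonical order: one Henderson-Hasselbalch net charge at pH 7.4,
ten residue-class frequencies, seven per-residue scale averages, the
Guruprasad instability index and the isoelectric point. The featurizer is
a pure function of the sequence and a :class:`ScaleConfig`; the trained
model bundle records a fingerprint of the config so that predictions can
never silently run against mismatched scales.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from nabh import scales as _defaults
from nabh.seqio import STANDARD_AA

_STANDARD_SET = frozenset(STANDARD_AA)

#: Canonical feature order; the trained ensemble stores and checks it.
FEATURE_NAMES: tuple[str, ...] = (
    "charge_at_pH7.4",
    "freq_acidic",
    "freq_all_basic",
    "freq_all_helix_breaker",
    "freq_aromatic",
    "freq_basic",
    "freq_hbond",
    "freq_hydroxyl",
    "freq_nonpolar",
    "freq_ring",
    "freq_strong_helix_breaker",
    "helix_propensity",
    "hydrophobicity_index",
    "hydropathy_index",
    "instability_index",
    "isoelectric_point",
    "rna_ligation",
    "redox_potential",
    "sheet_propensity",
    "turn_propensity",
)

_CLASS_FOR_FEATURE = {
    "freq_acidic": "acidic",
    "freq_all_basic": "all_basic",
    "freq_all_helix_breaker": "helix_breaker",
    "freq_aromatic": "aromatic",
    "freq_basic": "basic",
    "freq_hbond": "hbond",
    "freq_hydroxyl": "hydroxyl",
    "freq_nonpolar": "nonpolar",
    "freq_ring": "ring",
    "freq_strong_helix_breaker": "strong_helix_breaker",
}

_SCALE_FOR_FEATURE = {
    "helix_propensity": "helix_propensity",
    "hydrophobicity_index": "hydrophobicity",
    "hydropathy_index": "hydropathy",
    "rna_ligation": "rna_ligation",
    "redox_potential": "redox",
    "sheet_propensity": "sheet_propensity",
    "turn_propensity": "turn_propensity",
}


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 20-value descriptor of one peptide segment."""

    values: tuple[float, ...]
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError(
                f"expected {len(self.names)} feature values, got {len(self.values)}"
            )
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("feature values must all be finite")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[self.names.index(name)]


@dataclass(frozen=True)
class ScaleConfig:
    """All per-residue constants the featurizer depends on.

    Everything is plain data and overridable: residue class sets, the seven
    per-residue scales, the side-chain/termini pKa tables and the dipeptide
    instability weights. :meth:`fingerprint` hashes the whole configuration
    so a model bundle can verify it scores with the scales it was trained
    on.
    """

    class_sets: Mapping[str, frozenset[str]]
    scales: Mapping[str, Mapping[str, float]]
    pka_side_chain: Mapping[str, float]
    basic_side_chains: frozenset[str]
    pka_nterm: float
    pka_cterm: float
    diwv: Mapping[str, Mapping[str, float]]

    @classmethod
    def default(cls) -> "ScaleConfig":
        return cls(
            class_sets=dict(_defaults.CLASS_SETS),
            scales={k: dict(v) for k, v in _defaults.SCALES.items()},
            pka_side_chain=dict(_defaults.PKA_SIDE_CHAIN),
            basic_side_chains=_defaults.BASIC_SIDE_CHAINS,
            pka_nterm=_defaults.PKA_NTERM,
            pka_cterm=_defaults.PKA_CTERM,
            diwv=_defaults.dipeptide_instability_weights(),
        )

    def __post_init__(self) -> None:
        for name, scale in self.scales.items():
            missing = _STANDARD_SET - set(scale)
            if missing:
                raise ValueError(f"scale {name!r} is missing residues {sorted(missing)}")
        for name, cls_set in self.class_sets.items():
            if not set(cls_set) <= _STANDARD_SET:
                raise ValueError(f"class set {name!r} contains non-standard residues")

    def _canonical(self) -> dict:
        return {
            "class_sets": {k: sorted(v) for k, v in sorted(self.class_sets.items())},
            "scales": {k: dict(sorted(v.items())) for k, v in sorted(self.scales.items())},
            "pka_side_chain": dict(sorted(self.pka_side_chain.items())),
            "basic_side_chains": sorted(self.basic_side_chains),
            "pka_nterm": self.pka_nterm,
            "pka_cterm": self.pka_cterm,
            "diwv": {a: dict(sorted(row.items())) for a, row in sorted(self.diwv.items())},
        }

    def fingerprint(self) -> str:
        """Stable hash of every constant; stored in model-bundle manifests."""
        blob = json.dumps(self._canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self._canonical(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScaleConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(
            class_sets={k: frozenset(v) for k, v in raw["class_sets"].items()},
            scales=raw["scales"],
            pka_side_chain=raw["pka_side_chain"],
            basic_side_chains=frozenset(raw["basic_side_chains"]),
            pka_nterm=float(raw["pka_nterm"]),
            pka_cterm=float(raw["pka_cterm"]),
            diwv=raw["diwv"],
        )


_DEFAULT_CONFIG: ScaleConfig | None = None


def default_config() -> ScaleConfig:
    """The shared default :class:`ScaleConfig` (built once)."""
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = ScaleConfig.default()
    return _DEFAULT_CONFIG


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = set(sequence) - _STANDARD_SET
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)} in sequence")


def class_frequency(sequence: str, cls: frozenset[str] | set[str]) -> float:
    """Fraction of residues that belong to the class set; always in [0, 1]."""
    _check_sequence(sequence)
    return sum(c in cls for c in sequence) / len(sequence)


def scale_average(sequence: str, scale: Mapping[str, float]) -> float:
    """Arithmetic mean of a per-residue scale over the peptide."""
    _check_sequence(sequence)
    try:
        return sum(scale[c] for c in sequence) / len(sequence)
    except KeyError as exc:
        raise ValueError(f"scale does not define residue {exc.args[0]!r}") from exc


def charge_at_pH(
    sequence: str,
    pH: float,
    config: ScaleConfig | None = None,
    include_termini: bool = False,
) -> float:
    """Henderson-Hasselbalch net charge of the peptide at the given pH.

    Basic groups contribute ``+1 / (1 + 10**(pH - pKa))`` and acidic groups
    ``-1 / (1 + 10**(pKa - pH))``. Termini are excluded by default because
    scored segments are internal stretches of a longer chain.
    """
    _check_sequence(sequence)
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    config = config or default_config()
    charge = 0.0
    for residue in sequence:
        pka = config.pka_side_chain.get(residue)
        if pka is None:
            continue
        if residue in config.basic_side_chains:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    if include_termini:
        charge += 1.0 / (1.0 + 10.0 ** (pH - config.pka_nterm))
        charge -= 1.0 / (1.0 + 10.0 ** (config.pka_cterm - pH))
    return charge


def isoelectric_point(
    sequence: str,
    config: ScaleConfig | None = None,
    include_termini: bool = False,
    tol: float = 1e-6,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Conventions for degenerate compositions: a peptide with no ionizable
    groups returns 7.0; a peptide whose charge keeps one sign over the
    whole scale (e.g. only basic side chains with termini excluded) clamps
    to the nearer endpoint, where its residual charge is already below
    1e-3.
    """
    _check_sequence(sequence)
    config = config or default_config()
    ionizable = any(c in config.pka_side_chain for c in sequence)
    if not ionizable and not include_termini:
        return 7.0
    lo, hi = 0.0, 14.0
    f_lo = charge_at_pH(sequence, lo, config, include_termini)
    f_hi = charge_at_pH(sequence, hi, config, include_termini)
    if f_lo <= 0.0:
        return lo
    if f_hi >= 0.0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if charge_at_pH(sequence, mid, config, include_termini) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def instability_index(sequence: str, config: ScaleConfig | None = None) -> float:
    """Guruprasad instability index: ``(10 / L) * sum_i DIWV(x_i, x_{i+1})``."""
    _check_sequence(sequence)
    if len(sequence) < 2:
        raise ValueError("instability index requires at least two residues")
    config = config or default_config()
    total = 0.0
    for a, b in zip(sequence, sequence[1:]):
        total += config.diwv[a][b]
    return 10.0 * total / len(sequence)


def compute_features(sequence: str, config: ScaleConfig | None = None) -> FeatureVector:
    """Assemble the full ordered 20-feature descriptor of a peptide."""
    _check_sequence(sequence)
    if len(sequence) < 2:
        raise ValueError("featurization requires at least two residues")
    config = config or default_config()
    values: list[float] = []
    for name in FEATURE_NAMES:
        if name == "charge_at_pH7.4":
            values.append(charge_at_pH(sequence, 7.4, config))
        elif name in _CLASS_FOR_FEATURE:
            values.append(class_frequency(sequence, config.class_sets[_CLASS_FOR_FEATURE[name]]))
        elif name in _SCALE_FOR_FEATURE:
            values.append(scale_average(sequence, config.scales[_SCALE_FOR_FEATURE[name]]))
        elif name == "instability_index":
            values.append(instability_index(sequence, config))
        elif name == "isoelectric_point":
            values.append(isoelectric_point(sequence, config))
        else:  # pragma: no cover - canon and dispatch tables are in sync
            raise AssertionError(f"unhandled feature {name}")
    return FeatureVector(values=tuple(values))


def featurize_sequences(
    sequences: list[str], config: ScaleConfig | None = None
) -> np.ndarray:
    """Feature matrix (n_sequences, 20) in canonical column order."""
    config = config or default_config()
    return np.array(
        [compute_features(s, config).values for s in sequences], dtype=float
    )
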
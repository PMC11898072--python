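"""Published reference figures of the original NABhClassifier server.

These numbers are reported results of the original web-server ensemble
(trained on the real KhpB/albumin helices, which are not redistributed
here). They serve as arithmetic cross-checks for the metric and recovery
calculators; nothing in this package fits to them.
"""

from __future__ import annotations

#: Average feature relevance (%) across the eight core models; sums to 100.
PUBLISHED_FEATURE_RELEVANCE: dict[str, float] = {
    "freq_basic": 31.40,
    "redox_potential": 12.73,
    "isoelectric_point": 7.80,
    "freq_hbond": 4.74,
    "instability_index": 4.62,
    "charge_at_pH7.4": 4.46,
    "freq_all_basic": 4.25,
    "rna_ligation": 4.16,
    "freq_nonpolar": 3.93,
    "turn_propensity": 3.30,
    "helix_propensity": 3.12,
    "freq_ring": 2.99,
    "freq_aromatic": 2.10,
    "hydropathy_index": 1.86,
    "sheet_propensity": 1.81,
    "hydrophobicity_index": 1.81,
    "freq_all_helix_breaker": 1.80,
    "freq_strong_helix_breaker": 1.11,
    "freq_acidic": 1.03,
    "freq_hydroxyl": 0.98,
}

#: Held-out confusion matrices [[TP, FP], [FN, TN]] per core member.
PUBLISHED_CONFUSION: dict[str, tuple[int, int, int, int]] = {
    "gradient_boosting": (748, 3, 10, 775),
    "svm": (749, 2, 15, 770),
    "ada_boost": (748, 3, 5, 780),
    "logistic_regression": (746, 5, 7, 778),
    "stacking": (748, 3, 10, 775),
    "random_forest": (748, 3, 15, 770),
    "bagging": (747, 4, 16, 769),
    "mlp": (743, 8, 8, 777),
}

#: Recovery of double-stranded RNA-binding proteins: (targets, counts at
#: index cutoffs 1.0 / 0.875 / 0.75).
PUBLISHED_DSRBP_RECOVERY = {
    "targets": 474,
    "counts": {1.0: 352, 0.875: 417, 0.75: 454},
}
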
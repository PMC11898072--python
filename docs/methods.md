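# Methods

## The model

The method treats nucleic acid-binding helix (NABh) detection as a
two-stage problem: a cheap, high-recall *segment proposal* step followed
by a discriminative *classification* step.

**Segment proposal.** A window of `window = 6` residues slides with step 1
over the protein; a window qualifies when at least `min_hits = 4` of its
residues come from the helix-favouring alphabet {A, E, H, K, L, M, Q, R}.
Six residues is roughly the minimum for a stable α-helical turn structure,
hence the window length and the ≥ 6 floor on reported segments. All
indices covered by any qualifying window are unioned and each maximal run
becomes one candidate segment. Two properties make this delimitation rule
the right default: it is deterministic and order-independent, and it
reduces to the single window when exactly one qualifies. Runs separated by
even a one-residue gap are *not* merged — a gap position belongs to no
qualifying window, so no evidence supports helicity there. The rule is a
composition heuristic, not secondary-structure prediction; proposals are
deliberately permissive (albumin-like helices qualify too) and the
discriminative work happens downstream.

**Featurization.** Each segment maps to 20 scalar features in a frozen
canonical order (stored in the model manifest and checked at prediction
time). Scale choices, all overridable through `ScaleConfig` /
`--config`:

| feature group | scale | notes |
|---|---|---|
| charge at pH 7.4, pI | Henderson–Hasselbalch with EMBOSS side-chain pKa (C 8.5, D 3.9, E 4.1, H 6.5, K 10.5, R 12.5, Y 10.1) | termini excluded by default: segments are internal |
| class frequencies | acidic {D,E}; basic {K,R}; all-basic {K,R,H}; aromatic {F,W,Y}; ring {F,W,Y,H,P}; hydroxyl {S,T,Y}; H-bond {S,T,Y,N,Q,D,E,K,R,H,W}; nonpolar {A,V,L,I,M,F,W,P,G}; helix breakers {P,G}; strong breaker {P} | "basic" vs "all basic" resolved as without/with the weakly basic histidine |
| helix/sheet/turn propensity | Chou–Fasman preference parameters | mean over residues |
| hydropathy | Kyte–Doolittle | mean |
| hydrophobicity | Eisenberg consensus | mean |
| RNA ligation | in-house enrichment scale: R 1.0, K 0.85, H 0.7, M 0.5, D/E −0.6 | substitute — see below |
| redox potential | in-house scale, non-zero only for C, M, W, Y, H | substitute — see below |
| instability | Guruprasad dipeptide weights, (10/L)·Σ DIWV | cross-checked against biopython's implementation |

The RNA-ligation and redox scales are this package's own constructions
(no canonical published scale exists for either concept as a per-residue
average): values follow the known enrichment of RNA interfaces in R, K, H
and M and their depletion in D and E, and the set of redox-active side
chains. They are data, not code, so a better scale can be dropped in
without retraining code paths.

**Isoelectric point numerics.** The pI is located by bisection on
[0, 14] to a default tolerance of 1e-6 pH units (tight enough that the
residual charge at the root stays below 1e-3 even for long, heavily
ionizable peptides). Conventions for degenerate inputs: no ionizable
groups → 7.0; charge one-signed over the whole scale (possible with
termini excluded, e.g. only basic side chains) → clamp to the nearer
endpoint, which by monotonicity of the charge curve is the |charge|
minimizer.

**Classification.** Fourteen families are registered; the operational
core is the eight with published accuracies above 0.99, in fixed member
order: gradient boosting, SVM, AdaBoost, logistic regression, stacking,
random forest, bagging, MLP. Each is fitted by grid search
(accuracy-scored, stratified 3-fold) over a modest default grid (tree
counts {100, 300}; SVM C {0.1, 1, 10} × {RBF, linear}; MLP one hidden
layer {16, 64}; …). Scale-sensitive families train behind a z-score
standardizer fitted on the training split only; tree ensembles take raw
features. The stacking member stacks the other seven core families under a
logistic meta-learner (its composition is otherwise unspecified upstream).
All randomness derives from one top-level seed via `numpy` seed-sequence
spawning, so every artifact is reproducible bit-for-bit given the seed.

**Consensus.** Votes are hard per-model calls (each family's native
0.5/sign rule, never averaged probabilities). The NABh index is the
fraction of positive votes; with n = 8 it takes the nine lattice values
{0, 0.125, …, 1}. Tiers: *strong* at exactly 1.0, *likely* in
[threshold, 1.0), *unreliable* below the reporting threshold
(default 0.75, configurable). The member count n is carried in the bundle
manifest, not hard-coded, so a rebuilt core with a different member count
still yields a lawful index.

## Evaluation conventions

Metrics are computed from the confusion matrix [[TP, FP], [FN, TN]] with
*support-weighted* two-class precision/recall/F1 (supports TP+FN and
FP+TN). This choice is forced by arithmetic: it reproduces the published
per-model precision values from the published confusion matrices (e.g.
gradient boosting 0.9916), whereas positive-class-only precision (0.9960)
does not. Weighted recall is then identically equal to accuracy. AUC-ROC
comes from the rank statistic over decision scores
(`decision_function` where available, else positive-class probability);
the test suite checks it against the brute-force pairwise definition.
Cross-validation is repeated stratified 70/30 shuffle-splitting at fixed
hyperparameters, 50 iterations by default (an upstream description also
mentions 100; the count is a parameter, not a constant). Feature
relevance is permutation importance (accuracy drop, 10 repeats per
feature per member, clipped at zero), averaged over the eight members and
normalized to percentages summing to 100 — the attribution method behind
the published relevance table is not documented, so permutation
importance is the declared substitute. The feature-saturation analysis
retrains each core family on the top-k features (k = 3…20) in relevance
order, keeping selected columns in canonical order so k = 20 is exactly
the full-feature run.

## The synthetic corpus

The generator emulates the *structure* of the real training corpus, not
its sequences: 2560 positive 22-mers (basic-enriched: 35% probability
mass on {K, R, H}, helix-former-rich, each carrying an RxxxH motif as in
the R3H domain of KhpB), 701 albumin-like negatives (helix-forming but
basic-depleted, so they pass the helix scanner — reproducing the logic
that the discriminator is featurization, not helix detection) and 1859
uniform-random 22-mers, split 70/30 stratified. Composition masses were
chosen once so that class overlap is small but non-zero (held-out
accuracies land near 0.97–0.98 rather than 1.0), mimicking the
near-but-not-exactly-perfect published metrics; perfect separation would
make the ensemble and consensus tests vacuous. Toy proteomes plant
positive-like helices inside helix-poor scaffolds (120–300 residues) with
keyword-bearing annotations ("polymerase", "helicase", …) against
neutral-annotation background proteins.

What the generator does *not* emulate: the phylogenetic structure of 2560
bacterial KhpB orthologs (real positives are a conserved family, not
i.i.d. draws), real albumin helix geometry, and realistic proteome
annotation text. Passing the synthetic benchmark therefore shows that the
pipeline can learn and recover the intended composition signal end to
end — not that it reproduces the published accuracy on the real corpus,
which is not redistributable.

## Problem sizes

The test suite trains the full eight-member core once on the
default-size corpus (5120 peptides; about 1–2 minutes on one CPU) and
otherwise uses reduced fixtures (a few hundred peptides) chosen to keep
each analysis operation's behaviour observable at small n.

## Known limitations

- The recurrent-network candidate from the original 15-family comparison
  is not in the registry: a sequence model over 20 unordered scalar
  features is conceptually underspecified. The other 14 families are.
- The helix scanner has no notion of structural context; any
  composition-qualifying stretch is proposed, including genuine helices
  with no binding role. Specificity rests entirely on the ensemble.
- The RNA-ligation and redox scales are substitutes (above); trained
  models are therefore not expected to be weight-compatible with the
  original server.
- Scored segments are whatever length the scanner produces (≥ 6); the
  training corpus is fixed-length 22-mers, so features of much longer
  segments are mild extrapolations. The upstream behaviour (cap at 22 or
  not) is unknown; segments are scored as extracted.
- Grid-search spaces are intentionally modest defaults and overridable;
  the original exhaustive grids were not published in reusable form.
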
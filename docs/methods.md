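# Methods

## What the package models

`molbench` implements an evaluation methodology for molecular property
prediction, not a prediction model. Its premise: before trusting any QSAR
benchmark number, one must control (1) data quality — duplicates,
contradictory measurements, label noise; (2) the split — random vs
scaffold-disjoint, repeated over many seeds; (3) the metric — ranking
metrics vs threshold-dependent predictive values; and (4) the chemistry —
activity cliffs and cutoff-straddling edge cases that make some test
molecules intrinsically fragile. Every stage is a small, separately tested
operation; models are deliberately boring baselines (random forest, linear
SVM, gradient-boosted trees) whose role is to expose the methodology, plus
an "external" hook for comparing predictions produced elsewhere.

## Curation

Activity values in nM (IC50/EC50/Ki/Kd pooled by default) convert to
pIC50 = 9 − log10(value/nM), so 1 µM ↦ 6.0. Rows with a relation other
than `=` are rejected at load time. After canonicalization (RDKit),
exact duplicates (same canonical SMILES, same pIC50) collapse; a molecule
whose remaining measurements span more than 1.0 log unit is dropped as
contradictory, otherwise the median is kept. The 1.0-log-unit default
approximates inter-assay reproducibility of binding data and is
configurable. The 400-character length filter counts the raw SMILES string
as provided, since fixed-width model inputs see the raw string. Curation
sorts by canonical SMILES before aggregation, so any row order yields a
byte-identical dataset.

Classification labels are active (1) iff pIC50 ≥ cutoff, default 6.0.

## Representations

Six fixed representations: an 11-descriptor PhysChem block (MolWt, MolLogP,
NumHDonors, NumHAcceptors, NumRotatableBonds, NumAtoms, NumHeavyAtoms,
MolMR, PSA, FormalCharge, NumRings — in that column order; NumAtoms counts
implicit hydrogens, NumHeavyAtoms does not), the full RDKit 2D descriptor
set (dimension recorded at runtime because it is toolkit-version
dependent; optional z-score normalization, off by default), 166-key MACCS
(RDKit's unused key 0 dropped for a stable layout), Morgan fingerprints in
bit and count form (radius 2, 2048 bits by default — the common ECFP4
configuration), and hashed atom-pair counts. Descriptor failures impute
the column median of successful rows and are logged on the matrix, keeping
it rectangular without dropping molecules. Tanimoto similarity on bit
vectors defines 0/0 as 1.0 (identical emptiness).

## Splitting

Random split: seeded permutation, sizes ⌊0.8n⌋/⌊0.1n⌋/remainder.
Balanced scaffold split: molecules group by Bemis–Murcko framework
(acyclic molecules form one empty-scaffold group); groups larger than half
the target test size are queued first in (size-descending, lexicographic)
order, the rest shuffled by the seed; each group then goes to train if it
fits under train's target count, else val, else test. No scaffold ever
crosses partitions; an unpopulatable partition is an error, not a silent
imbalance. The protocol runs both methods over seeds 0..29 and the
manifests are persisted and reused by all downstream experiments —
comparisons across models are always on identical splits.

Scaffolds are achiral Murcko frameworks; chirality flags are ignored.

## Cliffs and edge cases

A scaffold is an activity-cliff (AC) scaffold iff its member pIC50 span is
≥ 2.0 log units (inclusive — "at least two orders of magnitude");
singletons are never AC. AC status is a dataset-level property; per-split
AC fractions derive from the manifests. The edge-case rule is pinned to the
cross-cutoff reading: a scaffold group is an edge group iff it has members
in [5, 6) and in [6, 7]; within such groups, all molecules with pIC50 in
[5, 7] are edge cases. The alternative reading (group span merely reaching
across the window) flags strictly more molecules; the cross-cutoff rule
matches the motivation that edge molecules are analogs coerced into
opposite classes, and both window and threshold are arguments.

## Metrics

All metrics are implemented in-package and cross-checked in tests against
brute-force oracles and sklearn/scipy:

- AUROC by the rank (Mann–Whitney) formulation, tied scores earning half
  credit; AUPRC as step-wise average precision (no trapezoidal PR
  interpolation, which is optimistic).
- PPV = TP/(TP+FP), NPV = TN/(TN+FN) at an explicit threshold; when none
  is given, Youden's J threshold is used if the minority-class fraction is
  below 0.4, else 0.5. Youden candidates are the distinct observed scores
  (positive iff score ≥ t); ties in J break toward the higher threshold.
  The threshold is fit on the same prediction set being evaluated — an
  optimistic convention, stated here deliberately.
- RMSE, MAE, R² (baseline = label mean, may be negative), Pearson r.
- Zero-denominator metrics serialize as explicit nulls, never 0, so
  aggregation cannot silently absorb undefined values.

## Statistics over repeated splits

Pairwise model comparison uses the two-sided Mann–Whitney U test at
α = 0.05 (scipy backend; exact null when combined n ≤ 16 without ties,
else normal approximation with tie and continuity corrections). No
multiple-testing correction by default — a Bonferroni flag exists but the
protocol's convention is unadjusted pairwise p-values. Win counting
emulates single-split practice: per-fold best (ties within relative
1e-12 award nobody) and best-mean over all C(seeds, 3) triples.
Non-significant performance differences can be imputed to zero for
difference maps. Variability analysis correlates per-model metric means
with their standard deviations across seeds.

## Models

RF: 500 trees. The package default sets `max_features="sqrt"` for both
tasks (sklearn's classifier default; for regression the library default of
all features makes tree construction quadratic in the 2048-bit
fingerprint width at no measurable accuracy benefit on these tasks) —
overridable through `ModelSpec` hyperparameters. SVM: linear kernel
(LinearSVR/LinearSVC); classification scores are min-max-scaled decision
values, recorded as such in provenance. XGBoost: library defaults.
Traditional models ignore the validation partition; it stays in every
manifest for model families that need it. Test labels are never passed to
a fitting call.

## The synthetic generator

Molecules are assembled by prefixing substituent SMILES fragments (H,
methyl…butyl, hydroxyl, halogens, amino, acetyl, aldehyde, isopropyl,
dimethylamino, …) onto ring-scaffold templates (single rings and
ring–linker–ring frameworks), so every emitted SMILES validates and has a
non-empty Murcko scaffold by construction. Labels follow

    pIC50 = scaffold base + substituent effect + cliff term + noise

with scaffold bases skew-normal (right-skewed by default, like screening
potency data) and substituent effects drawn per scaffold
(context-dependent) from N(0, 0.3²) clipped to ±0.8.

Scaffold occupancy is heavy-tailed, P(size) ∝ size^−1.5 on 1..18: most
scaffolds are singletons or pairs, a few analog series are large, as in
curated screening extracts. Planted AC scaffolds are the largest groups —
cliffs surface where chemists explored hardest — so ~10% AC scaffolds end
up holding ~35–40% of the molecules, the shape real curated extracts
show. Within an AC scaffold, a quarter of the members (at least one) are
lifted to exactly `cliff_magnitude` (default 2.5) above the weakest
remaining analog: a cliff series has several potent analogs, not a lone
outlier, which is what makes AC-stratified error visibly worse. The
±0.8 effect clip guarantees non-cliff spans stay below the 2.0 threshold,
making ground truth an exact oracle for cliff annotation at σ = 0 (the
guarantee needs cliff_magnitude > 1.6, twice the clip).

Edge groups are re-based near the cutoff with two members forced onto
opposite sides inside [5, 7]. Noise is Gaussian or heteroscedastic
(σ(y) = σ₀ + k·|y − y₀|). The calibration constructor bisects the base
location against a Monte-Carlo replicate of the full noiseless label model
(sizes, role assignment, cliff lifts, cutoff-anchored edge groups; no
molecule assembly) to hit a requested positive rate at the cutoff; the
planted structure shifts the rate by several points, so calibrating the
base-plus-effect convolution alone would miss.

Descriptor datasets label each molecule with its own computed MolWt or
NumAtoms — noiseless, exactly recomputable labels isolating representation
capacity. The size ladder is pinned to
{0.1, 0.2, 0.4, 0.6, 0.8, 1, 2, 4, 6, 8, 10, 20, 40, 60, 80, 100}×1000;
published descriptions of such ladders elide the middle of the list, and
this reconstruction is regular in each decade.

**What the generator does not emulate.** Scaffold bases are independent
random draws, so structure carries no information across scaffolds: under
a scaffold split, test labels are unpredictable by construction and
ranking metrics sit at chance. This is deliberate — it makes the
inter-scaffold generalization gap maximally visible — but it means passing
tests say nothing about real-data inter-scaffold transfer, where shared
pharmacophores do carry signal. Intra-scaffold behaviour (cliffs, edge
fragility, size ladders) is the generator's faithful regime. There is also
no claim of pharmacological realism: fragment diversity is small, no
stereochemistry, no 3D.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small study conditions — tens to
a few hundred scaffolds, 10–30 split seeds, a 100/1k/10k ladder — chosen
so the full pipeline runs end-to-end on a laptop-class single core while
leaving every protocol element intact. Determinism: every stochastic step
takes one explicit `numpy` Generator seeded from its caller; no global
random state. Tie-breaks (group ordering, Youden, win counting) are
documented above. Degenerate inputs (single-class partitions, constant
vectors, zero denominators) raise or return explicit undefined markers;
benchmark grids record such cells as failures and continue.

## Known limitations

- Duplicate/contradiction semantics and the edge-case rule are pinned
  conventions where the field's usage varies; both are configurable.
- The Youden threshold is computed on the evaluated set itself
  (optimistic); fitting it on validation predictions would need models
  that use the validation partition.
- No stereochemistry-aware deduplication; canonical-SMILES identity only.
- `cross_set_similarity` aggregates as per-query nearest-neighbour (max)
  similarity against the reference set — one pinned convention among the
  several "train/test similarity" definitions in use.
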
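# Methods

## Fragment hybridization

**Model.** Input ligands are assumed to occupy a single coordinate frame
(e.g. docked into one binding pocket). A *cut site* is a directed acyclic
single bond a→b between two heavy atoms whose cleavage leaves at least
`min_fragment_heavy_atoms` heavy atoms on each side (default 3 — a guard
that fragment swaps exchange pharmacophore-sized pieces, not methyl caps;
the value is a package choice, configurable). Two cut sites from different
ligands *match* when both endpoint pairs superimpose within `d_max`
(default 1.0 Å) and the bond vectors subtend at most `theta_max`
(default 15°). Both tests are boundary-inclusive. The displacement reported
is the larger of the two endpoint distances; a midpoint variant
(`displacement_mode="midpoint"`) exists because the per-endpoint versus
midpoint convention differs between published implementations — the
per-endpoint form is the default as the stricter reading.

A matched pair produces a hybrid by joining the head fragment of one ligand
to the tail fragment of the other with a new single bond; atoms keep their
original coordinates. Both complementary hybrids arise because every
ordered ligand pair and both bond directions are enumerated. Junction atoms
have their stereo descriptors cleared: the swap invalidates any prior
configuration assignment there.

**Why sanitization cannot reject an enumerated hybrid.** Cutting a single
bond removes exactly one neighbour from each junction atom and the new
junction bond restores exactly one, so every atom's explicit valence is
conserved and rings are never touched. Valence/aromaticity failures are
therefore impossible for enumerated cut sites; the drop-counting path in
`recombine` is defensive (it fires only for hand-built, inconsistent cut
bonds, e.g. ring bonds) and a test asserts `valence_drops == 0` across all
fixture libraries.

**Determinism.** No randomness anywhere: all pairings are enumerated
exhaustively, deduplication is by stereo-aware canonical SMILES with parents
excluded, and output is sorted by canonical SMILES.

**Untangling.** The optional relaxation adds hydrogens, builds a UFF force
field, and anchors every atom not adjacent to a geometrically distorted
bond (length outside [0.7, 1.9] Å) with strong harmonic position restraints
(force constant 10⁴ kcal mol⁻¹ Å⁻²; hard fixed points destabilize the BFGS
line search). Only the junction region can move, the parents' binding
geometry is preserved, and the canonical SMILES is verified unchanged —
otherwise the hybrid is passed through unrelaxed and flagged.

## Classifier

2048-bit Morgan fingerprints of radius 2 (ECFP4), no counts, no chirality
flags (both configurable). The MLP — 2048 → 512 → 128 → 1 with ReLU hidden
activations, one 20% inverted-dropout layer between the hidden layers, and
a sigmoid output — is implemented directly on NumPy: the pre-installed
stack has no framework that expresses this architecture with dropout while
persisting weights as plain arrays. Training uses Adam
(lr 10⁻³, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸), binary cross-entropy, batch
size 32, 20 epochs. One seed drives He weight initialization, per-epoch
shuffling and the dropout masks, so training is bit-reproducible; at
inference dropout is the identity. Models persist as `spec.json` plus
`weights.npz` plus the bit-packed training fingerprints (retained because
the applicability domain downstream is defined against them) — no pickled
code.

The 80/20 split is stratified (scikit-learn) and seeded. Metric panels are
computed in exact rational arithmetic before display rounding to 3
decimals; undefined ratios (zero denominators) are reported as `None`
rather than 0 or 1. ROC-AUC is the Mann–Whitney rank statistic with
midrank tie handling. Note that for the confusion matrix (TP = 88, FP = 0,
TN = 154, FN = 8) the class-1 F1 is 2·(1·0.9167)/1.9167 ≈ 0.957; the
package reproduces the arithmetic, so a report quoting 0.975 for that cell
is internally inconsistent with its own precision/recall.

## Triage funnel

Stage order is fixed: activity (p ≥ 0.5) → applicability domain → QED → SA.
All four flags are computed for every compound (they are independent facts,
and `final_pass` is their conjunction, so reordering stages never changes
the survivor set — only the per-stage exclusion counts, which the report
records together with the configured order).

* **Applicability domain**: exact maximum Tanimoto of the query ECFP4
  against the *entire* training set (actives and inactives — the domain
  bounds where the model has seen chemistry at all), linear scan, never an
  approximate neighbour search. Tanimoto of two all-zero vectors is defined
  as 1.0.
* **QED**: the canonical weighted-geometric-mean form over the eight
  desirability functions, delegated to RDKit's implementation; an
  unweighted variant is selectable.
* **SA score**: Ertl-style fragment-contribution score with complexity
  penalties, delegated to the versioned contribution table packaged with
  RDKit (offline-reproducible); the scorer is pluggable and the result is
  clamped into [1, 10].

Survivors are ranked by probability descending with ties broken by id.

## Early-recognition statistics

With N compounds, n actives, Ra = n/N and 1-based best-first ranks rᵢ:

* RIE = (1/n)·Σᵢ e^(−α·rᵢ/N) ÷ [(1/N)(1 − e^(−α))/(e^(α/N) − 1)]
* BEDROC = RIE·Ra·sinh(α/2)/(cosh(α/2) − cosh(α/2 − α·Ra)) +
  1/(1 − e^(α(1−Ra))), clipped into [0, 1] against floating-point spill at
  the extremes
* EF@f = (actives in top ⌈f·N⌉ / ⌈f·N⌉)/(n/N); ceil is the default top-k
  convention, floor/round selectable

Scores follow the docking convention (lower = better) behind a
`lower_is_better` flag; ranks use a stable sort on (score, input order) so
BEDROC is deterministic under ties, while only the AUC uses midranks.
α defaults to 160.9 — the weight at which roughly the top 2% of a ranked
library dominates the statistic — matching the convention used when
validating docking protocols against spiked decoy sets. These formulas
are cross-checked in the tests against RDKit's independent implementations
and against direct-summation and pairwise-comparison oracles.

**Selectivity gaps** are plain differences of per-compound docking scores
between two sites (gap = score_site2 − score_site1 > 0 meaning site-1
preference for negative-better scores). **MM/GBSA aggregation** computes
per-frame ΔE = EC − (ER + EL) and reports mean ± sample SD (n − 1
denominator); scores and energies are consumed from tables, never computed
here.

## Synthetic data: what it emulates, what it does not

* **Aligned sets**: k ≤ 4 ligands X–C₆H₄–CH₂–T with distinct halide head
  markers X and tail heteroatoms T on literal, exactly superimposed
  coordinates. At `min_fragment_heavy_atoms = 2` each ligand has exactly
  one cut site and the complete hybrid set is the k(k−1) head/tail crosses,
  enumerated into a manifest from string templates — never from the code
  under test. A perturbation knob shifts one ligand's cut-bond endpoint out
  of tolerance. This exercises the geometry and combinatorics exactly, but
  not the scale (thousands of hybrids) or the conformational diversity of
  a real docked ensemble.
* **Activity sets**: actives grown from a planted 2-aminobenzothiazole
  motif with random substituents from a fixed vocabulary; decoys from
  motif-free templates, rejection-sampled against accidental motif hits;
  optional label-flip noise (< 0.5). With zero noise the classes are
  separable in ECFP4 space by construction, so a green recovery test
  establishes that the training machinery learns recoverable signal — not
  that real bioactivity data is this easy. Defaults (600/600) mirror the
  balanced curated-set sizes typical of this workflow.
* **Funnel libraries**: instances of five exemplar molecules (caffeine —
  sub-threshold probability; perfluoropentane — outside the applicability
  domain; stearic acid — QED fail; morphine — SA fail; ibuprofen — passes
  everything), with the training reference set containing all but the
  out-of-domain exemplar. The generator measures the exemplars' actual
  QED/SA/Tanimoto values at build time and raises `InfeasiblePlantError`
  rather than emit a library that would not realize the planted counts.
* **Ranked screens**: perfect/worst/random orderings (bounds and null
  calibration are closed-form) and an exponential mode concentrating
  actives early; the default validation geometry (130 actives in 1130)
  mirrors a typical spiked-decoy enrichment study.
* **Energy tables**: EC constructed as ER + EL + Δ with Δ ~ N(μ, σ), so
  the aggregate is known in expectation.

All generators are pure functions of their seed.

## Numerical and design choices

* One canonicalization dialect (RDKit canonical SMILES, stereo retained)
  everywhere, including dedup keys; salts reduced to the largest organic
  component before canonicalization.
* Activity threshold inclusive (p ≥ 0.5); geometric boundaries inclusive
  (≤ 1.0 Å, ≤ 15°).
* The shuffled-label null in the acceptance suite runs at the full 600/600:
  a held-out split of 240 gives the null AUC an SD of ≈ 0.037, which is
  what makes the [0.4, 0.6] acceptance band hold for ≥ 95% of seeds; a
  smaller split fails on sampling variance alone.
* Batch size 32 where the training regimen leaves it open; recorded in
  `ModelSpec`.
* CLI exit codes: 0 success, 2 configuration, 3 input data, 4 stage
  failure. Artifacts carry a config hash; logs (the only
  timestamp-bearing outputs) are excluded from byte-identity guarantees.

## Known limitations

* Hybridization is single-cut only (no double-cut/core swaps) and never
  re-aligns inputs; the MCS-based rigid aligner is a convenience utility,
  never invoked implicitly.
* The MLP trains on CPU at curated-set scale (~10³ compounds, ~15 s); it is
  not meant for 10⁶-compound training sets.
* QED/SA delegate to RDKit; swapping in alternative implementations is
  supported (pluggable scorer) but not bundled.
* Enrichment statistics assume a fully ranked library; censored or tied
  score blocks beyond stable-sort resolution are not modelled.
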
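# hybridscreen

A toolkit for ligand-based discovery of allosteric kinase inhibitors, built
around the workflow used to search for selective binders of the JAK2
pseudokinase (JH2) domain:

1. **Fragment hybridization** (BREED-style): ligands docked or crystallized
   into one binding site share a coordinate frame; every acyclic single bond
   between heavy atoms is a potential cut site, and when two cut bonds from
   different ligands superimpose — both endpoints within `d_max = 1.0` Å and
   bond vectors within `theta_max = 15°` — the fragments on either side are
   swapped, producing hybrid molecules that inherit the parents' binding
   geometry.
2. **Bioactivity classification**: each molecule becomes a 2048-bit ECFP4
   (Morgan, radius 2) fingerprint; a multilayer perceptron
   (2048 → 512 → 128 → 1, ReLU, 20% dropout between the hidden layers,
   sigmoid output) trained with Adam (lr 10⁻³, batch 32, 20 epochs) on
   binary cross-entropy scores the probability of activity.
3. **Triage funnel**: predicted actives (p ≥ 0.5) are filtered by an
   applicability domain (max Tanimoto to the training set ≥ 0.4), then by
   drug-likeness (QED ≥ 0.7) and synthetic accessibility (SA ≤ 3).
4. **Screen validation and reporting**: early-recognition statistics
   (ROC-AUC, RIE and BEDROC at α = 160.9, EF@2%/5%), docking selectivity
   gaps between two binding sites, and MM/GBSA binding-energy aggregation
   ΔE = E(complex) − [E(receptor) + E(ligand)] as mean ± SD over trajectory
   frames.

Docking, pose generation and MD simulation themselves are out of scope; the
package consumes their outputs (aligned SDF files, score tables, per-frame
energy tables) and produces everything around them.

## Worked example

Synthetic fixtures make the whole pipeline runnable without any external
data. Four benzylic analogues sharing an exactly superimposed scaffold are
hybridized, a planted-motif dataset (300 actives carrying an
aminobenzothiazole substructure, 300 decoys) trains the classifier, and the
hybrid library is pushed through the funnel:

```bash
hybridscreen fixtures aligned  --out demo/
hybridscreen fixtures activity --seed 1 --out demo/
hybridscreen hybridize --in demo/aligned.sdf --out demo/hybrids.sdf \
    --min-frag 2 --report demo/generation.json
hybridscreen train  --data demo/activity.csv --seed 1 --out demo/model/
hybridscreen screen --model demo/model/ --in demo/hybrids.sdf \
    --out demo/screening.csv --report demo/funnel.json
```

`generation.json` reports

```json
{"pairs_tested": 48, "matches": 24, "valence_drops": 0,
 "duplicates_removed": 12, "novel_kept": 12, "generations_run": 1}
```

— all 4·3 ordered ligand pairs with 2 directed cut bonds each were tested,
every pairing matched (the scaffolds superimpose exactly), and the 24
matched recombinations collapse to the 12 distinct head/tail crosses once
parents and duplicates are removed. Training prints a held-out panel with
accuracy and ROC-AUC of 1.0 (the planted motif makes the classes separable
by construction), and `funnel.json` shows the hybrids — which do not carry
the active motif — excluded at the activity stage:

```json
{"stage_order": ["activity", "ad", "qed", "sa"],
 "survivors": [0, 0, 0, 0], "excluded": [12, 0, 0, 0], ...}
```

Enrichment statistics for a ranked screen (e.g. docking scores over a
spiked decoy library) come from `hybridscreen enrich`, and per-frame energy
tables aggregate with `hybridscreen mmgbsa`. `hybridscreen pipeline
--config config.json` chains every stage and stamps all artifacts with the
configuration hash so reruns are byte-identical.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates all synthetic inputs from the seed, runs the complete pipeline
(hybridize → train → predict → screen → enrich) plus the enrichment and
MM/GBSA aggregations on generated tables, prints the resulting counts and
statistics, and writes the results file.

## Layout

| module | contents |
| --- | --- |
| `hybridscreen.chemio` | SMILES/SDF/CSV I/O, canonicalization, deduplication |
| `hybridscreen.hybridize` | cut-site enumeration, bond-vector matching, recombination, library generation, optional junction relaxation |
| `hybridscreen.screenmodel` | ECFP4 featurization, stratified split, the NumPy MLP, metric panels |
| `hybridscreen.triage` | Tanimoto applicability domain, QED, SA score, the screening funnel |
| `hybridscreen.rankmetrics` | RIE/BEDROC/EF/ROC-AUC, selectivity gaps, MM/GBSA aggregation |
| `hybridscreen.fixtures` | seeded synthetic generators with known ground truth |
| `hybridscreen.cli` | the `hybridscreen` console script and pipeline driver |

See `docs/methods.md` for the scientific and numerical details.
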
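# peprank

Pose rescoring for protein–peptide docking: a machine-learned scoring
function that predicts the heavy-atom RMSD of a candidate peptide pose
relative to the native bound conformation, and ranks docking poses by
that prediction.

## The problem

Docking engines tuned for small molecules handle short peptides
(3–10 residues) poorly: their scoring functions rarely place a
near-native pose first. A practical remedy is *rescoring*: generate an
ensemble of candidate poses with any engine, then re-rank them with a
model trained to predict each pose's RMSD to the native structure —
lower predicted RMSD, better pose. `peprank` implements that model
together with the full workflow around it: dataset curation filters,
descriptor calculation, structure-aware data splitting, feature
selection, docking-power evaluation and an applicability-domain
analysis. A synthetic-structure generator makes the whole pipeline
testable without any external downloads or docking engines.

## The model

Each pose is described by five feature families:

* **Ramachandran index** (8 terms): fractions `R_i = n_i / N` of
  residues falling in four boxed regions of the (Φ, Ψ) plane, where `N`
  counts residues with both angles defined; arithmetic means of Φ and
  Ψ; and mean kernel-density probabilities of Φ and Ψ under densities
  fitted on a reference pool of peptide backbone angles.
* **3D shape descriptors** of the peptide heavy-atom cloud (diameter,
  eccentricity radius, shape indices, principal moments of inertia,
  RMS plane deviation), each also normalized by heavy-atom and
  rotatable-bond counts.
* **Interaction energies**: a Coulomb term with distance-dependent
  dielectric, `E = Σ C q_i q_j / (k r_ij²)`, the receptor–ligand
  contact count at 4.5 Å, the contact-normalized energy, and any
  external engine scores merged from tabular input.
* **Interaction fingerprints**: hashed counts over paired
  ligand/protein circular atom environments for every intermolecular
  heavy-atom contact.
* **One-hot peptide length** (3–10).

A gradient-boosting regressor (histogram gradient boosting by default,
scikit-learn defaults) is trained on these features after a cleaning
cascade — collinearity filtering (|R| > 0.9) on the 3D family, variance
(0.1) and forest-importance (0.001) filtering on the fingerprints — and
sequential forward selection minimizing cross-validated MAE under
grouped folds that keep structurally similar complexes (binding-pocket
TM-score > 0.4) on one side of every split.

Ranking quality is measured as **docking power**: the fraction of
complexes whose top-n ranked poses include one with RMSD strictly below
2.0 Å (heavy-atom) or 2.5 Å (backbone). Prediction reliability is
mapped with a 1-nearest-neighbor applicability domain in the
8-dimensional Ramachandran descriptor space.

## Worked example

```python
from peprank import (SyntheticSpec, simulate_feature_dataset,
                     grouped_stratified_split, grouped_kfold)
from peprank.model import PoseRmsdModel
from peprank.pipeline import run_synthetic_pipeline

out = run_synthetic_pipeline(SyntheticSpec(n_complexes=50, seed=1))
print(out["results"].summary())
print(f"held-out MAE {out['held_out_mae']:.2f} A, "
      f"R {out['held_out_r']:.3f}, top-1 DP {out['dp_curve'].top(1):.2f}")
```

prints (elided):

```
Pose RMSD regression results
========================================
algorithm:         hgb
n training rows:   874
n features:        8
...
CV mean MAE (A):   0.239
CV mean Pearson R: 0.999
SFS selection order (feature, CV MAE):
  sim_signal_00                0.439
  sim_signal_04                0.322
  ...
held-out MAE 0.24 A, R 0.999, top-1 DP 1.00
```

On this simulated corpus (50 complexes × 23 poses, planted low-noise
signal) the model recovers the pose ranking essentially perfectly: the
held-out MAE sits near the planted noise floor, and for every
evaluation complex the top-ranked pose is a sub-2 Å one. Real
crystallographic data is far harder; these numbers demonstrate the
machinery, not real-data performance.

The same workflow is scriptable from the shell:

```sh
peprank synth --out bundle --n-complexes 4 --poses 6 --seed 7
peprank featurize --data bundle --out features.tsv --density density.json
peprank cluster-split --similarity bundle/similarity.tsv \
    --lengths bundle/lengths.tsv --out split.tsv --clusters-out clusters.tsv
peprank train --features features.tsv --split split.tsv \
    --clusters clusters.tsv --out model.joblib --report cv.tsv
peprank score --model model.joblib --features features.tsv --out scores.tsv
peprank dp --scores scores.tsv --labels bundle/poses.tsv --out dp.tsv
```

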
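# Methods

## Scope and model

`peprank` treats peptide docking pose selection as a regression
problem: predict the heavy-atom RMSD (Å) of a candidate pose relative
to the native bound conformation, then rank poses by the prediction
(ascending). The regressor is interchangeable (`linear`, `elasticnet`,
`rf`, `gb`, `hgb`, `svr`), all with scikit-learn default
hyperparameters; histogram gradient boosting is the default because it
matches the tree ensembles in accuracy at a fraction of the training
cost. No hyperparameter tuning is performed — on this class of problem
it adds nothing over the defaults, and defaults keep runs reproducible
and cheap.

## Structure handling and curation

PDB input is read through gemmi: first MODEL only (the intended inputs
are X-ray structures), alternate locations resolved to the
highest-occupancy conformer with ties going to the first encountered.
The writer emits fixed-column PDB at 3 coordinate decimals; write→read
is a fixed point on names, chains and coordinates, and serial numbers
above 99999 wrap modulo 100000. Partial charges are an input contract
(they would come from a charge-assignment tool upstream); for
round-tripping synthetic fixtures they ride in the B-factor column at
two decimals, and the synthetic generator rounds its charges to match.

Receptor chains are "interacting" when at least one heavy atom lies
strictly closer than 5.0 Å to a peptide heavy atom. The curation
filters, each reported independently, discard complexes with (i) a
non-water small molecule or (ii) a metal ion within 7 Å of *any*
peptide atom (hydrogens included — the rule is about the peptide's
surroundings, and measuring to all atoms is the stricter reading),
(iii) peptide residue-numbering gaps, (iv) peptide residues missing
heavy atoms versus the standard templates (OXT never required), or
(v) receptors under 500 atoms. The metal list is the twelve standard
biologically relevant monatomic cations. Missing-residue detection uses
numbering gaps only — no SEQRES reconciliation — which is a documented
limitation for structures whose authors renumbered without gaps.

## Geometry

Dihedrals follow the IUPAC sign convention via the standard
atan2 formulation. RMSD between poses defaults to the fixed receptor
frame (no superposition): docking poses share the receptor's coordinate
system, and aligning first would flatter mislocated poses. A
`superpose=True` variant (Kabsch) is exposed because toolkits commonly
align by default; which convention a given external dataset used is
worth checking before comparing numbers. Heavy-atom RMSD is minimized
over chemically equivalent-atom permutations — Asp OD1/OD2, Glu
OE1/OE2, Phe/Tyr ring flips (CD and CE pairs swapped together), Arg
NH1/NH2, and the C-terminal O/OXT. The groups are independent across
residues, so without superposition the exact minimum is found
per-residue; with superposition the full product (≤2 options per
residue) is enumerated. Backbone RMSD uses N, CA, C, O and needs no
permutations. Binding pockets are whole receptor residues with any
atom within 10 Å of any peptide atom (inclusive boundary); contacts
are heavy-atom pairs strictly under 4.5 Å, the usual interaction-
fingerprint contact convention, configurable.

## Ramachandran index

Eight terms per peptide: four region fractions, two angle means, two
mean KDE densities. The region boxes on the (Φ, Ψ) plane are fixed
constants derived once from a 2-D angle-density analysis of a large
peptide pool:

| region | boxes (Φ range × Ψ range, degrees) |
|---|---|
| 1 | [−130, −50] × [120, 180]; [−75, −60] × [−50, −25] |
| 2 | [−150, −45] × [100, 180]; [−90, −45] × [−65, 0] |
| 3 | [−180, −30] × [−180, 180]; [−30, 105] × [−30, 90] |
| 4 | complement |

The printed boxes overlap (region 1's boxes sit inside region 2's), so
assignment tests regions in priority order 1 → 2 → 3 and falls through
to 4; only with that precedence do the counts partition the residues
and the fractions sum to exactly 1. Box boundaries are inclusive — a
measure-zero choice fixed for determinism. `N` counts residues with
*both* angles defined, which excludes the termini; a 2-residue peptide
therefore has no index and is rejected. Angle means are arithmetic on
[−180, 180] with no circular wrap-around, and the Φ/Ψ probability terms
evaluate two independent 1-D Gaussian KDEs (Scott's bandwidth) fitted
on a configurable training pool of backbone angles; the fitted pool is
serialized to JSON so inference reuses the training-time density. The
linear (non-circular) treatment mirrors the behavior of the standard
1-D KDE implementations; it slightly misweights angles near ±180°,
which the helix/sheet-dominated pools used here rarely visit.

## Descriptors

3D shape descriptors operate on the heavy-atom cloud: Diameter3D (max
pairwise distance), Radius3D (min over atoms of max distance to any
atom), GeometricalShapeIndex and PetitjeanIndex3D (both (D − R)/R, the
shared ratio convention), the three principal moments of inertia at
unit masses, and PBF as the RMS distance of atoms to their
least-squares plane (smallest principal axis of the gyration tensor).
Each value is also emitted divided by the heavy-atom count and by a
template-counted rotatable-bond number (Φ/Ψ torsions plus standard
side-chain χ counts; proline rings count 0). Surface-area (CPSA-class)
descriptors are not computed natively — they need a molecular-surface
engine — and can enter as external columns instead.

The electrostatic term uses ε(r) = k·r (k = 1 by default), i.e. each
intermolecular pair contributes C·q_i·q_j/(k·r²) with
C = 332.0636 kcal·Å/(mol·e²); no distance cutoff by default. The
contact-normalized score divides by the contact count, with a logged
0 convention when there are no contacts. Other engine scores
(force-field, Poisson–Boltzmann, empirical docking scores) are
external columns merged by (complex_id, pose_id) with strict join
integrity in both directions.

The interaction fingerprint is a deterministic, simplified
extended-connectivity scheme: bonds come from standard-residue
templates plus inter-residue peptide bonds (distance fallback at
1.9 Å for non-template residues); atom environments grow per depth
from (element, degree) seeds; for each contact pair the ligand and
protein environment identifiers, clamped at depths 2 and 4, are hashed
(seeded CRC-32) into 16,384 count buckets. Bucket identity is not
comparable with any other tool's fingerprints — irrelevant for
learning — but is bit-for-bit reproducible across runs and platforms.

## Splitting

Binding-pocket similarity arrives as a square TM-score matrix in
[0, 1] from an external structural aligner; asymmetric input (the two
per-pair chain-length normalizations) is symmetrized by the maximum,
matching the longer-chain normalization. Complexes connect when their
score strictly exceeds 0.4, and connected components become structural
clusters (labels: smallest member id). Train/evaluation splitting uses
scikit-learn's StratifiedGroupKFold with 4 splits — clusters as atomic
groups, peptide length as the stratum, first fold held out (≈25%) —
with length classes rarer than the split count pooled so stratification
stays well-defined on small data. Cross-validation folds come from
GroupKFold with shuffling; both are deterministic given the seed. A
greedy longest-first sequence-identity clustering (global alignment,
unit match/mismatch/gap scores, identity = matches/alignment length,
threshold 0.75) stands in for the external redundancy-reduction tool.

## Learning machinery

Cleaning: greedy column-order collinearity removal within the 3D
family (drop when |Pearson R| with a retained column exceeds 0.9;
constant columns are self-collinear), variance filtering (threshold
0.1 of {0.01, 0.1, 0.5}) and forest-importance filtering (impurity
importance > 0.001, fixed seed) for the fingerprint family. Sequential
forward selection adds, at each step, the feature minimizing
CV-average MAE over the grouped folds and returns the prefix with the
global best MAE; the selection order is preserved because
earlier-selected features carry more signal. An optional
`max_features` cap bounds the scan. Folds with zero prediction
variance are flagged and excluded from the Pearson-R average rather
than poisoning it. Predictions are clipped below at 0 Å. The trained
scorer persists as a single versioned joblib bundle carrying the
estimator, its ordered feature schema and training metadata; schema
alignment at predict time is by name, so column order is irrelevant.
One master seed expands deterministically into per-component seeds.

## Evaluation

Docking power: success for a complex at rank n means the minimum RMSD
label among its top-n poses is *strictly* below the threshold (2.0 Å
heavy-atom, 2.5 Å backbone by convention); the curve over n = 1..10 is
non-decreasing by construction, and monotone in the threshold. Pose
ranking is a stable sort, ties keeping input order.

Applicability domain: 1-NN Euclidean distances in the 8-dimensional
Ramachandran space (or any supplied descriptor block); pairs beyond
the 95th percentile of the distance distribution (linear-interpolation
percentile convention) are excluded as outliers, the rest binned at
every 10th percentile with right-closed edges, and per-bin MAE is
correlated against both bin midpoints and bin mean distances — the two
reasonable readings of "binned correlation"; with errors exactly equal
to distances the mean-distance variant is exactly 1. Distribution
shift between pose sets is quantified by the two-sample
Kolmogorov–Smirnov test (SciPy).

## Synthetic data: what it emulates and what it does not

The generator stands in for crystallographic complexes and docking
engines. Peptides are built by sequential internal-coordinate (NeRF)
placement at idealized geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N
1.329 Å, ω = 180°, standard angles, backbone + CB + terminal OXT);
only dihedral correctness matters for the descriptors, and requested
angles are reproduced to well under 1e−6°. Decoys hit a target RMSD
(0–20 Å) by pure translation (exact), backbone-dihedral noise, or
both, with bisection on the perturbation amplitude to within 5% — a
derivative-free scheme that terminates because the RMSD response is
monotone in the amplitude. Receptors are charged dummy-atom shells in
a radial band around the peptide. Pose ensembles default to 23 per
complex with at least two sub-2 Å poses, mirroring the docking
convention the evaluation assumes.

Feature tables with planted signal use standardized deterministic
transforms of the RMSD target plus N(0, σ) noise (σ = 0.1 by default,
0.05 in the low-noise pipeline recovery setting), alongside Gaussian
and Bernoulli noise columns and one-hot lengths; cluster structure is
dominated by singletons (new-cluster probability 0.6), matching the
shape of a redundancy-reduced structural dataset.

None of this reproduces real data's difficulty: no side chains beyond
CB, no sterics or energetics in decoy generation, planted features far
cleaner than real descriptors. Passing tests therefore demonstrate that
the machinery is correct and leak-free — not that the model would reach
any particular accuracy on crystallographic complexes.

## Problem sizes and numerical choices

The shipped pipeline runs at desk scale: 30–50 complexes × 23 poses,
SFS over ≤ 8–10 features with a fast linear selector and 5 grouped
folds, tree ensembles at defaults. Bisection tolerance for decoys is
5%; KDE integrals are checked to 1e−3; fraction sums to 1e−12;
builder round trips to 1e−6°. Degenerate inputs fail loudly: collinear
atom clouds (plane undefined), zero-variance angle pools, peptides
without scorable residues, folds with fewer than two rows,
zero-variance Pearson inputs.
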
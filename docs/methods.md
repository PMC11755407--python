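# Methods

## The problem setting

Binary activity classification against the PD-1/PD-L1 checkpoint is an
extreme-imbalance problem: curated public collections hold roughly 3 actives
per 200 inactives.  `pdlscreen` builds classifiers on such data and applies
them to approved-drug libraries under an applicability-domain (AD)
constraint, so that only predictions made inside the chemistry the model has
seen are trusted.

## Curation

Structures are standardized in a fixed order: (1) keep the fragment with
the most heavy atoms among carbon-containing fragments, breaking ties by the
lexicographically smallest canonical SMILES (a reproducible reading of
"remove small disconnected fragments"); (2) normalise functional-group and
mesomeric representation; (3) choose the canonical tautomer by RDKit's
deterministic tautomer scoring, configured **not** to erase sp3 or
double-bond stereochemistry — deduplication is stereochemistry-aware, so
enantiomers must survive as distinct records; (4) perceive aromaticity and
emit canonical SMILES plus the standard InChI.  The pipeline is idempotent;
a molecule with no organic fragment (a pure salt) raises an explicit
empty-structure error.

Duplicates are grouped on the stereo-aware InChI.  Groups that disagree on
the label become *conflict groups*; the default resolution policy is `drop`
(conservative — a molecule with contradictory assay labels carries no usable
signal), with `prefer_active`, `prefer_inactive` and `majority` available
where a user wants to mimic manual assay alignment.

Splits are stratified by class: each class contributes `round(f·n_c)`
molecules (at least one) to the test partition.  Plain random splitting
could leave the rare active class absent from a partition; stratification is
the minimal scheme that guarantees representation.  A second test set can be
carved out of the training ids for nested validation without disturbing the
primary partition.

## Descriptors

* **Fingerprints.** MACCS keys 1–166; hashed circular (Morgan) fingerprints,
  1024 bits.  The circular radius is 2 (the ECFP4-equivalent community
  default) and configurable; hashed path fingerprints use 2048 bits.
* **2D panel.** 242 named descriptors: the 42 molecular quantum numbers plus
  200 RDKit whole-molecule descriptors frozen by name in
  `pdlscreen._manifest_2d`.  Freezing the manifest makes column identity
  stable across runs and library patch versions; the information-content
  descriptors prone to numeric overflow (`Ipc`, `AvgIpc`) and the
  sometimes-undefined `BCUT2D_*` eigenvalue descriptors are excluded.  A
  descriptor undefined for a molecule is imputed 0 and flagged.
* **3D families.** AUTOCORR3D (80), MoRSE (224 — unweighted plus mass, van
  der Waals volume, polarizability, ion-polarity and I-state weighted
  blocks), RDF (210) and WHIM (114), computed on a single conformer.
  Conformers come either from ETKDG embedding (seeded) or from docked poses:
  `adopt_docked_pose` verifies that pre- and post-docking SDF records are
  the same molecule (equal InChI), matches atoms by subgraph isomorphism,
  and among automorphic matches picks the one whose mapped coordinates move
  least — a deterministic resolution of symmetry-equivalent atoms.
* **Voxel grids.** A cube of `n³` voxels (default 11³ = 1331, 15 Å side) is
  centred on the heavy-atom centroid.  Each atom's property weight —
  atomic number, Crippen logP or molar-refractivity contribution, or
  Gasteiger/MMFF partial charge with hydrogen contributions folded onto
  their heavy neighbours — is spread with an isotropic Gaussian of width
  σ = 0.7 × voxel pitch, truncated at 3σ.  The kernel is normalised over the
  full truncated lattice ball, so the grid total equals the total atomic
  weight exactly for molecules that fit; weight falling outside the cube is
  reported as a clipped fraction and warned about above 2 %.  Grid geometry
  is exposed in `GridSpec` because no single published geometry is canonical;
  results are therefore always labelled with their spec.

## Clustering and the applicability domain

Clustering uses a deterministic leader (sphere-exclusion) pass over
molecules in a canonical order (descending fingerprint popcount, then bit
pattern, then id): a molecule joins its most similar leader if that
similarity reaches the cutoff (default 0.25), otherwise it opens a new
cluster.  The largest four clusters are labelled A–D by decreasing size and
absorb the members of any smaller cluster.  The centroid of a cluster is the
member with the highest mean Tanimoto similarity to the rest (ties broken by
canonical SMILES).  Members whose similarity to their own centroid is below
0.195 move to the residual category X; centroids are then recomputed once —
a single pass keeps the procedure terminating and deterministic, at the cost
that a recomputed centroid may leave a few members marginally below the
threshold (these are reported, not hidden).

The AD rule is deliberately the only part of the cluster structure that
downstream stages depend on: a molecule is in-domain iff its **maximum**
Tanimoto similarity over the five centroids (A–D and X) is **≥ 0.195** —
the boundary itself is in-domain.  The similarity fingerprint family is the
same one the selected model uses (1024-bit circular by default).
Membership is monotone in the threshold.  Murcko-framework counts per
cluster summarise scaffold diversity; acyclic molecules share the empty
framework bin.

## Models

* **Balanced random forest** (the workhorse).  Each of 500 unpruned CART
  trees is grown on a bootstrap containing `n_min` actives and `n_min`
  inactives drawn with replacement, where `n_min` is the minority-class
  size — the imbalance handling that mirrors forcing the per-tree sample to
  the rare class size.  `max_features='sqrt'` per forest convention.  The
  predicted probability is the literal fraction of trees voting active, and
  OOB predictions for a molecule use only trees whose bootstrap excluded it.
  500 trees is the default (OOB metrics move by < 0.02 MCC going to 1000 on
  the synthetic fixture); tree count is configurable.
* **Descriptor importance** is permutation mean-decrease-accuracy: for each
  tree, accuracy on its OOB sample is compared before and after permuting
  one column; only columns the tree splits on are permuted (others cannot
  change its output and contribute zero), and decreases are averaged over
  all trees.  OOB samples above 500 rows are subsampled with the ranking
  seed for speed.  Top-*k* subsets (k ∈ {25, 50, 100, 150} typical) feed
  smaller forests.
* **SVM**: RBF-kernel C-SVM with balanced class weights on z-scored
  features; the default C = 3.593813663804626 and γ = 0.007742636826811269
  come from a 10-fold grid search over C ∈ [1, 50], γ ∈ [10⁻⁴, 10⁻²] on the
  original activity data.  Probabilities are Platt-calibrated.
* **MLP**: four hidden layers of 50 ReLU units, Adam, log loss, batch 36,
  up to 500 epochs, Glorot-style initialisation (the scikit-learn default),
  on z-scored features.  Determinism is best-effort within the backend.
* The forest consumes raw descriptor values (trees are scale-invariant);
  kernel and gradient methods get z-scoring.  The 0.64 screening threshold
  is only ever applied to the forest vote fraction.
* MCC with a zero denominator factor is defined as 0 (keeps the
  all-negative-prediction case finite); sensitivity/specificity follow the
  standard definitions SE = TP/(TP+FN), SP = TN/(TN+FP).

## Screening

A library molecule passes iff `p_active ≥ 0.64` **and** it is inside the
AD.  The probability threshold is a config constant (`ScreeningConfig`),
as is the AD threshold.  Docking affinities arrive as data (TSV of id and
ΔG in kcal/mol; duplicates keep the most negative value; malformed rows are
reported with line numbers) — this package never runs a docking engine.  An
optional ΔG ≤ −11 kcal/mol gate is off by default because docking is used
qualitatively, after the QSAR criteria.  Ranking is fully deterministic:
passed first, then descending probability, ascending ΔG, descending centroid
similarity, id.

## Synthetic data: what it emulates and what it does not

The generator emulates the *shape* of a curated bioactivity collection —
desk scale (default n = 3000), 1.4 % actives (the ratio of ~400 actives to
~28 000 molecules), optional symmetric label-flip noise — with activity
*structurally determined*: a molecule is truly active iff it contains a
biphenyl and an amide or 1,3-oxazole, motifs recurrently enriched in PD-L1
actives.  Molecules are assembled from a template grammar (ring cores ×
substituents) and every structure is verified against the planted SMARTS
rule after generation, so actives provably match and inactives provably do
not.  Two design points matter:

* the inactive pool contains deliberate hard negatives — biphenyl-without-
  amide and amide-without-biphenyl decoys — so the rule is a genuine
  conjunction, as in real SAR series where inactive analogues share the
  active scaffold;
* active templates place the second motif ortho or meta to the biphenyl
  junction, guaranteeing that some radius-2 circular environments span both
  motifs.  This makes the rule expressible in fingerprint space, so a
  fingerprint model can in principle reach MCC ≈ 1 and model-family
  comparisons measure the learner, not the representation ceiling.

Screening libraries add a planted-hit block and a block of molecules from
scaffold families absent from the grammar (steroid-like polycycles, crown
ethers, sugars, perfluorinated chains, cage hydrocarbons); unrelatedness is
asserted at generation time as maximum Tanimoto < 0.15 to grammar
exemplars, which exercises the AD filter.

What passing on synthetic data does **not** show: the generator does not
mimic real chemistry-space density, assay noise structure, activity cliffs
or 3D pose realism (3D tests use embedded geometries).  Near-perfect
recovery on the planted rule validates the machinery, not expected
performance on experimental data.

On label noise: with 1.4 % actives, a symmetric flip rate of 1 % creates
roughly 0.7 fake actives per true active.  Against such observed labels no
classifier — including a perfect oracle for the planted rule — can exceed
MCC ≈ 0.75, so end-to-end *recovery* checks are run at zero noise, where the
rule is exactly learnable; behaviour under the noisy default is reported as
a rank-based statistic (fraction of true actives above the 95th percentile
of inactive OOB probability) and as MCC against both observed and true
labels in the acceptance script.

## Pipeline and reproducibility

`run_pipeline` executes curate → featurize → cluster/AD → train →
screen from a YAML `RunConfig`, validating it up front.  One global seed is
fanned out per stage as `seed XOR crc32(stage_name)` (kept below 2³¹), so
stages are individually re-runnable; re-running an identical config
reproduces the OOB confusion matrix exactly.  Every stage writes its
artifact (CSV/JSON) and the manifest records seeds, artifact names, a config
hash and all headline metrics, so every number in a report traces to a file.

Problem sizes throughout the shipped tests and the acceptance script are
desk-scale choices (n = 3000 training molecules, 200-molecule libraries,
300–500 trees) — large enough that balanced bootstrap bags (~84 draws) carry
both decoy classes, small enough that the whole suite runs in about a
minute.

## Known limitations

* The leader-clustering membership is not meant to reproduce any particular
  proprietary clustering tool; only the centroid + threshold AD surface is
  contract.  Exact per-cluster counts on external datasets will differ.
* Single-pass centroid recomputation after X-pruning can leave borderline
  members slightly below the threshold relative to the new centroid.
* MMFF charge grids require MMFF-typeable molecules and raise otherwise.
* The 2D panel is a frozen 242-name manifest; other tools enumerate
  different panels, so numeric parity across packages is not a goal —
  column identity and reproducibility are.
* OOB probabilities are NaN for molecules in every bag (vanishingly rare
  beyond ~50 trees); they are treated as inactive in OOB metrics and warned
  about.
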
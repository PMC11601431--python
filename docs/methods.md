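# Methods

This note documents the models, conventions and numerical choices behind
`protpka`, in the order data flows through the package.

## Structures and conventions

Input is PDB (or mmCIF) parsed by gemmi and reduced to a heavy-atom
representation: hydrogens and deuteriums are dropped (experimental
structures mostly lack them, and all features are defined on heavy atoms),
waters are discarded, other heteroatoms are kept in a separate ligand list
that currently does not participate in features.  Alternate locations are
resolved to the highest-occupancy conformer, first record on a tie.
Residues are keyed by (chain, author residue number, insertion code);
coordinates are Å.

A *titratable site* is any Asp/Glu/His/Cys/Tyr/Lys residue with at least
one anchor atom present (Asp OD1/OD2, Glu OE1/OE2, His ND1/NE2, Cys SG,
Tyr OH, Lys NZ).  The anchor point — the centroid of the anchor atoms
present — is the origin for every distance-based feature and for graph
truncation, because it is where the proton chemistry happens.

**SASA.**  Shrake–Rupley with a 1.4 Å water probe and 960 golden-spiral
quadrature points per atom; van der Waals radii C 1.70, N 1.55, O 1.52,
S 1.80 Å, unknown elements 1.80 Å with a warning.  At 960 points the
per-atom quadrature error is below 2 % (verified against a doubling of the
point count and against an independent implementation); the isolated-atom
value is analytic, 4π(r+1.4)².

**Secondary structure.**  A deliberately small 3-state assigner: helix
requires backbone dihedrals in (−100° ≤ φ ≤ −30°, −80° ≤ ψ ≤ −4°) plus an
i→i+3/i+4 carbonyl-O to amide-N contact ≤ 3.5 Å; strand requires extended
dihedrals (φ < −90°, ψ ≥ 90° or ψ ≤ −150°); everything else, including
residues with incomplete backbone context, is coil.  This is not DSSP;
only the coarse H/E/C distinction feeds the models.

## Feature catalog (`protpka-feat-v1`)

Features come in the three physical groups that determine pK<sub>a</sub>
shifts — desolvation, hydrogen bonding, electrostatics — plus categorical
context.  Numeric entries: solution (model) pK<sub>a</sub>; buried ratio;
sidechain SASA; heavy-atom packing counts at 6/8/10 Å; polar / positive /
negative residue counts at 10 and 15 Å; nearest and second-nearest
distances to polar sidechain atoms, His sidechain nitrogens, carboxylate
oxygens, chargeable nitrogens, backbone O and backbone N.  Categorical:
residue type, secondary structure of the site and the majority class
within 10 Å, and the sign of the summed formal charge within 10 Å
(standard states at pH 7: Asp/Glu −1, Lys/Arg +1, His 0).

Conventions that matter:

- counts are **residue-level** (a residue with two qualifying atoms counts
  once); radii are inclusive (≤ r);
- distances are anchor-to-atom, self excluded; a missing partner yields a
  20 Å sentinel — twice the 10 Å electrostatic-relevance radius — so the
  features stay bounded and tree models see a plateau rather than a hole;
- the buried-ratio denominator is the sidechain SASA of the residue in an
  extended Gly-X-Gly tripeptide built with the package's own ideal
  geometry and scored with the package's own SASA engine.  This keeps the
  ratio exactly 0 for the reference conformation and independent of any
  external normalization table; the catalog version string would change if
  either convention did.

The catalog is ordered and versioned; model bundles record the version and
refuse mismatched feature tables.

## Labels, splits, augmentation

Experimental labels are keyed by a *unique residue* identity — protein
accession, residue number, mutation tag, conformational-state tag —
because the same residue appears under different numbers in different PDB
files and would otherwise leak between train and test.  Multiple
measurements of one residue remain separate records sharing one key and
always travel together through splits.  Rows with non-numeric pK<sub>a</sub>'s
(ranges like ">9") are skipped with a warning; values are required to lie
in [0, 16].

Splits are stratified residue-level 90/10 holdouts: unique keys are binned
into 5 quantile bins of their mean pK<sub>a</sub> (merged when a test draw
could not cover 5 strata), and each of the default 20 splits is drawn with
its own child seed spawned deterministically from the master seed via
`numpy.random.SeedSequence`.

Conformer augmentation adds alternative structures — in production,
predicted models; at desk scale, the jitter generator below — for training
residues whose |pK<sub>a</sub> shift| exceeds 2 units, capped at 10
conformers, each copy carrying the original label.  Augmentation is
applied strictly after splitting and only to the training side; the
leakage guard is property-tested and re-scanned in the acceptance script.

## Tree models

Acids (Asp, Glu, Cys, Tyr) and bases (His, Lys) get separate regressors:
the same environmental change shifts their pK<sub>a</sub>'s in opposite
directions (burial stabilizes the neutral form — up for acids, down for
bases; a nearby carboxylate stabilizes the protonated form of a base but
the protonated form of an acid too, with opposite sign on the shift).  A
partition guard refuses, e.g., Lys rows presented to the acid model.

`TreePkaRegressor` wraps five interchangeable tree families (sklearn
histogram gradient boosting — the default, sklearn GBM, xgboost, extra
trees, random forest) behind one interface.  Selection is by mean MSE over
a shuffled 10-fold CV across a small documented grid (histogram GBM:
depth {4, 6, 8} × learning rate {0.05, 0.1} × iterations {300, 600});
fitting is deterministic given the seed.  A single-valued label set falls
back to a constant predictor with a warning.  Feature attribution uses
permutation importance (mean MSE increase, ties broken by catalog order)
and partial-dependence slopes; both operate on the fitted model and are
the package's model-inspection surface.

The repeated-holdout protocol trains both partition models on every
split's training keys and emits one prediction per (record, structure)
pair of the test keys, so residues with several usable structures
contribute several test instances.

## Protonation classes and metrics

Protonation probability of an independent site is
`Prob = 1/(1+10^(pH−pKa))`; thresholding at 0.75/0.25 gives pK<sub>a</sub>
boundaries pH ± log10 3, displayed as 6.52/7.48 at pH 7.  Classification
uses the full-precision boundaries: the His solution value 6.5 lies just
*below* 6.5229 and is therefore deprotonated-leaning, which double
rounding would silently flip.  High pK<sub>a</sub> at fixed pH means
protonated; boundaries are inclusive into the titrating class.

Regression metrics (PCC, RMSE, maximum absolute error) are computed per
split and reported as mean ± SD (n−1).  Classification is pooled: class
labels from all splits accumulate into one 3×3 confusion table first.  The
two orders genuinely differ and the package asserts the difference with a
constructed counterexample.  Instances whose experimental *or* predicted
class is titrating are excluded from precision/recall and from the
critical error rate CER = (protonated predicted deprotonated +
deprotonated predicted protonated) / scored instances.  Because exclusion
depends on model output, two models evaluated on identical test data can
have different CER denominators; reports carry the denominator explicitly.
A metric whose denominator is empty (a class never predicted) is NaN,
never 0.

## Graph-attention model

The microenvironment graph holds every protein heavy atom within 10 Å of
the anchor point — the approximate range of pK<sub>a</sub>-relevant
electrostatics — with undirected edges between atoms closer than 4.0 Å
(covalent bonds plus close contacts).  Nodes carry a 66-wide embedding:
a 42-wide physicochemical block (residue-type one-hot, per-atom formal
charge class, aromaticity, donor/acceptor flags, backbone/sidechain role,
four radial distance bins plus the normalized anchor distance, anchor and
central-residue flags, acid/base character of the central residue, element
group) and a 24-wide one-hot over protein heavy-atom type classes (17
exact names, 6 merged families, 1 catch-all).  The width is versioned
(`protpka-node-v1`).

The regression target is the pK<sub>a</sub> *shift*; the solution value is
added back at prediction time.  One model serves acids and bases — the
acid/base character is a node feature — so the scarce Cys/Tyr data share
the trunk with the abundant Asp/Glu data.

Architecture: three single-head attention convolutions of width 42
(LeakyReLU(0.2) attention logits, per-target softmax over incoming edges
with self-loops, ELU update), global average pooling, a 32→16 ReLU MLP
with inverted dropout 0.2, linear output.  Training is full-batch Adam at
10⁻³ on MSE with early stopping (patience 20) on a 10 % validation slice;
the best-validation parameters are restored.  The implementation is pure
numpy over flat edge arrays with precomputed sparse scatter matrices;
backward passes are hand-derived and verified against finite differences
(with one-sided checks at ReLU kinks).  Given a seed the whole training
run is bit-reproducible, which is what makes the layer-freeze contract
testable bitwise: fine-tuning with `frozen_layers=k` leaves conv layers
0..k−1 untouched.

The ensemble trains k (default 10) members on distinct 9:1
train:validation splits drawn from per-member child seeds and averages
predicted shifts.  Capacity checks train with dropout active but always
evaluate in inference mode (dropout off), the standard definition of a
memorization test.

## Synthetic data generator

Each synthetic site is a Gly-X-Gly tripeptide (ideal backbone geometry,
extended conformation, NeRF-built sidechains) surrounded by

- *surrogate neighbors*: single-residue fragments placed so their contact
  atom (Ser OG = polar, Asp OD1 = carboxylate oxygen, Lys NZ = chargeable
  nitrogen, His ND1 = His-type nitrogen) sits at a planned distance from
  the anchor, oriented radially outward and clash-checked (≥ 2.4 Å);
- a *burial cage*: single-carbon pseudo-residues on two interleaved
  spherical shells (6.0 and 8.2 Å; 48 + 64 positions) consumed in a fixed
  order, so cage occupancy — and hence the computed buried ratio — is
  monotone and nested in the requested burial level.

Ground-truth labels are a monotone function of the *featurized*
descriptors, which makes generator and featurizer consistent by
construction: acid pK<sub>a</sub> = model + 3.0·buried_ratio +
0.25·n_polar10 − 1.0·prox(d0_neg_O); base pK<sub>a</sub> = model −
2.0·buried_ratio − 0.25·n_polar15 + 1.5·prox(d0_neg_O), with
prox(d) = max(0, (20−d)/20).  The sign structure mirrors protein
electrostatics (burial and polar crowding raise acid and lower base
pK<sub>a</sub>'s; a nearby carboxylate does the reverse) and is what the
sign-opposition test recovers from trained models.  Observation noise is
additive Gaussian (default σ = 0.3, roughly the scale of experimental
uncertainty); labels are clipped to [0, 16].  Burial levels default to a
Beta(1, 2) draw — most sites modestly buried, a tail deeply buried — which
leaves large shifts (> 2 units) a well-represented minority, so the
augmentation path is always exercised.  Default neighbor counts are 0–4
polar, 0–2 negative, 0–2 positive, 0–1 His at 3.5–9.5 Å.

Conformer jitter perturbs all coordinates with isotropic Gaussian noise
(amplitude ≤ 0.5 Å) and repairs steric clashes by halving the displacement
of offending atoms until no non-bonded pair (originally ≥ 2.2 Å) is closer
than 2.0 Å; this converges because the perturbation contracts toward the
clash-free input.

**What the generator does not emulate** — and hence what passing tests do
not show about real proteins: real folds (the cage is an abstract
desolvation knob, not packing), conformational coupling between ionization
and structure, waters and ligands, correlated multi-site titration, and
experimental label biases.  Tests on this generator demonstrate that the
pipeline recovers known monotone structure-to-pK<sub>a</sub> relationships
at realistic noise; they do not certify accuracy on experimental data.

## Problem sizes and numerical choices

The test and acceptance workloads run at desk scale by design: noise
recovery uses 2000 single-residue sites (holdout RMSE approaches the 0.3
noise floor), attribution and sign-opposition use 600 sites each, the
graph capacity check memorizes 20 noise-free graphs in a few hundred
epochs, and the
leakage scan covers 20 splits of 500 residues.  Tolerances: rigid-motion
invariance is exact for counts and categorical features, 10⁻⁶ Å for
distances, 1 % of the isolated-sphere area per atom for SASA (quadrature
is orientation dependent) and 2 % of the natural scale for sidechain-sum
quantities (buried ratio, sidechain SASA), where per-atom wobble
accumulates; quadrature convergence 2 %; the analytic sphere 1 %.
Degenerate inputs have defined behaviour throughout: empty structures and
water-only files raise format errors naming the offending content,
residues missing all anchor atoms are reported and skipped, constant
labels yield constant predictors with a warning, zero-variance PCC and
never-predicted-class precision surface as NaN.

## Known limitations

- The feature catalog is a faithful representative of the three physical
  groups, not a reconstruction of any particular published feature list;
  absolute feature values depend on the SASA and secondary-structure
  conventions above.
- The numpy graph network is CPU-bound and full-batch; it is sized for
  hundreds of graphs, not for database-scale pretraining.
- Ligands and waters are parsed but invisible to features; metal sites
  and cofactor effects on pK<sub>a</sub> are out of scope.
- Single-site Henderson–Hasselbalch ignores titration coupling between
  nearby residues.
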
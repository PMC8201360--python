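# Methods

## Peptide model and feature space

A peptide is a sequence over the 20 canonical amino-acid letters, at least
two residues long. Non-canonical and ambiguity codes (B, J, O, U, X, Z) are
rejected rather than translated, because the dipeptide feature space is
defined over exactly 20 letters (400 ordered pairs) and a silent remapping
would distort compositions.

The descriptor of a peptide is a fixed-order 407-vector:

| block | features | units / scale |
|---|---|---|
| scalars (7) | mass, length, GRAVY, n⁺, n⁻, net charge, hydrophobic fraction | Da; residues; dimensionless |
| dipeptides (400) | overlapping-pair relative frequencies, lexicographic AA…YY | each in [0, 1], summing to 1 |

Choices fixed for reproducibility:

* **Masses are average, not monoisotopic**, with one water added. The value
  is a descriptor for classification, not a spectral-matching mass; either
  convention is self-consistent, one had to be fixed.
* **Hydrophobicity is Kyte–Doolittle GRAVY**, the field default when a
  "hydrophobicity score" is named without a scale.
* **Charged-residue counts, not pH-dependent charges**: n⁺ counts K, R and H,
  n⁻ counts D and E, termini are uncharged. These are composition counts;
  no Henderson–Hasselbalch model is implied.
* The scalar block is completed by **net charge** (n⁺ − n⁻) and the
  **hydrophobic-residue fraction** over {A, V, L, I, M, F, W, C}. These two
  are a declared convention of this package: they are minimal, standard
  descriptors that bring the dimensionality to the fixed 407 the classifiers
  consume.

## Classifier pair and training protocol

Per property category the protocol is: random oversampling of the minority
class to parity → stratified 70%:30% split → fit kNN and RF → evaluate on
the held-out 30%.

* **Oversampling is plain duplication with replacement**, seeded; no
  synthetic-example interpolation. Balancing happens **before** the split.
  This ordering is deliberate — it is the protocol this package
  reproduces — but it lets duplicated minority examples appear on both
  sides of the split, which biases held-out metrics optimistically when
  classes are imbalanced. On balanced inputs (the synthetic defaults) the
  oversampler is a no-op and no leakage occurs.
* **kNN**: k = 2, Euclidean distance. The seven scalar descriptors are
  z-scored on the training set (a zero-variance scalar standardizes to 0);
  the 400 dipeptide frequencies are left in their natural scale. Scaling is
  block-wise on purpose: the scalars live on wildly different scales (mass
  in hundreds of Da against fractions), so they must be standardized, but
  per-feature unit variance on the sparse dipeptide block inflates
  rare-pair noise — a pair seen once in training acquires a tiny variance
  and a huge standardized spike — until 400 noise dimensions swamp the
  signal and accuracy collapses to chance. The frequencies are already
  commensurable (bounded, unit-sum), so they need no rescaling.
* **kNN tie rules** (k = 2 gives 1-vs-1 ties often): positive fraction
  > ½ wins; at exactly ½ the nearer neighbour's class wins; an exact
  nearest-distance tie between opposite classes resolves to positive. All
  three rules are deterministic and tested.
* **RF**: 1000 bootstrap CART trees, Gini criterion, per-split feature
  subset of ⌊√407⌋ = 20 (scikit-learn's `max_features="sqrt"`), majority
  vote with exact vote ties resolved to positive. Trees are scale-invariant,
  so the RF consumes raw features.
* **Evaluation panel**: accuracy, sensitivity, specificity from the
  confusion matrix; the 95% CI on accuracy is the exact Clopper–Pearson
  (beta-quantile) interval; the no-information rate is the majority-class
  prevalence of the test set; the p-value is the one-sided exact binomial
  tail P(X ≥ correct | n, p = NIR). A single-class test set yields NaN for
  the undefined rate, with a warning, rather than an error.

**Consensus.** The property registry carries the full 22-label vocabulary
and the two supported subsets (14 kNN, 11 RF, intersection 11). A consensus
call requires both methods positive *and* a property in the intersection.
Multi-functionality counts per-peptide positive properties either over
any-method calls (default) or consensus-only calls; the default follows the
broader reading of "all possible predicted putative bioactive peptides".

## Comparative pipeline

* **Presence** is strict "maximum replicate intensity > 0" by default; the
  threshold is a parameter since no universal intensity cutoff exists.
* **Mean centering** subtracts, per sample column, the mean over *detected*
  (nonzero) cells and leaves zeros untouched, so normalisation never
  manufactures presence. Detection is "nonzero" rather than "positive" so
  the operation is idempotent on its own output. No log transform is
  applied.
* **ANOVA screen** is standard one-way ANOVA of replicate intensities
  across species, per peptide, α = 0.05; peptides without two species
  groups of two replicates are skipped with a warning. With triplicates per
  species the test is weak; it is a screen, not an inference procedure.
* **Core/variable partition**: core = present in every species; variable =
  detected but not universal. Peptides detected nowhere belong to neither.
* **Hierarchical clustering** wraps scipy's agglomerative linkage with
  complete (default) or average linkage and Euclidean or binary
  (Jaccard-complement) distance, the latter for presence rows.
* **k-modes** is Huang's algorithm written out: simple-matching
  dissimilarity, assignment to the nearest mode (ties to the lowest pattern
  id), column-wise majority mode updates (an exact 50/50 tie keeps the
  incumbent bit), iteration until assignments are stable, an emptied
  cluster re-seeded from the farthest point, best of 10 seeded restarts by
  total cost. k defaults to 28 in the CLI to mirror the pattern count of
  the motivating seven-species data set; no model-selection procedure for k
  is implied, and the library takes k as a parameter.
* **Correspondence analysis** is computed from the SVD of the standardized
  residuals S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}: principal inertias are σ²,
  principal coordinates D_r^{−1/2}UΣ and D_c^{−1/2}VΣ, and cos² is the
  squared coordinate over the point's squared χ²-distance to the centroid.
  The trivial dimension is excluded by construction; min(rows, cols) − 1
  dimensions are retained, so cos² sums to 1 per point and explained
  percentages to 100. The implementation is cross-checked in the tests
  against scikit-bio's CA and a direct eigendecomposition, and satisfies
  total inertia = χ²/n to 1e-9.

## Synthetic data

`gen_labeled_peptides` draws negative sequences uniformly over the 20
residues and positive sequences from a per-residue mixture placing
probability `effect` on an enriched set (default {K, R, W, L}, echoing the
cationic/hydrophobic bias of many bioactive peptides). The signal is purely
compositional — it maps directly onto the dipeptide block — with defaults
of 400 peptides per class and lengths uniform on 6–30 residues, the typical
tryptic range. What this does *not* emulate: motif/positional signal,
homology structure between related peptides, label noise, and the extreme
class imbalance of real bioactivity databases. Passing tests therefore
demonstrate that the machinery learns a compositional signal and stays at
chance without one; they do not certify accuracy on real training corpora.

`gen_presence_matrix` plants n_core universal peptides and n_variable
peptides assigned round-robin to n_patterns distinct non-trivial binary
species profiles; intensities are lognormal (σ = `noise_sd` log-units
around a base of e²) where present and exactly 0 where absent. Presence is
therefore noise-free by construction and the planted partition is always
recovered exactly — intensity noise exercises normalisation and ANOVA, not
presence calling. Defaults (7 species, 1218 core, 1600 variable, 28
patterns, triplicates) mirror the seven-species mucus scenario the package
was built around. Real data additionally have detection dropout near the
sensitivity limit, which the generator deliberately omits.

## Numerical and design notes

* Problem sizes in the test suite and acceptance script (400 peptides per
  class, a 2818 × 7 planted matrix, 8-row exhaustive k-modes instances)
  were chosen so every oracle can be computed exactly (brute-force distance
  scans, full partition enumeration, closed-form binomial quantities) while
  the full suite runs in seconds.
* All stochastic stages take explicit seeds (NumPy `default_rng`); the CLI
  records seeds in a per-run `manifest.json`.
* Abundance TSV round-trips are bit-exact (`repr` floats on write,
  `float_precision="round_trip"` on read).
* Known limitations: no post-translational modifications, isoelectric
  point, or structure-derived features; no probabilistic vote fusion
  (consensus is a strict AND); protein-level inference is limited to the
  ≥ 2-supporting-peptides filter; k-modes optimises a non-convex objective
  and restarts only make the global optimum likely, not guaranteed, beyond
  the exhaustively verified small instances.
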
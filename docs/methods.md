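# Methods

## Model

`qnasom` treats site-of-metabolism (SOM) prediction as binary
classification of individual heavy atoms. A molecule is a
hydrogen-suppressed graph; its 0/1 connectivity matrix *C* ignores bond
order (single, double, and aromatic bonds all contribute 1). Each atom is
summarized by the QNA pair

    P_i = B_i Σ_k E_ik B_k,   Q_i = B_i Σ_k E_ik A_k B_k,

with A_i = (IP_i + EA_i)/2, B_i = (IP_i − EA_i)^(−1/2) from tabulated
ground-state atomic ionization potentials and electron affinities (eV),
and E = exp(−C/2). A and B are, up to constants, the Mulliken
electronegativity and the inverse square root of chemical hardness; E is
a graph heat-kernel that decays with topological distance, so (P_i, Q_i)
mixes the electronic character of the whole molecule as seen from atom
*i*. Negative EA values (e.g., nitrogen) are legitimate; the table only
requires IP > EA so that B is real.

Assumptions worth stating: descriptors are computed on heavy atoms only
(hydrogens are suppressed before anything else happens); topology is the
only structural input — no charges, hybridization, stereochemistry, or
3-D geometry; and for multi-fragment records (salts, mixtures) only the
largest connected component is kept, with a warning, because the
exponential kernel would otherwise couple atoms of unrelated fragments
through a block-diagonal E (they would not interact, but their pooled
statistics would).

## Numerical choices

* exp(−C/2) is computed by symmetric eigendecomposition (`eigh`), exact
  for real symmetric C, and symmetrized afterwards; agreement with a
  40-term Taylor series is enforced in tests to 1e−9.
* "Normalized P and Q" is realized as z-scoring with the mean and
  population SD of the **training partition only**, applied unchanged to
  test/validation rows; a zero-variance feature maps to 0. This choice
  (over range scaling or an internal QNA normalization) is the
  convention expected by the downstream classifiers and cannot leak
  test-set statistics.
* Ties: SMOTE neighbor-distance ties break by lower row index; atom
  ranking ties break by lower atom index (stable sorts throughout).

## Class balancing

Atom-level SOM data are imbalanced at SOM:non-SOM ≈ 0.05 or worse, and
a 0.5-threshold classifier trained on raw data mostly learns to say
"non-SOM". SMOTE is implemented from first principles: for each minority
row, the k = 5 nearest minority neighbors (Euclidean, in normalized
(P, Q) space) define candidate segments; synthetic rows are drawn
uniformly on a segment to a uniformly chosen neighbor; the synthetic
count is spread as evenly as possible over minority rows (remainder
assigned at random) until minority:majority = 1, which puts the minority
class at ~50% of the training set (48–50% on small sets where integer
rounding bites). Synthetic rows carry `synthetic=True` and a `smote:`
mol_id namespace disjoint from real molecules, so molecule-level splits
can never place them in a test fold; the evaluation code additionally
asserts this on every fold. Balancing is applied to training partitions
only.

## Classifiers

All four share one fit/predict_proba contract over the two features.

* Gaussian naive Bayes: per-class Gaussian likelihood per feature;
  appropriate because only two continuous features exist.
* Random forest: 100 trees, each grown on a bootstrap sample of 70% of
  the training rows (with replacement). The empirically strongest and
  the recommended default.
* RBF network (bespoke): k-means with k = 2 places Gaussian bases; each
  width is the RMS radius of its cluster (global-scale fallback for a
  degenerate cluster); activations below 1e−8 are clamped to 0; a
  logistic-regression output maps activations to probability. This
  mirrors the classic Weka-style RBFNetwork design (unsupervised
  pre-clustering, then a linear output layer).
* MLP: two hidden layers of 10 tanh units, early-stopped on an internal
  20% validation carve-out of the training rows.

The convolutional network sometimes mentioned alongside these
architectures is deliberately not implemented: a convolution is not
well-defined over a 2-feature input row, and guessing an architecture
would not be testable against anything.

## Evaluation protocol

Splits are **molecule-level**: all atoms of a molecule land on one side.
Atom-level splitting would place near-duplicate descriptor rows of the
same molecule on both sides and inflate every metric; molecule-level
splitting is standard practice in SOM prediction. The default protocol
is five repeated random 2:1 train/test splits, reporting per-repeat
Se, Sp, BA = (Se+Sp)/2 at threshold 0.5 and Mann–Whitney AUC
(tie-corrected; verified to 1e−12 against trapezoidal ROC integration),
aggregated as mean ± sample SD. Leave-one-molecule-out CV pools the
out-of-fold scores before computing a single AUC, because a per-fold AUC
is undefined when a fold holds a single molecule (often a single class).
Per-repeat averaging (not pooling) is used for the repeated-split
protocol. Top-k hit rates (k = 1, 2, 3) count molecules whose k
top-scoring atoms include a true SOM; molecules without any SOM are
excluded with a warning.

## Synthetic data generator

Real SOM compilations cannot be redistributed here, so the generator
produces what the pipeline needs to be falsifiable: connected random
trees with ring closures, valence-capped (C 4, N 3, O 2, S 2), elements
drawn C/N/O/S with weights 0.70/0.12/0.12/0.06, 5–14 heavy atoms —
drug-like fragment sizes that keep eigendecompositions instant. Each
molecule gets a uniform reaction-type and isoform label so grouped
subset compilation (seven reaction types, five isoform-reaction pairs)
is testable. Labels come from a rule in descriptor space: an atom is a
SOM iff its true raw Q exceeds a threshold set at the pooled quantile
matching the target SOM:non-SOM ratio (default 0.05, the documented
upper bound of real sets). Optional label noise flips labels with a
stated probability.

Because the rule is deterministic in the descriptors, a classifier
seeing (P, Q) has a Bayes ceiling of perfect separation — parameter
recovery (held-out BA ≥ 0.95 for the forest on 500 noiseless molecules)
is therefore a meaningful correctness check, and chance behavior on
permuted labels (BA ≈ 0.5) guards against leakage. What passing these
tests does **not** show: that QNA descriptors separate real SOMs this
well. Real metabolic regioselectivity depends on electronics,
accessibility, and enzyme specifics that a topological rule does not
emulate; real-data performance must be measured on real annotated SDF
files, which the same pipeline accepts unchanged.

Problem sizes used by the shipped checks: 200–500 molecules
(~2,000–4,700 atoms) for pipeline-level runs, 300 molecules for the
balancing protocol in `scripts/acceptance.py`, five seeded repeats —
sizes at which every quantity is stable to well under the tolerances
asserted.

## Known limitations

* Bond order, charges, stereochemistry, tautomers, and 3-D geometry are
  out of scope; V3000 SDF is not parsed.
* The element table ships IP/EA for H, B, C, N, O, F, Si, P, S, Cl, Br,
  I; other elements require a user-supplied table
  (`load_element_table(path)`).
* Whether the original QNA formulation includes hydrogens in C is an
  open question; this package computes descriptors on the
  hydrogen-suppressed graph, consistent with its heavy-atom-only
  labeling.
* A molecule annotated with several reaction records is represented
  once per record during subset compilation, so its non-SOM atoms
  appear in every subset that includes it.
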
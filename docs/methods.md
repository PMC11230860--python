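# Methods

This note documents the models, conventions, and design choices behind
`molscreen`, in the spirit of the model documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic benchmark does and does not show.

## Per-target binding-likelihood model

### Input representation

A molecule arrives as a SMILES string and is parsed with RDKit into a
heavy-atom graph (hydrogens implicit). The network consumes four blocks:

* **atom features** (26 dims): element one-hot over
  {C, N, O, S, F, Cl, Br, I, P, other} ⊕ degree one-hot 0–5 ⊕ formal
  charge one-hot clipped to [−2, 2] ⊕ aromaticity flag ⊕ hybridization
  one-hot {sp, sp², sp³, other};
* **bond features** (6 dims): bond-order one-hot
  {single, double, triple, aromatic} ⊕ conjugation flag ⊕ in-ring flag,
  with every chemical bond expanded to two directed arcs;
* **atom neighbor table**: the arcs pointing into each atom;
* **bond neighbor table**: for each arc, the arcs feeding its source atom,
  excluding its own reverse.

Elements or hybridizations outside the vocabulary map to catch-all slots
(logged, never an exception), so screening libraries with exotic atoms
degrade gracefully. The vocabulary identifier is persisted with every
trained model, and prediction refuses inputs featurized under a different
scheme. Stereochemistry and 3-D geometry are deliberately not encoded.

### Architecture

A directed-arc message-passing encoder followed by a feed-forward head:

    h⁰_e  = ReLU(W_i [x_src(e) ; e_e])                 arc initialization
    m_e^t = Σ_{k→src(e), k≠rev(e)} h^{t−1}_k           incoming messages
    h^t_e = ReLU(h⁰_e + W_h m_e^t)                     t = 1 … depth−1
    s_v   = Σ_{e→v} h^{depth−1}_e                      atom aggregation
    a_v   = ReLU(W_o [x_v ; s_v])                      atom embedding
    g     = mean_v a_v                                 molecule readout
    p     = σ(MLP(g))                                  score in (0, 1)

Defaults: message-passing depth 3, message dimension 64, head widths
1024/1024/512 with ReLU activations, and a final sigmoid that guarantees
the [0, 1] score codomain. The incoming-message sum is computed as a
segment sum over arc destinations minus the reverse arc's state — exactly
equivalent to the neighbor-list formulation but vectorizable.

The encoder, head, backpropagation, and Adam optimizer are implemented
directly in NumPy (float64 throughout). Gradients are verified against
central finite differences in the test suite; at exact ReLU kinks the
implementation takes the zero subgradient.

### Training regime

Minibatch Adam on the mean squared error between the sigmoid output and
{0, 1} labels: 100 epochs, learning rate 0.001, batch size 128 (all
configurable). Binary labels trained by MSE regression through a bounded
output is an unusual but serviceable pairing; the sigmoid keeps scores in
range and MSE behaves as a Brier-style loss. Data are split 70/10/20 into
train/validation/test, stratified by label (small, balanced datasets make
unstratified splits risk degenerate class ratios); split sizes are the
floored fractions per class with the remainder assigned to train, so 400
molecules split 280/40/80 and 302 split 212/30/60. By default the weights
from the epoch with the lowest validation loss are retained
(`model_selection="best_valid"`); last-epoch weights are available via
config. Seeds for splitting, initialization, and shuffling are separate
and recorded in the results object; training is a pure function of
(data, config, seed).

## Ensemble and screening

The ensemble score is the unweighted arithmetic mean of the three
per-target scores — no weighting variants, no imputation when a sub-score
is missing (that is an error). Classification is boundary-inclusive:
score ≥ threshold is positive, so a threshold of 1.0 remains satisfiable.
Screening returns the library ranked by descending ensemble score with
ties broken by molecule id (stable), and reports unparseable SMILES in a
separate rejects list rather than failing the run.

## Evaluation conventions

* **AUROC** uses the Mann–Whitney formulation (ties count ½), computed via
  scikit-learn and cross-checked in the tests against brute-force pairwise
  concordance.
* **AUPRC** is the step-wise, non-interpolated summation (average
  precision); interpolated variants differ and are not offered.
* **Undefined metrics** (zero denominators, e.g. precision with no
  positive predictions) are reported as `None`, never coerced to 0 and
  never raised; averages exclude them with an explicit exclusion count,
  since silently coercing to 0 biases averages downward.

### Balanced-subsampling validation

With P positives and N ≫ P negatives, each repetition draws a
uniform-without-replacement negative subset of size P (configurable),
pools it with *all* positives, and binarizes at each threshold. Sampling
is independent across repetitions and deterministic per seed. Two
aggregation orders are computed, because they differ in general and
published tables rarely say which was used: the **mean of per-repetition
metrics** and the **metrics of the mean counts**. The report carries both;
the tabular output defaults to the counts-derived form, which is exactly
reproducible from its own printed TP/FN/TN/FP columns. Structural
invariants hold by construction: TP + FN equals the positive-set size in
every row, TN + FP equals the per-repetition sample size, and the averaged
FP converges to the hypergeometric expectation of the sampled pool (tested
within three standard errors). A running-average trace of FP is stored so
convergence over repetitions can be inspected.

## Synthetic data generator

The generator emulates the statistical structure of a curated
active/decoy study without any external download:

* **Motifs.** Each target gets a distinct fused ring system — indole for
  SERT, quinoline for D2, benzofuran for NMDA — standing in for a
  target-specific pharmacophore, so the three models must learn three
  different functions.
* **Actives** are built by attaching 1–4 random small decorations (alkyl,
  halogen, hydroxyl, amine, nitrile, ...) at random substitutable
  positions of the motif scaffold; **decoys** grow the same way from a
  pool of motif-free scaffolds (cyclohexane, benzene, pyridine, THF,
  piperidine, chains, ...) and are verified by substructure search to
  contain no target's motif. All molecules are RDKit-sanitized and
  deduplicated by canonical SMILES.
* **Ki values** are sampled log-uniformly — affinity data are treated as
  log-scaled in practice — from (0.1, 10] nM for actives and
  [1, 100] µM for decoys, keeping the active interval strictly below the
  inactive one.
* **Sizes** default to the reference design: 200/200 actives/decoys for
  SERT and D2, 152/150 for NMDA, and a screening library of 154 positives
  against 5744 negatives. A `scaled(factor)` spec supports proportionally
  smaller studies for fast tests.
* **Disjointness.** The screening library is generated with the canonical
  SMILES of every training molecule of the same spec excluded, enforcing
  the rule that no external-validation compound occurs in training.

Everything is a pure function of (spec, seed); independent, reproducible
random streams are derived per population from the root seed.

### What the benchmark does and does not show

The motif signal is, by construction, learnable: a single substructure
separates the classes, so models reach AUROC ≈ 1.0 and the screen ranks
essentially all true positives on top (enrichment factor ≈ 10 at the top
decile, the maximum possible at this prevalence). Passing tests therefore
demonstrate that the pipeline's machinery — featurization, training,
ensembling, resampling — is correct, *not* that the architecture would
reach any particular performance on real affinity data, where
structure–activity relationships are far subtler, decoys are
property-matched, and assay noise exists. The generator also makes no
attempt at physicochemical decoy matching or 3-D realism. A
label-scrambling control (permute all labels before splitting, retrain,
evaluate on the held-out split) confirms the pipeline cannot manufacture
signal from noise: its AUROC sits near 0.5.

## Numerical and operational choices

* float64 arithmetic end to end; fits are bit-reproducible for a fixed
  seed on a given platform.
* Glorot-uniform weight initialization, zero biases; Adam with standard
  moment parameters (0.9/0.999, ε = 10⁻⁸).
* Ki unit normalization at read time with exact factors (nM/µM/mM/M);
  activity filtering is boundary-inclusive (Ki = threshold passes).
* Duplicate detection and disjointness use RDKit canonical SMILES; no
  salt stripping or tautomer normalization is attempted.
* Model archives are single zip files (weights, JSON config and
  featurization identifier, loss history); loading refuses truncated
  archives and vocabulary mismatches.
* Problem sizes in the test suite: unit tests run a 15%-scale study with a
  reduced network (128/64 head, 15 epochs); the acceptance tests and the
  acceptance script run the full-size study at 30 epochs, since the
  synthetic signal converges well before the reference 100.

## Known limitations

* No hyperparameter search, GPU path, or alternative encoders
  (fingerprints, SMILES-CNN); the package implements one architecture
  well.
* MSE-on-labels is kept for fidelity to the reference regime; a
  cross-entropy option would be the natural extension.
* The message-passing depth/width defaults are conventional choices; the
  reference design fixes only the head.
* Published threshold-sweep tables based on rounded averaged counts
  reproduce their own metric panels only to about ±0.01; comparisons at
  finer precision are not meaningful.
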
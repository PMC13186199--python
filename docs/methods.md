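# Methods

## Problem and model

The quantity predicted is ΔΔG, the change in Gibbs free energy of unfolding
caused by a single amino-acid substitution, in kcal/mol, with the convention
that ΔΔG ≥ 0 is stabilizing. Thermodynamics imposes antisymmetry: the
reverse mutation (B→A applied to the mutant chain) has exactly the negated
ΔΔG. A useful sequence-only predictor should (i) be accurate on held-out
proteins and (ii) respect antisymmetry without having it hard-coded.

The predictor is a two-branch fusion regressor:

* **Global branch** — the difference of mean-pooled per-residue embeddings
  of the mutant and wild-type chains (width d, 1280 for the real ESM-2
  650M backend, configurable for the synthetic backend). Mean pooling makes
  the delta exactly antisymmetric under chain swap, which is the structural
  hook that lets the trained model approximate antisymmetric predictions.
  The embedding model is frozen; only the head is trained.
* **Local branch** — 25 features of the mutated site:
  ΔRSA (1), ΔV_ΦΨ (4, sine/cosine-encoded dihedral differences — the
  encoding removes the ±180° wrap-around artifact of raw angles),
  ΔDisorder (1), ΔAAP (13), P(SS) of the wild-type and mutant residue
  (3 + 3). All Δ blocks are mutant minus wild type. Under direct/reverse
  swap, the 19 difference components negate and the two P(SS) triples
  exchange — the local counterpart of the global antisymmetry.
* Each branch passes through two linear layers with an H-swish nonlinearity
  (x·min(max(x+3,0),6)/6) to 128 dimensions; hidden widths 256 (global) and
  64 (local). The branches are fused element-wise with two learnable
  128-vectors, `f = G∘w_G + R∘w_R`; concatenation (256-dim) and flattened
  outer product (16384-dim) are selectable alternatives, with the decoder
  input width adapting. Fusion weights start at all-ones (a neutral pass-
  through), linear layers at Xavier-uniform.
* **Decoder** — the fused vector is treated as one channel of length equal
  to the fused width: Conv1d(1→16, kernel 3, padding 1) → BatchNorm → ReLU,
  Conv1d(16→32) → BatchNorm → ReLU, flatten, Linear(→64) → BatchNorm →
  Linear(→1). Batch-norm precedes ReLU, matching the model's defining
  composition. At evaluation time batch-norm uses running statistics, so
  prediction is a pure function of (parameters, input); evaluating a
  never-trained batch-norm layer is an error, not a silent fallback.

The head is implemented directly on NumPy with explicit per-layer backward
passes (the network is small and fixed-topology); every backward pass is
verified against central-difference numerical gradients in the test suite.

### Optimisation

Mean-squared-error loss, Adam (lr 1e-3, β = 0.9/0.999), batch size 64, at
most 500 epochs, early stopping with patience 20 on held-out RMSE, best
parameters restored. The held-out set is the cross-validation fold being
left out (or an internal 10% split when none is given). Features are
standardised column-wise on the training set. All randomness — initial
weights, batch order, validation split — flows from one `random_state`.
These optimisation hyperparameters are this package's choices; the
architecture widths are likewise choices where the original description is
silent.

Ablations (`wo_local`, `wo_global`) zero the excluded branch's contribution
at the fusion point while keeping the decoder width constant, so ablated and
full models differ only in which information reaches the decoder.

### Cross-validation and ensembling

Proteins are clustered by single-linkage on pairwise global-alignment
identity (Needleman–Wunsch edit distance via edlib; identity
= 1 − d/max(len); default threshold 0.25) and clusters are assigned greedily
— largest first, to the currently smallest fold — so no two chains above the
threshold straddle folds. Reverse records inherit their direct counterpart's
fold, preventing a mutation pair from leaking across the boundary. A `fold`
column in the input CSV overrides the splitter, so externally published
splits can be reproduced exactly. The final predictor is the arithmetic mean
of the k fold models; checkpoints carry a feature signature (embedding
provider id + property-table version) and loading with a mismatched
signature is an error.

### Metrics

RMSE, Pearson correlation, and sign-classification accuracy (ΔΔG ≥ 0
stabilizing; an exact zero is stabilizing on both sides of the comparison).
Antisymmetry is scored over matched direct/reverse pairs: r_d-r is the
Pearson correlation of the two prediction vectors (−1 ideal) and
⟨δ⟩ = mean of (direct + reverse)/2 (0 ideal); the (d+r)/2 form follows the
established antisymmetry-evaluation convention for this pair of diagnostics.
Stratified reports use RSA > 0.5 (exposed) / < 0.1 (buried) and the argmax
of the wild-type P(SS) triple for the secondary-structure class; using
predicted P(SS) rather than DSSP on crystal structures is a deliberate
deviation that keeps the analysis sequence-only.

## The 25 local features in detail

RSA is ASA normalised by the residue's theoretical maximum ASA, clamped to
[0, 1]; when the annotation source reports RSA directly, that value is used.
The 13 amino-acid properties (Kyte–Doolittle hydropathy, molecular weight,
van der Waals volume, Grantham polarity, pI, net charge at pH 7, H-bond
donor and acceptor counts, Vihinen flexibility, Chou–Fasman helix and sheet
propensities, maximum ASA, aromaticity) are shipped as a versioned raw CSV
and z-normalised across the 20 residues at load time; the identity of the
property set is a design choice and any 20×13 table with the same shape can
be substituted. Eight-state secondary structure collapses H,G,I→helix,
E,B→sheet, rest→coil before renormalisation. Mutant-chain annotations come
from running the annotation provider on the full mutant sequence, not from
copying wild-type values with the letter changed.

## Synthetic study

The generator emulates the statistical structure the model assumes, making
every mechanism testable without downloads:

* sequences are uniform-random over the 20 letters (default 40 proteins,
  50–150 residues);
* annotations are drawn around residue-letter-dependent base values with
  per-position jitter, so substitutions genuinely move the local features;
* embeddings are hash-seeded pseudo-Gaussian rows keyed by the whole chain,
  so a single substitution perturbs every pooled dimension slightly —
  mimicking a language model's global sensitivity;
* the ground truth is a planted *linear* function of the true fused
  features, with the two P(SS) weight triples constrained to opposite signs
  so the noise-free ΔΔG is exactly antisymmetric; each branch's planted
  contribution is scaled to unit standard deviation (ΔΔG spread
  ≈ 1.4 kcal/mol, comparable to curated stability data);
* matched direct and reverse records receive independent Gaussian noise
  (default σ = 0.3 kcal/mol), so antisymmetry in the predictions must be
  learned, not inherited from shared noise.

The default study — 500 direct+reverse pairs, d = 32, σ = 0.3, five
homology folds — is the condition under which the acceptance properties are
measured; the reduced d keeps a full training run at desk scale. What
passing shows: the architecture can recover a planted fused signal to near
the noise floor, learns antisymmetry from paired data, and the fused model
beats either single branch when both carry signal. What it does not show:
performance on real mutation data, where the ΔΔG landscape is non-linear in
any fixed feature set, experimental noise is heteroscedastic, stabilizing
mutations are rare, and real embeddings/annotations are correlated in ways
the synthetic providers do not reproduce. Reproducing published benchmark
numbers additionally requires the 650M-parameter embedding checkpoint,
structure-annotation runs for every chain, and the original training set
and splits; that workflow is supported through the same interfaces but is
not part of the test suite.

## Numerical and degenerate-input choices

* Mutation codes are 1-based; every interface validates the wild-type
  letter against the sequence.
* Duplicate records (same protein, substitution, direction) are averaged;
  rerunning deduplication is the identity.
* P(SS) triples are renormalised when they deviate from 1 by more than
  1e-3; RSA clamps to [0, 1]; ddG values round-trip CSV at 9 significant
  digits.
* Pearson correlation of a constant vector is reported as NaN with a
  warning rather than raised.
* Fewer homology clusters than folds leaves folds empty with a logged
  warning; training on an empty fold aborts.
* Chains beyond the real embedding backend's 1022-token limit use a
  1000-residue window centred on the mutation, applied identically to both
  chains.
* Embedding cache entries are stamped with provider id and width; corrupt
  or mismatched entries are recomputed, never trusted.

## Known limitations

* The planted ground truth is linear, so the synthetic study cannot probe
  the decoder's non-linear capacity.
* The synthetic embedding provider has no evolutionary structure; feature
  importance conclusions (e.g. fusion-weight magnitudes) on synthetic data
  say nothing about real embeddings.
* The homology splitter is O(n²) in the number of chains with a global
  alignment per pair — fine for curated stability sets (thousands of
  chains), not for proteome-scale input.
* Outer-product fusion inflates the decoder input to 16384 dimensions and
  is practical only with reduced decoder widths.
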
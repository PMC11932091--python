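# Methods

## Model

`dtifuse` predicts a binary drug–target interaction from two feature views
per entity, learned in two stages.

**Relational view.** Known positive interactions from the *training split
only* form the binary matrix `E` (drugs × proteins); test pairs never
contribute edges, so no label information leaks into the features. A drug's
interaction profile is its row of `E`, a protein's its column. Pairwise
profile cosine similarity, thresholded strictly at τ = 0.3 (a value chosen
against over-sparsity of the resulting graphs), defines undirected drug–drug
and protein–protein similarity networks with no self-loops. Profiles with no
training interactions get similarity 0 by definition — they become isolated
nodes rather than dividing by zero. Initial node features are standard-normal
draws: 167-d for drugs (the MACCS fingerprint length) and 256-d for proteins;
the "uniform" strategy replicates one random row across nodes so embedding
differences come from topology alone, the "random" strategy (default) draws
each node independently.

Contrastive pre-training is a bootstrap-style two-view scheme with no
negative pairs. Each epoch draws two augmentations (each undirected edge
dropped with probability 0.2, each node's feature row zeroed with
probability 0.2 — midpoints of common graph-contrastive practice, both
configurable). An online and a target encoder — two graph-convolution layers
with symmetric normalization and self-loops, `D̃^{-1/2}(A+I)D̃^{-1/2}`, ReLU
between, widths input → 300 → 300 — encode one view each. The online output
passes through a single affine predictor; the loss is the negative mean row
cosine against the *detached* target embedding, scaled to lie in [−2, 2].
Adam (lr 1e-3) updates the online encoder and predictor; the target follows
by EMA with decay 0.99. Self-loops in the convolution ensure isolated nodes
still propagate their own features. The asymmetric loss (one predictor
branch, target detached) is implemented exactly as stated above; a
symmetrized variant was deliberately not added. After training, the online
encoder applied to the un-augmented network yields the 300-d relational
features, which are then frozen.

**Structural view.** Molecules are parsed with RDKit and featurized with
eight atomic properties (atomic number, total bond count, formal charge,
chirality tag, hydrogen count, hybridization, aromaticity, mass × 0.01) and
four bond properties (type, conjugation, ring membership, stereochemistry);
categorical properties are one-hot with an out-of-range bucket. Each bond
becomes two directed edges. The directed message-passing encoder initializes
each edge state as `ReLU(W_in [x_src ; e])`; for each of 2 message steps,
the message into edge (v→w) sums incoming edge states at v *excluding the
reverse edge* (w→v), and the update is `ReLU(h0 + W_m m)` with no bias on
`W_m`, so an edge receiving no messages keeps its initial state (this also
defines single-atom molecules: a zero incoming sum). Atom states are
`ReLU(W_atom [x_v ; Σ incoming h])`; the readout is the mean over atoms
(mean rather than sum keeps the scale size-independent; configurable in
principle but fixed here). All hidden widths are 300.

Protein sequences are tokenized per residue (20 standard amino acids plus
ambiguity codes; pad = 0, unknown characters map to a dedicated token),
truncated/right-padded to a fixed length (default 1000, covering the vast
majority of real proteins), embedded, passed through two same-padded 1-d
convolutions with ReLU, and globally max-pooled *masked to true sequence
positions*, which makes the output invariant to the amount of padding. An
all-pad degenerate input falls back to pooling over all positions and stays
well defined.

**Classifier.** Per entity, relational and structural 300-d blocks
concatenate (relational first) to 600-d; drug then protein vectors
concatenate to the 1200-d classifier input. Three hidden affine layers
(defaults 1024 → 512 → 256, a conventional funnel; dropout 0.1, LeakyReLU
slope 0.01) feed a final affine layer; the interaction probability is the
sigmoid of its logit. Training minimizes binary cross-entropy computed in
the numerically stable logit form. Ablation variants: "RF" feeds relational
features only, "SF" structural only (600-d input each).

**Training protocol.** Two stages: contrastive pre-training completes first
and the relational features are frozen; the structural encoders and MLP then
train jointly with Adam. The best supervised epoch is selected by validation
AUC with early-stopping patience. Entities absent from the training
interaction network receive a zero relational vector at prediction time
(cold start); their structural features are still computed from SMILES or
sequence. Supervised-stage arithmetic runs in float32 by default (float64
available via config); the contrastive stage runs in float64.

## Evaluation protocols

Negatives are sampled uniformly from unoccupied (drug, protein) grid cells,
unique and disjoint from all existing pairs, once per dataset before
splitting so all folds partition one fixed pair table. Cross-validation
holds out 10% of pairs once as a shared test set and splits the remainder
into 10 validation folds; each fold's model trains on the other nine.
Imbalanced benchmarks rebuild the pair table at 1:1, 1:5 or 1:10
positive:negative ratios. Identity-based folds compute pairwise local-
alignment sequence identities (Smith–Waterman with affine gaps via
Biopython's `PairwiseAligner`; BLOSUM62, gap open 10, extend 0.5 — the
classic defaults of the standard local-alignment tool; identity = identical
columns / alignment length, 0 when no positive-scoring alignment exists)
and cluster proteins by average-linkage agglomerative clustering on
distance 1 − identity into 10 groups; every pair joins its protein's
cluster, so folds do not share close homologs. Metrics are AUC, AUPR
(average precision) and accuracy/recall/precision at threshold 0.5,
reported per fold with mean and standard deviation.

## Synthetic benchmark

The generator emulates the guilt-by-association regularity of real DTI
data: drugs and proteins belong to latent blocks; a (drug-block,
protein-block) cell is "active" with probability 0.3 (each drug block
guaranteed at least one active partner), and a positive interaction appears
with probability 0.5 in active cells versus 0.02 elsewhere. Each drug block
carries a curated chemical scaffold decorated per drug with small
substituents (validated with RDKit); each protein block carries a fixed
length-8 motif inserted into random background sequence. Negatives are
drawn 1:1 by the shared sampler. The fixed benchmark used throughout is
200 drugs × 150 proteins with 8 × 6 blocks and generator seed 7; sequences
are 100 residues, a desk-scale stand-in for real protein lengths.

Setting affinity equal to background removes all signal and serves as a
negative control: a correct pipeline should score near AUC 0.5 there.

What passing these benchmarks does **not** show: real chemistry (binding
physics, 3-D structure), realistic chemical diversity (one scaffold per
block is far cleaner than real chemotypes), realistic sequence families, or
performance at public-benchmark scale. The synthetic results demonstrate
that every stage transmits its intended signal, not that published
benchmark numbers are reproduced.

## Desk-scale study settings

The planted-benchmark experiments (tests and `scripts/acceptance.py`) run
contrastive pre-training for 200 epochs and supervised training for 30
epochs, with encoder widths sized for a single CPU: token embedding 32,
convolution channels 32 → 300 with kernels 5 and 3, MLP hidden sizes
256/128/64, batch size 2048, supervised lr 1e-3, sequence budget 100
tokens. These are the package's chosen study conditions for the synthetic
scale; the library defaults (embedding 128, channels 128 → 300, kernels
7/7, MLP 1024/512/256, lr 1e-4, batch 128, 2000 contrastive epochs) remain
the reference configuration for larger data. The ablation and
initialization comparisons train on a fixed fold with training seeds 0–2.

## Numerical choices and edge cases

- Cosine of any zero vector (profiles or embedding rows) is defined as 0.
- The similarity threshold is a strict inequality ("exceeds").
- Contrastive-loss gradients flow only through the online/predictor branch;
  the target is detached. A non-finite loss aborts with a diagnostic.
- BCE on probabilities clips at 1e-7; training uses the fused logit form.
- Ranking ties break lexicographically by (drug id, protein id).
- All randomness flows from per-run seeds through `numpy` `SeedSequence`
  spawning; identical seeds reproduce loss histories bit-for-bit.

## Known limitations

- Pure-NumPy training is practical at desk scale only; thousands of
  entities per batch or long proteins would need a tensor framework.
- The contrastive stage's augmentation rates, EMA decay, learning rate and
  hidden width are not dictated by theory; they are exposed in config and
  the defaults above were fixed once for all experiments.
- Local-alignment identity of short unrelated sequences can be high (a
  single matching residue yields identity 1); cluster folds are meaningful
  for realistic sequence lengths, not toy two-letter strings.
- The relational view is transductive: an entity outside the training
  interaction network has no relational embedding and falls back to zeros.
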
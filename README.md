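# dtifuse

Drug–target interaction (DTI) prediction for cheminformatics and drug-
repurposing work. `dtifuse` scores candidate (drug, protein) pairs by fusing
two complementary views of each entity:

- **Relational features** — drugs and proteins are embedded from the *known
  interaction network itself*. The binary interaction matrix
  `E ∈ {0,1}^{|V_d|×|V_p|}` gives each drug an interaction profile (its row)
  and each protein one (its column); profile cosine similarity
  `Sim_ij = g_i·g_j / (‖g_i‖‖g_j‖)` above a threshold τ = 0.3 defines
  drug–drug and protein–protein similarity networks. A two-view graph
  contrastive scheme without negative pairs — stochastic edge dropping and
  node-feature masking, online and target two-layer GCN encoders, a linear
  predictor, loss `L = −(2/N) Σ_i cos(z_i, h_i)`, Adam on the online branch
  and an exponential moving average `ξ ← τξ + (1−τ)θ` on the target — yields
  a 300-d relational embedding per node.
- **Structural features** — molecules are parsed from SMILES into directed
  molecular graphs (8 atom and 4 bond properties; every bond is two directed
  edges) and encoded by a directed message-passing network whose messages
  exclude each edge's reverse; protein sequences are tokenized per residue,
  embedded, passed through two 1-d convolutions and globally max-pooled.
  Each entity again gets a 300-d vector.

Per entity the two blocks concatenate into a 600-d vector
(`X = concat(X^r, X^s)`); the drug and protein vectors feed a three-layer
MLP (dropout + LeakyReLU) with a final sigmoid head, trained with binary
cross-entropy. Everything runs on NumPy via a small built-in reverse-mode
autograd; there is no GPU or deep-learning-framework dependency.

The package also ships the evaluation protocols that matter for honest DTI
benchmarking: unique negative sampling, 10-fold cross-validation with a
shared held-out test set, imbalanced (1:5, 1:10) negative ratios, and
protein sequence-identity cluster folds (local-alignment identities +
agglomerative clustering) that keep close homologs out of each other's
training data. A synthetic generator plants block structure (shared
scaffolds per drug block, shared sequence motifs per protein block, block-
level interaction affinities) so the whole pipeline is testable without
external downloads.

## Worked example

```bash
python examples/04_end_to_end.py
```

trains the full model on a 60-drug × 40-protein planted dataset and prints:

```
training loss: 0.728 -> 0.369
test AUC 0.829  AUPR 0.783  ACC 0.778  recall 0.829  precision 0.723
top-5 scored test pairs (score, true label):
  D0056 - P0039: 0.874  label=1
  ...
```

The AUC well above 0.5 shows the fused features recover the planted
block-affinity structure on held-out pairs; the top-ranked test pairs are
dominated by true interactions. The other scripts in `examples/` demonstrate
dataset simulation, relational-network construction + contrastive
pre-training, and the structural encoders in isolation.

A thin CLI mirrors the main library entry points:

```bash
dtifuse simulate --out-prefix /tmp/toy
dtifuse eval --drugs /tmp/toy_drugs.tsv --proteins /tmp/toy_proteins.tsv \
             --pairs /tmp/toy_pairs.tsv --folds 2
```

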
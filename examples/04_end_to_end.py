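"""Train the full fused model on a small planted dataset and evaluate it.

Stage 1 pre-trains relational features contrastively and freezes them;
stage 2 trains the structural encoders and the MLP head jointly on binary
cross-entropy, selecting the best epoch by validation AUC. The held-out test
set is scored with AUC/AUPR plus thresholded accuracy, recall and precision.
"""

from dtifuse import (SyntheticSpec, TrainConfig, compute_metrics,
                     make_cv_splits, predict_pairs, rank_predictions,
                     simulate_dti, train_model)

sim = simulate_dti(SyntheticSpec(n_drugs=60, n_proteins=40, n_drug_blocks=4,
                                 n_protein_blocks=3, seed=7, seq_length=80))
ds = sim.dataset
split = make_cv_splits(ds, k=5, test_frac=0.1, seed=0)

cfg = TrainConfig(gcl_epochs=100, sup_epochs=10, sup_lr=1e-3, batch_size=512,
                  cnn_emb_dim=16, cnn_channels=(16, 300), cnn_kernels=(5, 3),
                  mlp_hidden=(128, 64, 32), max_seq_len=100, seed=0)
model = train_model(ds, split.folds[0], cfg)
print(f"training loss: {model.history['train_loss'][0]:.3f} -> "
      f"{model.history['train_loss'][-1]:.3f}")

test = [ds.pairs[i] for i in split.test_idx]
rep = compute_metrics([p.label for p in test], predict_pairs(model, test))
print(f"test AUC {rep.auc:.3f}  AUPR {rep.aupr:.3f}  ACC {rep.acc:.3f}  "
      f"recall {rep.recall:.3f}  precision {rep.precision:.3f}")

top = rank_predictions(model, test, top_k=5)
print("top-5 scored test pairs (score, true label):")
for pair, score in top:
    print(f"  {pair.drug_id} - {pair.protein_id}: {score:.3f}  label={pair.label}")
# An AUC well above 0.5 shows the fused relational + structural features
# recover the planted block-affinity structure on unseen pairs.
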
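"""End-to-end training, prediction and evaluation.

Training is two-stage: relational features are contrastively pre-trained on
similarity networks built from the split's training positives and then
frozen; the structural encoders and the MLP head train jointly on binary
cross-entropy over labeled pairs, with the best epoch chosen by validation
AUC. Variants: "full" fuses relational and structural features (1200-d
classifier input), "RF" uses relational features only, "SF" structural only
(600-d each). Entities absent from the training interaction network receive
a zero relational vector (cold start).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.metrics import (accuracy_score, average_precision_score,
                             precision_score, recall_score, roc_auc_score)

from . import autograd as ag
from .classifier import MLPClassifier
from .contrastive import extract_relational_features, train_gcl
from .data import FoldSplit, InteractionDataset, InteractionPair, make_cv_splits
from .optim import Adam
from .relational import build_interaction_matrix, build_relational_network
from .structural import (DMPNNEncoder, ProteinCNNEncoder, batch_molgraphs,
                         batch_tokens, smiles_to_molgraph, tokenize_protein)

__all__ = ["TrainConfig", "MetricsReport", "CVResult", "TrainedModel",
           "train_model", "predict_pairs", "compute_metrics", "run_cv",
           "rank_predictions"]


@dataclass
class TrainConfig:
    """A config plus data and a seed fully determines a run."""

    # relational-network construction
    sim_threshold: float = 0.3
    drug_init: str = "random"
    protein_init: str = "random"
    drug_init_dim: int = 167
    protein_init_dim: int = 256
    # contrastive pre-training
    gcl_epochs: int = 2000
    p_edge: float = 0.2
    p_feat: float = 0.2
    ema_decay: float = 0.99
    gcl_lr: float = 1e-3
    gcl_hidden: int = 300
    # structural encoders
    dmpnn_layers: int = 2
    max_seq_len: int = 1000
    cnn_emb_dim: int = 128
    cnn_channels: tuple[int, int] = (128, 300)
    cnn_kernels: tuple[int, int] = (7, 7)
    # classifier + supervised training
    mlp_hidden: tuple[int, ...] = (1024, 512, 256)
    dropout: float = 0.1
    leaky_slope: float = 0.01
    sup_epochs: int = 50
    sup_lr: float = 1e-4
    batch_size: int | None = 128
    patience: int = 10
    # protocol
    variant: str = "full"            # full | RF | SF
    precision: str = "float32"       # supervised-stage arithmetic
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def __post_init__(self):
        if self.variant not in ("full", "RF", "SF"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class MetricsReport:
    auc: float
    aupr: float
    acc: float
    recall: float
    precision: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CVResult:
    folds: list[MetricsReport]
    mean: MetricsReport
    std: MetricsReport


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """AUC, AUPR plus thresholded accuracy/recall/precision."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC/AUPR need both classes present")
    pred = (s >= threshold).astype(int)
    return MetricsReport(
        auc=float(roc_auc_score(y, s)),
        aupr=float(average_precision_score(y, s)),
        acc=float(accuracy_score(y, pred)),
        recall=float(recall_score(y, pred, zero_division=0)),
        precision=float(precision_score(y, pred, zero_division=0)),
    )


@dataclass
class TrainedModel:
    config: TrainConfig
    classifier: MLPClassifier
    drug_rel: dict[str, np.ndarray]        # id -> 300-d relational feature
    prot_rel: dict[str, np.ndarray]
    dmpnn: DMPNNEncoder | None
    cnn: ProteinCNNEncoder | None
    drug_smiles: dict[str, str]
    prot_seqs: dict[str, str]
    history: dict = field(default_factory=dict)

    def _rel(self, table: dict, key: str) -> np.ndarray:
        return table.get(key, np.zeros(300))


def train_model(dataset: InteractionDataset, split: tuple[np.ndarray, np.ndarray],
                config: TrainConfig) -> TrainedModel:
    """Train on (train_idx, val_idx) index arrays into ``dataset.pairs``."""
    train_idx, val_idx = split
    train_pairs = [dataset.pairs[i] for i in train_idx]
    val_pairs = [dataset.pairs[i] for i in val_idx]
    if not any(p.label == 1 for p in train_pairs):
        raise ValueError("training split contains no positive pairs")

    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(8) % (2 ** 31)]
    (s_dnet, s_pnet, s_dgcl, s_pgcl, s_enc, s_clf, s_shuffle, s_drop) = seeds

    drug_ids = [d.drug_id for d in dataset.drugs]
    prot_ids = [p.protein_id for p in dataset.proteins]
    didx = {d: i for i, d in enumerate(drug_ids)}
    pidx = {p: i for i, p in enumerate(prot_ids)}

    # --- stage 1: relational features (frozen after pre-training) ---
    drug_rel: dict[str, np.ndarray] = {}
    prot_rel: dict[str, np.ndarray] = {}
    history: dict = {}
    if config.variant in ("full", "RF"):
        im = build_interaction_matrix(train_pairs, dataset.drugs, dataset.proteins)
        for entity, init, dim, s_net, s_gcl, table, ids in (
            ("drug", config.drug_init, config.drug_init_dim, s_dnet, s_dgcl, drug_rel, drug_ids),
            ("protein", config.protein_init, config.protein_init_dim, s_pnet, s_pgcl,
             prot_rel, prot_ids),
        ):
            net = build_relational_network(im, entity, threshold=config.sim_threshold,
                                           init_strategy=init, init_dim=dim, seed=s_net)
            state = train_gcl(net, epochs=config.gcl_epochs, p_edge=config.p_edge,
                              p_feat=config.p_feat, lr=config.gcl_lr,
                              decay=config.ema_decay, hidden_dim=config.gcl_hidden,
                              seed=s_gcl)
            feats = extract_relational_features(state.online, net)
            for k, i in zip(ids, range(len(ids))):
                table[k] = feats[i]
            history[f"gcl_loss_{entity}"] = state.loss_history

    # --- stage 2: supervised training ---
    use_struct = config.variant in ("full", "SF")
    dtype = np.float32 if config.precision == "float32" else np.float64
    dmpnn = cnn = None
    graphs = tokens = None
    if use_struct:
        dmpnn = DMPNNEncoder(n_layers=config.dmpnn_layers, seed=s_enc, dtype=dtype)
        cnn = ProteinCNNEncoder(emb_dim=config.cnn_emb_dim, channels=config.cnn_channels,
                                kernel_sizes=config.cnn_kernels, seed=s_enc + 1, dtype=dtype)
        graphs = [smiles_to_molgraph(d.smiles) for d in dataset.drugs]
        tokens = [tokenize_protein(p.sequence, config.max_seq_len) for p in dataset.proteins]

    in_dim = 1200 if config.variant == "full" else 600
    clf = MLPClassifier(in_dim=in_dim, hidden=config.mlp_hidden, dropout=config.dropout,
                        leaky_slope=config.leaky_slope, seed=s_clf, dtype=dtype)
    params = list(clf.parameters())
    if use_struct:
        params += dmpnn.parameters() + cnn.parameters()
    opt = Adam(params, lr=config.sup_lr)
    shuffle_rng = np.random.default_rng(s_shuffle)
    drop_rng = np.random.default_rng(s_drop)

    rel_d_mat = np.stack([drug_rel.get(d, np.zeros(300)) for d in drug_ids]).astype(dtype) \
        if config.variant != "SF" else None
    rel_p_mat = np.stack([prot_rel.get(p, np.zeros(300)) for p in prot_ids]).astype(dtype) \
        if config.variant != "SF" else None

    tr_d = np.asarray([didx[p.drug_id] for p in train_pairs], dtype=np.intp)
    tr_p = np.asarray([pidx[p.protein_id] for p in train_pairs], dtype=np.intp)
    tr_y = np.asarray([p.label for p in train_pairs], dtype=float)
    n_train = len(train_pairs)
    bs = config.batch_size or n_train

    def forward_batch(d_idx, p_idx, training: bool):
        """Classifier input tensor for pair index arrays (into the dataset)."""
        blocks_d, blocks_p = [], []
        if config.variant != "SF":
            blocks_d.append(ag.constant(rel_d_mat[d_idx]))
            blocks_p.append(ag.constant(rel_p_mat[p_idx]))
        if use_struct:
            ud, inv_d = np.unique(d_idx, return_inverse=True)
            up, inv_p = np.unique(p_idx, return_inverse=True)
            hd = dmpnn.forward(batch_molgraphs([graphs[i] for i in ud]))
            tok, lens = batch_tokens([tokens[i] for i in up])
            hp = cnn.forward(tok, lens)
            blocks_d.append(ag.rows(hd, inv_d))
            blocks_p.append(ag.rows(hp, inv_p))
        x = ag.concat(blocks_d + blocks_p, axis=1)
        return clf.logits(x, dropout_active=training, rng=drop_rng)

    def scores_for(pairs: list[InteractionPair]) -> np.ndarray:
        d = np.asarray([didx[p.drug_id] for p in pairs], dtype=np.intp)
        pr = np.asarray([pidx[p.protein_id] for p in pairs], dtype=np.intp)
        z = forward_batch(d, pr, training=False).data[:, 0]
        return 1.0 / (1.0 + np.exp(-z))

    val_y = np.asarray([p.label for p in val_pairs], dtype=int)
    best_auc, best_state, since_best = -np.inf, None, 0
    train_losses, val_aucs = [], []
    for epoch in range(config.sup_epochs):
        order = shuffle_rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, bs):
            sel = order[start:start + bs]
            logits = forward_batch(tr_d[sel], tr_p[sel], training=True)
            loss = ag.bce_with_logits(logits, tr_y[sel][:, None])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(sel)
        train_losses.append(epoch_loss / n_train)
        if len(val_pairs) > 0 and len(np.unique(val_y)) == 2:
            auc = float(roc_auc_score(val_y, scores_for(val_pairs)))
            val_aucs.append(auc)
            if auc > best_auc:
                best_auc, since_best = auc, 0
                best_state = [p.data.copy() for p in params]
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if best_state is not None:
        for p, saved in zip(params, best_state):
            p.data = saved
    history.update(train_loss=train_losses, val_auc=val_aucs)

    return TrainedModel(
        config=config, classifier=clf, drug_rel=drug_rel, prot_rel=prot_rel,
        dmpnn=dmpnn, cnn=cnn,
        drug_smiles={d.drug_id: d.smiles for d in dataset.drugs},
        prot_seqs={p.protein_id: p.sequence for p in dataset.proteins},
        history=history,
    )


def predict_pairs(model: TrainedModel, pairs: list[InteractionPair],
                  smiles: dict[str, str] | None = None,
                  sequences: dict[str, str] | None = None) -> np.ndarray:
    """Interaction probability per pair; deterministic (dropout off).

    Unseen drugs/proteins get a zero relational vector; their structural
    features are computed from SMILES/sequence (supplied via ``smiles`` /
    ``sequences`` if not part of the training universe).
    """
    cfg = model.config
    smiles = {**model.drug_smiles, **(smiles or {})}
    sequences = {**model.prot_seqs, **(sequences or {})}
    blocks_d, blocks_p = [], []
    if cfg.variant != "SF":
        blocks_d.append(np.stack([model._rel(model.drug_rel, p.drug_id) for p in pairs]))
        blocks_p.append(np.stack([model._rel(model.prot_rel, p.protein_id) for p in pairs]))
    if cfg.variant != "RF":
        uniq_d = sorted({p.drug_id for p in pairs})
        uniq_p = sorted({p.protein_id for p in pairs})
        hd = model.dmpnn.encode([smiles_to_molgraph(smiles[d]) for d in uniq_d])
        hp = model.cnn.encode([tokenize_protein(sequences[q], cfg.max_seq_len)
                               for q in uniq_p])
        d_at = {d: i for i, d in enumerate(uniq_d)}
        p_at = {q: i for i, q in enumerate(uniq_p)}
        blocks_d.append(np.stack([hd[d_at[p.drug_id]] for p in pairs]))
        blocks_p.append(np.stack([hp[p_at[p.protein_id]] for p in pairs]))
    x = np.concatenate(blocks_d + blocks_p, axis=1)
    return model.classifier.predict_proba(x)


def run_cv(dataset: InteractionDataset, config: TrainConfig, k: int = 10,
           test_frac: float = 0.1, split: FoldSplit | None = None) -> CVResult:
    """k-fold cross-validation; each fold's model is scored on the shared
    held-out test set and per-metric mean/std are aggregated."""
    if split is None:
        split = make_cv_splits(dataset, k=k, test_frac=test_frac, seed=config.seed)
    test_pairs = [dataset.pairs[i] for i in split.test_idx]
    eval_on_test = len(test_pairs) > 0
    reports = []
    for f, (train_idx, val_idx) in enumerate(split.folds):
        fold_cfg = TrainConfig(**{**config.to_dict(), "seed": config.seed + f})
        model = train_model(dataset, (train_idx, val_idx), fold_cfg)
        pairs = test_pairs if eval_on_test else [dataset.pairs[i] for i in val_idx]
        scores = predict_pairs(model, pairs)
        labels = [p.label for p in pairs]
        reports.append(compute_metrics(labels, scores))
    names = ("auc", "aupr", "acc", "recall", "precision")
    mean = MetricsReport(**{n: float(np.mean([getattr(r, n) for r in reports])) for n in names})
    std = MetricsReport(**{n: float(np.std([getattr(r, n) for r in reports])) for n in names})
    return CVResult(folds=reports, mean=mean, std=std)


def rank_predictions(model: TrainedModel, candidate_pairs: list[InteractionPair],
                     top_k: int | None = None, smiles: dict[str, str] | None = None,
                     sequences: dict[str, str] | None = None,
                     ) -> list[tuple[InteractionPair, float]]:
    """Candidates ordered by descending score; ties break lexicographically
    by (drug_id, protein_id)."""
    scores = predict_pairs(model, candidate_pairs, smiles=smiles, sequences=sequences)
    order = sorted(range(len(candidate_pairs)),
                   key=lambda i: (-scores[i], candidate_pairs[i].drug_id,
                                  candidate_pairs[i].protein_id))
    if top_k is not None:
        order = order[:top_k]
    return [(candidate_pairs[i], float(scores[i])) for i in order]
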
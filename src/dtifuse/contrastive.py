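"""Two-view graph contrastive pre-training of relational node features.

A bootstrap-style scheme without negative pairs: two stochastic augmentations
(edge dropping, node-feature masking) of the relational similarity network are
encoded by an online and a target two-layer GCN of identical shape. The online
embedding passes through a linear predictor and is pulled toward the detached
target embedding by a negative mean row-cosine loss, bounded in [-2, 2]. The
online branch trains by Adam; the target follows by an exponential moving
average xi <- tau*xi + (1-tau)*theta, which prevents representation collapse.
After training, the online encoder applied to the un-augmented network yields
the 300-d relational feature of every node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .optim import Adam
from .relational import RelationalNetwork

__all__ = [
    "ContrastiveView",
    "GCNEncoder",
    "Predictor",
    "GCLState",
    "augment",
    "normalized_adjacency",
    "contrastive_loss",
    "ema_update",
    "train_gcl",
    "extract_relational_features",
]

RELATIONAL_DIM = 300


@dataclass
class ContrastiveView:
    A: np.ndarray
    X: np.ndarray


def augment(network: RelationalNetwork, p_edge: float, p_feat: float,
            seed: int) -> ContrastiveView:
    """Drop each undirected edge with prob ``p_edge`` (both directions
    together) and zero each node's feature row with prob ``p_feat``."""
    if not (0.0 <= p_edge < 1.0 and 0.0 <= p_feat < 1.0):
        raise ValueError("augmentation probabilities must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    A = network.A.astype(np.int8).copy()
    ii, jj = np.nonzero(np.triu(A, k=1))
    drop = rng.random(ii.size) < p_edge
    A[ii[drop], jj[drop]] = 0
    A[jj[drop], ii[drop]] = 0
    X = network.X.copy()
    mask = rng.random(X.shape[0]) < p_feat
    X[mask] = 0.0
    return ContrastiveView(A=A, X=X)


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D^-1/2 (A + I) D^-1/2."""
    A_hat = np.asarray(A, dtype=float) + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class GCNEncoder:
    """Two graph-convolution layers (ReLU between): input -> hidden -> 300."""

    def __init__(self, in_dim: int, hidden_dim: int = RELATIONAL_DIM,
                 out_dim: int = RELATIONAL_DIM, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_dim = in_dim
        self.W1 = ag.parameter(_glorot(rng, in_dim, hidden_dim))
        self.b1 = ag.parameter(np.zeros(hidden_dim))
        self.W2 = ag.parameter(_glorot(rng, hidden_dim, out_dim))
        self.b2 = ag.parameter(np.zeros(out_dim))

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, view: ContrastiveView) -> Tensor:
        if view.X.shape[1] != self.in_dim:
            raise ValueError(
                f"feature width {view.X.shape[1]} does not match encoder input {self.in_dim}")
        A_hat = ag.constant(normalized_adjacency(view.A))
        X = ag.constant(view.X)
        H1 = ag.relu(ag.add(ag.matmul(ag.matmul(A_hat, X), self.W1), self.b1))
        H2 = ag.add(ag.matmul(ag.matmul(A_hat, H1), self.W2), self.b2)
        return H2

    def copy_from(self, other: "GCNEncoder"):
        for mine, theirs in zip(self.parameters(), other.parameters()):
            mine.data = theirs.data.copy()


class Predictor:
    """Single affine map 300 -> 300 on the online branch."""

    def __init__(self, dim: int = RELATIONAL_DIM, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W = ag.parameter(_glorot(rng, dim, dim))
        self.b = ag.parameter(np.zeros(dim))

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]

    def forward(self, H: Tensor) -> Tensor:
        return ag.add(ag.matmul(H, self.W), self.b)


def contrastive_loss(Z_oe: Tensor, H_te) -> Tensor:
    """-(2/N) * sum_i cos(z_i, h_i); the target branch is detached."""
    return ag.neg_cosine_rows(Z_oe, H_te)


def ema_update(target: GCNEncoder, online: GCNEncoder, decay: float):
    """xi <- decay * xi + (1 - decay) * theta, elementwise."""
    if not 0.0 <= decay <= 1.0:
        raise ValueError("decay must lie in [0, 1]")
    for xi, theta in zip(target.parameters(), online.parameters()):
        xi.data = decay * xi.data + (1.0 - decay) * theta.data


@dataclass
class GCLState:
    online: GCNEncoder
    target: GCNEncoder
    predictor: Predictor
    decay: float
    loss_history: list[float] = field(default_factory=list)


def train_gcl(network: RelationalNetwork, epochs: int = 2000, p_edge: float = 0.2,
              p_feat: float = 0.2, lr: float = 1e-3, decay: float = 0.99,
              hidden_dim: int = RELATIONAL_DIM, seed: int = 0) -> GCLState:
    """Contrastive pre-training loop; returns the state with loss history.

    Each epoch draws two fresh views (child seeds spawned from ``seed``),
    encodes them with the online and target encoders, applies the predictor
    to the online branch, takes one Adam step on the negative-cosine loss and
    one EMA step on the target. Deterministic given ``seed``.
    """
    if network.n_nodes < 1:
        raise ValueError("network must have at least one node")
    ss = np.random.SeedSequence(seed)
    init_seed, aug_seed = (int(s) for s in ss.generate_state(2) % (2 ** 31))
    online = GCNEncoder(network.X.shape[1], hidden_dim, seed=init_seed)
    target = GCNEncoder(network.X.shape[1], hidden_dim, seed=init_seed + 1)
    target.copy_from(online)
    predictor = Predictor(seed=init_seed + 2)
    opt = Adam(online.parameters() + predictor.parameters(), lr=lr)
    state = GCLState(online=online, target=target, predictor=predictor, decay=decay)
    aug_rng = np.random.default_rng(aug_seed)
    for epoch in range(epochs):
        s1, s2 = (int(x) for x in aug_rng.integers(0, 2 ** 31, size=2))
        v1 = augment(network, p_edge, p_feat, s1)
        v2 = augment(network, p_edge, p_feat, s2)
        Z = predictor.forward(online.forward(v1))
        H_te = target.forward(v2).detach()
        loss = contrastive_loss(Z, H_te)
        if not np.isfinite(loss.data):
            raise RuntimeError(f"non-finite contrastive loss at epoch {epoch}: {loss.data}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        ema_update(target, online, decay)
        state.loss_history.append(float(loss.data))
    return state


def extract_relational_features(online: GCNEncoder, network: RelationalNetwork) -> np.ndarray:
    """Embeddings of the un-augmented network; |V| x 300."""
    view = ContrastiveView(A=network.A, X=network.X)
    return online.forward(view).data.copy()
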
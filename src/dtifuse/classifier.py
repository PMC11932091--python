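"""Feature fusion and the MLP classification head.

Per entity the 300-d relational and 300-d structural vectors concatenate
(relational first) into a 600-d fused vector; the drug and protein fused
vectors concatenate into the classifier input. Three hidden affine layers,
each followed by dropout and LeakyReLU, feed a final affine layer producing
one logit; the interaction probability is its sigmoid, and training minimizes
binary cross-entropy in the numerically stable logit form.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["fuse", "classify", "MLPClassifier", "bce_loss"]

FUSED_DIM = 600


def fuse(relational: np.ndarray, structural: np.ndarray) -> np.ndarray:
    """Concatenate per-entity features, relational block first."""
    relational = np.asarray(relational)
    structural = np.asarray(structural)
    if relational.shape[-1] != 300 or structural.shape[-1] != 300:
        raise ValueError("both feature blocks must have width 300")
    return np.concatenate([relational, structural], axis=-1)


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class MLPClassifier:
    """Three hidden layers (dropout + LeakyReLU each) and a final logit layer."""

    def __init__(self, in_dim: int = 2 * FUSED_DIM, hidden: tuple[int, ...] = (1024, 512, 256),
                 dropout: float = 0.1, leaky_slope: float = 0.01, seed: int = 0,
                 dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.dropout = dropout
        self.leaky_slope = leaky_slope
        self.in_dim = in_dim
        self.dtype = dtype
        dims = [in_dim, *hidden]
        self.layers = [(ag.parameter(_glorot(rng, a, b), dtype), ag.parameter(np.zeros(b), dtype))
                       for a, b in zip(dims[:-1], dims[1:])]
        self.W_out = ag.parameter(_glorot(rng, dims[-1], 1), dtype)
        self.b_out = ag.parameter(np.zeros(1), dtype)

    def parameters(self) -> list[Tensor]:
        out = []
        for W, b in self.layers:
            out += [W, b]
        return out + [self.W_out, self.b_out]

    def logits(self, x, dropout_active: bool = False, rng=None) -> Tensor:
        """Raw logits for a batch (n, in_dim); ``x`` may be a Tensor so the
        encoders upstream receive gradients."""
        h = x if isinstance(x, Tensor) else ag.constant(
            np.atleast_2d(np.asarray(x, dtype=self.dtype)))
        if dropout_active and rng is None:
            rng = np.random.default_rng(0)
        for W, b in self.layers:
            h = ag.add(ag.matmul(h, W), b)
            h = ag.dropout(h, self.dropout, rng, active=dropout_active)
            h = ag.leaky_relu(h, self.leaky_slope)
        out = ag.add(ag.matmul(h, self.W_out), self.b_out)
        return out

    def predict_proba(self, x) -> np.ndarray:
        """Deterministic probabilities (dropout inactive)."""
        z = self.logits(x, dropout_active=False).data[:, 0]
        return 1.0 / (1.0 + np.exp(-z))


def classify(x_drug: np.ndarray, x_protein: np.ndarray, model: MLPClassifier,
             dropout_active: bool = False, rng=None) -> np.ndarray:
    """Probability of interaction for fused 600-d drug/protein vectors."""
    x = np.concatenate([np.atleast_2d(x_drug), np.atleast_2d(x_protein)], axis=1)
    if x.shape[1] != model.in_dim:
        raise ValueError(f"expected input width {model.in_dim}, got {x.shape[1]}")
    if dropout_active:
        z = model.logits(x, dropout_active=True, rng=rng).data[:, 0]
        return 1.0 / (1.0 + np.exp(-z))
    return model.predict_proba(x)


def bce_loss(probabilities: np.ndarray, labels: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy on probabilities, clipped for safety."""
    p = np.clip(np.asarray(probabilities, dtype=float), eps, 1.0 - eps)
    y = np.asarray(labels, dtype=float)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())
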
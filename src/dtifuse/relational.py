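"""Relational similarity networks derived from the bipartite interaction matrix.

Known drug-protein interactions define a binary matrix E (drugs x proteins).
A drug's row (a protein's column) is its interaction profile; profile cosine
similarity above a threshold (default 0.3, chosen against over-sparsity)
places an edge in a homogeneous drug-drug or protein-protein network. Node
features are initialized randomly — 167-d for drugs (the MACCS fingerprint
length) and 256-d for proteins — either independently per node ("random") or
one shared random row ("uniform"), the two strategies whose contrast the
downstream evaluation probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DrugRecord, InteractionPair, ProteinRecord

__all__ = [
    "InteractionMatrix",
    "RelationalNetwork",
    "DRUG_FEATURE_DIM",
    "PROTEIN_FEATURE_DIM",
    "build_interaction_matrix",
    "cosine_similarity",
    "profile_similarity_matrix",
    "build_relational_network",
    "init_node_features",
    "save_network",
    "load_network",
]

DRUG_FEATURE_DIM = 167     # MACCS key count
PROTEIN_FEATURE_DIM = 256


@dataclass
class InteractionMatrix:
    E: np.ndarray                     # binary, |drugs| x |proteins|
    drug_index: dict[str, int]
    protein_index: dict[str, int]


@dataclass
class RelationalNetwork:
    A: np.ndarray        # binary symmetric adjacency, zero diagonal
    X: np.ndarray        # initial node features, one row per node
    entity: str          # "drug" or "protein"

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


def build_interaction_matrix(train_pairs: list[InteractionPair], drugs: list[DrugRecord],
                             proteins: list[ProteinRecord]) -> InteractionMatrix:
    """E[i, j] = 1 iff (drug i, protein j) is a positive training pair.

    Only label-1 pairs contribute; negatives and unlisted cells stay 0. Built
    from training pairs only so held-out interactions never leak edges.
    """
    didx = {d.drug_id: i for i, d in enumerate(drugs)}
    pidx = {p.protein_id: j for j, p in enumerate(proteins)}
    E = np.zeros((len(drugs), len(proteins)), dtype=np.int8)
    for pair in train_pairs:
        if pair.drug_id not in didx:
            raise KeyError(f"unknown drug id {pair.drug_id!r}")
        if pair.protein_id not in pidx:
            raise KeyError(f"unknown protein id {pair.protein_id!r}")
        if pair.label == 1:
            E[didx[pair.drug_id], pidx[pair.protein_id]] = 1
    return InteractionMatrix(E=E, drug_index=didx, protein_index=pidx)


def cosine_similarity(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Profile cosine; 0 if either profile is all-zero (no evidence)."""
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    if g_i.shape != g_j.shape:
        raise ValueError("profiles must have equal length")
    ni, nj = np.linalg.norm(g_i), np.linalg.norm(g_j)
    if ni == 0 or nj == 0:
        return 0.0
    return float(g_i @ g_j / (ni * nj))


def profile_similarity_matrix(profiles: np.ndarray) -> np.ndarray:
    """All pairwise profile cosines; zero-norm rows yield zero similarity."""
    P = np.asarray(profiles, dtype=float)
    norms = np.linalg.norm(P, axis=1)
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, P @ P.T / np.where(denom > 0, denom, 1.0), 0.0)
    return S


def init_node_features(n_nodes: int, dim: int, strategy: str = "random",
                       seed: int = 0) -> np.ndarray:
    """Standard-normal node features; "uniform" replicates one random row so
    embedding differences come from topology alone."""
    if dim <= 0:
        raise ValueError("feature dimension must be positive")
    rng = np.random.default_rng(seed)
    if strategy == "random":
        return rng.standard_normal((n_nodes, dim))
    if strategy == "uniform":
        row = rng.standard_normal(dim)
        return np.tile(row, (n_nodes, 1))
    raise ValueError(f"unknown init strategy {strategy!r}")


def build_relational_network(E, entity: str, threshold: float = 0.3,
                             init_strategy: str = "random", init_dim: int | None = None,
                             seed: int = 0) -> RelationalNetwork:
    """Threshold the profile-cosine matrix into an adjacency (strict '>')."""
    E_arr = E.E if isinstance(E, InteractionMatrix) else np.asarray(E)
    if entity == "drug":
        profiles = E_arr.astype(float)
        dim = DRUG_FEATURE_DIM if init_dim is None else init_dim
    elif entity == "protein":
        profiles = E_arr.T.astype(float)
        dim = PROTEIN_FEATURE_DIM if init_dim is None else init_dim
    else:
        raise ValueError(f"entity must be 'drug' or 'protein', got {entity!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    S = profile_similarity_matrix(profiles)
    A = (S > threshold).astype(np.int8)
    np.fill_diagonal(A, 0)
    X = init_node_features(profiles.shape[0], dim, init_strategy, seed)
    return RelationalNetwork(A=A, X=X, entity=entity)


def save_network(network: RelationalNetwork, edge_path, feature_path):
    """Edge list as TSV (node_i, node_j, one row per undirected edge) plus a
    dense .npy feature matrix; round-trips bit-exactly."""
    ii, jj = np.nonzero(np.triu(network.A, k=1))
    with open(edge_path, "w") as fh:
        fh.write("node_i\tnode_j\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\n")
    np.save(feature_path, network.X)


def load_network(edge_path, feature_path, entity: str) -> RelationalNetwork:
    X = np.load(feature_path)
    n = X.shape[0]
    A = np.zeros((n, n), dtype=np.int8)
    with open(edge_path) as fh:
        next(fh)
        for line in fh:
            i, j = map(int, line.split())
            A[i, j] = A[j, i] = 1
    return RelationalNetwork(A=A, X=X, entity=entity)
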
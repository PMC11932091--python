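"""Structural feature encoders: molecules via a directed message-passing
network, proteins via token embedding + 1-d CNN + masked global max-pool.

Molecules are parsed from SMILES with RDKit and featurized with eight atomic
properties (atomic number, bond count, formal charge, chirality, hydrogen
count, hybridization, aromaticity, atomic mass) and four bond properties
(bond type, conjugation, ring membership, stereochemistry); categorical
properties are one-hot with an out-of-range bucket, mass is scaled by 0.01.
Each chemical bond becomes two directed edges. Hidden states live on directed
edges; the message into edge (v -> w) sums incoming edge states at v while
excluding the reverse edge (w -> v), the defining trait of the directed
variant. Both encoders output a 300-d vector per entity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "MolecularGraph",
    "MolGraphBatch",
    "TokenSequence",
    "DMPNNEncoder",
    "ProteinCNNEncoder",
    "smiles_to_molgraph",
    "batch_molgraphs",
    "tokenize_protein",
    "batch_tokens",
    "ATOM_FEATURE_DIM",
    "BOND_FEATURE_DIM",
    "STRUCT_DIM",
    "PROTEIN_VOCAB",
    "PAD_TOKEN",
    "UNK_TOKEN",
]

STRUCT_DIM = 300

_ATOMIC_NUMS = list(range(1, 37)) + [53]       # H..Kr and I; bucket for others
_DEGREES = [0, 1, 2, 3, 4, 5]
_CHARGES = [-2, -1, 0, 1, 2]
_CHIRAL_TAGS = [0, 1, 2, 3]
_NUM_HS = [0, 1, 2, 3, 4]
_HYBRID = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
_STEREO = list(range(6))

ATOM_FEATURE_DIM = (len(_ATOMIC_NUMS) + 1) + (len(_DEGREES) + 1) + (len(_CHARGES) + 1) \
    + (len(_CHIRAL_TAGS) + 1) + (len(_NUM_HS) + 1) + (len(_HYBRID) + 1) + 1 + 1
BOND_FEATURE_DIM = (len(_BOND_TYPES) + 1) + 1 + 1 + (len(_STEREO) + 1)


def _one_hot(value, choices) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0           # out-of-range bucket
    return vec


def _atom_features(atom: Chem.Atom) -> list[float]:
    return (
        _one_hot(atom.GetAtomicNum(), _ATOMIC_NUMS)
        + _one_hot(atom.GetTotalDegree(), _DEGREES)
        + _one_hot(atom.GetFormalCharge(), _CHARGES)
        + _one_hot(int(atom.GetChiralTag()), _CHIRAL_TAGS)
        + _one_hot(atom.GetTotalNumHs(), _NUM_HS)
        + _one_hot(atom.GetHybridization(), _HYBRID)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + [atom.GetMass() * 0.01]
    )


def _bond_features(bond: Chem.Bond) -> list[float]:
    return (
        _one_hot(bond.GetBondType(), _BOND_TYPES)
        + [1.0 if bond.GetIsConjugated() else 0.0]
        + [1.0 if bond.IsInRing() else 0.0]
        + _one_hot(int(bond.GetStereo()), _STEREO)
    )


@dataclass
class MolecularGraph:
    """Featurized molecule; every bond appears as two directed edges."""

    atom_features: np.ndarray   # (n_atoms, ATOM_FEATURE_DIM)
    bond_features: np.ndarray   # (n_directed_edges, BOND_FEATURE_DIM)
    edge_src: np.ndarray        # source atom of each directed edge
    edge_dst: np.ndarray        # destination atom
    rev_index: np.ndarray       # index of each edge's reverse

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_src.shape[0]


def smiles_to_molgraph(smiles: str) -> MolecularGraph:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() < 1:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    atom_feats = np.asarray([_atom_features(a) for a in mol.GetAtoms()], dtype=float)
    src, dst, bfeats, rev = [], [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = _bond_features(bond)
        e = len(src)
        src += [i, j]
        dst += [j, i]
        bfeats += [f, f]
        rev += [e + 1, e]
    return MolecularGraph(
        atom_features=atom_feats,
        bond_features=np.asarray(bfeats, dtype=float).reshape(len(src), BOND_FEATURE_DIM),
        edge_src=np.asarray(src, dtype=np.intp),
        edge_dst=np.asarray(dst, dtype=np.intp),
        rev_index=np.asarray(rev, dtype=np.intp),
    )


@dataclass
class MolGraphBatch:
    """Several molecular graphs packed into shared index arrays."""

    atom_features: np.ndarray
    bond_features: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    rev_index: np.ndarray
    atom_mol: np.ndarray        # molecule id per atom
    n_mols: int
    n_atoms_per_mol: np.ndarray


def batch_molgraphs(graphs: list[MolecularGraph]) -> MolGraphBatch:
    atom_off = 0
    edge_off = 0
    afs, bfs, srcs, dsts, revs, mols, counts = [], [], [], [], [], [], []
    for m, g in enumerate(graphs):
        afs.append(g.atom_features)
        bfs.append(g.bond_features)
        srcs.append(g.edge_src + atom_off)
        dsts.append(g.edge_dst + atom_off)
        revs.append(g.rev_index + edge_off)
        mols.append(np.full(g.n_atoms, m, dtype=np.intp))
        counts.append(g.n_atoms)
        atom_off += g.n_atoms
        edge_off += g.n_edges
    return MolGraphBatch(
        atom_features=np.concatenate(afs, axis=0),
        bond_features=np.concatenate(bfs, axis=0) if edge_off else
        np.zeros((0, BOND_FEATURE_DIM)),
        edge_src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.intp),
        edge_dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.intp),
        rev_index=np.concatenate(revs) if revs else np.zeros(0, dtype=np.intp),
        atom_mol=np.concatenate(mols),
        n_mols=len(graphs),
        n_atoms_per_mol=np.asarray(counts, dtype=float),
    )


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class DMPNNEncoder:
    """Directed message passing on molecular graphs with mean-pool readout.

    Edge states initialize as ReLU(W_in [x_src ; e]); each of ``n_layers``
    steps updates h_e = ReLU(h0_e + W_m m_e) where m_e sums incoming edge
    states excluding the reverse (no bias on W_m, so an edge with no incoming
    messages keeps its initial state). Atom states are
    ReLU(W_atom [x_v ; sum incoming h] + b); readout averages atoms per
    molecule into a 300-d vector.
    """

    def __init__(self, hidden_dim: int = STRUCT_DIM, n_layers: int = 2, seed: int = 0,
                 dtype=np.float64):
        rng = np.random.default_rng(seed)
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.dtype = dtype
        self.W_in = ag.parameter(
            _glorot(rng, ATOM_FEATURE_DIM + BOND_FEATURE_DIM, hidden_dim), dtype)
        self.b_in = ag.parameter(np.zeros(hidden_dim), dtype)
        self.W_msg = ag.parameter(_glorot(rng, hidden_dim, hidden_dim), dtype)
        self.W_atom = ag.parameter(_glorot(rng, ATOM_FEATURE_DIM + hidden_dim, hidden_dim), dtype)
        self.b_atom = ag.parameter(np.zeros(hidden_dim), dtype)

    def parameters(self) -> list[Tensor]:
        return [self.W_in, self.b_in, self.W_msg, self.W_atom, self.b_atom]

    def forward(self, batch: MolGraphBatch) -> Tensor:
        n_atoms = batch.atom_features.shape[0]
        x_atom = ag.constant(batch.atom_features.astype(self.dtype, copy=False))
        if batch.edge_src.size > 0:
            x_src = ag.rows(x_atom, batch.edge_src)
            e_in = ag.concat(
                [x_src, ag.constant(batch.bond_features.astype(self.dtype, copy=False))], axis=1)
            h0 = ag.relu(ag.add(ag.matmul(e_in, self.W_in), self.b_in))
            h = h0
            for _ in range(self.n_layers):
                node_sum = ag.segment_sum(h, batch.edge_dst, n_atoms)
                incoming = ag.rows(node_sum, batch.edge_src)
                h_rev = ag.rows(h, batch.rev_index)
                m = ag.add(incoming, ag.mul(h_rev, -1.0))
                h = ag.relu(ag.add(h0, ag.matmul(m, self.W_msg)))
            atom_msg = ag.segment_sum(h, batch.edge_dst, n_atoms)
        else:
            atom_msg = ag.constant(np.zeros((n_atoms, self.hidden_dim), dtype=self.dtype))
        a_in = ag.concat([x_atom, atom_msg], axis=1)
        a = ag.relu(ag.add(ag.matmul(a_in, self.W_atom), self.b_atom))
        mol_sum = ag.segment_sum(a, batch.atom_mol, batch.n_mols)
        inv_counts = (1.0 / batch.n_atoms_per_mol)[:, None].astype(self.dtype)
        return ag.mul(mol_sum, ag.constant(inv_counts))

    def encode(self, graphs: list[MolecularGraph]) -> np.ndarray:
        return self.forward(batch_molgraphs(graphs)).data.copy()


# --- protein tokenization -------------------------------------------------

PAD_TOKEN = 0
UNK_TOKEN = 1
_RESIDUES = "ACDEFGHIKLMNPQRSTVWYBZXUO"  # 20 standard + ambiguity codes
PROTEIN_VOCAB = {"<pad>": PAD_TOKEN, "<unk>": UNK_TOKEN}
PROTEIN_VOCAB.update({aa: i + 2 for i, aa in enumerate(_RESIDUES)})
VOCAB_SIZE = len(PROTEIN_VOCAB)


@dataclass
class TokenSequence:
    tokens: np.ndarray     # (L_s,) integer tokens, pad = 0
    true_length: int


def tokenize_protein(sequence: str, max_len: int = 1000) -> TokenSequence:
    """Residue-level tokens, right-padded with 0 to ``max_len`` (longer
    sequences truncate); unknown characters map to the unknown token."""
    if len(sequence) == 0:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()[:max_len]
    toks = np.full(max_len, PAD_TOKEN, dtype=np.intp)
    for i, ch in enumerate(seq):
        toks[i] = PROTEIN_VOCAB.get(ch, UNK_TOKEN)
    return TokenSequence(tokens=toks, true_length=len(seq))


def batch_tokens(seqs: list[TokenSequence]) -> tuple[np.ndarray, np.ndarray]:
    tokens = np.stack([s.tokens for s in seqs])
    lengths = np.asarray([s.true_length for s in seqs])
    return tokens, lengths


class ProteinCNNEncoder:
    """Embedding -> two same-padded 1-d convolutions (ReLU) -> masked global
    max-pool over true sequence positions -> 300-d."""

    def __init__(self, emb_dim: int = 128, channels: tuple[int, int] = (128, STRUCT_DIM),
                 kernel_sizes: tuple[int, int] = (7, 7), seed: int = 0, dtype=np.float64):
        if channels[-1] != STRUCT_DIM:
            raise ValueError(f"last channel count must be {STRUCT_DIM}")
        rng = np.random.default_rng(seed)
        self.emb = ag.parameter(rng.standard_normal((VOCAB_SIZE, emb_dim)) * 0.1, dtype)
        self.kernel_sizes = kernel_sizes
        c_prev = emb_dim
        self.convs = []
        for k, c in zip(kernel_sizes, channels):
            W = ag.parameter(_glorot(rng, k * c_prev, c).reshape(k, c_prev, c), dtype)
            b = ag.parameter(np.zeros(c), dtype)
            self.convs.append((W, b))
            c_prev = c

    def parameters(self) -> list[Tensor]:
        out = [self.emb]
        for W, b in self.convs:
            out += [W, b]
        return out

    def forward(self, tokens: np.ndarray, lengths: np.ndarray) -> Tensor:
        x = ag.embedding(self.emb, tokens)            # (B, L, De)
        for W, b in self.convs:
            x = ag.relu(ag.conv1d_same(x, W, b))
        L = tokens.shape[1]
        mask = np.arange(L)[None, :] < lengths[:, None]
        return ag.masked_max(x, mask)                  # (B, 300)

    def encode(self, seqs: list[TokenSequence]) -> np.ndarray:
        tokens, lengths = batch_tokens(seqs)
        return self.forward(tokens, lengths).data.copy()
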
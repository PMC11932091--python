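"""Interaction datasets: records, TSV/FASTA IO, negative sampling and splits.

A dataset is the universe every later stage indexes into: a drug table
(id, SMILES), a protein table (id, amino-acid sequence) and a labeled pair
table. Splitting supports the three evaluation protocols used throughout:
random k-fold cross-validation with a fixed held-out test set, imbalanced
negative ratios, and protein sequence-identity cluster folds that keep
similar proteins out of each other's training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from rdkit import Chem
from rdkit import RDLogger
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "DrugRecord",
    "ProteinRecord",
    "InteractionPair",
    "InteractionDataset",
    "FoldSplit",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "read_proteins_fasta",
    "sample_negatives",
    "make_cv_splits",
    "make_imbalanced",
    "protein_identity_matrix",
    "make_cluster_splits",
]


class DatasetError(ValueError):
    """Raised when a dataset violates its integrity constraints."""


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str


@dataclass(frozen=True)
class InteractionPair:
    drug_id: str
    protein_id: str
    label: int


@dataclass
class InteractionDataset:
    drugs: list[DrugRecord]
    proteins: list[ProteinRecord]
    pairs: list[InteractionPair]

    def __post_init__(self):
        self.validate()

    def validate(self):
        drug_ids = [d.drug_id for d in self.drugs]
        if len(set(drug_ids)) != len(drug_ids):
            raise DatasetError("duplicate drug ids")
        prot_ids = [p.protein_id for p in self.proteins]
        if len(set(prot_ids)) != len(prot_ids):
            raise DatasetError("duplicate protein ids")
        for p in self.proteins:
            if len(p.sequence) < 1:
                raise DatasetError(f"empty sequence for protein {p.protein_id!r}")
        dset, pset = set(drug_ids), set(prot_ids)
        seen = set()
        for pr in self.pairs:
            if pr.drug_id not in dset:
                raise DatasetError(f"pair references unknown drug id {pr.drug_id!r}")
            if pr.protein_id not in pset:
                raise DatasetError(f"pair references unknown protein id {pr.protein_id!r}")
            key = (pr.drug_id, pr.protein_id)
            if key in seen:
                raise DatasetError(f"duplicate pair {key}")
            if pr.label not in (0, 1):
                raise DatasetError(f"non-binary label for pair {key}")
            seen.add(key)

    @property
    def positives(self) -> list[InteractionPair]:
        return [p for p in self.pairs if p.label == 1]

    @property
    def negatives(self) -> list[InteractionPair]:
        return [p for p in self.pairs if p.label == 0]

    def drug_map(self) -> dict[str, DrugRecord]:
        return {d.drug_id: d for d in self.drugs}

    def protein_map(self) -> dict[str, ProteinRecord]:
        return {p.protein_id: p for p in self.proteins}


@dataclass
class FoldSplit:
    """Index sets into a dataset's pair list.

    ``test_idx`` is a shared held-out set (possibly empty for cluster folds);
    ``folds`` is a list of (train_idx, val_idx) arrays whose validation sets
    partition the non-test pool.
    """

    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def to_json(self, path):
        payload = {
            "test": [int(i) for i in self.test_idx],
            "folds": [
                {"train": [int(i) for i in tr], "val": [int(i) for i in va]}
                for tr, va in self.folds
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FoldSplit":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            test_idx=np.asarray(payload["test"], dtype=np.intp),
            folds=[
                (np.asarray(f["train"], dtype=np.intp), np.asarray(f["val"], dtype=np.intp))
                for f in payload["folds"]
            ],
        )


def _check_smiles(drug: DrugRecord):
    mol = Chem.MolFromSmiles(drug.smiles)
    if mol is None or mol.GetNumAtoms() < 1:
        raise DatasetError(f"unparsable SMILES for drug {drug.drug_id!r}: {drug.smiles!r}")


def read_dataset(drug_path, protein_path, pair_path, validate_smiles=True) -> InteractionDataset:
    """Load the TSV trio (drug table, protein table, pair table)."""
    ddf = pd.read_csv(drug_path, sep="\t", dtype=str)
    pdf = pd.read_csv(protein_path, sep="\t", dtype=str)
    idf = pd.read_csv(pair_path, sep="\t", dtype={"drug_id": str, "protein_id": str, "label": int})
    drugs = [DrugRecord(r.drug_id, r.smiles) for r in ddf.itertuples()]
    proteins = [ProteinRecord(r.protein_id, r.sequence) for r in pdf.itertuples()]
    pairs = [InteractionPair(r.drug_id, r.protein_id, int(r.label)) for r in idf.itertuples()]
    ds = InteractionDataset(drugs, proteins, pairs)
    if validate_smiles:
        for d in drugs:
            _check_smiles(d)
    return ds


def write_dataset(dataset: InteractionDataset, drug_path, protein_path, pair_path):
    pd.DataFrame([(d.drug_id, d.smiles) for d in dataset.drugs],
                 columns=["drug_id", "smiles"]).to_csv(drug_path, sep="\t", index=False)
    pd.DataFrame([(p.protein_id, p.sequence) for p in dataset.proteins],
                 columns=["protein_id", "sequence"]).to_csv(protein_path, sep="\t", index=False)
    pd.DataFrame([(q.drug_id, q.protein_id, q.label) for q in dataset.pairs],
                 columns=["drug_id", "protein_id", "label"]).to_csv(pair_path, sep="\t", index=False)


def read_proteins_fasta(path) -> list[ProteinRecord]:
    """FASTA protein reader; the record id becomes the protein id."""
    return [ProteinRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def sample_negatives(dataset: InteractionDataset, ratio: float, seed: int) -> list[InteractionPair]:
    """Draw unique non-interacting (drug, protein) pairs with label 0.

    Pairs are sampled uniformly from the grid cells not occupied by any
    existing pair, mirroring the draw-a-drug-then-a-non-interacting-protein
    procedure with uniqueness enforced. Deterministic given ``seed``.
    """
    n_pos = len(dataset.positives)
    count = int(round(ratio * n_pos))
    n_d, n_p = len(dataset.drugs), len(dataset.proteins)
    occupied = {(q.drug_id, q.protein_id) for q in dataset.pairs}
    capacity = n_d * n_p - len(occupied)
    if count > capacity:
        raise DatasetError(
            f"requested {count} negatives but only {capacity} free (drug, protein) cells remain")
    rng = np.random.default_rng(seed)
    drug_ids = [d.drug_id for d in dataset.drugs]
    prot_ids = [p.protein_id for p in dataset.proteins]
    didx = {d: i for i, d in enumerate(drug_ids)}
    pidx = {p: i for i, p in enumerate(prot_ids)}
    occupied_flat = {didx[d] * n_p + pidx[p] for d, p in occupied}
    chosen: list[int] = []
    if n_d * n_p <= 2_000_000:
        free = np.setdiff1d(np.arange(n_d * n_p), np.fromiter(occupied_flat, dtype=np.int64),
                            assume_unique=False)
        chosen = list(rng.choice(free, size=count, replace=False))
    else:  # rejection sampling on large grids
        taken = set(occupied_flat)
        while len(chosen) < count:
            cell = int(rng.integers(0, n_d)) * n_p + int(rng.integers(0, n_p))
            if cell not in taken:
                taken.add(cell)
                chosen.append(cell)
    return [InteractionPair(drug_ids[c // n_p], prot_ids[c % n_p], 0) for c in chosen]


def make_cv_splits(dataset: InteractionDataset, k: int = 10, test_frac: float = 0.1,
                   seed: int = 0) -> FoldSplit:
    """Hold out ``test_frac`` of pairs once, then split the rest into ``k``
    validation folds; fold i trains on the remaining k-1 folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(dataset.pairs)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} pairs for {k}-fold CV, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(test_frac * n))
    test_idx = np.sort(order[:n_test])
    pool = order[n_test:]
    fold_chunks = np.array_split(pool, k)
    folds = []
    for i in range(k):
        val = np.sort(fold_chunks[i])
        train = np.sort(np.concatenate([fold_chunks[j] for j in range(k) if j != i])) \
            if k > 1 else np.array([], dtype=np.intp)
        folds.append((train.astype(np.intp), val.astype(np.intp)))
    return FoldSplit(test_idx=test_idx.astype(np.intp), folds=folds)


def make_imbalanced(dataset: InteractionDataset, neg_per_pos: int, seed: int) -> InteractionDataset:
    """Rebuild the pair table with ``neg_per_pos`` sampled negatives per positive."""
    positives = dataset.positives
    base = InteractionDataset(dataset.drugs, dataset.proteins, list(positives))
    negs = sample_negatives(base, float(neg_per_pos), seed)
    return InteractionDataset(dataset.drugs, dataset.proteins, list(positives) + negs)


_NONSTANDARD = str.maketrans({c: "X" for c in "JUO"})


def protein_identity_matrix(proteins: list[ProteinRecord], gap_open: float = 10.0,
                            gap_extend: float = 0.5,
                            substitution_scheme: str = "BLOSUM62") -> np.ndarray:
    """Pairwise local-alignment sequence identities in [0, 1].

    Identity = identical columns / alignment length of the optimal local
    (Smith-Waterman, affine gap) alignment; a pair with no positive-scoring
    alignment scores 0. Symmetric with unit diagonal.
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    for p in proteins:
        if len(p.sequence) == 0:
            raise DatasetError(f"empty sequence for protein {p.protein_id!r}")
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(substitution_scheme)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    n = len(proteins)
    seqs = [p.sequence.upper().translate(_NONSTANDARD) for p in proteins]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _local_identity(aligner, seqs[i], seqs[j])
    return out


def _local_identity(aligner, s1: str, s2: str) -> float:
    if aligner.score(s1, s2) <= 0:
        return 0.0
    aln = next(iter(aligner.align(s1, s2)))
    a, b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    length = len(a)
    return matches / length if length else 0.0


def make_cluster_splits(dataset: InteractionDataset, identity_matrix: np.ndarray,
                        n_clusters: int = 10) -> FoldSplit:
    """Fold assignment by agglomerative clustering of protein identities.

    Proteins are clustered (average linkage on distance 1 - identity) into
    ``n_clusters`` groups; each pair joins its protein's cluster, so no fold
    shares closely related proteins with its training data.
    """
    n_prot = len(dataset.proteins)
    if identity_matrix.shape != (n_prot, n_prot):
        raise ValueError("identity matrix shape does not match protein count")
    if n_clusters > n_prot:
        raise ValueError("more clusters requested than proteins")
    dist = 1.0 - identity_matrix
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    cluster_of = {p.protein_id: labels[i] for i, p in enumerate(dataset.proteins)}
    by_cluster: dict[int, list[int]] = {c: [] for c in sorted(set(labels))}
    for idx, pair in enumerate(dataset.pairs):
        by_cluster[cluster_of[pair.protein_id]].append(idx)
    all_idx = np.arange(len(dataset.pairs))
    folds = []
    for c in sorted(by_cluster):
        val = np.asarray(by_cluster[c], dtype=np.intp)
        train = np.setdiff1d(all_idx, val).astype(np.intp)
        folds.append((train, val))
    return FoldSplit(test_idx=np.array([], dtype=np.intp), folds=folds)


def protein_cluster_labels(identity_matrix: np.ndarray, n_clusters: int) -> np.ndarray:
    """Cluster labels only (1..n_clusters), for inspection and tests."""
    dist = 1.0 - identity_matrix
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=n_clusters, criterion="maxclust")
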
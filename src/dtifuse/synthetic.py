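"""Synthetic DTI benchmarks with planted block structure.

Emulates the guilt-by-association regularity real interaction data exhibits:
drugs and proteins fall into latent blocks, and whether a (drug-block,
protein-block) cell is "active" drives the interaction probability. Each drug
block carries a chemical scaffold (decorated per drug so molecules differ
within a block), each protein block carries a fixed length-8 sequence motif
inserted into random background — so the relational networks, the molecular
encoder and the sequence encoder all have recoverable signal. Setting
``block_affinity`` equal to ``background_prob`` removes all signal and serves
as the null control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .data import (DrugRecord, InteractionDataset, InteractionPair,
                   ProteinRecord, sample_negatives)

__all__ = ["SyntheticSpec", "SyntheticDTI", "simulate_dti",
           "fixture_molecules", "fixture_sequences", "write_block_labels"]

# Curated parsable scaffolds, one per latent drug block (cycled if needed).
SCAFFOLDS = [
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "C1CCCCC1",            # cyclohexane
    "c1ccoc1",             # furan
    "c1ccsc1",             # thiophene
    "c1cnc[nH]1",          # imidazole
    "c1ccc2ccccc2c1",      # naphthalene
    "c1cncnc1",            # pyrimidine
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccc2ncccc2c1",      # quinoline
    "C1COCCN1",            # morpholine
    "C1CCNCC1",            # piperidine
    "Oc1ccccc1",           # phenol
    "Nc1ccccc1",           # aniline
    "OC(=O)c1ccccc1",      # benzoic acid
    "Cc1ccccc1",           # toluene
    "C1CCOC1",             # tetrahydrofuran
    "c1cscn1",             # thiazole
    "C1CCNC1",             # pyrrolidine
    "c1ccc(cc1)C#N",       # benzonitrile
]

# Small substituents appended to a scaffold SMILES; concatenation after a
# ring-closure digit or terminal atom stays parsable for these scaffolds.
SUBSTITUENTS = ["C", "CC", "CCC", "O", "N", "F", "Cl", "Br", "CO", "CN",
                "C(C)C", "C=C", "C#N", "CF", "COC", "CCl"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """Generator settings; the defaults define the planted benchmark."""

    n_drugs: int = 200
    n_proteins: int = 150
    n_drug_blocks: int = 8
    n_protein_blocks: int = 6
    block_affinity: float = 0.5     # P(positive) in an active block cell
    background_prob: float = 0.02   # P(positive) elsewhere
    active_block_prob: float = 0.3  # P a (drug-block, protein-block) cell is active
    neg_ratio: float = 1.0          # sampled negatives per positive
    seq_length: int = 100
    motif_length: int = 8
    seed: int = 7

    def __post_init__(self):
        for p in (self.block_affinity, self.background_prob, self.active_block_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_drug_blocks > self.n_drugs or self.n_protein_blocks > self.n_proteins:
            raise ValueError("more blocks than entities")


@dataclass
class SyntheticDTI:
    dataset: InteractionDataset
    drug_blocks: np.ndarray          # block label per drug
    protein_blocks: np.ndarray       # block label per protein
    active_blocks: np.ndarray        # bool (n_drug_blocks, n_protein_blocks)
    spec: SyntheticSpec = field(repr=False, default=None)


def _decorate(scaffold: str, rng) -> str:
    """Append 1-2 substituents; falls back to the bare scaffold if the
    decorated string fails to parse."""
    out = scaffold
    for _ in range(int(rng.integers(1, 3))):
        cand = out + SUBSTITUENTS[int(rng.integers(len(SUBSTITUENTS)))]
        if Chem.MolFromSmiles(cand) is not None:
            out = cand
    return out


def fixture_molecules(n: int, seed: int = 0) -> list[str]:
    """``n`` valid toy SMILES (scaffolds plus decorations), deterministic."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        base = SCAFFOLDS[i % len(SCAFFOLDS)]
        out.append(base if i < len(SCAFFOLDS) else _decorate(base, rng))
    return out


def fixture_sequences(n: int, length: int = 100, seed: int = 0) -> list[str]:
    """``n`` random sequences over the 20-letter amino-acid alphabet."""
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list(AMINO_ACIDS), size=length)) for _ in range(n)]


def simulate_dti(spec: SyntheticSpec) -> SyntheticDTI:
    """Draw a dataset with planted (drug-block, protein-block) interaction
    structure; negatives come from the shared uniform sampler."""
    rng = np.random.default_rng(spec.seed)
    drug_blocks = rng.integers(0, spec.n_drug_blocks, size=spec.n_drugs)
    protein_blocks = rng.integers(0, spec.n_protein_blocks, size=spec.n_proteins)
    # ensure every block is inhabited
    drug_blocks[:spec.n_drug_blocks] = np.arange(spec.n_drug_blocks)
    protein_blocks[:spec.n_protein_blocks] = np.arange(spec.n_protein_blocks)

    active = rng.random((spec.n_drug_blocks, spec.n_protein_blocks)) < spec.active_block_prob
    for i in range(spec.n_drug_blocks):      # every drug block hits >= 1 protein block
        if not active[i].any():
            active[i, int(rng.integers(spec.n_protein_blocks))] = True

    drugs = []
    for i in range(spec.n_drugs):
        scaffold = SCAFFOLDS[drug_blocks[i] % len(SCAFFOLDS)]
        drugs.append(DrugRecord(f"D{i:04d}", _decorate(scaffold, rng)))

    motifs = ["".join(rng.choice(list(AMINO_ACIDS), size=spec.motif_length))
              for _ in range(spec.n_protein_blocks)]
    proteins = []
    for j in range(spec.n_proteins):
        seq = list(rng.choice(list(AMINO_ACIDS), size=spec.seq_length))
        pos = int(rng.integers(0, spec.seq_length - spec.motif_length + 1))
        seq[pos:pos + spec.motif_length] = motifs[protein_blocks[j]]
        proteins.append(ProteinRecord(f"P{j:04d}", "".join(seq)))

    prob = np.where(active[drug_blocks][:, protein_blocks],
                    spec.block_affinity, spec.background_prob)
    hits = rng.random((spec.n_drugs, spec.n_proteins)) < prob
    positives = [InteractionPair(drugs[i].drug_id, proteins[j].protein_id, 1)
                 for i, j in zip(*np.nonzero(hits))]
    base = InteractionDataset(drugs, proteins, positives)
    neg_seed = int(rng.integers(0, 2 ** 31))
    negatives = sample_negatives(base, spec.neg_ratio, neg_seed) if spec.neg_ratio > 0 else []
    dataset = InteractionDataset(drugs, proteins, positives + negatives)
    return SyntheticDTI(dataset=dataset, drug_blocks=drug_blocks,
                        protein_blocks=protein_blocks, active_blocks=active, spec=spec)


def write_block_labels(sim: SyntheticDTI, path):
    """Ground-truth block labels as a side TSV (for tests and inspection)."""
    rows = [("drug", d.drug_id, int(b)) for d, b in zip(sim.dataset.drugs, sim.drug_blocks)]
    rows += [("protein", p.protein_id, int(b))
             for p, b in zip(sim.dataset.proteins, sim.protein_blocks)]
    pd.DataFrame(rows, columns=["entity", "id", "block"]).to_csv(path, sep="\t", index=False)
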
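import numpy as np
import pytest

from dtifuse.data import (DrugRecord, InteractionDataset, InteractionPair,
                          ProteinRecord)


@pytest.fixture
def tiny_dataset() -> InteractionDataset:
    """3 drugs x 2 proteins with 4 labeled pairs."""
    drugs = [DrugRecord("d1", "CCO"), DrugRecord("d2", "c1ccccc1"),
             DrugRecord("d3", "CC(=O)O")]
    proteins = [ProteinRecord("p1", "MKVLITAGPT"), ProteinRecord("p2", "GGWWCHHKKA")]
    pairs = [InteractionPair("d1", "p1", 1), InteractionPair("d2", "p1", 1),
             InteractionPair("d2", "p2", 0), InteractionPair("d3", "p2", 1)]
    return InteractionDataset(drugs, proteins, pairs)


@pytest.fixture
def grid_dataset() -> InteractionDataset:
    """10 drugs x 10 proteins, 20 positives; room for negative sampling."""
    rng = np.random.default_rng(42)
    drugs = [DrugRecord(f"d{i}", "CCO") for i in range(10)]
    proteins = [ProteinRecord(f"p{j}", "MKVLITAGPT") for j in range(10)]
    cells = rng.choice(100, size=20, replace=False)
    pairs = [InteractionPair(f"d{c // 10}", f"p{c % 10}", 1) for c in cells]
    return InteractionDataset(drugs, proteins, pairs)
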
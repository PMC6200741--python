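import numpy as np
import pytest

from pepqsar.io import ANTI, NON_ANTI, LabeledDataset, PeptideRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(sequences_by_class: dict[str, list[str]]) -> LabeledDataset:
    """Build a labeled dataset from {label: [sequences]}."""
    records, labels = [], {}
    for label, seqs in sequences_by_class.items():
        for i, seq in enumerate(seqs):
            pid = f"{label.lower()}_{i}"
            records.append(PeptideRecord(id=pid, sequence=seq))
            labels[pid] = label
    return LabeledDataset(records=records, labels=labels)


@pytest.fixture
def tiny_dataset():
    return make_dataset(
        {
            ANTI: ["ACDEF", "CCSSP", "SPSPC", "TCLSL"],
            NON_ANTI: ["AVDIA", "VVAAD", "IIDAV", "ADAVI"],
        }
    )


def random_sequence(rng, length: int) -> str:
    from pepqsar.io import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
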
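"""Shared fixtures: tiny hand-built datasets and synthetic generators."""

from __future__ import annotations

import numpy as np
import pytest

from ofrbarcode import BarcodeDataset, SequenceRecord, SimSpec, generate_dataset


def make_dataset(spec: dict[str, list[str]], aligned: bool | None = None) -> BarcodeDataset:
    """Build a dataset from {species: [sequence, ...]}."""
    records = [
        SequenceRecord(sp, f"a{i + 1}", seq)
        for sp, seqs in spec.items()
        for i, seq in enumerate(seqs)
    ]
    return BarcodeDataset(records, aligned=aligned)


@pytest.fixture
def two_species_ds() -> BarcodeDataset:
    """Two species, composition-separated, two accessions each."""
    return make_dataset(
        {
            "A": ["A" * 80 + "C" * 20, "A" * 80 + "C" * 20],
            "B": ["A" * 20 + "C" * 80, "A" * 20 + "C" * 80],
        }
    )


@pytest.fixture
def benchmark_ds() -> BarcodeDataset:
    """Default synthetic benchmark: 10 species x 5 accessions, 600 nt."""
    ds, _ = generate_dataset(SimSpec(seed=42))
    return ds


def random_clean_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def naive_kmer_counts(seq: str, k: int) -> dict[str, int]:
    """Independent oracle: enumerate every substring position directly."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) <= set("ACGT"):
            counts[w] = counts.get(w, 0) + 1
    return counts
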
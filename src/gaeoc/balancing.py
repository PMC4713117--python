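"""Class-distribution balancing by majority-class partitioning.

For an imbalanced binary dataset the full minority class is set aside, the
majority class is shuffled (seeded) and split into q near-equal chunks of
roughly minority size, and each chunk is paired with the whole minority
class.  This yields q balanced replicates that together use every majority
sample exactly once.  Already-balanced datasets pass through unchanged as a
single replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import DataError, Dataset


@dataclass
class BalancedSet:
    """The balanced replicates derived from one imbalanced dataset."""

    replicates: list[Dataset]
    source_name: str
    minority_label: int
    n_minority: int
    n_majority: int

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def chunk_count(n_majority: int, n_minority: int) -> int:
    """Number of majority chunks: round(n_majority / n_minority), at least 1.

    Half-up rounding, so a 2.5:1 ratio gives 3 chunks.
    """
    return max(1, int(np.floor(n_majority / n_minority + 0.5)))


def balance_dataset(dataset: Dataset, rng_seed: int) -> BalancedSet:
    """Split an imbalanced binary dataset into balanced replicates.

    Equal class counts skip balancing (one replicate, identical rows).
    Otherwise the majority indices are shuffled with ``rng_seed`` and split
    into :func:`chunk_count` chunks; remainder rows go one-per-chunk, so any
    two chunks differ in size by at most 1.  Within a replicate the original
    row order of the input dataset is preserved.
    """
    if dataset.single_class:
        raise DataError(f"{dataset.name!r} has a single class; cannot balance")
    counts = dataset.class_counts()
    if len(counts) != 2:
        raise DataError("balance_dataset requires exactly two classes")

    (label_a, n_a), (label_b, n_b) = sorted(counts.items(), key=lambda kv: kv[1])
    minority_label, n_minority = label_a, n_a
    majority_label, n_majority = label_b, n_b

    minority_idx = np.flatnonzero(dataset.labels == minority_label)
    majority_idx = np.flatnonzero(dataset.labels == majority_label)

    if n_minority == n_majority:
        return BalancedSet(
            replicates=[dataset.subset(np.arange(dataset.n_samples),
                                       name=f"{dataset.name}#bal0")],
            source_name=dataset.name,
            minority_label=int(minority_label),
            n_minority=n_minority,
            n_majority=n_majority,
        )

    q = chunk_count(n_majority, n_minority)
    rng = np.random.default_rng(rng_seed)
    shuffled = rng.permutation(majority_idx)
    chunks = np.array_split(shuffled, q)

    replicates = []
    for i, chunk in enumerate(chunks):
        rows = np.sort(np.concatenate([minority_idx, chunk]))
        replicates.append(dataset.subset(rows, name=f"{dataset.name}#bal{i}"))
    return BalancedSet(
        replicates=replicates,
        source_name=dataset.name,
        minority_label=int(minority_label),
        n_minority=n_minority,
        n_majority=n_majority,
    )
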
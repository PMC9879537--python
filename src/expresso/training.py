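"""Negative-set sampling and k-fold partitions for re-classification.

The classifier is trained on orthopairs (positive) against random
interspecific pairs (negative, equal size, disjoint from the positives,
drawn without replacement). Training members receive unbiased scores via
out-of-fold re-classification, so the pair sets must also be split into k
stratified folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GenePair, PairSet
from .errors import PartitionError, SamplingError

__all__ = ["FoldPartition", "sample_negative_pairs", "make_fold_partition"]

# below this cross-product size the candidate pool is enumerated exactly;
# above it rejection sampling is used (duplicates/positives re-drawn)
_ENUMERATION_LIMIT = 200_000


def sample_negative_pairs(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    positives: PairSet,
    n: int | None = None,
    seed: int | None = None,
) -> PairSet:
    """Draw ``n`` distinct random interspecific pairs avoiding the positives.

    Sampling is uniform without replacement over the cross product
    ``genes_a x genes_b`` minus the positive set. ``n`` defaults to
    ``len(positives)`` (a balanced negative set).
    """
    genes_a = list(genes_a)
    genes_b = list(genes_b)
    pos = positives.as_set()
    if n is None:
        n = len(positives)
    total = len(genes_a) * len(genes_b)
    n_pos_in_pool = sum(
        1 for p in pos if p.gene_a in set(genes_a) and p.gene_b in set(genes_b)
    )
    pool = total - n_pos_in_pool
    if n > pool:
        raise SamplingError(
            f"requested {n} negative pairs but the candidate pool holds only {pool}"
        )
    rng = np.random.default_rng(seed)
    nb = len(genes_b)
    if total <= _ENUMERATION_LIMIT:
        candidates = [
            GenePair(a, b) for a in genes_a for b in genes_b if GenePair(a, b) not in pos
        ]
        idx = rng.choice(len(candidates), size=n, replace=False)
        chosen = [candidates[i] for i in idx]
    else:
        chosen_set: dict[GenePair, None] = {}
        while len(chosen_set) < n:
            batch = rng.integers(0, total, size=max(2 * (n - len(chosen_set)), 64))
            for code in batch:
                p = GenePair(genes_a[code // nb], genes_b[code % nb])
                if p not in pos and p not in chosen_set:
                    chosen_set[p] = None
                    if len(chosen_set) == n:
                        break
        chosen = list(chosen_set)
    return PairSet(chosen, label="negative")


@dataclass(frozen=True)
class FoldPartition:
    """A stratified partition of the training pairs into ``k`` folds."""

    k: int
    fold_of_pair: dict[GenePair, int]

    def pairs_in_fold(self, fold: int) -> list[GenePair]:
        return [p for p, f in self.fold_of_pair.items() if f == fold]

    def pairs_not_in_fold(self, fold: int) -> list[GenePair]:
        return [p for p, f in self.fold_of_pair.items() if f != fold]

    def to_frame(self, positives: PairSet):
        """Serializable table: gene_a, gene_b, label, fold."""
        import pandas as pd

        pos = positives.as_set()
        rows = [
            (p.gene_a, p.gene_b, "positive" if p in pos else "negative", f)
            for p, f in self.fold_of_pair.items()
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "label", "fold"])

    def write_tsv(self, path, positives: PairSet) -> None:
        self.to_frame(positives).to_csv(path, sep="\t", index=False)


def make_fold_partition(
    positives: PairSet,
    negatives: PairSet,
    k: int = 10,
    seed: int | None = None,
) -> FoldPartition:
    """Random stratified k-fold partition of positives plus negatives.

    Each label class is shuffled and split into folds whose sizes differ by at
    most one, so every training subset keeps the (near-)balanced class ratio.
    """
    if k < 2:
        raise PartitionError(f"fold count must be at least 2, got {k}")
    rng = np.random.default_rng(seed)
    fold_of: dict[GenePair, int] = {}
    for pairset in (positives, negatives):
        members = list(pairset)
        if len(members) < k:
            raise PartitionError(
                f"cannot split {len(members)} {pairset.label} pair(s) into {k} folds"
            )
        order = rng.permutation(len(members))
        for chunk, fold in zip(np.array_split(order, k), range(k)):
            for i in chunk:
                fold_of[members[i]] = fold
    overlap = positives.as_set() & negatives.as_set()
    if overlap:
        raise PartitionError(
            f"positive and negative sets overlap on {len(overlap)} pair(s)"
        )
    return FoldPartition(k=k, fold_of_pair=fold_of)
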
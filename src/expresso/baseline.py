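"""Pseudo-Euclidean distance baseline.

The classical alternative to the classifier: counts are normalized with
median-of-ratios size factors, incremented by 1, and each gene row is divided
by its median over the samples entering the comparison. Samples of the two
species are then either matched directly (label to label) or — where
morphology makes one-to-one matching impossible — grouped, and a group
contributes the squared minimal absolute residual over all its cross-species
label combinations. The distance is the square root of the summed squared
residuals. One biological replicate per sample label is drawn at random, and
the whole calculation is repeated (100 times by default) to expose the
replicate variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMap, GenePair
from .errors import MatchingError, NormalizationError

__all__ = [
    "SampleMatching",
    "DistanceResult",
    "size_factors",
    "normalize_for_distance",
    "pseudo_euclidean",
    "PseudoEuclideanBaseline",
    "read_matching",
    "write_matching",
]


@dataclass(frozen=True)
class SampleMatching:
    """Direct and grouped correspondences between the two species' labels."""

    direct: tuple[tuple[str, str], ...] = ()
    groups: tuple[tuple[frozenset[str], frozenset[str]], ...] = ()

    def __post_init__(self) -> None:
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        for la, lb in self.direct:
            if la in seen_a or lb in seen_b:
                raise MatchingError(f"label reused in matching: {la!r}/{lb!r}")
            seen_a.add(la)
            seen_b.add(lb)
        for ga, gb in self.groups:
            if not ga or not gb:
                raise MatchingError("group match sets must be non-empty")
            if ga & seen_a or gb & seen_b:
                raise MatchingError("label reused across matching entries")
            seen_a |= ga
            seen_b |= gb

    @property
    def labels_a(self) -> set[str]:
        out = {la for la, _ in self.direct}
        for ga, _ in self.groups:
            out |= ga
        return out

    @property
    def labels_b(self) -> set[str]:
        out = {lb for _, lb in self.direct}
        for _, gb in self.groups:
            out |= gb
        return out

    def swapped(self) -> "SampleMatching":
        return SampleMatching(
            direct=tuple((lb, la) for la, lb in self.direct),
            groups=tuple((gb, ga) for ga, gb in self.groups),
        )


@dataclass(frozen=True)
class DistanceResult:
    pair: GenePair
    distances: np.ndarray  # one value per resampling repeat

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def sd(self) -> float:
        return float(np.std(self.distances, ddof=1)) if len(self.distances) > 1 else 0.0


def size_factors(counts) -> np.ndarray:
    """Median-of-ratios (DESeq-style) per-sample size factors.

    ``factor_j = median_i(count_ij / geomean_i)`` over genes whose geometric
    mean across samples is positive (any zero count excludes the gene).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2:
        raise NormalizationError("count matrix must be 2-dimensional")
    eligible = (arr > 0).all(axis=1)
    if not eligible.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; size factors undefined"
        )
    logs = np.log(arr[eligible])
    log_geomean = logs.mean(axis=1)
    return np.exp(np.median(logs - log_geomean[:, None], axis=0))


def normalize_for_distance(
    emap: ExpressionMap,
    factors: Sequence[float] | None = None,
    columns: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Size-factor-normalize, add 1, and median-scale each gene row.

    ``columns`` restricts the matrix to the samples entering the comparison;
    the per-gene median divisor is taken over exactly those samples. After the
    +1 increment every median is >= 1, so the division is always defined.
    """
    counts = emap.data.to_numpy(dtype=float)
    if factors is None:
        factors = size_factors(counts)
    factors = np.asarray(factors, dtype=float)
    if (factors <= 0).any():
        raise NormalizationError("size factors must be positive")
    if factors.shape[0] != counts.shape[1]:
        raise NormalizationError("one size factor per sample column required")
    norm = counts / factors[None, :] + 1.0
    if columns is not None:
        cols = list(columns)
        norm = norm[:, cols]
        colnames = [emap.sample_ids[j] for j in cols]
    else:
        colnames = emap.sample_ids
    norm = norm / np.median(norm, axis=1, keepdims=True)
    return pd.DataFrame(norm, index=emap.gene_ids, columns=colnames)


def _label_replicates(emap: ExpressionMap, labels: Iterable[str]) -> dict[str, list[int]]:
    table = emap.label_columns()
    out = {}
    for lab in labels:
        if lab not in table:
            raise MatchingError(
                f"sample label {lab!r} absent from map {emap.species_id!r}"
            )
        out[lab] = table[lab]
    return out


class PseudoEuclideanBaseline:
    """Fit-once, score-many pseudo-Euclidean distance calculator.

    ``fit`` computes size factors and the normalized matrices restricted to
    the matched samples; ``distances`` evaluates many pairs at once over the
    resampling repeats; ``scores`` returns the negated mean distance so that
    larger is more orthopair-like (comparable to an ES ranking).
    """

    def __init__(
        self, matching: SampleMatching, repeats: int = 100, seed: int | None = None
    ) -> None:
        self.matching = matching
        self.repeats = repeats
        self.seed = seed

    def fit(self, map_a: ExpressionMap, map_b: ExpressionMap) -> "PseudoEuclideanBaseline":
        m = self.matching
        self.reps_a_ = _label_replicates(map_a, m.labels_a)
        self.reps_b_ = _label_replicates(map_b, m.labels_b)
        cols_a = sorted({j for cols in self.reps_a_.values() for j in cols})
        cols_b = sorted({j for cols in self.reps_b_.values() for j in cols})
        self.norm_a_ = normalize_for_distance(
            map_a, size_factors(map_a.data.to_numpy()), columns=cols_a
        )
        self.norm_b_ = normalize_for_distance(
            map_b, size_factors(map_b.data.to_numpy()), columns=cols_b
        )
        self.col_of_a_ = {s: j for j, s in enumerate(self.norm_a_.columns)}
        self.col_of_b_ = {s: j for j, s in enumerate(self.norm_b_.columns)}
        self.sample_ids_a_ = map_a.sample_ids
        self.sample_ids_b_ = map_b.sample_ids
        self.row_of_a_ = {g: i for i, g in enumerate(self.norm_a_.index)}
        self.row_of_b_ = {g: i for i, g in enumerate(self.norm_b_.index)}
        return self

    def _pick_columns(self, rng: np.random.Generator):
        """One replicate column per matched label, per species."""
        pick_a = {
            lab: self.col_of_a_[self.sample_ids_a_[rng.choice(cols)]]
            for lab, cols in self.reps_a_.items()
        }
        pick_b = {
            lab: self.col_of_b_[self.sample_ids_b_[rng.choice(cols)]]
            for lab, cols in self.reps_b_.items()
        }
        return pick_a, pick_b

    def distances(self, pairs: Sequence[GenePair]) -> list[DistanceResult]:
        """Per-pair distances over all resampling repeats (vectorized)."""
        pairs = [GenePair(*p) for p in pairs]
        A = self.norm_a_.to_numpy()
        B = self.norm_b_.to_numpy()
        rows_a = np.array([self.row_of_a_[p.gene_a] for p in pairs])
        rows_b = np.array([self.row_of_b_[p.gene_b] for p in pairs])
        rng = np.random.default_rng(self.seed)
        out = np.empty((len(pairs), self.repeats))
        for r in range(self.repeats):
            pick_a, pick_b = self._pick_columns(rng)
            total = np.zeros(len(pairs))
            for la, lb in self.matching.direct:
                resid = A[rows_a, pick_a[la]] - B[rows_b, pick_b[lb]]
                total += resid**2
            for ga, gb in self.matching.groups:
                ca = [pick_a[l] for l in sorted(ga)]
                cb = [pick_b[l] for l in sorted(gb)]
                # n_pairs x |ga| x |gb| absolute residuals; squared min per group
                diffs = np.abs(
                    A[np.ix_(rows_a, ca)][:, :, None] - B[np.ix_(rows_b, cb)][:, None, :]
                )
                total += diffs.min(axis=(1, 2)) ** 2
            out[:, r] = np.sqrt(total)
        return [DistanceResult(p, out[i].copy()) for i, p in enumerate(pairs)]

    def scores(self, pairs: Sequence[GenePair]) -> dict[GenePair, float]:
        """Negated mean distance per pair (higher = more similar profiles)."""
        return {res.pair: -res.mean for res in self.distances(pairs)}

    def to_frame(self, pairs: Sequence[GenePair]) -> pd.DataFrame:
        rows = [
            (r.pair.gene_a, r.pair.gene_b, r.mean, r.sd, self.repeats)
            for r in self.distances(pairs)
        ]
        return pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "mean_distance", "sd_distance", "repeats"]
        )


def pseudo_euclidean(
    pair: GenePair,
    map_a: ExpressionMap,
    map_b: ExpressionMap,
    matching: SampleMatching,
    repeats: int = 100,
    seed: int | None = None,
) -> DistanceResult:
    """Distance of a single pair (convenience wrapper over the batch scorer)."""
    scorer = PseudoEuclideanBaseline(matching, repeats=repeats, seed=seed)
    scorer.fit(map_a, map_b)
    return scorer.distances([pair])[0]


def read_matching(path) -> SampleMatching:
    """Read a matching TSV: columns type ('direct'/'group'), a_labels, b_labels
    (comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"type", "a_labels", "b_labels"}
    if not required.issubset(df.columns):
        raise MatchingError(f"matching file must have columns {sorted(required)}")
    direct = []
    groups = []
    for _, row in df.iterrows():
        la = [x.strip() for x in str(row["a_labels"]).split(",") if x.strip()]
        lb = [x.strip() for x in str(row["b_labels"]).split(",") if x.strip()]
        if row["type"] == "direct":
            if len(la) != 1 or len(lb) != 1:
                raise MatchingError("direct match must have one label per side")
            direct.append((la[0], lb[0]))
        elif row["type"] == "group":
            groups.append((frozenset(la), frozenset(lb)))
        else:
            raise MatchingError(f"unknown matching type {row['type']!r}")
    return SampleMatching(direct=tuple(direct), groups=tuple(groups))


def write_matching(matching: SampleMatching, path) -> None:
    rows = [("direct", la, lb) for la, lb in matching.direct]
    rows += [
        ("group", ",".join(sorted(ga)), ",".join(sorted(gb)))
        for ga, gb in matching.groups
    ]
    pd.DataFrame(rows, columns=["type", "a_labels", "b_labels"]).to_csv(
        path, sep="\t", index=False
    )
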
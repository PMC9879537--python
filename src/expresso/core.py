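"""Core data model and I/O.

An expression map is the K x m matrix of raw read counts produced by a
transcriptome atlas: K genes, m sample columns, with biological replicates of
one sample label appearing as separate columns (``root.1``, ``root.2``).
Counts are consumed raw throughout the classifier path; normalization happens
only inside the distance baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, GeneLookupError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMap",
    "GenePair",
    "PairSet",
    "OrthoGroup",
    "FeatureVector",
    "read_expression_map",
    "read_orthopairs",
    "write_orthopairs",
    "read_orthogroups",
    "write_orthogroups",
    "build_feature_vector",
    "build_feature_matrix",
]


def _split_replicate(sample_id: str) -> tuple[str, int | None]:
    """Split ``root.2`` into ``("root", 2)``; no integer suffix -> (id, None)."""
    head, dot, tail = sample_id.rpartition(".")
    if dot and tail.isdigit():
        return head, int(tail)
    return sample_id, None


@dataclass
class ExpressionMap:
    """A gene x sample read-count matrix for one species.

    Parameters
    ----------
    species_id:
        Free-text species tag; only used in messages and output files.
    data:
        ``pd.DataFrame`` with gene IDs as index and sample IDs as columns,
        integral non-negative values. Column order is the sample order and is
        preserved by every operation in the package.
    sample_labels:
        Per-column biological sample label (replicates of one label share it).
        Defaults to stripping a trailing ``.<int>`` replicate suffix from each
        sample ID.
    """

    species_id: str
    data: pd.DataFrame
    sample_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID {dup!r} in map {self.species_id!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r} in map {self.species_id!r}")
        if self.data.shape[1] == 0 or self.data.shape[0] == 0:
            raise FormatError(f"empty expression map for {self.species_id!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number) or np.isnan(
            values.astype(float)
        ).any():
            raise FormatError(
                f"non-numeric or missing counts in map {self.species_id!r}"
            )
        if (values < 0).any() or not np.array_equal(values, values.astype(np.int64)):
            bad = self.data.index[
                ((values < 0) | (values != values.astype(np.int64))).any(axis=1)
            ][0]
            raise FormatError(
                f"negative or non-integer count for gene {bad!r} "
                f"in map {self.species_id!r}"
            )
        self.data = self.data.astype(np.int64)
        self.data.index.name = "gene_id"
        if self.sample_labels is None:
            self.sample_labels = [_split_replicate(s)[0] for s in self.data.columns]
        if len(self.sample_labels) != self.data.shape[1]:
            raise FormatError("sample_labels length does not match sample count")
        self._row_index: dict[str, int] = {
            g: i for i, g in enumerate(self.data.index)
        }

    # -- basic accessors ----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._row_index

    def row(self, gene_id: str) -> np.ndarray:
        """Raw count vector of one gene, in native sample order."""
        try:
            i = self._row_index[gene_id]
        except KeyError:
            raise GeneLookupError(
                f"gene {gene_id!r} not found in map of species {self.species_id!r}"
            ) from None
        return self.data.to_numpy()[i]

    def label_columns(self) -> dict[str, list[int]]:
        """Mapping sample label -> column indices of its replicates (ordered)."""
        out: dict[str, list[int]] = {}
        for j, lab in enumerate(self.sample_labels):
            out.setdefault(lab, []).append(j)
        return out

    def subset_samples(self, columns: Sequence[int]) -> "ExpressionMap":
        """New map keeping only the given column indices (gene order kept)."""
        cols = list(columns)
        return ExpressionMap(
            species_id=self.species_id,
            data=self.data.iloc[:, cols].copy(),
            sample_labels=[self.sample_labels[j] for j in cols],
        )

    def write_tsv(self, path) -> None:
        df = self.data.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


class GenePair(NamedTuple):
    """An ordered interspecific gene pair: species-A gene first."""

    gene_a: str
    gene_b: str


@dataclass(frozen=True)
class PairSet:
    """A de-duplicated, order-preserving collection of gene pairs.

    ``label`` records the role of the set: ``"positive"`` (orthopairs),
    ``"negative"`` (random pairs) or ``"query"`` (pairs to be scored).
    """

    pairs: tuple[GenePair, ...]
    label: str = "query"

    def __init__(self, pairs: Iterable[GenePair], label: str = "query") -> None:
        seen: dict[GenePair, None] = {}
        for p in pairs:
            seen.setdefault(GenePair(*p), None)
        object.__setattr__(self, "pairs", tuple(seen))
        object.__setattr__(self, "label", label)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[GenePair]:
        return iter(self.pairs)

    def __contains__(self, pair) -> bool:
        return GenePair(*pair) in set(self.pairs)

    def as_set(self) -> frozenset[GenePair]:
        return frozenset(self.pairs)


@dataclass(frozen=True)
class OrthoGroup:
    """A group of co-orthologs spanning two species."""

    group_id: str
    genes_a: frozenset[str]
    genes_b: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes_a or not self.genes_b:
            raise FormatError(
                f"orthogroup {self.group_id!r} must contain genes of both species"
            )

    @property
    def is_orthopair(self) -> bool:
        return len(self.genes_a) == 1 and len(self.genes_b) == 1

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.genes_a), len(self.genes_b))

    def all_pairs(self) -> list[GenePair]:
        """All interspecific pairs in the group, deterministically ordered."""
        return [
            GenePair(a, b) for a in sorted(self.genes_a) for b in sorted(self.genes_b)
        ]


@dataclass(frozen=True)
class FeatureVector:
    """Concatenated raw-count profile of one interspecific pair (A first)."""

    pair: GenePair
    values: np.ndarray


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_map(path, species_id: str, labels_path=None) -> ExpressionMap:
    """Read a count matrix TSV (header = sample IDs, first column = gene ID).

    ``labels_path`` may point to a two-column sidecar TSV (sample_id,
    sample_label); otherwise labels derive from ``.<replicate>`` suffixes.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty expression map file: {path}") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"empty expression map file: {path}")
    if df.isna().any().any():
        raise FormatError(f"ragged or missing values in expression map: {path}")
    try:
        counts = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from None
    labels = None
    if labels_path is not None:
        side = pd.read_csv(
            labels_path, sep="\t", header=None, names=["sample_id", "sample_label"]
        )
        mapping = dict(zip(side["sample_id"], side["sample_label"]))
        missing = [s for s in counts.columns if s not in mapping]
        if missing:
            raise FormatError(f"sample(s) {missing} missing from label sidecar")
        labels = [mapping[s] for s in counts.columns]
    return ExpressionMap(species_id=species_id, data=counts, sample_labels=labels)


def read_orthopairs(path) -> PairSet:
    """Read a headerless two-column TSV of 1-to-1 orthologs (A gene, B gene)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("orthopair file %s is empty", path)
        return PairSet([], label="positive")
    if df.shape[1] != 2:
        raise FormatError(
            f"orthopair file {path} must have exactly 2 columns, found {df.shape[1]}"
        )
    raw = [GenePair(a, b) for a, b in zip(df[0], df[1])]
    ps = PairSet(raw, label="positive")
    if len(ps) < len(raw):
        logger.warning(
            "collapsed %d duplicate orthopair line(s) in %s", len(raw) - len(ps), path
        )
    return ps


def write_orthopairs(pairs: Iterable[GenePair], path) -> None:
    pd.DataFrame([(p.gene_a, p.gene_b) for p in pairs]).to_csv(
        path, sep="\t", header=False, index=False
    )


def _parse_gene_list(cell: str) -> frozenset[str]:
    if not isinstance(cell, str) or not cell.strip():
        return frozenset()
    return frozenset(g.strip() for g in cell.split(",") if g.strip())


def read_orthogroups(path, species_a: str, species_b: str) -> list[OrthoGroup]:
    """Read orthogroups from a TSV.

    Two dialects are auto-detected by header:

    * wide (OrthoFinder ``Orthogroups.tsv``): group-ID column followed by one
      column per species holding ", "-separated gene lists;
    * long: exactly the columns ``group_id``, ``species``, ``gene``.

    Groups lacking genes of either requested species are dropped (only
    interspecific groups are meaningful downstream).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:3]) == ["group_id", "species", "gene"]:
        groups: list[OrthoGroup] = []
        for gid, sub in df.groupby("group_id", sort=False):
            ga = frozenset(sub.loc[sub["species"] == species_a, "gene"])
            gb = frozenset(sub.loc[sub["species"] == species_b, "gene"])
            if ga and gb:
                groups.append(OrthoGroup(gid, ga, gb))
        return groups
    for col in (species_a, species_b):
        if col not in df.columns:
            raise ConfigurationError(
                f"species column {col!r} not found in {path} "
                f"(columns: {list(df.columns)})"
            )
    id_col = df.columns[0]
    groups = []
    for _, row in df.iterrows():
        ga = _parse_gene_list(row[species_a])
        gb = _parse_gene_list(row[species_b])
        if ga and gb:
            groups.append(OrthoGroup(str(row[id_col]), ga, gb))
    return groups


def write_orthogroups(
    groups: Iterable[OrthoGroup], path, species_a: str, species_b: str
) -> None:
    """Write groups in the wide (OrthoFinder-style) dialect."""
    rows = [
        {
            "Orthogroup": g.group_id,
            species_a: ", ".join(sorted(g.genes_a)),
            species_b: ", ".join(sorted(g.genes_b)),
        }
        for g in groups
    ]
    pd.DataFrame(rows, columns=["Orthogroup", species_a, species_b]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def build_feature_vector(
    pair: GenePair, map_a: ExpressionMap, map_b: ExpressionMap
) -> FeatureVector:
    """Concatenate the raw count rows of a pair, species A first.

    This is the input representation of the classifier: no normalization, no
    replicate averaging — each replicate column is its own feature.
    """
    values = np.concatenate([map_a.row(pair.gene_a), map_b.row(pair.gene_b)])
    return FeatureVector(pair=GenePair(*pair), values=values)


def build_feature_matrix(
    pairs: Sequence[GenePair], map_a: ExpressionMap, map_b: ExpressionMap
) -> np.ndarray:
    """Stacked feature vectors for many pairs (n_pairs x (m_A + m_B)).

    Vectorized equivalent of :func:`build_feature_vector` row by row.
    """
    ia = map_a._row_index
    ib = map_b._row_index
    try:
        rows_a = np.fromiter((ia[p.gene_a] for p in pairs), dtype=np.int64, count=len(pairs))
    except KeyError as exc:
        raise GeneLookupError(
            f"gene {exc.args[0]!r} not found in map of species {map_a.species_id!r}"
        ) from None
    try:
        rows_b = np.fromiter((ib[p.gene_b] for p in pairs), dtype=np.int64, count=len(pairs))
    except KeyError as exc:
        raise GeneLookupError(
            f"gene {exc.args[0]!r} not found in map of species {map_b.species_id!r}"
        ) from None
    A = map_a.data.to_numpy()
    B = map_b.data.to_numpy()
    return np.hstack([A[rows_a], B[rows_b]]).astype(np.float32)
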
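"""Classifier evaluation, breadth stratification, sample downsampling, and
the global-alignment identity utility.

AUC follows the Mann-Whitney formulation: the probability that a random
positive outscores a random negative, ties counted one half. Sensitivity is
TP/(TP+FN) and specificity TN/(TN+FP) at the score threshold, with a pair
predicted positive only when its score is strictly above the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .core import ExpressionMap
from .errors import EvaluationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "AlignmentResult",
    "roc_auc",
    "precision_recall",
    "sensitivity_specificity",
    "expression_breadth",
    "stratify_by_breadth",
    "downsample_by_clustering",
    "nw_identity",
    "read_fasta",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise EvaluationError("both classes must be present to evaluate a classifier")


def roc_auc(scores, labels):
    """AUC plus ROC curve points (fpr, tpr, thresholds)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return auc, fpr, tpr, thresholds


def precision_recall(scores, labels):
    """Average precision plus PR curve points (precision, recall, thresholds)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    ap = float(average_precision_score(labels, scores))
    return ap, precision, recall, thresholds


def sensitivity_specificity(scores, labels, threshold: float = 0.5):
    """Sensitivity and specificity under the strict score > threshold rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    counts = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return sensitivity, specificity, counts


# ---------------------------------------------------------------------------
# expression breadth
# ---------------------------------------------------------------------------

def expression_breadth(profile, min_fraction_of_max: float = 0.1) -> float:
    """Fraction of samples expressing the gene at >= a fraction of its max.

    Broadly expressed genes approach 1, tissue-specific genes approach
    1/n_samples. All-zero profiles are unclassifiable and return NaN.
    """
    profile = np.asarray(profile, dtype=float)
    if (profile < 0).any():
        raise EvaluationError("expression profile must be non-negative")
    m = profile.max()
    if m == 0:
        logger.warning("all-zero profile is unclassifiable for breadth")
        return float("nan")
    return float(np.mean(profile >= min_fraction_of_max * m))


def stratify_by_breadth(
    emap: ExpressionMap,
    min_fraction_of_max: float = 0.1,
    breadth_cutoff: float | None = None,
) -> tuple[dict[str, float], set[str], set[str]]:
    """Per-gene breadth plus broad/narrow gene sets.

    The split defaults to the median breadth across classifiable genes.
    """
    counts = emap.data.to_numpy()
    breadths = {}
    for g, row in zip(emap.gene_ids, counts):
        b = (
            float(np.mean(row >= min_fraction_of_max * row.max()))
            if row.max() > 0
            else float("nan")
        )
        breadths[g] = b
    values = np.array([b for b in breadths.values() if not np.isnan(b)])
    if len(values) == 0:
        raise EvaluationError("no classifiable genes for breadth stratification")
    cutoff = float(np.median(values)) if breadth_cutoff is None else breadth_cutoff
    broad = {g for g, b in breadths.items() if not np.isnan(b) and b >= cutoff}
    narrow = {g for g, b in breadths.items() if not np.isnan(b) and b < cutoff}
    return breadths, broad, narrow


# ---------------------------------------------------------------------------
# downsampling by sample clustering
# ---------------------------------------------------------------------------

def downsample_by_clustering(
    emap: ExpressionMap,
    cut_height: float,
    seed: int | None = None,
    exclude_labels: set[str] | None = None,
) -> ExpressionMap:
    """Reduce a map by clustering samples and keeping one random sample per
    cluster.

    Samples are clustered hierarchically (average linkage) under the distance
    1 - Pearson correlation of their count profiles; the tree is cut at
    ``cut_height`` and one uniformly random sample column per flat cluster is
    retained. Constant columns have undefined correlation; their distance to
    everything is set to 1. Gene order is preserved.
    """
    if not (0 < cut_height < 2):
        raise EvaluationError(f"cut_height must lie in (0, 2), got {cut_height}")
    cols = list(range(emap.n_samples))
    if exclude_labels:
        cols = [j for j in cols if emap.sample_labels[j] not in exclude_labels]
        if not cols:
            raise EvaluationError("excluding those labels removes every sample")
    sub = emap.subset_samples(cols)
    if sub.n_samples < 2:
        return sub
    X = sub.data.to_numpy().astype(float).T  # samples x genes
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    dist = 1.0 - corr
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant sample column(s): correlation distance set to 1",
            int(constant.sum()),
        )
        dist[constant, :] = 1.0
        dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    flat = fcluster(Z, t=cut_height, criterion="distance")
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cluster in np.unique(flat):
        members = np.flatnonzero(flat == cluster)
        keep.append(int(rng.choice(members)))
    keep.sort()
    return sub.subset_samples(keep)


# ---------------------------------------------------------------------------
# sequence identity (global alignment)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentResult:
    aligned_length: int
    identical_positions: int
    identity: float
    score: float

    def __post_init__(self) -> None:
        if self.identical_positions > self.aligned_length:
            raise ValueError("identical positions exceed alignment length")


def nw_identity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> AlignmentResult:
    """Global (Needleman-Wunsch) alignment identity under affine gap costs.

    ``gap_open`` is the score of the first residue of a gap and ``gap_extend``
    of each further residue. Identity = identical aligned positions divided by
    the alignment length, gapped columns included in the denominator.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if not seq_a or not seq_b:
        raise EvaluationError("sequences must be non-empty")
    subst = substitution_matrices.load(matrix)
    alphabet = set(str(subst.alphabet))
    for name, seq in (("first", seq_a), ("second", seq_b)):
        bad = set(seq.upper()) - alphabet
        if bad:
            raise EvaluationError(
                f"invalid residue(s) {sorted(bad)} in {name} sequence"
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = subst
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return AlignmentResult(
        aligned_length=len(row_a),
        identical_positions=identical,
        identity=identical / len(row_a),
        score=float(aln.score),
    )


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {record id: sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def out_of_fold_auc(es_table, positives) -> float:
    """AUC of final (median) out-of-fold scores against training labels.

    ``positives`` is the positive PairSet; every other pair in the table with
    out-of-fold provenance is a sampled negative. This is the pipeline-level
    summary of how well training pairs are re-classified.
    """
    pos = positives.as_set()
    frame = es_table.frame
    mask = frame["provenance"] == "out_of_fold"
    scores = frame.loc[mask, "final_es"].to_numpy()
    labels = [1 if p in pos else 0 for p in frame.index[mask]]
    return roc_auc(scores, labels)[0]


def evaluation_report(scores, labels, threshold: float = 0.5) -> pd.DataFrame:
    """One-row summary: AUC, average precision, sensitivity, specificity."""
    auc, *_ = roc_auc(scores, labels)
    ap, *_ = precision_recall(scores, labels)
    sens, spec, counts = sensitivity_specificity(scores, labels, threshold)
    return pd.DataFrame(
        [
            {
                "auc": auc,
                "average_precision": ap,
                "sensitivity": sens,
                "specificity": spec,
                "threshold": threshold,
                "TP": counts.TP,
                "FP": counts.FP,
                "TN": counts.TN,
                "FN": counts.FN,
            }
        ]
    )
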
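"""Evaluation against a truth set: enrichment, ranks, confusion labels, ROC.

The ROC here is prefix-based: the classifier "predict the top k genes" is
swept over k = 0..k_max, with TPR(k) = TP/|truth| and FPR(k) = FP/(N-|truth|)
computed per prefix. The partial AUC is the raw trapezoidal area under that
curve, unnormalized — over 2e4 genes with k_max = 1000 the FPR range is only
~0.045, so realistic values are a few hundredths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deg_ranking import GeneRanking

__all__ = [
    "TruthSet",
    "EvaluationReport",
    "enrichment_score",
    "rank_of_true_degs",
    "confusion_labels",
    "roc_curve",
    "partial_auc",
    "topk_true_positives",
    "evaluate_ranking",
    "DEFAULT_TOPK",
]

#: the conventional top-K grid for prediction-budget comparisons
DEFAULT_TOPK: tuple[int, ...] = (150, 250, 350, 450, 550)


@dataclass(frozen=True)
class TruthSet:
    """Identifiers of experimentally verified true DEGs (e.g. by RT-PCR)."""

    deg_ids: frozenset[str]

    def __init__(self, deg_ids) -> None:
        object.__setattr__(self, "deg_ids", frozenset(deg_ids))

    def __len__(self) -> int:
        return len(self.deg_ids)

    def member_mask(self, gene_ids: list[str]) -> np.ndarray:
        """Boolean mask over ``gene_ids``; every truth id must be present."""
        present = set(gene_ids)
        unknown = self.deg_ids - present
        if unknown:
            raise ValueError(
                f"truth ids not found in the gene list: {sorted(unknown)[:5]}"
                + ("..." if len(unknown) > 5 else "")
            )
        return np.fromiter((g in self.deg_ids for g in gene_ids), bool, len(gene_ids))


def _truth_mask(ranking: GeneRanking, truth: TruthSet) -> np.ndarray:
    if ranking.gene_ids is None:
        raise ValueError("ranking carries no gene identifiers")
    if len(truth) == 0:
        raise ValueError("truth set is empty")
    return truth.member_mask(ranking.gene_ids)


def enrichment_score(n_true_in_list: int, list_size: int) -> float:
    """Fraction of true DEGs in a gene list."""
    if list_size < 1:
        raise ValueError("list_size must be >= 1")
    if not 0 <= n_true_in_list <= list_size:
        raise ValueError(
            f"n_true_in_list={n_true_in_list} outside 0..{list_size}"
        )
    return n_true_in_list / list_size


def rank_of_true_degs(ranking: GeneRanking, truth: TruthSet) -> dict[str, int]:
    """1-based rank of every true DEG in the ranking's order.

    With an exclude-mode ranking, truth genes dropped by pruning have no
    rank and are omitted from the result.
    """
    mask = _truth_mask(ranking, truth)
    out: dict[str, int] = {}
    for pos, idx in enumerate(ranking.order, start=1):
        if mask[idx]:
            out[ranking.gene_ids[idx]] = pos
    return out


def confusion_labels(ranking: GeneRanking, truth: TruthSet, k: int) -> np.ndarray:
    """Per-gene label in {TP, FP, TN, FN} at prediction cutoff ``k``.

    Top-k truth genes are TP, top-k non-truth FP; below the cutoff truth
    genes are FN and the rest TN. Returned in input gene order.
    """
    n = ranking.n_genes
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    mask = _truth_mask(ranking, truth)
    predicted = np.zeros(n, dtype=bool)
    predicted[ranking.order[:k]] = True
    labels = np.where(
        predicted,
        np.where(mask, "TP", "FP"),
        np.where(mask, "FN", "TN"),
    )
    return labels


def roc_curve(ranking: GeneRanking, truth: TruthSet, k_max: int = 1000) -> np.ndarray:
    """(FPR, TPR) at every prefix k = 0..min(k_max, length of the order).

    Returns an array of shape (k+1, 2) starting at (0, 0); both coordinates
    are non-decreasing in k.
    """
    mask = _truth_mask(ranking, truth)
    n_true = int(mask.sum())
    n_false = ranking.n_genes - n_true
    if n_true == 0 or n_false == 0:
        raise ValueError("need at least one truth gene and one non-truth gene")
    kmax = min(k_max, len(ranking.order))
    hits = mask[ranking.order[:kmax]]
    tp = np.concatenate([[0], np.cumsum(hits)])
    ks = np.arange(kmax + 1)
    fp = ks - tp
    return np.column_stack([fp / n_false, tp / n_true])


def partial_auc(roc_points: np.ndarray) -> float:
    """Trapezoidal area under TPR as a function of FPR; unnormalized."""
    pts = np.asarray(roc_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need >= 2 (FPR, TPR) points")
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def topk_true_positives(
    ranking: GeneRanking, truth: TruthSet, ks=DEFAULT_TOPK
) -> dict[int, int]:
    """Number of true DEGs within each top-K prefix."""
    mask = _truth_mask(ranking, truth)
    out: dict[int, int] = {}
    for k in ks:
        if not 1 <= k <= ranking.n_genes:
            raise ValueError(f"K={k} outside 1..{ranking.n_genes}")
        out[int(k)] = int(mask[ranking.order[: min(k, len(ranking.order))]].sum())
    return out


@dataclass
class EvaluationReport:
    """Bundle of the standard metrics for one ranking against one truth set."""

    method: str
    roc_points: np.ndarray
    partial_auc: float
    topk_counts: dict[int, int]
    true_deg_ranks: dict[str, int]
    enrichment_before: float | None = None
    enrichment_after: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def fold_enrichment(self) -> float | None:
        if not self.enrichment_before or self.enrichment_after is None:
            return None
        return self.enrichment_after / self.enrichment_before


def evaluate_ranking(
    ranking: GeneRanking,
    truth: TruthSet,
    k_max: int = 1000,
    ks=DEFAULT_TOPK,
) -> EvaluationReport:
    """Compute ROC, partial AUC, top-K counts and true-DEG ranks in one go."""
    roc = roc_curve(ranking, truth, k_max=k_max)
    report = EvaluationReport(
        method=ranking.method,
        roc_points=roc,
        partial_auc=partial_auc(roc),
        topk_counts=topk_true_positives(ranking, truth, ks=ks),
        true_deg_ranks=rank_of_true_degs(ranking, truth),
    )
    if ranking.pruning is not None:
        mask = _truth_mask(ranking, truth)
        kept = ranking.pruning.survivor_mask
        report.enrichment_before = enrichment_score(int(mask.sum()), ranking.n_genes)
        n_kept = int(kept.sum())
        if n_kept:
            report.enrichment_after = enrichment_score(
                int((mask & kept).sum()), n_kept
            )
    return report
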
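"""The four gene-ranking statistics evaluated with and without pruning.

Every scorer returns one real score per gene, higher = more DEG-like, in
matrix row order. Ranking is a stable descending sort (ties broken by input
row order, for determinism). When a pruning result is supplied, the default
"append" mode ranks survivors first and pruned genes after — both sorted by
score — so a top-K prefix is defined for any K, and a kept gene's rank can
only improve relative to the unpruned ranking.

Scorers:

* fold change — on log-scale data, simply AD = |mean_A - mean_B|.
* t statistic — pooled-variance two-sample |t| with a small variance floor
  so zero-variance genes get a finite (large) score; Welch behind a flag.
* rank product — geometric mean, over all P1 x P2 ordered sample pairs, of
  the gene's per-pair fold-change rank, done separately for up- and
  down-regulation and combined by the better (smaller) of the two.
* WAD — AD weighted by min–max-normalized AG, upranking highly expressed
  genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .db_pruning import PruningResult

__all__ = [
    "GeneRanking",
    "score_fold_change",
    "score_ttest",
    "score_rank_product",
    "score_wad",
    "rank_genes",
    "SCORERS",
]


@dataclass
class GeneRanking:
    """A total (or survivor-only) order over genes.

    ``scores`` stays in input gene order; ``order`` lists gene indices from
    most to least DEG-like. With pruning in "exclude" mode, ``order`` covers
    survivors only.
    """

    method: str
    scores: np.ndarray
    order: np.ndarray
    gene_ids: list[str] | None = None
    pruning: PruningResult | None = None
    mode: str | None = None

    @property
    def n_genes(self) -> int:
        return len(self.scores)

    def top_k_indices(self, k: int) -> np.ndarray:
        return self.order[:k]

    def ranked_gene_ids(self) -> list[str]:
        if self.gene_ids is None:
            raise ValueError("ranking carries no gene identifiers")
        return [self.gene_ids[i] for i in self.order]


def score_fold_change(features) -> np.ndarray:
    """Absolute log fold change: on log-scale input this is exactly AD."""
    return features.ad.copy()


def score_ttest(
    matrix,
    features=None,
    variance_floor: float = 1e-8,
    welch: bool = False,
) -> np.ndarray:
    """Absolute two-sample t statistic per gene.

    Pooled-variance Student's t by default; ``welch=True`` uses per-condition
    variances. ``variance_floor`` is added inside the denominator's square
    root so genes with zero measured variance get a finite, very large score
    instead of infinity. Both conditions need >= 2 samples.
    """
    if variance_floor <= 0:
        raise ValueError("variance_floor must be positive")
    from .features import compute_features

    if features is None:
        features = compute_features(matrix)
    p1 = len(matrix.condition_columns("A"))
    p2 = len(matrix.condition_columns("B"))
    if p1 < 2 or p2 < 2:
        raise ValueError(
            "the t statistic needs >= 2 samples per condition; "
            "use fold change or rank product for smaller designs"
        )
    diff = np.abs(features.mean_a - features.mean_b)
    if welch:
        se2 = features.var_a / p1 + features.var_b / p2
    else:
        sp2 = ((p1 - 1) * features.var_a + (p2 - 1) * features.var_b) / (p1 + p2 - 2)
        se2 = sp2 * (1.0 / p1 + 1.0 / p2)
    return diff / np.sqrt(se2 + variance_floor)


def score_rank_product(matrix) -> np.ndarray:
    """Rank-product score over all ordered (A-sample, B-sample) pairs.

    For each pair, genes are ranked by the pairwise log difference B - A,
    once descending (rank 1 = most up-regulated) and once ascending (rank 1 =
    most down-regulated), with average ranks on ties. RP_up / RP_down are the
    geometric means of those ranks across pairs, and the score is
    -log(min(RP_up, RP_down)): 0 for a gene ranked first in every pair in
    either direction, more negative for core genes. Only the ranking is
    produced; the permutation-based significance of the original rank-product
    method is out of scope.
    """
    cols_a = matrix.condition_columns("A")
    cols_b = matrix.condition_columns("B")
    n = matrix.n_genes
    log_up = np.zeros(n)
    log_down = np.zeros(n)
    n_pairs = 0
    for a in cols_a:
        for b in cols_b:
            diff = matrix.values[:, b] - matrix.values[:, a]
            log_up += np.log(rankdata(-diff, method="average"))
            log_down += np.log(rankdata(diff, method="average"))
            n_pairs += 1
    mean_log_up = log_up / n_pairs
    mean_log_down = log_down / n_pairs
    # -log(min(RP_up, RP_down)) == -min(mean log rank up, mean log rank down)
    return -np.minimum(mean_log_up, mean_log_down)


def score_wad(features) -> np.ndarray:
    """Weighted average difference: AD times a min–max-normalized AG weight.

    The most-expressed gene gets weight 1 (score = its AD), the least gets 0.
    A constant-AG input degenerates to weight 1 everywhere (plain fold
    change).
    """
    ag = features.ag
    lo, hi = ag.min(), ag.max()
    if hi == lo:
        w = np.ones_like(ag)
    else:
        w = (ag - lo) / (hi - lo)
    return features.ad * w


def rank_genes(
    scores: np.ndarray,
    pruning: PruningResult | None = None,
    mode: str = "append",
    gene_ids: list[str] | None = None,
    method: str = "custom",
) -> GeneRanking:
    """Build a :class:`GeneRanking` from per-gene scores.

    Without pruning: stable descending sort. With pruning, mode ``append``
    (default) puts score-sorted survivors ahead of score-sorted pruned genes;
    mode ``exclude`` drops pruned genes from the order entirely.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if gene_ids is not None and len(gene_ids) != len(scores):
        raise ValueError("gene_ids length does not match scores")
    base = np.argsort(-scores, kind="stable")
    if pruning is None:
        order = base
    else:
        if len(pruning.survivor_mask) != len(scores):
            raise ValueError("pruning result does not match score vector length")
        kept_sorted = base[pruning.survivor_mask[base]]
        if mode == "append":
            order = np.concatenate([kept_sorted, base[~pruning.survivor_mask[base]]])
        elif mode == "exclude":
            order = kept_sorted
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return GeneRanking(
        method=method,
        scores=scores,
        order=order,
        gene_ids=gene_ids,
        pruning=pruning,
        mode=None if pruning is None else mode,
    )


def _fc(matrix, features):
    return score_fold_change(features)


def _rp(matrix, features):
    return score_rank_product(matrix)


def _ttest(matrix, features):
    return score_ttest(matrix, features)


def _wad(matrix, features):
    return score_wad(features)


#: method name -> scorer(matrix, features) for pipeline code
SCORERS = {"fc": _fc, "rp": _rp, "ttest": _ttest, "wad": _wad}
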
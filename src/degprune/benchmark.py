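"""End-to-end benchmark: each ranking method with and without pruning.

Mirrors the standard with/without comparison: one pruning pass (fixed r0 or
a radius search toward a target survivor count), then for every requested
method a pair of rankings and their evaluation reports. The JSON-able
summary keeps floats at 6 significant digits so repeated runs diff cleanly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .db_pruning import PruningParams, prune, search_radius
from .deg_ranking import SCORERS, rank_genes
from .evaluation import DEFAULT_TOPK, TruthSet, evaluate_ranking
from .features import compute_features

__all__ = ["BenchmarkConfig", "run_benchmark"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class BenchmarkConfig:
    methods: tuple[str, ...] = ("fc", "rp", "ttest", "wad")
    n0: int = 4
    r0: float | None = None  # fixed radius; otherwise search toward target_k
    target_k: int = 2000
    k_max: int = 1000
    ks: tuple[int, ...] = DEFAULT_TOPK
    mode: str = "append"
    rescale_features: bool = False

    def validate(self) -> None:
        unknown = [m for m in self.methods if m not in SCORERS]
        if unknown:
            raise ValueError(f"unknown method(s) {unknown}; choose from {sorted(SCORERS)}")
        if self.r0 is None and self.target_k < 1:
            raise ValueError("target_k must be >= 1")


def _round6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    return x


def run_benchmark(matrix, truth: TruthSet, config: BenchmarkConfig | None = None) -> dict:
    """Run pruning + every method with/without it; return a JSON-able report."""
    config = config or BenchmarkConfig()
    config.validate()
    features = compute_features(matrix)
    pruning_space = features.rescaled() if config.rescale_features else features

    if config.r0 is not None:
        r0 = config.r0
        pruning = prune(pruning_space, PruningParams(r0, config.n0))
    else:
        r0, pruning = search_radius(pruning_space, config.n0, config.target_k)

    truth_mask = truth.member_mask(matrix.gene_ids)
    n_true = int(truth_mask.sum())
    kept_true = int((truth_mask & pruning.survivor_mask).sum())
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "n_genes": matrix.n_genes,
        "n_samples_a": len(matrix.condition_columns("A")),
        "n_samples_b": len(matrix.condition_columns("B")),
        "n_true_degs": n_true,
        "pruning": {
            "r0": r0,
            "n0": config.n0,
            "mode": config.mode,
            "n_survivors": pruning.n_survivors,
            "n_pruned": pruning.n_pruned,
            "true_degs_kept": kept_true,
            "enrichment_before": n_true / matrix.n_genes,
            "enrichment_after": (
                kept_true / pruning.n_survivors if pruning.n_survivors else None
            ),
        },
        "methods": {},
    }
    before = report["pruning"]["enrichment_before"]
    after = report["pruning"]["enrichment_after"]
    report["pruning"]["fold_enrichment"] = (
        after / before if (after is not None and before > 0) else None
    )

    p1, p2 = report["n_samples_a"], report["n_samples_b"]
    for method in config.methods:
        if method == "ttest" and (p1 < 2 or p2 < 2):
            log.warning(
                "skipping t-test: %dx%d samples (need >= 2 per condition)", p1, p2
            )
            continue
        scores = SCORERS[method](matrix, features)
        entry = {}
        for label, prn in (("unpruned", None), ("pruned", pruning)):
            ranking = rank_genes(
                scores,
                pruning=prn,
                mode=config.mode,
                gene_ids=matrix.gene_ids,
                method=method,
            )
            ev = evaluate_ranking(ranking, truth, k_max=config.k_max, ks=config.ks)
            entry[label] = {
                "partial_auc": ev.partial_auc,
                "topk_true_positives": {str(k): v for k, v in ev.topk_counts.items()},
            }
        base_auc = entry["unpruned"]["partial_auc"]
        entry["partial_auc_improvement_pct"] = (
            100.0 * (entry["pruned"]["partial_auc"] - base_auc) / base_auc
            if base_auc > 0
            else None
        )
        report["methods"][method] = entry
    return _round6(report)
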
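"""Per-gene (AG, AD) features: the 2-D space shared by pruning and ranking.

For a gene with per-condition mean log expressions X^A and X^B:

    AG = (X^A + X^B) / 2        average expression level
    AD = |X^A - X^B|            average difference

Because the input is log-scale, AD is the absolute log fold change. True
differentially expressed genes tend to sit in the sparse high-AG/high-AD
boundary of this space, which is what density-based pruning exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["GeneFeatures", "compute_features"]


@dataclass
class GeneFeatures:
    """Per-gene feature records, in matrix row order.

    ``var_a``/``var_b`` hold unbiased (ddof=1) sample variances per condition;
    a condition with a single sample gets NaN as an "undefined" marker. They
    are carried for the t statistic and are not part of the pruning space.
    """

    gene_ids: list[str]
    mean_a: np.ndarray
    mean_b: np.ndarray
    ag: np.ndarray
    ad: np.ndarray
    var_a: np.ndarray
    var_b: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("mean_a", "mean_b", "ag", "ad", "var_a", "var_b"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)
        if not (
            np.all(np.isfinite(self.ag))
            and np.all(np.isfinite(self.ad))
            and np.all(self.ad >= 0)
        ):
            raise ValueError("ag/ad must be finite and ad non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def points(self) -> np.ndarray:
        """(N, 2) array of (AG, AD) coordinates."""
        return np.column_stack([self.ag, self.ad])

    def rescaled(self) -> "GeneFeatures":
        """Min–max rescale both axes to [0, 1] (a constant axis maps to 0).

        Off the default path: pruning distances are normally taken in raw log
        units, where "max radius = max AD" is meaningful. Rescaling is offered
        because the usable radius scale otherwise depends on the dataset.
        """

        def mm(x: np.ndarray) -> np.ndarray:
            lo, hi = x.min(), x.max()
            if hi == lo:
                return np.zeros_like(x)
            return (x - lo) / (hi - lo)

        return replace(self, ag=mm(self.ag), ad=mm(self.ad))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "mean_a": self.mean_a,
                "mean_b": self.mean_b,
                "ag": self.ag,
                "ad": self.ad,
                "var_a": self.var_a,
                "var_b": self.var_b,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def compute_features(matrix) -> GeneFeatures:
    """Map each gene of a designed, log-scale matrix to its feature record."""
    if matrix.design is None:
        raise ValueError("matrix has no group design attached")
    if not matrix.log_scale:
        raise ValueError("features require log-scale values; apply log_transform first")
    cols_a = matrix.condition_columns("A")
    cols_b = matrix.condition_columns("B")
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError("both conditions need at least one sample")
    va = matrix.values[:, cols_a]
    vb = matrix.values[:, cols_b]
    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    # ddof=1 is undefined for a single replicate; NaN marks it explicitly.
    var_a = va.var(axis=1, ddof=1) if len(cols_a) > 1 else np.full(matrix.n_genes, np.nan)
    var_b = vb.var(axis=1, ddof=1) if len(cols_b) > 1 else np.full(matrix.n_genes, np.nan)
    ag = (mean_a + mean_b) / 2.0
    ad = np.abs(mean_a - mean_b)
    return GeneFeatures(list(matrix.gene_ids), mean_a, mean_b, ag, ad, var_a, var_b)
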
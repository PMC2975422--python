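"""Synthetic two-condition expression data with known true DEGs.

The generator emulates the structure driving density-based pruning: in the
(AG, AD) plane, equally-expressed genes form a dense core hugging AD ~ 0
across the expression range, while true DEGs sit in the sparse boundary —
biased toward high expression and carrying a real between-condition shift.

Model (all in log2 units):

* non-DEG gene i: baseline mu_i ~ Normal(baseline_mean, baseline_sd^2);
  every sample value = mu_i + Normal(0, noise_sd^2).
* DEG gene i: baseline additionally shifted up by ``deg_level_shift``
  (except a ``hard_deg_fraction`` of "hard" DEGs left at the core's
  expression level, emulating the minority of true DEGs buried in the dense
  region); condition B additionally shifted by delta_i = s_i * U(effect_min,
  effect_max) with sign s_i uniform on {-1, +1} — truth sets contain both
  directions.

Everything is deterministic for a fixed seed. The defaults (10000 genes, 100
DEGs, 10 samples per condition, baseline 7 +/- 1.5, replicate noise 0.3,
level shift 1.5, effect 1-3) give a desk-scale dataset with the qualitative
geometry of real microarray series; no probe-level or array-effect structure
is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression_data import ExpressionMatrix, GroupDesign
from .evaluation import TruthSet

__all__ = ["SimulationConfig", "simulate"]


@dataclass
class SimulationConfig:
    n_genes: int = 10000
    n_deg: int = 100
    n_a: int = 10
    n_b: int = 10
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.3
    deg_level_shift: float = 1.5
    effect_min: float = 1.0
    effect_max: float = 3.0
    hard_deg_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.n_deg <= self.n_genes:
            raise ValueError("n_deg must be in 0..n_genes")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("need at least one sample per condition")
        if self.n_a + self.n_b < 2:
            raise ValueError("need at least two samples in total")
        if self.baseline_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("sd parameters must be positive")
        if self.effect_min > self.effect_max:
            raise ValueError("effect_min must be <= effect_max")
        if not 0 <= self.hard_deg_fraction <= 1:
            raise ValueError("hard_deg_fraction must be in [0, 1]")


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, TruthSet]:
    """Draw one (matrix, truth set) pair from the generative model above."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_genes, config.n_a + config.n_b

    width = len(str(n))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n)]
    sample_ids = [f"A{i + 1:02d}" for i in range(config.n_a)] + [
        f"B{i + 1:02d}" for i in range(config.n_b)
    ]
    assignment = {s: ("A" if s.startswith("A") else "B") for s in sample_ids}

    deg_idx = rng.choice(n, size=config.n_deg, replace=False)
    n_hard = int(round(config.hard_deg_fraction * config.n_deg))
    shifted_idx = deg_idx[n_hard:]  # deg_idx is already in random order

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    mu[shifted_idx] += config.deg_level_shift

    values = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(n, p))
    if config.n_deg:
        sign = rng.choice([-1.0, 1.0], size=config.n_deg)
        delta = sign * rng.uniform(config.effect_min, config.effect_max, config.n_deg)
        values[deg_idx, config.n_a :] += delta[:, None]

    matrix = ExpressionMatrix(
        gene_ids,
        sample_ids,
        values,
        design=GroupDesign(assignment, label_names={"A": "control", "B": "treated"}),
        log_scale=True,
    )
    truth = TruthSet(gene_ids[i] for i in deg_idx)
    return matrix, truth
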
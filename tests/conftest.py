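import numpy as np
import pytest

from degprune import (
    ExpressionMatrix,
    GeneFeatures,
    GroupDesign,
    SimulationConfig,
    simulate,
)


def features_from_points(ag, ad, gene_ids=None):
    """Build GeneFeatures directly from (AG, AD) coordinates.

    Means are reconstructed so the AG/AD identities hold exactly:
    mean_a = ag + ad/2, mean_b = ag - ad/2.
    """
    ag = np.asarray(ag, dtype=float)
    ad = np.asarray(ad, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(ag))]
    nan = np.full(len(ag), np.nan)
    return GeneFeatures(gene_ids, ag + ad / 2, ag - ad / 2, ag, ad, nan, nan)


def brute_force_neighbor_counts(points, r0):
    """Independent O(N^2) neighbor counter: strict d^2 < r0^2, self excluded."""
    pts = np.asarray(points, dtype=float)
    dx = pts[:, 0][:, None] - pts[:, 0][None, :]
    dy = pts[:, 1][:, None] - pts[:, 1][None, :]
    within = (dx * dx + dy * dy) < r0 * r0
    np.fill_diagonal(within, False)
    return within.sum(axis=1)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples (2 A + 2 B), log2 scale."""
    design = GroupDesign({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    values = np.array(
        [
            [2.0, 2.0, 4.0, 4.0],
            [5.0, 5.0, 5.0, 5.0],
            [1.0, 3.0, 6.0, 8.0],
        ]
    )
    return ExpressionMatrix(["g1", "g2", "g3"], ["a1", "a2", "b1", "b2"], values, design)


@pytest.fixture(scope="session")
def small_simulation():
    """2000-gene simulation shared by tests that just need realistic structure."""
    return simulate(SimulationConfig(n_genes=2000, n_deg=40, seed=7))
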
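"""Shared fixtures: generated reference panels and a crosstalk-free signature.

The "crossfree" fixtures carry zero off-type marker expression with equal
per-type totals, so every engine recovers mixing proportions exactly; they
anchor the oracle-equivalence and exact-recovery tests.  The "noisy" panel
uses the generator defaults (20x marker fold change, log-normal sigma 0.2),
the realistic regime for accuracy benchmarks.
"""

import numpy as np
import pandas as pd
import pytest

from cortexmix.containers import MarkerPanel
from cortexmix.synthetic import (
    SyntheticConfig,
    marker_panel_from_config,
    reference_panel_from_profiles,
    simulate_reference_profiles,
)

CELL_TYPES = ("neuron", "astrocyte", "oligodendrocyte", "microglia")


@pytest.fixture(scope="session")
def noisy_config():
    return SyntheticConfig(noise_sigma=0.2, n_replicates=3, seed=7)


@pytest.fixture(scope="session")
def noisy_panel(noisy_config):
    expr, labels = simulate_reference_profiles(noisy_config)
    return reference_panel_from_profiles(expr, labels)


@pytest.fixture(scope="session")
def noisy_markers(noisy_config):
    return marker_panel_from_config(noisy_config)


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticConfig(noise_sigma=0.0, n_replicates=2, seed=1)


@pytest.fixture(scope="session")
def noiseless_panel(noiseless_config):
    expr, labels = simulate_reference_profiles(noiseless_config)
    return reference_panel_from_profiles(expr, labels)


@pytest.fixture(scope="session")
def crossfree():
    """Zero-crosstalk signature, panel, and exactly mixed bulk samples."""
    rng = np.random.default_rng(0)
    markers = MarkerPanel(
        {ct: tuple(f"{ct[:3].upper()}{i:02d}" for i in range(12)) for ct in CELL_TYPES}
    )
    genes = list(markers.genes)
    S = np.zeros((len(genes), len(CELL_TYPES)))
    for k, ct in enumerate(CELL_TYPES):
        S[12 * k : 12 * (k + 1), k] = rng.uniform(5, 50, 12)
    S = S / S.sum(axis=0) * 1000.0  # equal per-type totals
    signature = pd.DataFrame(S, index=genes, columns=list(CELL_TYPES))
    expr = pd.DataFrame(
        {f"{ct}_{r}": signature[ct] for ct in CELL_TYPES for r in (1, 2)}
    )
    labels = pd.Series({c: c.rsplit("_", 1)[0] for c in expr.columns})
    panel = reference_panel_from_profiles(expr, labels)
    truth = np.vstack(
        [
            np.eye(4),
            [[0.5, 0.5, 0.0, 0.0],
             [0.1, 0.3, 0.55, 0.05],
             [0.25, 0.25, 0.25, 0.25],
             [0.02, 0.76, 0.17, 0.05]],
        ]
    )
    bulk = pd.DataFrame(
        S @ truth.T, index=genes, columns=[f"mix{i}" for i in range(len(truth))]
    )
    truth_df = pd.DataFrame(truth, index=bulk.columns, columns=list(CELL_TYPES))
    return {
        "markers": markers,
        "signature": signature,
        "panel": panel,
        "bulk": bulk,
        "truth": truth_df,
    }


def simplex_grid(step: float = 0.01) -> np.ndarray:
    """All 4-simplex grid points at the given resolution (brute-force oracle support)."""
    n = int(round(1 / step))
    pts = []
    for a in range(n + 1):
        for b in range(n + 1 - a):
            for c in range(n + 1 - a - b):
                pts.append((a, b, c, n - a - b - c))
    return np.asarray(pts, dtype=float) / n


def grid_least_squares_oracle(bulk: pd.DataFrame, signature: pd.DataFrame, step: float = 0.01):
    """Exhaustive simplex-grid least squares: argmin_p ||v - S p|| per sample.

    Independent of every engine: normalizes columns the same TPM-like way and
    scans the full grid.
    """
    S = signature.to_numpy(dtype=float)
    S = S / S.sum(axis=0)
    V = bulk.loc[signature.index].to_numpy(dtype=float)
    V = V / V.sum(axis=0)
    grid = simplex_grid(step)
    quad = np.einsum("ij,jk,ik->i", grid, S.T @ S, grid)
    out = np.empty((V.shape[1], S.shape[1]))
    for j in range(V.shape[1]):
        score = quad - 2 * (grid @ (S.T @ V[:, j]))
        out[j] = grid[np.argmin(score)]
    return pd.DataFrame(out, index=bulk.columns, columns=signature.columns)
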
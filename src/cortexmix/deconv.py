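"""Cell-type proportion estimation from bulk expression.

Three engines share one interface:

``ssnmf``
    Semi-supervised non-negative matrix factorization.  The marker-row bulk
    matrix ``V`` (markers x samples) is factorized as ``V ~ W H`` under the
    Frobenius loss with Lee-Seung multiplicative updates.  The semi-supervised
    constraint ties each basis column to a named cell type: for a marker of
    type *k*, the entries of its row of ``W`` in columns other than *k* are
    held at exactly zero throughout.  ``W`` is initialized from the reference
    panel's per-type marker means and ``H`` uniformly; the output proportions
    are the columns of ``H`` renormalized to the simplex.

``dsa``
    Digital-sorting linear estimation.  Uses only marker identities: the
    per-sample mean expression of each type's markers ``M`` is modeled as
    ``M[j, k] = s_k * p[j, k]`` with a shared per-type scale ``s_k``; the
    scales are recovered from the sum-to-one constraint by non-negative least
    squares of ``M x = 1`` and the proportions are ``M * x`` renormalized.

``mean_profile``
    Marker-mean profile estimation (population-specific expression analysis
    style).  Each marker row is scaled to unit maximum across samples to
    balance magnitudes; a sample's estimate for a type is the mean of that
    type's scaled markers, renormalized per sample.  The result is a
    *relative* abundance index, not an absolute mRNA proportion.

All engines first rescale each bulk sample to a common total over the marker
rows in use (TPM-style within-sample normalization), which makes the
estimates invariant to arbitrary per-sample scale factors.  Estimates are
relative mRNA fractions; no cell-size or mRNA-content correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import MarkerPanel, ReferencePanel, check_expression
from .exceptions import ConfigurationError, DataError

__all__ = [
    "DeconvolutionResult",
    "ssnmf_deconvolve",
    "dsa_deconvolve",
    "mean_profile_deconvolve",
    "deconvolve",
    "ENGINES",
]

_EPS = 1e-12


@dataclass
class DeconvolutionResult:
    """Uniform result contract for all engines.

    ``proportions`` is samples x cell types on the simplex.  ``signature`` is
    the fitted marker-by-type basis (ssNMF only).  ``objective_trace`` holds
    the per-iteration Frobenius residual for iterative engines and is
    non-increasing for multiplicative updates.
    """

    proportions: pd.DataFrame
    engine: str
    signature: pd.DataFrame | None = None
    objective_trace: "list[float]" = field(default_factory=list)
    iterations: int = 0
    converged: bool = True
    relative_index: bool = False


def _marker_layout(bulk: pd.DataFrame, markers: MarkerPanel):
    """Intersect the marker panel with the bulk genes.

    Returns (ordered gene list, {cell_type: slice into that list}).  Raises
    if any cell type has no marker present in the bulk matrix.
    """
    present = set(bulk.index)
    genes: list = []
    slices: dict = {}
    for ct in markers.cell_types:
        hit = [g for g in markers.assignments[ct] if g in present]
        if not hit:
            raise DataError(f"cell type {ct!r} has no marker present in the bulk matrix")
        slices[ct] = slice(len(genes), len(genes) + len(hit))
        genes.extend(hit)
    return genes, slices


def _normalized_marker_matrix(bulk: pd.DataFrame, genes: Sequence[str]) -> np.ndarray:
    """Marker-row bulk with each sample scaled to unit total over the markers."""
    V = bulk.loc[list(genes)].to_numpy(dtype=float)
    if (V < 0).any():
        raise DataError("bulk expression contains negative values")
    totals = V.sum(axis=0)
    zero = totals <= 0
    if zero.any():
        bad = [bulk.columns[i] for i in np.argwhere(zero).ravel()]
        raise DataError(f"samples with zero total marker expression: {bad[:5]}")
    return V / totals


def _ssnmf_core(
    V: np.ndarray,
    W0: np.ndarray,
    mask: np.ndarray,
    max_iter: int,
    tol: float,
    H0: np.ndarray | None = None,
):
    """Multiplicative-update ssNMF on dense arrays.

    ``mask`` is True where W entries are allowed to be nonzero (the
    own-type block); off-mask entries are held at zero after every update.
    """
    W = np.where(mask, W0, 0.0)
    # scale-free basis: unit column sums keep W and the normalized V on the
    # same footing so the _EPS regularizer is inert
    W = W / (W.sum(axis=0, keepdims=True) + _EPS)
    n_types, n_samples = W.shape[1], V.shape[1]
    H = np.full((n_types, n_samples), 1.0 / n_types) if H0 is None else H0.copy()
    norm_v = float(np.linalg.norm(V))
    trace = []
    prev = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        W[~mask] = 0.0
        obj = float(np.linalg.norm(V - W @ H))
        trace.append(obj)
        if prev is not None and (
            abs(prev - obj) <= tol * max(prev, _EPS) or obj <= 1e-10 * norm_v
        ):
            converged = True
            break
        prev = obj
    return W, H, trace, it, converged


def ssnmf_deconvolve(
    bulk: pd.DataFrame,
    panel: ReferencePanel,
    markers: MarkerPanel,
    *,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int | None = None,
    n_restarts: int = 0,
) -> DeconvolutionResult:
    """Marker-constrained semi-supervised NMF deconvolution.

    ``seed``/``n_restarts`` enable optional random restarts of ``H``; the
    default initialization (panel-derived ``W``, uniform ``H``) is
    deterministic, so restarts are off unless requested.
    """
    check_expression(bulk, "bulk")
    genes, slices = _marker_layout(bulk, markers)
    missing_in_panel = [ct for ct in markers.cell_types
                        if not any(g in panel.expression.index for g in markers.assignments[ct])]
    if missing_in_panel:
        raise DataError(f"cell types with no marker in the reference panel: {missing_in_panel}")
    genes = [g for g in genes if g in panel.expression.index]
    if not genes:
        raise DataError("no shared marker genes between bulk and reference panel")
    genes, slices = _marker_layout(bulk.loc[genes], markers)

    V = _normalized_marker_matrix(bulk, genes)
    cell_types = list(markers.cell_types)
    mask = np.zeros((len(genes), len(cell_types)), dtype=bool)
    for k, ct in enumerate(cell_types):
        mask[slices[ct], k] = True
    W0 = panel.type_means(genes)[cell_types].to_numpy(dtype=float)

    best = None
    inits = [None] + list(range(n_restarts))
    rng = np.random.default_rng(seed)
    for init in inits:
        W, H, trace, iters, converged = _ssnmf_core(V, W0, mask, max_iter, tol)
        if init is not None:
            # seeded random restart: perturb the H start (kept for robustness studies)
            Hr = rng.uniform(0.5, 1.5, size=H.shape) / len(cell_types)
            W, H, trace, iters, converged = _ssnmf_core(V, W0, mask, max_iter, tol, H0=Hr)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace, iters, converged)
    W, H, trace, iters, converged = best

    props = (H / (H.sum(axis=0) + _EPS)).T
    proportions = pd.DataFrame(props, index=bulk.columns, columns=cell_types)
    signature = pd.DataFrame(W, index=genes, columns=cell_types)
    return DeconvolutionResult(
        proportions=proportions,
        engine="ssnmf",
        signature=signature,
        objective_trace=trace,
        iterations=iters,
        converged=converged,
    )


def dsa_deconvolve(bulk: pd.DataFrame, markers: MarkerPanel) -> DeconvolutionResult:
    """Digital-sorting linear estimation from marker means alone."""
    check_expression(bulk, "bulk")
    genes, slices = _marker_layout(bulk, markers)
    V = _normalized_marker_matrix(bulk, genes)
    cell_types = list(markers.cell_types)
    M = np.column_stack([V[slices[ct]].mean(axis=0) for ct in cell_types])  # samples x K
    if np.linalg.matrix_rank(M) < len(cell_types):
        raise DataError(
            "marker-mean matrix is rank-deficient across samples; "
            "add samples with more varied composition or more specific markers"
        )
    x, _ = nnls(M, np.ones(M.shape[0]))
    P = M * x
    sums = P.sum(axis=1)
    if (sums <= 0).any():
        bad = [bulk.columns[i] for i in np.argwhere(sums <= 0).ravel()]
        raise DataError(f"degenerate digital-sorting solution for samples {bad[:5]}")
    P = P / sums[:, None]
    return DeconvolutionResult(
        proportions=pd.DataFrame(P, index=bulk.columns, columns=cell_types),
        engine="dsa",
    )


def mean_profile_deconvolve(bulk: pd.DataFrame, markers: MarkerPanel) -> DeconvolutionResult:
    """Marker-mean relative abundance index (scaled-profile averaging)."""
    check_expression(bulk, "bulk")
    genes, slices = _marker_layout(bulk, markers)
    V = _normalized_marker_matrix(bulk, genes)
    cell_types = list(markers.cell_types)

    row_max = V.max(axis=1)
    dead = row_max <= 0
    if dead.any():
        dropped = [genes[i] for i in np.argwhere(dead).ravel()]
        warnings.warn(f"markers with zero expression in all samples dropped: {dropped[:10]}")
        live_markers = markers.restrict_to([g for g, d in zip(genes, dead) if not d])
        return mean_profile_deconvolve(bulk, live_markers)

    scaled = V / row_max[:, None]
    est = np.column_stack([scaled[slices[ct]].mean(axis=0) for ct in cell_types])
    sums = est.sum(axis=1)
    est = np.where(sums[:, None] > 0, est / np.where(sums[:, None] > 0, sums[:, None], 1.0), 1.0 / len(cell_types))
    return DeconvolutionResult(
        proportions=pd.DataFrame(est, index=bulk.columns, columns=cell_types),
        engine="mean_profile",
        relative_index=True,
    )


ENGINES: "dict[str, Callable]" = {
    "ssnmf": ssnmf_deconvolve,
    "dsa": dsa_deconvolve,
    "mean_profile": mean_profile_deconvolve,
}


def deconvolve(
    bulk: pd.DataFrame,
    panel: ReferencePanel | None = None,
    markers: MarkerPanel | None = None,
    engine: "str | Callable" = "ssnmf",
    **opts,
) -> DeconvolutionResult:
    """Dispatch to one of the three engines (or a user-supplied callable).

    A callable engine receives ``(bulk, panel, markers)`` and must return a
    :class:`DeconvolutionResult` or a proportions DataFrame.
    """
    if callable(engine):
        out = engine(bulk, panel, markers)
        if isinstance(out, DeconvolutionResult):
            return out
        return DeconvolutionResult(proportions=out, engine=getattr(engine, "__name__", "custom"))
    if markers is None:
        raise ConfigurationError("a marker panel is required")
    if engine == "ssnmf":
        if panel is None:
            raise ConfigurationError("the ssnmf engine requires a reference panel")
        return ssnmf_deconvolve(bulk, panel, markers, **opts)
    if engine == "dsa":
        return dsa_deconvolve(bulk, markers, **opts)
    if engine == "mean_profile":
        return mean_profile_deconvolve(bulk, markers, **opts)
    raise ConfigurationError(
        f"unknown engine {engine!r}; valid engines: {sorted(ENGINES)}"
    )
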
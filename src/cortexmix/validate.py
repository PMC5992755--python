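"""Accuracy and robustness harness for the deconvolution engines.

The harness mirrors the validation design used for brain reference panels:
chimeric admixtures are assembled at known proportions from purified donor
samples (by pooling reads, or directly in expression space as a fast proxy),
deconvolved with a reference panel from which the contributing donors are
held out, and scored with the root-mean-square error

    RMSE = sqrt( sum_i (yhat_i - y_i)^2 / n )

pooled over every compared proportion entry.  Two further checks probe the
panel itself: leave-one-out cross-validation of the purified samples
(self-type recovery) and single-gene dropout (sensitivity of the estimates
to any one marker).

The default design follows the published chimeric grid: 32 proportion
distributions inside per-type ranges (neurons 2-36% of reads, astrocytes
22-76%, oligodendrocytes 6-62%, microglia 1-5%), repeated 720 times while
rotating donors, with 400,000 reads per library.  Exact distribution vectors
can be supplied as a file; otherwise a seeded low-discrepancy draw inside
the ranges is used and flagged as generated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from ._rng import child_rng
from .containers import MarkerPanel, ReferencePanel
from .deconv import (
    DeconvolutionResult,
    _marker_layout,
    _normalized_marker_matrix,
    _ssnmf_core,
    deconvolve,
    dsa_deconvolve,
    mean_profile_deconvolve,
)
from .exceptions import ConfigurationError, DataError

__all__ = [
    "PAPER_RANGES",
    "ChimericDesign",
    "EvaluationResult",
    "LoocvResult",
    "rmse",
    "allocate_reads",
    "build_chimeric_design",
    "pool_chimeric_library",
    "run_chimeric_validation",
    "gene_dropout_robustness",
    "loocv_accuracy",
]

#: Published per-type read-contribution ranges for the chimeric grid.
PAPER_RANGES: "dict[str, tuple[float, float]]" = {
    "neuron": (0.02, 0.36),
    "astrocyte": (0.22, 0.76),
    "oligodendrocyte": (0.06, 0.62),
    "microglia": (0.01, 0.05),
}


def rmse(estimated: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Root-mean-square error over all compared proportion entries."""
    if isinstance(estimated, pd.DataFrame) and isinstance(truth, pd.DataFrame):
        if list(estimated.columns) != list(truth.columns) or list(estimated.index) != list(truth.index):
            if set(estimated.columns) == set(truth.columns) and set(estimated.index) == set(truth.index):
                truth = truth.loc[estimated.index, estimated.columns]
            else:
                raise DataError("estimated and truth matrices have mismatched labels")
        a, b = estimated.to_numpy(dtype=float), truth.to_numpy(dtype=float)
    else:
        a, b = np.asarray(estimated, dtype=float), np.asarray(truth, dtype=float)
        if a.shape != b.shape:
            raise DataError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def allocate_reads(proportions: np.ndarray, total_reads: int) -> np.ndarray:
    """Largest-remainder integer allocation: counts sum exactly to ``total_reads``."""
    p = np.asarray(proportions, dtype=float)
    if total_reads < 1:
        raise ConfigurationError("total_reads must be >= 1")
    raw = p * total_reads
    base = np.floor(raw).astype(int)
    short = total_reads - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


@dataclass(frozen=True)
class ChimericDesign:
    """Grid of known admixture proportions plus the repeat plan."""

    distributions: np.ndarray  # n_distributions x n_cell_types
    cell_types: tuple
    repeats: int
    total_reads: int
    ranges: Mapping[str, tuple]
    seed: int = 0
    source: str = "generated"

    def __post_init__(self):
        dist = np.asarray(self.distributions, dtype=float)
        object.__setattr__(self, "distributions", dist)
        if dist.ndim != 2 or dist.shape[1] != len(self.cell_types):
            raise ConfigurationError("distributions must be n x n_cell_types")
        if dist.shape[0] < 1 or self.repeats < 1:
            raise ConfigurationError("need at least one distribution and one repeat")
        sums = dist.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            i = int(np.argmax(np.abs(sums - 1.0)))
            raise ConfigurationError(f"distribution {i} sums to {sums[i]:.12f}, not 1")
        for k, ct in enumerate(self.cell_types):
            lo, hi = self.ranges[ct]
            bad = (dist[:, k] < lo - 1e-12) | (dist[:, k] > hi + 1e-12)
            if bad.any():
                i = int(np.argmax(bad))
                raise ConfigurationError(
                    f"distribution {i}: {ct} proportion {dist[i, k]:.4f} outside [{lo}, {hi}]"
                )

    @property
    def n_distributions(self) -> int:
        return int(self.distributions.shape[0])

    @property
    def n_tasks(self) -> int:
        return self.n_distributions * self.repeats


def build_chimeric_design(
    ranges: Mapping[str, tuple] | None = None,
    n_distributions: int = 32,
    repeats: int = 720,
    total_reads: int = 400_000,
    seed: int = 0,
    vectors: "np.ndarray | pd.DataFrame | None" = None,
) -> ChimericDesign:
    """Build the admixture design.

    If ``vectors`` is supplied (one row per distribution, columns in
    cell-type order) the vectors are validated against the ranges and used
    verbatim.  Otherwise ``n_distributions`` vectors are drawn with a seeded
    Halton low-discrepancy sequence inside the ranges, renormalized to the
    simplex and re-checked against the ranges.
    """
    ranges = dict(PAPER_RANGES if ranges is None else ranges)
    cell_types = tuple(ranges)
    lo = np.array([ranges[ct][0] for ct in cell_types])
    hi = np.array([ranges[ct][1] for ct in cell_types])
    if lo.sum() > 1 + 1e-12 or hi.sum() < 1 - 1e-12:
        raise ConfigurationError(
            f"infeasible ranges: sum of minima {lo.sum():.3f} must be <= 1 <= sum of maxima {hi.sum():.3f}"
        )
    if vectors is not None:
        if isinstance(vectors, pd.DataFrame):
            vectors = vectors[list(cell_types)].to_numpy(dtype=float)
        return ChimericDesign(
            distributions=np.asarray(vectors, dtype=float),
            cell_types=cell_types,
            repeats=repeats,
            total_reads=total_reads,
            ranges=ranges,
            seed=seed,
            source="supplied",
        )
    sampler = qmc.Halton(d=len(cell_types), seed=int(seed) & 0x7FFFFFFF)
    kept: list = []
    guard = 0
    while len(kept) < n_distributions:
        u = sampler.random(128)
        cand = lo + u * (hi - lo)
        cand = cand / cand.sum(axis=1, keepdims=True)
        ok = np.all((cand >= lo - 1e-12) & (cand <= hi + 1e-12), axis=1)
        kept.extend(cand[ok])
        guard += 1
        if guard > 1000:
            raise ConfigurationError("could not draw feasible distributions inside the ranges")
    dist = np.array(kept[:n_distributions])
    return ChimericDesign(
        distributions=dist,
        cell_types=cell_types,
        repeats=repeats,
        total_reads=total_reads,
        ranges=ranges,
        seed=seed,
        source="generated",
    )


def pool_chimeric_library(
    donors: "Mapping[str, pd.Series] | Mapping[str, np.ndarray]",
    proportions: "Mapping[str, float] | Sequence[float]",
    total_reads: int = 400_000,
    mode: str = "expression",
    seed: int = 0,
) -> tuple:
    """Build one chimeric sample at known proportions.

    ``donors`` maps cell type to either an expression profile
    (:class:`pandas.Series`, ``mode="expression"``) or a read pool (array of
    gene tags, ``mode="reads"``).  Returns ``(sample, truth)`` where
    ``sample`` is a gene-indexed Series (expression column, or read counts in
    read mode) and ``truth`` the known proportion vector as a Series.

    Read mode allocates per-type read counts by largest-remainder rounding so
    they sum exactly to ``total_reads``, then samples reads without
    replacement from each donor pool (with replacement if the pool is
    smaller, with a warning).
    """
    cell_types = list(donors)
    p = (
        np.array([proportions[ct] for ct in cell_types], dtype=float)
        if isinstance(proportions, Mapping)
        else np.asarray(proportions, dtype=float)
    )
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ConfigurationError("proportions must lie on the simplex")
    truth = pd.Series(p, index=cell_types, name="truth")

    if mode == "expression":
        profiles = pd.DataFrame({ct: donors[ct] for ct in cell_types})
        sample = profiles.to_numpy() @ p
        return pd.Series(sample, index=profiles.index, name="chimeric"), truth
    if mode != "reads":
        raise ConfigurationError(f"unknown mode {mode!r}; use 'expression' or 'reads'")

    counts = allocate_reads(p, total_reads)
    rng = child_rng(seed, "chimeric-reads")
    reads = []
    for ct, k in zip(cell_types, counts):
        pool = np.asarray(donors[ct])
        if pool.size == 0:
            raise DataError(f"missing donor read pool for cell type {ct!r}")
        if k == 0:
            continue
        if k <= pool.size:
            reads.append(rng.choice(pool, size=k, replace=False))
        else:
            warnings.warn(
                f"{ct}: donor pool ({pool.size} reads) smaller than allocation ({k}); "
                "sampling with replacement"
            )
            reads.append(rng.choice(pool, size=k, replace=True))
    reads = np.concatenate(reads)
    sample = pd.Series(reads).value_counts().sort_index()
    sample.name = "chimeric"
    return sample, truth


@dataclass
class EvaluationResult:
    """Pooled accuracy of a validation run."""

    estimated: pd.DataFrame
    truth: pd.DataFrame
    rmse: float
    per_task: pd.Series
    n: int = 0

    def __post_init__(self):
        if self.n == 0:
            self.n = int(self.estimated.size)


def _donor_rotation(panel: ReferencePanel, cell_types, seed: int):
    """Seeded donor permutation per type; task (r, d) uses perm[(r + d) % n]."""
    donors = {}
    for ct in cell_types:
        samples = panel.samples_of(ct)
        if not samples:
            raise DataError(f"no reference donors for cell type {ct!r}")
        rng = child_rng(seed, "donor-rotation", ct)
        donors[ct] = tuple(np.array(samples)[rng.permutation(len(samples))])
    return donors


def run_chimeric_validation(
    panel: ReferencePanel,
    markers: MarkerPanel,
    design: ChimericDesign,
    engine: "str | Callable" = "ssnmf",
    holdout: bool = True,
    mode: str = "expression",
    seed: int = 0,
    read_pools: "Mapping[str, np.ndarray] | None" = None,
) -> EvaluationResult:
    """Run the full admixture benchmark and score it with the pooled RMSE.

    For each task (repeat r, distribution d) one donor per cell type is
    chosen by deterministic rotation of a seeded permutation; a chimeric
    sample is assembled at the design proportions and deconvolved with a
    reference panel that, when ``holdout`` is set, excludes every
    contributing donor.
    """
    cell_types = list(design.cell_types)
    for ct in cell_types:
        n_donors = len(panel.samples_of(ct))
        if n_donors == 0:
            raise DataError(f"no reference donors for cell type {ct!r}")
        if holdout and n_donors < 2:
            raise DataError(
                f"holdout requires >= 2 donors per type; {ct!r} has {n_donors}"
            )
    donors = _donor_rotation(panel, cell_types, seed)

    genes, slices = _marker_layout(panel.expression, markers)
    mask = np.zeros((len(genes), len(cell_types)), dtype=bool)
    for k, ct in enumerate(cell_types):
        mask[slices[ct], k] = True
    expr = panel.expression.loc[genes]

    # cache type-mean signatures per excluded-donor combination
    w_cache: dict = {}

    def signature_for(excluded: tuple) -> np.ndarray:
        if excluded not in w_cache:
            cols = []
            for ct in cell_types:
                keep = [s for s in panel.samples_of(ct) if s not in excluded]
                cols.append(expr[keep].to_numpy().mean(axis=1))
            w_cache[excluded] = np.column_stack(cols)
        return w_cache[excluded]

    # assemble every task column first, then fit
    n_tasks = design.n_tasks
    V = np.empty((len(genes), n_tasks))
    truths = np.empty((n_tasks, len(cell_types)))
    task_ids = []
    exclusions: list = []
    i = 0
    for r in range(design.repeats):
        for d in range(design.n_distributions):
            p = design.distributions[d]
            chosen = {ct: donors[ct][(r + d) % len(donors[ct])] for ct in cell_types}
            if mode == "expression":
                V[:, i] = expr[[chosen[ct] for ct in cell_types]].to_numpy() @ p
            else:
                if read_pools is None:
                    raise ConfigurationError("read mode requires read_pools")
                sample, _ = pool_chimeric_library(
                    {ct: read_pools[chosen[ct]] for ct in cell_types},
                    p,
                    total_reads=design.total_reads,
                    mode="reads",
                    seed=(seed * 100_003 + i) & 0x7FFFFFFF,
                )
                V[:, i] = sample.reindex(genes).fillna(0.0).to_numpy(dtype=float)
            truths[i] = p
            exclusions.append(tuple(sorted(chosen.values())) if holdout else ())
            task_ids.append(f"rep{r + 1:03d}_dist{d + 1:02d}")
            i += 1

    estimates = np.empty((n_tasks, len(cell_types)))
    if engine == "ssnmf":
        for i in range(n_tasks):
            estimates[i] = _fast_ssnmf_column(V[:, i], signature_for(exclusions[i]), mask)
    elif engine in ("dsa", "mean_profile"):
        # these engines need several samples per fit; group tasks that share
        # a hold-out combination and fit each group jointly
        fit = dsa_deconvolve if engine == "dsa" else mean_profile_deconvolve
        groups: dict = {}
        for i, excl in enumerate(exclusions):
            groups.setdefault(excl, []).append(i)
        for excl, idx in groups.items():
            bulk = pd.DataFrame(V[:, idx], index=genes, columns=[task_ids[i] for i in idx])
            res = fit(bulk, markers)
            estimates[idx] = res.proportions[cell_types].to_numpy()
    else:
        for i in range(n_tasks):
            bulk = pd.DataFrame({task_ids[i]: V[:, i]}, index=genes)
            sub = panel.drop_samples(exclusions[i]) if exclusions[i] else panel
            res = deconvolve(bulk, sub, markers, engine=engine)
            estimates[i] = res.proportions.loc[task_ids[i], cell_types].to_numpy()

    est_df = pd.DataFrame(estimates, index=task_ids, columns=cell_types)
    tru_df = pd.DataFrame(truths, index=task_ids, columns=cell_types)
    per_task = pd.Series(
        np.sqrt(((estimates - truths) ** 2).mean(axis=1)), index=task_ids, name="rmse"
    )
    return EvaluationResult(
        estimated=est_df, truth=tru_df, rmse=rmse(est_df, tru_df), per_task=per_task
    )


def _fast_ssnmf_column(v, W0, mask) -> np.ndarray:
    """ssNMF core on a single pre-extracted marker-row column."""
    total = v.sum()
    if total <= 0:
        raise DataError("chimeric sample has zero total marker expression")
    v = (v / total)[:, None]
    _, H, _, _, _ = _ssnmf_core(v, W0, mask, max_iter=2000, tol=1e-6)
    h = H[:, 0]
    return h / h.sum()


def gene_dropout_robustness(
    panel: ReferencePanel,
    markers: MarkerPanel,
    design: ChimericDesign,
    engine: str = "ssnmf",
    mode: str = "expression",
    seed: int = 0,
) -> tuple:
    """Sensitivity of the chimeric estimates to any single marker gene.

    For each marker gene the whole validation is re-run with that gene
    removed, and the RMSE between the full-panel and dropped-gene proportion
    estimates is recorded.  Genes that are the sole marker of their type are
    skipped with a warning.  Returns ``(per_gene, summary)`` where
    ``per_gene`` is a Series of RMSE deltas and ``summary`` a dict with the
    mean and sd.
    """
    full = run_chimeric_validation(panel, markers, design, engine=engine, mode=mode, seed=seed)
    deltas = {}
    for ct in markers.cell_types:
        genes = [g for g in markers.assignments[ct] if g in panel.expression.index]
        if len(genes) < 2:
            warnings.warn(
                f"cell type {ct!r} has a single marker; dropout of {genes} skipped"
            )
            continue
        for gene in genes:
            reduced = markers.drop_gene(gene)
            res = run_chimeric_validation(
                panel, reduced, design, engine=engine, mode=mode, seed=seed
            )
            deltas[gene] = rmse(res.estimated, full.estimated)
    per_gene = pd.Series(deltas, name="rmse_delta")
    summary = {
        "mean": float(per_gene.mean()),
        "sd": float(per_gene.std(ddof=1)) if len(per_gene) > 1 else 0.0,
        "n_genes": int(len(per_gene)),
    }
    return per_gene, summary


@dataclass
class LoocvResult:
    """Leave-one-out self-recovery of the purified reference samples."""

    proportions: pd.DataFrame  # sample x cell type, each row from its own held-out fit
    self_proportions: pd.Series
    mean_accuracy: float
    sd_accuracy: float
    rmse_one_hot: float


def loocv_accuracy(
    panel: ReferencePanel, markers: MarkerPanel, engine: "str | Callable" = "ssnmf"
) -> LoocvResult:
    """One LOOCV pass: deconvolve each held-out purified sample as a bulk.

    Returns each sample's predicted proportion for its labeled type, the
    mean/sd across samples, and the RMSE of the predicted vectors against
    one-hot label vectors.
    """
    for ct in set(panel.labels.values()):
        if len(panel.samples_of(ct)) < 2:
            raise DataError(
                f"LOOCV needs >= 2 samples per cell type; {ct!r} has {len(panel.samples_of(ct))}"
            )
    cell_types = list(markers.cell_types)
    rows = []
    self_props = {}
    # hold-out order is sample-ID lexicographic for reproducibility
    for sample in sorted(panel.sample_ids):
        training = panel.drop_samples([sample])
        bulk = panel.expression[[sample]]
        res = deconvolve(bulk, training, markers, engine=engine)
        props = res.proportions.loc[sample, cell_types]
        rows.append(props.to_numpy(dtype=float))
        self_props[sample] = float(props[panel.labels[sample]])
    ordered = sorted(panel.sample_ids)
    proportions = pd.DataFrame(rows, index=ordered, columns=cell_types)
    one_hot = pd.DataFrame(
        [[1.0 if ct == panel.labels[s] else 0.0 for ct in cell_types] for s in ordered],
        index=ordered,
        columns=cell_types,
    )
    self_series = pd.Series(self_props, name="self_proportion").loc[ordered]
    return LoocvResult(
        proportions=proportions,
        self_proportions=self_series,
        mean_accuracy=float(self_series.mean()),
        sd_accuracy=float(self_series.std(ddof=1)),
        rmse_one_hot=rmse(proportions, one_hot),
    )
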
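"""Synthetic data with the statistical structure the deconvolution pipeline assumes.

The generator emulates the three kinds of input the analysis needs:

* purified cell-type reference profiles (brain cell types: neurons,
  astrocytes, oligodendrocytes, microglia) in which each marker gene is
  over-expressed by a configurable fold in its own cell type and sits at a
  baseline everywhere else, under multiplicative log-normal sample noise;
* read-level pools per sample, drawn multinomially from the sample's
  expression profile, for read-mode admixture experiments;
* case/control bulk cohorts whose true underlying cell proportions shift
  with disease status by configurable effect sizes, together with the true
  proportions (for recovery testing) and a metadata table with technical
  covariates (RIN, PMI, age at death, batch).

All randomness flows through one integer seed fanned out per stage (see
:mod:`cortexmix._rng`), so identical configurations reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .containers import MarkerPanel, ReferencePanel
from .exceptions import ConfigurationError, DataError

__all__ = [
    "BRAIN_CELL_TYPES",
    "SyntheticConfig",
    "SyntheticCohortSpec",
    "simulate_reference_profiles",
    "simulate_read_pools",
    "simulate_bulk_cohort",
    "reference_panel_from_profiles",
    "marker_panel_from_config",
]

BRAIN_CELL_TYPES = ("neuron", "astrocyte", "oligodendrocyte", "microglia")

#: Control-group mean proportions used by default for cohort simulation.
#: Chosen inside the admixture ranges used for chimeric validation
#: (neurons 2-36%, astrocytes 22-76%, oligodendrocytes 6-62%, microglia 1-5%).
DEFAULT_CONTROL_MEANS = {
    "neuron": 0.35,
    "astrocyte": 0.30,
    "oligodendrocyte": 0.30,
    "microglia": 0.05,
}

#: Default planted case/control effects (shift of the case group mean
#: proportion), matching effect magnitudes typical of AD temporal cortex:
#: neuronal loss of 0.17 and astrocytosis of 0.23 in proportion units.
DEFAULT_EFFECTS = {"neuron": -0.17, "astrocyte": 0.23}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the purified reference-profile generator.

    ``marker_fold_change`` is the expected over-expression of a marker in its
    own cell type relative to the ``baseline_expression`` it has elsewhere.
    ``noise_sigma`` is the standard deviation of the log of the multiplicative
    log-normal noise applied per matrix entry (0 disables noise).
    """

    cell_types: tuple = BRAIN_CELL_TYPES
    n_genes: int = 500
    n_markers_per_type: int = 50
    n_replicates: int = 3
    marker_fold_change: float = 20.0
    noise_sigma: float = 0.2
    baseline_expression: float = 10.0
    seed: int = 42

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def validate(self) -> "SyntheticConfig":
        if self.n_cell_types < 2:
            raise ConfigurationError("need at least 2 cell types")
        if self.n_markers_per_type < 1 or self.n_replicates < 1:
            raise ConfigurationError("n_markers_per_type and n_replicates must be >= 1")
        if self.n_markers_per_type * self.n_cell_types > self.n_genes:
            raise ConfigurationError(
                f"n_markers_per_type * n_cell_types = "
                f"{self.n_markers_per_type * self.n_cell_types} exceeds n_genes = {self.n_genes}"
            )
        if not self.marker_fold_change > 1:
            raise ConfigurationError("marker_fold_change must be > 1 (markers must be over-expressed)")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if not self.baseline_expression > 0:
            raise ConfigurationError("baseline_expression must be > 0")
        return self

    def gene_ids(self) -> list:
        """Marker genes first (grouped by cell type), then background genes."""
        genes = []
        for ct in self.cell_types:
            tag = ct[:3].upper()
            genes.extend(f"{tag}M{i + 1:03d}" for i in range(self.n_markers_per_type))
        n_background = self.n_genes - len(genes)
        genes.extend(f"BG{i + 1:04d}" for i in range(n_background))
        return genes


def marker_panel_from_config(config: SyntheticConfig) -> MarkerPanel:
    """The marker panel planted by :func:`simulate_reference_profiles`."""
    config.validate()
    assignments = {}
    for ct in config.cell_types:
        tag = ct[:3].upper()
        assignments[ct] = tuple(f"{tag}M{i + 1:03d}" for i in range(config.n_markers_per_type))
    return MarkerPanel(assignments)


def simulate_reference_profiles(config: SyntheticConfig) -> tuple:
    """Generate purified reference-sample expression and the sample labels.

    Returns ``(expression, labels)`` where ``expression`` is a gene-by-sample
    DataFrame with ``n_replicates`` columns per cell type and ``labels`` is a
    Series mapping sample id to cell type.  With ``noise_sigma = 0`` a marker
    row equals exactly ``baseline * fold`` in its own type and ``baseline``
    elsewhere; otherwise each entry is multiplied by ``exp(N(0, sigma^2))``.
    """
    config.validate()
    genes = config.gene_ids()
    rng = child_rng(config.seed, "reference-profiles")

    columns = []
    labels = {}
    mean_matrix = []
    for ct in config.cell_types:
        mean = np.full(len(genes), config.baseline_expression)
        tag = ct[:3].upper()
        own = [i for i, g in enumerate(genes) if g.startswith(f"{tag}M")]
        mean[own] = config.baseline_expression * config.marker_fold_change
        for rep in range(config.n_replicates):
            sample = f"{ct}_{rep + 1:02d}"
            columns.append(sample)
            labels[sample] = ct
            mean_matrix.append(mean)
    values = np.column_stack(mean_matrix)
    if config.noise_sigma > 0:
        noise = np.exp(rng.normal(0.0, config.noise_sigma, size=values.shape))
        values = values * noise
    expression = pd.DataFrame(values, index=genes, columns=columns)
    return expression, pd.Series(labels, name="cell_type")


def reference_panel_from_profiles(expression: pd.DataFrame, labels: pd.Series) -> ReferencePanel:
    """Wrap generated profiles as a :class:`ReferencePanel` (all human)."""
    return ReferencePanel(
        expression=expression,
        labels=dict(labels),
        species={s: "human" for s in expression.columns},
        provenance={s: "synthetic purified sample" for s in expression.columns},
    )


def simulate_read_pools(
    profiles: pd.DataFrame, pool_size: int, seed: int = 0
) -> "dict[str, np.ndarray]":
    """Draw a gene-tagged read pool per sample.

    Each sample's pool holds exactly ``pool_size`` reads; a read's gene is
    drawn multinomially with probability proportional to the sample's
    expression.  Returns ``{sample_id: array of gene symbols}``.
    """
    if pool_size < 1:
        raise ConfigurationError("pool_size must be >= 1")
    rng = child_rng(seed, "read-pools")
    genes = profiles.index.to_numpy()
    pools = {}
    for sample in profiles.columns:
        weights = profiles[sample].to_numpy(dtype=float)
        if (weights < 0).any():
            raise DataError(f"sample {sample!r}: negative expression")
        total = weights.sum()
        if total <= 0:
            raise DataError(f"sample {sample!r}: all-zero expression profile, cannot draw reads")
        counts = rng.multinomial(pool_size, weights / total)
        reads = np.repeat(genes, counts)
        rng.shuffle(reads)
        pools[sample] = reads
    return pools


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Design of a case/control bulk cohort with planted proportion effects.

    ``effect_per_type`` shifts the case-group mean proportion of the named
    cell types; the complement is absorbed by the unshifted types in
    proportion to their control means so each planted shift is realized
    exactly (if every type is shifted the means are renormalized instead).
    ``proportion_noise_sd`` is the per-type truncated-Gaussian sd around the
    group mean; ``expression_noise_sigma`` is the log-sd of the multiplicative
    noise on the bulk expression columns.
    """

    n_cases: int = 60
    n_controls: int = 60
    effect_per_type: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    control_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CONTROL_MEANS))
    proportion_noise_sd: float = 0.05
    expression_noise_sigma: float = 0.2
    covariate_spec: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "RIN": ("normal", 7.0, 1.0),
            "PMI": ("normal", 12.0, 6.0),
            "age_at_death": ("normal", 85.0, 8.0),
            "batch": ("choice", ("b1", "b2")),
        }
    )
    seed: int = 42

    def validate(self, cell_types: Sequence[str]) -> "SyntheticCohortSpec":
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("n_cases and n_controls must be >= 1")
        if self.proportion_noise_sd < 0 or self.expression_noise_sigma < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        means = np.array([self.control_means[ct] for ct in cell_types], dtype=float)
        if (means < 0).any() or not np.isclose(means.sum(), 1.0, atol=1e-9):
            raise ConfigurationError("control mean proportions must lie on the simplex")
        unknown = set(self.effect_per_type) - set(cell_types)
        if unknown:
            raise ConfigurationError(f"effects reference unknown cell types: {sorted(unknown)}")
        self.group_means(cell_types)  # raises if a shifted mean leaves [0, 1]
        return self

    def group_means(self, cell_types: Sequence[str]) -> "tuple[np.ndarray, np.ndarray]":
        """(control, case) mean proportion vectors implied by the planted effects."""
        control = np.array([self.control_means[ct] for ct in cell_types], dtype=float)
        case = control.copy()
        shifted = [i for i, ct in enumerate(cell_types) if ct in self.effect_per_type]
        for i in shifted:
            case[i] += self.effect_per_type[cell_types[i]]
        if (case < 0).any() or (case > 1).any():
            bad = [cell_types[i] for i in np.argwhere((case < 0) | (case > 1)).ravel()]
            raise ConfigurationError(
                f"planted effects push mean proportion of {bad} outside [0, 1]"
            )
        free = [i for i in range(len(case)) if i not in shifted]
        deficit = 1.0 - case.sum()
        if free and abs(deficit) > 0:
            weights = control[free] / control[free].sum()
            case[free] += deficit * weights
        if (case < 0).any() or (case > 1).any():
            raise ConfigurationError(
                "absorbing the planted effects pushes an unshifted mean proportion outside [0, 1]"
            )
        case = np.clip(case, 0.0, 1.0)
        case = case / case.sum()
        return control, case


def _draw_proportions(rng, mean: np.ndarray, sd: float, n: int) -> np.ndarray:
    """Truncated-Gaussian perturbation around ``mean``, renormalized to the simplex."""
    draws = rng.normal(mean, sd, size=(n, mean.size)) if sd > 0 else np.tile(mean, (n, 1))
    draws = np.clip(draws, 0.0, 1.0)
    sums = draws.sum(axis=1, keepdims=True)
    # all-zero rows are vanishingly unlikely; fall back to the group mean
    zero = sums.ravel() <= 0
    if zero.any():
        draws[zero] = mean
        sums = draws.sum(axis=1, keepdims=True)
    return draws / sums


def simulate_bulk_cohort(
    profiles: pd.DataFrame, labels: pd.Series, spec: SyntheticCohortSpec
) -> tuple:
    """Simulate a case/control bulk cohort from purified reference profiles.

    Each subject receives a true proportion vector drawn around its group
    mean; the bulk column is the proportion-weighted combination of the
    cell-type mean profiles, under multiplicative log-normal noise.

    Returns ``(bulk, true_proportions, metadata)``: the gene-by-sample bulk
    matrix, the sample-by-cell-type truth, and a metadata table with
    ``status`` plus the configured covariates.
    """
    cell_types = []
    for s in profiles.columns:
        ct = labels[s]
        if ct not in cell_types:
            cell_types.append(ct)
    spec.validate(cell_types)

    type_means = pd.DataFrame(
        {ct: profiles[[s for s in profiles.columns if labels[s] == ct]].mean(axis=1) for ct in cell_types}
    )
    control_mean, case_mean = spec.group_means(cell_types)

    rng = child_rng(spec.seed, "bulk-cohort")
    n = spec.n_cases + spec.n_controls
    status = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls)
    group_mean = np.where(status[:, None] == "case", case_mean, control_mean)

    props = np.empty((n, len(cell_types)))
    for i in range(n):
        props[i] = _draw_proportions(rng, group_mean[i], spec.proportion_noise_sd, 1)[0]

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    bulk_values = type_means.to_numpy() @ props.T
    if spec.expression_noise_sigma > 0:
        bulk_values = bulk_values * np.exp(
            rng.normal(0.0, spec.expression_noise_sigma, size=bulk_values.shape)
        )
    bulk = pd.DataFrame(bulk_values, index=profiles.index, columns=sample_ids)
    truth = pd.DataFrame(props, index=sample_ids, columns=cell_types)

    meta = {"sample_id": sample_ids, "donor_id": sample_ids, "status": status}
    for name, dist in spec.covariate_spec.items():
        kind = dist[0]
        if kind == "normal":
            _, mu, sd = dist
            meta[name] = rng.normal(mu, sd, size=n)
        elif kind == "choice":
            meta[name] = rng.choice(np.asarray(dist[1], dtype=object), size=n)
        else:
            raise ConfigurationError(f"unknown covariate distribution kind {kind!r} for {name!r}")
    metadata = pd.DataFrame(meta).set_index("sample_id")
    return bulk, truth, metadata
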
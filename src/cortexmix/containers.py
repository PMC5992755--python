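"""Core in-memory containers.

Expression matrices are plain :class:`pandas.DataFrame` objects with gene
symbols in the row index and sample identifiers in the columns, holding
non-negative linear-space abundances (TPM-like).  Proportion matrices are
DataFrames with samples in rows and cell types in columns, each row on the
probability simplex.  The two small classes below add the structure that a
bare DataFrame cannot carry: the marker-to-cell-type map and the labeled
purified-sample reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

__all__ = ["MarkerPanel", "ReferencePanel", "check_expression", "check_proportions"]


def check_expression(matrix: pd.DataFrame, name: str = "expression") -> pd.DataFrame:
    """Validate a gene-by-sample expression matrix and return it unchanged.

    Raises :class:`DataError` on negative entries, non-numeric values, or
    duplicated gene/sample identifiers, naming the offending cell.
    """
    if not isinstance(matrix, pd.DataFrame):
        raise DataError(f"{name}: expected a pandas DataFrame, got {type(matrix).__name__}")
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise DataError(f"{name}: duplicate gene identifiers {dupes[:5]}")
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise DataError(f"{name}: duplicate sample identifiers {dupes[:5]}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise DataError(f"{name}: non-numeric values present")
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise DataError(f"{name}: missing value at gene {matrix.index[g]!r}, sample {matrix.columns[s]!r}")
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise DataError(
            f"{name}: negative value {values[g, s]!r} at gene {matrix.index[g]!r}, "
            f"sample {matrix.columns[s]!r}; linear-space abundances must be non-negative"
        )
    return matrix


def check_proportions(props: pd.DataFrame, name: str = "proportions", atol: float = 1e-6) -> pd.DataFrame:
    """Validate a sample-by-cell-type proportion matrix (rows on the simplex)."""
    values = props.to_numpy(dtype=float)
    if (values < -atol).any() or (values > 1 + atol).any():
        raise DataError(f"{name}: entries outside [0, 1]")
    row_sums = values.sum(axis=1)
    bad = np.abs(row_sums - 1.0) > atol
    if bad.any():
        i = int(np.argmax(bad))
        raise DataError(f"{name}: row {props.index[i]!r} sums to {row_sums[i]:.8f}, not 1")
    return props


@dataclass(frozen=True)
class MarkerPanel:
    """Map from cell type to the gene symbols that mark it.

    Each gene may mark at most one cell type, and every cell type must carry
    at least one marker.
    """

    assignments: Mapping[str, tuple]

    def __post_init__(self):
        cleaned = {}
        seen: dict[str, str] = {}
        for cell_type, genes in self.assignments.items():
            genes = tuple(genes)
            if len(genes) == 0:
                raise ConfigurationError(f"cell type {cell_type!r} has no markers")
            for gene in genes:
                if gene in seen:
                    raise ConfigurationError(
                        f"gene {gene!r} assigned to both {seen[gene]!r} and {cell_type!r}; "
                        "markers must be unique to one cell type"
                    )
                seen[gene] = cell_type
            cleaned[cell_type] = genes
        object.__setattr__(self, "assignments", cleaned)

    @property
    def cell_types(self) -> tuple:
        return tuple(self.assignments)

    @property
    def genes(self) -> tuple:
        return tuple(g for genes in self.assignments.values() for g in genes)

    def type_of(self, gene: str) -> str:
        for cell_type, genes in self.assignments.items():
            if gene in genes:
                return cell_type
        raise KeyError(gene)

    def restrict_to(self, genes: Iterable[str]) -> "MarkerPanel":
        """Keep only the given genes; raises if a cell type loses all markers."""
        keep = set(genes)
        out = {}
        for cell_type, gs in self.assignments.items():
            retained = tuple(g for g in gs if g in keep)
            if not retained:
                raise DataError(f"cell type {cell_type!r} lost all markers in restriction")
            out[cell_type] = retained
        return MarkerPanel(out)

    def drop_gene(self, gene: str) -> "MarkerPanel":
        out = {ct: tuple(g for g in gs if g != gene) for ct, gs in self.assignments.items()}
        return MarkerPanel(out)


@dataclass
class ReferencePanel:
    """Labeled purified-sample expression restricted (or restrictable) to markers.

    Parameters
    ----------
    expression
        Gene-by-sample matrix of the purified reference samples.
    labels
        Mapping sample id -> cell type.
    species
        Optional mapping sample id -> {"human", "mouse"}.
    provenance
        Optional free-text description per sample.
    """

    expression: pd.DataFrame
    labels: Mapping[str, str]
    species: Mapping[str, str] = field(default_factory=dict)
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        check_expression(self.expression, "reference panel expression")
        self.labels = dict(self.labels)
        missing = [s for s in self.expression.columns if s not in self.labels]
        if missing:
            raise DataError(f"samples without a cell-type label: {missing[:5]}")
        for sample, sp in dict(self.species).items():
            if sp not in ("human", "mouse"):
                raise DataError(f"sample {sample!r}: species must be 'human' or 'mouse', got {sp!r}")

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.expression.columns)

    @property
    def cell_types(self) -> tuple:
        seen = []
        for s in self.expression.columns:
            ct = self.labels[s]
            if ct not in seen:
                seen.append(ct)
        return tuple(seen)

    def samples_of(self, cell_type: str) -> tuple:
        return tuple(s for s in self.expression.columns if self.labels[s] == cell_type)

    def type_means(self, genes: Iterable[str] | None = None) -> pd.DataFrame:
        """Mean expression profile per cell type (genes x cell types)."""
        expr = self.expression if genes is None else self.expression.loc[list(genes)]
        cols = {ct: expr[list(self.samples_of(ct))].mean(axis=1) for ct in self.cell_types}
        return pd.DataFrame(cols)

    def drop_samples(self, sample_ids: Iterable[str]) -> "ReferencePanel":
        drop = set(sample_ids)
        keep = [s for s in self.expression.columns if s not in drop]
        return ReferencePanel(
            expression=self.expression[keep],
            labels={s: self.labels[s] for s in keep},
            species={s: v for s, v in dict(self.species).items() if s in keep},
            provenance={s: v for s, v in dict(self.provenance).items() if s in keep},
        )

    def restrict_genes(self, genes: Iterable[str]) -> "ReferencePanel":
        genes = [g for g in genes if g in self.expression.index]
        return ReferencePanel(
            expression=self.expression.loc[genes],
            labels=self.labels,
            species=self.species,
            provenance=self.provenance,
        )
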
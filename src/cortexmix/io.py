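"""Readers and writers for the pipeline's file formats.

The canonical matrix format is TSV with genes in rows and a header of
sample ids (UTF-8, '.' decimal); CSV is accepted on read.  Marker lists are
two-column TSV (gene_symbol, cell_type) or a YAML map of cell type to gene
list.  Proportions are written as TSV with sample_id plus one column per
cell type, cell types in sorted order for deterministic output.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MarkerPanel, check_expression
from .exceptions import DataError

__all__ = [
    "read_expression",
    "write_expression",
    "read_markers",
    "write_markers",
    "read_proportions",
    "write_proportions",
    "read_metadata",
    "default_marker_panel",
]

logger = logging.getLogger(__name__)


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_expression(path, orientation: str = "genes_by_samples") -> pd.DataFrame:
    """Read a non-negative expression matrix.

    ``orientation`` is ``genes_by_samples`` (default), ``samples_by_genes``,
    or ``auto`` (transposes when there are fewer rows than columns, the
    usual signature of a samples-in-rows table).  Duplicate gene rows are
    collapsed by sum with a logged count; negative or non-numeric cells and
    duplicate sample ids are errors that name the offending location.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dupes = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
    if dupes:
        raise DataError(f"{path.name}: duplicate sample ids {dupes[:5]}")
    raw = pd.read_csv(path, sep=sep, index_col=0)
    if orientation not in ("genes_by_samples", "samples_by_genes", "auto"):
        raise DataError(f"unknown orientation {orientation!r}")
    if orientation == "samples_by_genes" or (
        orientation == "auto" and raw.shape[0] < raw.shape[1]
    ):
        raw = raw.T
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise DataError(
                f"{path.name}: non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, "
                f"sample {col!r}"
            )
        raw[col] = converted
    if raw.columns.duplicated().any():
        dupes = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise DataError(f"{path.name}: duplicate sample ids {dupes[:5]}")
    values = raw.to_numpy(dtype=float)
    if np.isnan(values).any():
        g, s = np.argwhere(np.isnan(values))[0]
        raise DataError(f"{path.name}: empty cell at gene {raw.index[g]!r}, sample {raw.columns[s]!r}")
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise DataError(
            f"{path.name}: negative value {values[g, s]} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}"
        )
    if raw.index.duplicated().any():
        n_dup = int(raw.index.duplicated().sum())
        logger.warning("%s: collapsed %d duplicated gene rows by sum", path.name, n_dup)
        raw = raw.groupby(level=0, sort=False).sum()
    return check_expression(raw, path.name)


def write_expression(matrix: pd.DataFrame, path) -> None:
    check_expression(matrix, "expression")
    matrix.to_csv(path, sep=_sep_for(Path(path)), index_label="gene")


def read_markers(path) -> MarkerPanel:
    """Read a marker panel from two-column TSV/CSV or a YAML map.

    A gene assigned to two cell types is an error quoting both assignments.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise DataError(f"{path.name}: expected a mapping of cell type to gene list")
        assignments = {ct: tuple(genes) for ct, genes in mapping.items()}
    else:
        table = pd.read_csv(path, sep=_sep_for(path))
        cols = [c.lower() for c in table.columns]
        if "gene_symbol" in cols and "cell_type" in cols:
            table.columns = cols
        elif table.shape[1] >= 2:
            table.columns = ["gene_symbol", "cell_type", *cols[2:]]
        else:
            raise DataError(f"{path.name}: need columns gene_symbol, cell_type")
        assignments = {}
        for ct, group in table.groupby("cell_type", sort=False):
            assignments[ct] = tuple(group["gene_symbol"])
    seen: dict = {}
    for ct, genes in assignments.items():
        for g in genes:
            if g in seen and seen[g] != ct:
                raise DataError(
                    f"{path.name}: gene {g!r} assigned to both {seen[g]!r} and {ct!r}"
                )
            seen[g] = ct
    return MarkerPanel(assignments)


def write_markers(markers: MarkerPanel, path) -> None:
    rows = [(g, ct) for ct in markers.cell_types for g in markers.assignments[ct]]
    pd.DataFrame(rows, columns=["gene_symbol", "cell_type"]).to_csv(
        path, sep=_sep_for(Path(path)), index=False
    )


def read_proportions(path) -> pd.DataFrame:
    path = Path(path)
    props = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return props


def write_proportions(proportions: pd.DataFrame, path) -> None:
    """Write sample-by-cell-type proportions with sorted cell-type columns."""
    out = proportions[sorted(proportions.columns)]
    out.to_csv(path, sep=_sep_for(Path(path)), index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in meta.columns:
        raise DataError(f"{path.name}: metadata needs a sample_id column")
    if meta["sample_id"].duplicated().any():
        raise DataError(f"{path.name}: duplicate sample_id values")
    return meta.set_index("sample_id")


def default_marker_panel() -> MarkerPanel:
    """The packaged default marker list for the four major brain cell types.

    A compact set of well-known literature markers (e.g. GFAP and AQP4 for
    astrocytes, MBP and PLP1 for oligodendrocytes); it is a generic default,
    not the curated panel of any specific study, and callers with a curated
    list should supply their own file.
    """
    ref = importlib.resources.files("cortexmix.data").joinpath("brain_markers_default.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_markers(path)
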
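"""Assembly, quality control, and iterative curation of the reference panel.

A reference panel is a set of purified (or purified-enough) cell-type
samples.  Because such samples come from both human and mouse experiments,
gene symbols are first harmonized to a canonical uppercase namespace
(case-insensitive symbol identity; no orthology tables, which suffices for
the well-known marker namespace).  Candidate markers are then filtered for
specificity, the panel is inspected with a marker-space PCA, and finally
samples whose leave-one-out predicted self-type composition does not exceed
a threshold (default 0.80, strict) are removed, iterating to a fixpoint.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .containers import MarkerPanel, ReferencePanel, check_expression
from .exceptions import ConfigurationError, CurationError, DataError
from .validate import loocv_accuracy

__all__ = [
    "CurationReport",
    "harmonize_species",
    "extract_markers",
    "qc_pca",
    "loocv_curate",
]

logger = logging.getLogger(__name__)

_SYMBOL_RE = re.compile(r"^[A-Za-z][A-Za-z0-9\-\.]*$")


def harmonize_species(
    matrix: pd.DataFrame, species: str, markers: MarkerPanel | None = None
) -> pd.DataFrame:
    """Map gene symbols to a canonical uppercase namespace.

    Mouse-style symbols ("Gfap") and human symbols ("GFAP") collapse to the
    same canonical row.  Symbols that do not look like gene symbols are
    dropped with a logged count; duplicate canonical rows are collapsed by
    sum.  If a marker panel is given, an empty intersection with its
    namespace raises.
    """
    if species not in ("human", "mouse"):
        raise ConfigurationError(f"species must be 'human' or 'mouse', got {species!r}")
    check_expression(matrix, "expression")
    keep = [g for g in matrix.index if _SYMBOL_RE.match(str(g))]
    dropped = len(matrix.index) - len(keep)
    if dropped:
        logger.info("harmonize_species: dropped %d unmappable gene identifiers", dropped)
    out = matrix.loc[keep]
    out = out.rename(index=lambda g: str(g).upper())
    if out.index.duplicated().any():
        n_dup = int(out.index.duplicated().sum())
        logger.info("harmonize_species: collapsed %d duplicate canonical symbols by sum", n_dup)
        out = out.groupby(level=0, sort=False).sum()
    if markers is not None:
        marker_space = {m.upper() for m in markers.genes}
        if not marker_space.intersection(out.index):
            raise DataError(
                f"no overlap between the {species} matrix and the marker namespace "
                "after harmonization"
            )
    return out


def extract_markers(
    panel: ReferencePanel, candidates: MarkerPanel, min_specificity: float = 2.0
) -> MarkerPanel:
    """Keep candidate markers that are specific to their assigned type.

    A marker is retained when its mean expression in its own cell type is at
    least ``min_specificity`` times its highest mean in any other type.  The
    output is always a subset of the candidates with unchanged assignments.
    """
    if min_specificity <= 0:
        raise ConfigurationError("min_specificity must be positive")
    means = panel.type_means()
    retained: dict = {}
    for ct in candidates.cell_types:
        if ct not in panel.cell_types:
            raise DataError(f"candidate cell type {ct!r} absent from the reference panel")
        kept = []
        for gene in candidates.assignments[ct]:
            if gene not in means.index:
                continue
            own = means.loc[gene, ct]
            others = means.loc[gene].drop(ct)
            if own >= min_specificity * others.max():
                kept.append(gene)
        if not kept:
            raise DataError(
                f"cell type {ct!r} lost all candidate markers at "
                f"min_specificity={min_specificity}"
            )
        retained[ct] = tuple(kept)
    return MarkerPanel(retained)


def qc_pca(panel: ReferencePanel, markers: MarkerPanel | None = None, n_components: int = 2):
    """PCA of log-scaled marker expression plus the label silhouette.

    Expression is restricted to marker genes when a panel is supplied, each
    sample is rescaled to a common total of 10^4 (TPM-like, making the
    result invariant to per-sample scale factors), transformed with
    log(x + 1), and centered by the PCA.  Returns
    ``(coordinates, silhouette)`` where ``coordinates`` is samples x
    components and ``silhouette`` the mean silhouette of the cell-type labels
    in the top-2 component space.
    """
    expr = panel.expression
    if markers is not None:
        genes = [g for g in markers.genes if g in expr.index]
        if not genes:
            raise DataError("no marker genes present in the panel expression")
        expr = expr.loc[genes]
    labels = [panel.labels[s] for s in expr.columns]
    if len(set(labels)) < 2:
        raise DataError("silhouette undefined: panel contains a single cell type")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise DataError(f"need >= 2 samples per cell type for QC PCA; too few for {small}")
    values = expr.to_numpy(dtype=float)
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        bad = [expr.columns[i] for i in np.argwhere(totals <= 0).ravel()]
        raise DataError(f"samples with zero total marker expression: {bad[:5]}")
    X = np.log1p(values / totals * 1e4).T  # samples x genes
    if X.shape[0] < n_components:
        raise DataError(
            f"fewer samples ({X.shape[0]}) than requested components ({n_components})"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    sil = float(silhouette_score(coords[:, :2], labels))
    coordinates = pd.DataFrame(
        coords, index=expr.columns, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return coordinates, sil


@dataclass
class CurationReport:
    """Per-round LOOCV self-proportions and the retention outcome."""

    rounds: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["round", "sample_id", "cell_type", "predicted_self_proportion", "retained"]
        )
    )
    rounds_run: int = 0
    threshold: float = 0.80

    def add_round(self, round_no: int, self_props: pd.Series, labels, removed: set):
        rows = pd.DataFrame(
            {
                "round": round_no,
                "sample_id": self_props.index,
                "cell_type": [labels[s] for s in self_props.index],
                "predicted_self_proportion": self_props.to_numpy(),
                "retained": [s not in removed for s in self_props.index],
            }
        )
        self.rounds = rows if self.rounds.empty else pd.concat([self.rounds, rows], ignore_index=True)
        self.rounds_run = round_no

    @property
    def retained_samples(self) -> list:
        last = self.rounds[self.rounds["round"] == self.rounds_run]
        return last.loc[last["retained"], "sample_id"].tolist()


def loocv_curate(
    panel: ReferencePanel,
    markers: MarkerPanel,
    engine: str = "ssnmf",
    threshold: float = 0.80,
    max_rounds: int = 10,
) -> tuple:
    """Iteratively remove reference samples that fail LOOCV self-recovery.

    Per round, every sample is held out and deconvolved as a one-column bulk
    against the remaining panel; samples whose predicted self-type
    proportion is not strictly greater than ``threshold`` are removed
    simultaneously.  Rounds repeat until no removal occurs or ``max_rounds``
    is reached.  Returns ``(curated_panel, report)``.
    """
    if not 0 < threshold < 1:
        raise ConfigurationError(f"threshold must be in (0, 1), got {threshold}")
    if max_rounds < 1:
        raise ConfigurationError("max_rounds must be >= 1")
    report = CurationReport(threshold=threshold)
    current = panel
    for round_no in range(1, max_rounds + 1):
        result = loocv_accuracy(current, markers, engine=engine)
        self_props = result.self_proportions
        removed = {s for s, p in self_props.items() if not p > threshold}
        report.add_round(round_no, self_props, current.labels, removed)
        if removed:
            survivors = current.drop_samples(removed)
            counts = pd.Series([survivors.labels[s] for s in survivors.sample_ids]).value_counts()
            depleted = [
                ct for ct in current.cell_types
                if counts.get(ct, 0) < 2
            ]
            if depleted:
                raise CurationError(
                    f"curation round {round_no} would leave cell type(s) {depleted} with "
                    "fewer than 2 samples; stopping with partial report",
                    report=report,
                )
            current = survivors
        else:
            break
    return current, report
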
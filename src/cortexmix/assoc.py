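"""Association of inferred cell-type proportions with phenotype.

Cell-type proportions are analyzed on their natural scale (no logit
transform), so effects are differences in proportion units.  The module
offers ordinary least squares per cell type, random-intercept linear mixed
models for multi-region or family-clustered designs, bidirectional stepwise
covariate selection by AIC, Monte-Carlo power estimation, and fixed-effect
inverse-variance meta-analysis.  Wald two-sided p-values are reported
throughout; no multiple-testing correction is applied by default (a
Benjamini-Hochberg helper is provided).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import child_rng
from .exceptions import ConfigurationError, DataError

__all__ = [
    "AssociationResult",
    "fit_association",
    "fit_mixed_association",
    "select_covariates",
    "estimate_power",
    "meta_analyze",
    "adjust_pvalues",
]


@dataclass
class AssociationResult:
    """Effect of a predictor on one cell type's proportion."""

    cell_type: str
    predictor: str
    effect: float
    std_error: float
    p_value: float
    n: int
    model: str = "ols"
    covariates: tuple = ()
    flags: tuple = ()


#: Category names treated as the reference level of a categorical predictor,
#: so reported effects read e.g. "case vs control" or "carrier vs non-carrier".
_REFERENCE_LEVELS = ("control", "ctrl", "non", "noncarrier", "non_carrier", "non-carrier", "wt", "reference")


def _design_matrix(
    metadata: pd.DataFrame,
    predictor: str,
    covariates: Sequence[str],
    reference: "str | None" = None,
):
    """Numeric design matrix with dummies for categoricals.

    Returns (X DataFrame with intercept, name of the predictor column whose
    coefficient is reported).  For a categorical predictor the baseline is
    ``reference`` when given, else a control-like level if one is present,
    else the first level in sorted order.
    """
    cols = [predictor, *covariates]
    missing = [c for c in cols if c not in metadata.columns]
    if missing:
        raise DataError(f"metadata lacks columns: {missing}")
    X = metadata[cols].copy()
    predictor_col = predictor
    frames = []
    for c in cols:
        col = X[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            cat = col.astype("category")
            levels = list(cat.cat.categories)
            if c == predictor:
                if len(levels) < 2:
                    raise DataError(f"predictor {c!r} has fewer than 2 levels")
                base = None
                if reference is not None:
                    if reference not in levels:
                        raise DataError(
                            f"reference level {reference!r} not among {levels} of {c!r}"
                        )
                    base = reference
                else:
                    base = next(
                        (lv for lv in levels if str(lv).lower() in _REFERENCE_LEVELS), levels[0]
                    )
                cat = cat.cat.reorder_categories([base, *[lv for lv in levels if lv != base]])
            dummies = pd.get_dummies(cat, prefix=c, drop_first=True, dtype=float)
            if c == predictor:
                predictor_col = dummies.columns[0]
            frames.append(dummies)
        else:
            frames.append(col.astype(float).to_frame())
    X = pd.concat(frames, axis=1)
    X.insert(0, "Intercept", 1.0)
    return X, predictor_col


def _check_collinearity(X: pd.DataFrame):
    values = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(values)
    if rank < X.shape[1]:
        # identify aliased columns by greedy rank growth
        aliased = []
        kept: list = []
        for j, name in enumerate(X.columns):
            trial = values[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(name)
        raise DataError(f"collinear design: aliased columns {aliased}")


def _aligned(proportions: pd.DataFrame, metadata: pd.DataFrame, cell_type: str):
    if cell_type not in proportions.columns:
        raise DataError(f"unknown cell type {cell_type!r}")
    shared = proportions.index.intersection(metadata.index)
    if len(shared) == 0:
        raise DataError("no shared sample ids between proportions and metadata")
    return proportions.loc[shared, cell_type].astype(float), metadata.loc[shared]


def fit_association(
    proportions: pd.DataFrame,
    metadata: pd.DataFrame,
    cell_type: str,
    predictor: str,
    covariates: Sequence[str] = (),
    reference: "str | None" = None,
) -> AssociationResult:
    """OLS of one cell type's proportion on a predictor plus covariates.

    ``reference`` picks the baseline level of a categorical predictor.
    """
    y, meta = _aligned(proportions, metadata, cell_type)
    X, pred_col = _design_matrix(meta, predictor, covariates, reference)
    data = pd.concat([y.rename("_y"), X], axis=1).dropna()
    if len(data) < X.shape[1] + 1:
        raise DataError(
            f"too few complete cases ({len(data)}) for {X.shape[1]} coefficients"
        )
    y, X = data["_y"], data.drop(columns="_y")
    if float(np.var(y)) == 0.0:
        raise DataError(f"outcome {cell_type!r} proportion is constant")
    if float(np.var(X[pred_col])) == 0.0:
        raise DataError(f"predictor {predictor!r} has no variance among complete cases")
    _check_collinearity(X)
    fit = sm.OLS(y, X).fit()
    return AssociationResult(
        cell_type=cell_type,
        predictor=predictor,
        effect=float(fit.params[pred_col]),
        std_error=float(fit.bse[pred_col]),
        p_value=float(fit.pvalues[pred_col]),
        n=int(fit.nobs),
        model="ols",
        covariates=tuple(covariates),
    )


def fit_mixed_association(
    proportions: pd.DataFrame,
    metadata: pd.DataFrame,
    cell_type: str,
    predictor: str,
    covariates: Sequence[str] = (),
    grouping: str = "donor_id",
    random_slopes: bool = False,
    reference: "str | None" = None,
) -> AssociationResult:
    """Random-intercept linear mixed model (optionally random slopes).

    Groups repeated observations by donor or family.  Singular or
    non-converged fits are flagged in ``flags`` rather than dropped.
    """
    y, meta = _aligned(proportions, metadata, cell_type)
    if grouping not in meta.columns:
        raise DataError(f"grouping column {grouping!r} absent from metadata")
    X, pred_col = _design_matrix(meta, predictor, covariates, reference)
    data = pd.concat([y.rename("_y"), X, meta[grouping].rename("_g")], axis=1).dropna()
    groups = data["_g"]
    if groups.nunique() < 2:
        raise DataError("need >= 2 grouping units for a mixed model")
    y, X = data["_y"], data.drop(columns=["_y", "_g"])
    _check_collinearity(X)
    exog_re = X[["Intercept", pred_col]] if random_slopes else X[["Intercept"]]
    flags: list = []
    if not (groups.value_counts() >= 2).any():
        # the random-intercept variance is unidentified; the fit collapses
        # to ordinary regression and is flagged rather than rejected
        flags.append("no_replication_within_groups")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
        fit = model.fit(reml=True)
        for w in caught:
            if "singular" in str(w.message).lower():
                flags.append("singular_fit")
            elif "converge" in str(w.message).lower():
                flags.append("convergence_warning")
    if not fit.converged and "convergence_warning" not in flags:
        flags.append("convergence_warning")
    return AssociationResult(
        cell_type=cell_type,
        predictor=predictor,
        effect=float(fit.fe_params[pred_col]),
        std_error=float(fit.bse_fe[pred_col]),
        p_value=float(fit.pvalues[pred_col]),
        n=int(len(y)),
        model="mixed" + ("+slopes" if random_slopes else ""),
        covariates=tuple(covariates),
        flags=tuple(dict.fromkeys(flags)),
    )


def select_covariates(
    data: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
) -> tuple:
    """Bidirectional stepwise covariate selection minimizing AIC.

    Starts from the full model over ``candidates`` and alternates removal
    and re-addition steps until no move lowers the AIC.  Deterministic given
    the data.  Returns ``(selected, aic_path)`` where ``aic_path`` records
    each accepted step.
    """
    candidates = list(candidates)
    if outcome not in data.columns:
        raise DataError(f"outcome column {outcome!r} absent")
    if not candidates:
        return [], []

    def aic_of(subset: Sequence[str]) -> float:
        cols = [outcome, *subset]
        d = data[cols].dropna()
        y = d[outcome].astype(float)
        if subset:
            X, _ = _design_matrix(d, subset[0], subset[1:])
        else:
            X = pd.DataFrame({"Intercept": np.ones(len(d))}, index=d.index)
        return float(sm.OLS(y, X).fit().aic)

    current = list(candidates)
    path = [("start", tuple(current), aic_of(current))]
    best_aic = path[0][2]
    improved = True
    while improved:
        improved = False
        moves = []
        for c in current:
            subset = [x for x in current if x != c]
            moves.append(("drop", c, subset, aic_of(subset)))
        for c in candidates:
            if c not in current:
                subset = current + [c]
                moves.append(("add", c, subset, aic_of(subset)))
        if moves:
            kind, c, subset, aic = min(moves, key=lambda m: m[3])
            if aic < best_aic - 1e-9:
                current = list(subset)
                best_aic = aic
                path.append((f"{kind} {c}", tuple(current), aic))
                improved = True
    return current, path


def estimate_power(
    n_per_group: "int | tuple",
    effect: float,
    noise_sd: float,
    alpha: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the two-group proportion comparison.

    Simulates ``n_sims`` datasets in which the group means differ by
    ``effect`` with Gaussian noise ``noise_sd``, fits the group contrast
    with :func:`fit_association`, and returns the rejection fraction at
    ``alpha``.
    """
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be positive")
    if n_sims < 100:
        raise ConfigurationError("n_sims must be >= 100 for a stable estimate")
    n1, n2 = (n_per_group, n_per_group) if np.isscalar(n_per_group) else n_per_group
    rng = child_rng(seed, "power")
    status = np.array(["case"] * n1 + ["control"] * n2)
    meta = pd.DataFrame({"group": status}, index=[f"s{i}" for i in range(n1 + n2)])
    mean = np.where(status == "case", effect, 0.0)
    hits = 0
    for _ in range(n_sims):
        y = rng.normal(mean, noise_sd)
        props = pd.DataFrame({"cell": y}, index=meta.index)
        res = fit_association(props, meta, "cell", "group")
        hits += res.p_value < alpha
    return hits / n_sims


def meta_analyze(results: Iterable[AssociationResult]) -> AssociationResult:
    """Fixed-effect inverse-variance pooling of per-study effects."""
    results = list(results)
    if len(results) < 2:
        raise ConfigurationError("meta-analysis needs >= 2 results")
    cell_types = {r.cell_type for r in results}
    predictors = {r.predictor for r in results}
    if len(cell_types) > 1 or len(predictors) > 1:
        raise DataError(
            f"cannot pool mismatched results: cell types {sorted(cell_types)}, "
            f"predictors {sorted(predictors)}"
        )
    effects = np.array([r.effect for r in results], dtype=float)
    ses = np.array([r.std_error for r in results], dtype=float)
    finite = np.isfinite(ses) & (ses > 0)
    if not finite.any():
        raise DataError("no result has a finite standard error")
    w = np.zeros_like(ses)
    w[finite] = 1.0 / ses[finite] ** 2
    pooled = float(np.sum(w * effects) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    z = pooled / pooled_se
    p = float(2 * stats.norm.sf(abs(z)))
    return AssociationResult(
        cell_type=results[0].cell_type,
        predictor=results[0].predictor,
        effect=pooled,
        std_error=pooled_se,
        p_value=min(p, 1.0) if p > 0 else np.nextafter(0, 1),
        n=int(sum(r.n for r in results)),
        model="fixed-effect meta",
        covariates=tuple(sorted({c for r in results for c in r.covariates})),
    )


def adjust_pvalues(results: Iterable[AssociationResult], method: str = "fdr_bh") -> pd.DataFrame:
    """Tidy table of results with a multiplicity-adjusted p-value column."""
    results = list(results)
    table = pd.DataFrame(
        {
            "cell_type": [r.cell_type for r in results],
            "predictor": [r.predictor for r in results],
            "effect": [r.effect for r in results],
            "std_error": [r.std_error for r in results],
            "p_value": [r.p_value for r in results],
            "n": [r.n for r in results],
            "model": [r.model for r in results],
        }
    )
    table["p_adjusted"] = multipletests(table["p_value"], method=method)[1]
    return table
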
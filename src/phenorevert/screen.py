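"""Discriminating-panel selection.

Per variable, a linear model of the log-value on group membership adjusted
for age and sex; Benjamini-Hochberg control of the false discovery rate
across variables; an absolute effect-size floor expressed in control-group
standard deviations; and greedy correlation pruning so that of any set of
highly correlated selected variables only the one with the largest absolute
effect survives.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError

__all__ = ["SelectionConfig", "SelectionResult", "univariate_screen",
           "correlation_prune", "selection_frame"]


@dataclass
class SelectionConfig:
    alpha_adj: float = 0.05
    effect_floor: float = 0.5
    prune_r: float = 0.8
    covariates: tuple[str, ...] = ("age", "sex")

    def __post_init__(self) -> None:
        if not 0 < self.alpha_adj < 1:
            raise ConfigError(f"alpha_adj must be in (0,1), got {self.alpha_adj}")
        if self.effect_floor < 0:
            raise ConfigError(f"effect_floor must be >= 0, got {self.effect_floor}")
        if not 0 < self.prune_r <= 1:
            raise ConfigError(f"prune_r must be in (0,1], got {self.prune_r}")


@dataclass
class SelectionResult:
    variable: str
    beta_group: float
    effect_sd: float
    p_raw: float
    p_adj: float
    passed_univariate: bool
    kept_after_prune: bool = False
    pruned_by: str | None = None
    note: str | None = None


def _design_matrix(y: np.ndarray, covariates: pd.DataFrame,
                   names: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(y, dtype=float), y.astype(float)]
    labels = ["intercept", "group"]
    for name in names:
        if name not in covariates.columns:
            raise DataError(f"covariate {name!r} missing from metadata")
        col = covariates[name]
        if name == "sex" or col.dtype == object:
            col = (col == "M").astype(float)  # single male indicator
        cols.append(np.asarray(col, dtype=float))
        labels.append(name)
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise DataError("covariates contain missing values")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which columns are redundant for a useful message
        bad = []
        for j in range(2, X.shape[1]):
            keep = [i for i in range(X.shape[1]) if i != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(labels[j])
        raise DataError(f"collinear covariates: {bad or labels[2:]}")
    return X, labels


def univariate_screen(matrix: pd.DataFrame, y, covariates: pd.DataFrame,
                      cfg: SelectionConfig | None = None) -> list[SelectionResult]:
    """Covariate-adjusted screen of every variable.

    ``matrix`` holds log-transformed values (samples x variables), ``y`` the
    binary group indicator (1 = case), ``covariates`` the per-sample age and
    sex.  Effects are the group coefficient divided by the control group's
    log-scale SD, so a positive effect means elevated in cases.

    All variables share the same regressor matrix, so the least-squares
    problems are solved in one pass.
    """
    cfg = cfg or SelectionConfig()
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DataError("y must be a 0/1 case indicator")
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if min(n0, n1) < 3:
        raise DataError(f"need >= 3 samples per group, have {n0} controls / {n1} cases")

    X, _ = _design_matrix(y, covariates, cfg.covariates)
    Y = matrix.to_numpy(dtype=float)
    n, k = X.shape
    dof = n - k
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)                       # k x p
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[1, 1])

    control_sd = matrix.loc[np.asarray(y) == 0].std(axis=0, ddof=1).to_numpy()
    constant = (Y.max(axis=0) - Y.min(axis=0)) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta[1] / se, 0.0)
        effect = np.where(control_sd > 0, beta[1] / control_sd, 0.0)
    p_raw = 2.0 * sps.t.sf(np.abs(tvals), dof)
    p_raw = np.where(constant, 1.0, p_raw)
    effect = np.where(constant, 0.0, effect)

    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    results = []
    for j, var in enumerate(matrix.columns):
        passed = bool(p_adj[j] < cfg.alpha_adj
                      and abs(effect[j]) >= cfg.effect_floor
                      and not constant[j])
        results.append(SelectionResult(
            variable=str(var),
            beta_group=float(beta[1, j]),
            effect_sd=float(effect[j]),
            p_raw=float(p_raw[j]),
            p_adj=float(p_adj[j]),
            passed_univariate=passed,
            note="constant variable" if constant[j] else None,
        ))
    return results


def correlation_prune(results: list[SelectionResult], matrix: pd.DataFrame,
                      cfg: SelectionConfig | None = None) -> list[SelectionResult]:
    """Finalize kept flags: greedy by descending |effect|, drop candidates
    correlated above ``prune_r`` (pooled Pearson on the log values) with any
    already-kept variable.  Ties in |effect| break alphabetically, so the
    result is invariant to input variable order.
    """
    cfg = cfg or SelectionConfig()
    by_var = {r.variable: r for r in results}
    candidates = [r for r in results if r.passed_univariate]
    for r in results:
        r.kept_after_prune = False
        r.pruned_by = None
    if not candidates:
        return results
    names = [r.variable for r in candidates]
    corr = matrix[names].corr().to_numpy()
    order = sorted(range(len(candidates)),
                   key=lambda i: (-abs(candidates[i].effect_sd), candidates[i].variable))
    kept: list[int] = []
    for i in order:
        blockers = [j for j in kept if abs(corr[i, j]) > cfg.prune_r]
        if blockers:
            worst = max(blockers, key=lambda j: abs(corr[i, j]))
            candidates[i].pruned_by = candidates[worst].variable
        else:
            kept.append(i)
            candidates[i].kept_after_prune = True
    # restore ties to the caller's objects (same instances; nothing to copy)
    return [by_var[r.variable] for r in results]


def selection_frame(results: list[SelectionResult]) -> pd.DataFrame:
    """Tabular view of a selection run."""
    return pd.DataFrame([r.__dict__ for r in results])
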
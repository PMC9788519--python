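"""Orthogonal projections to latent structures discriminant analysis.

A two-component model for a single binary response: one predictive
component (scores ``t_pred``, correlated with class) and one orthogonal
component (``t_orth``, class-uncorrelated systematic variation) in the
Trygg-Wold single-y orthogonal-filtering construction.  Classification
uses ``t_pred`` alone; the model is oriented so the case class sits at
positive ``t_pred``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocess import ScalingStats

__all__ = ["OPLSModel", "CVResult", "fit_oplsda", "project", "cross_validate"]

SCHEMA_VERSION = 1


@dataclass
class OPLSModel:
    """Weights, loadings and score statistics of a fitted model."""

    variables: list[str]
    w_pred: np.ndarray
    p_pred: np.ndarray
    w_orth: np.ndarray
    p_orth: np.ndarray
    b: float
    class_means_tpred: dict[str, float]
    hc_mean_tpred: float
    cutoff_tpred: float | None = None
    scaling: ScalingStats | None = None
    training_scores: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self, path) -> None:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "variables": self.variables,
            "w_pred": self.w_pred.tolist(),
            "p_pred": self.p_pred.tolist(),
            "w_orth": self.w_orth.tolist(),
            "p_orth": self.p_orth.tolist(),
            "b": self.b,
            "class_means_tpred": self.class_means_tpred,
            "hc_mean_tpred": self.hc_mean_tpred,
            "cutoff_tpred": self.cutoff_tpred,
            "scaling": self.scaling.to_dict() if self.scaling else None,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "OPLSModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            variables=doc["variables"],
            w_pred=np.asarray(doc["w_pred"]),
            p_pred=np.asarray(doc["p_pred"]),
            w_orth=np.asarray(doc["w_orth"]),
            p_orth=np.asarray(doc["p_orth"]),
            b=doc["b"],
            class_means_tpred=doc["class_means_tpred"],
            hc_mean_tpred=doc["hc_mean_tpred"],
            cutoff_tpred=doc["cutoff_tpred"],
            scaling=ScalingStats.from_dict(doc["scaling"]) if doc["scaling"] else None,
        )


@dataclass
class CVResult:
    """Out-of-fold predictive scores from repeated stratified CV."""

    oof_tpred: np.ndarray        # n_samples x n_repeats
    aggregate: np.ndarray        # per-sample mean over repeats
    y: np.ndarray
    fold_assignments: np.ndarray  # n_samples x n_repeats


def _as_matrix(Z) -> tuple[np.ndarray, list[str]]:
    if isinstance(Z, pd.DataFrame):
        return Z.to_numpy(dtype=float), [str(c) for c in Z.columns]
    Z = np.asarray(Z, dtype=float)
    return Z, [f"x{j}" for j in range(Z.shape[1])]


def fit_oplsda(Z, y, sample_ids=None, orthogonal: bool = True,
               scaling: ScalingStats | None = None) -> OPLSModel:
    """Fit the 1+1-component model on a standardized matrix.

    ``orthogonal=False`` skips the orthogonal filtering step, which reduces
    the model exactly to single-component PLS1 (used as an equivalence
    check, not in the pipeline).
    """
    X, variables = _as_matrix(Z)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise DataError(f"need exactly two classes, got {classes}")
    if not np.isfinite(X).all():
        raise DataError("matrix contains missing or non-finite values")
    if np.allclose(X.std(axis=0), 0):
        raise DataError("zero-variance matrix")
    yc = (y == classes.max()).astype(float)
    yc = yc - yc.mean()

    w = X.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise DataError("response is orthogonal to every variable")
    w /= nw
    t = X @ w
    p = X.T @ t / (t @ t)

    if orthogonal:
        w_orth = p - (w @ p) * w
        n_orth = np.linalg.norm(w_orth)
        if n_orth < 1e-12:
            # no structured orthogonal variation: fall back to a fixed unit
            # direction orthogonal to w so the invariants still hold
            e = np.zeros_like(w)
            e[int(np.argmin(np.abs(w)))] = 1.0
            w_orth = e - (w @ e) * w
            n_orth = np.linalg.norm(w_orth)
        w_orth /= n_orth
        t_orth = X @ w_orth
        tt_orth = t_orth @ t_orth
        p_orth = X.T @ t_orth / tt_orth if tt_orth > 0 else np.zeros_like(w)
        Xf = X - np.outer(t_orth, p_orth)
    else:
        w_orth = np.zeros_like(w)
        t_orth = np.zeros(len(X))
        p_orth = np.zeros_like(w)
        Xf = X

    w_pred = Xf.T @ yc
    w_pred /= np.linalg.norm(w_pred)
    t_pred = Xf @ w_pred
    p_pred = Xf.T @ t_pred / (t_pred @ t_pred)
    b = (t_pred @ yc) / (t_pred @ t_pred)

    case = y == classes.max()
    if t_pred[case].mean() < t_pred[~case].mean():
        w_pred, p_pred, t_pred, b = -w_pred, -p_pred, -t_pred, -b

    ids = list(sample_ids) if sample_ids is not None else list(range(len(y)))
    scores = pd.DataFrame({"sample_id": ids, "t_pred": t_pred, "t_orth": t_orth})
    return OPLSModel(
        variables=variables,
        w_pred=w_pred, p_pred=p_pred, w_orth=w_orth, p_orth=p_orth,
        b=float(b),
        class_means_tpred={"control": float(t_pred[~case].mean()),
                           "case": float(t_pred[case].mean())},
        hc_mean_tpred=float(t_pred[~case].mean()),
        scaling=scaling,
        training_scores=scores,
    )


def project(model: OPLSModel, Znew, sample_ids=None) -> pd.DataFrame:
    """Score new standardized rows: remove the orthogonal component, then
    apply the predictive weights.  Re-projecting the training matrix
    reproduces the training scores."""
    X, variables = _as_matrix(Znew)
    if isinstance(Znew, pd.DataFrame):
        missing = [v for v in model.variables if v not in variables]
        extra = [v for v in variables if v not in model.variables]
        if missing or extra:
            raise DataError(f"variable mismatch; missing={missing[:5]} extra={extra[:5]}")
        X = Znew[model.variables].to_numpy(dtype=float)
    elif X.shape[1] != len(model.variables):
        raise DataError(f"expected {len(model.variables)} variables, got {X.shape[1]}")
    t_orth = X @ model.w_orth
    Xf = X - np.outer(t_orth, model.p_orth)
    t_pred = Xf @ model.w_pred
    if sample_ids is None:
        sample_ids = (list(Znew.index) if isinstance(Znew, pd.DataFrame)
                      else list(range(len(X))))
    return pd.DataFrame({"sample_id": sample_ids, "t_pred": t_pred, "t_orth": t_orth})


def _stratified_folds(y: np.ndarray, folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold labels with near-equal class balance in every fold."""
    assignment = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def cross_validate(X, y, folds: int = 5, repeats: int = 10,
                   seed: int = 0) -> CVResult:
    """Repeated stratified cross-validation of the model.

    Scaling statistics and the model fit are computed inside each training
    split only; the held-out fold is standardized with the training fold's
    statistics and projected.  The per-sample aggregate score is the mean
    out-of-fold ``t_pred`` over repeats.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise DataError(f"need exactly two classes, got {classes}")
    if counts.min() < folds:
        raise DataError(f"smallest class ({counts.min()}) below fold count {folds}")
    n = len(y)
    oof = np.empty((n, repeats))
    assign = np.empty((n, repeats), dtype=int)
    for rep in range(repeats):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 211, rep])
        fold_of = _stratified_folds(y, folds, rng)
        assign[:, rep] = fold_of
        for f in range(folds):
            test = fold_of == f
            train = ~test
            mu = Xm[train].mean(axis=0)
            sd = Xm[train].std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)  # constant-in-fold columns: no-op
            Ztr = (Xm[train] - mu) / sd
            Zte = (Xm[test] - mu) / sd
            model = fit_oplsda(Ztr, y[train])
            oof[test, rep] = project(model, Zte)["t_pred"].to_numpy()
    return CVResult(oof_tpred=oof, aggregate=oof.mean(axis=1),
                    y=y, fold_assignments=assign)
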
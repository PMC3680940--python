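"""Percent-density mimic model and case-control risk scores.

Two statsmodels-style model classes:

* :class:`DensityMimic` — a lasso-penalized linear model of sqrt(percent
  density) on principal-component scores, reproducing a reference (reader)
  percent-density measurement.  ``fit`` selects lambda by repeated tenfold
  likelihood cross-validation unless one is supplied.  Predictions are made on
  the sqrt-PD scale, floored at 0, squared, and capped at 100.

* :class:`RiskScoreModel` — lasso-penalized logistic regression of
  case-control status on PCs (score 1), PCs plus an *unpenalized* PD term
  (score 2: the score is forced to be independent of PD), or PCs plus a
  *penalized* PD term (score 3).  The resulting score for an image is the sum
  of the nonzero PC coefficients times the image's PC values; the PD
  coefficient is never part of the score.

Both ``fit`` methods return Results objects carrying coefficients, lambda,
diagnostics and a ``summary()`` table.  The functional wrappers at the bottom
(`cv_lambda`, `fit_lasso`, `predict_pd`, `compute_score`) expose the same
operations without the class shells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lasso as _lasso
from .lasso import CVConfig, LassoFit

__all__ = ["DensityMimic", "DensityMimicResults", "RiskScoreModel",
           "RiskScoreResults", "CVConfig", "cv_lambda", "fit_lasso",
           "predict_pd", "compute_score", "load_model", "save_model"]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=np.float64)
    return pd.DataFrame(X, columns=[f"PC{i+1}" for i in range(X.shape[1])])


class DensityMimic:
    """Lasso model of sqrt(reference PD) on PC scores."""

    def __init__(self, pd_reference, pc_scores):
        self.pcs = _as_frame(pc_scores)
        y = np.asarray(pd_reference, dtype=np.float64).ravel()
        if len(y) != len(self.pcs):
            raise ValueError("pd_reference and pc_scores length mismatch")
        if np.any(y < 0) or np.any(y > 100):
            raise ValueError("percent density must lie in [0, 100]")
        self.endog_sqrt = np.sqrt(y)

    def fit(self, lam: float | None = None,
            cv_config: CVConfig | None = None) -> "DensityMimicResults":
        X = self.pcs.to_numpy(dtype=np.float64)
        cv_config = cv_config or CVConfig()
        if lam is None:
            lam = _lasso.cv_lambda(X, self.endog_sqrt, family="gaussian",
                                   cfg=cv_config)
        fit = _lasso.fit_penalized(X, self.endog_sqrt, lam, family="gaussian")
        return DensityMimicResults(model=self, fit=fit,
                                   columns=tuple(self.pcs.columns),
                                   cv_config=cv_config)


@dataclass
class DensityMimicResults:
    model: DensityMimic | None
    fit: LassoFit
    columns: tuple
    cv_config: CVConfig | None = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(np.r_[self.fit.intercept, self.fit.coef],
                         index=["intercept"] + list(self.columns))

    @property
    def lam(self) -> float:
        return self.fit.lam

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.fit.coef))

    def linear_predictor(self, pcs) -> np.ndarray:
        pcs = _as_frame(pcs)
        missing = [c for c in self.columns if c not in pcs.columns]
        if missing:
            raise KeyError(f"missing PC columns: {missing[:5]}")
        return self.fit.linear_predictor(
            pcs[list(self.columns)].to_numpy(dtype=np.float64))

    def predict(self, pcs) -> np.ndarray:
        """Percent density: linear predictor on the sqrt-PD scale, floored at
        0, squared, capped at 100."""
        eta = np.maximum(self.linear_predictor(pcs), 0.0)
        return np.minimum(eta ** 2, 100.0)

    def summary(self) -> str:
        lines = ["Density mimic model (lasso on sqrt PD)",
                 f"  lambda          : {self.lam:.6g}",
                 f"  nonzero PCs     : {self.n_nonzero} / {len(self.columns)}",
                 f"  intercept       : {self.fit.intercept:.4f}",
                 f"  converged       : {self.fit.converged}"]
        nz = [(c, v) for c, v in zip(self.columns, self.fit.coef) if v != 0]
        for c, v in nz[:15]:
            lines.append(f"    {c:<10s} {v:+.5f}")
        if len(nz) > 15:
            lines.append(f"    ... ({len(nz) - 15} more)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": "density_mimic", "family": "gaussian",
            "lambda": self.lam, "intercept": self.fit.intercept,
            "coef": dict(zip(self.columns, self.fit.coef.tolist())),
            "cv": None if self.cv_config is None else {
                "folds": self.cv_config.folds,
                "repeats": self.cv_config.repeats,
                "seed": self.cv_config.seed},
        }


class RiskScoreModel:
    """Lasso-penalized logistic model of case status; emits an image score.

    ``score_id`` 1: PCs only, all penalized.  2: PD forced in unpenalized.
    3: PD included in the penalty.  The image score always uses the PC
    coefficients only.
    """

    def __init__(self, status, pc_scores, pd_values=None, score_id: int = 1):
        if score_id not in (1, 2, 3):
            raise ValueError("score_id must be 1, 2 or 3")
        if score_id in (2, 3) and pd_values is None:
            raise ValueError(f"score {score_id} requires pd_values")
        self.score_id = score_id
        self.pcs = _as_frame(pc_scores)
        self.status = np.asarray(status, dtype=np.float64).ravel()
        if set(np.unique(self.status)) - {0.0, 1.0}:
            raise ValueError("status must be binary 0/1")
        self.pd_values = (None if pd_values is None
                          else np.asarray(pd_values, dtype=np.float64).ravel())

    def fit(self, lam: float | None = None,
            cv_config: CVConfig | None = None) -> "RiskScoreResults":
        cv_config = cv_config or CVConfig()
        Xp = self.pcs.to_numpy(dtype=np.float64)
        if self.score_id == 1:
            X = Xp
            penalized = np.ones(X.shape[1], dtype=bool)
            unpen_for_cv = None
        elif self.score_id == 2:
            X = np.hstack([self.pd_values[:, None], Xp])
            penalized = np.r_[False, np.ones(Xp.shape[1], bool)]
            unpen_for_cv = self.pd_values
        else:  # score 3: PD penalized along with the PCs
            X = np.hstack([self.pd_values[:, None], Xp])
            penalized = np.ones(X.shape[1], dtype=bool)
            unpen_for_cv = None
        if lam is None:
            if self.score_id == 2:
                lam = _lasso.cv_lambda(Xp, self.status, family="binomial",
                                       unpenalized=unpen_for_cv, cfg=cv_config)
            else:
                lam = _lasso.cv_lambda(X, self.status, family="binomial",
                                       cfg=cv_config)
        fit = _lasso.fit_penalized(X, self.status, lam, family="binomial",
                                   penalized=penalized)
        has_pd = self.score_id in (2, 3)
        cols = (("PD",) if has_pd else ()) + tuple(self.pcs.columns)
        return RiskScoreResults(model=self, fit=fit, columns=cols,
                                score_id=self.score_id, has_pd=has_pd,
                                cv_config=cv_config)


@dataclass
class RiskScoreResults:
    model: RiskScoreModel | None
    fit: LassoFit
    columns: tuple
    score_id: int
    has_pd: bool
    cv_config: CVConfig | None = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(np.r_[self.fit.intercept, self.fit.coef],
                         index=["intercept"] + list(self.columns))

    @property
    def pc_coef(self) -> pd.Series:
        coef = self.fit.coef[1:] if self.has_pd else self.fit.coef
        cols = self.columns[1:] if self.has_pd else self.columns
        return pd.Series(coef, index=list(cols))

    @property
    def n_nonzero_pcs(self) -> int:
        return int(np.count_nonzero(self.pc_coef.to_numpy()))

    def score(self, pcs) -> np.ndarray:
        """Sum of nonzero PC coefficients times PC values (PD excluded)."""
        pcs = _as_frame(pcs)
        coef = self.pc_coef
        missing = [c for c in coef.index if c not in pcs.columns]
        if missing:
            raise KeyError(f"missing PC columns: {missing[:5]}")
        return pcs[list(coef.index)].to_numpy(np.float64) @ coef.to_numpy()

    def summary(self) -> str:
        lines = [f"Risk score model (score {self.score_id}, penalized logistic)",
                 f"  lambda          : {self.fit.lam:.6g}",
                 f"  nonzero PCs     : {self.n_nonzero_pcs} / {len(self.pc_coef)}",
                 f"  PD in model     : "
                 f"{'unpenalized' if self.score_id == 2 else 'penalized' if self.score_id == 3 else 'absent'}",
                 f"  intercept       : {self.fit.intercept:.4f}"]
        if self.has_pd:
            lines.append(f"  PD coefficient  : {self.fit.coef[0]:+.5f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": "risk_score", "family": "binomial",
            "score_id": self.score_id, "lambda": self.fit.lam,
            "intercept": self.fit.intercept,
            "coef": dict(zip(self.columns, self.fit.coef.tolist())),
            "penalized": dict(zip(self.columns,
                                  self.fit.penalized.astype(bool).tolist())),
            "cv": None if self.cv_config is None else {
                "folds": self.cv_config.folds,
                "repeats": self.cv_config.repeats,
                "seed": self.cv_config.seed},
        }


# ---------------------------------------------------------------------------
# functional surface + serialization
# ---------------------------------------------------------------------------

def cv_lambda(X, y, family="gaussian", unpenalized=None, cfg=None) -> float:
    return _lasso.cv_lambda(X, y, family=family, unpenalized=unpenalized,
                            cfg=cfg)


def fit_lasso(X, y, family="gaussian", lam=0.0, unpenalized=None):
    """Fit at a fixed lambda; ``unpenalized`` columns (prepended) are excluded
    from the l1 term."""
    X = np.asarray(X, dtype=np.float64)
    if unpenalized is not None and np.size(unpenalized):
        U = np.asarray(unpenalized, dtype=np.float64)
        if U.ndim == 1:
            U = U[:, None]
        Xall = np.hstack([U, X])
        mask = np.r_[np.zeros(U.shape[1], bool), np.ones(X.shape[1], bool)]
        return _lasso.fit_penalized(Xall, y, lam, family=family, penalized=mask)
    return _lasso.fit_penalized(X, y, lam, family=family)


def predict_pd(results_or_fit, pcs) -> np.ndarray:
    """Percent density from a mimic model: sqrt-scale linear predictor,
    floored at 0, squared, capped at 100."""
    if isinstance(results_or_fit, DensityMimicResults):
        return results_or_fit.predict(pcs)
    eta = results_or_fit.linear_predictor(np.asarray(pcs, dtype=np.float64))
    return np.minimum(np.maximum(eta, 0.0) ** 2, 100.0)


def compute_score(results: RiskScoreResults, pcs) -> np.ndarray:
    return results.score(pcs)


def save_model(results, path) -> None:
    with open(path, "w") as fh:
        json.dump(results.to_dict(), fh, indent=1, sort_keys=True)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    cols = tuple(d["coef"].keys())
    if d["kind"] == "density_mimic":
        coef = np.array([d["coef"][c] for c in cols])
        fit = LassoFit(intercept=d["intercept"], coef=coef, lam=d["lambda"],
                       family="gaussian", penalized=np.ones(len(cols), bool),
                       n_iter=0, converged=True)
        return DensityMimicResults(model=None, fit=fit, columns=cols)
    has_pd = "PD" in cols
    if has_pd:   # serialization may have reordered keys; PD is always first
        cols = ("PD",) + tuple(c for c in cols if c != "PD")
    coef = np.array([d["coef"][c] for c in cols])
    pen = np.array([d["penalized"][c] for c in cols], dtype=bool)
    fit = LassoFit(intercept=d["intercept"], coef=coef, lam=d["lambda"],
                   family="binomial", penalized=pen, n_iter=0, converged=True)
    return RiskScoreResults(model=None, fit=fit, columns=cols,
                            score_id=int(d["score_id"]), has_pd=has_pd)
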
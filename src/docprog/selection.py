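"""Two-stage imaging feature selection.

Stage 1 is a univariate screen: keep every imaging feature whose Pearson
correlation with the follow-up CRS-R score is significant (two-sided,
uncorrected, alpha = 0.05 by default).

Stage 2 is competitive adaptive reweighted sampling coupled with PLS
regression (CARS-PLSR): over N Monte-Carlo runs the variable set is
shrunk along an exponentially decreasing retention schedule, variables
compete through weight-proportional resampling on |regression
coefficient|, and the subset with the smallest cross-validated RMSE wins.
The whole procedure is a pure function of (X, y, hyperparameters, seed).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from ._utils import spawn_seed
from .exceptions import ConfigurationError
from .model import cv_rmse, fit_plsr

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of one selection stage (filter or CARS)."""

    stage: str
    kept_indices: np.ndarray  # ordered indices into the input feature axis
    r: np.ndarray | None = None  # per-feature Pearson r (filter stage)
    p: np.ndarray | None = None  # per-feature two-sided p (filter stage)
    cars_history: list[dict] = field(default_factory=list)
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "stage": self.stage,
            "kept_indices": [int(i) for i in self.kept_indices],
            "r": None if self.r is None else [float(v) for v in self.r],
            "p": None if self.p is None else [float(v) for v in self.p],
            "cars_history": [
                {k: (v if not isinstance(v, np.ndarray) else [int(x) for x in v])
                 for k, v in rec.items()}
                for rec in self.cars_history
            ],
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def correlation_filter(
    features: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> SelectionResult:
    """Keep features significantly correlated with the response.

    Feature j survives iff the two-sided p-value of Pearson r(x_j, y) is
    below ``alpha``. Constant features get r = 0, p = 1 and never survive.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 4:
        raise ConfigurationError("need n >= 4 for the correlation filter")
    if y.std() == 0:
        raise ConfigurationError("response is constant")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    xnorm = np.linalg.norm(Xc, axis=0)
    ynorm = np.linalg.norm(yc)
    constant = xnorm == 0
    if constant.any():
        logger.info("correlation filter: %d constant features", constant.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ Xc) / (xnorm * ynorm)
    r[constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[constant] = 1.0
    kept = np.flatnonzero(p < alpha)
    return SelectionResult(stage="filter", kept_indices=kept, r=r, p=p)


def _retention_schedule(p: int, runs: int) -> np.ndarray:
    """Exponentially decreasing retained-count schedule: p at run 1, 2 at N."""
    if runs < 2:
        return np.array([max(2, p)])
    k = math.log(p / 2.0) / (runs - 1)
    a = (p / 2.0) ** (1.0 / (runs - 1))
    i = np.arange(1, runs + 1)
    counts = np.ceil(p * a * np.exp(-k * i) - 1e-9).astype(int)
    return np.clip(counts, 2, p)


def cars_plsr_select(
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 50,
    sample_fraction: float = 0.8,
    max_lv: int = 10,
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """CARS-PLSR variable subset selection.

    Per Monte-Carlo run *i* (i = 1..N): fit a PLS model on a random
    ``sample_fraction`` of the rows using the currently retained
    variables; rank variables by |coefficient|; keep the top
    ceil(p * a * exp(-k i)) (schedule calibrated so retention is p at run
    1 and 2 at run N); perform adaptive reweighted sampling (p draws with
    replacement, probability proportional to normalized |coefficient|) and
    retain the unique draw; record the K-fold cross-validated RMSE of a
    refit on the retained set. The variable set with minimal RMSECV wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ConfigurationError("CARS needs at least 2 variables")
    if n < cv_folds:
        raise ConfigurationError("need n >= cv_folds")
    if not (0 < sample_fraction <= 1):
        raise ConfigurationError("sample_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    # standardize once so |b| values are comparable across variables
    sds = X.std(axis=0, ddof=0)
    Z = (X - X.mean(axis=0)) / np.where(sds == 0, 1.0, sds)

    schedule = _retention_schedule(p, runs)
    retained = np.arange(p)
    history: list[dict] = []
    best_rmse, best_set = np.inf, retained.copy()
    n_sample = max(cv_folds, int(round(sample_fraction * n)))

    for i, target in enumerate(schedule, start=1):
        sub_rng = np.random.default_rng(spawn_seed(rng))
        rows = sub_rng.choice(n, size=min(n_sample, n), replace=False)
        lv = int(min(max_lv, len(retained), len(rows) - 1))
        coef, _ = fit_plsr(Z[np.ix_(rows, retained)], y[rows], lv)
        absb = np.abs(coef)
        if absb.sum() == 0:
            logger.info("CARS run %d: all-zero coefficients; stopping", i)
            break
        # enforced retention: top-|b| variables down the schedule
        keep_n = int(min(target, len(retained)))
        order = np.argsort(-absb)
        forced = order[:keep_n]
        w = absb[forced] / absb[forced].sum()
        # adaptive reweighted sampling: p draws with replacement
        draws = sub_rng.choice(len(forced), size=p, replace=True, p=w)
        new_local = np.unique(draws)
        retained = np.sort(retained[forced[new_local]])
        if len(retained) < 2:
            logger.info("CARS run %d: retained set collapsed; stopping", i)
            break
        lv_cv = int(min(max_lv, len(retained), n - 2))
        rmse = cv_rmse(Z[:, retained], y, lv_cv, folds=cv_folds)
        history.append(
            {"run": i, "n_retained": len(retained), "rmsecv": float(rmse),
             "indices": retained.copy()}
        )
        if rmse < best_rmse:
            best_rmse, best_set = rmse, retained.copy()

    if not history:
        logger.warning("CARS produced no evaluable subsets; returning all variables")
    return SelectionResult(
        stage="cars", kept_indices=best_set, cars_history=history, seed=seed
    )
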
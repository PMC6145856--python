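"""Prognostic PLS regression model.

The core estimator regresses the follow-up CRS-R total score (0-23, kept
on its natural scale) on z-scored predictors: a selected subset of the 253
imaging features plus age, duration of the disorder and two etiology
dummies (trauma as reference). A partial least squares (PLS1) fit with
three latent variables handles the collinearity among connectivity
features; predictor importance is assessed with sMC F-values (variance of
each predictor split into the part explained by the PLS prediction
direction and the residual); and a ROC-derived cutoff on the predicted
score turns the regression into a recovery / non-recovery classifier
(predicted score >= cutoff means recovery, defined as GOS >= 3).

Usage follows the Model / Results convention::

    model = PrognosticPLSModel.from_dataframe(table)
    res = model.fit(seed=0)
    print(res.summary())
    preds = res.predict(new_table)
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .exceptions import ConfigurationError, PipelineError
from .synthetic import CLINICAL_FEATURES

logger = logging.getLogger(__name__)

RECOVERY, NON_RECOVERY = "recovery", "non_recovery"


# --------------------------------------------------------------------------
# Low-level PLS machinery
# --------------------------------------------------------------------------

def fit_plsr(
    X: np.ndarray, y: np.ndarray, n_latent: int = 3
) -> tuple[np.ndarray, float]:
    """PLS1 regression; returns (coefficients, intercept).

    Predictions are ``intercept + X @ coefficients``. With ``n_latent``
    equal to the rank of the centered design this reproduces the
    least-squares solution. A constant response yields zero coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= n_latent:
        raise ConfigurationError("need n > n_latent observations")
    if y.std() == 0:
        return np.zeros(p), float(y[0])
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_latent > rank:
        warnings.warn(f"n_latent reduced from {n_latent} to rank {rank}")
        n_latent = max(1, rank)
    pls = PLSRegression(n_components=n_latent, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X, y)
    coef = np.asarray(pls.coef_, dtype=float)
    coef = coef.ravel() if coef.size == p else coef.reshape(-1)[:p]
    intercept = float(y.mean() - X.mean(axis=0) @ coef)
    return coef, intercept


def cv_rmse(
    X: np.ndarray, y: np.ndarray, n_latent: int, folds: int = 5
) -> float:
    """Deterministic K-fold cross-validated RMSE of a PLS fit."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < folds:
        raise ConfigurationError("folds must not exceed n")
    kf = KFold(n_splits=folds, shuffle=False)
    sq = np.empty(n)
    for train, test in kf.split(X):
        lv = min(n_latent, len(train) - 1, X.shape[1])
        coef, icpt = fit_plsr(X[train], y[train], lv)
        sq[test] = (y[test] - (icpt + X[test] @ coef)) ** 2
    return float(np.sqrt(sq.mean()))


def choose_n_latent(
    X: np.ndarray, y: np.ndarray, folds: int = 5, max_lv: int = 10
) -> int:
    """Number of latent variables minimizing CV RMSE; ties -> smallest."""
    if max_lv < 1:
        raise ConfigurationError("max_lv must be >= 1")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < folds:
        raise ConfigurationError("folds must not exceed n")
    upper = min(max_lv, p, n - 2)
    errors = [cv_rmse(X, y, lv, folds) for lv in range(1, upper + 1)]
    return int(np.argmin(errors)) + 1


def smc_importance(
    X: np.ndarray, y: np.ndarray, coefficients: np.ndarray
) -> np.ndarray:
    """sMC F-values: per-predictor variance split along the PLS direction.

    Each (centered) predictor x_j is projected onto the centered fitted
    values yhat = X @ b; F_j = SSR_j / (SSE_j / (n - 2)) with SSR the
    squared norm of the projection and SSE the residual. Predictors
    orthogonal to the prediction direction get F = 0; exactly collinear
    predictors get F = inf.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ConfigurationError("need n >= 3 for sMC")
    Xc = X - X.mean(axis=0)
    yhat = Xc @ np.asarray(coefficients, dtype=float)
    denom = float(yhat @ yhat)
    if denom <= 1e-30:
        logger.info("sMC: constant fitted values; all F set to 0")
        return np.zeros(X.shape[1])
    proj = (yhat @ Xc) / denom  # per-feature projection coefficient
    ssr = proj**2 * denom
    sse = (Xc**2).sum(axis=0) - ssr
    sse = np.maximum(sse, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(sse > 1e-30, ssr / (sse / (n - 2)), np.inf)
    f[ssr <= 1e-30] = 0.0
    return f


# --------------------------------------------------------------------------
# ROC cutoff
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    cutoff: float
    auc: float
    curve: pd.DataFrame  # columns: threshold, sensitivity, specificity


def roc_cutoff(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Optimal classification cutoff on the predicted-score ROC curve.

    Candidates are the midpoints between consecutive sorted unique scores
    plus +-inf; the winner maximizes sensitivity + specificity (Youden),
    with ties broken toward higher specificity, then the lower threshold.
    AUC is the trapezoidal area over all thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ConfigurationError("roc_cutoff requires both classes present")
    pos, neg = scores[labels], scores[~labels]
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = (pos[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] < candidates[:, None]).mean(axis=1)
    youden = sens + spec
    best = np.flatnonzero(youden == youden.max())
    best = best[np.lexsort((candidates[best], -spec[best]))[0]]
    # AUC: Mann-Whitney with tie correction (equals the trapezoid over the
    # full step curve).
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    curve = pd.DataFrame(
        {"threshold": candidates, "sensitivity": sens, "specificity": spec}
    )
    return RocResult(cutoff=float(candidates[best]), auc=float(auc), curve=curve)


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for the full fit: selection, PLS and cutoff."""

    filter_alpha: float = 0.05
    use_filter: bool = True
    use_cars: bool = True
    cars_runs: int = 50
    cars_sample_fraction: float = 0.8
    cv_folds: int = 5
    n_latent: int | str = 3  # or "cv"
    max_lv: int = 10
    domain: str = "combined"  # combined | imaging | clinical


def imaging_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(("resemblance::", "fc::"))]


def clinical_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in CLINICAL_FEATURES if c in df.columns]


class PrognosticPLSModel:
    """Multidomain prognostic model builder.

    Parameters
    ----------
    X : DataFrame
        Feature table; imaging columns are named ``resemblance::*`` /
        ``fc::*``, clinical columns are ``age``, ``duration``,
        ``etiology_stroke``, ``etiology_anoxia``.
    y : array-like
        CRS-R total score at follow-up (response, natural 0-23 scale).
    labels : array-like of bool, optional
        Recovery labels (GOS >= 3); required to derive the cutoff.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[float],
        labels: Sequence[bool] | None = None,
        config: ModelConfig | None = None,
    ) -> None:
        self.X = X.copy()
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != len(X):
            raise ConfigurationError("X and y must have the same length")
        self.labels = None if labels is None else np.asarray(labels, dtype=bool)
        self.config = config or ModelConfig()

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        response: str = "crsr_t1",
        label: str = "gos_t1",
        config: ModelConfig | None = None,
    ) -> "PrognosticPLSModel":
        """Build from a cohort table carrying features and outcomes."""
        rows = table
        if "group" in table.columns:
            rows = table[table["group"] == "patient"]
        rows = rows[rows[response].notna()]
        y = rows[response].to_numpy(dtype=float)
        labels = None
        if label in rows.columns and rows[label].notna().all():
            labels = rows[label].to_numpy(dtype=float) >= 3
        feats = imaging_columns(rows) + clinical_columns(rows)
        return cls(rows[feats], y, labels=labels, config=config)

    # -- fitting -----------------------------------------------------------
    def fit(self, seed: int = 0) -> "PrognosticPLSResults":
        from . import selection as sel  # local import avoids a cycle

        cfg = self.config
        img_cols = imaging_columns(self.X)
        clin_cols = clinical_columns(self.X)
        if cfg.domain == "clinical":
            img_cols = []
        selection_info: dict = {}
        selected_img = list(img_cols)
        if img_cols and cfg.use_filter:
            filt = sel.correlation_filter(
                self.X[img_cols].to_numpy(dtype=float), self.y, alpha=cfg.filter_alpha
            )
            selected_img = [img_cols[i] for i in filt.kept_indices]
            selection_info["filter"] = {
                "n_kept": len(selected_img),
                "alpha": cfg.filter_alpha,
            }
        if len(selected_img) >= 2 and cfg.use_cars:
            cars = sel.cars_plsr_select(
                self.X[selected_img].to_numpy(dtype=float),
                self.y,
                runs=cfg.cars_runs,
                sample_fraction=cfg.cars_sample_fraction,
                cv_folds=min(cfg.cv_folds, len(self.y)),
                max_lv=cfg.max_lv,
                seed=seed,
            )
            selected_img = [selected_img[i] for i in cars.kept_indices]
            selection_info["cars"] = {
                "n_kept": len(selected_img),
                "runs": cfg.cars_runs,
            }
        feature_names = (
            selected_img + clin_cols if cfg.domain != "imaging" else selected_img
        )
        if not feature_names:
            raise PipelineError("no features survived selection")

        Xmat = self.X[feature_names].to_numpy(dtype=float)
        means = Xmat.mean(axis=0)
        sds = Xmat.std(axis=0, ddof=0)
        degenerate = sds == 0
        if degenerate.any():
            logger.info("constant predictors standardized with sd=1: %s",
                        [feature_names[i] for i in np.nonzero(degenerate)[0]])
            sds = np.where(degenerate, 1.0, sds)
        Z = (Xmat - means) / sds

        n_latent = cfg.n_latent
        if n_latent == "cv":
            n_latent = choose_n_latent(
                Z, self.y, folds=min(cfg.cv_folds, len(self.y)), max_lv=cfg.max_lv
            )
        n_latent = int(min(n_latent, Z.shape[1], len(self.y) - 1))
        coef, intercept = fit_plsr(Z, self.y, n_latent)
        smc = smc_importance(Z, self.y, coef)

        scores = intercept + Z @ coef
        ss_res = float(((self.y - scores) ** 2).sum())
        ss_tot = float(((self.y - self.y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

        cutoff = auc = None
        roc = None
        if self.labels is not None and 0 < self.labels.sum() < len(self.labels):
            roc = roc_cutoff(scores, self.labels)
            cutoff, auc = roc.cutoff, roc.auc

        return PrognosticPLSResults(
            model=self,
            feature_names=list(feature_names),
            imaging_feature_names=list(selected_img),
            train_means=means,
            train_sds=sds,
            n_latent=n_latent,
            coefficients=coef,
            intercept=intercept,
            cutoff=cutoff,
            auc=auc,
            smc_f=smc,
            rsquared=r2,
            fitted_scores=scores,
            selection_info=selection_info,
            roc=roc,
            seed=seed,
        )


@dataclass
class PrognosticPLSResults:
    """Fitted prognostic model: coefficients, importance, cutoff, scores."""

    model: PrognosticPLSModel | None
    feature_names: list[str]
    imaging_feature_names: list[str]
    train_means: np.ndarray
    train_sds: np.ndarray
    n_latent: int
    coefficients: np.ndarray
    intercept: float
    cutoff: float | None
    auc: float | None
    smc_f: np.ndarray
    rsquared: float
    fitted_scores: np.ndarray | None = None
    selection_info: dict = field(default_factory=dict)
    roc: RocResult | None = None
    seed: int = 0

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.feature_names, name="coef")

    @property
    def importance(self) -> pd.Series:
        return pd.Series(self.smc_f, index=self.feature_names, name="smc_f")

    # -- prediction --------------------------------------------------------
    def predict(self, table: pd.DataFrame) -> pd.DataFrame:
        """Score new subjects; returns id, score, imaging subscore, label."""
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise ConfigurationError(f"missing features: {missing}")
        X = table[self.feature_names].to_numpy(dtype=float)
        Z = (X - self.train_means) / self.train_sds
        scores = self.intercept + Z @ self.coefficients
        img_idx = [
            i for i, nm in enumerate(self.feature_names)
            if nm in self.imaging_feature_names
        ]
        img_sub = Z[:, img_idx] @ self.coefficients[img_idx]
        out = pd.DataFrame(
            {
                "predicted_score": scores,
                "imaging_subscore": img_sub,
            },
            index=table.index,
        )
        if self.cutoff is not None:
            out["label"] = np.where(scores >= self.cutoff, RECOVERY, NON_RECOVERY)
        return out

    def predict_labels(self, table: pd.DataFrame) -> np.ndarray:
        if self.cutoff is None:
            raise PipelineError("model has no classification cutoff")
        preds = self.predict(table)
        return (preds["label"] == RECOVERY).to_numpy()

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Prognostic PLS regression results",
            "=" * 46,
            f"n latent variables: {self.n_latent}",
            f"features: {len(self.feature_names)} "
            f"({len(self.imaging_feature_names)} imaging)",
            f"apparent R^2: {self.rsquared:.3f}",
        ]
        if self.auc is not None:
            lines.append(f"training AUC: {self.auc:.3f}  cutoff: {self.cutoff:.2f}")
        lines.append("-" * 46)
        lines.append(f"{'feature':<34}{'coef':>12}{'sMC F':>12}")
        order = np.argsort(-np.nan_to_num(self.smc_f, posinf=1e300))
        for i in order:
            lines.append(
                f"{self.feature_names[i]:<34}"
                f"{self.coefficients[i]:>12.4f}{self.smc_f[i]:>12.2f}"
            )
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema": "docprog.model/1",
            "feature_names": self.feature_names,
            "imaging_feature_names": self.imaging_feature_names,
            "train_means": self.train_means.tolist(),
            "train_sds": self.train_sds.tolist(),
            "n_latent": self.n_latent,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "auc": self.auc,
            "smc_f": [
                None if not np.isfinite(v) else float(v) for v in self.smc_f
            ],
            "rsquared": self.rsquared,
            "selection_info": self.selection_info,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PrognosticPLSResults":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        smc = np.array(
            [np.inf if v is None else v for v in d["smc_f"]], dtype=float
        )
        return cls(
            model=None,
            feature_names=d["feature_names"],
            imaging_feature_names=d["imaging_feature_names"],
            train_means=np.array(d["train_means"]),
            train_sds=np.array(d["train_sds"]),
            n_latent=d["n_latent"],
            coefficients=np.array(d["coefficients"]),
            intercept=d["intercept"],
            cutoff=d["cutoff"],
            auc=d["auc"],
            smc_f=smc,
            rsquared=d["rsquared"],
            selection_info=d.get("selection_info", {}),
            seed=d.get("seed", 0),
        )
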
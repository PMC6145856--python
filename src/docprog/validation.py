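"""Internal and external validation machinery.

* confusion-matrix metrics (accuracy, sensitivity, specificity, PPV, NPV, F1);
* optimism-corrected bootstrap of the apparent R^2 with feature selection
  re-run inside every replicate (the classic guard against
  selection-induced optimism);
* out-of-bag (OOB) classification: per held-out subject, a majority vote
  over bootstrap models trained on the remaining rows;
* permutation tests of pipeline-level association;
* Bland-Altman agreement between predicted and observed scores;
* the three-way comparison of clinical-only, imaging-only and combined
  models via bootstrap accuracy distributions, repeated-measures ANOVA,
  paired t-tests and the root-mean-square standardized effect (psi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import spawn_seed
from .exceptions import ConfigurationError, PipelineError
from .model import ModelConfig, PrognosticPLSModel, PrognosticPLSResults

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Confusion metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(
        cls, predicted: Sequence[bool], actual: Sequence[bool]
    ) -> "ConfusionCounts":
        p = np.asarray(predicted, dtype=bool)
        a = np.asarray(actual, dtype=bool)
        return cls(
            tp=int((p & a).sum()),
            fp=int((p & ~a).sum()),
            tn=int((~p & ~a).sum()),
            fn=int((~p & a).sum()),
        )


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Standard rates; undefined rates (zero denominator) are None."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    n = tp + fp + tn + fn

    def _rate(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "accuracy": _rate(tp + tn, n),
        "sensitivity": _rate(tp, tp + fn),
        "specificity": _rate(tn, tn + fp),
        "ppv": _rate(tp, tp + fp),
        "npv": _rate(tn, tn + fn),
        "f1": _rate(2 * tp, 2 * tp + fp + fn),
    }


# --------------------------------------------------------------------------
# Internal validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimismReport:
    apparent_r2: float
    optimism: float
    corrected_r2: float
    b_effective: int
    b_requested: int
    negative_optimism: bool

    def as_dict(self) -> dict:
        return {
            "apparent_r2": self.apparent_r2,
            "optimism": self.optimism,
            "corrected_r2": self.corrected_r2,
            "b_effective": self.b_effective,
            "b_requested": self.b_requested,
            "negative_optimism": self.negative_optimism,
        }


def _fit_on(table: pd.DataFrame, config: ModelConfig, seed: int) -> PrognosticPLSResults:
    model = PrognosticPLSModel.from_dataframe(table, config=config)
    return model.fit(seed=seed)


def _r2(results: PrognosticPLSResults, table: pd.DataFrame, response: str = "crsr_t1") -> float:
    rows = table[table[response].notna()] if response in table else table
    y = rows[response].to_numpy(dtype=float)
    pred = results.predict(rows)["predicted_score"].to_numpy()
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(((y - pred) ** 2).sum()) / ss_tot


def optimism_bootstrap(
    table: pd.DataFrame,
    config: ModelConfig | None = None,
    B: int = 1000,
    seed: int = 0,
) -> OptimismReport:
    """Optimism-corrected apparent R^2.

    Each replicate resamples the training rows with replacement, re-runs
    the full pipeline (correlation filter + CARS + PLS) on the resample,
    and scores that model on both the resample and the original table;
    the mean difference of the two R^2 values is the optimism, subtracted
    from the apparent R^2 of the full-data fit.
    """
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    patients = table[table["group"] == "patient"] if "group" in table else table
    apparent_fit = _fit_on(patients, config, seed=spawn_seed(rng))
    apparent = _r2(apparent_fit, patients)
    n = len(patients)
    optimisms = []
    for b in range(B):
        sub = spawn_seed(rng)
        idx = np.random.default_rng(sub).integers(0, n, size=n)
        boot = patients.iloc[idx].reset_index(drop=True)
        if boot["crsr_t1"].nunique() < 2:
            logger.info("replicate %d skipped: degenerate response", b)
            continue
        try:
            fit_b = _fit_on(boot, config, seed=sub)
        except PipelineError:
            logger.info("replicate %d skipped: no features survived", b)
            continue
        optimisms.append(_r2(fit_b, boot) - _r2(fit_b, patients))
    if not optimisms:
        raise PipelineError("no usable bootstrap replicates")
    optimism = float(np.mean(optimisms))
    return OptimismReport(
        apparent_r2=float(apparent),
        optimism=optimism,
        corrected_r2=float(apparent - optimism),
        b_effective=len(optimisms),
        b_requested=B,
        negative_optimism=optimism < 0,
    )


def oob_accuracy(
    table: pd.DataFrame,
    config: ModelConfig | None = None,
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Out-of-bag classification estimate.

    For each subject i, B bootstrap models (full pipeline, cutoff
    included) are trained on resamples of the remaining n-1 rows and vote
    recovery / non-recovery for subject i; the majority label (ties ->
    non-recovery, the conservative call) is compared with the GOS truth.
    """
    config = config or ModelConfig()
    patients = table[table["group"] == "patient"] if "group" in table else table
    n = len(patients)
    if n < 10:
        raise ConfigurationError("need at least 10 subjects for OOB estimation")
    truth = patients["gos_t1"].to_numpy(dtype=float) >= 3
    rng = np.random.default_rng(seed)
    votes_for = np.zeros(n)
    votes_total = np.zeros(n)
    for i in range(n):
        rest = patients.drop(patients.index[i])
        row_i = patients.iloc[[i]]
        for b in range(B):
            sub = spawn_seed(rng)
            idx = np.random.default_rng(sub).integers(0, n - 1, size=n - 1)
            boot = rest.iloc[idx].reset_index(drop=True)
            labels_b = boot["gos_t1"].to_numpy(dtype=float) >= 3
            if labels_b.all() or not labels_b.any() or boot["crsr_t1"].nunique() < 2:
                continue  # degenerate resample: this vote abstains
            try:
                fit_b = _fit_on(boot, config, seed=sub)
                pred = bool(fit_b.predict_labels(row_i)[0])
            except (PipelineError, ConfigurationError):
                continue
            votes_total[i] += 1
            votes_for[i] += pred
    predicted = votes_for > votes_total / 2.0  # ties -> non-recovery
    counts = ConfusionCounts.from_predictions(predicted, truth)
    out = confusion_metrics(counts)
    out["counts"] = counts
    out["votes_cast"] = votes_total.sum()
    return out


def permutation_test(
    statistic_fn: Callable[[pd.DataFrame, np.ndarray], float],
    table: pd.DataFrame,
    y: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """p = (1 + #{permuted >= observed}) / (1 + B), permuting the response.

    ``statistic_fn(table, y)`` must recompute the statistic from scratch
    (feature selection included) so the permutation reflects the whole
    pipeline.
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    observed = float(statistic_fn(table, y))
    count = 0
    permuted = np.empty(B)
    for b in range(B):
        perm = np.random.default_rng(spawn_seed(rng)).permutation(y)
        permuted[b] = statistic_fn(table, perm)
        count += permuted[b] >= observed
    p = (1 + count) / (1 + B)
    return {"observed": observed, "p": float(p), "permuted": permuted}


def bland_altman(predicted: np.ndarray, observed: np.ndarray) -> dict:
    """Agreement via differences d = predicted - observed."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed) or len(predicted) < 3:
        raise ConfigurationError("need equal-length arrays with n >= 3")
    d = predicted - observed
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    note = None
    if sd == 0:
        p = 1.0
        note = "zero-variance differences; t-test degenerate"
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return {
        "mean_diff": mean_diff,
        "lower_limit": mean_diff - 1.96 * sd,
        "upper_limit": mean_diff + 1.96 * sd,
        "t_test_p": p,
        "note": note,
    }


# --------------------------------------------------------------------------
# Single-domain vs combination comparison
# --------------------------------------------------------------------------

def _accuracy(results: PrognosticPLSResults, table: pd.DataFrame) -> float:
    truth = table["gos_t1"].to_numpy(dtype=float) >= 3
    pred = results.predict_labels(table)
    return float((pred == truth).mean())


def _rm_anova(acc: np.ndarray) -> float:
    """One-way repeated-measures ANOVA p across models (columns)."""
    n, k = acc.shape
    grand = acc.mean()
    ss_subj = k * ((acc.mean(axis=1) - grand) ** 2).sum()
    ss_treat = n * ((acc.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((acc - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_treat
    df_treat = k - 1
    df_err = (k - 1) * (n - 1)
    if ss_err <= 0 or df_err <= 0:
        return 1.0 if ss_treat <= 1e-15 else 0.0
    f = (ss_treat / df_treat) / (ss_err / df_err)
    return float(stats.f.sf(f, df_treat, df_err))


def _psi(a: np.ndarray, b: np.ndarray) -> float:
    """Signed root-mean-square standardized effect between two paired
    accuracy distributions: sign(mean diff) * RMS((a - b)/sd_pooled)."""
    d = a - b
    sd_pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if sd_pooled == 0:
        return 0.0
    rms = float(np.sqrt(np.mean((d / sd_pooled) ** 2)))
    return float(np.sign(d.mean()) * rms) if d.mean() != 0 else 0.0


DOMAINS = ("combined", "imaging", "clinical")


def compare_models(
    train_table: pd.DataFrame,
    test_tables: Mapping[str, pd.DataFrame],
    config: ModelConfig | None = None,
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Bootstrap accuracy distributions for the three feature domains.

    Per replicate, the training rows are resampled with replacement and a
    clinical-only, an imaging-only and a combined model are fitted (full
    selection pipeline each); each model's classification accuracy is
    recorded on every test table. Returns, per test table: mean +- sd per
    domain, a repeated-measures ANOVA p across the three domains, pairwise
    paired-t p-values and the psi effect size per pair.
    """
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    patients = (
        train_table[train_table["group"] == "patient"]
        if "group" in train_table
        else train_table
    )
    n = len(patients)
    acc: dict[str, dict[str, list[float]]] = {
        name: {d: [] for d in DOMAINS} for name in test_tables
    }
    for b in range(B):
        sub = spawn_seed(rng)
        idx = np.random.default_rng(sub).integers(0, n, size=n)
        boot = patients.iloc[idx].reset_index(drop=True)
        labels_b = boot["gos_t1"].to_numpy(dtype=float) >= 3
        if labels_b.all() or not labels_b.any() or boot["crsr_t1"].nunique() < 2:
            continue
        fits = {}
        try:
            for domain in DOMAINS:
                fits[domain] = _fit_on(
                    boot, replace(config, domain=domain), seed=sub
                )
        except (PipelineError, ConfigurationError):
            logger.info("replicate %d excluded: a domain produced no model", b)
            continue
        for name, tab in test_tables.items():
            for domain in DOMAINS:
                acc[name][domain].append(_accuracy(fits[domain], tab))

    report: dict = {"B_effective": None}
    for name in test_tables:
        mat = np.column_stack([np.asarray(acc[name][d]) for d in DOMAINS])
        report["B_effective"] = mat.shape[0]
        entry: dict = {"domains": {}}
        for j, d in enumerate(DOMAINS):
            entry["domains"][d] = {
                "mean": float(mat[:, j].mean()),
                "sd": float(mat[:, j].std(ddof=1)),
            }
        entry["anova_p"] = _rm_anova(mat)
        entry["pairwise"] = {}
        for j1 in range(len(DOMAINS)):
            for j2 in range(j1 + 1, len(DOMAINS)):
                a, c = mat[:, j1], mat[:, j2]
                key = f"{DOMAINS[j1]}_vs_{DOMAINS[j2]}"
                if np.allclose(a, c):
                    t_p = 1.0
                else:
                    t_p = float(stats.ttest_rel(a, c).pvalue)
                entry["pairwise"][key] = {"paired_t_p": t_p, "psi": _psi(a, c)}
        entry["accuracies"] = {d: acc[name][d] for d in DOMAINS}
        report[name] = entry
    return report
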
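"""Risk models and survival evaluation statistics.

Covers the whole evaluation protocol used around a prognostic gene
signature: multivariable Cox fitting over the signature genes, linear risk
scoring, the pairwise concordance index C = K/M over censoring-valid pairs,
median-split risk stratification with hazard ratio / Kaplan-Meier /
log-rank readouts, and event-stratified k-fold cross-validated C-index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numba
import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.model_selection import StratifiedKFold

from ._coxph import cox_newton
from .exceptions import ConvergenceError, ValidationError
from .io import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["RiskModel", "ConcordanceResult", "StratificationResult", "KFoldResult",
           "fit_risk_model", "predict_risk", "concordance_index",
           "stratify_and_test", "kfold_cindex"]


@dataclass
class RiskModel:
    """Cox proportional-hazards risk model over a gene signature.

    The risk score of a sample is the linear predictor sum_g beta_g * x_g;
    higher scores mean higher predicted hazard.
    """

    genes: list[str]
    coef: np.ndarray
    n: int
    n_events: int
    converged: bool
    se: np.ndarray | None = None
    dropped_genes: list[str] = field(default_factory=list)


@dataclass
class ConcordanceResult:
    """K concordant pairs out of M censoring-valid pairs; C-index = K/M."""

    concordant: int
    valid: int

    @property
    def c_index(self) -> float:
        return self.concordant / self.valid


@dataclass
class StratificationResult:
    groups: pd.Series                      # sample -> "high" / "low"
    hazard_ratio: float | None             # exp(beta) of the group indicator
    hr_ci: tuple[float, float] | None      # Wald 95% CI
    logrank_p: float
    km_curves: dict[str, pd.DataFrame]     # group -> columns time, survival
    group_sizes: dict[str, int]
    events_per_group: dict[str, int]


@dataclass
class KFoldResult:
    mean: float
    per_fold: list[float]
    fold_of_sample: pd.Series              # sample -> fold id


def _align(expr: ExpressionMatrix, genes: Sequence[str], clinical: ClinicalTable
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Samples x genes design matrix aligned to the clinical table's samples."""
    missing = [g for g in genes if g not in expr.genes]
    if missing:
        raise ValidationError(f"signature genes absent from expression matrix: {missing}")
    samples = [s for s in clinical.samples if s in expr.samples]
    if len(samples) < len(clinical.samples):
        raise ValidationError("clinical samples absent from expression matrix")
    sub = expr.subset(genes=list(genes), samples=samples)
    clin = clinical.subset(samples)
    return sub.values.T.copy(), clin.time, clin.event, samples


def fit_risk_model(expr: ExpressionMatrix, genes: Sequence[str],
                   clinical: ClinicalTable) -> RiskModel:
    """Multivariable Cox partial-likelihood fit over the signature genes.

    Zero-variance genes are dropped with a warning before fitting; ties in
    survival time use the Efron approximation.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("empty gene signature")
    X, time, event, _ = _align(expr, genes, clinical)
    if event.sum() < 2:
        raise ValidationError(f"need at least 2 events, found {int(event.sum())}")
    keep = X.std(axis=0) > 0
    dropped = [g for g, k in zip(genes, keep) if not k]
    if dropped:
        logger.warning("dropping zero-variance genes: %s", dropped)
        genes = [g for g, k in zip(genes, keep) if k]
        X = X[:, keep]
    if not genes:
        raise ValidationError("all signature genes have zero variance")
    fit = cox_newton(X, time, event)
    if not fit.converged:
        raise ConvergenceError(
            "Cox fit did not converge", {"n_iter": fit.n_iter, "loglik": fit.loglik,
                                         "beta": fit.beta.tolist()})
    return RiskModel(genes, fit.beta, fit.n, fit.n_events, fit.converged,
                     se=fit.se, dropped_genes=dropped)


def predict_risk(model: RiskModel, expr: ExpressionMatrix) -> pd.Series:
    """Linear-predictor risk score per sample."""
    missing = [g for g in model.genes if g not in expr.genes]
    if missing:
        raise ValidationError(f"model genes absent from expression matrix: {missing}")
    sub = expr.subset(genes=model.genes)
    return pd.Series(sub.values.T @ model.coef, index=sub.samples, name="risk")


def concordance_index(time: np.ndarray, event: np.ndarray,
                      score: np.ndarray) -> ConcordanceResult:
    """Censoring-aware concordance C = K/M.

    A pair is valid when the two times differ and the sample with the
    shorter time experienced the event (Harrell's orderable pairs); a valid
    pair is concordant when the shorter-lived sample has the strictly
    higher score. Tied scores count in M but not in K.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    score = np.asarray(score, dtype=float)
    n = len(time)
    if not (len(event) == len(score) == n):
        raise ValidationError("time, event and score must have equal length")
    if n < 2:
        raise ValidationError("need at least 2 samples")
    if n > 3000:  # O(n log n) path for large cohorts
        k, m = _concordance_fenwick(time, event, score)
        if m == 0:
            raise ValidationError("no censoring-valid comparable pairs")
        return ConcordanceResult(int(k), int(m))
    iu, ju = np.triu_indices(n, k=1)
    dt = time[iu] - time[ju]
    # shorter-lived member of each pair and its event status
    first_is_shorter = dt < 0
    short_event = np.where(first_is_shorter, event[iu], event[ju])
    valid = (dt != 0) & (short_event == 1)
    short_score = np.where(first_is_shorter, score[iu], score[ju])
    long_score = np.where(first_is_shorter, score[ju], score[iu])
    concordant = valid & (short_score > long_score)
    m = int(valid.sum())
    if m == 0:
        raise ValidationError("no censoring-valid comparable pairs")
    return ConcordanceResult(int(concordant.sum()), m)


@numba.njit(cache=False)
def _concordance_fenwick(time, event, score):  # pragma: no cover - via concordance_index
    """K and M counted with a Fenwick tree over score ranks, O(n log n)."""
    n = len(time)
    order = np.argsort(time, kind="mergesort")
    uniq = np.unique(score)
    rank = np.searchsorted(uniq, score) + 1  # 1-based ranks
    size = len(uniq)
    tree = np.zeros(size + 1, dtype=np.int64)
    k_count = 0
    m_count = 0
    inserted = 0
    hi = n  # walk tied-time groups from the latest time backwards
    while hi > 0:
        lo = hi - 1
        while lo > 0 and time[order[lo - 1]] == time[order[hi - 1]]:
            lo -= 1
        for p in range(lo, hi):  # samples in this group vs strictly later times
            i = order[p]
            if event[i] == 1:
                m_count += inserted
                r = rank[i] - 1  # count inserted scores strictly below score[i]
                while r > 0:
                    k_count += tree[r]
                    r -= r & (-r)
        for p in range(lo, hi):
            r = rank[order[p]]
            while r <= size:
                tree[r] += 1
                r += r & (-r)
            inserted += 1
        hi = lo
    return k_count, m_count


def stratify_and_test(score: pd.Series, clinical: ClinicalTable) -> StratificationResult:
    """Median-split risk stratification with HR, KM curves and log-rank test.

    High-risk = risk score strictly greater than the cohort median (samples
    at the median fall to low-risk). The hazard ratio is exp(beta) from a
    univariate Cox fit on the group indicator, with Wald 95% CI; a group
    with zero events makes the HR non-estimable but KM and log-rank are
    still reported.
    """
    clin = clinical.subset(list(score.index))
    time, event = clin.time, clin.event
    if len(score) < 10:
        raise ValidationError("need at least 10 samples for stratification")
    med = float(np.median(score.to_numpy()))
    high = score.to_numpy() > med
    if high.sum() == 0 or high.sum() == len(score):
        raise ValidationError("median split is degenerate (all scores on one side)")
    groups = pd.Series(np.where(high, "high", "low"), index=score.index, name="group")

    events_per_group = {"high": int(event[high].sum()), "low": int(event[~high].sum())}
    hr = hr_ci = None
    if min(events_per_group.values()) > 0:
        fit = cox_newton(high.astype(float)[:, None], time, event)
        if fit.converged:
            beta, se = float(fit.beta[0]), float(fit.se[0])
            hr = float(np.exp(beta))
            hr_ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
        else:
            logger.warning("group Cox fit did not converge; HR not reported")
    else:
        logger.warning("a risk group has zero events; HR non-estimable")

    lr = logrank_test(time[high], time[~high], event[high], event[~high])
    km_curves = {}
    for name, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        km_curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    return StratificationResult(
        groups=groups, hazard_ratio=hr, hr_ci=hr_ci,
        logrank_p=float(lr.p_value), km_curves=km_curves,
        group_sizes={"high": int(high.sum()), "low": int((~high).sum())},
        events_per_group=events_per_group,
    )


def _stratified_folds(event: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Event-stratified fold test-index sets, deterministic given seed."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(event)), event)]


def _cv_cindex(X: np.ndarray, time: np.ndarray, event: np.ndarray,
               fold_tests: list[np.ndarray]) -> tuple[float, list[float]]:
    """Mean k-fold C-index of a design matrix; empty design scores the 0.5 baseline."""
    per_fold: list[float] = []
    n = len(time)
    all_idx = np.arange(n)
    for test in fold_tests:
        if X.shape[1] == 0:
            per_fold.append(0.5)
            continue
        train = np.setdiff1d(all_idx, test, assume_unique=True)
        Xtr = X[train]
        keep = Xtr.std(axis=0) > 0
        if not keep.any():
            per_fold.append(0.5)
            continue
        fit = cox_newton(Xtr[:, keep], time[train], event[train])
        if not fit.converged:
            raise ConvergenceError("Cox fit failed in CV fold")
        scores = X[np.ix_(test, np.flatnonzero(keep))] @ fit.beta
        try:
            res = concordance_index(time[test], event[test], scores)
        except ValidationError:
            logger.warning("CV fold without comparable pairs skipped")
            continue
        per_fold.append(res.c_index)
    if not per_fold:
        raise ValidationError("no CV fold produced a valid C-index")
    return float(np.mean(per_fold)), per_fold


def kfold_cindex(expr: ExpressionMatrix, genes: Sequence[str],
                 clinical: ClinicalTable, folds: int = 10, seed: int = 0
                 ) -> KFoldResult:
    """Event-stratified k-fold cross-validated C-index of a gene signature.

    Each sample lands in exactly one test fold. Per fold, a Cox model is fit
    on the training split and the concordance of its risk scores is measured
    on the held-out split; an empty signature scores the 0.5 baseline.
    """
    if folds < 2:
        raise ValidationError("need at least 2 folds")
    genes = list(genes)
    if genes:
        X, time, event, samples = _align(expr, genes, clinical)
    else:
        samples = [s for s in clinical.samples if s in expr.samples]
        clin = clinical.subset(samples)
        X, time, event = np.zeros((len(samples), 0)), clin.time, clin.event
    fold_tests = _stratified_folds(event, folds, seed)
    mean, per_fold = _cv_cindex(X, time, event, fold_tests)
    fold_of_sample = pd.Series(index=samples, dtype=int, name="fold")
    for k, test in enumerate(fold_tests):
        fold_of_sample.iloc[test] = k
    return KFoldResult(mean, per_fold, fold_of_sample)
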
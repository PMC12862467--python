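"""Feature-selection chains and the logistic radiomics signature.

Nine selection chains are supported, each a left-to-right composition of
stages that can only shrink the feature set:

    corr+lasso, lr+lasso, corr+lasso+stepwise, lr+lasso+stepwise,
    xgboost+lasso+stepwise, rf+lasso+stepwise, gbm+lasso+stepwise,
    svm+lasso+stepwise, lasso+stepwise

Stage semantics:

* ``corr`` — of each pair with |Pearson r| > 0.90, drop the feature with
  the smaller absolute point-biserial correlation with the label.
* ``lr`` — univariate logistic regression; keep Wald p < .05.
* ``lasso`` — L1-penalized logistic regression, penalty chosen by
  stratified cross-validated log-loss with the 1-SE rule; keep features
  with nonzero coefficients.
* ``stepwise`` — bidirectional AIC search on an unpenalized logistic
  model, started from the incoming set.
* ``xgboost``/``rf``/``gbm``/``svm`` — fit the model, rank features by
  its importance (|weight| for the linear-kernel SVM) and keep the top
  ``min(20, p)`` as candidates for the following lasso.

All stages operate on the training cohort only; standardization
parameters are part of the fitted signature so no statistic computed on
held-out cohorts ever enters selection or fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import FoldingError, InputError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "CHAIN_NAMES",
    "SelectionChain",
    "FeatureMatrix",
    "reduce_features",
    "fit_logistic_signature",
    "LogisticSignature",
    "crossval_auc",
]

CHAIN_NAMES = (
    "corr+lasso",
    "lr+lasso",
    "corr+lasso+stepwise",
    "lr+lasso+stepwise",
    "xgboost+lasso+stepwise",
    "rf+lasso+stepwise",
    "gbm+lasso+stepwise",
    "svm+lasso+stepwise",
    "lasso+stepwise",
)

_STAGES = ("corr", "lr", "lasso", "stepwise", "xgboost", "rf", "gbm", "svm")


@dataclass(frozen=True)
class FeatureMatrix:
    """Patients x features with binary labels and cohort assignment."""

    X: pd.DataFrame  # index: patient_id
    y: pd.Series  # {0,1}
    cohort: pd.Series  # {"training", "internal_test", "external_test"}

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index) or not self.X.index.equals(self.cohort.index):
            raise InputError("X, y and cohort must share the same patient index")
        if not np.all(np.isin(self.y.dropna().unique(), (0, 1))):
            raise InputError("labels must be binary 0/1")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, cohort: str) -> "FeatureMatrix":
        keep = self.cohort == cohort
        return FeatureMatrix(self.X.loc[keep], self.y.loc[keep], self.cohort.loc[keep])

    def drop_incomplete(self) -> "FeatureMatrix":
        keep = self.X.notna().all(axis=1) & self.y.notna()
        return FeatureMatrix(self.X.loc[keep], self.y.loc[keep], self.cohort.loc[keep])

    def take(self, index) -> "FeatureMatrix":
        return FeatureMatrix(self.X.loc[index], self.y.loc[index], self.cohort.loc[index])


@dataclass(frozen=True)
class SelectionChain:
    """A named stage composition with its hyperparameters.

    ``fast=True`` shrinks the cross-validation and ensemble sizes (fewer
    lasso folds/penalties, smaller forests) for large sweeps; the stage
    semantics are unchanged.
    """

    name: str
    corr_threshold: float = 0.90
    p_threshold: float = 0.05
    lasso_folds: int = 5
    lasso_n_penalties: int = 8
    lasso_rule: str = "1se"  # "1se" (strongest penalty within 1 SE) or "min"
    importance_top_k: int = 20
    stepwise_max_iter: int = 30
    n_estimators: int = 100
    fast: bool = False

    def __post_init__(self) -> None:
        stages = self.name.split("+")
        if any(s not in _STAGES for s in stages):
            raise ParameterError(f"unknown selection chain {self.name!r}")
        if self.fast:
            object.__setattr__(self, "lasso_folds", min(self.lasso_folds, 3))
            object.__setattr__(self, "lasso_n_penalties", min(self.lasso_n_penalties, 6))
            object.__setattr__(self, "n_estimators", min(self.n_estimators, 50))

    @property
    def stages(self) -> list[str]:
        return self.name.split("+")


def default_chains(fast: bool = False) -> list[SelectionChain]:
    return [SelectionChain(n, fast=fast) for n in CHAIN_NAMES]


# ---------------------------------------------------------------------------
# logistic helpers


def _standardize(X: np.ndarray, mu=None, sd=None):
    if mu is None:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd

_RIDGE_FALLBACK_C = 1e4  # l2 penalty 1e-4, used only when the MLE diverges


def _fit_unpenalized(X: np.ndarray, y: np.ndarray):
    """MLE logistic fit; ridge fallback (penalty 1e-4) under separation.

    Returns (intercept, coef, loglik, used_fallback).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(C=np.inf, max_iter=500).fit(X, y)
        fallback = not np.all(np.abs(model.coef_) < 1e2) or model.n_iter_[0] >= 500
        if fallback:
            log.info("separable design: refitting with ridge penalty 1e-4")
            model = LogisticRegression(C=_RIDGE_FALLBACK_C, max_iter=1000).fit(X, y)
    eta = model.decision_function(X)
    loglik = float(-np.sum(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)))
    return float(model.intercept_[0]), model.coef_[0].copy(), loglik, fallback


def _intercept_loglik(y: np.ndarray) -> float:
    p = y.mean()
    if p in (0.0, 1.0):
        return 0.0
    n = len(y)
    return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))


def _aic(loglik: float, n_features: int) -> float:
    return 2.0 * (n_features + 1) - 2.0 * loglik


def _wald_p_univariate(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wald p-value of the slope in a one-feature logistic model."""
    from scipy import stats

    X = x.reshape(-1, 1)
    b0, coef, _, fallback = _fit_unpenalized(X, y)
    eta = b0 + X @ coef
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    design = np.column_stack([np.ones_like(x), x])
    info = design.T @ (design * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return 1.0
    se = np.sqrt(max(cov[1, 1], 1e-300))
    z = coef[0] / se
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# stages


def _stage_corr(X: pd.DataFrame, y: np.ndarray, chain: SelectionChain) -> list[str]:
    cols = list(X.columns)
    vals = X.to_numpy(dtype=float)
    std = vals.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.nan_to_num(np.corrcoef(vals, rowvar=False), nan=0.0)
        pb = np.abs(np.array([
            np.corrcoef(vals[:, j], y)[0, 1] if std[j] > 0 else 0.0 for j in range(len(cols))
        ]))
    pb = np.nan_to_num(pb, nan=0.0)
    alive = np.ones(len(cols), dtype=bool)
    # visit the strongest correlations first for a deterministic outcome
    pairs = [
        (abs(corr[i, j]), i, j)
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if abs(corr[i, j]) > chain.corr_threshold or (std[i] > 0 and np.allclose(vals[:, i], vals[:, j]))
    ]
    for _, i, j in sorted(pairs, key=lambda t: (-t[0], t[1], t[2])):
        if alive[i] and alive[j]:
            drop = i if pb[i] < pb[j] or (pb[i] == pb[j] and i > j) else j
            alive[drop] = False
    return [c for c, a in zip(cols, alive) if a]


def _stage_lr(X: pd.DataFrame, y: np.ndarray, chain: SelectionChain) -> list[str]:
    Xs, _, _ = _standardize(X.to_numpy(dtype=float))
    return [
        c for j, c in enumerate(X.columns)
        if _wald_p_univariate(Xs[:, j], y) < chain.p_threshold
    ]


def _lasso_penalty_grid(Xs: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    # C below c0 gives the all-zero solution; sweep 3 decades upward
    grad0 = np.abs(Xs.T @ (y - y.mean())).max()
    c0 = 1.0 / max(grad0, 1e-12)
    return c0 * np.logspace(0.0, 3.0, n)


def _stage_lasso(X: pd.DataFrame, y: np.ndarray, chain: SelectionChain, rng: np.random.Generator) -> list[str]:
    Xs, _, _ = _standardize(X.to_numpy(dtype=float))
    cs = _lasso_penalty_grid(Xs, y, chain.lasso_n_penalties)
    k = min(chain.lasso_folds, int(np.bincount(y.astype(int)).min()))
    if k < 2:
        raise FoldingError("lasso CV needs at least 2 samples of each class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
    losses = np.zeros((k, len(cs)))
    for f, (tr, va) in enumerate(skf.split(Xs, y)):
        for ci, c in enumerate(cs):
            m = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear").fit(Xs[tr], y[tr])
            eta = m.decision_function(Xs[va])
            losses[f, ci] = np.mean(
                np.logaddexp(0.0, -eta) * y[va] + np.logaddexp(0.0, eta) * (1 - y[va])
            )
    mean = losses.mean(axis=0)
    se = losses.std(axis=0, ddof=1) / np.sqrt(k)
    best = int(np.argmin(mean))
    if chain.lasso_rule == "min":
        chosen = cs[best]
    else:  # 1-SE rule: strongest penalty whose loss is within one SE of the best
        ok = np.nonzero(mean <= mean[best] + se[best])[0]
        chosen = cs[ok.min()]
    m = LogisticRegression(l1_ratio=1.0, C=chosen, solver="liblinear").fit(Xs, y)
    kept = [c for c, w in zip(X.columns, m.coef_[0]) if w != 0.0]
    if not kept:
        warnings.warn("lasso stage shrank every coefficient to zero", stacklevel=2)
    return kept


def _stage_stepwise(X: pd.DataFrame, y: np.ndarray, chain: SelectionChain) -> list[str]:
    pool = list(X.columns)
    Xs, _, _ = _standardize(X.to_numpy(dtype=float))
    cols = {c: Xs[:, j] for j, c in enumerate(pool)}

    def aic_of(subset: list[str]) -> float:
        if not subset:
            return _aic(_intercept_loglik(y), 0)
        M = np.column_stack([cols[c] for c in subset])
        _, _, ll, _ = _fit_unpenalized(M, y)
        return _aic(ll, len(subset))

    current = list(pool)
    current_aic = aic_of(current)
    for _ in range(chain.stepwise_max_iter):
        moves: list[tuple[float, str, str]] = []
        for c in current:
            trial = [f for f in current if f != c]
            moves.append((aic_of(trial), "drop", c))
        for c in pool:
            if c not in current:
                moves.append((aic_of(current + [c]), "add", c))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[2]))
        best_aic, op, feat = moves[0]
        if best_aic >= current_aic - 1e-10:
            break
        current = [f for f in current if f != feat] if op == "drop" else current + [feat]
        current_aic = best_aic
    return [c for c in pool if c in current]


def _stage_importance(
    X: pd.DataFrame, y: np.ndarray, chain: SelectionChain, kind: str, rng: np.random.Generator
) -> list[str]:
    Xs, _, _ = _standardize(X.to_numpy(dtype=float))
    state = int(rng.integers(2**31))
    if kind == "xgboost":
        from xgboost import XGBClassifier

        m = XGBClassifier(
            n_estimators=chain.n_estimators, max_depth=3, learning_rate=0.1,
            random_state=state, verbosity=0, n_jobs=1,
        ).fit(Xs, y)
        imp = m.feature_importances_
    elif kind == "rf":
        from sklearn.ensemble import RandomForestClassifier

        m = RandomForestClassifier(
            n_estimators=chain.n_estimators, random_state=state, n_jobs=1
        ).fit(Xs, y)
        imp = m.feature_importances_
    elif kind == "gbm":
        from sklearn.ensemble import GradientBoostingClassifier

        m = GradientBoostingClassifier(
            n_estimators=chain.n_estimators, random_state=state
        ).fit(Xs, y)
        imp = m.feature_importances_
    elif kind == "svm":
        from sklearn.svm import LinearSVC

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = LinearSVC(C=1.0, random_state=state, max_iter=5000).fit(Xs, y)
        imp = np.abs(m.coef_[0])
    else:  # pragma: no cover
        raise ParameterError(kind)
    k = min(chain.importance_top_k, X.shape[1])
    order = np.argsort(-imp, kind="stable")[:k]
    keep = set(X.columns[order])
    return [c for c in X.columns if c in keep]


def reduce_features(fm: FeatureMatrix, chain: SelectionChain, seed: int = 0) -> list[str]:
    """Apply the chain's stages to the training matrix; returns kept names.

    An empty intermediate set short-circuits the chain (with a warning)
    rather than raising.
    """
    Xdf = fm.X
    y = fm.y.to_numpy(dtype=int)
    if Xdf.shape[1] < 1:
        raise InputError("need at least one feature")
    if len(np.unique(y)) < 2:
        raise InputError("training labels contain a single class")
    rng = np.random.default_rng(seed)
    kept = list(Xdf.columns)
    for stage in chain.stages:
        if not kept:
            warnings.warn(f"chain {chain.name!r}: empty feature set before {stage!r}", stacklevel=2)
            return []
        sub = Xdf[kept]
        if stage == "corr":
            kept = _stage_corr(sub, y, chain)
        elif stage == "lr":
            kept = _stage_lr(sub, y, chain)
        elif stage == "lasso":
            kept = _stage_lasso(sub, y, chain, rng)
        elif stage == "stepwise":
            kept = _stage_stepwise(sub, y, chain)
        else:
            kept = _stage_importance(sub, y, chain, stage, rng)
    if not kept:
        warnings.warn(f"chain {chain.name!r} selected no features", stacklevel=2)
    return kept


# ---------------------------------------------------------------------------
# signature


@dataclass(frozen=True)
class LogisticSignature:
    """A fitted logistic model; the score is the linear predictor (log-odds)."""

    features: tuple[str, ...]
    mu: np.ndarray
    sd: np.ndarray
    intercept: float
    coef: np.ndarray
    used_ridge_fallback: bool = False

    def score(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[list(self.features)].to_numpy(dtype=float) - self.mu) / self.sd
        return self.intercept + Z @ self.coef

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "intercept": self.intercept,
            "coefficients": dict(zip(self.features, self.coef.tolist())),
            "standardization_mean": dict(zip(self.features, self.mu.tolist())),
            "standardization_sd": dict(zip(self.features, self.sd.tolist())),
            "used_ridge_fallback": self.used_ridge_fallback,
        }


def fit_logistic_signature(fm: FeatureMatrix, features: list[str]) -> LogisticSignature:
    """Standardize by train mean/sd and fit a maximum-likelihood logistic model."""
    if not features:
        raise InputError("cannot fit a signature on an empty feature list")
    missing = [f for f in features if f not in fm.X.columns]
    if missing:
        raise InputError(f"features not in matrix: {missing}")
    y = fm.y.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise InputError("training labels contain a single class")
    Xs, mu, sd = _standardize(fm.X[features].to_numpy(dtype=float))
    b0, coef, _, fallback = _fit_unpenalized(Xs, y)
    return LogisticSignature(
        features=tuple(features), mu=mu, sd=sd, intercept=b0, coef=coef,
        used_ridge_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# cross-validated AUC


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from scipy.stats import rankdata

    pos = labels == 1
    n1, n0 = pos.sum(), (~pos).sum()
    if n1 == 0 or n0 == 0:
        return np.nan
    r = rankdata(scores)
    return float((r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def crossval_auc(
    fm: FeatureMatrix, chain: SelectionChain, folds: int = 10, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Stratified k-fold CV with selection and fitting re-run per fold.

    Returns (mean AUC, per-fold AUCs).  A fold whose selection is empty
    scores every sample identically (AUC 0.5 by the tie convention).
    """
    y = fm.y.to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        if counts.min() < 2:
            raise FoldingError("a class is too small to stratify")
        folds = int(counts.min())
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(2**31, size=folds)
    aucs = []
    for f, (tr, va) in enumerate(skf.split(fm.X.to_numpy(), y)):
        fm_tr = fm.take(fm.X.index[tr])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected = reduce_features(fm_tr, chain, seed=int(fold_seeds[f]))
        if selected:
            sig = fit_logistic_signature(fm_tr, selected)
            scores = sig.score(fm.X.iloc[va])
        else:
            scores = np.zeros(len(va))
        aucs.append(_auc(scores, y[va]))
    per_fold = np.array(aucs)
    return float(np.nanmean(per_fold)), per_fold
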
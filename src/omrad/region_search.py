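"""The core procedure: sweep every selection chain over every margin band.

For each (band spec, chain) pair the training cohort drives feature
selection, a cross-validated training AUC, and a final logistic
signature refit on the full training cohort; the refit model is then
scored on the internal (and, when present, external) test cohorts.
Models are ranked primarily by internal-test AUC, with ties broken by
higher training CV AUC, then by narrower band (smaller inner+outer; the
original whole-lesion VOI counts as the widest region), then by (inner,
outer) order so the ranking is fully deterministic.

Per-pair seeds are derived from the master seed and the pair's identity,
so the ranking does not depend on evaluation order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SearchError, ParameterError
from .evaluation import roc_auc_ci
from .margin import MarginBandSpec
from .selection import (
    CHAIN_NAMES,
    FeatureMatrix,
    LogisticSignature,
    SelectionChain,
    crossval_auc,
    fit_logistic_signature,
    reduce_features,
)

log = logging.getLogger(__name__)

__all__ = ["RegionModelResult", "grid_search", "summarize_top_regions"]

_ORIGINAL_TIEBREAK_WIDTH = 1000  # the whole lesion is the widest "band"


@dataclass(frozen=True)
class RegionModelResult:
    spec: MarginBandSpec
    chain_name: str
    selected_features: tuple[str, ...]
    signature: LogisticSignature | None
    auc_train_cv: float
    auc_internal: float
    ci_internal: tuple[float, float]
    auc_external: float | None
    ci_external: tuple[float, float] | None
    n_evaluable: dict

    @property
    def tiebreak_width(self) -> int:
        return _ORIGINAL_TIEBREAK_WIDTH if self.spec.is_original else self.spec.width


def _pair_seed(master_seed: int, spec: MarginBandSpec, chain_name: str) -> int:
    chain_idx = CHAIN_NAMES.index(chain_name) if chain_name in CHAIN_NAMES else 97
    ss = np.random.SeedSequence(
        entropy=int(master_seed) % 2**31,
        spawn_key=(spec.inner_mm, spec.outer_mm, int(spec.is_original), chain_idx),
    )
    return int(ss.generate_state(1)[0] % 2**31)


def _score_cohort(sig: LogisticSignature | None, fm: FeatureMatrix, cohort: str):
    sub = fm.subset(cohort).drop_incomplete()
    if len(sub.X) == 0:
        return None, None, 0
    if sub.y.nunique() < 2:
        return None, None, len(sub.X)
    if sig is None:
        return 0.5, (0.5, 0.5), len(sub.X)
    scores = sig.score(sub.X)
    auc, ci = roc_auc_ci(scores, sub.y.to_numpy())
    return auc, ci, len(sub.X)


def evaluate_pair(
    fm: FeatureMatrix,
    spec: MarginBandSpec,
    chain: SelectionChain,
    seed: int,
    cv_folds: int = 10,
) -> RegionModelResult:
    """Select, cross-validate, refit and score one (spec, chain) pair."""
    pair_seed = _pair_seed(seed, spec, chain.name)
    train = fm.subset("training").drop_incomplete()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        selected = reduce_features(train, chain, seed=pair_seed)
        cv_auc, _ = crossval_auc(train, chain, folds=cv_folds, seed=pair_seed)
        sig = fit_logistic_signature(train, selected) if selected else None
    auc_int, ci_int, n_int = _score_cohort(sig, fm, "internal_test")
    auc_ext, ci_ext, n_ext = _score_cohort(sig, fm, "external_test")
    return RegionModelResult(
        spec=spec,
        chain_name=chain.name,
        selected_features=tuple(selected),
        signature=sig,
        auc_train_cv=cv_auc,
        auc_internal=auc_int if auc_int is not None else 0.5,
        ci_internal=ci_int if ci_int is not None else (np.nan, np.nan),
        auc_external=auc_ext,
        ci_external=ci_ext,
        n_evaluable={"training": len(train.X), "internal_test": n_int, "external_test": n_ext},
    )


def _rank_key(r: RegionModelResult):
    return (
        -r.auc_internal,
        -r.auc_train_cv,
        r.tiebreak_width,
        r.spec.inner_mm,
        r.spec.outer_mm,
        r.chain_name,
    )


def grid_search(
    features_by_spec: dict[MarginBandSpec, FeatureMatrix],
    chains: list[SelectionChain],
    seed: int = 0,
    cv_folds: int = 10,
    min_train_fraction: float = 0.5,
) -> list[RegionModelResult]:
    """Evaluate every chain on every band spec; return the ranked results.

    Patients whose band is empty (missing feature rows) are dropped from
    that spec only; a spec evaluable on less than ``min_train_fraction``
    of the training cohort is skipped with a warning.
    """
    if not features_by_spec:
        raise SearchError("no feature matrices supplied")
    results: list[RegionModelResult] = []
    specs = sorted(features_by_spec, key=lambda s: (not s.is_original, s.inner_mm, s.outer_mm))
    n_train_full = None
    for spec in specs:
        fm = features_by_spec[spec]
        train = fm.subset("training")
        if n_train_full is None:
            n_train_full = len(train.X)
        n_eval = len(train.drop_incomplete().X)
        if n_train_full and n_eval < min_train_fraction * n_train_full:
            log.warning(
                "spec %s evaluable on %d/%d training patients; skipped",
                spec.name, n_eval, n_train_full,
            )
            continue
        if train.drop_incomplete().y.nunique() < 2:
            log.warning("spec %s training labels single-class; skipped", spec.name)
            continue
        for chain in chains:
            results.append(evaluate_pair(fm, spec, chain, seed=seed, cv_folds=cv_folds))
    if not results:
        raise SearchError("no evaluable (spec, chain) configuration")
    results.sort(key=_rank_key)
    return results


def summarize_top_regions(results: list[RegionModelResult], k: int = 8) -> pd.DataFrame:
    """Top-k slice of the ranking as a table of spec coordinates and AUCs."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if not results:
        raise SearchError("empty result list")
    rows = []
    for rank, r in enumerate(results[:k], start=1):
        rows.append(
            {
                "rank": rank,
                "region": r.spec.name,
                "inner_mm": r.spec.inner_mm,
                "outer_mm": r.spec.outer_mm,
                "is_original": r.spec.is_original,
                "chain": r.chain_name,
                "auc_internal": r.auc_internal,
                "auc_train_cv": r.auc_train_cv,
                "auc_external": r.auc_external,
                "n_features": len(r.selected_features),
            }
        )
    return pd.DataFrame(rows)


def results_to_frame(results: list[RegionModelResult]) -> pd.DataFrame:
    """Full AUC matrix (one row per spec x chain) for CSV export."""
    rows = []
    for r in results:
        rows.append(
            {
                "region": r.spec.name,
                "inner_mm": r.spec.inner_mm,
                "outer_mm": r.spec.outer_mm,
                "is_original": r.spec.is_original,
                "chain": r.chain_name,
                "auc_train_cv": r.auc_train_cv,
                "auc_internal": r.auc_internal,
                "ci_internal_lo": r.ci_internal[0],
                "ci_internal_hi": r.ci_internal[1],
                "auc_external": r.auc_external,
                "selected_features": "|".join(r.selected_features),
                "n_train": r.n_evaluable.get("training"),
            }
        )
    return pd.DataFrame(rows)
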
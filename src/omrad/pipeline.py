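"""End-to-end study orchestration.

``run_full_study`` executes the whole workflow on a cohort directory or
an in-memory phantom cohort: isotropic resampling, band enumeration,
feature extraction over every band, the chain x region grid search,
Youden-cutoff risk stratification with the cutoff frozen on the training
cohort, and Kaplan-Meier/log-rank analyses per endpoint and cohort.

One master seed fans out to per-stage seeds through
``numpy.random.SeedSequence.spawn``; the report embeds the seed, a
config hash and the package version, and contains no timestamps, so
re-running the same configuration reproduces it byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import InputError
from .evaluation import km_logrank, youden_cutoff
from .features import SELECTED_FEATURES, extract_features_by_spec
from .image_io import read_mask, read_volume, resample_isotropic
from .margin import MarginBandSpec, enumerate_band_specs
from .phantom import PhantomTruth, generate_cohort
from .region_search import RegionModelResult, grid_search, results_to_frame, summarize_top_regions
from .selection import FeatureMatrix, SelectionChain, default_chains

log = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_full_study", "extract_cohort_features", "load_cohort_dir"]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration for a full study run."""

    seed: int = 0
    cohort_dir: str | None = None  # read a written cohort; else simulate
    phantom_n: int = 60
    phantom: PhantomTruth = field(default_factory=PhantomTruth)
    max_mm: int = 10
    inner_range: tuple[int, int] | None = None  # optional reduced sweep
    outer_range: tuple[int, int] | None = None
    include_original: bool = True  # reduced sweeps may cover band pairs only
    registry: tuple[str, ...] = SELECTED_FEATURES
    bin_width: float = 25.0
    chains: tuple[str, ...] = tuple(c.name for c in default_chains())
    fast_chains: bool = False
    cv_folds: int = 10
    target_spacing_mm: float = 1.0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # output location; not part of the study identity
        d["phantom"]["planted_band"] = {
            "inner_mm": self.phantom.planted_band.inner_mm,
            "outer_mm": self.phantom.planted_band.outer_mm,
        }
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _to_jsonable(o):
    if hasattr(o, "item"):
        return o.item()
    return str(o)


def band_specs_for(config: StudyConfig) -> list[MarginBandSpec]:
    if config.inner_range is None and config.outer_range is None:
        return enumerate_band_specs(config.max_mm)
    ilo, ihi = config.inner_range or (0, config.max_mm)
    olo, ohi = config.outer_range or (0, config.max_mm)
    specs = [MarginBandSpec(is_original=True)] if config.include_original else []
    for inner in range(ilo, ihi + 1):
        for outer in range(olo, ohi + 1):
            if inner == 0 and outer == 0:
                continue
            specs.append(MarginBandSpec(inner, outer))
    return specs


def load_cohort_dir(cohort_dir: str, target_spacing_mm: float = 1.0):
    """Load a written cohort directory into (records, table).

    Records are (patient_id, volume, lesion_mask, label, cohort) tuples
    with volumes resampled to the isotropic target spacing.
    """
    csv_path = os.path.join(cohort_dir, "patients.csv")
    if not os.path.exists(csv_path):
        raise InputError(f"no patients.csv in {cohort_dir}")
    table = pd.read_csv(csv_path).set_index("patient_id")
    if len(table) == 0:
        raise InputError("cohort table has zero patients")
    records = []
    for pid, row in table.iterrows():
        vol = read_volume(os.path.join(cohort_dir, row["image_path"]))
        mask = read_mask(os.path.join(cohort_dir, row["mask_path"]), companion=vol)
        vol = resample_isotropic(vol, target_spacing_mm, mode="continuous")
        mask = resample_isotropic(mask, target_spacing_mm, mode="nearest")
        records.append((str(pid), vol, mask, int(row["label"]), str(row["cohort"])))
    return records, table


def extract_cohort_features(
    records,
    specs,
    registry=SELECTED_FEATURES,
    bin_width: float = 25.0,
    labels: pd.Series | None = None,
    cohorts: pd.Series | None = None,
) -> dict[MarginBandSpec, FeatureMatrix]:
    """Per-spec feature matrices over a cohort.

    ``records`` iterates (patient_id, volume, lesion_mask, label, cohort).
    Patients whose band is empty for a spec get a missing (NaN) row in
    that spec's matrix only.
    """
    registry = list(registry)
    per_spec: dict[MarginBandSpec, dict[str, dict[str, float]]] = {s: {} for s in specs}
    ids, lab, coh = [], {}, {}
    for pid, vol, mask, label, cohort in records:
        ids.append(pid)
        lab[pid] = label
        coh[pid] = cohort
        feats = extract_features_by_spec(vol, mask, specs, registry, bin_width)
        for s in specs:
            v = feats[s]
            per_spec[s][pid] = v if v is not None else {k: np.nan for k in registry}
    out: dict[MarginBandSpec, FeatureMatrix] = {}
    y = pd.Series(lab, name="label").loc[ids] if labels is None else labels.loc[ids]
    c = pd.Series(coh, name="cohort").loc[ids] if cohorts is None else cohorts.loc[ids]
    for s in specs:
        X = pd.DataFrame.from_dict(per_spec[s], orient="index").loc[ids, registry]
        out[s] = FeatureMatrix(X=X, y=y, cohort=c)
    return out


def _stratify(results: list[RegionModelResult], fm: FeatureMatrix, table: pd.DataFrame | None) -> dict:
    best = results[0]
    sig = best.signature
    if sig is None:  # winning chain selected no features; nothing to threshold
        log.warning("top-ranked model has an empty signature; skipping stratification")
        return {"cutoff": None, "youden_j": None, "cohorts": {}, "groups": {}}
    train = fm.subset("training").drop_incomplete()
    cutoff, j = youden_cutoff(sig.score(train.X), train.y.to_numpy())
    strat: dict = {"cutoff": cutoff, "youden_j": j, "cohorts": {}}
    groups_all: dict[str, str] = {}
    for cohort in ("training", "internal_test", "external_test"):
        sub = fm.subset(cohort).drop_incomplete()
        if len(sub.X) == 0:
            continue
        scores = sig.score(sub.X)
        groups = np.where(scores >= cutoff, "high", "low")
        groups_all.update(dict(zip(sub.X.index, groups)))
        entry = {
            "n": len(sub.X),
            "n_high": int((groups == "high").sum()),
            "n_low": int((groups == "low").sum()),
        }
        if table is not None:
            for endpoint in ("os", "dfs"):
                tcol, ecol = f"time_{endpoint}", f"event_{endpoint}"
                if tcol in table.columns and len(set(groups)) == 2:
                    t = table.loc[sub.X.index, tcol].to_numpy()
                    e = table.loc[sub.X.index, ecol].to_numpy()
                    if e.sum() >= 1:
                        km = km_logrank(groups, t, e)
                        entry[f"logrank_{endpoint}"] = {
                            "statistic": km["logrank_statistic"],
                            "p": km["logrank_p"],
                            "median_high": km["groups"]["high"]["median"],
                            "median_low": km["groups"]["low"]["median"],
                        }
        strat["cohorts"][cohort] = entry
    strat["groups"] = groups_all
    return strat


def run_full_study(config: StudyConfig) -> dict:
    """Execute the whole workflow; returns (and optionally writes) the report."""
    root = np.random.SeedSequence(int(config.seed) % 2**31)
    ss_sim, ss_search = root.spawn(2)
    seed_sim = int(ss_sim.generate_state(1)[0] % 2**31)
    seed_search = int(ss_search.generate_state(1)[0] % 2**31)

    if config.cohort_dir is not None:
        records, table = load_cohort_dir(config.cohort_dir, config.target_spacing_mm)
        log.info("loaded %d patients from %s", len(records), config.cohort_dir)
    else:
        cohort = generate_cohort(config.phantom_n, config.phantom, seed=seed_sim)
        records = [
            (p.patient_id, p.volume, p.lesion_mask, p.label, p.cohort)
            for p in cohort.patients
        ]
        table = cohort.table
    if len(records) == 0:
        raise InputError("cohort has zero patients")

    specs = band_specs_for(config)
    log.info("extracting %d features over %d regions", len(config.registry), len(specs))
    features_by_spec = extract_cohort_features(
        records, specs, config.registry, config.bin_width
    )

    chains = [SelectionChain(name, fast=config.fast_chains) for name in config.chains]
    log.info("grid search: %d chains x %d regions", len(chains), len(specs))
    results = grid_search(features_by_spec, chains, seed=seed_search, cv_folds=config.cv_folds)
    best = results[0]
    strat = _stratify(results, features_by_spec[best.spec], table)

    report = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "config": config.to_dict(),
        "n_regions": len(specs),
        "n_models": len(results),
        "selected": {
            "region": best.spec.name,
            "inner_mm": best.spec.inner_mm,
            "outer_mm": best.spec.outer_mm,
            "is_original": best.spec.is_original,
            "chain": best.chain_name,
            "features": list(best.selected_features),
            "model": best.signature.to_dict() if best.signature else None,
            "auc_train_cv": best.auc_train_cv,
            "auc_internal": best.auc_internal,
            "ci_internal": list(best.ci_internal),
            "auc_external": best.auc_external,
        },
        "stratification": {k: v for k, v in strat.items() if k != "groups"},
        "top_regions": summarize_top_regions(results, k=8).to_dict(orient="records"),
    }

    if config.out_dir is not None:
        os.makedirs(config.out_dir, exist_ok=True)
        results_to_frame(results).to_csv(
            os.path.join(config.out_dir, "auc_matrix.csv"), index=False
        )
        pd.Series(strat["groups"], name="risk_group").rename_axis("patient_id").to_csv(
            os.path.join(config.out_dir, "risk_groups.csv")
        )
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_to_jsonable)
    report["_results"] = results  # in-memory extras, not serialized
    return report
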
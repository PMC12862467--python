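"""Synthetic hepatobiliary-phase phantom cohorts with a planted margin effect.

Each phantom patient is a smooth bright liver background (mean 120, SD
10 after Gaussian smoothing) containing a darker ellipsoidal lesion
(mean 80).  The planted signal is *texture heterogeneity*, not a mean
shift: voxel noise inside the planted margin band has a standard
deviation ``rim_noise_sd`` for label-0 patients and ``rim_noise_sd *
effect_size`` for label-1 patients, so effect_size = 1 makes the two
classes identically distributed.  Survival times are exponential with a
label-dependent hazard ratio and independent uniform censoring, so
prognostic separation flows through the binary label exactly as
microvascular invasion drives prognosis in the clinical setting this
emulates.

A configurable fraction of lesions gets an adjacent zero-intensity
spherical cavity recorded in an organ label map (liver = 1, cavity = 2),
exercising the nontarget-tissue flagging of outward expansions.

Everything is driven by one master seed; identical seeds give
bit-identical cohorts.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError, ParameterError
from .image_io import MaskVolume, VolumeGrid, write_mask, write_volume
from .margin import MarginBandSpec

__all__ = ["PhantomTruth", "PhantomPatient", "PhantomCohort", "generate_cohort",
           "generate_survival", "truth_check", "write_cohort"]


@dataclass(frozen=True)
class PhantomTruth:
    """Generative parameters of a phantom cohort (the planted ground truth)."""

    planted_band: MarginBandSpec = MarginBandSpec(inner_mm=5, outer_mm=0)
    effect_size: float = 2.0
    label_prevalence: float = 0.4
    semi_axis_range_mm: tuple[float, float] = (8.0, 12.0)
    background_mean: float = 120.0
    background_sd: float = 10.0  # smooth (2 mm correlated) liver texture
    background_voxel_sd: float = 8.0  # white scanner noise outside the lesion
    lesion_mean: float = 80.0
    lesion_noise_sd: float = 8.0
    rim_noise_sd: float = 12.0
    background_jitter: float = 0.35  # per-patient lognormal SD, liver noise level
    interior_jitter: float = 0.35  # per-patient lognormal SD, lesion-core noise level
    rim_sd_jitter: float = 0.2  # per-patient lognormal SD, rim noise level
    depth_jitter: float = 0.7  # per-patient lognormal SD per 1 mm depth shell
    sd_clip: tuple[float, float] = (3.0, 45.0)  # bounds on the rim noise level
    cavity_fraction: float = 0.25
    margin_mm: int = 10
    os_baseline_median: float = 60.0
    os_hazard_ratio: float = 2.5
    dfs_baseline_median: float = 36.0
    dfs_hazard_ratio: float = 3.0
    censor_range: tuple[float, float] = (24.0, 96.0)
    train_fraction: float = 0.7
    external_fraction: float = 0.0
    master_seed: int = 0


@dataclass(frozen=True)
class PhantomPatient:
    patient_id: str
    volume: VolumeGrid
    lesion_mask: MaskVolume
    organ_labels: np.ndarray | None  # liver=1, cavity=2; None when no cavity map
    label: int
    cohort: str


@dataclass(frozen=True)
class PhantomCohort:
    patients: list[PhantomPatient]
    table: pd.DataFrame  # patient_id, label, cohort, survival columns
    truth: PhantomTruth


def generate_survival(
    labels: np.ndarray,
    hazard_ratio: float,
    baseline_median: float,
    censor_range: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with a class hazard ratio, uniform censoring.

    Returns (time, event) in months; event=0 encodes censoring.
    """
    labels = np.asarray(labels, dtype=int)
    lam0 = np.log(2.0) / baseline_median
    lam = lam0 * np.where(labels == 1, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.uniform(*censor_range, size=len(labels))
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    return np.maximum(time, 0.01), event


def _make_patient_volume(
    truth: PhantomTruth, label: int, with_cavity: bool, rng: np.random.Generator
) -> tuple[VolumeGrid, MaskVolume, np.ndarray | None]:
    a, b = truth.semi_axis_range_mm
    semis = rng.uniform(a, b, size=3)
    pad = truth.margin_mm + 4
    half = np.ceil(semis + pad).astype(int)
    shape = tuple(2 * half + 1)
    center = half + rng.uniform(-2, 2, size=3)
    grids = np.indices(shape, dtype=np.float64)
    d2 = sum(((grids[i] - center[i]) / semis[i]) ** 2 for i in range(3))
    lesion = d2 <= 1.0

    # Per-patient nuisance variability: each tissue compartment draws its
    # own lognormal factor on the noise level.  Without this, any band
    # touching the rim separates the classes perfectly and the region
    # sweep degenerates; with independent factors per compartment, a band
    # that mixes in non-rim tissue picks up label-independent variance
    # and is genuinely penalized relative to the planted band.
    g_bg = float(np.exp(truth.background_jitter * rng.standard_normal()))
    g_bgv = float(np.exp(truth.background_jitter * rng.standard_normal()))
    g_core = float(np.exp(truth.interior_jitter * rng.standard_normal()))
    g_rim = float(np.exp(truth.rim_sd_jitter * rng.standard_normal()))

    # liver background: smooth correlated texture plus voxel-scale
    # scanner noise (present everywhere in real acquisitions)
    bg_noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    bg_noise *= g_bg * truth.background_sd / max(bg_noise.std(), 1e-12)
    vox = truth.background_mean + bg_noise
    vox += g_bgv * truth.background_voxel_sd * rng.standard_normal(shape)

    noise = rng.standard_normal(shape)
    vox[lesion] = truth.lesion_mean + g_core * truth.lesion_noise_sd * noise[lesion]

    # planted rim: heterogeneity scaled by the class effect.  The rim noise
    # level also varies randomly between 1 mm depth shells, so a thin
    # sub-shell gives a noisier read of the patient's rim heterogeneity
    # than the full planted band — without this depth decorrelation every
    # band touching the rim would be equally informative and the planted
    # region would not be identifiable even in principle.
    spec = truth.planted_band
    rim_sd = truth.rim_noise_sd * g_rim * (truth.effect_size if label == 1 else 1.0)
    mask_u8 = lesion
    dist_in = ndimage.distance_transform_edt(mask_u8)
    dist_out = ndimage.distance_transform_edt(~mask_u8)
    rim = (mask_u8 & (dist_in <= spec.inner_mm)) | (~mask_u8 & (dist_out <= spec.outer_mm))
    n_shells = spec.inner_mm + spec.outer_mm
    shell_mult = np.exp(truth.depth_jitter * rng.standard_normal(max(n_shells, 1)))
    shell_idx = np.where(
        mask_u8,
        np.clip(np.ceil(dist_in).astype(int) - 1, 0, max(spec.inner_mm - 1, 0)),
        spec.inner_mm + np.clip(np.ceil(dist_out).astype(int) - 1, 0, max(spec.outer_mm - 1, 0)),
    )
    base = np.where(mask_u8, truth.lesion_mean, truth.background_mean)
    sd_field = rim_sd * shell_mult[np.clip(shell_idx, 0, len(shell_mult) - 1)]
    # lognormal tails are clipped: tissue/scanner noise levels are bounded,
    # and unbounded SDs inflate the discretized gray-level range
    sd_field = np.clip(sd_field, *truth.sd_clip)
    vox[rim] = base[rim] + sd_field[rim] * noise[rim]

    organ = None
    if with_cavity:
        organ = np.ones(shape, dtype=np.int16)
        # zero-intensity sphere tangent to the lesion surface, 2 mm out
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        r_cav = 6.0
        # distance from center to surface along direction for an ellipsoid
        t_surf = 1.0 / np.sqrt(sum((direction[i] / semis[i]) ** 2 for i in range(3)))
        cav_center = center + direction * (t_surf + 2.0 + r_cav)
        c2 = sum((grids[i] - cav_center[i]) ** 2 for i in range(3))
        cavity = c2 <= r_cav**2
        vox[cavity] = 0.0
        organ[cavity] = 2

    return (
        VolumeGrid(vox, spacing=(1.0, 1.0, 1.0)),
        MaskVolume(lesion, spacing=(1.0, 1.0, 1.0)),
        organ,
    )


def _assign_cohorts(labels: np.ndarray, truth: PhantomTruth, rng: np.random.Generator) -> np.ndarray:
    n = len(labels)
    cohorts = np.empty(n, dtype=object)
    idx = rng.permutation(n)
    n_ext = int(round(truth.external_fraction * n))
    n_train = int(round(truth.train_fraction * (n - n_ext)))
    ext, rest = idx[:n_ext], idx[n_ext:]
    cohorts[ext] = "external_test"
    cohorts[rest[:n_train]] = "training"
    cohorts[rest[n_train:]] = "internal_test"
    return cohorts


def generate_cohort(n: int, truth: PhantomTruth | None = None, seed: int = 0) -> PhantomCohort:
    """Generate *n* phantom patients with images, labels and survival.

    Deterministic: the same ``(n, truth, seed)`` reproduces the cohort
    bit-identically.
    """
    truth = truth if truth is not None else PhantomTruth()
    if n < 20:
        raise InputError(f"cohorts need n >= 20, got {n}")
    if truth.semi_axis_range_mm[0] < max(truth.planted_band.inner_mm, 8):
        raise ParameterError(
            "semi-axes must be >= 8 mm (and at least the planted inner depth) "
            "so the inner rim exists"
        )
    truth = replace(truth, master_seed=int(seed))
    root = np.random.SeedSequence(int(seed) % 2**31)
    ss_labels, ss_surv, ss_cohort, *ss_patients = root.spawn(3 + n)
    rng_l = np.random.default_rng(ss_labels)
    labels = (rng_l.random(n) < truth.label_prevalence).astype(int)
    # guarantee both classes so downstream modelling is well-posed
    if labels.sum() == 0:
        labels[0] = 1
    elif labels.sum() == n:
        labels[0] = 0
    cavity_draw = rng_l.random(n) < truth.cavity_fraction
    cohorts = _assign_cohorts(labels, truth, np.random.default_rng(ss_cohort))

    rng_s = np.random.default_rng(ss_surv)
    t_os, e_os = generate_survival(
        labels, truth.os_hazard_ratio, truth.os_baseline_median, truth.censor_range, rng_s
    )
    t_dfs, e_dfs = generate_survival(
        labels, truth.dfs_hazard_ratio, truth.dfs_baseline_median, truth.censor_range, rng_s
    )

    patients = []
    for i in range(n):
        vol, mask, organ = _make_patient_volume(
            truth, int(labels[i]), bool(cavity_draw[i]), np.random.default_rng(ss_patients[i])
        )
        patients.append(
            PhantomPatient(
                patient_id=f"P{i:04d}", volume=vol, lesion_mask=mask,
                organ_labels=organ, label=int(labels[i]), cohort=str(cohorts[i]),
            )
        )
    table = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "label": labels,
            "cohort": cohorts,
            "time_os": t_os,
            "event_os": e_os,
            "time_dfs": t_dfs,
            "event_dfs": e_dfs,
        }
    ).set_index("patient_id")
    return PhantomCohort(patients=patients, table=table, truth=truth)


def truth_check(results, truth: PhantomTruth, recovery_distance: int = 2) -> dict:
    """Compare a ranked grid-search result list against the planted band.

    Distance is Manhattan in (inner, outer); the original whole-lesion
    VOI is treated as the full-depth band (inner = margin range, outer 0).
    """
    planted = truth.planted_band

    def coords(spec: MarginBandSpec) -> tuple[int, int]:
        if spec.is_original:
            return (truth.margin_mm, 0)
        return (spec.inner_mm, spec.outer_mm)

    pi, po = coords(planted)
    top = results[0].spec
    ti, to = coords(top)
    distance = abs(ti - pi) + abs(to - po)
    planted_rank = next(
        (k + 1 for k, r in enumerate(results)
         if not r.spec.is_original
         and (r.spec.inner_mm, r.spec.outer_mm) == (planted.inner_mm, planted.outer_mm)),
        None,
    )
    return {
        "top1_spec": top,
        "top1_distance": int(distance),
        "planted_rank": planted_rank,
        "recovered": bool(distance <= recovery_distance),
    }


def write_cohort(cohort: PhantomCohort, out_dir: str) -> None:
    """Write a ready-to-run cohort directory (NIfTI + patients.csv + truth.json)."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for p in cohort.patients:
        img = os.path.join(out_dir, f"{p.patient_id}_image.nii.gz")
        msk = os.path.join(out_dir, f"{p.patient_id}_mask.nii.gz")
        write_volume(p.volume, img)
        write_mask(p.lesion_mask, msk)
        row = {
            "patient_id": p.patient_id,
            "image_path": os.path.basename(img),
            "mask_path": os.path.basename(msk),
            "label": p.label,
            "cohort": p.cohort,
        }
        if p.organ_labels is not None:
            organ_path = os.path.join(out_dir, f"{p.patient_id}_organ.nii.gz")
            write_volume(
                VolumeGrid(p.organ_labels.astype(np.float32), p.volume.spacing, p.volume.origin),
                organ_path,
            )
            row["liver_mask_path"] = os.path.basename(organ_path)
        rows.append(row)
    meta = pd.DataFrame(rows).set_index("patient_id")
    table = meta.join(cohort.table.drop(columns=["label", "cohort"]))
    table.to_csv(os.path.join(out_dir, "patients.csv"))
    truth_d = asdict(cohort.truth)
    truth_d["planted_band"] = {
        "inner_mm": cohort.truth.planted_band.inner_mm,
        "outer_mm": cohort.truth.planted_band.outer_mm,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth_d, fh, indent=2)
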
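"""Radiomics features over margin-band regions.

The signature of interest consists of seven features:

======================================  =============================
name                                    meaning
======================================  =============================
logarithm_firstorder_Minimum            darkest voxel after log compression
logarithm_glcm_Imc1                     co-occurrence informational correlation
original_shape_Elongation               sqrt(lambda2/lambda1) of the lesion
wavelet_LHL_glcm_MCC                    maximal correlation coefficient
wavelet_HLH_ngtdm_Busyness              rate of local gray-tone change
log_sigma_3_0_mm_3D_glcm_ClusterShade   co-occurrence skewness (LoG 3 mm)
wavelet_HHH_glcm_JointEntropy           co-occurrence entropy (bits)
======================================  =============================

Feature names follow the ``<filter>_<family>_<statistic>`` convention.
Intensity features are computed on the band region of the filtered
volume; shape features are always computed on the original lesion mask.
Gray levels are discretized with a fixed bin width (default 25 intensity
units) anchored at the in-region minimum, so all texture features are
invariant under adding a constant to the intensities.

Degenerate-region conventions (single gray level, or no co-occurring
pair): JointEntropy = 0, ClusterShade = 0, Imc1 = 0, MCC = 1,
Busyness = 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._kernels import (
    GLCM_OFFSETS,
    discretize_coords,
    glcm_counts,
    glcm_counts_multi,
    ngtdm_sums,
)
from .errors import DegenerateShapeError, InputError, ParameterError, RegistryError
from .filters import SUBBAND_NAMES, laplacian_of_gaussian, logarithm_transform, wavelet_subbands
from .image_io import MaskVolume, VolumeGrid, require_same_grid
from .margin import MarginBandSpec, band_distance_fields, band_from_distances

__all__ = [
    "SELECTED_FEATURES",
    "DiscretizedRegion",
    "discretize",
    "glcm_features",
    "ngtdm_busyness",
    "firstorder_minimum",
    "shape_elongation",
    "extract_features",
    "FeatureExtractor",
    "extract_features_by_spec",
    "icc_filter",
]

#: The seven-feature signature registry used throughout the pipeline.
SELECTED_FEATURES = (
    "logarithm_firstorder_Minimum",
    "logarithm_glcm_Imc1",
    "original_shape_Elongation",
    "wavelet_LHL_glcm_MCC",
    "wavelet_HLH_ngtdm_Busyness",
    "log_sigma_3_0_mm_3D_glcm_ClusterShade",
    "wavelet_HHH_glcm_JointEntropy",
)

DEFAULT_BIN_WIDTH = 25.0


# ---------------------------------------------------------------------------
# discretization


@dataclass(frozen=True)
class DiscretizedRegion:
    """Gray levels 1..G at in-region voxels (0 outside), cropped to the region."""

    levels: np.ndarray  # int32, region bounding box
    n_levels: int
    bin_width: float
    coords: np.ndarray | None = None  # (n, 3) in-region voxel indices

    @property
    def voxel_count(self) -> int:
        return int((self.levels > 0).sum())

    @property
    def voxel_coords(self) -> np.ndarray:
        if self.coords is not None:
            return self.coords
        return np.ascontiguousarray(np.argwhere(self.levels > 0))


def _crop_to_mask(arrs: Sequence[np.ndarray], mask: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    idx = np.nonzero(mask)
    lo = [int(a.min()) for a in idx]
    hi = [int(a.max()) + 1 for a in idx]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return [a[sl] for a in arrs], mask[sl]


def discretize(vol: VolumeGrid, mask: MaskVolume, bin_width: float = DEFAULT_BIN_WIDTH) -> DiscretizedRegion:
    """Fixed-bin-width discretization anchored at the in-mask minimum.

    ``level(v) = floor((x(v) - min) / bin_width) + 1`` and
    ``G = floor((max - min) / bin_width) + 1``.
    """
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be positive, got {bin_width}")
    if mask.is_empty:
        raise InputError("cannot discretize an empty region")
    require_same_grid(vol, mask)
    return _discretize_arrays(vol.voxels, mask.voxels, bin_width)


def _discretize_arrays(voxels: np.ndarray, mask: np.ndarray, bin_width: float) -> DiscretizedRegion:
    (vals,), m = _crop_to_mask([voxels], mask)
    return _discretize_cropped(vals, m, bin_width)


def _discretize_cropped(
    vals: np.ndarray, m: np.ndarray, bin_width: float, coords: np.ndarray | None = None
) -> DiscretizedRegion:
    inside = vals[m]
    lo = inside.min()
    hi = inside.max()
    n_levels = int(np.floor((hi - lo) / bin_width)) + 1
    levels = np.zeros(vals.shape, dtype=np.int32)
    lv = np.floor((inside - lo) / bin_width).astype(np.int32) + 1
    np.clip(lv, 1, n_levels, out=lv)  # guards float round-up at the max
    levels[m] = lv
    return DiscretizedRegion(
        levels=levels, n_levels=n_levels, bin_width=float(bin_width), coords=coords
    )


# ---------------------------------------------------------------------------
# texture features

_GLCM_DEGENERATE = {"JointEntropy": 0.0, "ClusterShade": 0.0, "Imc1": 0.0, "MCC": 1.0}


def _glcm_direction_features(p: np.ndarray, which: Iterable[str]) -> dict[str, float]:
    G = p.shape[0]
    i = np.arange(1, G + 1, dtype=np.float64)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    out: dict[str, float] = {}
    for stat in which:
        if stat == "JointEntropy":
            out[stat] = float(-(p[nz] * np.log2(p[nz])).sum())
        elif stat == "ClusterShade":
            mu_x = float((i * px).sum())
            mu_y = float((i * py).sum())
            ii, jj = np.meshgrid(i, i, indexing="ij")
            out[stat] = float((((ii + jj - mu_x - mu_y) ** 3) * p).sum())
        elif stat == "Imc1":
            hxy = float(-(p[nz] * np.log2(p[nz])).sum())
            outer = px[:, None] * py[None, :]
            valid = nz & (outer > 0)
            hxy1 = float(-(p[valid] * np.log2(outer[valid])).sum())
            hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
            hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
            denom = max(hx, hy)
            out[stat] = (hxy - hxy1) / denom if denom > 0 else 0.0
        elif stat == "MCC":
            keep = px > 0
            if keep.sum() < 2:
                out[stat] = 1.0
                continue
            ps = p[np.ix_(keep, keep)]
            pxs = px[keep]
            pys = py[keep]
            q = (ps / pxs[:, None]) @ (ps / pys[None, :]).T
            lam = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
            out[stat] = float(np.sqrt(np.clip(lam[1], 0.0, 1.0)))
        else:  # pragma: no cover
            raise RegistryError(f"unknown GLCM statistic {stat!r}")
    return out


def _batch_mcc(p: np.ndarray) -> np.ndarray:
    """MCC per direction for a stack of normalized symmetric GLCMs (d, G, G).

    Q = diag(1/px) P diag(1/py) P^T is similar to the symmetric matrix
    M = C C^T with C = diag(px^-1/2) P diag(py^-1/2), so the eigenvalues
    come from a (batched) symmetric solver.
    """
    px = p.sum(axis=2)  # (d, G); symmetric => py = px
    out = np.empty(p.shape[0])
    full = (px > 0).all(axis=1)
    if full.any():
        rt = np.sqrt(px[full])
        c = p[full] / rt[:, :, None] / rt[:, None, :]
        m = c @ np.swapaxes(c, 1, 2)
        lam = np.linalg.eigvalsh(m)
        out[full] = np.sqrt(np.clip(lam[:, -2], 0.0, 1.0))
    for d in np.nonzero(~full)[0]:  # a gray level absent in this direction
        keep = px[d] > 0
        if keep.sum() < 2:
            out[d] = 1.0
            continue
        ps = p[d][np.ix_(keep, keep)]
        rt = np.sqrt(px[d][keep])
        c = ps / rt[:, None] / rt[None, :]
        lam = np.linalg.eigvalsh(c @ c.T)
        out[d] = np.sqrt(np.clip(lam[-2], 0.0, 1.0))
    return out


def glcm_features(
    region: DiscretizedRegion,
    which: Sequence[str] = ("Imc1", "MCC", "ClusterShade", "JointEntropy"),
) -> dict[str, float]:
    """Direction-averaged GLCM statistics (Chebyshev distance 1, 13 directions).

    Matrices are symmetrized and normalized per direction; directions
    with no co-occurring in-region pair are skipped from the average.
    """
    if region.voxel_count == 0:
        raise InputError("empty discretized region")
    if region.n_levels == 1:
        return {k: _GLCM_DEGENERATE[k] for k in which}
    counts = glcm_counts(
        np.ascontiguousarray(region.levels), region.voxel_coords, region.n_levels, GLCM_OFFSETS
    )
    return _glcm_stats_from_counts(counts, region.n_levels, which)


def _glcm_stats_from_counts(
    counts: np.ndarray, G: int, which: Sequence[str]
) -> dict[str, float]:
    totals = counts.sum(axis=(1, 2))
    valid = totals > 0
    if not valid.any() or G == 1:
        return {k: _GLCM_DEGENERATE[k] for k in which}
    p = counts[valid] / totals[valid][:, None, None]
    i = np.arange(1, G + 1, dtype=np.float64)
    px = p.sum(axis=2)
    py = p.sum(axis=1)
    out: dict[str, float] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        hxy = -(p * logp).sum(axis=(1, 2))
        for stat in which:
            if stat == "JointEntropy":
                out[stat] = float(hxy.mean())
            elif stat == "ClusterShade":
                mu_x = (i[None, :] * px).sum(axis=1)
                mu_y = (i[None, :] * py).sum(axis=1)
                grid = i[:, None] + i[None, :]  # (G, G) of i+j
                dev = grid[None, :, :] - (mu_x + mu_y)[:, None, None]
                out[stat] = float(((dev**3) * p).sum(axis=(1, 2)).mean())
            elif stat == "Imc1":
                outer = px[:, :, None] * py[:, None, :]
                log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
                hxy1 = -np.where(p > 0, p * log_outer, 0.0).sum(axis=(1, 2))
                hx = -np.where(px > 0, px * np.log2(np.where(px > 0, px, 1.0)), 0.0).sum(axis=1)
                hy = -np.where(py > 0, py * np.log2(np.where(py > 0, py, 1.0)), 0.0).sum(axis=1)
                denom = np.maximum(hx, hy)
                vals = np.where(denom > 0, (hxy - hxy1) / np.where(denom > 0, denom, 1.0), 0.0)
                out[stat] = float(vals.mean())
            elif stat == "MCC":
                out[stat] = float(_batch_mcc(p).mean())
            else:
                raise RegistryError(f"unknown GLCM statistic {stat!r}")
    return out


def ngtdm_busyness(region: DiscretizedRegion) -> float:
    """Neighbourhood gray-tone-difference busyness.

    ``(sum_i p_i s_i) / (sum_i sum_j |i p_i - j p_j|)`` over levels with
    positive probability; a zero denominator (single occupied level)
    returns 0.
    """
    if region.voxel_count == 0:
        raise InputError("empty discretized region")
    s, n = ngtdm_sums(np.ascontiguousarray(region.levels), region.voxel_coords, region.n_levels)
    total = n.sum()
    p = n / total
    occ = p > 0
    lv = np.arange(1, region.n_levels + 1, dtype=np.float64)
    ip = lv[occ] * p[occ]
    denom = np.abs(ip[:, None] - ip[None, :]).sum()
    if denom == 0:
        return 0.0
    return float((p[occ] * s[occ]).sum() / denom)


def firstorder_minimum(vol: VolumeGrid, mask: MaskVolume) -> float:
    """Minimum intensity over in-mask voxels."""
    if mask.is_empty:
        raise InputError("empty mask")
    require_same_grid(vol, mask)
    return float(vol.voxels[mask.voxels].min())


_FIRSTORDER = {
    "Minimum": np.min,
    "Maximum": np.max,
    "Mean": np.mean,
    "Median": np.median,
    "Variance": np.var,
}


def shape_elongation(mask: MaskVolume) -> float:
    """sqrt(lambda2 / lambda1) of the covariance of in-mask physical coordinates.

    1 for a sphere, -> 0 for a needle.  Raises for masks whose voxels are
    coplanar/collinear (covariance not full rank) or fewer than 4 voxels.
    """
    if mask.is_empty:
        raise InputError("empty mask")
    coords = np.argwhere(mask.voxels).astype(np.float64) * np.asarray(mask.spacing)
    if coords.shape[0] < 4:
        raise DegenerateShapeError("shape features need at least 4 mask voxels")
    cov = np.cov(coords.T)
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if lam[0] <= 0 or lam[2] <= 1e-9 * lam[0]:
        raise DegenerateShapeError("mask voxels are coplanar or collinear")
    return float(np.sqrt(lam[1] / lam[0]))


# ---------------------------------------------------------------------------
# feature registry / extraction

_LOG_SIGMA_RE = re.compile(r"^log_sigma_(\d+)_(\d+)_mm_3D$")
_FAMILIES = ("firstorder", "glcm", "ngtdm", "shape")


@dataclass(frozen=True)
class FeatureSpec:
    """Parsed feature name: intensity filter, feature family, statistic."""

    name: str
    filter_key: tuple  # ("original",) | ("logarithm",) | ("log_sigma", mm) | ("wavelet", "LHL")
    family: str
    stat: str


def parse_feature_name(name: str) -> FeatureSpec:
    for fam in _FAMILIES:
        token = f"_{fam}_"
        if token in name:
            prefix, stat = name.split(token, 1)
            break
    else:
        raise RegistryError(f"cannot parse feature name {name!r}")
    if prefix == "original":
        fk: tuple = ("original",)
    elif prefix == "logarithm":
        fk = ("logarithm",)
    elif prefix.startswith("wavelet_"):
        sub = prefix.split("_", 1)[1]
        if sub not in SUBBAND_NAMES:
            raise RegistryError(f"unknown wavelet subband in {name!r}")
        fk = ("wavelet", sub)
    else:
        m = _LOG_SIGMA_RE.match(prefix)
        if not m:
            raise RegistryError(f"unknown filter prefix in {name!r}")
        fk = ("log_sigma", float(f"{m.group(1)}.{m.group(2)}"))
    if fam == "shape":
        if stat != "Elongation":
            raise RegistryError(f"unsupported shape statistic {stat!r}")
    elif fam == "firstorder":
        if stat not in _FIRSTORDER:
            raise RegistryError(f"unsupported first-order statistic {stat!r}")
    elif fam == "glcm":
        if stat not in _GLCM_DEGENERATE:
            raise RegistryError(f"unsupported GLCM statistic {stat!r}")
    elif fam == "ngtdm" and stat != "Busyness":
        raise RegistryError(f"unsupported NGTDM statistic {stat!r}")
    return FeatureSpec(name=name, filter_key=fk, family=fam, stat=stat)


class FeatureExtractor:
    """Computes a named feature set over (volume, lesion, band) triples.

    Filtered volumes are computed once per patient volume and reused for
    every band of the same lesion, which makes the 121-region sweep cheap.
    """

    def __init__(self, registry: Sequence[str] = SELECTED_FEATURES, bin_width: float = DEFAULT_BIN_WIDTH):
        self.specs = [parse_feature_name(n) for n in registry]
        self.bin_width = float(bin_width)
        self._filter_keys = sorted(
            {s.filter_key for s in self.specs if s.family != "shape"}, key=str
        )

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def prepare(self, vol: VolumeGrid) -> dict[tuple, np.ndarray]:
        """Apply every needed intensity filter to one volume."""
        out: dict[tuple, np.ndarray] = {}
        wavelet_cache = None
        for fk in self._filter_keys:
            if fk[0] == "original":
                out[fk] = np.asarray(vol.voxels, dtype=np.float64)
            elif fk[0] == "logarithm":
                out[fk] = logarithm_transform(vol).voxels
            elif fk[0] == "log_sigma":
                out[fk] = laplacian_of_gaussian(vol, sigma_mm=fk[1]).voxels
            elif fk[0] == "wavelet":
                if wavelet_cache is None:
                    wavelet_cache = wavelet_subbands(vol)
                out[fk] = wavelet_cache[fk[1]].voxels
        return out

    def extract(
        self,
        filtered: Mapping[tuple, np.ndarray],
        lesion_mask: MaskVolume,
        band_voxels: np.ndarray,
        shape_cache: dict | None = None,
    ) -> dict[str, float]:
        # one bounding-box crop shared by every intensity feature; all
        # discretizations and co-occurrence passes run over the same
        # coordinate list (fused across filters for the GLCM kernel)
        idx = np.nonzero(band_voxels)
        sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
        m = band_voxels[sl]
        coords = np.ascontiguousarray(np.argwhere(m))
        values: dict[str, float] = {}
        levels_cache: dict[tuple, tuple[np.ndarray, int]] = {}

        def levels_of(fk: tuple) -> tuple[np.ndarray, int]:
            if fk not in levels_cache:
                arr = np.ascontiguousarray(filtered[fk][sl], dtype=np.float64)
                levels_cache[fk] = discretize_coords(arr, coords, self.bin_width)
            return levels_cache[fk]

        glcm_needed: dict[tuple, list[FeatureSpec]] = {}
        for fs in self.specs:
            if fs.family == "shape":
                if shape_cache is not None and fs.name in shape_cache:
                    values[fs.name] = shape_cache[fs.name]
                else:
                    values[fs.name] = shape_elongation(lesion_mask)
                    if shape_cache is not None:
                        shape_cache[fs.name] = values[fs.name]
            elif fs.family == "firstorder":
                arr = filtered[fs.filter_key][sl]
                values[fs.name] = float(_FIRSTORDER[fs.stat](arr[m]))
            elif fs.family == "glcm":
                glcm_needed.setdefault(fs.filter_key, []).append(fs)
            elif fs.family == "ngtdm":
                levels, G = levels_of(fs.filter_key)
                region = DiscretizedRegion(levels, G, self.bin_width, coords)
                values[fs.name] = ngtdm_busyness(region)
        if glcm_needed:
            keys = list(glcm_needed)
            per_filter = [levels_of(fk) for fk in keys]
            g_max = max(G for _, G in per_filter)
            stack = np.stack([lv for lv, _ in per_filter])
            counts = glcm_counts_multi(stack, coords, g_max, GLCM_OFFSETS)
            for f, fk in enumerate(keys):
                G = per_filter[f][1]
                feats = _glcm_stats_from_counts(
                    counts[f][:, :G, :G], G, [s.stat for s in glcm_needed[fk]]
                )
                for s in glcm_needed[fk]:
                    values[s.name] = feats[s.stat]
        return values


def extract_features(
    vol: VolumeGrid,
    lesion_mask: MaskVolume,
    band: MaskVolume,
    registry: Sequence[str] = SELECTED_FEATURES,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict[str, float]:
    """Compute the named features for one band of one lesion.

    Intensity features use the band mask, shape features the lesion mask.
    Raises :class:`InputError` on an empty band.
    """
    require_same_grid(vol, lesion_mask)
    require_same_grid(vol, band)
    if band.is_empty:
        raise InputError("band is empty; mark this patient-region missing upstream")
    ex = FeatureExtractor(registry, bin_width)
    return ex.extract(ex.prepare(vol), lesion_mask, band.voxels)


def extract_features_by_spec(
    vol: VolumeGrid,
    lesion_mask: MaskVolume,
    specs: Sequence[MarginBandSpec],
    registry: Sequence[str] = SELECTED_FEATURES,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict[MarginBandSpec, dict[str, float] | None]:
    """All band specs of one lesion; ``None`` marks empty (missing) bands.

    The distance fields and filtered volumes are shared across specs.
    """
    require_same_grid(vol, lesion_mask)
    ex = FeatureExtractor(registry, bin_width)
    filtered = ex.prepare(vol)
    dist_in, dist_out = band_distance_fields(lesion_mask)
    shape_cache: dict = {}
    out: dict[MarginBandSpec, dict[str, float] | None] = {}
    for spec in specs:
        band = band_from_distances(lesion_mask, dist_in, dist_out, spec)
        if band.is_empty:
            out[spec] = None
            continue
        out[spec] = ex.extract(filtered, lesion_mask, band.voxels, shape_cache)
    return out


# ---------------------------------------------------------------------------
# reproducibility filter


def icc_filter(
    rater_a: pd.DataFrame,
    rater_b: pd.DataFrame,
    threshold: float = 0.75,
) -> tuple[list[str], pd.Series]:
    """Retain features whose two-rater ICC exceeds *threshold* (strictly).

    Uses the two-way random-effects, absolute-agreement, single-measure
    coefficient (ICC2).  Inputs are patients x features frames indexed by
    patient id; only shared patients and feature columns are compared.
    """
    import pingouin as pg  # deferred: slow import

    patients = rater_a.index.intersection(rater_b.index)
    features = [c for c in rater_a.columns if c in rater_b.columns]
    if len(patients) < 3:
        raise InputError(f"ICC needs >= 3 shared patients, got {len(patients)}")
    if not features:
        raise InputError("no shared feature columns between raters")
    iccs = {}
    for feat in features:
        long = pd.DataFrame(
            {
                "patient": np.tile(patients, 2),
                "rater": np.repeat(["a", "b"], len(patients)),
                "value": np.concatenate(
                    [rater_a.loc[patients, feat].to_numpy(), rater_b.loc[patients, feat].to_numpy()]
                ),
            }
        )
        import warnings

        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            res = pg.intraclass_corr(
                data=long, targets="patient", raters="rater", ratings="value"
            ).set_index("Type")
        key = "ICC(A,1)" if "ICC(A,1)" in res.index else "ICC2"
        iccs[feat] = float(res.loc[key, "ICC"])
    icc_series = pd.Series(iccs, name="ICC")
    retained = [f for f in features if icc_series[f] > threshold]
    return retained, icc_series
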
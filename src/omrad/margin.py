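"""Margin-band VOI geometry.

A margin band is parameterized by an inward erosion depth and an outward
expansion distance, both in millimetres:

    band(inner a, outer b) = dilate(mask, b) \\ erode(mask, a)

with a Euclidean ball structuring element of the stated radius.  On an
isotropic grid both morphological operations are thresholds of the exact
Euclidean distance transform, which is how they are computed here:

    dilate(mask, b) = mask  OR  {background voxel : dist to mask <= b}
    erode(mask, a)  = {mask voxel : dist to background > a}

Sweeping inner and outer over the integers 0..10 mm yields 120 band
regions; together with the unmodified lesion VOI each lesion contributes
121 regions.  The (0,0) pair is the empty set and is excluded from the
sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError, PairingError, ParameterError
from .image_io import MaskVolume, require_same_grid

__all__ = [
    "MarginBandSpec",
    "NontargetReport",
    "enumerate_band_specs",
    "band_distance_fields",
    "make_band",
    "band_from_distances",
    "nontarget_report",
]


@dataclass(frozen=True, order=True)
class MarginBandSpec:
    """(inner erosion mm, outer expansion mm) band parameterization.

    ``is_original`` marks the unmodified lesion VOI, which is a region of
    its own, distinct from any (inner, outer) pair.
    """

    inner_mm: int = 0
    outer_mm: int = 0
    is_original: bool = False

    def __post_init__(self) -> None:
        if self.inner_mm < 0 or self.outer_mm < 0:
            raise ParameterError("band widths must be non-negative integers")

    @property
    def is_degenerate(self) -> bool:
        """The (0,0) non-original band is the empty set."""
        return not self.is_original and self.inner_mm == 0 and self.outer_mm == 0

    @property
    def width(self) -> int:
        return self.inner_mm + self.outer_mm

    @property
    def name(self) -> str:
        if self.is_original:
            return "original"
        return f"in{self.inner_mm}_out{self.outer_mm}"


def enumerate_band_specs(max_mm: int = 10, include_original: bool = True) -> list[MarginBandSpec]:
    """All integer (inner, outer) bands in [0, max_mm]^2 except (0,0).

    Order: the original VOI first (when requested), then lexicographic in
    (inner_mm, outer_mm).  ``max_mm=10`` yields 120 bands, 121 specs with
    the original.
    """
    if max_mm < 1:
        raise ParameterError(f"max_mm must be >= 1, got {max_mm}")
    specs: list[MarginBandSpec] = []
    if include_original:
        specs.append(MarginBandSpec(is_original=True))
    for inner in range(max_mm + 1):
        for outer in range(max_mm + 1):
            if inner == 0 and outer == 0:
                continue
            specs.append(MarginBandSpec(inner, outer))
    return specs


def _check_band_inputs(mask: MaskVolume) -> None:
    if mask.is_empty:
        raise InputError("band geometry requires a nonempty lesion mask")
    if not mask.is_isotropic:
        raise ParameterError(
            f"band geometry requires an isotropic grid, spacing is {mask.spacing}"
        )


def band_distance_fields(mask: MaskVolume) -> tuple[np.ndarray, np.ndarray]:
    """Exact Euclidean distances (mm) defining every band of one lesion.

    Returns ``(dist_in, dist_out)``: for mask voxels the distance to the
    nearest background voxel centre, for background voxels the distance
    to the nearest mask voxel centre (each zero on the other side).
    Computing these once serves the whole 121-region sweep.
    """
    _check_band_inputs(mask)
    m = mask.voxels
    s = mask.spacing[0]
    dist_in = ndimage.distance_transform_edt(m, sampling=s)
    dist_out = ndimage.distance_transform_edt(~m, sampling=s)
    return dist_in, dist_out


def band_from_distances(
    mask: MaskVolume, dist_in: np.ndarray, dist_out: np.ndarray, spec: MarginBandSpec
) -> MaskVolume:
    """Construct one band from precomputed distance fields."""
    if spec.is_original:
        return mask
    m = mask.voxels
    # erode(a) keeps dist_in > a; dilate(b) adds dist_out <= b
    band = (m & (dist_in <= spec.inner_mm)) | (~m & (dist_out <= spec.outer_mm))
    return MaskVolume(band, mask.spacing, mask.origin)


def make_band(mask: MaskVolume, spec: MarginBandSpec) -> MaskVolume:
    """dilate(mask, outer) minus erode(mask, inner), Euclidean ball radii in mm.

    The degenerate (0,0) non-original spec returns an empty mask (flagged
    through :attr:`MaskVolume.is_empty`) rather than raising; an erosion
    that consumes a small lesion with ``outer_mm=0`` does the same.
    """
    _check_band_inputs(mask)
    if spec.is_original:
        return mask
    if spec.is_degenerate:
        return MaskVolume(np.zeros(mask.shape, dtype=bool), mask.spacing, mask.origin)
    dist_in, dist_out = band_distance_fields(mask)
    return band_from_distances(mask, dist_in, dist_out, spec)


@dataclass(frozen=True)
class NontargetReport:
    """Per-band count of voxels falling outside the organ (liver) label."""

    spec: MarginBandSpec
    assessable: bool
    counts_by_label: dict[int, int]

    @property
    def total_outside(self) -> int:
        return sum(self.counts_by_label.values())

    @property
    def flagged(self) -> bool:
        return self.total_outside > 0

    def to_frame(self, patient_id: str = "") -> pd.DataFrame:
        rows = [
            {
                "patient_id": patient_id,
                "inner_mm": self.spec.inner_mm,
                "outer_mm": self.spec.outer_mm,
                "label": label,
                "voxels_outside": n,
            }
            for label, n in sorted(self.counts_by_label.items())
        ]
        if not rows:
            rows = [
                {
                    "patient_id": patient_id,
                    "inner_mm": self.spec.inner_mm,
                    "outer_mm": self.spec.outer_mm,
                    "label": -1,
                    "voxels_outside": 0,
                }
            ]
        return pd.DataFrame(rows)


def nontarget_report(
    band: MaskVolume,
    organ_mask=None,
    spec: MarginBandSpec | None = None,
    liver_label: int = 1,
) -> NontargetReport:
    """Count band voxels lying outside the organ label.

    ``organ_mask`` is an integer label volume (a :class:`VolumeGrid` or a
    raw array on the same grid) in which ``liver_label`` marks target
    tissue; any other value is a nontarget label and is counted
    separately.  When no organ mask is available the report is marked not
    assessable instead of raising.
    """
    spec = spec if spec is not None else MarginBandSpec(is_original=True)
    if organ_mask is None:
        return NontargetReport(spec=spec, assessable=False, counts_by_label={})
    organ = organ_mask.voxels if hasattr(organ_mask, "voxels") else np.asarray(organ_mask)
    if organ.shape != band.shape:
        raise PairingError(
            f"band and organ mask shapes differ: {band.shape} vs {organ.shape}"
        )
    if hasattr(organ_mask, "same_grid"):
        require_same_grid(band, organ_mask, "band and organ mask")
    outside = band.voxels & (organ.astype(np.int64) != liver_label)
    labels, counts = np.unique(organ[outside], return_counts=True)
    return NontargetReport(
        spec=spec,
        assessable=True,
        counts_by_label={int(l): int(c) for l, c in zip(labels, counts)},
    )
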
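"""Isocontour volumetry, TNR estimation and planar lung-shunt quantification.

The target volume on an activity map (MAA SPECT/CT or 90Y PET/CT) is
segmented with a percentage isocontour: every voxel inside a search VOI
whose value is at least ``threshold_pct`` percent of the VOI-local maximum
belongs to the "molecular tumor volume" (MTV). The threshold references the
maximum inside the search VOI, comparison is inclusive (>=), and no
connectivity filtering is applied.

The hepatopulmonary shunt (HPS) is quantified on conjugate planar views
with geometric-mean counts: for each ROI, GM = sqrt(sum_anterior x
sum_posterior), and HPS = GM_lung / (GM_lung + GM_liver). A shunt above 20%
contraindicates treatment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np

__all__ = [
    "ActivityMap",
    "VOIMask",
    "VolumetryResult",
    "PlanarScan",
    "ShuntResult",
    "isocontour_volume",
    "fit_isocontour_to_reference",
    "tumor_to_normal_ratio",
    "lung_shunt_fraction",
    "load_activity_map",
    "save_activity_map",
    "load_mask",
    "save_mask",
]

HPS_CONTRAINDICATION = 0.20


@dataclass(frozen=True)
class ActivityMap:
    """3-D voxel grid of non-negative activity (arbitrary units) + spacing (mm)."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 3:
            raise ValueError("activity map must be 3-D")
        if np.any(v < 0):
            raise ValueError("activity values must be >= 0")
        sp = tuple(float(s) for s in self.spacing_mm)
        object.__setattr__(self, "spacing_mm", sp)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing_mm must be three positive values")

    @property
    def voxel_ml(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz / 1000.0  # mm^3 -> ml


@dataclass(frozen=True)
class VOIMask:
    """Boolean voxel mask aligned to an :class:`ActivityMap`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 3:
            raise ValueError("VOI mask must be 3-D")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class VolumetryResult:
    mtv_ml: float
    threshold_pct: float
    voxel_count: int
    mask: VOIMask

    def to_json(self) -> str:
        return json.dumps(
            {
                "mtv_ml": self.mtv_ml,
                "threshold_pct": self.threshold_pct,
                "voxel_count": self.voxel_count,
            }
        )


@dataclass(frozen=True)
class PlanarScan:
    """Anterior/posterior planar count maps with lung and liver ROIs."""

    anterior: np.ndarray
    posterior: np.ndarray
    lung_roi: np.ndarray
    liver_roi: np.ndarray

    def __post_init__(self) -> None:
        ant = np.asarray(self.anterior, dtype=float)
        post = np.asarray(self.posterior, dtype=float)
        lung = np.asarray(self.lung_roi, dtype=bool)
        liver = np.asarray(self.liver_roi, dtype=bool)
        for name, arr in (("anterior", ant), ("posterior", post)):
            if arr.ndim != 2 or np.any(arr < 0):
                raise ValueError(f"{name} must be a 2-D non-negative count map")
        if not (ant.shape == post.shape == lung.shape == liver.shape):
            raise ValueError("count maps and ROIs must share one shape")
        if np.any(lung & liver):
            raise ValueError("lung and liver ROIs must be disjoint")
        object.__setattr__(self, "anterior", ant)
        object.__setattr__(self, "posterior", post)
        object.__setattr__(self, "lung_roi", lung)
        object.__setattr__(self, "liver_roi", liver)


@dataclass(frozen=True)
class ShuntResult:
    hps: float
    contraindicated: bool
    gm_lung: float
    gm_liver: float


def _check_threshold(threshold_pct: float) -> None:
    if not (1.0 <= threshold_pct <= 100.0):
        raise ValueError("threshold_pct must be in [1, 100]")


def isocontour_volume(
    amap: ActivityMap, search_voi: VOIMask, threshold_pct: float
) -> VolumetryResult:
    """Segment the MTV at ``threshold_pct`` percent of the VOI-local maximum.

    Voxels with value >= threshold are included, so a uniform map yields the
    full VOI even at 100%. Raises if the VOI contains no signal.
    """
    _check_threshold(threshold_pct)
    if search_voi.mask.shape != amap.values.shape:
        raise ValueError("search VOI shape must match the activity map")
    inside = amap.values[search_voi.mask]
    if inside.size == 0 or inside.max() <= 0:
        raise ValueError("no signal in VOI")
    cutoff = threshold_pct / 100.0 * inside.max()
    selected = search_voi.mask & (amap.values >= cutoff)
    count = int(selected.sum())
    return VolumetryResult(count * amap.voxel_ml, float(threshold_pct), count, VOIMask(selected))


def fit_isocontour_to_reference(
    amap: ActivityMap,
    search_voi: VOIMask,
    reference_ml: float,
    candidate_pcts: Sequence[float],
) -> VolumetryResult:
    """Pick the candidate threshold whose MTV is closest to a reference volume.

    Emulates the per-patient visual adjustment of the isocontour level; ties
    resolve to the lower threshold.
    """
    cands = sorted(float(c) for c in candidate_pcts)
    if not cands:
        raise ValueError("candidate_pcts must be non-empty")
    for c in cands:
        _check_threshold(c)
    best: Optional[VolumetryResult] = None
    best_err = math.inf
    for c in cands:  # ascending, so strict '<' keeps the lower tied threshold
        res = isocontour_volume(amap, search_voi, c)
        err = abs(res.mtv_ml - reference_ml)
        if err < best_err:
            best, best_err = res, err
    assert best is not None
    return best


def tumor_to_normal_ratio(
    amap: ActivityMap, tumor_vois: Sequence[VOIMask], normal_voi: VOIMask
) -> float:
    """Unweighted mean over tumors of (tumor mean uptake / normal mean uptake)."""
    if not tumor_vois:
        raise ValueError("need at least one tumor VOI")
    if normal_voi.voxel_count == 0:
        raise ValueError("normal VOI is empty")
    normal_mean = float(amap.values[normal_voi.mask].mean())
    if normal_mean <= 0:
        raise ValueError("zero uptake in normal VOI")
    ratios = []
    for voi in tumor_vois:
        if voi.voxel_count == 0:
            raise ValueError("empty tumor VOI")
        ratios.append(float(amap.values[voi.mask].mean()) / normal_mean)
    return float(np.mean(ratios))


def lung_shunt_fraction(scan: PlanarScan) -> ShuntResult:
    """Geometric-mean HPS from conjugate planar views.

    GM(ROI) = sqrt(anterior-sum x posterior-sum); HPS = GM(lung) /
    (GM(lung) + GM(liver)). Contraindicated above 20%.
    """
    gm_lung = math.sqrt(
        float(scan.anterior[scan.lung_roi].sum()) * float(scan.posterior[scan.lung_roi].sum())
    )
    gm_liver = math.sqrt(
        float(scan.anterior[scan.liver_roi].sum()) * float(scan.posterior[scan.liver_roi].sum())
    )
    if gm_liver <= 0:
        raise ValueError("no counts in liver ROI")
    hps = gm_lung / (gm_lung + gm_liver)
    return ShuntResult(hps, hps > HPS_CONTRAINDICATION, gm_lung, gm_liver)


# ---------------------------------------------------------------------------
# NIfTI IO


def _affine(spacing_mm: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_activity_map(amap: ActivityMap, path: Union[str, Path]) -> None:
    nib.save(nib.Nifti1Image(amap.values.astype(np.float32), _affine(amap.spacing_mm)), str(path))


def load_activity_map(path: Union[str, Path]) -> ActivityMap:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ActivityMap(np.asarray(img.dataobj, dtype=float), spacing)


def save_mask(mask: VOIMask, spacing_mm: Sequence[float], path: Union[str, Path]) -> None:
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(spacing_mm)), str(path))


def load_mask(path: Union[str, Path]) -> VOIMask:
    img = nib.load(str(path))
    return VOIMask(np.asarray(img.dataobj) > 0)
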
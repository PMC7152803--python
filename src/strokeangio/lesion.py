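"""Ischemic lesion segmentation and longitudinal area trajectories.

The photothrombotic lesion appears on en-face angiograms as a dark,
avascular region against the bright surrounding capillary bed.  Area is
measured per imaging depth and per timepoint; trajectories are normalized to
the day-8 value, the earliest day at which the lesion fits fully in the
field of view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk

from .angiogram import EnFaceMap


@dataclass
class LesionMask:
    """Binary lesion mask with area, centroid and provenance."""

    mask: np.ndarray
    area_px: int
    center_xy: tuple[float, float]  # (cx, cy), NaN when empty
    depth_um: float | None = None
    source: str = "automated"

    @classmethod
    def from_array(cls, mask: np.ndarray, depth_um: float | None = None,
                   source: str = "automated") -> "LesionMask":
        mask = np.asarray(mask, dtype=bool)
        area = int(mask.sum())
        if area:
            cy, cx = ndimage.center_of_mass(mask)
        else:
            cx = cy = float("nan")
        return cls(mask=mask, area_px=area, center_xy=(float(cx), float(cy)),
                   depth_um=depth_um, source=source)

    @property
    def is_empty(self) -> bool:
        return self.area_px == 0


@dataclass
class LesionTrajectory:
    """Per-depth lesion areas over timepoints, normalized to a reference day."""

    timepoints_days: list[float]
    depths_um: list[float]
    area_px: pd.DataFrame          # index = day, columns = depth
    normalized_area: pd.DataFrame  # area / area(reference_day), per depth
    reference_day: float


def segment_lesion(
    enface: EnFaceMap | np.ndarray,
    vessel_mask: np.ndarray | None = None,
    smooth_sigma: float = 3.0,
    dark_quantile: float = 0.02,
    closing_radius_px: int = 5,
    min_component_px: int = 100,
    min_solidity: float = 0.9,
    depth_um: float | None = None,
) -> LesionMask:
    """Automated lesion segmentation: largest dark, vessel-free region.

    Deterministic surrogate for manual outlining.  The en-face map is
    Gaussian-smoothed (``smooth_sigma``, so the vascularized bed reads as a
    high local mean) and thresholded at the midpoint between the dark-core
    level (the ``dark_quantile`` intensity quantile) and the vascularized
    level (the image median): for a blurred step edge the half-contrast
    contour sits on the true boundary, making the recovered area insensitive
    to the smoothing scale.  The dark region is restricted to vessel-free
    pixels when a vessel mask is given, morphologically closed, and reduced
    to the largest connected component that is at least ``min_component_px``
    large and at least ``min_solidity`` solid (the photothrombotic lesion is
    a compact, roughly elliptical region, unlike the ragged inter-capillary
    pockets of normally vascularized tissue); the winner is hole-filled.
    Returns an empty mask (with a warning) when no component qualifies.
    """
    img = enface.image if isinstance(enface, EnFaceMap) else np.asarray(enface, float)
    smoothed = ndimage.gaussian_filter(img, smooth_sigma)
    dark = np.quantile(smoothed, dark_quantile)
    bright = np.median(smoothed)
    thr = 0.5 * (dark + bright)
    low = smoothed <= thr
    if vessel_mask is not None:
        low &= ~np.asarray(vessel_mask, bool)
    if closing_radius_px > 0:
        low = ndimage.binary_closing(low, structure=disk(closing_radius_px))
    labels, n = ndimage.label(low)
    if n:
        from skimage.measure import regionprops

        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        solidity = np.zeros(n)
        for prop in regionprops(labels):
            solidity[prop.label - 1] = prop.solidity
        # the scan protocol centers the ROI on the lesion, so dark pockets
        # touching the image border are background, not lesion — unless
        # nothing else qualifies
        border = np.unique(np.concatenate([
            labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
        interior = np.ones(n, dtype=bool)
        interior[border[border > 0] - 1] = False
        qualified = (sizes >= min_component_px) & (solidity >= min_solidity)
        for candidates in (np.flatnonzero(interior & qualified),
                           np.flatnonzero(qualified)):
            if candidates.size:
                best = int(candidates[np.argmax(sizes[candidates])]) + 1
                mask = ndimage.binary_fill_holes(labels == best)
                return LesionMask.from_array(mask, depth_um=depth_um,
                                             source="automated")
    warnings.warn("no lesion component above minimum size: empty lesion mask",
                  stacklevel=2)
    return LesionMask.from_array(np.zeros(img.shape, bool), depth_um=depth_um,
                                 source="automated")


def load_manual_lesion(path, expected_shape: tuple[int, int] | None = None,
                       depth_um: float | None = None) -> LesionMask:
    """Load a manually drawn lesion mask (TIFF/PNG, strictly two-valued).

    Manual masks are the authoritative path; the automated operator above is
    the reproducible surrogate.
    """
    import tifffile
    from imageio.v3 import imread

    path = str(path)
    arr = tifffile.imread(path) if path.lower().endswith((".tif", ".tiff")) else imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse any color axis
        arr = arr.max(axis=-1)
    levels = np.unique(arr)
    if len(levels) > 2:
        raise ValueError(f"manual mask is not binary: {len(levels)} distinct values")
    mask = arr > levels.min() if len(levels) == 2 else np.zeros_like(arr, bool)
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise ValueError(f"mask shape {mask.shape} != expected {tuple(expected_shape)}")
    return LesionMask.from_array(mask, depth_um=depth_um, source="manual")


def lesion_trajectory(
    masks: dict[float, dict[float, LesionMask | int]],
    reference_day: float = 8.0,
) -> LesionTrajectory:
    """Normalize per-depth lesion areas to the reference (day 8) value.

    ``masks`` maps day -> {depth_um -> LesionMask or raw pixel area}.  Each
    depth requires an entry at ``reference_day``; a zero reference area
    leaves that depth's normalized column as NaN (flagged with a warning).
    """
    days = sorted(masks)
    if reference_day not in masks:
        raise ValueError(f"reference day {reference_day} missing")
    depths = sorted({d for per_depth in masks.values() for d in per_depth})

    def area_of(v):
        return v.area_px if isinstance(v, LesionMask) else int(v)

    area = pd.DataFrame(index=days, columns=depths, dtype=float)
    for day, per_depth in masks.items():
        for depth, m in per_depth.items():
            area.loc[day, depth] = area_of(m)

    norm = area.copy()
    for depth in depths:
        ref = area.loc[reference_day, depth]
        if not np.isfinite(ref) or ref == 0:
            warnings.warn(f"reference area is 0/missing at depth {depth}: "
                          "normalization undefined", stacklevel=2)
            norm[depth] = np.nan
        else:
            norm[depth] = area[depth] / ref

    return LesionTrajectory(timepoints_days=days, depths_um=depths,
                            area_px=area, normalized_area=norm,
                            reference_day=reference_day)


def depth_pair_scatter(traj: LesionTrajectory) -> pd.DataFrame:
    """Adjacent-depth area pairs (shallower on x, deeper on y), per timepoint.

    When the lesion grows with depth every point lies above the y = x line.
    """
    rows = []
    for d_lo, d_hi in zip(traj.depths_um[:-1], traj.depths_um[1:]):
        for day in traj.timepoints_days:
            rows.append({
                "day": day,
                "depth_shallow_um": d_lo,
                "depth_deep_um": d_hi,
                "area_shallow_px": traj.area_px.loc[day, d_lo],
                "area_deep_px": traj.area_px.loc[day, d_hi],
            })
    return pd.DataFrame(rows)
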
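"""Lesion-center-referenced capillary orientation statistics.

Three per-pixel angle maps drive the analysis, all undirected (mod pi) and
reduced into [-pi/2, pi/2), with the image convention x to the right and y
pointing down:

* ``alpha`` — local structure orientation from the structure tensor of the
  vessel-enhanced en-face angiogram;
* ``beta`` — orientation of the line through the pixel and the ischemic
  lesion center;
* ``theta = wrap_pi(alpha - beta)`` — orientation relative to the lesion
  direction; ``theta = 0`` means the local capillary points at the lesion.

Capillaries with ``|theta| <= pi/12`` (+/-15 deg) count as aligned with the
lesion direction; the aligned fraction over the vessel mask is the headline
radial-reorganization statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage

from .synthgen import wrap_half_pi
from .vessels import SegmentGraph, VesselMask

ALIGNMENT_HALF_ANGLE = np.pi / 12  # +/-15 deg


@dataclass
class OrientationMaps:
    """Per-pixel alpha/beta/theta/coherence maps plus the lesion center."""

    alpha: np.ndarray
    beta: np.ndarray
    theta: np.ndarray
    coherence: np.ndarray
    center_xy: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "theta"):
            a = getattr(self, name)
            if np.any(a < -np.pi / 2) or np.any(a >= np.pi / 2):
                raise ValueError(f"{name} outside [-pi/2, pi/2)")
        if np.any(self.coherence < 0) or np.any(self.coherence > 1):
            raise ValueError("coherence outside [0, 1]")


@dataclass
class AngularDistribution:
    """Histogram of theta over vessel pixels and the aligned fraction."""

    bin_edges: np.ndarray
    counts: np.ndarray
    aligned_fraction: float
    n_pixels: int

    def as_dataframe(self):
        import pandas as pd

        frac = self.counts / max(self.n_pixels, 1)
        return pd.DataFrame({
            "bin_lo_rad": self.bin_edges[:-1],
            "bin_hi_rad": self.bin_edges[1:],
            "count": self.counts,
            "fraction": frac,
        })


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------

def structure_tensor_orientation(
    image: np.ndarray,
    grad_sigma: float = 1.0,
    window_sigma: float = 3.0,
    eps: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel dominant structure orientation and coherence.

    The structure tensor is the Gaussian-windowed (``window_sigma``) outer
    product of Gaussian-derivative gradients (``grad_sigma``):
    ``J = G * [Ix^2, IxIy; IxIy, Iy^2]``.  The dominant eigenvector of J is
    the gradient direction; the structure (ridge) orientation ``alpha`` is
    perpendicular to it, reduced into [-pi/2, pi/2).  Coherence is
    ``(l_max - l_min)/(l_max + l_min)``, set to 0 where the tensor trace is
    below ``eps`` (featureless regions).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expects a 2-D image")
    Iy = ndimage.gaussian_filter(image, grad_sigma, order=(1, 0))
    Ix = ndimage.gaussian_filter(image, grad_sigma, order=(0, 1))
    Jxx = ndimage.gaussian_filter(Ix * Ix, window_sigma)
    Jxy = ndimage.gaussian_filter(Ix * Iy, window_sigma)
    Jyy = ndimage.gaussian_filter(Iy * Iy, window_sigma)

    grad_orient = 0.5 * np.arctan2(2.0 * Jxy, Jxx - Jyy)
    alpha = wrap_half_pi(grad_orient + np.pi / 2.0)

    trace = Jxx + Jyy
    root = np.sqrt((Jxx - Jyy) ** 2 + 4.0 * Jxy ** 2)
    coherence = np.where(trace > eps, root / np.maximum(trace, eps), 0.0)
    return alpha, np.clip(coherence, 0.0, 1.0)


def synthesize_beta_map(
    shape: tuple[int, int], center_xy: tuple[float, float]
) -> np.ndarray:
    """Orientation of the line through each pixel and the lesion center.

    ``beta = atan2(cy - py, cx - px)`` reduced mod pi into [-pi/2, pi/2):
    undirected, matching ``alpha``.  A pixel coinciding with the center gets
    beta = 0.  The center may lie outside the image.
    """
    ny, nx = shape
    cx, cy = center_xy
    py, px = np.mgrid[0:ny, 0:nx]
    dy = cy - py
    dx = cx - px
    beta = wrap_half_pi(np.arctan2(dy, dx))
    at_center = (dy == 0) & (dx == 0)
    if at_center.any():
        beta = np.where(at_center, 0.0, beta)
    return beta


def theta_map(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """``theta = alpha - beta`` wrapped into [-pi/2, pi/2) (mod pi)."""
    alpha = np.asarray(alpha, float)
    beta = np.asarray(beta, float)
    if alpha.shape != beta.shape:
        raise ValueError(f"shape mismatch: {alpha.shape} vs {beta.shape}")
    return wrap_half_pi(alpha - beta)


def compute_orientation_maps(
    enhanced: np.ndarray,
    center_xy: tuple[float, float],
    grad_sigma: float = 1.0,
    window_sigma: float = 3.0,
) -> OrientationMaps:
    """Full alpha/beta/theta/coherence stack for one enhanced en-face map."""
    alpha, coherence = structure_tensor_orientation(enhanced, grad_sigma, window_sigma)
    beta = synthesize_beta_map(enhanced.shape, center_xy)
    theta = theta_map(alpha, beta)
    return OrientationMaps(alpha=alpha, beta=beta, theta=theta,
                           coherence=coherence, center_xy=tuple(center_xy))


# ---------------------------------------------------------------------------
# Distribution statistics
# ---------------------------------------------------------------------------

def angular_distribution(
    theta: np.ndarray,
    mask: VesselMask | np.ndarray,
    coherence: np.ndarray | None = None,
    n_bins: int = 18,
    coherence_floor: float = 0.0,
) -> AngularDistribution:
    """Histogram theta over vessel pixels; aligned fraction at |theta|<=pi/12.

    Pixels are optionally gated by ``coherence >= coherence_floor`` (default
    floor 0 includes everything).
    """
    m = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask, bool)
    if m.shape != np.shape(theta):
        raise ValueError("mask/theta shape mismatch")
    if coherence is not None and coherence_floor > 0:
        m = m & (np.asarray(coherence) >= coherence_floor)
    vals = np.asarray(theta)[m]
    if vals.size == 0:
        raise ValueError("empty vessel mask: no pixels to histogram")
    edges = np.linspace(-np.pi / 2, np.pi / 2, n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    aligned = float(np.mean(np.abs(vals) <= ALIGNMENT_HALF_ANGLE))
    return AngularDistribution(bin_edges=edges, counts=counts,
                               aligned_fraction=aligned, n_pixels=int(vals.size))


def segment_theta_values(
    theta: np.ndarray, graph: SegmentGraph
) -> np.ndarray:
    """One theta per segment: circular (mod pi) mean over its chain pixels.

    Gives a segment-weighted alternative to the per-pixel histogram; the
    values are approximately independent draws, one per capillary segment.
    """
    out = []
    for seg in graph.segments:
        t = theta[seg.pixels[:, 0], seg.pixels[:, 1]]
        # mod-pi circular mean via angle doubling
        z = np.exp(2j * t).mean()
        out.append(float(wrap_half_pi(0.5 * np.angle(z))))
    return np.array(out)


def aligned_fraction_of(values: np.ndarray) -> float:
    """Fraction of orientations within the +/-15 deg alignment band."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("no orientation values")
    return float(np.mean(np.abs(values) <= ALIGNMENT_HALF_ANGLE))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_hsv(
    theta: np.ndarray, coherence: np.ndarray, image: np.ndarray
) -> np.ndarray:
    """HSV composite: hue = orientation, saturation = coherence, value = image.

    ``hue = (theta + pi/2)/pi`` maps [-pi/2, pi/2) onto the full color wheel,
    so theta = -pi/2 and theta -> +pi/2 meet at the same (wrapped) hue —
    consistent with theta being an undirected mod-pi angle.  The brightness
    channel is the input image min-max rescaled to [0, 1].
    """
    img = np.asarray(image, float)
    lo, hi = img.min(), img.max()
    value = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    hsv = np.stack([
        (np.asarray(theta) + np.pi / 2) / np.pi,
        np.clip(np.asarray(coherence), 0, 1),
        value,
    ], axis=-1)
    return hsv_to_rgb(hsv)
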
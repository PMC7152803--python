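"""Synthetic cortical vascular scenes with known ground truth.

Every downstream stage (angiogram construction, vessel enhancement,
orientation statistics, lesion quantification, stall detection) is validated
against scenes produced here: straight capillary tubes laid on a lateral
grid, an optional avascular lesion disk, a controllable fraction of segments
oriented toward the lesion center, complex repeated B-frames with bulk phase
and speckle-like noise, and per-segment intermittent stall events painted
into a time series.

The defaults emulate the study geometry: a 1 mm x 1 mm region sampled as a
450 x 500 lateral grid, 2 repeated B-scans per slow-axis position, and
60-frame angiogram time series.  :meth:`SceneSpec.small` gives the 128 x 128
grid used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .angiogram import AngiogramSeries, BFramePair

_HALF_PI = np.pi / 2.0


def wrap_half_pi(angle):
    """Wrap an undirected orientation (mod pi) into [-pi/2, pi/2)."""
    return (np.asarray(angle) + _HALF_PI) % np.pi - _HALF_PI


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and signal parameters of a synthetic vascular scene.

    Lateral grid is ``grid_ny`` slow-axis positions by ``grid_nx`` A-lines
    (y, x); ``grid_nz`` axial pixels are only used when rendering complex
    B-frames.  ``align_fraction`` of the ``n_segments`` straight tubes are
    laid along the local direction to ``lesion_center_xy`` (so their true
    orientation offset theta is 0, up to ``aligned_jitter_rad``); the rest
    get theta drawn uniformly on [-pi/2, pi/2).  A disk of
    ``lesion_radius_px`` around the center is kept avascular.
    """

    grid_nx: int = 500
    grid_ny: int = 450
    grid_nz: int = 64
    roi_size_um: float = 1000.0
    n_segments: int = 200
    align_fraction: float = 0.0
    lesion_center_xy: tuple[float, float] | None = None
    lesion_radius_px: int = 0
    vessel_radius_px: int = 1
    vessel_intensity: float = 1.0
    background_intensity: float = 0.05
    noise_sigma: float = 0.02
    seed: int = 0
    segment_length_px: tuple[float, float] = (14.0, 30.0)
    aligned_jitter_rad: float = 0.0
    non_touching: bool = False
    max_overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.align_fraction <= 1.0:
            raise ValueError("align_fraction must be in [0, 1]")
        if min(self.grid_nx, self.grid_ny, self.grid_nz, self.n_segments) <= 0:
            raise ValueError("all counts must be positive")
        if self.vessel_radius_px < 0 or self.lesion_radius_px < 0:
            raise ValueError("radii must be non-negative")
        if self.aligned_jitter_rad > np.pi / 12:
            raise ValueError("aligned jitter must keep |theta| <= pi/12")
        cx, cy = self.center_xy
        r = self.lesion_radius_px
        if r > 0 and not (
            0 <= cx - r and cx + r < self.grid_nx and 0 <= cy - r and cy + r < self.grid_ny
        ):
            raise ValueError("lesion disk must lie inside the grid")

    @property
    def center_xy(self) -> tuple[float, float]:
        if self.lesion_center_xy is not None:
            return tuple(self.lesion_center_xy)
        return ((self.grid_nx - 1) / 2.0, (self.grid_ny - 1) / 2.0)

    @classmethod
    def small(cls, **overrides) -> "SceneSpec":
        """128 x 128 grid with ~200 segments — the test-suite default."""
        defaults = dict(grid_nx=128, grid_ny=128, grid_nz=48, roi_size_um=256.0,
                        n_segments=200)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class StallProcessSpec:
    """Bernoulli stall process painted into an angiogram time series.

    Each of the ``stall_segment_fraction`` eligible segments independently
    stalls in each of ``n_frames`` frames with probability ``stall_prob``.
    A stall occupies the whole frame (inter-volume spacing >= 10 s, so
    sub-frame dynamics are not resolved).  The defaults give roughly half of
    the ever-stalled segments a single event over 60 frames, matching a
    quiescent baseline.
    """

    n_frames: int = 60
    stall_prob: float = 0.025
    stall_segment_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        for p in (self.stall_prob, self.stall_segment_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-scene truth for validation.

    ``segment_theta`` holds each segment's true orientation relative to the
    lesion-center direction (radians in [-pi/2, pi/2)); ``stall_log`` maps
    segment index -> sorted array of stalled frame indices (filled when a
    series is rendered).
    """

    segment_centerlines: list[np.ndarray]
    segment_theta: np.ndarray
    lesion_mask: np.ndarray
    lesion_area_px: int
    stall_log: dict[int, np.ndarray] = field(default_factory=dict)
    n_frames: int | None = None

    @property
    def n_stall_events(self) -> int:
        return int(sum(len(v) for v in self.stall_log.values()))


@dataclass
class VesselScene:
    """Rendered noise-free scene: clean image plus per-segment pixel support."""

    image: np.ndarray            # (ny, nx) clean en-face intensity
    vessel_mask: np.ndarray      # (ny, nx) bool, union of all tubes
    labels: np.ndarray           # (ny, nx) int, first-owner segment id + 1
    lesion_mask: np.ndarray      # (ny, nx) bool
    segment_pixels: list[tuple[np.ndarray, np.ndarray]]  # (rows, cols) per tube
    spec: SceneSpec


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def _paint_tube(centerline_rc: tuple[np.ndarray, np.ndarray], radius: int,
                shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Dilate a pixel chain to a tube of the given radius; returns (rr, cc)."""
    rr, cc = centerline_rc
    if radius == 0:
        return rr, cc
    pad = radius + 1
    r0, r1 = rr.min() - pad, rr.max() + pad + 1
    c0, c1 = cc.min() - pad, cc.max() + pad + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    canvas = np.zeros((min(r1, shape[0]) - r0c, min(c1, shape[1]) - c0c), dtype=bool)
    canvas[rr - r0c, cc - c0c] = True
    canvas = ndimage.binary_dilation(canvas, structure=disk_footprint(radius))
    tr, tc = np.nonzero(canvas)
    return tr + r0c, tc + c0c


def generate_scene(spec: SceneSpec) -> tuple[VesselScene, GroundTruth]:
    """Lay ``n_segments`` straight capillary tubes around an avascular lesion.

    The first ``round(align_fraction * n_segments)`` segments are oriented
    along the direction from their midpoint to the lesion center (true
    theta = 0 plus optional jitter within +/-pi/12); the rest get theta
    uniform on [-pi/2, pi/2).  No vessel pixel falls inside the lesion disk.
    Identical spec (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.grid_ny, spec.grid_nx
    cx, cy = spec.center_xy
    r_lesion = spec.lesion_radius_px

    lesion_mask = np.zeros((ny, nx), dtype=bool)
    if r_lesion > 0:
        rr, cc = draw_disk((cy, cx), r_lesion, shape=(ny, nx))
        lesion_mask[rr, cc] = True
    # a lesion disk engulfing every grid corner leaves nothing to vascularize
    corners = np.array([[0, 0], [0, nx - 1], [ny - 1, 0], [ny - 1, nx - 1]], float)
    if r_lesion > 0 and np.all(np.hypot(corners[:, 1] - cx, corners[:, 0] - cy) <= r_lesion):
        raise ValueError("lesion disk covers the whole grid: no vascularized area")

    n_aligned = int(round(spec.align_fraction * spec.n_segments))
    labels = np.zeros((ny, nx), dtype=np.int32)
    occupied = np.zeros((ny, nx), dtype=bool)
    centerlines: list[np.ndarray] = []
    thetas: list[float] = []
    segment_pixels: list[tuple[np.ndarray, np.ndarray]] = []

    # tube pixels are the centerline dilated by vessel_radius_px, so keeping
    # centerline pixels at least this far out keeps every vessel pixel off
    # the lesion disk; the extra 0.5 clears the rasterized disk boundary
    clearance = r_lesion + spec.vessel_radius_px + 0.5
    # Straight segments under-cover the ring just outside the lesion (half
    # the orientations/offsets that would reach it are clipped), which would
    # leave an unrealistic avascular halo; capillaries in the penumbra crowd
    # the boundary, so midpoint sampling doubles the ring's nominal share.
    ring_w = 0.5 * float(np.mean(spec.segment_length_px))
    ring_area = np.pi * ((clearance + ring_w) ** 2 - clearance ** 2)
    p_ring = min(0.4, 2.0 * ring_area / (nx * ny)) if r_lesion > 0 else 0.0
    for s in range(spec.n_segments):
        aligned = s < n_aligned
        # theta is drawn once per segment, BEFORE placement: rejection
        # sampling of the position then cannot distort the theta marginal
        # (radial segments are harder to fit near borders and the lesion,
        # so redrawing theta on rejection would bias against alignment)
        if aligned:
            theta = (rng.uniform(-spec.aligned_jitter_rad, spec.aligned_jitter_rad)
                     if spec.aligned_jitter_rad > 0 else 0.0)
        else:
            theta = rng.uniform(-_HALF_PI, _HALF_PI)
        for _attempt in range(5000):
            length = rng.uniform(*spec.segment_length_px)
            if rng.random() < p_ring:
                rho = np.sqrt(rng.uniform(clearance ** 2, (clearance + ring_w) ** 2))
                psi = rng.uniform(0, 2 * np.pi)
                mx, my = cx + rho * np.cos(psi), cy + rho * np.sin(psi)
                if not (1.0 <= mx < nx - 1 and 1.0 <= my < ny - 1):
                    continue
            else:
                mx = rng.uniform(1.0, nx - 2.0)
                my = rng.uniform(1.0, ny - 2.0)
            if np.hypot(mx - cx, my - cy) <= clearance:
                continue
            beta_mid = np.arctan2(cy - my, cx - mx)
            phi = beta_mid + theta
            dx, dy = 0.5 * length * np.cos(phi), 0.5 * length * np.sin(phi)
            x0, y0 = int(round(mx - dx)), int(round(my - dy))
            x1, y1 = int(round(mx + dx)), int(round(my + dy))
            if not (0 <= x0 < nx and 0 <= x1 < nx and 0 <= y0 < ny and 0 <= y1 < ny):
                continue
            rr, cc = draw_line(y0, x0, y1, x1)
            inside = np.hypot(cc - cx, rr - cy) <= clearance
            if inside.any():
                # clip at the lesion boundary instead of rejecting, keeping
                # the contiguous piece that contains the midpoint: capillaries
                # hug the avascular edge, and placement acceptance stays
                # independent of theta (the midpoint is outside the disk, so
                # at least half the segment always survives)
                mid_idx = int(np.argmin(np.hypot(cc - mx, rr - my)))
                if inside[mid_idx]:
                    continue
                lo = mid_idx
                while lo > 0 and not inside[lo - 1]:
                    lo -= 1
                hi = mid_idx
                while hi < len(rr) - 1 and not inside[hi + 1]:
                    hi += 1
                rr, cc = rr[lo:hi + 1], cc[lo:hi + 1]
                # pieces shorter than ~3 tube widths read as blobs, not
                # tubes; rejection resamples the position only, so the
                # theta marginal is untouched
                if len(rr) < 6 * spec.vessel_radius_px + 2:
                    continue
            tr, tc = _paint_tube((rr, cc), spec.vessel_radius_px, (ny, nx))
            if spec.non_touching:
                # +2 guarantees >= 2 px separation even across diagonals
                wr, wc = _paint_tube((rr, cc), spec.vessel_radius_px + 2, (ny, nx))
                if occupied[wr, wc].any():
                    continue
            elif occupied[tr, tc].mean() > spec.max_overlap_fraction:
                # capillaries in an en-face MIP cross at points; they do not
                # run on top of each other, and a mostly-shared segment could
                # never visibly disappear when it stalls
                continue
            break
        else:
            raise RuntimeError(
                f"could not place segment {s}: grid too crowded or lesion too large"
            )
        occupied[tr, tc] = True
        new = labels[tr, tc] == 0
        labels[tr[new], tc[new]] = s + 1
        centerlines.append(np.column_stack([rr, cc]))
        thetas.append(float(wrap_half_pi(theta)))
        segment_pixels.append((tr, tc))

    vessel_mask = labels > 0
    image = np.full((ny, nx), spec.background_intensity, dtype=float)
    image[vessel_mask] = spec.vessel_intensity

    scene = VesselScene(image=image, vessel_mask=vessel_mask, labels=labels,
                        lesion_mask=lesion_mask, segment_pixels=segment_pixels,
                        spec=spec)
    truth = GroundTruth(segment_centerlines=centerlines,
                        segment_theta=np.array(thetas),
                        lesion_mask=lesion_mask,
                        lesion_area_px=int(lesion_mask.sum()))
    return scene, truth


# ---------------------------------------------------------------------------
# Complex B-frame rendering
# ---------------------------------------------------------------------------

def render_bframe_pair(
    scene: VesselScene,
    position_index: int,
    bulk_phase: float = 0.0,
    spec: SceneSpec | None = None,
    seed: int = 0,
) -> BFramePair:
    """Render the two repeated complex B-scans at one slow-axis position.

    Static tissue gets a fixed speckle-like complex field shared by both
    repeats; vessel voxels (a band of ``2*vessel_radius_px + 1`` axial pixels
    around the focal plane, at the scene's vessel columns for this row) get
    an independent uniform random phase per repeat — the decorrelation that
    angiography detects.  Both repeats receive independent circular complex
    Gaussian noise of scale ``noise_sigma``; the whole second repeat is then
    multiplied by ``exp(i * bulk_phase)``, emulating sub-pixel bulk motion.
    """
    spec = spec or scene.spec
    if not 0 <= position_index < spec.grid_ny:
        raise IndexError(f"position_index {position_index} outside 0..{spec.grid_ny - 1}")
    nz, nx = spec.grid_nz, spec.grid_nx
    focal_z = nz // 2
    z_lo = max(focal_z - spec.vessel_radius_px, 0)
    z_hi = min(focal_z + spec.vessel_radius_px + 1, nz)

    # Parenchyma backscatters as strongly as blood on the structural image;
    # the angiographic contrast is decorrelation, not amplitude.  The static
    # speckle field therefore carries the vessel-level amplitude and is
    # shared by both repeats.
    rng_static = np.random.default_rng([spec.seed, 104729, position_index])
    static = spec.vessel_intensity * np.exp(
        1j * rng_static.uniform(0, 2 * np.pi, size=(nz, nx))
    )

    vessel_cols = scene.vessel_mask[position_index]
    frames = []
    rng = np.random.default_rng([seed, position_index])
    for _repeat in range(2):
        frame = static.copy()
        if vessel_cols.any():
            n_dyn = int(vessel_cols.sum()) * (z_hi - z_lo)
            phases = rng.uniform(0, 2 * np.pi, size=(z_hi - z_lo, int(vessel_cols.sum())))
            amps = spec.vessel_intensity * rng.rayleigh(
                scale=1 / np.sqrt(2), size=phases.shape
            )
            block = amps * np.exp(1j * phases)
            sub = frame[z_lo:z_hi]
            sub[:, vessel_cols] = block
            del n_dyn
        if spec.noise_sigma > 0:
            noise = rng.normal(0, spec.noise_sigma / np.sqrt(2), size=(2, nz, nx))
            frame = frame + noise[0] + 1j * noise[1]
        frames.append(frame)
    frame_a, frame_b = frames
    frame_b = frame_b * np.exp(1j * bulk_phase)
    return BFramePair(frame_a, frame_b, position_index)


# ---------------------------------------------------------------------------
# Stall-bearing angiogram time series
# ---------------------------------------------------------------------------

def render_angiogram_series(
    scene: VesselScene,
    truth: GroundTruth,
    stall: StallProcessSpec,
    spec: SceneSpec | None = None,
    frame_interval_s: float = 10.0,
) -> AngiogramSeries:
    """Paint a 60-frame-style en-face series with per-segment stall dropouts.

    In frames where a segment is stalled all of its pixels are drawn at the
    background level (the angiographic signature of interrupted RBC flow);
    otherwise at the vessel level.  The Bernoulli stall draw is recorded in
    ``truth.stall_log`` so detection can be checked event-for-event.
    Additive Gaussian noise (clipped at zero) is applied per frame.
    """
    spec = spec or scene.spec
    rng = np.random.default_rng(stall.seed)
    n_seg = len(scene.segment_pixels)
    n_eligible = int(round(stall.stall_segment_fraction * n_seg))
    eligible = rng.choice(n_seg, size=n_eligible, replace=False) if n_eligible else np.array([], int)

    stalled = np.zeros((stall.n_frames, n_seg), dtype=bool)
    for s in eligible:
        stalled[:, s] = rng.random(stall.n_frames) < stall.stall_prob

    truth.stall_log = {
        int(s): np.flatnonzero(stalled[:, s]) for s in range(n_seg)
    }
    truth.n_frames = stall.n_frames

    frames = []
    base = np.full(scene.image.shape, spec.background_intensity, dtype=float)
    for f in range(stall.n_frames):
        frame = base.copy()
        for s in range(n_seg):
            if not stalled[f, s]:
                tr, tc = scene.segment_pixels[s]
                frame[tr, tc] = spec.vessel_intensity
        # stalled segments are painted last: every one of their pixels drops
        # to background, guaranteeing each logged stall is visible in the
        # frame (an idealization at crossing points, where a real stalled
        # capillary would stay partially lit by the crossing one)
        for s in range(n_seg):
            if stalled[f, s]:
                tr, tc = scene.segment_pixels[s]
                frame[tr, tc] = spec.background_intensity
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0, spec.noise_sigma, size=frame.shape)
        frames.append(np.maximum(frame, 0.0))
    times = frame_interval_s * np.arange(stall.n_frames)
    return AngiogramSeries(frames, frame_times_s=times)


def lesioned_variant(spec: SceneSpec, lesion_radius_px: int,
                     **overrides) -> SceneSpec:
    """Convenience: same scene spec with a lesion disk of the given radius."""
    return replace(spec, lesion_radius_px=lesion_radius_px, **overrides)


def truth_segment_graph(scene: VesselScene, truth: GroundTruth):
    """Segment graph whose segments ARE the ground-truth centerlines.

    Bypasses mask/skeleton extraction so detection can be validated
    event-for-event against ``truth.stall_log`` with segment ids matching
    the generator's indices.
    """
    import networkx as nx

    from .vessels import Segment, SegmentGraph

    graph = nx.MultiGraph()
    segments = []
    nodes = []
    for s, chain in enumerate(truth.segment_centerlines):
        a, b = 2 * s, 2 * s + 1
        nodes.extend([np.empty((0, 2), dtype=int)] * 2)
        graph.add_edge(a, b, segment=s, length=len(chain))
        segments.append(Segment(id=s, pixels=np.asarray(chain), endpoints=(a, b)))
    skeleton = np.zeros(scene.vessel_mask.shape, dtype=bool)
    for chain in truth.segment_centerlines:
        skeleton[chain[:, 0], chain[:, 1]] = True
    return SegmentGraph(nodes=nodes, segments=segments, graph=graph,
                        skeleton=skeleton)
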
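"""Capillary stalling-event detection and statistics.

A stalling event is the complete disappearance of a capillary segment on one
angiogram frame: when red-blood-cell flow is interrupted the decorrelation
signal collapses to the background level.  Because consecutive volumes are
>= 10 s apart, each flagged frame counts as one event (runs of flagged
frames are not merged by default).

Two headline statistics:

* stalling event density — total events over the series divided by the
  vascularized (vessel-positive, lesion-excluded) area;
* stall incidence — fraction of capillary segments with at least one event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .angiogram import AngiogramSeries
from .lesion import LesionMask
from .vessels import SegmentGraph, VesselMask

logger = logging.getLogger(__name__)


@dataclass
class SegmentTrace:
    """Per-frame mean intensity of one segment and its local background."""

    segment_id: int
    intensity: np.ndarray       # per kept frame, mean over the segment region
    background: np.ndarray      # per kept frame, mean over the local annulus
    stalled: np.ndarray | None = None  # filled by detect_stalls
    excluded: bool = False      # degenerate contrast; dropped from statistics

    @property
    def n_frames(self) -> int:
        return len(self.intensity)


@dataclass
class StallStats:
    """Aggregate stalling statistics over one angiogram time series."""

    n_events: int
    n_stalled_segments: int
    n_segments_total: int
    vascularized_area_px: int
    event_density_per_px2: float
    incidence: float
    event_count_histogram: dict[int, int]  # events-per-segment -> n segments
    event_density_per_mm2: float | None = None
    per_segment_events: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        hist_events = sum(k * v for k, v in self.event_count_histogram.items())
        if hist_events != self.n_events:
            raise ValueError("histogram does not account for every event")
        if sum(self.event_count_histogram.values()) != self.n_stalled_segments:
            raise ValueError("histogram does not account for every stalled segment")
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError("incidence outside [0, 1]")


def segment_traces(
    series: AngiogramSeries,
    graph: SegmentGraph,
    vessel_mask: VesselMask | np.ndarray | None = None,
    dilate_px: int = 1,
    annulus_px: tuple[int, int] = (3, 6),
) -> list[SegmentTrace]:
    """Per-frame mean intensity of each segment and a local background.

    The segment region is its pixel chain dilated by ``dilate_px``; the
    background reference is a surrounding annulus (between ``annulus_px``
    dilations) with all vessel pixels excluded, so the reference tracks
    local parenchyma rather than neighboring capillaries.  Frames must be
    co-registered 2-D en-face angiograms.
    """
    frames = series.kept_frames
    shape = frames[0].shape
    vmask = (vessel_mask.mask if isinstance(vessel_mask, VesselMask)
             else np.asarray(vessel_mask, bool) if vessel_mask is not None
             else graph.skeleton)
    stack = np.stack(frames, axis=0)  # (t, y, x)
    flat = stack.reshape(len(frames), -1)

    traces = []
    r_in, r_out = annulus_px
    for seg in graph.segments:
        region = np.zeros(shape, dtype=bool)
        rows, cols = seg.pixels[:, 0], seg.pixels[:, 1]
        if rows.min() < 0 or rows.max() >= shape[0] or cols.max() >= shape[1]:
            raise ValueError(f"segment {seg.id} has pixels outside the frame")
        region[rows, cols] = True
        if dilate_px > 0:
            region = ndimage.binary_dilation(region, disk(dilate_px))
        annulus = (ndimage.binary_dilation(region, disk(r_out))
                   & ~ndimage.binary_dilation(region, disk(r_in))
                   & ~vmask)
        if not annulus.any():  # crowded neighborhood: fall back to off-vessel
            annulus = ~vmask
        seg_idx = np.flatnonzero(region.ravel())
        bg_idx = np.flatnonzero(annulus.ravel())
        traces.append(SegmentTrace(
            segment_id=seg.id,
            intensity=flat[:, seg_idx].mean(axis=1),
            background=flat[:, bg_idx].mean(axis=1),
        ))
    return traces


def detect_stalls(
    trace: SegmentTrace,
    drop_ratio: float = 0.25,
    min_contrast: float = 1e-9,
) -> tuple[np.ndarray, int]:
    """Flag frames where the segment has vanished into the background.

    Frame ``f`` is stalled when ``intensity[f] <= background[f] +
    drop_ratio * (median flowing intensity - background[f])``: the signal has
    collapsed to within ``drop_ratio`` of the background, relative to the
    segment's own typical flowing level (its median over the series).  Each
    flagged frame is one stalling event.  Segments whose median does not
    exceed the background (``min_contrast``) carry no information and are
    marked ``excluded``.
    """
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames to detect stalls")
    med = float(np.median(trace.intensity))
    contrast = med - trace.background
    if np.median(contrast) <= min_contrast:
        trace.excluded = True
        trace.stalled = np.zeros(trace.n_frames, dtype=bool)
        logger.info("segment %d excluded: no flowing contrast", trace.segment_id)
        return trace.stalled, 0
    threshold = trace.background + drop_ratio * contrast
    flags = trace.intensity <= threshold
    trace.stalled = flags
    return flags, int(flags.sum())


def merge_event_runs(flags: np.ndarray) -> int:
    """Optional alternative event count: consecutive flagged frames merge
    into a single event (off by default in the statistics)."""
    flags = np.asarray(flags, bool).astype(int)
    return int(np.sum(np.diff(np.concatenate([[0], flags])) == 1))


def _segment_in_lesion(seg, lesion: np.ndarray) -> bool:
    return bool(lesion[seg.pixels[:, 0], seg.pixels[:, 1]].all())


def stall_statistics(
    traces: list[SegmentTrace],
    graph: SegmentGraph,
    mask: VesselMask,
    lesion: LesionMask | np.ndarray | None = None,
    drop_ratio: float = 0.25,
    px_area_um2: float | None = None,
) -> StallStats:
    """Aggregate events into density, incidence and the event-count histogram.

    The vascularized area is the vessel-mask-positive pixel count outside the
    lesion; segments lying entirely inside the lesion are excluded from both
    the event count and the segment total (very few capillaries survive
    there, and the region is excluded from density by definition).
    ``px_area_um2`` converts density to events per mm^2.
    """
    if not graph.segments:
        raise ValueError("no segments")
    lesion_arr = None
    if lesion is not None:
        lesion_arr = lesion.mask if isinstance(lesion, LesionMask) else np.asarray(lesion, bool)

    seg_by_id = {s.id: s for s in graph.segments}
    events: dict[int, int] = {}
    n_total = 0
    for tr in traces:
        seg = seg_by_id[tr.segment_id]
        if lesion_arr is not None and _segment_in_lesion(seg, lesion_arr):
            continue
        if tr.stalled is None:
            detect_stalls(tr, drop_ratio=drop_ratio)
        if tr.excluded:
            continue
        n_total += 1
        n_ev = int(tr.stalled.sum())
        if n_ev:
            events[tr.segment_id] = n_ev

    n_events = sum(events.values())
    hist: dict[int, int] = {}
    for n_ev in events.values():
        hist[n_ev] = hist.get(n_ev, 0) + 1

    if lesion_arr is not None:
        vasc = int((mask.mask & ~lesion_arr).sum())
    else:
        vasc = int(mask.mask.sum())
    density = n_events / vasc if vasc else float("nan")
    density_mm2 = density / (px_area_um2 * 1e-6) if px_area_um2 else None
    return StallStats(
        n_events=n_events,
        n_stalled_segments=len(events),
        n_segments_total=n_total,
        vascularized_area_px=vasc,
        event_density_per_px2=density,
        incidence=(len(events) / n_total) if n_total else float("nan"),
        event_count_histogram=hist,
        event_density_per_mm2=density_mm2,
        per_segment_events=events,
    )


def compare_conditions(baseline: StallStats, followup: StallStats) -> dict:
    """Ratios and differences of the stalling statistics across conditions.

    Includes the proportion of single-event stalled segments per condition
    (repeated stalling shifts that proportion down after injury).  A zero
    baseline density leaves the ratio as NaN (flagged).
    """
    def ratio(a, b):
        if b == 0 or not np.isfinite(b):
            logger.warning("zero/undefined baseline: ratio flagged as nan")
            return float("nan")
        return a / b

    def single_fraction(s: StallStats):
        return (s.event_count_histogram.get(1, 0) / s.n_stalled_segments
                if s.n_stalled_segments else float("nan"))

    return {
        "density_ratio": ratio(followup.event_density_per_px2,
                               baseline.event_density_per_px2),
        "density_difference_per_px2": (followup.event_density_per_px2
                                       - baseline.event_density_per_px2),
        "incidence_ratio": ratio(followup.incidence, baseline.incidence),
        "incidence_difference": followup.incidence - baseline.incidence,
        "single_event_fraction_baseline": single_fraction(baseline),
        "single_event_fraction_followup": single_fraction(followup),
    }
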
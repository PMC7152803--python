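"""Acquisition-protocol arithmetic.

The study geometry is fixed by the scan protocol: a 1 mm x 1 mm region
sampled with 450 slow-axis positions of 500 A-lines each, every B-scan
repeated twice for angiography, at a 90 Hz fast-axis rate.  These helpers
derive the timing quantities that follow from that geometry.
"""

from __future__ import annotations

N_SLOW_POSITIONS = 450     # B-frames per volume (slow axis, y)
N_ALINES = 500             # A-lines per B-frame (fast axis, x)
N_REPEATS = 2              # repeated B-scans per position (angiography)
FAST_AXIS_RATE_HZ = 90.0   # B-frame rate
N_VOLUMES_ACQUIRED = 100   # repeated volume scans per session
N_VOLUMES_KEPT = 60        # motion-free volumes retained for analysis
ALIGNMENT_THRESHOLD_DEG = 15.0  # |theta| band counted as lesion-aligned


def volume_scan_time_s(
    n_slow: int = N_SLOW_POSITIONS,
    n_repeats: int = N_REPEATS,
    fast_rate_hz: float = FAST_AXIS_RATE_HZ,
) -> float:
    """Seconds per volumetric angiography scan: n_slow * n_repeats / rate."""
    if n_slow <= 0 or n_repeats <= 0 or fast_rate_hz <= 0:
        raise ValueError("scan parameters must be positive")
    return n_slow * n_repeats / fast_rate_hz


def series_duration_min(
    n_volumes: int = N_VOLUMES_ACQUIRED, **scan_kwargs
) -> float:
    """Minutes to acquire a repeated-volume time series."""
    return n_volumes * volume_scan_time_s(**scan_kwargs) / 60.0


def alignment_threshold_rad(deg: float = ALIGNMENT_THRESHOLD_DEG) -> float:
    """The +/- alignment half-angle in radians (15 deg ~ 0.26 rad ~ pi/12)."""
    import math

    return math.radians(deg)
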
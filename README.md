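# strokeangio

Analysis toolkit for longitudinal OCT angiography of the mouse cortex after a
photothrombotic (focal ischemic) stroke. It covers the full post-acquisition
chain — from repeated complex B-scans to the three quantitative readouts of
post-stroke vascular remodeling:

1. **Angiogram construction** — repeated B-scans at each slow-axis position
   are phase-corrected for sub-pixel bulk motion (global phase fluctuation,
   GPF) and turned into decorrelation angiograms via the complex-difference
   magnitude `|A₁ − A₂|`; volumes are Gaussian-smoothed, quality-filtered
   (first 60 motion-free volumes), averaged, and flattened into en-face maps
   by maximum-intensity projection over ±15 axial pixels around the focus.
2. **Capillary orientation** — per-pixel structure-tensor orientation α of
   the vessel-enhanced en-face map, a synthesized map β of the direction from
   each pixel to the ischemic lesion center, and their mod-π difference
   θ = wrap(α − β). Capillaries with |θ| ≤ π/12 (±15°, ≈0.26 rad) count as
   *aligned* with the lesion direction; the aligned fraction over the vessel
   mask quantifies radial reorganization of the regenerated network.
3. **Lesion area and capillary stalling** — the avascular lesion is
   segmented on en-face angiograms (manual masks loadable; deterministic
   automated surrogate included) and its area tracked per depth, normalized
   to day 8. On 60-frame angiogram time series, a *stalling event* is the
   complete disappearance of a capillary segment in one frame; the package
   reports stalling event density (events per vascularized, lesion-excluded
   area), stall incidence (fraction of segments with ≥1 event), and the
   event-count histogram.

Because no imaging data are deposited with the study this pipeline targets,
the package ships a synthetic-data generator (`strokeangio.synthgen`) that
emulates the acquisition — 1 mm × 1 mm ROI scanned as 450 × 500 lateral
positions, 2 repeats per B-scan, 60-volume time series, controllable
fraction of lesion-directed capillaries, avascular lesion disk, speckle and
phase noise, per-segment stall processes — with full ground truth, so every
stage is verifiable end to end.

## Worked example

Run the bundled end-to-end pipeline on a synthetic scene (half of the
capillary segments oriented toward a 16-px lesion, default stall process):

```bash
strokeangio run --seed 3 --out demo_run
```

which prints (abridged):

```json
{
  "seed": 3,
  "n_segments": 75,
  "lesion_area_px": 800,
  "lesion_center_xy": [63.44, 63.52],
  "aligned_fraction": 0.589,
  "n_orientation_pixels": 7887,
  "stalls": {
    "n_events": 17,
    "n_stalled_segments": 11,
    "n_segments_total": 75,
    "incidence": 0.147,
    "event_count_histogram": {"1": 5, "2": 6}
  }
}
```

Reading the numbers: the automated lesion segmentation recovers 800 px
against a true disk of π·16² ≈ 804 px, centered within 0.1 px of the true
center (63.5, 63.5). The measured aligned fraction 0.589 sits between the
uniform baseline (1/6 ≈ 0.167, no preferred orientation) and full radial
alignment, as expected for a scene built with half its segments
lesion-directed. Of 75 extracted capillary segments, 11 stalled at least
once across the 60 frames (incidence 0.147) for 17 events in total; the
histogram says 5 segments stalled once and 6 twice. `demo_run/` also
contains the θ/coherence maps (TIFF), the orientation histogram (CSV + PNG),
the HSV orientation rendering, and the per-segment stall timeline figure.

The same stages are available as library functions
(`strokeangio.correct_gpf`, `compute_angiogram`, `frangi`, `make_mask`,
`compute_orientation_maps`, `segment_lesion`, `detect_stalls`, ...) and as
CLI subcommands (`simulate`, `angio`, `enhance`, `orient`, `lesion`,
`stalls`, `run`).

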
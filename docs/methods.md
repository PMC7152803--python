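# Methods

This note documents the models, conventions and numerical choices behind
`strokeangio`, and what the synthetic validation does and does not show.

## Angiogram model

OCT angiography derives vascular contrast from temporal decorrelation: light
backscattered by moving red blood cells changes phase and amplitude between
two B-scans repeated at the same slow-axis position, while static parenchyma
does not. The literature describes the detection statistic loosely as a
"phase and intensity difference"; this package commits to the
complex-difference magnitude

    D(z, x) = | A₁(z, x) − A₂(z, x) |

which responds jointly to both channels, is zero on static tissue and
non-negative everywhere. Separate |Δφ| and |ΔI| channels are available for
diagnostics (`compute_angiogram_channels`).

**Global phase fluctuation (GPF) correction.** Sub-pixel bulk motion between
repeats multiplies the second frame by an unknown unit-modulus phasor.
Because dynamic tissue is a small minority of a cortical B-frame, the phase
of `Σ_z A₁·conj(A₂)` estimates that phasor; multiplying the second frame by
`exp(iφ̂)` drives the static-tissue phase difference to zero. The correction
is estimated per A-line by default (robust to line-to-line galvo jitter); a
whole-frame variant is available. The corrected angiogram is provably
invariant (to machine precision) to any global phase applied to the second
repeat, and on synthetic frames with 5% dynamic pixels the bulk phase is
recovered to < 0.01 rad.

**Conventions.** Volumes are row-major `(z, y, x)` — z axial (increasing
downward from the first axial pixel), y the slow axis, x the fast axis;
en-face maps are `(y, x)`. Default voxel geometry: 4.15 µm axial (half the
8.3 µm two-pixel axial resolution), 1000/450 µm and 1000/500 µm lateral for
the full-size grid. The en-face projection is the per-pixel maximum over an
inclusive ±15-pixel band around the focal plane (31 axial pixels).

**Quality filter.** Manual rejection of motion-corrupted volumes is replaced
by a deterministic rule: a volume is rejected when its whole-frame mean
deviates from the series median by more than k·MAD (normal-consistent MAD,
k = 5); the first 60 passing volumes are kept in order. An explicit
keep-list overrides the rule.

## Vessel enhancement and the capillary mask

Two enhancement products serve different purposes:

* **Orientation/masking map** — a single multiscale Frangi vesselness pass
  (scales {1, 1.5, 2} px, β = 0.5, c = half the maximum Hessian norm) on the
  averaged en-face angiogram. Thresholding this map with the triangle
  method (suited to the heavily right-skewed unimodal histogram of a
  vesselness image; Otsu under-segments it badly) gives the binary
  capillary mask, with components under 10 px removed. On synthetic tubes
  the mask reaches Dice ≈ 0.92 against ground truth.
* **Sequential cascade** (`vessels.enhance`) — tubeness (gamma-normalized
  `max(0, −λ_min)` of the Hessian, σ = 2 px) followed by Frangi, the
  doubly ridge-sharpened product. It is retained for visualization and as
  an alternative input, but compounding two ridge filters narrows the
  apparent vessel (mask Dice caps near 0.79) and measurably degrades the
  structure-tensor orientation on tube phantoms, so the default pipeline
  does not feed it into the mask or the orientation stage.

**Segment graph.** The mask is skeletonized (8-connectivity); skeleton
pixels with one neighbor are endpoints, with ≥3 neighbors junction clusters;
segments are the maximal chains between node clusters. Chains shorter than
5 px (skeletonization spurs) are pruned. Node clusters with exactly two
incident chains are corner artifacts of skeletonization, not junctions, and
their chains are fused. The partition identity
`Σ segment lengths + node pixels + pruned pixels = skeleton pixels` is
enforced by test.

## Orientation analysis

All orientations are undirected (mod π) in [−π/2, π/2), with x to the right
and y pointing down (image convention).

* **α** — structure-tensor orientation of the vesselness map:
  `J = G_w ⊛ [Ix², IxIy; IxIy, Iy²]` with Gaussian-derivative gradients at
  σ_g = 1 px and window σ_w = 3 px. The dominant eigenvector of J is the
  gradient direction; α is perpendicular to it. The 3-px window was chosen
  to cover the ~3 px tube diameter; at 2 px the estimator is visibly biased
  on tube phantoms. Coherence = (λ_max − λ_min)/(λ_max + λ_min), zero where
  the tensor trace vanishes.
* **β** — orientation of the line through the pixel and the lesion center,
  `wrap(atan2(cy − py, cx − px))`; a pixel coinciding with the center gets
  β = 0. The lesion center defaults to the centroid of the lesion mask,
  with manual override.
* **θ = wrap(α − β)** — orientation relative to the lesion direction;
  θ = 0 means the capillary points at the lesion.

The angular distribution is the histogram of θ over mask-positive pixels
(18 bins by default); the aligned fraction counts |θ| ≤ π/12 (±15°). Pixel
weighting is the primary statistic; a segment-weighted variant (circular
mod-π mean of θ per segment, `segment_theta_values`) provides approximately
independent draws — it is the right basis for the chi-square uniformity
test, because adjacent pixels of one segment share orientation and would
overdisperse a pixel-level chi-square. No coherence gate is applied by
default (floor 0, configurable). The HSV rendering maps hue = (θ + π/2)/π,
saturation = coherence, value = normalized brightness; θ = ±π/2 meet at the
same wrapped hue, consistent with a mod-π angle.

## Lesion segmentation and trajectories

Manual lesion masks (binary TIFF/PNG) are the authoritative path
(`load_manual_lesion`). The automated surrogate exploits that the lesion is
dark and avascular: the en-face map is Gaussian-smoothed (σ = 3 px) and
thresholded at the midpoint between the dark-core level (2% quantile) and
the vascularized level (median) — for a blurred step edge the half-contrast
contour sits on the true boundary, so the recovered area is insensitive to
the smoothing scale. The dark region is restricted to vessel-free pixels,
morphologically closed (disk 5 px), and reduced to the largest connected
component that is ≥100 px and ≥0.9 solid — the photothrombotic lesion is
compact and roughly elliptical, unlike ragged inter-capillary pockets; in a
centered scan, border-touching components are deprioritized. On synthetic
disks (radius 25–40 px, dense vasculature) area error stays below ~7% and
the centroid within 1 px.

Longitudinal trajectories normalize each depth's area by its day-8 value
(the earliest day the lesion fits the field of view); a zero reference is
flagged and leaves that depth undefined. Areas are reported in px² and,
via voxel geometry, µm². Adjacent-depth scatter pairs (shallow vs deep)
reproduce the qualitative depth-ordering readout: when lesions grow with
depth, all points lie above y = x.

## Stalling analysis

Per segment, the trace is the per-frame mean intensity over the pixel chain
dilated by the tube radius; the background reference is a surrounding
annulus (between 3- and 6-px dilations) with all vessel pixels excluded.
Frame f is flagged stalled when

    I_seg(f) ≤ I_bg(f) + drop_ratio · (median_f I_seg − I_bg(f))

with drop_ratio = 0.25: the signal has collapsed to within a quarter of the
segment's own typical flowing contrast. Segments whose median never exceeds
the background are excluded as uninformative. Each flagged frame is one
event — consecutive volumes are ≥10 s apart, so runs of flagged frames are
not merged (a merge-runs option exists, off by default).

Statistics: event density = total events / vascularized area (vessel-mask
pixels outside the lesion; reported per px² and per mm²), incidence =
stalled segments / total segments, plus the events-per-segment histogram.
Segments lying entirely inside the lesion are excluded from both counts.
The identities `Σ count·hist[count] = n_events` and
`Σ hist = n_stalled_segments` are enforced at construction.

## Synthetic-data generator

The generator emulates the study geometry: full-size scenes are 450 × 500
lateral pixels over 1 mm²; the test-suite default (`SceneSpec.small`) is a
128 × 128 grid with 200 straight capillary tubes of radius 1 px and length
14–30 px, vessel level 1.0, parenchyma 0.05, additive Gaussian noise
σ = 0.02 clipped at zero, and 60-frame series at 10 s spacing. Design
choices that matter for validity:

* **θ marginal is exact.** Each segment's true orientation offset θ is
  drawn *before* placement (aligned segments: θ = 0, optional jitter within
  ±π/12; others: uniform on [−π/2, π/2)); rejection sampling then only
  retries the position, so boundary and lesion constraints cannot distort
  the θ distribution — with align_fraction 0 the aligned measure is exactly
  30°/180° = 1/6 in expectation.
* **Lesion boundary.** Segments crossing the avascular disk are clipped at
  its edge (keeping the piece containing the midpoint, minimum ~3 tube
  widths) rather than rejected, and midpoint sampling doubles the boundary
  ring's nominal share: regenerating capillaries crowd the penumbra, and
  without the compensation straight segments systematically under-cover the
  ring, leaving an artificial dark halo that would bias area estimates.
* **Overlap.** Candidate tubes sharing more than half their pixels with
  already-placed tubes are rejected: in an en-face MIP capillaries cross at
  points, they do not run on top of each other.
* **B-frames.** Static parenchyma carries a vessel-level speckle field
  (fixed random phase per voxel, shared by both repeats): structural
  backscatter of tissue and blood is comparable, and the angiographic
  contrast is decorrelation, not amplitude. Vessel voxels get independent
  Rayleigh-amplitude, uniform-phase draws per repeat; both repeats receive
  circular complex Gaussian noise; the second is multiplied by
  `exp(i·bulk_phase)`.
* **Stalls.** A Bernoulli process per eligible segment per frame
  (defaults: probability 0.025, 25% of segments eligible — at 60 frames
  this leaves roughly half of ever-stalled segments with a single event, a
  quiescent baseline). A stall occupies a whole frame. Stalled segments
  are painted last, so every logged stall is fully at background level —
  an idealization at crossing points, where a real stalled capillary would
  stay partially lit by the crossing one.

**What passing tests show — and don't.** The generator has straight tubes,
stationary geometry, frame-level stalls, Gaussian noise, and a circular
lesion; real angiograms add curvature, depth-dependent blur and tail
artifacts, inter-volume registration error, flow-speed-dependent
decorrelation, and irregular lesion shapes. Recovery results (aligned
fraction within a few points of truth, stall F1 ≈ 1 at half-contrast noise,
lesion area within ~7%) therefore validate the *implementation* of each
operator and its statistical behavior under controlled conditions, not
field performance on animal data; the detection thresholds (triangle mask,
drop_ratio 0.25, solidity 0.9) would need re-examination on real series.

## Problem sizes

The test suite and the acceptance script run on 128² scenes (192² for
lesion studies) with 60-frame series, 40 seeds for the uniformity property
and 100 seeds for phase recovery — sizes at which every property is stable
while a full run completes in well under a minute on one core; the full
450 × 500 geometry is available through the same configuration objects.

## Known limitations

* No inter-volume registration: time series are assumed co-registered (the
  generator guarantees it; real awake-animal data may not).
* No 3-D vessel graph, diameter estimation, or sub-pixel centerlines.
* The stall/flow model carries no biology: stall probabilities are free
  parameters of the generator, not estimates of cortical physiology.
* Group-level inference (animal-to-animal comparisons) is out of scope; the
  package exports per-dataset statistics and descriptive comparisons only.
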
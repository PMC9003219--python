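# Methods

## Measurement model

A plantar pressure image is a non-negative H×W grid (default 400×120,
origin top-left, y down, forefoot at the top).  The foot-progression angle
(FPA) is derived from an axis-aligned *angle-box* whose diagonal is the
foot axis from the heel centre to the metatarsal head; with box height A1
and width A2 (pixels), θ = arctan(A2/A1) in degrees.  Detection boxes
arrive in normalized centre/size form and are converted to continuous
pixel corners P = ((x∓w/2)·W, (y∓h/2)·H); nothing is ever rounded to
integer pixels.

Which diagonal of the box is the axis is not decidable from the box alone:
it is selected by the foot profile.  Out-toeing left feet use the
top-left→bottom-right diagonal, out-toeing right feet the mirrored one,
and in-toeing swaps the diagonal within each side.  The *sign* of θ
likewise comes from the profile's toeing class: out-toeing positive,
in-toeing negative.  This convention is chosen to match the clinical
definition of in-toeing as FPA < 0°; a data source that only labels
out-toeing feet (the default `two_class` mode) therefore always yields
non-negative angles.

Classification uses the closed adult interval: θ ∈ [0°, 20°] is normal,
below in-toeing, above out-toeing.  Both thresholds are configurable
(`CHILD_THRESHOLDS = (5, 13)` is provided for paediatric cohorts).
Zero-area angle-boxes — and zero-height ones, whose 90° arctangent cannot
be a heel-to-forefoot axis — yield measurements flagged `missing` rather
than exceptions; missing rows are carried through every table and excluded
(with reported counts) from statistics only.

## Synthetic generator

The generator is a geometric phantom, not a biomechanical model: its job
is to provide images whose ground truth is known exactly.  A foot is a sum
of anisotropic Gaussian pressure blobs in a foot-local frame (lateral u,
axial a, fractions of foot width 56 px / length 240 px):

| region | (u, a) | σ(u, a) | peak |
|---|---|---|---|
| heel | (0, 0) | (0.22, 0.070) | solved so total = 100 |
| sole ridge | (0, 0.45) | (0.18, 0.260) | 28 |
| lateral midfoot | (−0.25, 0.33) | (0.17, 0.054) | 25 |
| metatarsal band | (0, 0.58) | (0.25, 0.046) | 90 |
| hallux | (+0.22, 0.79) | (0.125, 0.038) | 80 |
| lesser toes ×3 | (−0.06…−0.34, 0.75…0.775) | small | 30–40 |

The low sole ridge keeps the footprint contiguous at the segmentation
threshold, as real stance images are; the midfoot blob sits laterally
because the medial arch carries little load (this asymmetry is what the
side classifier reads); the heel amplitude is solved so the pressure at
the heel centre equals the configured peak (100 units) despite overlap.
Pressure is evaluated at pixel centres, so a right foot (the left field
mirrored about the vertical midline) is a pixel-exact array flip.

To impose θ, all blobs distal to the heel are rigidly rotated about the
heel centre, so the rear axis point (G2 = heel centre) is invariant and
the angle recomputed from the two ground-truth points equals the request
to machine precision.  The front point (G1) is the metatarsal-band centre,
which for the on-axis band equals its pressure centroid.  Positive θ on a
left foot swings the forefoot toward the image left.  Each sample carries
the exact axis points, the angle-box (tight box of the two points), the
profile-box (tight box of the noiseless support at 10% of peak) and the
profile class.

Noise is additive i.i.d. Gaussian, clipped at zero, applied after
rendering; the default dataset noise is 5 pressure units (5% of heel
peak), a mild sensor-noise level.  Dataset FPA magnitudes are drawn from
Normal(5.58°, 1.9°) truncated to [0°, 20°] — centred on the normal-range
cohort mean this pipeline is intended for (5.58 ± 0.10° SE at n = 367
corresponds to an SD of about 1.9°) — with signs set by the toeing class.

What the phantom does *not* emulate: realistic pedobarographic pressure
distributions, partial or merged footprints, dynamic roll-over sequences,
or annotator disagreement about the front-point landmark.  A green
recovery test therefore establishes that the geometry, sign conventions
and bookkeeping are correct and that the baseline detector is unbiased on
smooth single-foot images — not that it would match a trained network on
clinical data.

On the paper-format 120 px-wide canvas a realistically proportioned foot
cannot rotate ±30° without leaving the frame.  The generator therefore
validates, per sample, that both axis points stay ≥2 px inside the canvas
and lets Gaussian tails clip at the edge (exactly as a physical plate
truncates a foot), with |θ| ≤ 30° as the hard input bound.

## Baseline detector

Segmentation thresholds at 10% of the maximum pressure.  Connectivity is
decided on a lightly smoothed copy (Gaussian σ = 2 px) so sensor noise
cannot fracture the sole into islands — the reported mask remains the
raw-thresholded pixels within the kept region, so a single bright pixel
still yields a one-pixel box.  The largest component by pressure mass is
kept together with components within 25 px of it (toes, nearby speckle).

Side classification compares pressure mass in the two column halves of the
midfoot band (45–65% of the footprint's row extent): the lighter half is
the medial (arch) side; in this package's convention a left foot has its
arch on the image-right half.  Confidence is 0.5 + 0.5·|Δm|/Σm, and an
exactly symmetric band ties to `left` at 0.5.

Axis points are pressure-weighted centroids: the front point over the
metatarsal band (15–45% of row extent from the top, after excluding the
top 15% as toes) and the rear point over the heel band (65–100%).  All
band fractions and the toe cut are heuristic defaults, deliberately
config-exposed.  A segment whose row extent is less than twice its column
extent is rejected as not a full footprint (an isolated heel or forefoot
fragment has no heel-to-metatarsal axis) — this aspect gate is what turns
"only a heel blob" into a missing detection.  In `four_class` mode the
toeing direction is read from the sign of the front-minus-rear horizontal
offset (ties, θ = 0, default to out-toeing).

## Evaluation

Point distances are Euclidean, front (|G1P1|) and rear (|G2P2|) scored
separately.  AP matches detections to at most one ground-truth box per
image per class at IoU ≥ 0.5 (greedy in confidence order, ties broken by
image id for determinism) and integrates the all-point interpolated
precision–recall curve; 11-point interpolation and other IoU thresholds
are options.  mAP is the unweighted class mean.

The statistical battery: mean ± SE (SE = sample SD with n−1 denominator
over √n), two-sided paired t-tests, one-way ANOVA
(F = (SSB/(k−1))/(SSW/(N−k))) and Fisher's LSD post hoc — pairwise t with
the pooled ANOVA error variance, df = N−k, *unadjusted* p-values, which is
the definition of LSD — all at α = 0.01 by default.  Statistics are
computed from the defining formulas; scipy supplies only the t/F tail
probabilities.  Degenerate inputs (zero error variance) are reported as
flagged entries, not exceptions.  Missing measurements are deleted
pairwise per comparison and every report carries the exclusion counts.

One note on the reference analysis this mirrors: the source cohort's
model-vs-ground-truth FPA differences are described in one place as
1.3–1.9° while the summary means differ by 0.28–1.17°; this package
implements the summary-table computation (group means compared by
ANOVA/LSD) and leaves that discrepancy to the reader.

## Numerical choices and limitations

* All box edges and angles are continuous; round-trips between normalized
  and pixel coordinates hold to 1e−9.
* Dataset generation derives per-sample seeds from the top-level seed via
  `numpy` `SeedSequence`; identical configuration and seed reproduce every
  file byte-for-byte.
* The mirror symmetry of the geometry is exact in real arithmetic; in
  floats it holds to ~ulp(W)/box-size, which is why property tests use a
  1e−6-degree tolerance for arbitrarily small boxes.
* The baseline detector is a stand-in: it assumes a single, roughly
  vertical foot per image, breaks down beyond |θ| ≈ 25° (band geometry),
  and its confidence is only a ranking score for AP bookkeeping.
* No proprietary pressure-plate formats are read; grids are CSV matrices
  or 8-bit grayscale PNG.
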
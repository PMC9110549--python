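# Methods

`ioct-hrfuse` estimates high-resolution (HR) intra-operative OCT B-scans
by fusing low-resolution (LR) video frames acquired while both the
scanner and the retina hold still, gates the results on speckle
statistics, and evaluates image quality with full- and no-reference
metrics. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic tests do and do not show.

## Pipeline model

A surgical video pairs a biomicroscope view with an embedded iOCT B-scan
stream (nominally 440×300 px). The scanning region appears in the
microscope view as a white rectangle containing cyan and magenta arrow
glyphs. The pipeline:

1. **Scan-marker detection.** Grayscale → binary threshold at 0.9× the
   frame maximum → Canny edges → probabilistic Hough segments → segments
   grouped into near-horizontal/vertical position clusters → candidate
   axis-aligned quadrilaterals scored by the fraction of their perimeter
   lying on the bright mask (≥ 0.9 required; ties broken by area). Each
   accepted side is refined to sub-pixel precision as the
   brightness-weighted centroid of the bright mask in a ±3 px band. The
   Hough sampling is seeded, so detection is deterministic. The grouping
   assumes a near-axis-aligned marker, which matches the microscope feeds
   this models; a rotated marker would need a quadrilateral fit on the
   raw segments.
2. **Arrow anchors.** Within the rectangle (dilated 2 px), the cyan and
   magenta glyphs are segmented in HSV (hue 170–210° / 280–340° on the
   0–360° circle, saturation and value ≥ 0.4) and reduced to
   value-weighted centroids. Two sub-pixel points per frame represent the
   scan position.
3. **Retinal feature tracking.** One manually seeded point (e.g. a vessel
   bifurcation) is followed with a pyramidal Lucas–Kanade sparse
   optical-flow tracker (3 levels, 21×21 window, ≤ 30 Gauss–Newton
   iterations per level, update threshold 0.01 px). The track is declared
   lost — permanently, unless re-seeded — when the mean absolute window
   residual exceeds 12 intensity levels or the point leaves the frame.
4. **Stationarity.** A stability interval is a maximal run of frames in
   which every tracked point (both arrow anchors and the retinal feature)
   moves ≤ `tol_step` = 1.5 px frame-to-frame **and** ≤ `tol_total` =
   3 px from the interval's first frame, with at least `min_len` = 8
   frames. "Constant position" needs a numeric tolerance because real
   trackers never return bit-identical coordinates; both the
   previous-frame and first-frame checks are enforced so neither slow
   drift nor oscillation slips through. Whether a stationarity rule of
   "more than eight frames" means ≥ 8 or ≥ 9 is a convention; ≥ 8 is the
   default and `min_len` is configurable.
5. **Rigid registration and fusion.** Each B-scan of an interval is
   registered to the interval's first B-scan with a rotation+translation
   transform about the image centre (no scale or shear: deformable
   registration could fold or stretch anatomy, which is exactly what
   fusion must not invent). The estimator maximizes normalized
   cross-correlation: a 0.5° rotation grid over ±5° with per-rotation
   translation by sub-pixel phase correlation seeds a Nelder–Mead
   refinement of (θ, tx, ty) (explicit initial simplex of 0.25° / 0.5 px
   steps; NM's default 5%-of-x0 simplex degenerates near zero). Three
   numerical choices matter and were validated on phantoms with known
   transforms:
   * scoring happens on `log1p` intensities — the homomorphic transform
     turns multiplicative speckle into roughly stationary additive noise
     (without it, lateral errors at 4-look speckle roughly double);
   * both images are Gaussian-smoothed (σ = 1 px) for scoring only;
   * NCC is evaluated on a fixed central window (`t_range/2 + 5` px
     inside the border) intersected with the warp's valid coverage.
     Keeping the scoring domain independent of the candidate transform
     and away from frame borders removes a systematic ~0.4 px bias that
     border padding otherwise induces along the weakly textured axis.
   Fusion warps every frame onto the reference grid (bilinear), averages
   per pixel over contributing frames only (a coverage map counts them),
   and copies reference pixels where no frame contributes. Averaging is
   done in float without brightness pre-normalization; stationary-frame
   exposure is stable enough that normalization would only add a degree
   of freedom. An optional NCC floor (suggested 0.5) drops badly
   registered frames instead of blurring the average; it is off by
   default because dropped frames must be an explicit, audited choice.
6. **Quality gating.** Five ROIs are anchored to a retinal-layer label
   mask: one background rectangle (32×32), two small homogeneous
   rectangles (16×8) on the second and last layers, two large contrast
   rectangles (96×12) on the first and last layers. ROI centres are drawn
   uniformly at random among placements wholly inside the target label
   (enumerated by a sliding-window containment test, so the distribution
   is exactly uniform and failures are detected, not timed out). Metrics,
   with population (divide-by-n) variances on the stored 0–255 scale:

   * SNR = 10·log₁₀( max(F²) / σ²_b ) in dB, F the linear-magnitude
     image, σ²_b the background-ROI variance;
   * ENL = (1/H) Σ_h μ²_h/σ²_h over the H = 2 homogeneous ROIs;
   * CNR = (1/R) Σ_r (μ_r − μ_b)/√(σ²_r + σ²_b), signed, over R = 4
     regions — the two large contrast ROIs plus the two homogeneous ROIs
     (the reading of "two small + two large = four" adopted here).

   An image is accepted iff SNR ≥ 70.0 ∧ CNR ≥ 3.0 ∧ ENL ≥ 10.0
   (inclusive; all configurable). The thresholds assume the 0–255
   intensity scale — rescaling shifts SNR by a constant — and assume
   stored intensities are linear magnitude; an `inverse_log` flag
   un-compresses log-display data first. ROI sizes are this package's
   defaults (chosen so the homogeneous ROIs fit inside one layer band of
   a 440×300 scan); only the shapes, not sizes, are prescribed anywhere.
7. **Export.** Accepted (LR, HR) pairs are written in a training-ready
   `train/val/test` layout at 70/10/20, sizes by largest-remainder
   rounding, assignment uniformly random under a seed, per-image by
   default with an optional grouping key for per-subject splits.

Layer masks normally come from an external semantic-segmentation model
(read as integer-label PNG). The built-in fallback,
`segment_layers_heuristic`, is plumbing, not a clinical segmenter: it
smooths anisotropically (σ = 1 px axial, 5 px lateral — heavy lateral
averaging suppresses speckle without displacing surfaces), thresholds at
the top-band background mean + 4 SD, takes the first/last crossings per
column as the retina's top/bottom envelope, median-filters the curves
(width 9) against single-column speckle outliers, drops 6 unreliable
border columns, and splits the interior into equal-fraction bands.

## Evaluation metrics

* **PSNR** = 10·log₁₀(max_val²/MSE), +∞ for identical images.
* **SSIM** — the standard 11×11 Gaussian-window (σ = 1.5), K1 = 0.01,
  K2 = 0.03 parameterisation (delegated to scikit-image; the test suite
  carries an independently coded implementation as an oracle).
* **GCF** (global contrast factor) — gamma-linearize (γ = 2.2), perceptual
  luminance 100·√l, mean absolute 4-neighbour luminance difference per
  resolution level, 9 levels built by 2× superpixel averaging of linear
  luminance (ragged edge pixels averaged into the last superpixel), and
  the published weight polynomial w(f) = (−0.406385·f + 0.334573)·f +
  0.0877526, f = i/9.
* **NIQE** — MSCN normalization (7×7 Gaussian, σ = 7/6), per-patch GGD fit
  of the MSCN coefficients plus AGGD fits of the four orientation
  products, at two scales (96 px patches and 48 px on the 2×-averaged
  image), giving 36 features per patch; shape parameters by moment
  matching on a fixed α-grid [0.2, 10] step 0.001. Fitting keeps patches
  whose mean local σ exceeds 0.75× the sharpest patch; scoring uses all
  patches. Score = √( (ν₁−ν₂)ᵀ[(Σ₁+Σ₂)/2]⁻¹(ν₁−ν₂) ), ridge-regularized
  (ε = 10⁻⁶ × mean variance) if the pooled covariance is singular. Lower
  is better. The model is fitted on the accepted-HR set by default;
  fitting and scoring on the same set is possible but not the default,
  since in-sample scoring understates the distance of the corpus to
  itself. Deep-feature metrics (perceptual loss, FID) require an
  externally trained network; the report format accepts externally
  computed per-image values so tables stay complete.

## Synthetic data: what it emulates, and what it does not

The generator produces (a) layered B-scan phantoms: parallel sinusoidal
boundary surfaces, per-layer reflectivities (default 40/170/90/120/200
over background 8 on 440×300 — the second and last layers are distinct so
the homogeneous/contrast ROI scheme is meaningful), a smooth ±12% lateral
reflectivity modulation (vessel-scale texture; also what gives rigid
registration its lateral information), and fully-developed multiplicative
speckle — i.i.d. gamma noise with shape L (the number of looks) and unit
mean on linear reflectivity, clipped to [0, 255]. No noise model is
prescribed by the problem; gamma multiplicative speckle is the standard
fully-developed model and gives the testable identity ENL ≈ L. (b)
Microscope scenes (default 480×360): smoothed-noise fundus texture that
moves rigidly with the retina, a 1 px white marker outline, filled pure
cyan/magenta triangles ≥ 30 px² (guaranteed detectable; real-colour
tolerance lives in the configurable HSV gates), and a Gaussian-bump
feature point. (c) Scripted motion: ~3 px/frame bounded random-walk drift
interrupted by stationary segments with sub-pixel jitter ≤ 0.2 px
(configurable; jitter exercises the tolerance logic). All geometry goes
into a JSON manifest; geometry is seed-independent while speckle and
texture vary with the seed.

Not emulated: photorealistic fundus appearance, instrument shadows,
A-scan-level OCT physics, axial motion, illumination flicker, rolling
shutter. Consequences worth knowing:

* **Clipping truncates speckle.** At reflectivity 200 and L = 1, the
  [0, 255] clip inflates ENL from 1 to ~2.5. ENL-physics checks therefore
  use low-reflectivity (40) homogeneous regions where clipping is
  negligible; ENL measured on bright layers of real (or synthetic) 8-bit
  data reads high for the same reason.
* **SNR gain under fusion is less than 10·log₁₀N.** Background variance
  falls by N (+9 dB at N = 8) but max(F²) is an extreme-value statistic
  that averaging also shrinks; the measured net gain is ~+3 dB at N = 8,
  monotone in N.
* Passing tests show the pipeline recovers *scripted* ground truth under
  this noise model; they cannot certify performance on surgical video
  with non-rigid retina motion, specular artefacts or low signal.

## Problem sizes used in tests

The test suite and the acceptance script run on scaled phantoms chosen to
keep statistics meaningful: 440×300 phantoms for registration and metric
orientation, 260×200 flat phantoms with a 64×64 probe ROI for ENL physics
(10 seeds per condition), 20 registrations per noise condition, 20 random
20-frame scripts (320×240 scenes) for stationarity, and a 28-frame
two-interval video (220×150 B-scans) for the end-to-end run. The
end-to-end demonstration separates its two planted intervals by fusion
depth (16 vs 8 frames ⇒ 2× ENL) with thresholds 25 dB / 1 / 110 placed
between the two deterministic outcomes; the default 70/3/10 gate is
exercised separately on float images engineered around those exact
thresholds, because legitimately exceeding 70 dB SNR requires the
sub-quantization background variance of fused float averages, not 8-bit
single frames.

## Known limitations

* Marker detection requires a near-axis-aligned rectangle and a marker
  brighter than 0.9× the frame maximum.
* The stability rule compares positions only; a depth (axial) shift of
  the retina is invisible to it and would blur the fused B-scan — the
  optional NCC floor is the guard.
* The heuristic segmenter assumes a single connected retina band per
  column; detachments or large fluid pockets violate that.
* NIQE models fitted on small corpora (< ~50 patches) have noisy
  covariances; the ridge keeps scores finite but comparisons between
  models of very different corpus sizes are not meaningful.
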
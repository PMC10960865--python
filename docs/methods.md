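# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions that make the test suite exact.

## Puncta (endocytosis) index

The index scores the abundance of diffraction-limited vesicles as a texture
statistic: the raw image is divided pixelwise by its median-filtered
version, and the dispersion of the ratio over a cytosolic ROI is reported.
The median filter estimates the local "smooth" background; puncta, being
narrower than the window, are largely removed from the filtered image and
therefore survive the division as excursions above 1.

Conventions (all stated so tests can be exact):

- **Window.** Square footprint of exactly the stated size; default 5×5 for
  the `sd` variant (spinning-disk data) and 10×10 for the `skewness`
  variant (laser-scanning data). For even sizes the anchor is the
  upper-left pixel of the central 2×2 block. The filter is a rank filter
  selecting the element of rank ⌊w²/2⌋ of the sorted window (the upper of
  the two middle elements when w² is even); no averaging, which is what
  makes the statistic *exactly* scale invariant.
- **Border.** Reflect padding (edge pixel repeated). ROIs in validation
  stay clear of both the image border band and the cell rim.
- **Division floor.** Filtered values below 10⁻⁶ × image maximum are
  clamped before division, so dark pixels cannot produce infinities. An
  all-zero image is rejected as degenerate.
- **Dispersion.** `sd`: sample standard deviation (n−1 denominator).
  `skewness`: the biased moment coefficient g₁ = m₃/m₂^{3/2}; a different
  convention would be a one-line change and is deliberately not exposed.
- **Preconditions.** The image must be larger than the window and the ROI
  must contain more pixels than the window area.

## Colocalization, recruitment, and the other image metrics

- **Pearson colocalization** is the product-moment correlation over masked
  pixels only; zero variance in either channel over the mask is an error,
  not a silent 0.
- **Co-recruitment index.** Fold change per channel = mean over a response
  window / mean over a baseline window, after subtracting one scalar
  background per channel (clipping at 0). The baseline window is every
  frame strictly before the event frame; the response window is the last 3
  frames of the series. Both windows are configurable because the original
  assay does not state them; the last-3-frames default reads the plateau
  rather than the peak and is robust to single-frame noise. The inclusion
  gate is bait fold ≥ 1.30, inclusive at the boundary ("at least 30 %").
  The prey fold (the CI) is reported for every cell with the flag, so
  gating decisions remain auditable.
- **Translocation index** is a declared stand-in for cytosolic-depletion
  quantification: 1 − mean(post)/mean(pre), clipped to [0, 1] with a
  warning on negative raw values. The original figure panels do not define
  their formula; this one is monotone in depletion, dimensionless, and 0 at
  no change, which is all downstream comparisons require.
- **Focal-adhesion enrichment** is mean FA-mask intensity over mean
  cytosol-mask intensity after optional shared background subtraction; the
  masks must be disjoint. Again a declared convention where the source
  quantification is unstated.
- **Background** defaults to 0 (caller-supplied); a helper estimates it as
  the histogram mode of pixels outside the cell mask (256 bins), the usual
  camera-offset heuristic.

## Synthetic generators

All generators are pure functions of (params, seed); per-cell sub-streams
are spawned from a single `SeedSequence`, so datasets are reproducible
without coupling between cells.

- **Cell images.** Expected intensity = background + cytosol plateau inside
  a disk (or polygon) + a sum of isotropic Gaussian spots of stated peak
  amplitude and σ, centred uniformly in the region (disk sampling keeps the
  full kernel inside). Noise is an optional two-stage camera model: Poisson
  on the expected counts, then additive Gaussian read noise, then a clip at
  0. Defaults (256² image, disk radius 100 px, background 10, cytosol 100,
  amplitude 300, σ 1.5 px, shot noise on, read noise σ 2) give a realistic
  regime where the shot-noise floor of the index is clearly below the
  puncta signal. The returned ROI is the region eroded by 8 px, emulating a
  hand-drawn ROI that avoids the bright cell rim. Not emulated: optical
  PSF anisotropy, uneven illumination, nuclei, membrane structures, photo-
  bleaching — so a passing recovery test shows the *estimator* is correct,
  not that real images are this clean.
- **Colocalization pairs** reuse round(f·n) of channel 1's spot positions
  in channel 2 and draw the rest independently; noise independent per
  channel. f = 1 with noise off gives r = 1 identically.
- **Recruitment series** follow baseline·(1 + (fold−1)·S(t)) with S a
  linear ramp that is 0 before the event and saturates at exactly 1 after
  `rise_time`. The exact plateau is deliberate: with noise off, the
  recovered fold equals the generating fold bit-for-bit, which pins the
  whole CI code path. Baseline 100 a.u., 1-min frames, 5 pre / 20 post
  frames by default, matching a typical dimerizer time course of tens of
  minutes.
- **Tracks** follow a correlated random walk at fixed speed: heading
  increments are Gaussian with variance 2Δt/τ (τ = persistence time; τ = ∞
  gives straight lines), the standard one-parameter discretization of a
  persistent walk. Chemotactic bias b ∈ [0, 1] mixes the unit axis vector
  into the step direction as a renormalized convex combination; this leaves
  the step length — hence the speed — unchanged, so bias moves only the
  FMI, mirroring the observation that speed and FMI separate empirically.
  The heading itself evolves unbiased (an internal compass); the bias acts
  on the emitted step. For a uniformly distributed heading the expected
  projection of a unit step on the axis is then the 1-D integral
  implemented in `expected_step_projection`, which is the independent
  prediction the recovery tests use (the integrand has a removable 0/0 at
  b = 0.5, θ = π, handled explicitly). Defaults match the acquisition
  cadence of the migration assays: Δt = 10 min, 16 h duration → 97 frames;
  speed 0.5 µm/min; τ = 30 min. Positional noise is off by default. Not
  emulated: cell–cell collisions, confinement, speed heterogeneity between
  cells.
- **Growth** is exact exponential doubling, the inverse of the
  doubling-time estimator; the pair round-trips to machine precision.

## Track statistics

- **Ingest.** TrackMate-style columns (`TRACK_ID`, `FRAME`, `POSITION_X`,
  `POSITION_Y`, optional `POSITION_T`), extra columns ignored, rows sorted
  per track. Gaps are linearly interpolated (default, logged) or the track
  is split; duplicates are an error; 1-point tracks are dropped with a
  warning.
- **MSD** averages squared displacements over all overlapping start points
  within a track, then averages tracks with equal weight — the standard
  time-then-ensemble estimator, maximizing use of 97-frame tracks.
- **Persistence ratio** is computed as a per-track curve; group summaries
  use the median and quartiles, which are robust to the heavy right tails
  of speed-like quantities. Frames where the cell has not yet moved (D = 0)
  are excluded rather than defined.
- **FMI axis** is a configurable unit vector, default +y (toward the
  high-serum reservoir in the chemotaxis chamber); |FMI| ≤ d/D always, by
  the projection inequality.

## Group statistics

- **Wilcoxon rank-sum**: exact enumeration (via the Mann–Whitney null) for
  untied samples with both n ≤ 25 in auto mode, else the normal
  approximation with mid-ranks, tie-corrected variance and continuity
  correction. Both modes are exposed because the original analyses do not
  state which their R calls used.
- **Steel–Dwass (asymptotic)**: each pair is ranked on its own; the
  standardized statistic Z uses the tie-corrected null variance
  mn/12·[(N+1) − Σ(t³−t)/(N(N−1))]; the two-sided p is the studentized
  range survival function (k groups, ∞ df) at √2|Z|. The ∞-df CDF,
  k∫φ(z)[Φ(z)−Φ(z−q)]^{k−1}dz, is evaluated by 240-node Gauss–Legendre
  quadrature on z ∈ [−9, 9] (validated against published critical values
  q₀.₀₅ = 2.772 (k=2), 3.314 (k=3), and against an independent adaptive
  quadrature to ~1e−9). For k = 2 the procedure reduces exactly to the
  normal-approximation rank-sum test without continuity correction, which
  is the cross-check the calibration tests use. All p-values are clipped to
  [0, 1] after approximation.
- **Calibration.** Because the pairwise p-values are studentized-range
  calibrated, it is the *familywise* error under a k-group null that sits
  at the nominal α (measured ≈ 0.049 at α = 0.05 over 10⁴ three-group
  null replicates, n = 20 per group); any single pair rejects far less
  often. Quartiles use linear interpolation between order statistics
  (numpy's default, "type 7"), whiskers at 1.5×IQR beyond the quartiles,
  and error bars are 2×SEM with the sample (n−1) standard deviation.

## Pipeline

Configs are YAML mappings validated by pydantic models with unknown keys
forbidden, so schema violations fail before any computation. One global
seed is expanded deterministically per group and per cell; the manifest
records package and library versions, the seed and the fully resolved
config, and identical config + seed reproduces every CSV byte for byte
(manifests contain no timestamps for this reason). Two-group runs are
compared by Wilcoxon, three or more by Steel–Dwass, matching the reporting
convention the measurements come from.

## Problem sizes in validation

Validation simulations use 128² images (disk radius 50 px) for per-cell
image metrics, 256²–512² for colocalization Monte-Carlo checks, and
500-track ensembles at the 10-min/97-frame cadence for migration recovery;
the Steel–Dwass null calibration uses 10⁴ three-group replicates. These
sizes give standard errors comfortably inside the stated recovery
tolerances (e.g. mean FMI within ±0.05) while keeping the full suite fast.

## Known limitations

- The translocation and focal-adhesion quantifications are declared
  conventions, not reconstructions of the original (unstated) formulas.
- The puncta index is a texture statistic, not a count; it saturates once
  puncta crowd each other, and the simulator's monotonicity guarantees are
  statistical, not per-image.
- The Steel–Dwass implementation is asymptotic only (no exact small-sample
  mode), matching the named reference option; for very small groups its
  p-values are approximate.
- The track model has no interaction, confinement or speed heterogeneity;
  recovery results bound estimator error, not biological realism.
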
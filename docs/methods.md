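# Methods

## The quantity

Macular ellipsoid-zone intensity (mEZi) is the peak-intensity ratio of the
two innermost outer-retinal hyperreflective bands on an SD-OCT B-scan: the
ellipsoid zone (EZ) over the external limiting membrane (ELM).  Taking the
ratio against the ELM cancels scan-to-scan gain: multiplying a whole image
by a constant leaves every sector's mEZi unchanged, which is asserted
directly on phantoms.  Within a sampling window the statistic is
`max-over-columns(EZ peak) / max-over-columns(ELM peak)` — the highest EZ
value divided by the highest ELM value, not the mean of per-column ratios.

## Per-scan pipeline

1. **Log transform** `v -> log(1+v)`, rescaled to the original dynamic
   range.  OCT reflectivity spans decades; the log compresses it so one
   global threshold can separate bands from background.  The map is
   strictly monotone, so peak locations are unchanged.  Images already on
   the working (log) scale are passed through untouched — the transform is
   never applied twice.
2. **Central crop** to 4000 µm about the fovea column (metadata, or the
   image centre by default; automatic foveal detection is out of scope).
   The EZ grows indistinct with eccentricity, so only the central macula
   is quantified.
3. **Inner-retina elimination.**  A global Otsu split on the cropped log
   image marks hyperreflective pixels.  Per column, suprathreshold runs
   separated by less than 120 µm are merged (EZ and RPE are distinct peaks
   of one complex) and the *deepest* merged run is taken as the outer
   complex; the inner-retinal complex, lying hundreds of µm shallower,
   is zeroed.  Because the dim ELM can fall below a global threshold, the
   retained window extends 100 µm above the run (more than the largest
   plausible ELM–EZ gap, far less than the gap to the inner retina) and
   40 µm below it (so the RPE tail is not clipped).  The operation is
   idempotent: re-running it on its own output changes nothing.
4. **Peak extraction.**  Per column, local maxima are located on a
   depth-smoothed profile (Gaussian, σ = 6 µm): bands are several pixels
   wide while speckle spikes are essentially single-pixel, so smoothing
   suppresses spurious maxima without moving band centres.  The recorded
   peak *intensity* is the raw maximum within one pixel of the located
   peak, so noise-free amplitudes are reported exactly.  The shallowest
   qualifying peak is the ELM; the EZ is the next deeper peak whose
   separation lies in [10, 80] µm — this anatomical window is what stops
   the brighter RPE (≈ 90–110 µm below the ELM) from being taken as the
   EZ.  Columns without such a pair are invalid.  Prominence (6%) and
   height (5%) thresholds are relative to the column maximum, so a
   uniformly attenuated column still yields peaks.
5. **Vessel-shadow exclusion.**  An overlying vessel attenuates the whole
   outer-band region of its columns.  The statistic is the per-column
   summed intensity over the outer-band rows, where the row window tracks
   the retina: the ELM-to-EZ depth interval interpolated across valid
   columns (padded 4 px above / 10 px below), so tilted or curved scans
   are measured in the right place even where the shadow broke peak
   detection.  Columns below `median − 3·MAD` (normal-consistent MAD) are
   flagged and each flagged run is dilated by one column per side.  A
   column is never flagged unless its deficit also exceeds 25% of the
   median: shadows suppress signal drastically, whereas disease-related
   intensity loss is gradual and must stay in the analysis (a noise-free
   scan whose EZ is 25% dimmer over half its width has MAD = 0, and the
   plain MAD rule would discard the diseased half wholesale).
6. **Failure detection.**  A scan is rejected when fewer than 50% of its
   analysed columns are valid, or when the fitted EZ depth spans more than
   40% of the image height across the crop — the signature of a steeply
   curved posterior pole whose bands run off the frame.  A failed scan
   contributes no sectors; the thresholds are configurable because the
   failure criterion of the original instrument is not published.

## Sector geometry and aggregation

The automated protocol tiles the 4000-µm extent with 220 equal half-open
bins per line scan (boundary pixels belong to the lower bin); exactly 220
records are always returned, with exclusions flagged rather than dropped.
The manual-protocol emulation samples 21 windows of 150 µm centred every
200 µm from the fovea to ±2000 µm; the outermost windows are clipped at
the crop edge.  Per-eye mEZi is the unweighted mean of all valid sector
values pooled across the eye's scans (design: 11 horizontal + 11 vertical
lines); scan-then-eye two-stage averaging is available as an option.  On a
laterally uniform phantom the two protocols agree to well under 1%, which
is why average values are comparable despite the different sampling
densities.

## Agreement statistics

* **Deming regression** with error-variance ratio λ = 1 by default (the
  common method-comparison default; neither method is a gold standard).
  Closed form: `slope = [s_yy − λ s_xx + sqrt((s_yy − λ s_xx)² +
  4 λ s_xy²)]/(2 s_xy)`, intercept through the centroid.  As λ → ∞ the
  fit tends to OLS of y on x; at λ = 1 swapping the axes inverts the
  slope.  Deming regression has no canonical R²; the squared Pearson
  correlation of the raw pairs is reported alongside, and standard errors
  come from a leave-one-out jackknife.
* **Bland-Altman**: differences AM − MM, SD with the n−1 denominator,
  limits of agreement mean ± 1.96 SD, plus an OLS of difference on
  average for proportional bias.
* **Compensation**: the difference-vs-average OLS fitted on the
  calibration set.  Applied to a *pair*, the correction is evaluated at
  the pair average — the exact inverse of the fitted relation, driving a
  refit on the same data to (0, 0) to machine precision.  Applied to a
  *lone* automated value, the value itself stands in for the average
  (`AM_c = AM − (a + b·AM)`); both forms reduce to subtracting the mean
  bias when b = 0.  The lone-value form is isolated in one function so an
  iterative solve for the latent average could be swapped in.
* **Replicate CIs**: t-based, df = k−1 (k = 5 replicates in the emulated
  design), and coverage counts values inside the closed interval.
* **Mann-Whitney**: exact permutation enumeration (midranks, handles
  ties) when either group has fewer than 8 observations; tie-corrected
  normal approximation otherwise.

## Phantoms

Each band (inner-retinal complex, ELM, EZ, RPE) is an axial Gaussian with
configurable amplitude (scalar or per-column profile), centre depth and
width; all bands share one posterior surface (tilt + quadratic curvature),
which preserves the anatomical depth ordering everywhere.  Band shape is
not specified by any published description of the method; Gaussians match
the peaked appearance of hyperreflective bands and make ground truth
analytic.  Amplitudes live on the post-log working scale so truth is exact
on the scale the quantifier operates on; `to_linear` exports a
linear-intensity image for end-to-end tests through the log stage (the
inverse map preserves ratios up to a global gain).

Default geometry: 1024 × 512 px, 9000 µm scan length, 4 µm axial pitch;
inner complex 700 µm, ELM 960 µm (amp 60), EZ 1012 µm (amp 240), RPE
1068 µm (amp 255).  Band centres sit on integer pixel rows at the default
pitch, and σ_ELM = σ_EZ = 10 µm, so axial sampling droop cancels exactly
in the EZ/ELM ratio — ground truth stays exact rather than carrying a
sub-percent sampling bias.  The ELM–EZ gap (52 µm) sits inside the
extractor's [10, 80] µm window; the ELM–RPE gap (108 µm) sits outside it.

Speckle is a mean-one gamma multiplicative field with coefficient of
variation `speckle_factor`, followed by additive Gaussian noise and
clipping at zero; vessel shadows multiply everything below the
inner-retina/ELM midline by `1 − attenuation`.  Real OCT speckle is
correlated and Rayleigh-like, the point-spread function is anisotropic,
and pathology (drusen, hyperreflective foci) disrupts band continuity —
none of which the phantom emulates.  Passing tests therefore demonstrate
correctness of the extraction and statistics under controlled band
anatomy and noise, not clinical robustness on degraded scans.

The paired-measurement generator draws a latent true mEZi per eye from
its group's normal distribution (defaults: means 4.08 / 3.14 / 2.36, SDs
0.42 / 0.43 / 0.52 for normal / mild-to-moderate / severe groups) and
observes `mm = latent + e₁`, `am = slope·latent + bias + e₂` with
independent Gaussian errors.  In the calibration emulation
(`scripts/acceptance.py` and the acceptance tests) the generating line is
slope 1.047, intercept −0.058 with per-method noise SD 0.179, sized so
the raw-pair squared correlation is ≈ 0.914; the agreement-geometry
emulation uses a constant 0.09 bias with difference SD 0.344, giving
limits of agreement near (−0.59, +0.76); the validation emulation uses
slope 1.004, intercept 0.139 and noise SD 0.041 (squared correlation
≈ 0.99) with 11 eyes per group.  A single iid error SD cannot reproduce a
given correlation and a larger difference SD simultaneously, which is why
the line-recovery and agreement-geometry emulations are run as two
designs rather than one.

## En-face maps

Sector values are scattered at (line position, lateral centre) over the
central 4000-µm square and assembled on a 220 × 220 lattice whose cell
centres coincide with the default sector centres; scan-line positions are
snapped to cell centres, so measured cells hold their source values
exactly (coincident horizontal/vertical crossings are averaged).  The
rest is filled by planar linear interpolation with nearest-neighbour fill
outside the measured hull — both convex operations, so interpolated
values never leave the measured range.  A single scan line is collinear
and admits no triangulation; it is filled entirely by nearest neighbour.
The colour ramp is a two-stop linear blue-to-yellow blend
(`maps.MEZI_CMAP`): each RGB channel is linear in the value, so a higher
mEZi is never bluer than a lower one (the popular perceptual maps wobble
at their dark tail and violate that guarantee).  Scale defaults to the
1st–99th percentile of the map, overridable.

## Problem sizes and determinism

Phantom tests use single scans or 22-scan eyes at the default 1024 × 512
geometry (a scan quantifies in tens of milliseconds; a full eye in about
two seconds).  Agreement tests use n = 160 calibration and n = 33
validation tables, matching the emulated designs, with 20 random datasets
of n = 50–200 for the Deming brute-force cross-check.  All stochastic
tests are seeded; `scripts/acceptance.py` derives every stream from its
`--seed` argument, and identical seeds reproduce bit-identical phantoms
and tables.

## Known limitations

* Foveal localisation relies on metadata or the image centre; no foveal
  bulge/depression detection.
* Layer segmentation is minimal by design: only the ELM/EZ peaks are
  located, not boundary surfaces; multi-layer segmentation and B-scan
  registration are out of scope.
* The vessel-shadow deficit floor (25% of median energy) trades
  sensitivity to faint shadows for robustness against excluding genuine
  disease-related loss.
* Device raw formats (.e2e, .vol) are not read; export to TIFF/PNG with a
  geometry sidecar first.
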
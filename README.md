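# ezquant

Automated quantification of **macular ellipsoid-zone intensity (mEZi)** on
SD-OCT B-scans.

The ellipsoid zone (EZ) — the outer retina's second hyperreflective band,
anatomically the photoreceptor inner-segment ellipsoid — loses reflectivity
in a range of retinal and optic-nerve diseases, including glaucoma.  Its
intensity is only meaningful relative to an internal reference, so the
quantity of interest is the ratio of the EZ band's peak intensity to that
of the external limiting membrane (ELM, the first outer-retinal band):

```
mEZi = max-peak(EZ) / max-peak(ELM),  averaged over the central macula
```

`ezquant` implements the full automated pipeline for this biomarker, for
researchers quantifying outer-retinal change on macular line-scan OCT:

* **bands** — log transform, central 4000-µm crop, inner-retina
  elimination by global (Otsu) thresholding, per-A-scan ELM/EZ peak
  extraction with an anatomical separation constraint, vessel-shadow
  exclusion and scan-failure detection;
* **mezi** — sector geometry (220 evenly spaced sectors per line scan for
  the automated protocol; 21 windows of 150 µm at 200-µm spacing for the
  manual-protocol emulation) and per-eye aggregation over the 11 + 11
  line-scan grid;
* **agreement** — Deming errors-in-variables regression, Bland-Altman
  limits of agreement, a difference-vs-average compensation model,
  replicate t-based confidence intervals with coverage counting, and
  Mann-Whitney group comparison — the statistics used to calibrate and
  validate the automated method against manual grading;
* **maps** — en-face topographic mEZi maps (yellow = high, blue = low);
* **phantom** — synthetic OCT B-scans with Gaussian-profile bands, posterior
  tilt/curvature, speckle, vessel shadows and *exact* ground truth, so the
  whole pipeline is testable without clinical data;
* a thin `ezquant` command line (`phantom`, `quantify`, `calibrate`,
  `validate`, `map`) over the library.

## Worked example

Quantify a 22-scan synthetic eye with mild speckle
(`examples/01_quantify_phantom_eye.py`):

```text
true mEZi (configured EZ/ELM amplitude ratio): 4.000
measured per-eye mEZi:  3.974  (4829 sectors over 22 scans)
recovery error: 0.66%
sector spread (SD): 0.225
```

The phantom was built with EZ amplitude 240 and ELM amplitude 60, so the
true ratio is 4.0; the pipeline recovers it to 0.66% from 4,829 valid
sectors pooled across 11 horizontal and 11 vertical line scans.

Calibrate the automated against the manual method on a simulated paired
design (`examples/03_calibration_statistics.py`):

```text
n = 160 paired eyes
Deming:       AM = 1.047(MM) -0.028   (jackknife SE 0.023 / 0.072)
correlation:  R^2 = 0.920
Bland-Altman: mean difference +0.112, LoA [-0.340, 0.565]
compensation: diff = -0.024 +0.045 * average
```

The generating line was AM = 1.047·MM − 0.058; the Deming fit recovers the
slope exactly and the intercept within one jackknife standard error.  The
Bland-Altman limits of agreement bracket ~95% of between-method
differences; the compensation model is the regression of difference on
average, later used to correct lone automated values.

The other examples cover vessel-shadow exclusion and failure flagging
(`02`), replicate-CI coverage (`04`), and en-face maps with a localised
inferior defect (`05`).

## Reading clinical data

`ezquant quantify` accepts 8/16-bit grayscale TIFF or PNG B-scans.  Scan
geometry (µm per pixel laterally and axially, meridian, fovea column) is
taken from a JSON sidecar next to each image or from the
`--lateral-um-per-px` / `--axial-um-per-px` / `--center-col` flags; see
`docs/methods.md` for the processing parameters and their defaults.

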
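"""Outer-retinal band extraction from SD-OCT B-scans.

The quantifier works on one B-scan at a time.  A B-scan is a 2-D raster
whose rows run axially (row 0 at the vitreous, deeper rows toward the
choroid) and whose columns are A-scans.  The outer retina shows up as a
stack of hyperreflective bands; the two of interest here are the external
limiting membrane (ELM, the innermost band, used as the intensity
reference) and the ellipsoid zone (EZ, the next band out).  This module
implements the preprocessing chain that isolates those two bands per
A-scan:

    log transform -> central crop -> inner-retina elimination
        -> per-column ELM/EZ peak extraction -> vessel-shadow exclusion
        -> failure detection

Everything downstream (sector ratios, per-eye averages, maps) consumes the
:class:`OuterBandExtraction` this module produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

__all__ = [
    "BScanImage",
    "CropWindow",
    "OuterBandExtraction",
    "BScanError",
    "CropError",
    "ScanFailedError",
    "log_transform",
    "crop_central_region",
    "eliminate_inner_retina",
    "extract_bands",
    "detect_vessel_shadows",
    "detect_failure",
]

MERIDIANS = ("horizontal", "vertical")


class BScanError(ValueError):
    """Invalid B-scan input (geometry, pixel values, meridian label)."""


class CropError(ValueError):
    """A requested lateral crop does not fit inside the image."""


class ScanFailedError(RuntimeError):
    """Raised when quantification is requested on a failed extraction."""


class CropWindow(NamedTuple):
    """Half-open pixel bounds ``[row_lo, row_hi) x [col_lo, col_hi)``."""

    row_lo: int
    row_hi: int
    col_lo: int
    col_hi: int


@dataclass
class BScanImage:
    """A grayscale B-scan plus its physical scan geometry.

    Parameters
    ----------
    pixels
        2-D float array, finite and non-negative.  Row 0 is the vitreous
        (top); rows increase toward the choroid.
    lateral_um_per_px, axial_um_per_px
        Pixel pitch in micrometres.  Both must be positive.
    scan_id
        Opaque label carried through to the per-sector output tables.
    meridian
        ``"horizontal"`` or ``"vertical"``.
    is_log_transformed
        Whether the intensities are already on the logarithmic working
        scale the quantifier operates on.
    """

    pixels: np.ndarray
    lateral_um_per_px: float
    axial_um_per_px: float
    scan_id: str = ""
    meridian: str = "horizontal"
    is_log_transformed: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise BScanError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise BScanError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise BScanError("pixels must be non-negative")
        if self.lateral_um_per_px <= 0 or self.axial_um_per_px <= 0:
            raise BScanError("pixel pitches must be positive")
        if self.meridian not in MERIDIANS:
            raise BScanError(f"meridian must be one of {MERIDIANS}, got {self.meridian!r}")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def lateral_extent_um(self) -> float:
        return self.width_px * self.lateral_um_per_px


@dataclass
class OuterBandExtraction:
    """Per-A-scan ELM/EZ peak locations and intensities.

    Arrays are indexed by column of the (cropped) image the extraction was
    run on.  Depths are row indices; missing entries are NaN.  ``valid_mask``
    marks columns where both peaks were found with plausible ordering and
    separation; ``shadow_mask`` marks columns excluded as vessel shadows
    (a subset of the invalid columns once shadows have been detected).
    """

    elm_depth_px: np.ndarray
    elm_peak: np.ndarray
    ez_depth_px: np.ndarray
    ez_peak: np.ndarray
    valid_mask: np.ndarray
    crop_window: CropWindow
    failed: bool
    image_shape: tuple[int, int]
    shadow_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.shadow_mask is None:
            self.shadow_mask = np.zeros_like(np.asarray(self.valid_mask, bool))

    @property
    def n_columns(self) -> int:
        return len(self.valid_mask)

    @property
    def valid_fraction(self) -> float:
        """Valid columns over *all* analysed columns (a column where no band
        was found still counts in the denominator)."""
        if self.n_columns == 0:
            return 0.0
        return float(np.count_nonzero(self.valid_mask)) / self.n_columns


def log_transform(image: BScanImage, rescale: bool = True) -> BScanImage:
    """Map intensities through ``v -> log(1 + v)``.

    OCT reflectivity spans several decades; the log compresses that range
    so a single global threshold can separate the hyperreflective bands
    from background.  With ``rescale`` (the default) the result is scaled
    back to the original dynamic range, so the output maximum equals the
    input maximum.  The map is strictly monotone, so per-column peak
    locations are preserved.

    An already-transformed image is returned unchanged with a warning; the
    transform is never applied twice.
    """
    if image.is_log_transformed:
        warnings.warn("image is already log-transformed; returning it unchanged",
                      stacklevel=2)
        return image
    out = np.log1p(image.pixels)
    if rescale:
        vmax = image.pixels.max()
        if vmax > 0:
            out = out * (vmax / np.log1p(vmax))
    return replace(image, pixels=out, is_log_transformed=True)


def crop_central_region(image: BScanImage, center_col: int | None = None,
                        extent_um: float = 4000.0) -> BScanImage:
    """Crop the scan laterally to ``extent_um`` centred on ``center_col``.

    The EZ grows less distinct with eccentricity, so quantification is
    restricted to the central macula (4000 µm by default).  ``center_col``
    defaults to the image centre; automatic foveal detection is out of
    scope, so callers with sidecar metadata should pass the fovea column.

    Returns a new image spanning the half-open column interval of width
    ``round(extent_um / lateral_um_per_px)`` pixels; the axial extent is
    unchanged.
    """
    width_cols = int(round(extent_um / image.lateral_um_per_px))
    if width_cols > image.width_px:
        short = extent_um - image.lateral_extent_um
        raise CropError(
            f"requested extent {extent_um:g} um exceeds the scan width "
            f"{image.lateral_extent_um:g} um by {short:g} um")
    if center_col is None:
        center_col = image.width_px // 2
    if not 0 <= center_col < image.width_px:
        raise CropError(f"center_col {center_col} outside image width {image.width_px}")
    col_lo = center_col - width_cols // 2
    col_hi = col_lo + width_cols
    if col_lo < 0 or col_hi > image.width_px:
        raise CropError(
            f"crop [{col_lo}, {col_hi}) crosses the image edge "
            f"(width {image.width_px}); re-centre or shorten the extent")
    return replace(image, pixels=image.pixels[:, col_lo:col_hi].copy())


def _deepest_run_bounds(mask_col: np.ndarray) -> tuple[int, int] | None:
    """Half-open row bounds of the deepest True run, or None if empty."""
    idx = np.flatnonzero(mask_col)
    if idx.size == 0:
        return None
    hi = idx[-1]
    # walk back to the start of the trailing contiguous run
    breaks = np.flatnonzero(np.diff(idx) > 1)
    lo = idx[breaks[-1] + 1] if breaks.size else idx[0]
    return int(lo), int(hi) + 1


def eliminate_inner_retina(image: BScanImage,
                           merge_gap_um: float = 120.0,
                           elm_margin_um: float = 100.0,
                           tail_margin_um: float = 40.0,
                           ) -> tuple[BScanImage, CropWindow]:
    """Zero out everything above the outer-retinal complex, per column.

    A global histogram split (Otsu) on the cropped log image separates
    hyperreflective pixels from background.  Per column, suprathreshold
    runs separated by less than ``merge_gap_um`` are merged (the EZ and
    RPE bands are distinct peaks but belong to one complex), and the
    deepest merged run is taken as the outer complex.  Because the dim ELM
    can fall below a global threshold, the retained window is extended
    upward by ``elm_margin_um`` — enough to cover the largest plausible
    ELM–EZ separation but far less than the gap to the inner retina.

    The window also keeps ``tail_margin_um`` below the run so the RPE's
    subthreshold tail is not clipped.  Columns with no suprathreshold run
    are zeroed entirely; whether enough columns survive is judged later by
    :func:`detect_failure`.

    Returns the masked image and the bounding window of its support.
    """
    px = image.pixels
    out = np.zeros_like(px)
    if px.max() > 0 and px.min() != px.max():
        thr = threshold_otsu(px)
        mask = px >= thr
        gap_px = max(1, int(round(merge_gap_um / image.axial_um_per_px)))
        mask = ndimage.binary_closing(mask, structure=np.ones((gap_px, 1), bool))
        margin_px = int(round(elm_margin_um / image.axial_um_per_px))
        tail_px = int(round(tail_margin_um / image.axial_um_per_px))
        nrows = px.shape[0]
        for c in range(px.shape[1]):
            bounds = _deepest_run_bounds(mask[:, c])
            if bounds is None:
                continue
            lo, hi = bounds
            lo = max(0, lo - margin_px)
            hi = min(nrows, hi + tail_px)
            out[lo:hi, c] = px[lo:hi, c]
    window = _support_window(out)
    return replace(image, pixels=out), window


def _support_window(pixels: np.ndarray) -> CropWindow:
    rows = np.flatnonzero(np.any(pixels > 0, axis=1))
    cols = np.flatnonzero(np.any(pixels > 0, axis=0))
    if rows.size == 0:
        return CropWindow(0, 0, 0, 0)
    return CropWindow(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def extract_bands(image: BScanImage, window: CropWindow,
                  gap_min_um: float = 10.0, gap_max_um: float = 80.0,
                  min_valid_frac: float = 0.5,
                  peak_prominence_frac: float = 0.06,
                  peak_height_frac: float = 0.05,
                  smooth_sigma_um: float = 6.0) -> OuterBandExtraction:
    """Locate the ELM and EZ peaks in every A-scan of the masked image.

    Peaks are located on a depth-smoothed copy of each column (Gaussian,
    ``smooth_sigma_um``): hyperreflective bands are several pixels wide
    while speckle spikes are essentially single-pixel, so smoothing
    suppresses spurious maxima without moving the band centres.  The peak
    *intensity* recorded is the raw (unsmoothed) maximum within one pixel
    of the located peak, so noise-free amplitudes are reported exactly.

    Prominence and height thresholds are relative to the column maximum,
    so a uniformly attenuated column still yields its peaks.  The
    shallowest qualifying peak is assigned to the ELM; the EZ is the next
    deeper peak whose axial separation from the ELM lies within
    ``[gap_min_um, gap_max_um]`` — the separation window is what stops the
    much brighter RPE from being grabbed as the EZ.  Columns with fewer
    than two qualifying peaks, or no peak pair with plausible separation,
    are marked invalid.

    The extraction is flagged ``failed`` when fewer than ``min_valid_frac``
    of the window's columns are valid.
    """
    n = image.width_px
    elm_depth = np.full(n, np.nan)
    ez_depth = np.full(n, np.nan)
    elm_peak = np.zeros(n)
    ez_peak = np.zeros(n)
    valid = np.zeros(n, bool)
    gap_lo = gap_min_um / image.axial_um_per_px
    gap_hi = gap_max_um / image.axial_um_per_px
    sigma_px = smooth_sigma_um / image.axial_um_per_px
    smooth = ndimage.gaussian_filter1d(image.pixels, sigma_px, axis=0) \
        if sigma_px > 0 else image.pixels
    nrows = image.height_px

    for c in range(window.col_lo, window.col_hi):
        col = smooth[:, c]
        cmax = col.max()
        if cmax <= 0:
            continue
        peaks, _ = find_peaks(col, prominence=peak_prominence_frac * cmax,
                              height=peak_height_frac * cmax)
        if peaks.size < 2:
            continue
        elm = peaks[0]
        deeper = peaks[1:]
        gaps = deeper - elm
        ok = (gaps >= gap_lo) & (gaps <= gap_hi)
        if not ok.any():
            continue
        ez = deeper[np.flatnonzero(ok)[0]]
        raw = image.pixels[:, c]
        elm_depth[c] = elm
        ez_depth[c] = ez
        elm_peak[c] = raw[max(0, elm - 1):min(nrows, elm + 2)].max()
        ez_peak[c] = raw[max(0, ez - 1):min(nrows, ez + 2)].max()
        valid[c] = True

    n_valid = int(np.count_nonzero(valid))
    failed = n == 0 or n_valid < min_valid_frac * n
    return OuterBandExtraction(
        elm_depth_px=elm_depth, elm_peak=elm_peak,
        ez_depth_px=ez_depth, ez_peak=ez_peak,
        valid_mask=valid, crop_window=window, failed=failed,
        image_shape=image.pixels.shape,
    )


def detect_vessel_shadows(image: BScanImage, extraction: OuterBandExtraction,
                          k: float = 3.0, dilate: int = 1,
                          pad_above_px: int = 4,
                          pad_below_px: int = 10,
                          min_deficit_frac: float = 0.25) -> OuterBandExtraction:
    """Flag columns darkened by overlying retinal vessels.

    A vessel in the inner retina casts a shadow that attenuates the whole
    outer-band region of its columns, so the per-column summed intensity
    over the outer-band rows is the detection statistic.  The outer-band
    row window follows the retina: per column it spans the ELM-to-EZ depth
    interpolated across the valid columns (padded a few pixels above the
    ELM and below the EZ), so a tilted or curved scan is measured in the
    right place even where the shadow itself broke peak detection.
    Columns whose energy falls below ``median - k * MAD`` (MAD scaled to
    be consistent with a normal SD) are marked invalid, and each
    contiguous run of flagged columns is dilated by ``dilate`` columns per
    side to catch the shadow penumbra.  A column is never flagged unless
    its energy deficit also exceeds ``min_deficit_frac`` of the median:
    vessel shadows suppress the signal drastically, whereas genuine
    disease-related intensity loss is gradual and must stay in the
    analysis.  Shadowed columns can keep
    plausible peak values (a uniform attenuation cancels in the EZ/ELM
    ratio) but are excluded from every downstream average.
    """
    win = extraction.crop_window
    n = extraction.n_columns
    height = extraction.image_shape[0]
    inside = np.zeros(n, bool)
    inside[win.col_lo:win.col_hi] = True
    vcols = np.flatnonzero(extraction.valid_mask)
    if vcols.size:
        cols = np.arange(n)
        elm = np.interp(cols, vcols, extraction.elm_depth_px[vcols])
        ez = np.interp(cols, vcols, extraction.ez_depth_px[vcols])
        lo = np.clip(np.floor(elm).astype(int) - pad_above_px, 0, height)
        hi = np.clip(np.ceil(ez).astype(int) + pad_below_px, 0, height)
        energy = np.array([image.pixels[lo[c]:hi[c], c].sum() for c in range(n)])
    else:
        energy = image.pixels[win.row_lo:win.row_hi, :].sum(axis=0)
    e = energy[inside]
    shadow = np.zeros_like(inside)
    if e.size:
        med = np.median(e)
        mad = 1.4826 * np.median(np.abs(e - med))
        deficit = max(k * mad, min_deficit_frac * med)
        shadow = inside & (energy < med - deficit)
        if dilate > 0 and shadow.any():
            shadow = ndimage.binary_dilation(shadow, iterations=dilate) & inside
    return replace(extraction,
                   valid_mask=extraction.valid_mask & ~shadow,
                   shadow_mask=extraction.shadow_mask | shadow)


def detect_failure(extraction: OuterBandExtraction,
                   min_valid_frac: float = 0.5,
                   axial_range_frac: float = 0.4) -> bool:
    """Decide whether a scan must be discarded entirely.

    A scan fails when (a) fewer than ``min_valid_frac`` of its analysed
    columns yielded a valid ELM/EZ pair, or (b) the EZ depth spans more
    than ``axial_range_frac`` of the image height across the crop — the
    signature of a highly curved posterior pole whose bands run off the
    frame.  A failed scan contributes no sectors.
    """
    if extraction.failed:
        return True
    if extraction.valid_fraction < min_valid_frac:
        return True
    depths = extraction.ez_depth_px[extraction.valid_mask]
    if depths.size:
        height = extraction.image_shape[0]
        if (np.nanmax(depths) - np.nanmin(depths)) > axial_range_frac * height:
            return True
    return False
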
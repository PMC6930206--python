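"""End-to-end quantification of a single B-scan.

Convenience wrapper binding the preprocessing chain to the sector
geometry: log transform (if needed) -> central crop -> inner-retina
elimination -> band extraction -> vessel-shadow exclusion -> failure
check -> sector ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import bands, mezi

__all__ = ["ScanResult", "quantify_bscan"]


@dataclass
class ScanResult:
    """Everything produced from one B-scan."""

    image: bands.BScanImage            # the cropped working-scale image
    extraction: bands.OuterBandExtraction
    sectors: list[mezi.SectorMeasurement] | None
    failed: bool


def quantify_bscan(image: bands.BScanImage,
                   center_col: int | None = None,
                   extent_um: float = mezi.ANALYSIS_EXTENT_UM,
                   protocol: str = "am",
                   n_sectors: int = mezi.AM_SECTORS_PER_SCAN,
                   gap_min_um: float = 10.0, gap_max_um: float = 80.0,
                   shadow_k: float = 3.0,
                   min_valid_frac: float = 0.5,
                   axial_range_frac: float = 0.4) -> ScanResult:
    """Run the full per-scan pipeline and return sectors (or a failure).

    ``protocol`` selects the sector geometry: ``"am"`` (``n_sectors``
    evenly spaced bins) or ``"mm"`` (21 manual-protocol windows).  A scan
    that fails band extraction or the failure check yields
    ``sectors=None`` and ``failed=True`` instead of raising.
    """
    if not image.is_log_transformed:
        image = bands.log_transform(image)
    cropped = bands.crop_central_region(image, center_col=center_col,
                                        extent_um=extent_um)
    masked, window = bands.eliminate_inner_retina(cropped)
    extraction = bands.extract_bands(masked, window,
                                     gap_min_um=gap_min_um,
                                     gap_max_um=gap_max_um,
                                     min_valid_frac=min_valid_frac)
    extraction = bands.detect_vessel_shadows(masked, extraction, k=shadow_k)
    failed = bands.detect_failure(extraction, min_valid_frac=min_valid_frac,
                                  axial_range_frac=axial_range_frac)
    if failed:
        return ScanResult(image=cropped, extraction=extraction,
                          sectors=None, failed=True)
    if protocol == "am":
        sectors = mezi.am_quantify_scan(extraction, cropped, n_sectors=n_sectors)
    elif protocol == "mm":
        sectors = mezi.mm_quantify_scan(extraction, cropped)
    else:
        raise ValueError(f"unknown protocol {protocol!r}; use 'am' or 'mm'")
    return ScanResult(image=cropped, extraction=extraction,
                      sectors=sectors, failed=False)
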
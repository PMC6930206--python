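"""Sector-wise and per-eye macular EZ intensity (mEZi).

mEZi is the ratio of the EZ band's peak intensity to the ELM band's peak
intensity — the ELM acting as an internal reference that cancels scan-to-
scan brightness variation — averaged over the central macula.  Two sector
geometries are implemented over the same 4000-µm analysis extent:

* the automated protocol: 220 evenly spaced sectors per line scan;
* the manual protocol: 21 sampling windows per meridian, 150 µm wide,
  centred every 200 µm from the fovea out to ±2000 µm eccentricity.

Within a sector the ratio is max-over-columns EZ peak divided by
max-over-columns ELM peak.  Per-eye mEZi is the unweighted mean of all
valid sector values pooled across the eye's line scans (the full design
is 11 horizontal plus 11 vertical lines).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import BScanImage, OuterBandExtraction, ScanFailedError

__all__ = [
    "ANALYSIS_EXTENT_UM",
    "AM_SECTORS_PER_SCAN",
    "MM_SAMPLE_WIDTH_UM",
    "MM_SAMPLE_SPACING_UM",
    "MM_MAX_ECCENTRICITY_UM",
    "LINES_PER_MERIDIAN",
    "SCAN_LENGTH_UM",
    "SectorMeasurement",
    "EyeMeasurement",
    "compute_sector_ratio",
    "am_quantify_scan",
    "mm_quantify_scan",
    "quantify_eye",
    "sectors_to_frame",
]

# scan-grid geometry of the emulated acquisition protocol
SCAN_LENGTH_UM = 9000.0          #: length of each line scan
LINES_PER_MERIDIAN = 11          #: line scans analysed per meridian
ANALYSIS_EXTENT_UM = 4000.0      #: central macular extent analysed
AM_SECTORS_PER_SCAN = 220        #: automated sectors per line scan
MM_SAMPLE_WIDTH_UM = 150.0       #: manual sampling-window width
MM_SAMPLE_SPACING_UM = 200.0     #: manual window centre spacing
MM_MAX_ECCENTRICITY_UM = 2000.0  #: outermost manual window centre


@dataclass
class SectorMeasurement:
    """One sector's EZ/ELM ratio at a signed lateral eccentricity (µm)."""

    sector_id: int
    lateral_center_um: float
    mezi: float | None
    excluded: bool
    exclusion_reason: str = "none"  # none | vessel_shadow | no_valid_peak

    def __post_init__(self) -> None:
        assert self.excluded == (self.mezi is None)


@dataclass
class EyeMeasurement:
    """Aggregated mEZi for one eye."""

    eye_id: str
    group: str
    mezi: float | None
    n_sectors_used: int
    n_scans_used: int
    failed: bool

    def to_dict(self) -> dict:
        return {"eye_id": self.eye_id, "group": self.group, "mezi": self.mezi,
                "n_sectors_used": self.n_sectors_used,
                "n_scans_used": self.n_scans_used, "failed": self.failed}


def _sector_ratio(extraction: OuterBandExtraction, col_lo: int,
                  col_hi: int) -> tuple[float | None, str]:
    valid = extraction.valid_mask[col_lo:col_hi]
    if not valid.any():
        shadowed = extraction.shadow_mask[col_lo:col_hi].any()
        return None, "vessel_shadow" if shadowed else "no_valid_peak"
    elm = extraction.elm_peak[col_lo:col_hi][valid].max()
    ez = extraction.ez_peak[col_lo:col_hi][valid].max()
    if elm <= 0:
        return None, "no_valid_peak"
    return float(ez / elm), "none"


def compute_sector_ratio(extraction: OuterBandExtraction, col_lo: int,
                         col_hi: int) -> float | None:
    """EZ/ELM ratio over the half-open column range, or None.

    The within-sector statistic is the highest EZ peak across the range's
    valid columns divided by the highest ELM peak across the same columns.
    Missing (None) when the range contains no valid column.
    """
    value, _ = _sector_ratio(extraction, col_lo, col_hi)
    return value


def _sector_edges(n_cols: int, n_sectors: int) -> np.ndarray:
    return np.round(np.linspace(0, n_cols, n_sectors + 1)).astype(int)


def am_quantify_scan(extraction: OuterBandExtraction, image: BScanImage,
                     n_sectors: int = AM_SECTORS_PER_SCAN,
                     ) -> list[SectorMeasurement]:
    """Automated-protocol quantification: ``n_sectors`` equal lateral bins.

    Partitions the analysis extent into ``n_sectors`` half-open bins (a
    boundary pixel belongs to the lower-index sector) and computes the
    sector ratio in each.  Always returns exactly ``n_sectors`` records —
    sectors with no valid column are flagged excluded, never dropped.

    Raises :class:`ScanFailedError` on a failed extraction.
    """
    if extraction.failed:
        raise ScanFailedError(f"scan {image.scan_id!r}: band extraction failed")
    n_cols = image.width_px
    edges = _sector_edges(n_cols, n_sectors)
    pitch = image.lateral_um_per_px
    half = n_cols / 2.0
    out = []
    for s in range(n_sectors):
        lo, hi = int(edges[s]), int(edges[s + 1])
        value, reason = _sector_ratio(extraction, lo, hi)
        center_um = ((lo + hi) / 2.0 - half) * pitch
        out.append(SectorMeasurement(sector_id=s, lateral_center_um=center_um,
                                     mezi=value, excluded=value is None,
                                     exclusion_reason=reason))
    return out


def mm_quantify_scan(extraction: OuterBandExtraction, image: BScanImage,
                     ) -> list[SectorMeasurement]:
    """Manual-protocol quantification: 21 sampling windows per meridian.

    Windows are 150 µm wide and centred at eccentricities
    0, ±200, …, ±2000 µm from the fovea (assumed at the lateral centre of
    the cropped scan).  The outermost windows are clipped at the edge of
    the 4000-µm analysis extent.  Windows with no valid column (e.g.
    fully inside a vessel shadow) are flagged excluded.
    """
    if extraction.failed:
        raise ScanFailedError(f"scan {image.scan_id!r}: band extraction failed")
    n_cols = image.width_px
    pitch = image.lateral_um_per_px
    half_extent = n_cols * pitch / 2.0
    centers = np.arange(-MM_MAX_ECCENTRICITY_UM,
                        MM_MAX_ECCENTRICITY_UM + MM_SAMPLE_SPACING_UM / 2,
                        MM_SAMPLE_SPACING_UM)
    out = []
    for s, c in enumerate(centers):
        lo_um = c - MM_SAMPLE_WIDTH_UM / 2.0
        hi_um = c + MM_SAMPLE_WIDTH_UM / 2.0
        lo = max(0, int(round((lo_um + half_extent) / pitch)))
        hi = min(n_cols, int(round((hi_um + half_extent) / pitch)))
        value, reason = _sector_ratio(extraction, lo, hi)
        out.append(SectorMeasurement(sector_id=s, lateral_center_um=float(c),
                                     mezi=value, excluded=value is None,
                                     exclusion_reason=reason))
    return out


def quantify_eye(scans: Sequence[Sequence[SectorMeasurement] | None],
                 eye_id: str = "eye", group: str = "unknown",
                 min_scans: int = 1, two_stage: bool = False,
                 ) -> EyeMeasurement:
    """Aggregate sector measurements from an eye's line scans.

    ``scans`` holds one sector list per non-failed scan; failed scans are
    passed as None so they are counted but contribute nothing.  The
    default aggregation pools every valid sector value across all scans
    into one unweighted mean; ``two_stage=True`` averages per scan first
    and then across scans (a configurable alternative — the two agree
    whenever all scans contribute equally many valid sectors).
    """
    usable = [s for s in scans if s is not None]
    values_per_scan = [
        [m.mezi for m in scan if not m.excluded] for scan in usable]
    values_per_scan = [v for v in values_per_scan if v]
    n_scans = len(values_per_scan)
    if n_scans < min_scans:
        return EyeMeasurement(eye_id=eye_id, group=group, mezi=None,
                              n_sectors_used=0, n_scans_used=0, failed=True)
    if two_stage:
        mezi = float(np.mean([np.mean(v) for v in values_per_scan]))
    else:
        pooled = [x for v in values_per_scan for x in v]
        mezi = float(np.mean(pooled))
    n_sectors = sum(len(v) for v in values_per_scan)
    return EyeMeasurement(eye_id=eye_id, group=group, mezi=mezi,
                          n_sectors_used=n_sectors, n_scans_used=n_scans,
                          failed=False)


def sectors_to_frame(sectors: Sequence[SectorMeasurement], eye_id: str = "",
                     scan_id: str = "", meridian: str = "horizontal",
                     ) -> pd.DataFrame:
    """Tabulate sector measurements with the canonical CSV columns."""
    return pd.DataFrame({
        "eye_id": eye_id,
        "scan_id": scan_id,
        "meridian": meridian,
        "sector_id": [m.sector_id for m in sectors],
        "center_um": [m.lateral_center_um for m in sectors],
        "mezi": [m.mezi if m.mezi is not None else np.nan for m in sectors],
        "excluded": [m.excluded for m in sectors],
        "reason": [m.exclusion_reason for m in sectors],
    })
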
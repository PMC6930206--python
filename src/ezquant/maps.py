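"""En-face topographic mEZi maps.

Per-sector measurements from the horizontal and vertical line scans are
scattered over the central macular square and interpolated into a regular
lattice, giving the familiar en-face colour map: high mEZi rendered
yellow, low mEZi blue (the perceptually uniform ``cividis`` ramp is
monotone blue-to-yellow).  Measured cells keep their source values
exactly; everything else is filled by linear interpolation (with nearest-
neighbour fill outside the measured hull), so interpolated values never
leave the measured range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from scipy.interpolate import griddata

from .mezi import SectorMeasurement

__all__ = ["MeziMap", "MapError", "MEZI_CMAP", "build_map", "render_map"]

#: blue (low) -> yellow (high); a linear two-stop RGB blend, so every
#: channel is monotone and a higher value is never bluer than a lower one
MEZI_CMAP = LinearSegmentedColormap.from_list(
    "mezi_blue_yellow", ["#1f3d9c", "#f5d327"])


class MapError(ValueError):
    """No usable measurements to build a map from."""


@dataclass
class MeziMap:
    """A lattice of mEZi values over the central macular square.

    ``grid[i, j]`` covers the cell centred at ``(y_coords_um[i],
    x_coords_um[j])``; row/column coordinates increase with index (row 0
    is the most negative vertical eccentricity).  ``interpolation_mask``
    is True wherever the cell value was interpolated rather than measured.
    """

    grid: np.ndarray
    interpolation_mask: np.ndarray
    color_scale: tuple[float, float]
    x_coords_um: np.ndarray
    y_coords_um: np.ndarray
    extent_um: float

    @property
    def measured_values(self) -> np.ndarray:
        return self.grid[~self.interpolation_mask]


def default_line_positions(n_scans: int, grid_n: int,
                           extent_um: float = 4000.0) -> np.ndarray:
    """Evenly spread scan-line positions snapped to lattice cell centres."""
    centers = (np.arange(grid_n) + 0.5) * extent_um / grid_n - extent_um / 2
    idx = np.round(np.linspace(0, grid_n - 1, n_scans)).astype(int)
    return centers[idx]


def build_map(horizontal_scans: Sequence[Sequence[SectorMeasurement]],
              vertical_scans: Sequence[Sequence[SectorMeasurement]],
              h_positions_um: Sequence[float] | None = None,
              v_positions_um: Sequence[float] | None = None,
              grid_n: int = 220, extent_um: float = 4000.0,
              color_scale: tuple[float, float] | None = None) -> MeziMap:
    """Assemble an en-face lattice from per-scan sector measurements.

    A horizontal scan at vertical position ``y`` contributes its sector
    values along the row nearest ``y`` (columns follow each sector's
    lateral centre); a vertical scan at horizontal position ``x``
    contributes along the column nearest ``x``.  Scan positions default to
    an even spread over the square, snapped to cell centres.  Cells
    holding at least one measurement are marked measured (coincident
    measurements are averaged); excluded sectors contribute nothing and
    their cells are filled by interpolation from neighbours.
    """
    if not any(horizontal_scans) and not any(vertical_scans):
        raise MapError("no scans supplied")
    centers = (np.arange(grid_n) + 0.5) * extent_um / grid_n - extent_um / 2
    if h_positions_um is None:
        h_positions_um = default_line_positions(len(horizontal_scans), grid_n, extent_um)
    if v_positions_um is None:
        v_positions_um = default_line_positions(len(vertical_scans), grid_n, extent_um)

    def nearest_idx(coord: float) -> int:
        return int(np.argmin(np.abs(centers - coord)))

    acc = np.zeros((grid_n, grid_n))
    cnt = np.zeros((grid_n, grid_n), int)
    for scan, y in zip(horizontal_scans, h_positions_um):
        i = nearest_idx(y)
        for m in scan:
            if m.excluded:
                continue
            j = nearest_idx(m.lateral_center_um)
            acc[i, j] += m.mezi
            cnt[i, j] += 1
    for scan, x in zip(vertical_scans, v_positions_um):
        j = nearest_idx(x)
        for m in scan:
            if m.excluded:
                continue
            i = nearest_idx(m.lateral_center_um)
            acc[i, j] += m.mezi
            cnt[i, j] += 1
    measured = cnt > 0
    if not measured.any():
        raise MapError("all sectors excluded; nothing to map")

    values = acc[measured] / cnt[measured]
    ii, jj = np.nonzero(measured)
    points = np.column_stack([centers[ii], centers[jj]])
    Y, X = np.meshgrid(centers, centers, indexing="ij")
    # a single scan line is collinear: no planar triangulation exists, so
    # everything off the line is filled by nearest neighbour
    degenerate = len(np.unique(ii)) < 2 or len(np.unique(jj)) < 2
    if degenerate:
        grid = griddata(points, values, (Y, X), method="nearest")
    else:
        grid = griddata(points, values, (Y, X), method="linear")
        hole = ~np.isfinite(grid)
        if hole.any():
            grid[hole] = griddata(points, values, (Y[hole], X[hole]),
                                  method="nearest")
    grid[measured] = values

    if color_scale is None:
        color_scale = (float(np.percentile(grid, 1)), float(np.percentile(grid, 99)))
    return MeziMap(grid=grid, interpolation_mask=~measured,
                   color_scale=color_scale, x_coords_um=centers.copy(),
                   y_coords_um=centers.copy(), extent_um=extent_um)


def render_map(mezi_map: MeziMap, out_path, cmap=MEZI_CMAP,
               scale: tuple[float, float] | None = None, dpi: int = 100) -> str:
    """Write the map as a PNG with a colorbar.

    The default ramp runs monotonically from blue (low mEZi) to yellow
    (high mEZi).  Output is deterministic for identical input.
    """
    vmin, vmax = scale if scale is not None else mezi_map.color_scale
    if vmax <= vmin:
        vmax = vmin + 1e-9
    half_mm = mezi_map.extent_um / 2000.0
    fig, ax = plt.subplots(figsize=(5, 4), dpi=dpi)
    im = ax.imshow(mezi_map.grid, origin="lower", cmap=cmap, vmin=vmin, vmax=vmax,
                   extent=(-half_mm, half_mm, -half_mm, half_mm))
    ax.set_xlabel("horizontal eccentricity (mm)")
    ax.set_ylabel("vertical eccentricity (mm)")
    ax.set_title("macular EZ intensity (EZ/ELM)")
    fig.colorbar(im, ax=ax, label="mEZi")
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
    return str(out_path)


def map_to_frame(mezi_map: MeziMap):
    """Export the lattice as a tidy table (x_um, y_um, mezi, interpolated)."""
    import pandas as pd
    Y, X = np.meshgrid(mezi_map.y_coords_um, mezi_map.x_coords_um, indexing="ij")
    return pd.DataFrame({
        "x_um": X.ravel(), "y_um": Y.ravel(),
        "mezi": mezi_map.grid.ravel(),
        "interpolated": mezi_map.interpolation_mask.ravel(),
    })
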
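"""Synthetic OCT B-scan phantoms with known ground truth.

Clinical OCT data cannot ship with a software package, so every stage of
the quantifier is exercised against phantoms: B-scans whose outer-retinal
anatomy (inner-retina complex, ELM, EZ, RPE) is rendered as axially
localised Gaussian bands with configurable amplitudes, depths, posterior
tilt/curvature, speckle-like multiplicative noise, additive noise and
vessel-shadow columns.  Because the bands are analytic, the true EZ/ELM
peak ratio is known exactly per sector and globally, and the pipeline's
output can be compared against it.

Phantom intensities live on the *working* (post-log-transform) scale the
quantifier operates on, so ground truth is exact on that scale;
:func:`to_linear` exports a linear-intensity image for end-to-end tests
that include the log-transform stage.

The module also generates paired method-comparison tables
(:func:`generate_paired_measurements`) emulating a calibration design in
which the same eyes are quantified manually and automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BScanImage

__all__ = [
    "BANDS",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomSpecError",
    "generate_bscan",
    "to_linear",
    "generate_paired_measurements",
]

BANDS = ("inner_retina_complex", "ELM", "EZ", "RPE")

_DEFAULT_DEPTHS = {
    "inner_retina_complex": 700.0,
    "ELM": 960.0,
    "EZ": 1012.0,
    "RPE": 1068.0,
}
_DEFAULT_PEAKS = {
    "inner_retina_complex": 200.0,
    "ELM": 60.0,
    "EZ": 240.0,
    "RPE": 255.0,
}
_DEFAULT_SIGMAS = {
    "inner_retina_complex": 60.0,
    "ELM": 10.0,
    "EZ": 10.0,
    "RPE": 12.0,
}


class PhantomSpecError(ValueError):
    """The phantom specification violates an anatomical or numeric invariant."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic B-scan.

    Band depths are axial centres in µm at the lateral midline; all bands
    share the posterior surface model ``depth(x) = base + tilt_um * u +
    curvature_um * (2u)^2`` with ``u = x/L - 1/2``, so ``tilt_um`` is the
    total depth change across the frame and ``curvature_um`` the extra
    depth at the lateral edges relative to the centre.  A shared surface
    keeps the anatomical ordering (inner complex < ELM < EZ < RPE) intact
    at every lateral position.

    Peak values are on the working (post-log) scale and may be scalars or
    per-column arrays of length ``width_px`` (to model lateral intensity
    variation).  ``vessel_shadow_columns`` is a list of
    ``(center_um, width_um, attenuation_fraction)`` triples; everything
    below the inner-retina/ELM midline in those columns is multiplied by
    ``1 - attenuation_fraction``.
    """

    width_px: int = 1024
    height_px: int = 512
    lateral_scan_len_um: float = 9000.0
    axial_um_per_px: float = 4.0
    band_depths_um: Mapping[str, float] = field(default_factory=_DEFAULT_DEPTHS.copy)
    tilt_um: float = 0.0
    curvature_um: float = 0.0
    band_peak_values: Mapping[str, float | np.ndarray] = field(
        default_factory=_DEFAULT_PEAKS.copy)
    band_sigma_um: Mapping[str, float] = field(default_factory=_DEFAULT_SIGMAS.copy)
    noise_sd: float = 0.0
    speckle_factor: float = 0.0
    vessel_shadow_columns: Sequence[tuple[float, float, float]] = field(
        default_factory=list)
    analysis_extent_um: float = 4000.0
    n_truth_sectors: int = 220
    seed: int = 0
    meridian: str = "horizontal"
    scan_id: str = ""

    @property
    def lateral_um_per_px(self) -> float:
        return self.lateral_scan_len_um / self.width_px

    def validate(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise PhantomSpecError("width_px and height_px must both be >= 64")
        missing = [b for b in BANDS if b not in self.band_depths_um
                   or b not in self.band_peak_values or b not in self.band_sigma_um]
        if missing:
            raise PhantomSpecError(f"bands missing parameters: {missing}")
        d = self.band_depths_um
        if not (d["inner_retina_complex"] < d["ELM"] < d["EZ"] < d["RPE"]):
            raise PhantomSpecError(
                "band depth ordering must be inner complex < ELM < EZ < RPE")
        for b in BANDS:
            amp = np.asarray(self.band_peak_values[b], dtype=float)
            if amp.ndim not in (0, 1):
                raise PhantomSpecError(f"peak value for {b} must be scalar or 1-D")
            if amp.ndim == 1 and amp.size != self.width_px:
                raise PhantomSpecError(
                    f"per-column peak profile for {b} must have length width_px")
            if np.any(amp <= 0):
                raise PhantomSpecError(f"peak values must be positive ({b})")
            if self.band_sigma_um[b] <= 0:
                raise PhantomSpecError(f"band sigma must be positive ({b})")
        for center, width, att in self.vessel_shadow_columns:
            if width <= 0:
                raise PhantomSpecError("shadow width must be positive")
            if not 0 < att <= 1:
                raise PhantomSpecError("attenuation_fraction must be in (0, 1]")
        if self.noise_sd < 0 or self.speckle_factor < 0:
            raise PhantomSpecError("noise parameters must be non-negative")
        if self.n_truth_sectors < 1:
            raise PhantomSpecError("n_truth_sectors must be >= 1")

    def depth_um(self, band: str, x_um: np.ndarray) -> np.ndarray:
        """Axial centre of ``band`` as a function of lateral position (µm)."""
        u = np.asarray(x_um, dtype=float) / self.lateral_scan_len_um - 0.5
        return (self.band_depths_um[band]
                + self.tilt_um * u + self.curvature_um * (2.0 * u) ** 2)

    def amplitude(self, band: str) -> np.ndarray:
        """Per-column peak amplitude of ``band`` (length ``width_px``)."""
        amp = np.asarray(self.band_peak_values[band], dtype=float)
        if amp.ndim == 0:
            amp = np.full(self.width_px, float(amp))
        return amp


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a generated phantom.

    ``sector_mezi`` holds the true EZ/ELM peak ratio in each of the
    analysis sectors tiling the central ``analysis_extent_um`` (the same
    max-over-columns-then-ratio rule the quantifier applies);
    ``true_mezi`` is their mean over non-shadowed sectors.
    """

    true_mezi: float
    sector_mezi: np.ndarray
    shadowed_sector_ids: list[int]
    band_depths_px: dict[str, np.ndarray]
    band_peaks: dict[str, np.ndarray]
    analysis_cols: tuple[int, int]
    sector_col_edges: np.ndarray
    shadow_col_ranges: list[tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "true_mezi": self.true_mezi,
            "sector_mezi": self.sector_mezi.tolist(),
            "shadowed_sector_ids": self.shadowed_sector_ids,
            "analysis_cols": list(self.analysis_cols),
            "sector_col_edges": self.sector_col_edges.tolist(),
            "shadow_col_ranges": [list(r) for r in self.shadow_col_ranges],
            "band_depths_px": {k: v.tolist() for k, v in self.band_depths_px.items()},
        }


def _analysis_cols(width_px: int, lateral_um_per_px: float,
                   extent_um: float) -> tuple[int, int]:
    # mirrors bands.crop_central_region with the default (centre) column
    width_cols = int(round(extent_um / lateral_um_per_px))
    center = width_px // 2
    lo = center - width_cols // 2
    return lo, lo + width_cols


def _sector_edges(n_cols: int, n_sectors: int) -> np.ndarray:
    return np.round(np.linspace(0, n_cols, n_sectors + 1)).astype(int)


def generate_bscan(spec: PhantomSpec) -> tuple[BScanImage, PhantomTruth]:
    """Render a phantom B-scan and its ground truth.

    The noise-free image is the per-column sum of the four band Gaussians;
    vessel shadows, speckle (mean-one gamma multiplicative noise with
    coefficient of variation ``speckle_factor``) and additive Gaussian
    noise are applied afterwards, in that order.  Ground truth is computed
    from the noise-free band parameters, so it is exact.  The same spec
    (including ``seed``) always produces a bit-identical image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pitch = spec.lateral_um_per_px
    x_um = (np.arange(spec.width_px) + 0.5) * pitch
    z_um = np.arange(spec.height_px) * spec.axial_um_per_px

    clean = np.zeros((spec.height_px, spec.width_px))
    depths_px: dict[str, np.ndarray] = {}
    peaks: dict[str, np.ndarray] = {}
    for b in BANDS:
        d = spec.depth_um(b, x_um)
        amp = spec.amplitude(b)
        sig = spec.band_sigma_um[b]
        clean += amp[None, :] * np.exp(-((z_um[:, None] - d[None, :]) ** 2)
                                       / (2.0 * sig ** 2))
        depths_px[b] = d / spec.axial_um_per_px
        peaks[b] = amp

    img = clean.copy()
    shadow_top_um = 0.5 * (spec.band_depths_um["inner_retina_complex"]
                           + spec.band_depths_um["ELM"])
    shadow_col_ranges: list[tuple[int, int]] = []
    for center, width, att in spec.vessel_shadow_columns:
        lo = int(np.searchsorted(x_um, center - width / 2.0))
        hi = int(np.searchsorted(x_um, center + width / 2.0))
        lo, hi = max(0, lo), min(spec.width_px, hi)
        if hi <= lo:
            continue
        top = int(round(shadow_top_um / spec.axial_um_per_px))
        img[top:, lo:hi] *= (1.0 - att)
        shadow_col_ranges.append((lo, hi))

    if spec.speckle_factor > 0:
        shape = 1.0 / spec.speckle_factor ** 2
        img *= rng.gamma(shape, 1.0 / shape, size=img.shape)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, None, out=img)

    truth = _make_truth(spec, peaks, depths_px, shadow_col_ranges)
    image = BScanImage(pixels=img, lateral_um_per_px=pitch,
                       axial_um_per_px=spec.axial_um_per_px,
                       scan_id=spec.scan_id or f"phantom-seed{spec.seed}",
                       meridian=spec.meridian, is_log_transformed=True)
    return image, truth


def _make_truth(spec: PhantomSpec, peaks: dict[str, np.ndarray],
                depths_px: dict[str, np.ndarray],
                shadow_col_ranges: list[tuple[int, int]]) -> PhantomTruth:
    lo, hi = _analysis_cols(spec.width_px, spec.lateral_um_per_px,
                            spec.analysis_extent_um)
    edges = _sector_edges(hi - lo, spec.n_truth_sectors) + lo
    elm, ez = peaks["ELM"], peaks["EZ"]
    sector = np.empty(spec.n_truth_sectors)
    shadowed: list[int] = []
    for s in range(spec.n_truth_sectors):
        a, b = edges[s], edges[s + 1]
        sector[s] = ez[a:b].max() / elm[a:b].max()
        if any(a < s_hi and b > s_lo for s_lo, s_hi in shadow_col_ranges):
            shadowed.append(s)
    clean = np.setdiff1d(np.arange(spec.n_truth_sectors), shadowed)
    use = clean if clean.size else np.arange(spec.n_truth_sectors)
    return PhantomTruth(
        true_mezi=float(sector[use].mean()),
        sector_mezi=sector,
        shadowed_sector_ids=shadowed,
        band_depths_px=depths_px,
        band_peaks=peaks,
        analysis_cols=(lo, hi),
        sector_col_edges=edges,
        shadow_col_ranges=shadow_col_ranges,
    )


def to_linear(image: BScanImage, max_value: float = 65535.0) -> BScanImage:
    """Export a working-scale phantom as a linear-intensity image.

    The inverse map ``v = expm1(w / w_max * log1p(max_value))`` produces an
    image whose log transform (as applied by the pipeline) reproduces the
    working-scale intensities up to a global gain — which cancels in every
    EZ/ELM ratio.  Intended for end-to-end tests through the log stage.
    """
    if not image.is_log_transformed:
        raise ValueError("to_linear expects a working-scale (log) image")
    w = image.pixels
    wmax = w.max()
    if wmax <= 0:
        lin = np.zeros_like(w)
    else:
        lin = np.expm1(w / wmax * np.log1p(max_value))
    from dataclasses import replace
    return replace(image, pixels=lin, is_log_transformed=False)


def generate_paired_measurements(
        n_per_group: int,
        group_means: Sequence[float] = (4.08, 3.14, 2.36),
        group_sds: Sequence[float] = (0.42, 0.43, 0.52),
        method_bias: float = 0.0,
        method_slope: float = 1.0,
        noise_sd_each: float = 0.0,
        seed: int = 0,
        group_labels: Sequence[str] = ("normal", "mild_to_moderate", "severe"),
        n_per_group_each: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Simulate paired manual/automated mEZi measurements.

    Each eye has a latent true mEZi drawn from its group's normal
    distribution (defaults are the normal / mild-to-moderate / severe
    glaucoma group means and SDs of the emulated calibration design).  The
    manual method observes ``mm = latent + e1`` and the automated method
    ``am = method_slope * latent + method_bias + e2`` with independent
    Gaussian errors of SD ``noise_sd_each``.  With zero noise and an
    identity method (`slope=1`, `bias=0`) the two columns are identical.

    ``n_per_group_each`` overrides ``n_per_group`` with per-group counts
    (e.g. ``(40, 60, 60)`` for an unbalanced design).

    Returns a DataFrame with columns ``unit_id, group, mm, am``.
    """
    counts = (list(n_per_group_each) if n_per_group_each is not None
              else [int(n_per_group)] * len(group_labels))
    if len(counts) != len(group_labels) or len(group_means) != len(group_labels) \
            or len(group_sds) != len(group_labels):
        raise PhantomSpecError("group_means/sds/labels/counts lengths must match")
    if any(n < 2 for n in counts):
        raise PhantomSpecError("need at least 2 units per group")
    if any(sd <= 0 for sd in group_sds):
        raise PhantomSpecError("group SDs must be positive")
    if noise_sd_each < 0:
        raise PhantomSpecError("noise_sd_each must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    uid = 0
    for label, mean, sd, n in zip(group_labels, group_means, group_sds, counts):
        latent = rng.normal(mean, sd, n)
        e1 = rng.normal(0.0, noise_sd_each, n) if noise_sd_each > 0 else np.zeros(n)
        e2 = rng.normal(0.0, noise_sd_each, n) if noise_sd_each > 0 else np.zeros(n)
        mm = latent + e1
        am = method_slope * latent + method_bias + e2
        for i in range(n):
            rows.append((f"u{uid:04d}", label, mm[i], am[i]))
            uid += 1
    return pd.DataFrame(rows, columns=["unit_id", "group", "mm", "am"])
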
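import numpy as np
import pytest

from ezquant.phantom import PhantomSpec, generate_bscan
from ezquant.pipeline import quantify_bscan


@pytest.fixture
def make_spec():
    """Factory for phantom specs with test-friendly overrides."""

    def _make(**kw):
        return PhantomSpec(**kw)

    return _make


@pytest.fixture
def flat_phantom():
    """Noise-free flat phantom (true mEZi 4.0) and its truth."""
    return generate_bscan(PhantomSpec(seed=1))


@pytest.fixture
def run_pipeline():
    def _run(image, **kw):
        return quantify_bscan(image, **kw)

    return _run


def crop_offset(truth):
    """Column offset from full-image to cropped-analysis coordinates."""
    return truth.analysis_cols[0]


def shadow_cols_cropped(truth, i=0):
    """Shadow column range of truth, in cropped-image coordinates."""
    off = crop_offset(truth)
    lo, hi = truth.shadow_col_ranges[i]
    return lo - off, hi - off


@pytest.fixture
def outer_bands_spec():
    """Custom geometry used by the band-extraction unit tests.

    Inner complex at 100 µm, ELM 60 @ 250 µm, EZ 240 @ 290 µm,
    RPE 255 @ 340 µm; 2.5 µm axial pitch puts every band centre on an
    integer pixel row.
    """

    def _make(**kw):
        base = dict(
            axial_um_per_px=2.5,
            band_depths_um={"inner_retina_complex": 100.0, "ELM": 250.0,
                            "EZ": 290.0, "RPE": 340.0},
            band_sigma_um={"inner_retina_complex": 25.0, "ELM": 8.0,
                           "EZ": 10.0, "RPE": 10.0},
            band_peak_values={"inner_retina_complex": 200.0, "ELM": 60.0,
                              "EZ": 240.0, "RPE": 255.0},
            seed=0,
        )
        base.update(kw)
        return PhantomSpec(**base)

    return _make


def sector_values(sectors):
    return np.array([s.mezi for s in sectors if not s.excluded])
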
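"""Render an en-face mEZi map with a localised defect.

Builds a phantom eye whose inferior half has a 25% lower EZ amplitude —
the pattern of an inferior macular defect — quantifies all 22 line scans
and renders the topographic map (yellow = high mEZi, blue = low).
"""

import numpy as np

from ezquant import PhantomSpec, build_map, generate_bscan, quantify_bscan, render_map

h_scans, v_scans = [], []
for i in range(22):
    meridian = "horizontal" if i < 11 else "vertical"
    spec = PhantomSpec(seed=500 + i, meridian=meridian)
    if meridian == "horizontal" and i < 5:  # inferior lines
        spec.band_peak_values = {**spec.band_peak_values, "EZ": 180.0}
    elif meridian == "vertical":
        # vertical scans see low EZ over their inferior (first) half
        ez = np.full(spec.width_px, 240.0)
        ez[: spec.width_px // 2] = 180.0
        spec.band_peak_values = {**spec.band_peak_values, "EZ": ez}
    image, _ = generate_bscan(spec)
    result = quantify_bscan(image)
    (h_scans if meridian == "horizontal" else v_scans).append(result.sectors)

m = build_map(h_scans, v_scans)
half = m.grid.shape[0] // 2
print(f"inferior half mean mEZi: {m.grid[:half].mean():.3f}")
print(f"superior half mean mEZi: {m.grid[half:].mean():.3f}")
out = render_map(m, "scratch_map.png")
print(f"map written to {out} (blue = reduced mEZi inferiorly)")
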
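"""Rasterize a 62-channel DE vector into scalp topography maps.

Each pixel is a convex combination of the nearest electrode in each of the
four surrounding quadrants (classic bilinear interpolation on a grid);
pixels outside four-quadrant coverage are zero."""

import numpy as np

from mmha import default_layout, rasterize, stack_bands
from mmha.topomap import region_channels, save_debug_png

layout = default_layout()
print(f"montage: {len(layout)} electrodes, all inside the unit disc "
      f"(max radius {np.hypot(*layout.coords.T).max():.2f})")

# paint a synthetic pattern: high gamma DE over occipital channels
de = np.full((62, 5), 1.4)
occ = region_channels(layout, "occipital")
de[occ, 4] += 0.69  # + ln(4)/2, the generator's signature magnitude

stack = stack_bands(de, layout, size=64, band_names=["delta", "theta",
                                                     "alpha", "beta", "gamma"])
print(f"stack shape: {stack.maps.shape} (bands x H x W)")
gamma = stack.maps[4]
covered = gamma != 0
print(f"covered pixels: {covered.sum()} / {gamma.size}")
print(f"gamma map range on scalp: [{gamma[covered].min():.3f}, "
      f"{gamma[covered].max():.3f}] nats")
print("-> the maximum equals the boosted electrode value (convex weights "
      "never overshoot); the border is exactly zero.")

save_debug_png(stack, "topomap_debug.png")
print("wrote topomap_debug.png (bands side by side; bright = high DE)")
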
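"""Clinical views from one reconstructed cube: WLE-like RGB, NBE-like
single band, and vessel contrast versus wavelength.

The contrast curves show the depth effect: a superficial capillary
contrasts best in blue-green, a deep vessel at longer wavelengths.
"""

import numpy as np

from endospec import HSICube, SpectralGrid, nbe_view, synthesize_rgb, vessel_contrast_curve
from endospec.tissue import synth_dr_spectrum

grid = SpectralGrid()
bg = synth_dr_spectrum(0.8, 0.015, grid=grid).intensity
shallow = synth_dr_spectrum(0.65, 0.12, depth_um=20.0, grid=grid).intensity
deep = synth_dr_spectrum(0.65, 0.12, depth_um=350.0, grid=grid).intensity

data = np.tile(bg, (8, 12, 1))
data[2:6, 2:5] = shallow
data[2:6, 7:10] = deep
cube = HSICube(grid, data)

rgb = synthesize_rgb(cube)
print(f"RGB image {rgb.shape}, background pixel -> "
      f"RGB {np.round(rgb[0, 0], 3)} (reddish, as tissue should be)")

nbe = nbe_view(cube, 540.0)
print(f"NBE 540 nm view: vessel pixel {nbe[3, 3]:.2f} vs background "
      f"{nbe[0, 0]:.2f} (vessels dark against mucosa)")

v_shallow = np.zeros((8, 12), bool); v_shallow[2:6, 2:5] = True
v_deep = np.zeros((8, 12), bool); v_deep[2:6, 7:10] = True
background = ~(v_shallow | v_deep)
c_s, peak_s = vessel_contrast_curve(cube, v_shallow, background)
c_d, peak_d = vessel_contrast_curve(cube, v_deep, background)
print(f"superficial vessel contrast peaks at {peak_s:.0f} nm, "
      f"deep vessel at {peak_d:.0f} nm")
print("  -> the peak shifts to longer wavelengths with depth, the")
print("     physical basis of depth-selective narrow-band imaging")
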
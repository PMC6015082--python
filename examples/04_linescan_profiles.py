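"""Normalized line-scan profiles of cleaved-collagen signal.

Generates fields with a degradation bump anterior to the nucleus,
extracts maximal-intensity profiles along the cell axis, normalizes
each onto the common coordinate (cell back = -1, nucleus center = 0,
cell front = +1), and averages them.  The averaged curve peaks between
0 and 1 — degradation concentrated ahead of the nucleus, the
nucleo-anterior collagenolysis pattern.
"""

import numpy as np

from endopolar import average_profiles, extract_linescan, normalize_linescan
from endopolar.synthetic import generate_linescan_scene

curves = []
for seed in range(5):
    images, truth = generate_linescan_scene(seed=seed)
    row_um = truth["axis_row"] * 0.5
    line = np.array([[0.0, row_um], [59.5, row_um]])
    profile = extract_linescan(images, line, pixel_size=0.5, transverse_width_um=4.0)
    refs = (truth["cell_back_um"], truth["nucleus_center_um"], truth["cell_front_um"])
    curves.append(normalize_linescan(profile, refs))

avg = average_profiles(curves, channel="degradation")
peak = avg.loc[avg["mean"].idxmax()]
print(f"averaged {int(avg['n'].iloc[0])} normalized profiles "
      f"({len(avg)} grid points on [-1, 1])")
print(f"degradation peak at normalized coordinate {peak.grid_coord:+.2f} "
      f"(mean {peak['mean']:.0f} +/- {peak.sd:.0f} counts)")
print("coordinate 0 is the nucleus center; a peak in (0, 1) means "
      "degradation anterior to the nucleus")
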
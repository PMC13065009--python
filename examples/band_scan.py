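"""Frequency-resolved slope scan over a small grid of candidate bands.

For every valid (f_min, f_max) pair on a coarse 4-30 Hz grid the EKF is
tuned and run on a synthetic session whose alpha component accelerates,
and the mean frequency-slope per band is printed as a matrix.  Cells
covering the drifting 10 Hz rhythm carry its positive slope; cells away
from it hover near zero.
"""

import numpy as np

from oscitrack import GAConfig, default_bounds
from oscitrack.synth import SyntheticConfig, generate_dataset
from oscitrack.trends import band_grid_slopes

ds = generate_dataset(SyntheticConfig(
    n_channels=4, duration=600.0, seed=0, store_trajectories=False,
    freq_jitter_sd=0.05, amp_jitter_sd=0.1,
    freq_slopes=np.full(4, 1.2), mag_slopes=np.zeros(4)))

ga = GAConfig(bounds=default_bounds(4, 30), population_size=12,
              generations=6, seed=0)
mat = band_grid_slopes(ds.signals, f_grid=[4.0, 8.0, 13.0, 20.0, 30.0],
                       ga_config=ga, opt_window_s=30.0)
print("mean frequency slope (Hz/hour) per [f_min (rows), f_max (cols)]:")
print(mat.to_frame("freq").round(2).to_string())
print("\nNaN marks invalid/unscanned cells (f_min >= f_max or too narrow); "
      "bands containing 10 Hz inherit the imposed +1.2 Hz/hour drift, "
      "while cells away from the rhythm fluctuate around zero with the "
      "band-limited noise.")
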
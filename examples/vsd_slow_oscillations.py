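"""Simulate a wildtype-like and a desynchronized cortical field and compare
slow-oscillation power, frequency, and grid synchrony.

The synchronized movie mimics healthy cortex (all 1-mm tiles in phase); the
jittered movie mimics amyloid-depositing cortex, where tiles oscillate at the
same frequency but out of phase, collapsing the whole-field signal.
"""

import numpy as np

from slowosc import (
    VSDSimParams,
    compute_dff,
    generate_vsd_movie,
    grid_synchrony,
    mean_frequency,
    power_spectrum,
    total_slow_power,
)

for label, jitter in [("synchronized (WT-like)", 0.0), ("desynchronized (APP-like)", np.pi)]:
    movie, truth = generate_vsd_movie(
        VSDSimParams(tile_phase_jitter_rad=jitter, noise_sd=2.0, seed=1)
    )
    spec = power_spectrum(compute_dff(movie))
    sync = grid_synchrony(movie, tile_mm=1.0)
    print(f"{label}:")
    print(f"  sub-1-Hz power   {total_slow_power(spec):8.3f}  (dF/F %^2)")
    print(f"  mean frequency   {mean_frequency(spec):8.3f}  Hz")
    print(f"  synchrony index  {sync.synchrony_index:8.3f}  ({len(sync.tile_traces)} tiles)")

print(
    "\nBoth fields oscillate near 0.6 Hz, but phase dispersion across tiles "
    "collapses the whole-field power and the pairwise tile correlation, "
    "the signature of disrupted slow oscillations."
)
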
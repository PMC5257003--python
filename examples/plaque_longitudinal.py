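"""Simulate the same cortical field at two imaging sessions with different
plaque densities and compute the longitudinal change in count and burden —
the untreated-progression scenario, where deposition nearly doubles in a
month.
"""

from slowosc import (
    PlaqueSimParams,
    PlaqueStack,
    generate_plaque_volume,
    longitudinal_change,
    max_projection,
    plaque_metrics,
    segment_plaques,
)


def session_metrics(density, seed):
    params = PlaqueSimParams(
        volume_shape=(80, 256, 256), density_per_mm3=density, noise_sd=3.0, seed=seed
    )
    volume, _ = generate_plaque_volume(params)
    stack = PlaqueStack(volume=volume, voxel_size_um=params.voxel_size_um)
    seg = segment_plaques(
        max_projection(stack), pixel_area_um2=stack.pixel_area_um2, caa_rule=None
    )
    return plaque_metrics(seg, stack)


# several ~0.1 mm^3 fields per session, as in a longitudinal imaging protocol
n_fields = 8
s1 = [session_metrics(density=48.3, seed=100 + k) for k in range(n_fields)]
s2 = [session_metrics(density=84.6, seed=200 + k) for k in range(n_fields)]

for label, ms in [("session 1 (5 mo)", s1), ("session 2 (6 mo)", s2)]:
    dens = [m.density_per_mm3 for m in ms]
    burd = [m.burden_pct for m in ms]
    print(f"{label}: {sum(dens) / n_fields:5.1f} plaques/mm^3, "
          f"burden {sum(burd) / n_fields:.2f}%  ({n_fields} fields)")

# change of the session means: per-field ratios are unstable at ~5 counts/field
d1 = sum(m.density_per_mm3 for m in s1) / n_fields
d2 = sum(m.density_per_mm3 for m in s2) / n_fields
print(f"change in mean density: {(d2 - d1) / d1 * 100:+.1f}%")

# per-field pairing (same registered field across sessions) via longitudinal_change:
pair = longitudinal_change(s1[0], s2[0])
print(f"example single-field change: {pair.pct_change_count:+.1f}% "
      f"(count {s1[0].count} -> {s2[0].count})")

print(
    "\nDensity is the projected plaque count over the physical stack volume "
    "(~0.1 mm^3 per field); averaged over fields, the near-doubling of "
    "density reproduces untreated amyloid progression between sessions."
)
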
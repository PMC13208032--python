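"""Preprocess CT volumes and pair slices across acquisitions by physical z.

Applies the soft-tissue window (center 40 HU, width 400 HU -> [0, 1]),
standardizes the slice plane, and pairs slices of two acquisitions whose
z-grids are offset by 1 mm — each fixed slice gets its nearest moving
slice; slices beyond the shared physical range drop out.
"""

import numpy as np

from doseup.ctio import (CTVolume, pair_slices, standardize_plane,
                         to_eval_uint8, window_normalize)
from doseup.phantom import PhantomSpec, generate_phantom_subject

spec = PhantomSpec(grid_size=128, n_slices=6, organ_layout_seed=1, noise_sd=8.0)
(vol,), _ = generate_phantom_subject(spec, [0.4], seed=1)

unit = window_normalize(vol)  # HU -> [0,1] through the (40, 400) window
print(f"windowed range: [{unit.voxels.min():.3f}, {unit.voxels.max():.3f}]")

slice64 = standardize_plane(unit.voxels[2], train_size=64, canvas=128)
print(f"standardized slice: {slice64.shape}, 8-bit version dtype "
      f"{to_eval_uint8(slice64).dtype}")

# a second acquisition whose z-grid is shifted by 1 mm
other = CTVolume(unit.voxels.copy(), unit.spacing, origin=(0, 0, 1.0),
                 intensity_domain="unit")
pairs = pair_slices(unit, other, subject_id="demo",
                    fixed_domain="Post40", moving_domain="Post100")
print(f"\n{len(pairs)} slice pairs (fixed z -> moving z):")
for p in pairs:
    print(f"  {p.fixed_z:5.1f} mm -> {p.moving_z:5.1f} mm   |dz| = "
          f"{p.pairing_distance:.1f} mm")
print("Every fixed slice found a partner within half a slice spacing; "
      "the pairing is what makes weakly aligned supervision possible.")
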
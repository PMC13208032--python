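"""Generate a synthetic abdominal phantom subject at three contrast doses.

Builds one subject at dose fractions 0 (pre-contrast), 0.4 (low dose) and
1.0 (full dose), then prints the mean attenuation of a few regions at each
dose. Vessels enhance strongly and linearly with dose; the epaxial muscle
(the CNR reference tissue) does not enhance at all.
"""

import numpy as np

from doseup.phantom import PhantomSpec, generate_phantom_subject

spec = PhantomSpec(grid_size=128, n_slices=4, organ_layout_seed=7, noise_sd=8.0)
vols, truth = generate_phantom_subject(spec, [0.0, 0.4, 1.0], seed=7,
                                       dose_tags=["Pre", "Post40", "Post100"])

print(f"{'region':<16}{'Pre':>9}{'Post40':>9}{'Post100':>9}   (mean HU)")
for region in ("aorta", "cvc", "liver", "kidney_cortex", "epaxial_muscle"):
    mask = truth.region_masks[region]
    means = [v.voxels[mask].mean() for v in vols]
    print(f"{region:<16}" + "".join(f"{m:9.1f}" for m in means))

print(f"\n{len(truth.landmark_coords)} evaluation landmarks inside the body; "
      f"masks for {len(truth.region_masks)} regions.")
print("Vessel HU rises ~linearly with the dose fraction; the reference "
      "muscle stays flat, which is what makes it a usable CNR anchor.")
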
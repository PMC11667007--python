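"""Score agreement between masks with DSC, mean surface distance and
Hausdorff distance.

DSC measures voxel overlap (1 = identical); MSD is the symmetric mean
distance between the two surfaces in mm; HD is the worst-case surface
distance, sensitive to single protrusions.
"""

from segcurate import (PhantomParams, corrupt_random, corrupt_systematic,
                       dsc, generate_case, hausdorff, msd)

case = generate_case(PhantomParams(), seed=21)
lateral = corrupt_systematic(case, 5)
eroded = corrupt_random(case, 10, seed=4)

for name, other in [("lateral dilation m=5", lateral),
                    (f"random {eroded.record.op} m={eroded.record.magnitude}",
                     eroded)]:
    print(f"{name:26s} DSC={dsc(case.mask, other.mask):.3f}  "
          f"MSD={msd(case.mask, other.mask):.2f} mm  "
          f"HD={hausdorff(case.mask, other.mask):.2f} mm")
# HD equals the full corruption magnitude (the furthest displaced surface
# point), while MSD averages over the untouched far side and is much smaller.
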
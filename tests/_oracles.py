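"""Independent brute-force oracles shared by the test modules."""

import numpy as np

from aquaswing._geometry import minimum_image


def brute_force_bonds(positions, box, oo_cutoff=3.5, angle_cutoff=30.0):
    """All-pairs oracle for the geometric hydrogen-bond criterion."""
    n = positions.shape[0]
    cos_cut = np.cos(np.radians(angle_cutoff))
    bonds = set()
    for d in range(n):
        for a in range(n):
            if d == a:
                continue
            doo = minimum_image(positions[a, 0] - positions[d, 0], box)
            r = np.linalg.norm(doo)
            if r > oo_cutoff:
                continue
            for h in (0, 1):
                oh = minimum_image(positions[d, 1 + h] - positions[d, 0], box)
                cosang = (oh / np.linalg.norm(oh)) @ (doo / r)
                if cosang > cos_cut:
                    bonds.add((d, h, a))
    return bonds
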
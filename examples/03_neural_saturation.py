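"""How many harmonic orders does the neuronal field need?

Runs the densest (15 mm) triaxial array at the on-scalp (6.5 mm) and
SQUID-like (24 mm) offsets and prints the smallest irregular-harmonic
order that explains >= 99% of lead-field variance in >= 95% of sources.
On-scalp sensors see higher spatial frequencies, so they need more orders.
"""

import numpy as np

from opmarray import forward, geometry, subspace

scalp = geometry.make_scalp_surface()
cortex = geometry.make_cortical_source_space()
origin = geometry.expansion_origin_for(scalp)

for offset, label in ((6.5, "on-scalp OPM"), (24.0, "SQUID-like")):
    array = geometry.build_array(scalp, 3, spacing_mm=15, offset_mm=offset, seed=0)
    lf = forward.filter_weak_sources(forward.compute_leadfield(array, cortex))
    res = subspace.saturation_order(array, lf, L_max=15, origin=origin)
    dof = res.order_or_count ** 2 + 2 * res.order_or_count
    print(f"{label} ({offset} mm offset): saturation order L = "
          f"{res.order_or_count} ({dof} spatial degrees of freedom)")
    print("  fraction of sources with VE >= 0.99 per order:",
          np.array2string(res.ve_curve, precision=2))
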
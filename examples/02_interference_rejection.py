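"""How much brain signal does interference projection cost?

Builds 60-sensor single-axis and triaxial arrays, projects out external
(regular solid harmonic) interference subspaces of increasing order, and
prints the median and worst-case (2.5% quantile) lead-field loss in dB.
Triaxial arrays tolerate much higher interference orders than radial ones.
"""

import numpy as np

from opmarray import forward, geometry, projection
from opmarray.harmonics import build_basis

scalp = geometry.make_scalp_surface()
cortex = geometry.make_cortical_source_space()
origin = geometry.expansion_origin_for(scalp)

for n_axes, label in ((1, "single-axis"), (3, "triaxial")):
    array = geometry.build_array(scalp, n_axes, n_sensors=60, seed=0)
    lf = forward.filter_weak_sources(forward.compute_leadfield(array, cortex))
    basis = build_basis(array, 8, "external", origin)
    print(f"\n{label}: {array.n_channels} channels")
    for L in (1, 3, 6, 8):
        with np.errstate(invalid="ignore"):
            M = projection.external_projector(basis.truncated(L))
        res = projection.leadfield_attenuation(M, lf)
        print(f"  order L={L} ({M.rank_removed:3d} regressors): "
              f"median loss {res.median_db:6.2f} dB, "
              f"worst 2.5% {res.q2p5_db:6.2f} dB")
# Losses below ~1 dB are negligible; a radial-only array already loses
# several dB at L=3 while the triaxial array stays well under 1 dB.
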
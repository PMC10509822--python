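"""Shared fixtures: a small deterministic geometry bundle for unit tests and
the full-scale study pipeline (computed once per session) for the
acceptance-level checks."""

from __future__ import annotations

import numpy as np
import pytest

from opmarray import experiments, forward, geometry, subspace
from opmarray.harmonics import build_basis


@pytest.fixture(scope="session")
def small_bundle():
    """12-sensor triaxial array, 200-vertex cortex and filtered lead field."""
    return experiments.make_fixtures(seed=3)


@pytest.fixture(scope="session")
def default_head():
    scalp = geometry.make_scalp_surface()
    cortex = geometry.make_cortical_source_space()
    origin = geometry.expansion_origin_for(scalp)
    return scalp, cortex, origin


@pytest.fixture(scope="session")
def dense_pipeline(default_head):
    """Dense (15 mm) triaxial arrays at both scalp offsets, with saturation
    results and the eigenvector requirement — the study's core numbers."""
    scalp, cortex, origin = default_head
    out = {"origin": origin}
    for label, offset in (("opm", 6.5), ("squid", 24.0)):
        arr = geometry.build_array(scalp, 3, spacing_mm=15.0, offset_mm=offset,
                                   seed=0)
        lf = forward.filter_weak_sources(forward.compute_leadfield(arr, cortex),
                                         0.05)
        sat = subspace.saturation_order(arr, lf, L_max=15, origin=origin)
        out[label] = dict(array=arr, leadfield=lf, saturation=sat)
    out["k_required"] = subspace.required_eigenvectors(
        out["opm"]["leadfield"]).order_or_count
    return out


@pytest.fixture(scope="session")
def sixty_sensor_losses(default_head):
    """2.5%-quantile and median loss of the 60-sensor triaxial array for
    external orders 1..12."""
    from opmarray import projection

    scalp, cortex, origin = default_head
    arr = geometry.build_array(scalp, 3, n_sensors=60, seed=0)
    lf = forward.filter_weak_sources(forward.compute_leadfield(arr, cortex), 0.05)
    basis = build_basis(arr, 12, "external", origin)
    rows = {}
    for L in range(1, 13):
        with np.errstate(invalid="ignore"):
            M = projection.external_projector(basis.truncated(L))
        res = projection.leadfield_attenuation(M, lf, order=L)
        rows[L] = res
    return rows


@pytest.fixture(scope="session")
def matched_channel_losses(default_head):
    """Median L=3 losses for triaxial and single-axis arrays at ~90-300 channels."""
    from opmarray import projection

    scalp, cortex, origin = default_head
    out = {}
    for n_axes, counts in ((3, (31, 60, 100)), (1, (90, 180, 300))):
        df = projection.attenuation_sweep(scalp, cortex, n_sensors_list=counts,
                                          n_axes_list=(n_axes,), orders=(3,),
                                          seed=0, origin=origin)
        out[n_axes] = df
    return out
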